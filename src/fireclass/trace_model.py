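"""Domain types and CSV plumbing for evoked spike-train recordings.

A recording is a response to a supra-threshold step-current pulse: an ordered
list of spike times (ms, relative to stimulus onset) plus the stimulus epoch.
From it we derive the quantities the classification criteria consume: the
first-spike latency (delay), the inter-spike intervals (ISIs), the post-firing
silence (PFS, stimulus offset minus last spike), and dimensionless coordinates
in which ISIs are normalized to the shortest ISI of the train and time to the
first-to-last-spike span.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "ISISeries",
    "InsufficientSpikesError",
    "TraceValidationError",
    "derive_isi_series",
    "read_traces",
    "write_results",
    "read_results",
]


class TraceValidationError(ValueError):
    """A trace violates a structural invariant (ordering, signs, coverage)."""


class InsufficientSpikesError(ValueError):
    """Raised when an operation needs more spikes than the trace contains."""

    def __init__(self, n_spikes: int, needed: int = 2):
        self.n_spikes = n_spikes
        self.needed = needed
        super().__init__(
            f"insufficient spikes: have {n_spikes}, need at least {needed}"
        )


@dataclass
class SpikeTrain:
    """One evoked response: spike times within a step-current pulse.

    Times are in ms from stimulus onset; stimulus amplitude in pA; optional
    membrane-voltage samples (time ms, mV) support slow-wave amplitude
    measurement, or a pre-measured scalar amplitude may be given via
    ``swa_given``.
    """

    trace_id: str
    neuron_type: str
    spike_times: Sequence[float]
    stim_duration: float
    stim_amplitude: float = float("nan")
    cell_id: Optional[str] = None
    voltage: Optional[np.ndarray] = None  # shape (n, 2): time ms, mV
    swa_given: Optional[float] = None
    truncated: bool = False
    conditions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.stim_duration <= 0:
            raise TraceValidationError(
                f"{self.trace_id}: stim_duration must be > 0, "
                f"got {self.stim_duration}"
            )
        t = self.spike_times
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise TraceValidationError(
                    f"{self.trace_id}: spike times must be strictly increasing"
                )
            if t[0] < 0 or t[-1] > self.stim_duration + 1e-9:
                raise TraceValidationError(
                    f"{self.trace_id}: spike times must lie in "
                    f"[0, {self.stim_duration}] ms"
                )
        if self.voltage is not None:
            v = np.asarray(self.voltage, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2:
                raise TraceValidationError(
                    f"{self.trace_id}: voltage must be (n, 2) time/mV samples"
                )
            if np.any(~np.isfinite(v)):
                raise TraceValidationError(f"{self.trace_id}: NaN in voltage")
            if np.any(np.diff(v[:, 0]) <= 0):
                raise TraceValidationError(
                    f"{self.trace_id}: voltage time axis not strictly increasing"
                )
            self.voltage = v

    @property
    def n_spikes(self) -> int:
        return int(len(self.spike_times))


@dataclass
class ISISeries:
    """Derived interval representation of a spike train.

    ``norm_isis[k] = isis[k] / isi_min`` (so its minimum is exactly 1) and
    ``norm_times[k]`` places ISI_k at the time of the spike that *ends* it,
    rescaled so the first spike maps to 0 and the last to 1.
    """

    delay: float
    isis: np.ndarray
    pfs: float
    truncated: bool = False

    def __post_init__(self):
        self.isis = np.asarray(self.isis, dtype=float)
        if self.isis.size < 1:
            raise InsufficientSpikesError(1)
        if np.any(self.isis <= 0):
            raise TraceValidationError("every ISI must be > 0")
        if self.delay < 0 or self.pfs < -1e-9:
            raise TraceValidationError("delay and pfs must be non-negative")

    @property
    def n(self) -> int:
        return int(self.isis.size)

    @property
    def isi_min(self) -> float:
        return float(self.isis.min())

    @property
    def isi_max(self) -> float:
        return float(self.isis.max())

    @property
    def norm_isis(self) -> np.ndarray:
        return self.isis / self.isi_min

    @property
    def norm_times(self) -> np.ndarray:
        ends = np.cumsum(self.isis)  # spike k+1 relative to first spike
        span = ends[-1]
        return ends / span

    @property
    def stim_duration(self) -> float:
        return float(self.delay + self.isis.sum() + self.pfs)

    def subseries(self, start: int) -> "ISISeries":
        """The tail ``isis[start:]`` as its own series (renormalized).

        The delay of the tail is measured from stimulus onset to the spike
        that opens the first retained interval; PFS is unchanged.
        """
        if start < 0 or self.n - start < 1:
            raise InsufficientSpikesError(self.n - start + 1)
        new_delay = self.delay + float(self.isis[:start].sum())
        return ISISeries(new_delay, self.isis[start:], self.pfs, self.truncated)


def derive_isi_series(train: SpikeTrain) -> ISISeries:
    """Delay / ISIs / post-firing silence of a train with ≥ 2 spikes."""
    if train.n_spikes < 2:
        raise InsufficientSpikesError(train.n_spikes)
    t = np.asarray(train.spike_times, dtype=float)
    return ISISeries(
        delay=float(t[0]),
        isis=np.diff(t),
        pfs=float(train.stim_duration - t[-1]),
        truncated=train.truncated,
    )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_SPIKE_HEADER = [
    "trace_id", "neuron_type", "stim_duration_ms", "stim_amp_pA",
    "spike_times", "swa_mV",
]
_ISI_HEADER_FIXED = [
    "trace_id", "neuron_type", "stim_duration_ms", "stim_amp_pA",
    "delay_ms", "pfs_ms", "swa_mV",
]

DIALECTS = ("spike_times", "isi_export")


def _parse_float(text: str, row: int, fieldname: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise TraceValidationError(
            f"row {row}: field '{fieldname}' is not a number: {text!r}"
        ) from None


def read_traces(path, dialect: str = "spike_times") -> list[SpikeTrain]:
    """Read spike trains from a CSV file in one of the supported dialects.

    ``spike_times`` rows carry the spike times directly ("; "-separated, ms);
    ``isi_export`` rows carry delay, PFS, optional slow-wave amplitude and a
    ragged tail of ISIs, from which spike times are reconstructed so that
    :func:`derive_isi_series` round-trips.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    trains: list[SpikeTrain] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not (r[0].startswith("#"))]
    if not rows:
        logger.warning("empty trace file: %s", path)
        return trains
    header, body = rows[0], rows[1:]
    for idx, row in enumerate(body, start=2):  # 1-based incl. header
        if dialect == "spike_times":
            if len(row) < 5:
                raise TraceValidationError(
                    f"row {idx}: expected ≥5 fields {_SPIKE_HEADER}, got {len(row)}"
                )
            tid, ntype, dur, amp, times = row[:5]
            spikes = [
                _parse_float(x, idx, "spike_times")
                for x in times.split(";") if x.strip()
            ]
            swa_v = None
            if len(row) > 5 and row[5].strip() not in ("", "NA", "nan"):
                swa_v = _parse_float(row[5], idx, "swa_mV")
            trains.append(SpikeTrain(
                trace_id=tid, neuron_type=ntype, spike_times=spikes,
                stim_duration=_parse_float(dur, idx, "stim_duration_ms"),
                stim_amplitude=_parse_float(amp, idx, "stim_amp_pA"),
                swa_given=swa_v,
            ))
        else:  # isi_export
            if len(row) < 7:
                raise TraceValidationError(
                    f"row {idx}: expected ≥7 fields {_ISI_HEADER_FIXED}+isis, "
                    f"got {len(row)}"
                )
            tid, ntype, dur, amp, delay, pfs, swa = row[:7]
            isis = [
                _parse_float(x, idx, f"isi_{k + 1}")
                for k, x in enumerate(row[7:]) if x.strip()
            ]
            for k, isi in enumerate(isis):
                if isi <= 0:
                    raise TraceValidationError(
                        f"row {idx}: isi_{k + 1} must be > 0, got {isi}"
                    )
            delay_v = _parse_float(delay, idx, "delay_ms")
            spikes = delay_v + np.concatenate([[0.0], np.cumsum(isis)])
            swa_v = None if swa.strip() in ("", "NA", "nan") else \
                _parse_float(swa, idx, "swa_mV")
            trains.append(SpikeTrain(
                trace_id=tid, neuron_type=ntype, spike_times=spikes,
                stim_duration=_parse_float(dur, idx, "stim_duration_ms"),
                stim_amplitude=_parse_float(amp, idx, "stim_amp_pA"),
                swa_given=swa_v,
            ))
    return trains


def write_traces(trains: Sequence[SpikeTrain], path, dialect: str = "spike_times",
                 header_comment: Optional[str] = None) -> None:
    """Write trains to CSV in either dialect (inverse of :func:`read_traces`)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        if dialect == "spike_times":
            w.writerow(_SPIKE_HEADER)
            for tr in trains:
                w.writerow([
                    tr.trace_id, tr.neuron_type,
                    repr(tr.stim_duration), repr(tr.stim_amplitude),
                    ";".join(repr(float(t)) for t in tr.spike_times),
                    "" if tr.swa_given is None else repr(tr.swa_given),
                ])
        else:
            w.writerow(_ISI_HEADER_FIXED + ["isi_1..."])
            for tr in trains:
                s = derive_isi_series(tr)
                w.writerow([
                    tr.trace_id, tr.neuron_type,
                    repr(tr.stim_duration), repr(tr.stim_amplitude),
                    repr(s.delay), repr(s.pfs),
                    "" if tr.swa_given is None else repr(tr.swa_given),
                    *[repr(float(x)) for x in s.isis],
                ])


RESULT_FIELDS = [
    "trace_id", "neuron_type", "pattern", "completed",
    "model", "a1", "a2", "breakpoint", "p_21", "p_32", "p_43",
    "break_index", "swa_mV", "note",
]


def write_results(records: Sequence[dict], path,
                  header_comment: Optional[str] = None) -> None:
    """One CSV row per classified trace with per-stage diagnostics."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.DictWriter(fh, fieldnames=RESULT_FIELDS, extrasaction="ignore")
        w.writeheader()
        for rec in records:
            out = dict(rec)
            for key in RESULT_FIELDS:
                val = out.get(key)
                if isinstance(val, float) and math.isnan(val):
                    out[key] = ""
                elif val is None:
                    out[key] = ""
            w.writerow(out)


def read_results(path) -> list[dict]:
    """Re-read a results CSV written by :func:`write_results`."""
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    records = list(csv.DictReader(lines))
    for rec in records:
        for key in ("a1", "a2", "breakpoint", "p_21", "p_32", "p_43", "swa_mV"):
            rec[key] = float(rec[key]) if rec.get(key) else None
        rec["completed"] = rec.get("completed") in ("True", "true", "1")
        rec["break_index"] = int(rec["break_index"]) if rec.get("break_index") else None
    return records
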