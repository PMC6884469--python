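"""Threshold detectors for firing-pattern elements.

Each detector encodes one row of the quantitative criteria table: delay (D.),
terminal silence (SLN), transient stutter/burst onset (TSTUT./TSWB.), and
persistent interrupted firing (PSTUT/PSWB), plus measurement of slow-wave
amplitude (SWA) from a voltage trace.  All inequalities are strict: an input
sitting exactly on a threshold does not qualify.

Detectors operate on raw millisecond ISIs, so every decision is invariant
under a common rescaling of all times except the minimum-frequency clause
(``f_min``), which is an absolute rate threshold.

Tri-state results: detectors whose preconditions cannot be evaluated on a
given series return ``None`` ("not evaluable"), distinct from ``False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional

import numpy as np

from .trace_model import ISISeries, TraceValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CriteriaConfig",
    "BreakPoint",
    "Steady",
    "detect_delay",
    "detect_sln",
    "detect_transient_break",
    "classify_break",
    "detect_persistent_interrupted",
    "measure_swa",
]


@dataclass
class CriteriaConfig:
    """Tunable thresholds of the classification criteria.

    Defaults are the published values: DF = SF = 2 (delay / silence factors),
    F_pre = 2.5, F_post = 1.5, f_min = 25 Hz, F_PSTUT = F_PSWB = 5,
    SWA_min = 5 mV, S_RASP = 0.2, minimum adaptation slope 0.003, base
    significance 0.05 (Bonferroni sequence 0.05, 0.025, 0.05/3 down the
    regression ladder), and dV/dt thresholds 0.15 / 20 V s⁻¹ for slow-wave
    initiation / spike threshold.
    """

    DF: float = 2.0
    SF: float = 2.0
    S_RASP: float = 0.2
    a1_min: float = 0.003
    F_pre: float = 2.5
    F_post: float = 1.5
    f_min: float = 25.0          # Hz
    F_PSTUT: float = 5.0
    F_PSWB: float = 5.0
    SWA_min: float = 5.0         # mV
    alpha: float = 0.05
    p32_threshold: float = 0.025
    p43_threshold: float = 0.05 / 3.0
    dvdt_slow: float = 0.15      # V/s, slow-wave initiation threshold
    dvdt_spike: float = 20.0     # V/s, action-potential threshold
    tstut_break_indices: tuple = (2, 3, 4)
    enforce_fmin_for_pstut: bool = False
    rasp_k: tuple = (2, 3)

    def __post_init__(self):
        for name in ("DF", "SF", "S_RASP", "F_pre", "F_post", "f_min",
                     "F_PSTUT", "F_PSWB", "SWA_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.tstut_break_indices = tuple(sorted(self.tstut_break_indices))
        if any(i < 2 for i in self.tstut_break_indices):
            raise ValueError("tstut_break_indices must be ≥ 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tstut_break_indices"] = list(self.tstut_break_indices)
        d["rasp_k"] = list(self.rasp_k)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaConfig":
        d = dict(d)
        if "tstut_break_indices" in d:
            d["tstut_break_indices"] = tuple(d["tstut_break_indices"])
        if "rasp_k" in d:
            d["rasp_k"] = tuple(d["rasp_k"])
        return cls(**d)


@dataclass
class BreakPoint:
    """A qualifying transient-cluster boundary: the long ISI at 1-based
    index ``i`` separating a short high-frequency cluster from the rest."""

    index: int                 # 1-based ISI index of the long (break) ISI
    break_isi: float
    pre_mean: float            # mean of ISIs before the break
    post_mean: float           # mean of ISIs from the break onward
    ratio_pre: float           # ISI_i / ISI_{i-1}
    ratio_post: float          # ISI_i / ISI_{i+1}


class Steady(str, Enum):
    PSTUT = "PSTUT"
    PSWB = "PSWB"


def detect_delay(s: ISISeries, cfg: CriteriaConfig) -> Optional[bool]:
    """Delay criterion: first-spike latency > DF·(ISI₁+ISI₂)/2, strict."""
    if s.n < 2:
        return None
    return bool(s.delay > cfg.DF * (s.isis[0] + s.isis[1]) / 2.0)


def detect_sln(s: ISISeries, cfg: CriteriaConfig) -> Optional[bool]:
    """Terminal-silence criterion.

    PFS must strictly exceed both SF·(ISI_n + ISI_{n−1})/2 and SF·ISI_max.
    Not evaluable on truncated pulses (the silence is censored) or with
    fewer than two ISIs.
    """
    if s.n < 2 or s.truncated:
        return None
    cond1 = s.pfs > cfg.SF * (s.isis[-1] + s.isis[-2]) / 2.0
    cond2 = s.pfs > cfg.SF * s.isi_max
    return bool(cond1 and cond2)


def detect_transient_break(s: ISISeries,
                           cfg: CriteriaConfig) -> Optional[BreakPoint]:
    """Find the earliest qualifying transient cluster boundary.

    A 1-based ISI index ``i`` (candidates 2, 3, 4) qualifies when the break
    ISI dominates both neighbours (ISI_i > F_pre·ISI_{i−1} and
    ISI_i > F_post·ISI_{i+1}), the mean of ISIs from the break onward exceeds
    F_pre times the mean of the pre-break ISIs, and every pre-break ISI is
    shorter than 1/f_min (cluster rate above f_min).  Returns ``None`` when
    no candidate qualifies.
    """
    isis = s.isis
    n = s.n
    for i in cfg.tstut_break_indices:
        if i + 1 > n or i < 2:
            continue  # need ISI_{i+1}; i is 1-based
        isi_i = isis[i - 1]
        if not (isi_i > cfg.F_pre * isis[i - 2]):
            continue
        if not (isi_i > cfg.F_post * isis[i]):
            continue
        pre = isis[: i - 1]
        post = isis[i - 1:]
        if not (post.mean() > cfg.F_pre * pre.mean()):
            continue
        # pre-break cluster must fire above f_min (ISIs in ms)
        if not np.all(1000.0 / pre > cfg.f_min):
            continue
        return BreakPoint(
            index=i,
            break_isi=float(isi_i),
            pre_mean=float(pre.mean()),
            post_mean=float(post.mean()),
            ratio_pre=float(isi_i / isis[i - 2]),
            ratio_post=float(isi_i / isis[i]),
        )
    return None


def classify_break(b: BreakPoint, swa: Optional[float],
                   cfg: CriteriaConfig) -> str:
    """Resolve a transient break into bursting vs stuttering.

    The cluster is a slow-wave burst (TSWB.) only when a slow-wave amplitude
    is known and exceeds SWA_min; otherwise (including unknown SWA) it is a
    transient stutter (TSTUT.).
    """
    if b is None:
        raise ValueError("no break point to classify")
    if swa is None:
        logger.debug("SWA unknown at break i=%d: defaulting to TSTUT.", b.index)
        return "TSTUT."
    return "TSWB." if swa > cfg.SWA_min else "TSTUT."


def detect_persistent_interrupted(s: ISISeries, swa: Optional[float],
                                  cfg: CriteriaConfig) -> Optional[Steady]:
    """Persistent interrupted-firing criterion (PSTUT / PSWB).

    Uses the maximum ISI and its two neighbours:
    ISI_max/ISI_prev + ISI_max/ISI_next must strictly exceed F_PSTUT (F_PSWB
    with a known slow wave).  A maximum sitting at either end of the train
    has an undefined neighbour and does not qualify.  Optionally the
    inter-gap clusters must fire above f_min.
    """
    if s.n < 3:
        return None
    i = int(np.argmax(s.isis))
    if i == 0 or i == s.n - 1:
        return None
    isi_max = s.isis[i]
    ratio = isi_max / s.isis[i - 1] + isi_max / s.isis[i + 1]
    is_burst = swa is not None and swa > cfg.SWA_min
    threshold = cfg.F_PSWB if is_burst else cfg.F_PSTUT
    if not (ratio > threshold):
        return None
    if cfg.enforce_fmin_for_pstut:
        others = np.delete(s.isis, i)
        if not np.all(1000.0 / others > cfg.f_min):
            return None
    return Steady.PSWB if is_burst else Steady.PSTUT


def measure_swa(voltage: np.ndarray, cfg: CriteriaConfig) -> Optional[float]:
    """Slow-wave amplitude from a (time ms, mV) segment around a burst.

    SWA is the voltage difference between the action-potential threshold on
    top of the wave (first sample where dV/dt ≥ 20 V/s) and the initiation
    of the slow wave (first preceding sample where dV/dt ≥ 0.15 V/s).
    With mV and ms axes, dV/dt in mV/ms is numerically V/s.  Returns
    ``None`` when either crossing is absent.
    """
    v = np.asarray(voltage, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise TraceValidationError("voltage must be (n, 2) time/mV samples")
    if np.any(~np.isfinite(v)):
        raise TraceValidationError("NaN/inf in voltage samples")
    t, y = v[:, 0], v[:, 1]
    if np.any(np.diff(t) <= 0):
        raise TraceValidationError("voltage time axis not strictly increasing")
    dvdt = np.diff(y) / np.diff(t)  # mV/ms == V/s
    spike_idx = np.flatnonzero(dvdt >= cfg.dvdt_spike)
    if spike_idx.size == 0:
        return None
    k_spike = int(spike_idx[0])
    slow_idx = np.flatnonzero(dvdt[: k_spike + 1] >= cfg.dvdt_slow)
    if slow_idx.size == 0:
        return None
    k_slow = int(slow_idx[0])
    swa = float(y[k_spike] - y[k_slow])
    if k_slow == k_spike:
        import warnings
        warnings.warn("degenerate slow wave: no slow phase before upstroke")
    return swa
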