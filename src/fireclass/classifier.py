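"""Orchestration of the per-trace firing-pattern classification.

A firing pattern is an ordered sequence of elements in dot notation:
transients keep a trailing dot (D., ASP., RASP., ACSP., TSTUT., TSWB.),
steady states do not (NASP, SLN, PSTUT, PSWB).  A pattern is *completed*
when it ends in a steady state; recordings whose activity never settles are
reported as uncompleted (e.g. "ASP.", "RASP.ASP.").

Pipeline per trace (deterministic for fixed input and configuration):

1. derive the ISI series (delay, ISIs, post-firing silence);
2. transient-cluster boundary search; if one exists but the remainder after
   it still contains a qualifying persistent gap, the whole response is
   persistent interrupted firing (PSTUT/PSWB) — regression across stutter
   gaps is meaningless;
3. otherwise a found boundary contributes a TSTUT./TSWB. prefix and the
   remainder (excluding the break ISI) is classified on its own;
4. rapid-adaptation (RASP.) prefix check on the (remaining) ISIs;
5. nested-regression label on the rest (NASP / ASP. family / ACSP.);
6. terminal steady state: SLN if the post-firing silence qualifies, else
   NASP when the fit supports it, else the pattern stays uncompleted;
7. a qualifying first-spike latency prepends D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trace_model import (SpikeTrain, ISISeries, derive_isi_series,
                          InsufficientSpikesError)
from .pattern_criteria import (CriteriaConfig, Steady, classify_break,
                               detect_delay, detect_persistent_interrupted,
                               detect_sln, detect_transient_break, measure_swa)
from .adaptation_regression import (InsufficientDataError, detect_rasp_prefix,
                                    fit_ladder, label_from_fit)

logger = logging.getLogger(__name__)

__all__ = ["FiringPattern", "classify_trace", "format_pattern",
           "parse_pattern", "enumerate_pattern_space", "PatternParseError",
           "TRANSIENTS", "STEADY_STATES", "ELEMENTS", "UNCLASSIFIED"]

TRANSIENTS = ("D.", "ASP.", "RASP.", "ACSP.", "TSTUT.", "TSWB.")
STEADY_STATES = ("NASP", "SLN", "PSTUT", "PSWB")
#: the nine canonical elements used for phenotype profiles (ACSP. excluded:
#: accelerating spiking is defined but not part of the canonical element set)
ELEMENTS = ("ASP.", "D.", "RASP.", "NASP", "PSTUT", "PSWB", "SLN",
            "TSTUT.", "TSWB.")

UNCLASSIFIED = "UNCLASSIFIED(insufficient_spikes)"


class PatternParseError(ValueError):
    pass


@dataclass
class FiringPattern:
    """Ordered element sequence with completeness flag and diagnostics."""

    elements: list
    completed: bool
    diagnostics: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return format_pattern(self)

    @property
    def element_set(self) -> frozenset:
        return frozenset(self.elements)


def format_pattern(p: FiringPattern) -> str:
    """Dot-notation string; transients carry their own trailing dot."""
    return "".join(p.elements) if p.elements else UNCLASSIFIED


def parse_pattern(text: str) -> FiringPattern:
    """Inverse of :func:`format_pattern` on the valid-pattern set."""
    s = text.strip()
    if not s:
        raise PatternParseError("empty pattern string")
    elements: list[str] = []
    steady = None
    for st in STEADY_STATES:
        if s.endswith(st):
            steady = st
            s = s[: -len(st)]
            break
    while s:
        for tr in TRANSIENTS:
            if s.startswith(tr):
                elements.append(tr)
                s = s[len(tr):]
                break
        else:
            raise PatternParseError(f"unknown token at {s!r} in {text!r}")
    if steady is not None:
        elements.append(steady)
    pat = FiringPattern(elements=elements, completed=steady is not None)
    _validate_elements(pat)
    return pat


def _validate_elements(p: FiringPattern) -> None:
    steadies = [e for e in p.elements if e in STEADY_STATES]
    if len(steadies) > 1 or (steadies and p.elements[-1] != steadies[0]):
        raise PatternParseError(
            f"steady state must be unique and final: {p.elements}")
    if "D." in p.elements[1:]:
        raise PatternParseError("D. only allowed in first position")


def _regression_label(isis: np.ndarray, cfg: CriteriaConfig,
                      diagnostics: dict) -> Optional[str]:
    """Ladder label on a (sub)train's ISIs in segment-local coordinates."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 3:
        return None
    y = isis / isis.min()
    ends = np.cumsum(isis)
    x = ends / ends[-1]
    fit = fit_ladder(y, x, cfg)
    diagnostics.update(
        model=fit.model, a1=fit.a1, a2=fit.a2, breakpoint=fit.breakpoint,
        p_21=fit.p_21, p_32=fit.p_32, p_43=fit.p_43,
    )
    return label_from_fit(fit, cfg)


def classify_trace(train: SpikeTrain,
                   cfg: Optional[CriteriaConfig] = None) -> FiringPattern:
    """Classify one evoked response into its firing pattern."""
    if cfg is None:
        cfg = CriteriaConfig()
    diag: dict = {"trace_id": train.trace_id}

    try:
        s = derive_isi_series(train)
    except InsufficientSpikesError as err:
        logger.info("%s: %s", train.trace_id, err)
        return FiringPattern(elements=[], completed=False,
                             diagnostics={**diag, "note": str(err)})

    swa = train.swa_given
    if swa is None and train.voltage is not None:
        swa = measure_swa(train.voltage, cfg)
    diag["swa_mV"] = swa

    elements: list[str] = []
    completed = False
    delayed = detect_delay(s, cfg)

    tb = detect_transient_break(s, cfg)
    if tb is not None:
        diag["break_index"] = tb.index
        remainder = s.subseries(tb.index)  # excludes the break ISI itself
        pers_rem = (detect_persistent_interrupted(remainder, swa, cfg)
                    if remainder.n >= 3 else None)
        if pers_rem is not None:
            # further qualifying gaps beyond the first: persistent firing
            elements.append(pers_rem.value)
            completed = True
        else:
            prefix = classify_break(tb, swa, cfg)
            elements.append(prefix)
            elements.extend(_classify_spiking(remainder, s, cfg, diag))
            completed = elements[-1] in STEADY_STATES
    else:
        pers = detect_persistent_interrupted(s, swa, cfg)
        if pers is not None:
            elements.append(pers.value)
            completed = True
        else:
            elements.extend(_classify_spiking(s, s, cfg, diag))
            completed = bool(elements) and elements[-1] in STEADY_STATES

    if delayed:
        elements.insert(0, "D.")

    pat = FiringPattern(elements=elements, completed=completed,
                        diagnostics=diag)
    logger.debug("%s -> %s", train.trace_id, format_pattern(pat))
    return pat


def _classify_spiking(seg: ISISeries, full: ISISeries, cfg: CriteriaConfig,
                      diag: dict) -> list[str]:
    """Spiking-branch classification of a segment: RASP prefix, regression
    label, then the terminal steady state (SLN judged on the full train)."""
    elements: list[str] = []
    isis = seg.isis

    rasp, k = detect_rasp_prefix(isis, cfg)
    if rasp:
        elements.append("RASP.")
        diag["rasp_k"] = k
        isis = isis[k:]

    label = _regression_label(isis, cfg, diag)
    sln = detect_sln(full, cfg)

    if label is None:
        # too few ISIs (< 3) for the ladder: adaptation cannot be assessed
        if sln:
            elements.append("SLN")
        elif sln is False and not rasp:
            elements.append("NASP")
        return elements

    if label == "NASP":
        elements.append("SLN" if sln else "NASP")
    elif label == "ASP.NASP":
        elements.append("ASP.")
        elements.append("SLN" if sln else "NASP")
    elif label == "ASP.ASP.":
        elements.extend(["ASP.", "ASP."])
        if sln:
            elements.append("SLN")
    else:  # "ASP." or "ACSP."
        elements.append(label)
        if sln:
            elements.append("SLN")
    return elements


# ---------------------------------------------------------------------------
# Pattern-space grammar
# ---------------------------------------------------------------------------

#: transient chains that may precede a spiking steady state (NASP/SLN):
#: each main transient alone, ASP. preceded by a rapid/stutter/burst
#: transient, and double adaptation.
_CHAINS = (
    ("ASP.",), ("RASP.",), ("TSTUT.",), ("TSWB.",),
    ("RASP.", "ASP."), ("TSTUT.", "ASP."), ("TSWB.", "ASP."),
    ("ASP.", "ASP."),
)


def enumerate_pattern_space() -> set[str]:
    """All completed firing patterns under the composition grammar.

    The grammar: a transient chain (one of eight — the four main transients,
    ASP. preceded by RASP./TSTUT./TSWB., or ASP.ASP.) ends in NASP or SLN
    and may take a D. prefix (8 × 2 × 2 = 32); a bare spiking steady state
    with optional delay (NASP, SLN, D.NASP, D.SLN); and the persistent
    interrupted steady states standing alone (PSTUT, PSWB) — 38 in total.
    """
    patterns: set[str] = set()
    for steady in ("NASP", "SLN"):
        patterns.add(steady)
        patterns.add("D." + steady)
        for chain in _CHAINS:
            body = "".join(chain) + steady
            patterns.add(body)
            patterns.add("D." + body)
    patterns.update(("PSTUT", "PSWB"))
    return patterns
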