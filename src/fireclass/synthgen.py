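"""Synthetic spike-train and matrix generators.

Emulates the gallery of firing-pattern elements as idealized ISI sequences:
adaptation follows an exponential approach ISI_k = isi_inf − (isi_inf −
isi1)·exp(−k/τ), stutter/burst responses interleave short-ISI clusters with
long gaps, delayed responses start after a latency that satisfies the delay
criterion, and terminal silence leaves a post-firing gap that satisfies the
silence criterion.  Optional multiplicative Gaussian noise (parameterized by
a coefficient of variation) perturbs every ISI; multiplicative noise keeps
the scale-covariant criteria meaningful.  All randomness flows through a
seeded :class:`numpy.random.Generator`, so output is bit-reproducible.

Also generates synthetic neuron-type × element / property binary matrices
with planted associations for the screening statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trace_model import SpikeTrain
from .classifier import ELEMENTS

__all__ = ["GeneratorSpec", "generate", "generate_benchmark",
           "generate_property_matrices", "BENCHMARK_PATTERNS",
           "InfeasibleSpecError"]

#: composite patterns covered by the benchmark; every canonical element
#: appears in at least one completed pattern.
BENCHMARK_PATTERNS = (
    "D.NASP", "ASP.NASP", "ASP.SLN", "RASP.NASP", "RASP.ASP.",
    "TSTUT.NASP", "TSWB.NASP", "D.TSWB.NASP", "PSTUT", "PSWB",
)


class InfeasibleSpecError(ValueError):
    """The requested pattern cannot fit inside the stimulus epoch."""


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic train.

    Durations in ms, slow-wave amplitude in mV; ``tau_adapt`` is in ISI-index
    units; ``noise_cv`` is the coefficient of variation of the multiplicative
    ISI noise.
    """

    pattern: str = "NASP"
    stim_duration: float = 1000.0
    delay: Optional[float] = None      # None -> derived from the pattern
    isi1: float = 20.0
    isi_inf: float = 40.0
    tau_adapt: float = 2.0     # adaptation-onset exponent: larger = slower start
    n_isis: int = 14
    cluster_isi: float = 8.0
    cluster_size: int = 4              # spikes per stutter/burst cluster
    gap_isi: float = 100.0
    n_clusters: int = 4
    swa: Optional[float] = None        # mV; required for *SWB patterns
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.stim_duration <= 0 or self.isi1 <= 0:
            raise InfeasibleSpecError("durations must be positive")
        if self.noise_cv < 0:
            raise InfeasibleSpecError("noise_cv must be ≥ 0")
        if "SWB" in self.pattern and self.swa is None:
            raise InfeasibleSpecError(
                f"pattern {self.pattern!r} needs a slow-wave amplitude")


def _adapting_isis(isi1, isi_inf, n, exponent=2.0):
    """Adaptation with a slow onset: ISIs rise from isi1 to isi_inf along a
    quadratic ramp.  The gentle start keeps the transient clearly in the
    ordinary-adaptation regime (the first two or three ISIs barely move, so
    the rapid-adaptation test cannot fire), while the total rise carries the
    statistical weight of the adaptation."""
    k = np.arange(n, dtype=float)
    return isi1 + (isi_inf - isi1) * (k / (n - 1)) ** exponent


def _linear_ramp_isis(isi1, isi_end, n, jitter=0.004):
    """ISIs whose normalized values are linear in normalized time.

    Solved by fixed-point iteration (the abscissae depend on the ISIs
    themselves); a small deterministic alternating jitter keeps the plain
    line the best-supported model rather than leaving the piecewise models
    to fight over floating-point dust.
    """
    y = np.linspace(isi1, isi_end, n)
    for _ in range(80):
        x = np.cumsum(y)
        x = x / x[-1]
        y = isi1 + (isi_end - isi1) * (x - x[0]) / (1.0 - x[0])
    return y * (1.0 + jitter * (-1.0) ** np.arange(n))


def _build_isis(spec: GeneratorSpec) -> tuple[np.ndarray, float, str]:
    """Noise-free ISI sequence, target PFS mode ('sln'|'short'), per pattern."""
    p = spec.pattern
    steady = "SLN" if p.endswith("SLN") else (
        "PSTUT" if p.endswith("PSTUT") else (
            "PSWB" if p.endswith("PSWB") else "NASP"))

    if steady in ("PSTUT", "PSWB"):
        cluster = np.full(spec.cluster_size - 1, spec.cluster_isi)
        parts = []
        for j in range(spec.n_clusters):
            if j:
                parts.append([spec.gap_isi])
            parts.append(cluster)
        isis = np.concatenate(parts)
        return isis, "short", steady

    parts = []
    body = p
    if body.startswith("D."):
        body = body[2:]
    if body.startswith(("TSTUT.", "TSWB.")):
        body = body.split(".", 1)[1]
        # short high-rate cluster then one dominant break ISI
        parts.append(np.full(3, spec.cluster_isi))
        parts.append([spec.gap_isi])
    if body.startswith("RASP."):
        body = body[5:]
        # sharp rise over the first ISIs, slope well above S_RASP
        parts.append([spec.isi1, 3 * spec.isi1, 6 * spec.isi1])
        rest_isi1 = 6 * spec.isi1
    else:
        rest_isi1 = spec.isi1
    if body == "ASP.":
        # uncompleted adaptation: steady rise, no plateau, no silence
        parts.append(_linear_ramp_isis(rest_isi1, 2.0 * rest_isi1,
                                       spec.n_isis))
    elif body.startswith("ASP."):
        n_ad = max(2 * spec.n_isis // 3, 6)
        isi_inf = max(spec.isi_inf, 2.0 * rest_isi1)
        ad = _adapting_isis(rest_isi1, isi_inf, n_ad, spec.tau_adapt)
        parts.append(ad)
        if body == "ASP.NASP":
            parts.append(np.full(spec.n_isis - n_ad + 6, ad[-1]))
        # ASP.SLN: nothing after the adapting transient
    elif body in ("NASP", "SLN", ""):
        parts.append(np.full(spec.n_isis, rest_isi1))
    else:
        raise InfeasibleSpecError(f"unsupported pattern {spec.pattern!r}")
    isis = np.concatenate([np.asarray(x, dtype=float) for x in parts])
    return isis, ("sln" if steady == "SLN" else "short"), steady


def generate(spec: GeneratorSpec) -> SpikeTrain:
    """One synthetic train; the ground-truth label is ``spec.pattern``."""
    rng = np.random.default_rng(spec.seed)
    isis, pfs_mode, _ = _build_isis(spec)

    if spec.noise_cv > 0:
        clean = isis
        isis = clean * (1.0 + spec.noise_cv * rng.standard_normal(clean.size))
        isis = np.maximum(isis, 0.05 * clean)  # keep ISIs positive

    if spec.delay is not None:
        delay = spec.delay
    elif spec.pattern.startswith("D."):
        # safely above DF·(ISI1+ISI2)/2 even under noise
        delay = 3.0 * float(isis[0] + isis[1])
    else:
        delay = float(isis[0])

    total = delay + float(isis.sum())
    if pfs_mode == "sln":
        pfs = 2.5 * float(isis.max())  # strictly beyond the silence criterion
    else:
        pfs = 0.6 * float(np.median(isis))
    stim = spec.stim_duration
    if total + pfs > stim:
        stim = total + pfs  # grow the pulse to keep the recipe feasible
    elif pfs_mode == "short":
        # keep PFS short relative to the largest ISI so SLN cannot trigger
        stim = total + pfs

    spikes = delay + np.concatenate([[0.0], np.cumsum(isis)])
    return SpikeTrain(
        trace_id=f"syn-{spec.pattern}-{spec.seed}",
        neuron_type="synthetic",
        spike_times=spikes,
        stim_duration=stim,
        stim_amplitude=200.0,
        swa_given=spec.swa,
        conditions={"source": "synthetic"},
    )


def generate_benchmark(n_per_class: int = 1, noise_cv: float = 0.0,
                       seed: int = 0,
                       patterns: tuple = BENCHMARK_PATTERNS) -> list[tuple[SpikeTrain, str]]:
    """Labeled benchmark covering all nine elements across composite patterns.

    Returns ``[(train, true_pattern), ...]`` with ``n_per_class`` trains per
    pattern; deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be ≥ 1")
    root = np.random.default_rng(seed)
    out: list[tuple[SpikeTrain, str]] = []
    for pattern in patterns:
        for j in range(n_per_class):
            sub = int(root.integers(0, 2 ** 31 - 1))
            spec = GeneratorSpec(
                pattern=pattern, noise_cv=noise_cv, seed=sub,
                swa=8.0 if "SWB" in pattern else None,
            )
            out.append((generate(spec), pattern))
    return out


def generate_property_matrices(n_types: int, n_props: int,
                               planted: Optional[list] = None,
                               seed: int = 0,
                               element_prob: float = 0.35,
                               property_prob: float = 0.4,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary element and property matrices with optional planted links.

    ``planted`` is a list of ``(element, property_name, odds_ratio)``; an
    infinite odds ratio makes the property a copy of the element column.
    Entries are 1/0; unknowns are not generated (tests exercise them by
    masking).  Returns ``(elements_df, properties_df)`` indexed by type_id.
    """
    rng = np.random.default_rng(seed)
    types = [f"T{i:03d}" for i in range(n_types)]
    elem = pd.DataFrame(
        rng.random((n_types, len(ELEMENTS))) < element_prob,
        index=types, columns=list(ELEMENTS),
    ).astype(int)
    props = pd.DataFrame(
        rng.random((n_types, n_props)) < property_prob,
        index=types, columns=[f"P{j:03d}" for j in range(n_props)],
    ).astype(int)
    for element, prop, odds in planted or []:
        e = elem[element].to_numpy()
        if np.isinf(odds):
            props[prop] = e
            continue
        # P(prop|e=1) / P(prop|e=0) tuned through the odds ratio
        p0 = property_prob
        p1 = odds * p0 / (1 - p0 + odds * p0)
        prob = np.where(e == 1, p1, p0)
        props[prop] = (rng.random(n_types) < prob).astype(int)
    return elem, props
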