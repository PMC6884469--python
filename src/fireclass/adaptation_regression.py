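"""Piecewise-linear model selection for spike-frequency adaptation.

Normalized ISIs (ISI_k / ISI_min) are regressed on normalized time (first
spike → 0, last spike → 1).  Four nested models of increasing complexity are
fitted:

  M1  constant            Y = b₁                     (1 parameter)
  M2  line                Y = a₁X + b₁               (2 parameters)
  M3  line → plateau      continuous, a₂ = 0         (3 parameters)
  M4  two lines           continuous                 (4 parameters)

A more complex model is accepted only if it improves the fit significantly
under an extra-sum-of-squares F-test, with Bonferroni-corrected thresholds
down the ladder (0.05, 0.025, 0.05/3).  The fitted slopes map onto labels:
non-adapting (NASP), adapting (ASP.), adapting-then-non-adapting (ASP.NASP),
doubly adapting (ASP.ASP.), accelerating (ACSP.), with a guard slope of
0.003 against calling vanishingly weak trends adaptation.  A separate test
flags rapid adaptation (RASP.) confined to the first two or three ISIs.

Breakpoints are found by exhaustive search over interior data abscissae,
which keeps the fit deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pattern_criteria import CriteriaConfig

__all__ = ["RegressionFit", "fit_ladder", "label_from_fit",
           "detect_rasp_prefix", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    """Fewer points than the regression ladder can use."""


@dataclass
class RegressionFit:
    """Result of the nested model-selection ladder.

    SSE entries are monotone non-increasing down the ladder (a more complex
    model whose best constrained fit fails to improve on the simpler one is
    credited with the simpler model's SSE, which forces its F-statistic to
    zero and its p-value to 1 — the selection outcome is unchanged).
    """

    n: int
    model: str                       # selected: "M1" | "M2" | "M3" | "M4"
    a1: float
    b1: float
    a2: float
    b2: float
    breakpoint: Optional[float]      # x* of the selected model (M3/M4)
    sse: dict                        # {"M1": ..., "M2": ..., "M3": ..., "M4": ...}
    p_21: float
    p_32: float
    p_43: float

    def summary(self) -> str:
        lines = [
            f"Adaptation regression ladder (n = {self.n} normalized ISIs)",
            f"  selected model: {self.model}",
            f"  a1 = {self.a1:+.4f}  b1 = {self.b1:.4f}  "
            f"a2 = {self.a2:+.4f}  b2 = {self.b2:.4f}",
            f"  breakpoint x* = "
            + (f"{self.breakpoint:.3f}" if self.breakpoint is not None else "—"),
            "  SSE: " + "  ".join(f"{m}={self.sse[m]:.5g}"
                                  for m in ("M1", "M2", "M3", "M4")),
            f"  p(M2 vs M1) = {self.p_21:.4g}   p(M3 vs M2) = {self.p_32:.4g}"
            f"   p(M4 vs M3) = {self.p_43:.4g}",
        ]
        return "\n".join(lines)


def _f_test(sse_small: float, sse_large: float, df_extra: int,
            df_resid: int) -> float:
    """Extra-sum-of-squares F-test p-value; 1.0 when no improvement."""
    if df_resid <= 0:
        return 1.0
    num = (sse_small - sse_large) / df_extra
    if num <= 0:
        return 1.0
    if sse_large <= 0:
        return 0.0
    f = num / (sse_large / df_resid)
    return float(stats.f.sf(f, df_extra, df_resid))


def _fit_m3(x: np.ndarray, y: np.ndarray, xstar: float):
    """Continuous line-then-plateau at fixed breakpoint: Y = a1·min(X,x*)+b1."""
    z = np.minimum(x, xstar)
    A = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def _fit_m4(x: np.ndarray, y: np.ndarray, xstar: float):
    """Continuous two-segment line at fixed breakpoint."""
    z1 = np.minimum(x, xstar)
    z2 = np.maximum(x - xstar, 0.0)
    A = np.column_stack([z1, z2, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1]), float(coef[2])


def fit_ladder(norm_isis: Sequence[float],
               norm_times: Sequence[float],
               cfg: Optional[CriteriaConfig] = None) -> RegressionFit:
    """Fit the four nested models and compute the ladder p-values.

    Minimum data requirements: 3 points overall; the M2 comparison needs
    ≥ 4 points, M3 ≥ 5, M4 ≥ 6 — skipped comparisons report p = 1 and
    inherit the simpler model's SSE.
    """
    y = np.asarray(norm_isis, dtype=float)
    x = np.asarray(norm_times, dtype=float)
    n = y.size
    if n != x.size:
        raise ValueError("norm_isis and norm_times must have equal length")
    if n < 3:
        raise InsufficientDataError(
            f"insufficient for regression: {n} points, need ≥ 3")

    sse = {}
    # M1: constant
    b1_m1 = float(y.mean())
    sse["M1"] = float(((y - b1_m1) ** 2).sum())

    # M2: OLS line
    a1_m2, b1_m2 = 0.0, b1_m1
    if n >= 4:
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a1_m2, b1_m2 = float(coef[0]), float(coef[1])
        r = y - A @ coef
        sse["M2"] = min(float(r @ r), sse["M1"])
        p_21 = _f_test(sse["M1"], sse["M2"], 1, n - 2)
    else:
        sse["M2"] = sse["M1"]
        p_21 = 1.0

    # breakpoint candidates: interior data abscissae
    interior = np.unique(x[1:-1])
    interior = interior[(interior > x.min()) & (interior < x.max())]

    m3_best = None
    if n >= 5 and interior.size:
        for xs in interior:
            s, a1, b1 = _fit_m3(x, y, xs)
            if m3_best is None or s < m3_best[0] - 1e-15:
                m3_best = (s, a1, b1, float(xs))
    if m3_best is not None:
        sse["M3"] = min(m3_best[0], sse["M2"])
        p_32 = _f_test(sse["M2"], sse["M3"], 1, n - 3)
    else:
        sse["M3"] = sse["M2"]
        p_32 = 1.0

    m4_best = None
    if n >= 6 and interior.size:
        for xs in interior:
            s, a1, a2, b1 = _fit_m4(x, y, xs)
            if m4_best is None or s < m4_best[0] - 1e-15:
                m4_best = (s, a1, a2, b1, float(xs))
    if m4_best is not None:
        sse["M4"] = min(m4_best[0], sse["M3"])
        p_43 = _f_test(sse["M3"], sse["M4"], 1, n - 4)
    else:
        sse["M4"] = sse["M3"]
        p_43 = 1.0

    # selection: walk up while each step is significant at the ladder levels
    if cfg is None:
        cfg = CriteriaConfig()
    model = "M1"
    a1, b1, a2, b2, xstar = 0.0, b1_m1, 0.0, b1_m1, None
    if p_21 <= cfg.alpha and n >= 4:
        model, a1, b1 = "M2", a1_m2, b1_m2
        a2, b2 = a1_m2, b1_m2
        if p_32 < cfg.p32_threshold and m3_best is not None:
            model = "M3"
            _, a1, b1, xstar = m3_best
            a2 = 0.0
            b2 = a1 * xstar + b1  # plateau level (continuity)
            if p_43 < cfg.p43_threshold and m4_best is not None:
                model = "M4"
                _, a1, a2, b1, xstar = m4_best
                b2 = b1 + (a1 - a2) * xstar

    return RegressionFit(n=n, model=model, a1=a1, b1=b1, a2=a2, b2=b2,
                         breakpoint=xstar, sse=sse,
                         p_21=p_21, p_32=p_32, p_43=p_43)


def label_from_fit(fit: RegressionFit, cfg: CriteriaConfig) -> str:
    """Map a ladder fit onto a spiking label.

    NASP when the line does not beat the constant (p₂,₁ > α) or the slope is
    negligible (|a₁| ≤ 0.003); ACSP. for a significant negative slope
    (< −0.003); otherwise the adapting family: ASP.NASP when the plateau
    model wins (p₃,₂ < 0.025), ASP.ASP. when the two-line model additionally
    wins (p₄,₃ < 0.05/3 with second slope > 0.003), plain ASP. otherwise.
    """
    # slope of the plain line decides adapting vs not
    a_line = fit.a1 if fit.model != "M1" else 0.0
    if fit.model in ("M3", "M4"):
        a_line = fit.a1  # first-segment slope
    if fit.p_21 > cfg.alpha or abs(a_line) <= cfg.a1_min:
        return "NASP"
    if a_line < -cfg.a1_min:
        return "ACSP."
    if fit.p_32 < cfg.p32_threshold:
        if fit.p_43 < cfg.p43_threshold and fit.a2 > cfg.a1_min:
            return "ASP.ASP."
        return "ASP.NASP"
    return "ASP."


def _segment_norm(isis: np.ndarray):
    """Segment-local normalized coordinates: ISIs over their own minimum,
    abscissae at the spike ending each ISI over the segment's span."""
    isis = np.asarray(isis, dtype=float)
    ends = np.cumsum(isis)
    return isis / isis.min(), ends / ends[-1]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def detect_rasp_prefix(isis: Sequence[float],
                       cfg: CriteriaConfig) -> tuple[bool, int]:
    """Detect rapid adaptation confined to the first 2–3 ISIs.

    For k in {2, 3}: the OLS slope of the first k+1 ISIs — normalized to
    their minimum and regressed on the ISI index — must exceed S_RASP, and
    the remainder (ISI_{k+1}..ISI_n) must itself classify as NASP or as the
    adapting family.  Returns (True, smallest such k) or (False, 0).

    The index abscissa makes the slope a per-interval relative increase:
    rapid adaptation like 1→3→6 scores 2.5, a gentle ramp like
    1→1.05→1.1 scores 0.05.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 5:
        return False, 0
    for k in cfg.rasp_k:
        if isis.size - k < 3:  # remainder must support a fit
            continue
        head = isis[: k + 1]
        yh = head / head.min()
        xh = np.arange(1.0, k + 2.0)
        if not (_ols_slope(xh, yh) > cfg.S_RASP):
            continue
        rest = isis[k:]
        yr, xr = _segment_norm(rest)
        try:
            fit = fit_ladder(yr, xr, cfg)
        except InsufficientDataError:
            continue
        label = label_from_fit(fit, cfg)
        if label in ("NASP", "ASP.", "ASP.NASP", "ASP.ASP."):
            return True, int(k)
    return False, 0
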