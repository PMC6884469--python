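"""Categorical association screening: element × property 2×2 tables,
Barnard's unconditional exact test, and Benjamini–Hochberg FDR control.

Barnard's test treats the two columns of the 2×2 table as independent
binomials with a common nuisance success probability π under the null; the
p-value is the supremum over π of the probability of all outcomes whose
pooled-variance score statistic is at least as extreme (two-sided) as the
observed one.  The supremum is approximated by a dense grid refined around
the maximizer — deterministic to ~1e-8 in π resolution.

Screening keeps tables with more than 9 informative types of which the
element is expressed more than 3 times, and calls a pair significant when
its p-value is below 0.05 and survives BH at FDR < 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ContingencyTable", "AssociationResult", "build_tables",
           "barnard_exact", "fdr_bh", "screen"]


@dataclass
class ContingencyTable:
    """Counts: a = element+/property+, b = element+/property−,
    c = element−/property+, d = element−/property−."""

    a: int
    b: int
    c: int
    d: int
    element: str = ""
    property: str = ""

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        self.total = self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class AssociationResult:
    element: str
    property: str
    table: ContingencyTable
    p: float
    q: float
    significant: bool


def build_tables(elements: pd.DataFrame, properties: pd.DataFrame,
                 min_total: int = 9, min_positive: int = 3
                 ) -> list[ContingencyTable]:
    """One 2×2 table per (element, property) pair passing eligibility.

    Matrices are indexed by type_id with entries 1 (positive), 0 (negative)
    or NaN (unknown); unknowns are excluded pairwise.  A pair is kept when
    its informative total exceeds ``min_total`` and the element is expressed
    more than ``min_positive`` times among the informative types.
    """
    common = elements.index.intersection(properties.index)
    if len(common) == 0:
        raise ValueError("element and property matrices share no type_ids")
    E = elements.loc[common]
    P = properties.loc[common]
    tables = []
    for e in E.columns:
        ev = E[e]
        for pr in P.columns:
            pv = P[pr]
            ok = ev.notna() & pv.notna()
            if int(ok.sum()) <= min_total:
                continue
            ei = ev[ok].astype(int)
            pi = pv[ok].astype(int)
            if int((ei == 1).sum()) <= min_positive:
                continue
            tables.append(ContingencyTable(
                a=int(((ei == 1) & (pi == 1)).sum()),
                b=int(((ei == 1) & (pi == 0)).sum()),
                c=int(((ei == 0) & (pi == 1)).sum()),
                d=int(((ei == 0) & (pi == 0)).sum()),
                element=str(e), property=str(pr),
            ))
    return tables


def _score_matrix(n1: int, n2: int) -> np.ndarray:
    """Pooled-variance score statistic T(x1, x2) for successes x1 of n1 and
    x2 of n2; 0 where the pooled variance vanishes."""
    x1 = np.arange(n1 + 1)[:, None].astype(float)
    x2 = np.arange(n2 + 1)[None, :].astype(float)
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    return t


def _log_binom_coef(n: int) -> np.ndarray:
    from scipy.special import gammaln
    x = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)


def _tail_prob(mask: np.ndarray, n1: int, n2: int,
               pis: np.ndarray) -> np.ndarray:
    """P_π[outcome in mask] for each nuisance π (vectorized over π)."""
    x1 = np.arange(n1 + 1)[None, :]
    x2 = np.arange(n2 + 1)[None, :]
    lp = np.log(pis)[:, None]
    lq = np.log1p(-pis)[:, None]
    f1 = np.exp(_log_binom_coef(n1)[None, :] + x1 * lp + (n1 - x1) * lq)
    f2 = np.exp(_log_binom_coef(n2)[None, :] + x2 * lp + (n2 - x2) * lq)
    # (P, n1+1) @ (n1+1, n2+1) -> (P, n2+1), then row-dot with f2
    return np.einsum("pi,ij,pj->p", f1, mask, f2)


def barnard_exact(t: ContingencyTable, grid_size: int = 200,
                  refinements: int = 2) -> float:
    """Two-sided Barnard exact p-value with nuisance-grid maximization.

    The two groups are the property-positive (size a+c) and
    property-negative (size b+d) columns; successes are element-positive
    counts.  Degenerate designs (an empty group, or an all-positive /
    all-negative element row making the statistic undefined everywhere)
    return p = 1 with a warning.
    """
    if t.total <= 0:
        raise ValueError("empty table")
    n1, n2 = t.a + t.c, t.b + t.d
    if n1 == 0 or n2 == 0:
        warnings.warn("degenerate table: an empty margin; p = 1")
        return 1.0
    T = _score_matrix(n1, n2)
    t_obs = T[t.a, t.b]
    if t_obs == 0:
        return 1.0
    mask = (np.abs(T) >= abs(t_obs) - 1e-12).astype(float)

    lo, hi = 1e-8, 1 - 1e-8
    best_p, best_pi = 0.0, 0.5
    for _ in range(refinements + 1):
        pis = np.linspace(lo, hi, grid_size)
        probs = _tail_prob(mask, n1, n2, pis)
        k = int(np.argmax(probs))
        if probs[k] > best_p:
            best_p, best_pi = float(probs[k]), float(pis[k])
        step = (hi - lo) / (grid_size - 1)
        lo = max(1e-8, best_pi - 2 * step)
        hi = min(1 - 1e-8, best_pi + 2 * step)
    return min(best_p, 1.0)


def fdr_bh(pvals: Sequence[float], level: float = 0.25) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at the given FDR level."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=level, method="fdr_bh")
    return reject


def screen(elements: pd.DataFrame, properties: pd.DataFrame,
           alpha: float = 0.05, fdr_level: float = 0.25,
           min_total: int = 9, min_positive: int = 3
           ) -> list[AssociationResult]:
    """Full association screen: tables → Barnard p → BH → significance.

    Results are sorted by p-value; ``significant`` requires both p < alpha
    and survival of BH at ``fdr_level``.
    """
    tables = build_tables(elements, properties, min_total, min_positive)
    if not tables:
        return []
    pvals = np.array([barnard_exact(t) for t in tables])
    flags = fdr_bh(pvals, fdr_level)
    # BH-adjusted q-values for reporting
    _, qvals, *_ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
    results = [
        AssociationResult(
            element=t.element, property=t.property, table=t,
            p=float(p), q=float(q),
            significant=bool(p < alpha and flag),
        )
        for t, p, q, flag in zip(tables, pvals, qvals, flags)
    ]
    results.sort(key=lambda r: (r.p, r.element, r.property))
    return results
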