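"""Phenotype aggregation and firing-pattern-family clustering.

The set of firing patterns a neuron type exhibits across stimuli and
conditions is its firing-pattern phenotype.  Types are labeled by behavior
complexity: *simple* (one pattern everywhere), *multi-behavior* (one cell
switches pattern with stimulus amplitude), *subtype-split* (different cells
under the same conditions fire differently — the type divides into
electrophysiological subtypes), or *condition-dependent* (pattern
differences co-occur only with differing experimental conditions).

For clustering, each phenotype becomes a binary profile over the nine
canonical elements, weighted by rarity: W_e = (N − n_e)/N where n_e counts
the records expressing element e among N records.  Profiles are clustered
by a two-step-style procedure — agglomerative merging under a log-likelihood
(entropy-based) distance for weighted categorical data, with the leaf count
chosen by the standard BIC-change-ratio rule and reported together with a
silhouette score under the same distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .classifier import ELEMENTS, STEADY_STATES, parse_pattern

logger = logging.getLogger(__name__)

__all__ = ["PhenotypeRecord", "ElementProfile", "aggregate_phenotypes",
           "element_weights", "cluster_families", "family_distribution",
           "ClusterTree", "canonical_pattern_set"]

BEHAVIORS = ("simple", "multi-behavior", "subtype-split",
             "condition-dependent", "undetermined")


@dataclass
class PhenotypeRecord:
    type_id: str
    patterns: frozenset          # of pattern strings
    behavior: str
    subtype_ids: Optional[tuple] = None   # cell ids forming this subtype
    meta: dict = field(default_factory=dict)

    def element_vector(self) -> np.ndarray:
        elems = set()
        for p in self.patterns:
            elems |= set(parse_pattern(p).elements)
        return np.array([1.0 if e in elems else 0.0 for e in ELEMENTS])


@dataclass
class ElementProfile:
    type_id: str
    binary: np.ndarray           # over ELEMENTS
    weighted: np.ndarray         # binary × W_e


def canonical_pattern_set(patterns) -> frozenset:
    """Deduplicate patterns that differ only by a missing steady state.

    An uncompleted pattern (e.g. "ASP.") is absorbed by any completed
    pattern extending it ("ASP.NASP", "ASP.SLN"); otherwise it is kept with
    a wildcard marker.
    """
    pats = set(patterns)
    out = set()
    for p in pats:
        completed = any(p.endswith(st) for st in STEADY_STATES)
        if completed:
            out.add(p)
    for p in pats:
        if any(p.endswith(st) for st in STEADY_STATES):
            continue
        if any(q.startswith(p) and q != p for q in pats):
            continue  # absorbed by a completed extension
        out.add(p + "*")
    return frozenset(out)


def _conditions_key(conditions: dict) -> tuple:
    """Normalized hashable key over the metadata fields that define
    'same experimental conditions'."""
    fields = ("species", "method", "slice_orientation", "pipette_solution",
              "temperature_band")
    return tuple(str(conditions.get(f, "")).strip().lower() for f in fields)


def aggregate_phenotypes(traces: Sequence[dict],
                         amplitude_band_pA: float = 50.0
                         ) -> list[PhenotypeRecord]:
    """Fold classified traces into per-type phenotype records.

    Each trace dict needs: type_id, cell_id, pattern, stim_amplitude,
    conditions (dict).  Missing metadata on a type with heterogeneous
    patterns yields an 'undetermined' record rather than a guess.
    """
    df = pd.DataFrame(list(traces))
    required = {"type_id", "pattern"}
    if not required.issubset(df.columns):
        raise ValueError(f"traces must carry at least {sorted(required)}")
    records: list[PhenotypeRecord] = []
    for type_id, g in df.groupby("type_id", sort=True):
        patterns = canonical_pattern_set(g["pattern"])
        if len(patterns) == 1:
            records.append(PhenotypeRecord(type_id, patterns, "simple"))
            continue

        meta_ok = all(
            col in g.columns and g[col].notna().all()
            for col in ("cell_id", "stim_amplitude", "conditions")
        )
        if not meta_ok:
            records.append(PhenotypeRecord(type_id, patterns, "undetermined"))
            continue

        g = g.assign(
            _cond=g["conditions"].map(_conditions_key),
            _band=(g["stim_amplitude"] / amplitude_band_pA).round().astype(int),
            _cpat=g["pattern"].map(lambda p: next(iter(
                canonical_pattern_set([p])))),
        )

        # subtype split: different cells, same conditions and amplitude band,
        # different patterns
        split = False
        for _, gg in g.groupby(["_cond", "_band"]):
            per_cell = gg.groupby("cell_id")["_cpat"].agg(frozenset)
            if len(per_cell) > 1 and per_cell.nunique() > 1:
                split = True
                break
        if split:
            sig = g.groupby("cell_id")["_cpat"].agg(frozenset)
            for j, (s, cells) in enumerate(
                    sorted(sig.groupby(sig).groups.items(),
                           key=lambda kv: sorted(kv[1])), start=1):
                sub_pats = canonical_pattern_set(
                    g[g["cell_id"].isin(cells)]["pattern"])
                records.append(PhenotypeRecord(
                    f"{type_id}/sub{j}", sub_pats, "subtype-split",
                    subtype_ids=tuple(sorted(cells)),
                    meta={"parent": type_id}))
            continue

        # multi-behavior: one cell, different patterns at different
        # amplitudes under the same conditions
        multi = any(
            gg["_cpat"].nunique() > 1 and gg["_band"].nunique() > 1
            for _, gg in g.groupby(["cell_id", "_cond"])
        )
        if multi:
            records.append(PhenotypeRecord(type_id, patterns, "multi-behavior"))
            continue

        # differences co-occur only with differing conditions
        cond_only = all(
            gg["_cpat"].nunique() == 1 for _, gg in g.groupby("_cond")
        )
        behavior = "condition-dependent" if cond_only else "undetermined"
        records.append(PhenotypeRecord(type_id, patterns, behavior))
    return records


def element_weights(records: Sequence[PhenotypeRecord]) -> pd.Series:
    """Rarity weights W_e = (N − n_e)/N over the nine canonical elements."""
    n_rec = len(records)
    if n_rec == 0:
        raise ValueError("no phenotype records: N must be > 0")
    counts = np.zeros(len(ELEMENTS))
    for rec in records:
        counts += rec.element_vector()
    return pd.Series((n_rec - counts) / n_rec, index=list(ELEMENTS),
                     name="W_e")


def build_profiles(records: Sequence[PhenotypeRecord],
                   weights: Optional[pd.Series] = None
                   ) -> list[ElementProfile]:
    if weights is None:
        weights = element_weights(records)
    w = weights.reindex(list(ELEMENTS)).to_numpy()
    return [
        ElementProfile(rec.type_id, rec.element_vector(),
                       rec.element_vector() * w)
        for rec in records
    ]


# ---------------------------------------------------------------------------
# Two-step-style clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Binary merge tree over profiles with the chosen leaf partition."""

    labels: pd.Series            # type_id -> family index (0..k-1)
    n_leaves: int
    silhouette: float
    merges: list                 # (cluster_a, cluster_b, distance) in order
    bic: dict                    # k -> BIC

    def newick(self) -> str:
        """Newick text of the merge tree (distances as branch lengths)."""
        names = {i: f"{tid}" for i, tid in enumerate(self.labels.index)}
        nxt = len(names)
        for a, b, d in self.merges:
            names[nxt] = f"({names[a]},{names[b]}):{d:.4g}"
            nxt += 1
        return names[nxt - 1] + ";" if self.merges else \
            "(" + ",".join(names.values()) + ");"


def _cluster_cost(counts1: np.ndarray, n: int, w: np.ndarray) -> float:
    """Weighted entropy cost N_C · Σ_e W_e · H_e(C) of a cluster, where each
    element is a binary categorical attribute with n1 positives of n."""
    if n == 0:
        return 0.0
    p1 = counts1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p1 > 0, p1 * np.log(p1), 0.0)
              + np.where(p1 < 1, (1 - p1) * np.log(1 - p1), 0.0))
    return float(n * np.sum(w * h))


def cluster_families(profiles: Sequence[ElementProfile], max_k: int = 12,
                     weights: Optional[pd.Series] = None) -> ClusterTree:
    """Agglomerate weighted element profiles into firing-pattern families.

    Distance between clusters is the increase in weighted entropy cost upon
    merging (log-likelihood distance for categorical attributes).  Identical
    profiles are collapsed first (the pre-cluster step); agglomeration is
    recorded as a binary tree; the leaf count is picked by the BIC-change
    ratio rule, refined by the largest jump in merge distance, capped at
    ``max_k``.  Deterministic: profiles are ordered lexicographically by
    type_id and ties merge the lexicographically smallest pair.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    profiles = sorted(profiles, key=lambda p: p.type_id)
    ids = [p.type_id for p in profiles]
    X = np.vstack([p.binary for p in profiles]).astype(float)
    if weights is not None:
        w = weights.reindex(list(ELEMENTS)).to_numpy()
    else:
        # recover weights from the weighted vectors where expressed
        w = np.full(X.shape[1], np.nan)
        for p in profiles:
            mask = p.binary > 0
            w[mask] = p.weighted[mask]
        w = np.where(np.isnan(w), 1.0, w)

    n_items, _ = X.shape
    if np.all(X == X[0]):
        warnings.warn("all profiles identical: single leaf")
        labels = pd.Series(np.zeros(n_items, dtype=int), index=ids)
        return ClusterTree(labels, 1, float("nan"), [], {1: 0.0})

    # active clusters: id -> (member row-indices, positive counts, size)
    members = {i: [i] for i in range(n_items)}
    counts = {i: X[i].copy() for i in range(n_items)}
    sizes = {i: 1 for i in range(n_items)}
    costs = {i: _cluster_cost(counts[i], 1, w) for i in range(n_items)}
    next_id = n_items
    merges = []
    partitions = {n_items: dict(members)}  # k -> partition snapshot
    merge_dist = {}                        # k (after merge) -> distance

    active = sorted(members)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                merged_cost = _cluster_cost(
                    counts[a] + counts[b], sizes[a] + sizes[b], w)
                d = merged_cost - costs[a] - costs[b]
                key = (d, min(ids[members[a][0]], ids[members[b][0]]))
                if best is None or key < best[0]:
                    best = (key, a, b, merged_cost, d)
        _, a, b, merged_cost, d = best
        members[next_id] = members[a] + members[b]
        counts[next_id] = counts[a] + counts[b]
        sizes[next_id] = sizes[a] + sizes[b]
        costs[next_id] = merged_cost
        merges.append((a, b, d))
        active = [c for c in active if c not in (a, b)] + [next_id]
        partitions[len(active)] = {c: members[c] for c in active}
        merge_dist[len(active)] = d
        next_id += 1

    # BIC(k) = 2·Σ_C cost(C) + m_k·log n, one parameter per element per cluster
    bic = {}
    for k, part in partitions.items():
        total_cost = sum(_cluster_cost(
            sum(X[m] for m in mem), len(mem), w) for mem in part.values())
        bic[k] = 2.0 * total_cost + k * X.shape[1] * np.log(n_items)

    k_max_avail = min(max_k, n_items)
    ks = sorted(k for k in partitions if 1 <= k <= k_max_avail)
    n_leaves = _choose_k(bic, merge_dist, ks)

    part = partitions[n_leaves]
    lab = np.empty(n_items, dtype=int)
    for fam, (_, mem) in enumerate(sorted(part.items(),
                                          key=lambda kv: min(kv[1]))):
        lab[mem] = fam
    labels = pd.Series(lab, index=ids)

    sil = float("nan")
    if 1 < n_leaves < n_items:
        D = _pairwise_distance(X, w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sil = float(silhouette_score(D, lab, metric="precomputed"))
    return ClusterTree(labels, n_leaves, sil, merges, bic)


def _choose_k(bic: dict, merge_dist: dict, ks: list) -> int:
    """TwoStep-style leaf-count choice: BIC-change ratio for a coarse upper
    bound, then the largest ratio of successive merge distances."""
    if len(ks) == 1:
        return ks[0]
    d1 = bic[ks[0]] - bic[ks[1]] if len(ks) > 1 else 0.0  # change at k=1->2
    coarse = ks[-1]
    if d1 <= 0:
        # BIC already rising: fall back on distance refinement over all ks
        coarse = ks[-1]
    else:
        for i in range(len(ks) - 1):
            ratio = (bic[ks[i]] - bic[ks[i + 1]]) / d1
            if ratio < 0.04:
                coarse = ks[i]
                break
    cand = [k for k in ks if 2 <= k <= coarse and (k - 1) in merge_dist
            and k in merge_dist]
    if not cand:
        return max(2, min(coarse, ks[-1]))
    # merge_dist[m] is the cost of the merge producing m clusters; a good k
    # is cheap to reach (d at k) but expensive to destroy (d at k-1)
    def jump(k):
        destroy = merge_dist[k - 1]   # merge k -> k-1 clusters
        reach = merge_dist[k]         # merge k+1 -> k clusters
        return destroy / reach if reach > 0 else np.inf
    best = max(cand, key=lambda k: (jump(k), k))
    return best


def _pairwise_distance(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _cluster_cost(X[i] + X[j], 2, w)
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


def family_distribution(assignments: pd.DataFrame,
                        grouping: str) -> pd.DataFrame:
    """Percentage of each family within each group.

    ``assignments`` needs columns 'family' and the grouping column; rows of
    the output sum to 100.  Empty groups are omitted with a warning.
    """
    if assignments.empty:
        return pd.DataFrame()
    if grouping not in assignments.columns:
        raise ValueError(f"no grouping column {grouping!r}")
    valid = assignments.dropna(subset=[grouping, "family"])
    dropped = len(assignments) - len(valid)
    if dropped:
        warnings.warn(f"{dropped} records without {grouping!r}/family omitted")
    if valid.empty:
        return pd.DataFrame()
    table = pd.crosstab(valid[grouping], valid["family"])
    return table.div(table.sum(axis=1), axis=0) * 100.0
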