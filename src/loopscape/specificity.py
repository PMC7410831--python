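"""Cell-type- and group-specific entity calling by t-statistic ranking.

A loop (or enhancer, or gene) is cell-type specific for a query cell when
its Welch t-statistic comparing the query samples against all other samples
ranks in the top fraction.  Group-specific calling intersects two pairwise
rankings and subtracts the between-other-groups ranking:
(T1 and T2) minus T3, so a hit is high in the query group against both
other groups while the other two groups do not differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpecificSet:
    kind: str                 # loop | enhancer | gene
    target: str               # cell type or group name
    members: pd.Index
    top_frac: float
    t_stats: pd.DataFrame     # per-entity statistics used for the ranking


def welch_t(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Row-wise Welch (unequal-variance) t-statistic for group a vs group b."""
    A = X[:, mask_a]
    B = X[:, mask_b]
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 samples")
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    # identical constant groups: no evidence of difference
    return np.where(np.isfinite(t), t, 0.0)


def pooled_t(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance (Student) t-statistic, the flagged alternative."""
    A = X[:, mask_a]
    B = X[:, mask_b]
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 samples")
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=1) - B.mean(axis=1)) / denom
    return np.where(np.isfinite(t), t, 0.0)


_T_FLAVORS = {"welch": welch_t, "pooled": pooled_t}


def _top_by_t(t: pd.Series, top_frac: float) -> pd.Index:
    """Top floor(top_frac * N) entities by descending t; ties break by id."""
    n_take = int(np.floor(top_frac * len(t)))
    t = t.sort_index()  # stable argsort then breaks ties by ascending id
    order = np.argsort(-t.to_numpy(), kind="mergesort")
    return t.index[order[:n_take]]


def celltype_specific(
    matrix: pd.DataFrame,
    samples,
    query_cell: str,
    top_frac: float = 0.10,
    kind: str = "loop",
    t_flavor: str = "welch",
) -> SpecificSet:
    """Entities in the top fraction of the query-vs-rest t ranking."""
    cols = list(matrix.columns)
    cell_of = samples.cell_type_of()
    mask_q = np.array([cell_of.get(s) == query_cell for s in cols])
    if not mask_q.any():
        raise ValueError(f"cell type {query_cell!r} has no samples in the matrix")
    t = _T_FLAVORS[t_flavor](matrix.to_numpy(dtype=float), mask_q, ~mask_q)
    t = pd.Series(t, index=matrix.index, name="t")
    members = _top_by_t(t, top_frac)
    return SpecificSet(kind=kind, target=query_cell, members=members,
                       top_frac=top_frac, t_stats=t.to_frame())


def group_specific(
    matrix: pd.DataFrame,
    samples,
    top_frac: float = 0.10,
    kind: str = "loop",
    t_flavor: str = "welch",
) -> dict:
    """Group-specific sets, one per sample group, by (T1 & T2) - T3 ranking."""
    groups = samples.groups
    if len(groups) != 3:
        raise ValueError(f"group-specific calling needs exactly 3 groups, got {groups}")
    cols = list(matrix.columns)
    group_of = samples.group_of()
    masks = {g: np.array([group_of.get(s) == g for s in cols]) for g in groups}
    X = matrix.to_numpy(dtype=float)
    tfun = _T_FLAVORS[t_flavor]
    out = {}
    for g in groups:
        o1, o2 = [h for h in groups if h != g]
        t1 = pd.Series(tfun(X, masks[g], masks[o1]), index=matrix.index)
        t2 = pd.Series(tfun(X, masks[g], masks[o2]), index=matrix.index)
        t3 = pd.Series(tfun(X, masks[o1], masks[o2]), index=matrix.index)
        T1 = _top_by_t(t1, top_frac)
        T2 = _top_by_t(t2, top_frac)
        T3 = _top_by_t(t3, top_frac)
        members = (T1.intersection(T2)).difference(T3)
        members = pd.Index(sorted(members))
        stats = pd.DataFrame({"t1": t1, "t2": t2, "t3": t3})
        out[g] = SpecificSet(kind=kind, target=g, members=members,
                             top_frac=top_frac, t_stats=stats)
    return out


def specific_features_for(
    feature_matrix: pd.DataFrame,
    samples,
    query_cell: str,
    top_frac: float = 0.10,
    kind: str = "enhancer",
    t_flavor: str = "welch",
) -> SpecificSet:
    """Same ranking machinery applied to enhancer signal or gene expression."""
    return celltype_specific(feature_matrix, samples, query_cell,
                             top_frac=top_frac, kind=kind, t_flavor=t_flavor)
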