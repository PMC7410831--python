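"""Anchor construction, PET tabulation and loop significance scoring.

The pooled significance model assigns candidate anchor pairs to
equal-occupancy genomic-distance bins and, within a bin, expects PETs in
proportion to the product of the two anchors' ChIP efficiencies.  The
reported p-value is the Poisson upper tail P(X >= k) at that expected rate,
with Benjamini-Hochberg and Bonferroni control across candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import FeatureTrack, assign_points_to_disjoint, merge_intervals, overlaps_any

MIN_SPAN_DEFAULT = 10_000
MAX_SPAN_DEFAULT = 5_000_000
DOWNSAMPLE_CAP = 2_250_000


@dataclass
class AnchorSet:
    """Disjoint, genome-ordered anchor intervals with integer ids.

    ``efficiency[i]`` is the pooled PET-endpoint count inside anchor ``i``
    (the local ChIP-efficiency proxy); it is filled in by
    :func:`tabulate_pets` or set explicitly.
    """

    track: FeatureTrack
    efficiency: np.ndarray | None = None

    def __post_init__(self):
        df = self.track.df
        if len(df) > 1:
            same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
            overlap = df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]
            if (same & overlap).any():
                raise ValueError("anchors must be disjoint")
        if self.efficiency is not None:
            self.efficiency = np.asarray(self.efficiency, dtype=float)
            if len(self.efficiency) != len(df):
                raise ValueError("efficiency length must match anchor count")

    def __len__(self) -> int:
        return len(self.track)

    @property
    def midpoints(self) -> np.ndarray:
        return self.track.midpoints

    @property
    def chroms(self) -> np.ndarray:
        return self.track.chroms

    def spans(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Midpoint-to-midpoint distance for anchor-id pairs."""
        mids = self.midpoints
        return np.abs(mids[np.asarray(b)] - mids[np.asarray(a)])

    def to_bed(self) -> FeatureTrack:
        df = self.track.df.copy()
        df["label"] = [f"anchor_{i}" for i in range(len(df))]
        if self.efficiency is not None:
            df["score"] = self.efficiency
        return FeatureTrack(df)


def build_anchor_set(
    peak_tracks,
    extension_bp: int = 500,
    blacklist: FeatureTrack | None = None,
) -> AnchorSet:
    """Pool per-sample peaks, extend, merge, and blacklist-filter into anchors.

    Peaks are extended by ``extension_bp`` on both sides (clipped at 0),
    overlapping extended peaks are merged, and merged anchors overlapping any
    blacklist interval are removed.  Ids follow genome order.
    """
    if extension_bp < 0:
        raise ValueError("extension_bp must be >= 0")
    frames = [t.df for t in peak_tracks if len(t)]
    if not frames:
        raise ValueError("pooled peak set is empty")
    pooled = pd.concat(frames, ignore_index=True)
    pooled["start"] = np.maximum(pooled["start"] - extension_bp, 0)
    pooled["end"] = pooled["end"] + extension_bp
    merged = merge_intervals(FeatureTrack(pooled))
    if blacklist is not None and len(blacklist):
        keep = ~overlaps_any(merged, blacklist)
        merged = FeatureTrack(merged.df.loc[keep].reset_index(drop=True))
    if len(merged) == 0:
        raise ValueError("no anchors remain after blacklist filtering")
    return AnchorSet(merged)


def downsample_pets(pets: pd.DataFrame, cap: int = DOWNSAMPLE_CAP, seed: int = 0) -> pd.DataFrame:
    """Uniform without-replacement downsampling of PET records to ``cap``."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    if len(pets) <= cap:
        return pets
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pets), size=cap, replace=False)
    idx.sort()
    return pets.iloc[idx].reset_index(drop=True)


def tabulate_pets(
    pets: pd.DataFrame,
    anchors: AnchorSet,
    min_span: int = MIN_SPAN_DEFAULT,
    max_span: int = MAX_SPAN_DEFAULT,
):
    """Count PETs linking distinct anchors into one interaction-matrix column.

    A PET contributes iff both endpoint midpoints fall inside (distinct)
    anchors on the same chromosome and the anchor midpoint distance lies
    strictly inside (min_span, max_span).  Returns ``(counts, endpoint_counts)``
    where ``counts`` is a Series indexed by canonical (anchor_a, anchor_b)
    pairs (a < b) and ``endpoint_counts`` tallies all endpoint midpoints per
    anchor (the ChIP-efficiency summary).
    """
    mid1 = ((pets["start1"].to_numpy() + pets["end1"].to_numpy()) // 2)
    mid2 = ((pets["start2"].to_numpy() + pets["end2"].to_numpy()) // 2)
    c1 = pets["chrom1"].to_numpy()
    c2 = pets["chrom2"].to_numpy()
    a1 = assign_points_to_disjoint(c1, mid1, anchors.track)
    a2 = assign_points_to_disjoint(c2, mid2, anchors.track)

    endpoint_counts = np.zeros(len(anchors), dtype=np.int64)
    for arr in (a1, a2):
        hit = arr[arr >= 0]
        np.add.at(endpoint_counts, hit, 1)

    ok = (a1 >= 0) & (a2 >= 0) & (a1 != a2) & (c1 == c2)
    lo = np.minimum(a1[ok], a2[ok])
    hi = np.maximum(a1[ok], a2[ok])
    span = anchors.spans(lo, hi)
    inwin = (span > min_span) & (span < max_span)
    lo, hi = lo[inwin], hi[inwin]
    counts = (
        pd.Series(1, index=pd.MultiIndex.from_arrays([lo, hi], names=["anchor_a", "anchor_b"]))
        .groupby(level=[0, 1])
        .sum()
        .astype(np.int64)
    )
    return counts, endpoint_counts


def build_interaction_matrix(columns: dict, anchors: AnchorSet) -> pd.DataFrame:
    """Assemble per-sample tabulation columns into one raw count matrix.

    Rows are the union of observed anchor pairs across samples (zeros where a
    sample saw no PET); the index is a (anchor_a, anchor_b) MultiIndex in
    genome order.
    """
    mat = pd.DataFrame(columns).fillna(0).astype(np.int64)
    mat = mat.sort_index()
    mat.index.names = ["anchor_a", "anchor_b"]
    return mat


def _equal_occupancy_bins(span: np.ndarray, n_bins: int, min_pairs: int) -> np.ndarray:
    """Assign each pair to an equal-occupancy span bin; widen bins until every
    bin holds at least ``min_pairs`` pairs."""
    n = len(span)
    n_bins = max(1, min(n_bins, n // max(min_pairs, 1) or 1))
    while n_bins > 1 and n // n_bins < min_pairs:
        n_bins -= 1
    order = np.argsort(span, kind="mergesort")
    bin_of = np.empty(n, dtype=np.int64)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    return bin_of


def score_loops(
    pairs: pd.DataFrame,
    anchors: AnchorSet,
    n_distance_bins: int = 50,
    min_pairs_per_bin: int = 20,
    p_threshold: float | None = None,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Score pooled candidate anchor pairs for loop significance.

    ``pairs`` must have columns ``anchor_a``, ``anchor_b`` and ``count``
    (pooled PET counts over all samples; zero-count candidates allowed and
    recommended for honest calibration).  Anchor efficiencies must be set on
    ``anchors``.  Returns a DataFrame with the observed count ``k``, expected
    rate ``lam``, Poisson upper-tail ``p``, BH ``q``, Bonferroni ``q_bonf``
    and a boolean ``called`` column (p < p_threshold if given, else q < fdr).
    """
    if anchors.efficiency is None:
        raise ValueError("anchor efficiencies are required for scoring")
    df = pairs[["anchor_a", "anchor_b", "count"]].copy()
    eff = anchors.efficiency
    e_prod = eff[df["anchor_a"].to_numpy()] * eff[df["anchor_b"].to_numpy()]
    zero = e_prod <= 0
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} candidate pair(s) with zero-efficiency anchors")
        df = df.loc[~zero].reset_index(drop=True)
        e_prod = e_prod[~zero]
    df["span"] = anchors.spans(df["anchor_a"].to_numpy(), df["anchor_b"].to_numpy())
    bin_of = _equal_occupancy_bins(df["span"].to_numpy(), n_distance_bins, min_pairs_per_bin)

    k = df["count"].to_numpy(dtype=np.int64)
    lam = np.empty(len(df), dtype=float)
    for b in np.unique(bin_of):
        m = bin_of == b
        total = k[m].sum()
        lam[m] = total * e_prod[m] / e_prod[m].sum()
    p = stats.poisson.sf(k - 1, lam)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    q_bonf = np.minimum(p * len(p), 1.0)
    df["k"] = k
    df["lam"] = lam
    df["p"] = p
    df["q"] = q
    df["q_bonf"] = q_bonf
    df["span_bin"] = bin_of
    df["called"] = (p < p_threshold) if p_threshold is not None else (q < fdr)
    return df


ORIENTATION_CLASSES = ("convergent", "divergent", "tandem_plus", "tandem_minus")


def ctcf_orientation_summary(
    loops: pd.DataFrame,
    anchors: AnchorSet,
    motif_track: FeatureTrack,
) -> dict:
    """Classify two-motif loops by CTCF motif orientation.

    ``loops`` needs columns ``anchor_a``/``anchor_b`` (a precedes b in genome
    order).  Only loops whose both anchors contain exactly one motif enter the
    denominator.  Convergent means the lower-coordinate anchor's motif is on
    '+' and the higher-coordinate anchor's on '-'.
    """
    strands = motif_track.df["strand"].to_numpy()
    if (strands == ".").any():
        raise ValueError("motif track contains strand '.'")
    mids = motif_track.midpoints
    owner = assign_points_to_disjoint(motif_track.chroms, mids, anchors.track)
    n_motifs = np.zeros(len(anchors), dtype=np.int64)
    hit = owner >= 0
    np.add.at(n_motifs, owner[hit], 1)
    anchor_strand = np.full(len(anchors), "", dtype=object)
    anchor_strand[owner[hit]] = strands[hit]  # meaningful only where n_motifs == 1

    a = loops["anchor_a"].to_numpy()
    b = loops["anchor_b"].to_numpy()
    ok = (n_motifs[a] == 1) & (n_motifs[b] == 1)
    sa, sb = anchor_strand[a[ok]], anchor_strand[b[ok]]
    counts = {
        "convergent": int(np.sum((sa == "+") & (sb == "-"))),
        "divergent": int(np.sum((sa == "-") & (sb == "+"))),
        "tandem_plus": int(np.sum((sa == "+") & (sb == "+"))),
        "tandem_minus": int(np.sum((sa == "-") & (sb == "-"))),
    }
    n = sum(counts.values())
    pct = {k: (100.0 * v / n if n else float("nan")) for k, v in counts.items()}
    return {
        "counts": counts,
        "percent": pct,
        "n_included": n,
        "percent_convergent": pct["convergent"],
    }
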