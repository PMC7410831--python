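"""2x2 enrichment machinery over loop ends, anchors, genes and motifs.

All tests share one primitive: a two-sided Fisher exact test on a 2x2
contingency table, with the cross-product odds ratio, and BH adjustment
within the analysis-specific test family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import FeatureTrack, overlaps_any
from .loopcall import AnchorSet

CHROMATIN_STATES = ("TSS", "BIV", "TX", "REPRESS", "REPEAT", "ENH", "HET", "QUIES")


@dataclass
class EnrichmentResult:
    label: str
    a: int  # in-set and overlapping
    b: int  # in-set, not overlapping
    c: int  # out-of-set, overlapping
    d: int  # out-of-set, not overlapping
    odds_ratio: float
    p: float
    q: float | None = None
    degenerate: bool = False

    @property
    def log2_odds_ratio(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.log2(self.odds_ratio))


def fisher_2x2(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test with the cross-product odds ratio.

    The two-sided p sums hypergeometric probabilities not exceeding that of
    the observed table.  A zero cell makes the odds ratio degenerate
    (reported as +inf or 0 with a flag).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate table: an entire margin is zero")
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
        degenerate = num == 0
    else:
        odds = np.inf if num > 0 else 1.0
        degenerate = True
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(label, int(a), int(b), int(c), int(d), float(odds), float(p),
                            degenerate=degenerate)


def _bh_adjust(results: list) -> list:
    if not results:
        return results
    _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"label": r.label, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
         "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q}
        for r in results
    ])


# ---------------------------------------------------------------------------
# anchor degree / connectivity
# ---------------------------------------------------------------------------

def anchor_degrees(loops: pd.DataFrame, anchors: AnchorSet) -> np.ndarray:
    """Number of loops touching each anchor."""
    deg = np.zeros(len(anchors), dtype=np.int64)
    for col in ("anchor_a", "anchor_b"):
        np.add.at(deg, loops[col].to_numpy(), 1)
    return deg


DEFAULT_DEGREE_BINS = (1, 2, 3, 4, 5)  # last bin is open-ended (5+)


def connectivity_profile(
    loops: pd.DataFrame,
    anchors: AnchorSet,
    feature_tracks: dict,
    degree_bins=DEFAULT_DEGREE_BINS,
) -> pd.DataFrame:
    """Enrichment of functional elements across anchor-connectivity bins.

    Anchors are binned by their loop degree (the last bin is open-ended);
    for each (bin, feature) the 2x2 table compares in-bin anchors against
    anchors in all other bins for overlap with the feature track.
    """
    deg = anchor_degrees(loops, anchors)
    used = deg > 0
    results = []
    edges = list(degree_bins)
    overlap_flags = {
        name: overlaps_any(anchors.track, track) for name, track in feature_tracks.items()
    }
    for bi, lo in enumerate(edges):
        hi = edges[bi + 1] if bi + 1 < len(edges) else None
        in_bin = used & (deg >= lo) & ((deg < hi) if hi is not None else True)
        out_bin = used & ~in_bin
        if not in_bin.any():
            continue
        bin_label = f"{lo}+" if hi is None else (f"{lo}" if hi == lo + 1 else f"{lo}-{hi - 1}")
        for name, flags in overlap_flags.items():
            a = int((in_bin & flags).sum())
            b = int((in_bin & ~flags).sum())
            c = int((out_bin & flags).sum())
            d = int((out_bin & ~flags).sum())
            try:
                r = fisher_2x2(a, b, c, d, label=f"{name}:{bin_label}")
            except ValueError:
                continue  # feature absent (or universal) in this comparison
            results.append((name, bin_label, r))
    out = pd.DataFrame([
        {"feature": n, "degree_bin": bl, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
         "odds_ratio": r.odds_ratio, "p": r.p}
        for n, bl, r in results
    ])
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    return out


# ---------------------------------------------------------------------------
# loop-end overlap helpers
# ---------------------------------------------------------------------------

def loop_end_table(loops: pd.DataFrame) -> pd.DataFrame:
    """One row per loop end: (loop index, anchor id, side)."""
    ends = pd.concat([
        pd.DataFrame({"loop": loops.index, "anchor": loops["anchor_a"], "side": "a"}),
        pd.DataFrame({"loop": loops.index, "anchor": loops["anchor_b"], "side": "b"}),
    ], ignore_index=True)
    return ends


def state_enrichment(
    specific_loops: pd.Index,
    all_loops: pd.DataFrame,
    anchors: AnchorSet,
    state_track: FeatureTrack,
    cell: str = "",
) -> dict:
    """Chromatin-state enrichment at cell-type-specific loop ends.

    For each of the eight state labels the 2x2 table crosses loop ends
    (specific vs non-specific interaction) with overlap of that state.
    Also reports the state composition of specific loop ends.
    """
    labels = set(state_track.df["label"].unique())
    unknown = labels - set(CHROMATIN_STATES)
    if unknown:
        raise ValueError(f"unknown chromatin state label(s): {sorted(unknown)}")
    ends = loop_end_table(all_loops)
    is_spec = ends["loop"].isin(specific_loops).to_numpy()
    results = []
    comp = {}
    n_spec_ends = int(is_spec.sum())
    for state in CHROMATIN_STATES:
        sub = FeatureTrack(state_track.df[state_track.df["label"] == state])
        anchor_hit = overlaps_any(anchors.track, sub) if len(sub) else np.zeros(len(anchors), bool)
        hit = anchor_hit[ends["anchor"].to_numpy()]
        a = int((is_spec & hit).sum())
        b = int((is_spec & ~hit).sum())
        c = int((~is_spec & hit).sum())
        d = int((~is_spec & ~hit).sum())
        try:
            results.append(fisher_2x2(a, b, c, d, label=f"{cell}:{state}" if cell else state))
        except ValueError:
            pass  # state absent from (or covering) every loop end
        comp[state] = a / n_spec_ends if n_spec_ends else np.nan
    return {"results": results, "composition": comp}


def pairtype_enrichment(
    specific_loops: pd.Index,
    all_loops: pd.DataFrame,
    anchors: AnchorSet,
    specific_enhancers: FeatureTrack,
    specific_promoters: FeatureTrack,
) -> list:
    """ENH-ENH / ENH-TSS / TSS-TSS pair-type enrichment of specific loops.

    An end counts as ENH when its anchor overlaps a cell-type-specific
    enhancer and as TSS when it overlaps a specific gene's promoter window;
    an end may count as both, and a loop contributes to every matching
    combination.
    """
    if len(specific_loops) == 0:
        raise ValueError("empty specific loop set")
    if len(specific_enhancers) == 0 or len(specific_promoters) == 0:
        raise ValueError("empty specific feature sets")
    enh_hit = overlaps_any(anchors.track, specific_enhancers)
    tss_hit = overlaps_any(anchors.track, specific_promoters)
    a_ids = all_loops["anchor_a"].to_numpy()
    b_ids = all_loops["anchor_b"].to_numpy()
    is_spec = all_loops.index.isin(specific_loops)
    combos = {
        "ENH-ENH": enh_hit[a_ids] & enh_hit[b_ids],
        "ENH-TSS": (enh_hit[a_ids] & tss_hit[b_ids]) | (tss_hit[a_ids] & enh_hit[b_ids]),
        "TSS-TSS": tss_hit[a_ids] & tss_hit[b_ids],
    }
    results = []
    for name, has in combos.items():
        a = int((is_spec & has).sum())
        b = int((is_spec & ~has).sum())
        c = int((~is_spec & has).sum())
        d = int((~is_spec & ~has).sum())
        try:
            results.append(fisher_2x2(a, b, c, d, label=name))
        except ValueError:
            continue  # combination absent from every loop
    return results


def motif_enrichment(
    group_loops: pd.Index,
    all_loops: pd.DataFrame,
    anchors: AnchorSet,
    motif_tracks: dict,
    min_cell: int = 5,
) -> pd.DataFrame:
    """Per-TF motif enrichment at group-specific loop ends.

    TFs with any 2x2 cell below ``min_cell`` are excluded; BH adjusts across
    the TFs actually tested.
    """
    ends = loop_end_table(all_loops)
    is_spec = ends["loop"].isin(group_loops).to_numpy()
    anchor_ids = ends["anchor"].to_numpy()
    rows = []
    for tf, track in motif_tracks.items():
        hit = overlaps_any(anchors.track, track)[anchor_ids]
        a = int((is_spec & hit).sum())
        b = int((is_spec & ~hit).sum())
        c = int((~is_spec & hit).sum())
        d = int((~is_spec & ~hit).sum())
        if min(a, b, c, d) < min_cell:
            continue
        r = fisher_2x2(a, b, c, d, label=tf)
        rows.append({"tf": tf, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": r.odds_ratio, "p": r.p})
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    return out


def gene_connectivity_enrichment(
    gene_list,
    promoter_loop_counts: pd.Series,
    x_range=range(1, 11),
) -> pd.DataFrame:
    """Enrichment of a gene list among genes with >= X promoter-linked loops.

    ``promoter_loop_counts`` maps every annotated gene to its promoter loop
    degree (zeros included).  One Fisher test per X, BH-adjusted across X.
    """
    genes = promoter_loop_counts.index
    in_list = genes.isin(pd.Index(gene_list))
    if not in_list.any():
        raise ValueError("gene list is disjoint from the annotation")
    counts = promoter_loop_counts.to_numpy()
    rows = []
    for x in x_range:
        has = counts >= x
        a = int((in_list & has).sum())
        b = int((in_list & ~has).sum())
        c = int((~in_list & has).sum())
        d = int((~in_list & ~has).sum())
        if c + d == 0 or a + b == 0:
            # the list covers all (or no) genes: no information, OR = 1
            rows.append({"x": x, "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": 1.0, "log2_odds_ratio": 0.0, "p": 1.0})
            continue
        r = fisher_2x2(a, b, c, d, label=f"X>={x}")
        rows.append({"x": x, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": r.odds_ratio,
                     "log2_odds_ratio": r.log2_odds_ratio, "p": r.p})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    return out


def aggregate_signal_at_motifs(
    signal: dict,
    motif_track: FeatureTrack,
    flank_bp: int,
    anchor_subset: FeatureTrack | None = None,
) -> dict:
    """Average a per-bp signal across motif-centred windows.

    ``signal`` maps chromosome name to a per-bp numpy array.  Windows are
    centred on motif midpoints, reversed for '-'-strand motifs, and averaged
    elementwise into a profile of length 2*flank_bp + 1.  With
    ``anchor_subset`` only motifs falling inside those intervals contribute.
    Windows exceeding chromosome bounds are skipped and counted.
    """
    df = motif_track.df
    if anchor_subset is not None:
        keep = overlaps_any(motif_track, anchor_subset)
        df = df.loc[keep]
    profile = np.zeros(2 * flank_bp + 1)
    n_used = 0
    n_skipped = 0
    for row in df.itertuples(index=False):
        sig = signal.get(row.chrom)
        if sig is None:
            n_skipped += 1
            continue
        mid = (row.start + row.end) // 2
        lo, hi = mid - flank_bp, mid + flank_bp + 1
        if lo < 0 or hi > len(sig):
            n_skipped += 1
            continue
        win = sig[lo:hi]
        if row.strand == "-":
            win = win[::-1]
        profile += win
        n_used += 1
    if n_used:
        profile /= n_used
    return {"profile": profile, "n_motifs": n_used, "n_skipped": n_skipped}
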