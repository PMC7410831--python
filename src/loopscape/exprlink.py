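"""Loop-to-gene maps and loop-expression / loop-splicing coupling.

Genes map to loops under four geometric schemes (all / promoter /
contained / promoter-enhancer); loop interaction frequencies are then
correlated with gene expression across cell types against a
mapping-shuffled null, gene pairs sharing a loop are tested for
co-expression, linked-enhancer dose effects on expression are tabulated,
and intragenic promoter-to-gene-body loops are coupled to exon usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import fisher_2x2
from .intervals import FeatureTrack, overlaps_any


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list  # ordered (start, end) tuples
    biotype: str = "protein_coding"

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def n_middle_exons(self) -> int:
        return max(len(self.exons) - 2, 0)

    def exon_five_prime(self, i: int) -> int:
        s, e = self.exons[i]
        return s if self.strand == "+" else e


def genes_from_table(df: pd.DataFrame) -> list:
    """Build GeneModel objects from the reduced gene/exon table (row = exon)."""
    genes = []
    for gid, sub in df.groupby("gene_id", sort=True):
        first = sub.iloc[0]
        exons = list(zip(sub["exon_start"].astype(int), sub["exon_end"].astype(int)))
        genes.append(GeneModel(gid, first["chrom"], first["strand"],
                               int(first["start"]), int(first["end"]), exons,
                               first.get("biotype", "protein_coding")))
    return genes


def promoter_track(genes, upstream_bp: int = 500, downstream_bp: int = 0) -> FeatureTrack:
    """Strand-aware promoter windows immediately upstream of each TSS."""
    rows = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - upstream_bp, g.tss + max(downstream_bp, 1)
        else:
            s, e = g.tss - max(downstream_bp, 1), g.tss + upstream_bp
        rows.append((g.chrom, max(s, 0), e, g.strand, g.gene_id, 0.0))
    return FeatureTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label", "score"]))


# ---------------------------------------------------------------------------
# loop <-> gene maps
# ---------------------------------------------------------------------------

def _interval_distance(point: int, start: int, end: int) -> int:
    if start <= point < end:
        return 0
    return start - point if point < start else point - end + 1


MAP_SCHEMES = ("all", "promoter", "contained", "promoter_enhancer")


def map_loops_to_genes(
    loops: pd.DataFrame,
    anchors,
    genes,
    enhancer_track: FeatureTrack | None = None,
    scheme: str = "promoter",
    near_bp: int = 1000,
) -> pd.DataFrame:
    """(loop, gene) pairs under one of the four geometric mapping schemes.

    * all: the gene body, padded by ``near_bp``, overlaps the loop interval
      (outer anchor edge to outer anchor edge).
    * promoter: the TSS lies within ``near_bp`` of either anchor interval.
    * contained: the gene body lies entirely inside the loop interval and
      the TSS is more than ``near_bp`` from both anchors.
    * promoter_enhancer: the promoter rule holds at one anchor and the other
      anchor overlaps an enhancer peak.
    """
    if scheme not in MAP_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "promoter_enhancer" and enhancer_track is None:
        raise ValueError("promoter_enhancer scheme needs an enhancer track")
    adf = anchors.track.df
    a_ids = loops["anchor_a"].to_numpy()
    b_ids = loops["anchor_b"].to_numpy()
    a_start = adf["start"].to_numpy()[a_ids]
    a_end = adf["end"].to_numpy()[a_ids]
    b_start = adf["start"].to_numpy()[b_ids]
    b_end = adf["end"].to_numpy()[b_ids]
    chrom = adf["chrom"].to_numpy()[a_ids]
    loop_lo, loop_hi = a_start, b_end
    if enhancer_track is not None:
        anchor_enh = overlaps_any(anchors.track, enhancer_track)
    pairs = []
    for g in genes:
        on_chrom = np.nonzero(chrom == g.chrom)[0]
        if len(on_chrom) == 0:
            continue
        lo, hi = loop_lo[on_chrom], loop_hi[on_chrom]
        asr, aer = a_start[on_chrom], a_end[on_chrom]
        bsr, ber = b_start[on_chrom], b_end[on_chrom]
        tss = g.tss
        d_a = np.where((asr <= tss) & (tss < aer), 0,
                       np.where(tss < asr, asr - tss, tss - aer + 1))
        d_b = np.where((bsr <= tss) & (tss < ber), 0,
                       np.where(tss < bsr, bsr - tss, tss - ber + 1))
        prom_a = d_a <= near_bp
        prom_b = d_b <= near_bp
        if scheme == "all":
            hit = (g.start - near_bp < hi) & (g.end + near_bp > lo)
        elif scheme == "promoter":
            hit = prom_a | prom_b
        elif scheme == "contained":
            inside = (g.start >= lo) & (g.end <= hi)
            hit = inside & (d_a > near_bp) & (d_b > near_bp)
        else:  # promoter_enhancer
            enh_a = anchor_enh[a_ids[on_chrom]]
            enh_b = anchor_enh[b_ids[on_chrom]]
            hit = (prom_a & enh_b) | (prom_b & enh_a)
        for li in on_chrom[hit]:
            pairs.append((loops.index[li], g.gene_id))
    out = pd.DataFrame(pairs, columns=["loop_id", "gene_id"]).drop_duplicates()
    out["scheme"] = scheme
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# loop-expression correlation
# ---------------------------------------------------------------------------

def average_replicates(matrix: pd.DataFrame, samples) -> pd.DataFrame:
    """Average sample columns into one column per cell type."""
    cell_of = samples.cell_type_of()
    cols = [c for c in matrix.columns if c in cell_of]
    grouped = matrix[cols].T.groupby([cell_of[c] for c in cols]).mean().T
    return grouped


def _standardized_ranks(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks standardized to zero mean / unit ddof-1 norm."""
    R = stats.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    denom = np.sqrt((R**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = R / denom[:, None]
    return Z


def loop_expression_correlation(
    normM: pd.DataFrame,
    expression: pd.DataFrame,
    mapping: pd.DataFrame,
    samples=None,
    n_shuffles: int = 100,
    seed: int = 0,
    average_by_cell_type: bool = True,
) -> dict:
    """Spearman coupling of loop interaction frequency and gene expression.

    Correlations run across cell types (replicates averaged by default).
    The null shuffles the gene column of the mapping (preserving each loop's
    gene multiplicity) ``n_shuffles`` times.  Positive/negative coefficient
    counts for real vs shuffled pairs are compared by Fisher's exact test.
    """
    if average_by_cell_type:
        if samples is None:
            raise ValueError("averaging needs the sample sheet")
        normM = average_replicates(normM, samples)
        expression = average_replicates(expression, samples)
    shared = [c for c in normM.columns if c in expression.columns]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared cell types, got {len(shared)}")
    normM = normM[shared]
    expression = expression[shared]
    mapping = mapping[
        mapping["loop_id"].isin(normM.index) & mapping["gene_id"].isin(expression.index)
    ].reset_index(drop=True)
    loop_pos = pd.Index(normM.index).get_indexer(mapping["loop_id"])
    gene_pos = pd.Index(expression.index).get_indexer(mapping["gene_id"])
    ZL = _standardized_ranks(normM.to_numpy(dtype=float))
    ZG = _standardized_ranks(expression.to_numpy(dtype=float))
    real_rho = (ZL[loop_pos] * ZG[gene_pos]).sum(axis=1)
    ok = np.isfinite(real_rho)
    n_dropped = int((~ok).sum())

    rng = np.random.default_rng(seed)
    null_mean_abs = np.empty(n_shuffles)
    null_pos = 0
    null_neg = 0
    null_rho_mean = np.zeros(len(mapping))
    for s in range(n_shuffles):
        perm = rng.permutation(len(gene_pos))
        rho = (ZL[loop_pos] * ZG[gene_pos[perm]]).sum(axis=1)
        okn = np.isfinite(rho)
        null_mean_abs[s] = np.abs(rho[okn]).mean()
        null_pos += int((rho[okn] > 0).sum())
        null_neg += int((rho[okn] < 0).sum())
        null_rho_mean += np.nan_to_num(rho, nan=0.0)
    null_rho_mean /= n_shuffles

    pos = int((real_rho[ok] > 0).sum())
    neg = int((real_rho[ok] < 0).sum())
    sign_test = fisher_2x2(pos, neg, null_pos, null_neg, label="positive-correlation")
    out_pairs = mapping.copy()
    out_pairs["rho"] = real_rho
    out_pairs["null_mean_rho"] = null_rho_mean
    return {
        "pairs": out_pairs,
        "real_mean_abs_rho": float(np.abs(real_rho[ok]).mean()),
        "null_mean_abs_rho": float(null_mean_abs.mean()),
        "sign_test": sign_test,
        "n_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# co-expression of genes sharing a loop
# ---------------------------------------------------------------------------

def coexpression_in_loops(
    genes,
    loops: pd.DataFrame,
    anchors,
    variable_loops,
    expression: pd.DataFrame,
    samples=None,
    n_bins: int = 10,
    span_range=(10_000, 5_000_000),
    max_control_pairs: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median co-expression of gene pairs sharing a loop vs distance-matched
    pairs that do not, per TSS-distance bin."""
    if samples is not None:
        expression = average_replicates(expression, samples)
    genes = [g for g in genes if g.gene_id in expression.index]
    adf = anchors.track.df
    lo = adf["start"].to_numpy()[loops["anchor_a"].to_numpy()]
    hi = adf["end"].to_numpy()[loops["anchor_b"].to_numpy()]
    lchrom = adf["chrom"].to_numpy()[loops["anchor_a"].to_numpy()]
    var_mask = loops.index.isin(pd.Index(variable_loops))

    gene_loops = {}
    for gi, g in enumerate(genes):
        on = (lchrom == g.chrom) & (lo <= g.start) & (g.end <= hi)
        gene_loops[gi] = set(np.nonzero(on)[0])

    ZG = _standardized_ranks(expression.to_numpy(dtype=float))
    gidx = pd.Index(expression.index)
    edges = np.geomspace(span_range[0], span_range[1], n_bins + 1)
    rng = np.random.default_rng(seed)

    rows = []
    n_genes = len(genes)
    by_chrom: dict[str, list] = {}
    for gi, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(gi)
    for chrom, idxs in by_chrom.items():
        for ii in range(len(idxs)):
            for jj in range(ii + 1, len(idxs)):
                gi, gj = idxs[ii], idxs[jj]
                g1, g2 = genes[gi], genes[gj]
                dist = abs(g1.tss - g2.tss)
                if not (span_range[0] < dist < span_range[1]):
                    continue
                shared = gene_loops[gi] & gene_loops[gj]
                cat = "not_same_loop"
                if shared:
                    cat = "same_variable_loop" if any(var_mask[k] for k in shared) else "same_loop"
                p1 = gidx.get_loc(g1.gene_id)
                p2 = gidx.get_loc(g2.gene_id)
                rho = float((ZG[p1] * ZG[p2]).sum())
                rows.append((dist, cat, rho))
    df = pd.DataFrame(rows, columns=["distance", "category", "rho"])
    df["bin"] = np.clip(np.digitize(df["distance"], edges) - 1, 0, n_bins - 1)
    med = (
        df.groupby(["bin", "category"])["rho"]
        .agg(["median", "count"])
        .reset_index()
        .rename(columns={"median": "median_rho", "count": "n_pairs"})
    )
    return med


# ---------------------------------------------------------------------------
# enhancer dose response
# ---------------------------------------------------------------------------

def count_linked_specific_enhancers(
    specific_loops: pd.DataFrame,
    anchors,
    genes,
    specific_genes,
    specific_enhancers: FeatureTrack,
    near_bp: int = 1000,
) -> pd.Series:
    """Number of cell-type-specific enhancers linked to each specific gene's
    promoter through cell-type-specific loops."""
    gene_objs = [g for g in genes if g.gene_id in set(specific_genes)]
    prom_map = map_loops_to_genes(specific_loops, anchors, gene_objs, scheme="promoter",
                                  near_bp=near_bp)
    anchor_enh = overlaps_any(anchors.track, specific_enhancers)
    counts = {g.gene_id: 0 for g in gene_objs}
    adf = anchors.track.df
    by_gene = prom_map.groupby("gene_id")["loop_id"]
    loop_rows = specific_loops.loc[:, ["anchor_a", "anchor_b"]]
    for g in gene_objs:
        if g.gene_id not in by_gene.groups:
            continue
        linked = set()
        for lid in by_gene.get_group(g.gene_id):
            a = loop_rows.at[lid, "anchor_a"]
            b = loop_rows.at[lid, "anchor_b"]
            # the far (non-promoter) end must carry a specific enhancer
            da = _interval_distance(g.tss, adf.at[a, "start"], adf.at[a, "end"])
            db = _interval_distance(g.tss, adf.at[b, "start"], adf.at[b, "end"])
            far = b if da <= db else a
            if anchor_enh[far]:
                linked.add(far)
        counts[g.gene_id] = len(linked)
    return pd.Series(counts, name="n_linked_enhancers")


def enhancer_dose_response(records: pd.DataFrame) -> dict:
    """Expression by linked-enhancer count bins {1, 2, 3+} with rank-sum tests.

    ``records`` needs columns ``n_linked_enhancers`` and ``expression`` (one
    row per gene x cell type); genes with zero linked enhancers are
    excluded from the comparison.
    """
    rec = records[records["n_linked_enhancers"] >= 1].copy()
    rec["bin"] = np.where(rec["n_linked_enhancers"] >= 3, "3+",
                          rec["n_linked_enhancers"].astype(int).astype(str))
    tests = []
    bins = ["1", "2", "3+"]
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            x = rec.loc[rec["bin"] == bins[i], "expression"]
            y = rec.loc[rec["bin"] == bins[j], "expression"]
            if len(x) < 2 or len(y) < 2:
                continue
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            tests.append({"bins": f"{bins[i]} vs {bins[j]}", "p": float(p)})
    medians = rec.groupby("bin")["expression"].median().reindex(bins)
    return {"table": rec, "medians": medians, "tests": pd.DataFrame(tests)}


# ---------------------------------------------------------------------------
# intragenic loops and exon coupling
# ---------------------------------------------------------------------------

def find_intragenic_loops(
    genes,
    loops: pd.DataFrame,
    anchors,
    cage_track: FeatureTrack | None = None,
    promoter_bp: int = 1000,
    upstream_bp: int = 5000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Promoter-to-gene-body loops within single genes.

    Considers protein-coding genes with at least one middle exon; exons
    overlapping CAGE peaks are removed.  A loop qualifies when one anchor
    overlaps the promoter window (TSS +/- ``promoter_bp``) and the other
    overlaps the upstream window (``upstream_bp`` bp promoter-ward of a
    non-first exon's 5' boundary) of the same gene.  The matched exon index
    is recorded.
    """
    adf = anchors.track.df
    a_ids = loops["anchor_a"].to_numpy()
    b_ids = loops["anchor_b"].to_numpy()
    a_start, a_end = adf["start"].to_numpy()[a_ids], adf["end"].to_numpy()[a_ids]
    b_start, b_end = adf["start"].to_numpy()[b_ids], adf["end"].to_numpy()[b_ids]
    chrom = adf["chrom"].to_numpy()[a_ids]
    rows = []
    for g in genes:
        if g.biotype != "protein_coding" or g.n_middle_exons < 1:
            continue
        exon_idx = list(range(len(g.exons)))
        if cage_track is not None and len(cage_track):
            etrack = FeatureTrack(pd.DataFrame(
                [(g.chrom, s, e) for s, e in g.exons], columns=["chrom", "start", "end"]))
            # FeatureTrack sorts; exons are already sorted so order is stable
            cage_hit = overlaps_any(etrack, cage_track)
            exon_idx = [i for i in exon_idx if not cage_hit[i]]
        prom_lo, prom_hi = g.tss - promoter_bp, g.tss + promoter_bp
        on = chrom == g.chrom
        prom_a = on & (a_start < prom_hi) & (a_end > prom_lo)
        prom_b = on & (b_start < prom_hi) & (b_end > prom_lo)
        first_exon = 0 if g.strand == "+" else len(g.exons) - 1
        for ei in exon_idx:
            if ei == first_exon:
                continue
            fp = g.exon_five_prime(ei)
            if strand_aware:
                win = (fp - upstream_bp, fp) if g.strand == "+" else (fp, fp + upstream_bp)
            else:
                win = (fp - upstream_bp, fp)
            up_a = on & (a_start < win[1]) & (a_end > win[0])
            up_b = on & (b_start < win[1]) & (b_end > win[0])
            hit = (prom_a & up_b) | (prom_b & up_a)
            for li in np.nonzero(hit)[0]:
                body_anchor = b_ids[li] if (prom_a & up_b)[li] else a_ids[li]
                rows.append((loops.index[li], g.gene_id, ei, int(body_anchor)))
    out = pd.DataFrame(rows, columns=["loop_id", "gene_id", "exon_index", "body_anchor"])
    return out.drop_duplicates().reset_index(drop=True)


def exon_loop_correlation(
    exon_counts: pd.DataFrame,
    anchor_counts: pd.DataFrame,
    intragenic: pd.DataFrame,
    genes,
    anchors,
    due_flags: pd.Series | None = None,
    pair_bp: int = 5000,
    exclusion_bp: int = 20_000,
    n_perm: int = 100,
    seed: int = 0,
    min_obs: int = 5,
) -> dict:
    """Correlation of exon usage with intragenic-loop anchor strength.

    Real pairs match an exon to the gene-body anchor of an intragenic loop
    when their 5' boundaries lie within ``pair_bp``.  Controls are the other
    exons of the looping gene outside ``exclusion_bp`` of the anchor centre.
    The permutation null reshuffles exon identity among real pairs
    ``n_perm`` times.  Exon ids follow the convention ``geneid:exonindex``.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    adf = anchors.track.df
    shared = [c for c in exon_counts.columns if c in anchor_counts.columns]
    if len(shared) < min_obs:
        raise ValueError(f"need >= {min_obs} shared samples")
    E = exon_counts[shared]
    A = anchor_counts[shared]

    real_pairs = []
    control_pairs = []
    for row in intragenic.itertuples(index=False):
        g = gene_by_id.get(row.gene_id)
        if g is None:
            continue
        anchor_id = row.body_anchor
        if anchor_id not in A.index:
            continue
        a_start, a_end = int(adf.at[anchor_id, "start"]), int(adf.at[anchor_id, "end"])
        anchor_fp = a_start if g.strand == "+" else a_end
        anchor_centre = (a_start + a_end) // 2
        for ei in range(len(g.exons)):
            exon_id = f"{g.gene_id}:{ei}"
            if exon_id not in E.index:
                continue
            if due_flags is not None and not bool(due_flags.get(exon_id, False)):
                continue
            fp = g.exon_five_prime(ei)
            if abs(fp - anchor_fp) <= pair_bp:
                real_pairs.append((exon_id, anchor_id))
            elif abs(fp - anchor_centre) > exclusion_bp:
                control_pairs.append((exon_id, anchor_id))
    real_pairs = sorted(set(real_pairs))
    control_pairs = sorted(set(control_pairs))

    def _corr(pairs):
        vals = []
        for exon_id, anchor_id in pairs:
            x = E.loc[exon_id].to_numpy(dtype=float)
            y = A.loc[anchor_id].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_obs or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            vals.append(float(stats.pearsonr(x[ok], y[ok]).statistic))
        return np.asarray(vals)

    real_r = _corr(real_pairs)
    control_r = _corr(control_pairs)
    rng = np.random.default_rng(seed)
    exon_ids = [p[0] for p in real_pairs]
    anchor_ids = [p[1] for p in real_pairs]
    perm_means = np.empty(n_perm)
    for s in range(n_perm):
        perm = rng.permutation(len(exon_ids))
        rs = _corr(list(zip([exon_ids[i] for i in perm], anchor_ids)))
        perm_means[s] = rs.mean() if len(rs) else np.nan
    return {
        "real_r": real_r,
        "control_r": control_r,
        "perm_mean_r": perm_means,
        "n_real_pairs": len(real_pairs),
        "n_control_pairs": len(control_pairs),
    }
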