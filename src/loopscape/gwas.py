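"""LD-aware GWAS SNP enrichment in loop-anchor region sets.

SNP tables carry one row per SNP with an LD-cluster id and its r-squared to
the cluster lead.  Pruning keeps the most significant SNP per cluster;
overlap of a pruned SNP with a region set is delegated to the SNP itself or
any cluster mate with r2 >= 0.8 (the proxies).  Enrichment is a binned rank
fold change (bins of 50, 100, 200, 400 top pruned SNPs, then quartiles of
the remaining p-value distribution) against a permutation null over the
per-SNP p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, fisher_2x2
from .intervals import FeatureTrack, assign_points_to_disjoint, merge_intervals

GW_THRESHOLD_LITERAL = 1e-7     # the printed genome-wide cut, 10 x 10^-8
GW_THRESHOLD_CONVENTIONAL = 5e-8


def prune_and_expand(
    snps: pd.DataFrame,
    r2_min: float = 0.8,
    min_snps: int = 1000,
) -> pd.DataFrame:
    """One SNP per LD cluster (minimum p; ties by snp_id) with proxy positions.

    Studies with fewer than ``min_snps`` pruned SNPs are dropped.  The output
    has one row per pruned SNP, with ``proxy_pos`` holding the positions of
    the SNP itself plus cluster mates at r2 >= ``r2_min``.
    """
    out = []
    for study, sdf in snps.groupby("study_id", sort=True):
        sdf = sdf.sort_values(["p_value", "snp_id"], kind="mergesort")
        leads = sdf.drop_duplicates(subset="ld_cluster", keep="first")
        if len(leads) < min_snps:
            continue
        # LD clusters are intra-chromosomal: proxies share the lead's chrom
        proxy_pos = {}
        eligible = sdf[sdf["r2_to_lead"] >= r2_min]
        for cluster, cdf in eligible.groupby("ld_cluster", sort=False):
            proxy_pos[cluster] = cdf["pos"].to_numpy(dtype=np.int64)
        leads = leads.copy()
        leads["proxy_pos"] = [
            np.unique(np.append(proxy_pos.get(c, np.empty(0, np.int64)), p)).astype(np.int64)
            for c, p in zip(leads["ld_cluster"], leads["pos"])
        ]
        out.append(leads)
    if not out:
        return snps.iloc[0:0].assign(proxy_pos=None)
    return pd.concat(out, ignore_index=True)


def _snp_overlap_flags(pruned: pd.DataFrame, regions: FeatureTrack) -> np.ndarray:
    """Per pruned SNP: does it or any proxy lie inside a region?"""
    merged = merge_intervals(regions)
    flags = np.zeros(len(pruned), dtype=bool)
    all_chroms = []
    all_pos = []
    owner = []
    for i, row in enumerate(pruned.itertuples(index=False)):
        pp = np.atleast_1d(row.proxy_pos)
        all_pos.append(pp)
        all_chroms.append(np.repeat(row.chrom, len(pp)))
        owner.append(np.full(len(pp), i))
    if not all_pos:
        return flags
    pos = np.concatenate(all_pos)
    chroms = np.concatenate(all_chroms).astype(object)
    owner = np.concatenate(owner)
    hit = assign_points_to_disjoint(chroms, pos, merged) >= 0
    np.logical_or.at(flags, owner[hit], True)
    return flags


def _bin_sizes(n: int, base: int = 50) -> list:
    """Cumulative rank cutoffs: 50, 150, 350, 750, then remaining quartiles."""
    cuts = []
    for mult in (1, 2, 4, 8):
        nxt = (cuts[-1] if cuts else 0) + base * mult
        if nxt >= n:
            break
        cuts.append(nxt)
    start = cuts[-1] if cuts else 0
    remaining = n - start
    if remaining > 0:
        for qq in (0.25, 0.5, 0.75, 1.0):
            cuts.append(start + int(round(qq * remaining)))
    return sorted(set(c for c in cuts if 0 < c <= n))


def binned_rank_enrichment(
    pruned: pd.DataFrame,
    regions: FeatureTrack,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Binned rank fold-change enrichment with a permutation empirical p.

    For each cumulative p-value bin (thresholds set on the pruned SNPs), the
    fold change is the fraction of bin SNPs overlapping the regions divided
    by the fraction of all pruned study SNPs overlapping.  The empirical p
    counts permutations of the per-SNP p-values whose top-bin fold reaches
    the observed one, with add-one smoothing.
    """
    pruned = pruned.sort_values(["p_value", "snp_id"], kind="mergesort").reset_index(drop=True)
    n = len(pruned)
    flags = _snp_overlap_flags(pruned, regions)
    base_frac = flags.mean()
    if base_frac == 0:
        raise ValueError("no pruned SNP overlaps the regions; fold change undefined")
    cuts = _bin_sizes(n)
    feasible = n >= 750
    folds = []
    cum = np.cumsum(flags)
    for c in cuts:
        folds.append((cum[c - 1] / c) / base_frac)
    top_cut = cuts[0]
    obs_top = folds[0]

    rng = np.random.default_rng(seed)
    # permuting p-values is equivalent to drawing the top bin uniformly
    exceed = 0
    perm_tops = np.empty(n_perm)
    for s in range(n_perm):
        pick = rng.choice(n, size=top_cut, replace=False)
        perm_tops[s] = flags[pick].mean() / base_frac
    exceed = int((perm_tops >= obs_top).sum())
    emp_p = (1 + exceed) / (n_perm + 1)
    return {
        "bins": pd.DataFrame({"cum_rank": cuts, "fold": folds}),
        "top_bin_fold": float(obs_top),
        "empirical_p": float(emp_p),
        "base_frac": float(base_frac),
        "feasible": feasible,
        "perm_top_folds": perm_tops,
    }


def relative_enrichment(
    regions_a: FeatureTrack,
    regions_b: FeatureTrack,
    pruned: pd.DataFrame,
    gw_threshold: float = GW_THRESHOLD_LITERAL,
) -> EnrichmentResult:
    """Fisher comparison of genome-wide-significant SNP overlap between two
    region sets (overlap counts the pruned SNP or any proxy)."""
    if len(regions_a) == 0 or len(regions_b) == 0:
        raise ValueError("both region sets must be non-empty")
    gw = pruned[pruned["p_value"] < gw_threshold].reset_index(drop=True)
    if len(gw) == 0:
        raise ValueError("no genome-wide-significant pruned SNPs")
    fa = _snp_overlap_flags(gw, regions_a)
    fb = _snp_overlap_flags(gw, regions_b)
    a = int(fa.sum())
    b = int(len(gw) - a)
    c = int(fb.sum())
    d = int(len(gw) - c)
    return fisher_2x2(a, b, c, d, label="regions_a_vs_b")
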