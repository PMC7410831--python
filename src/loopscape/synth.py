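"""Synthetic cohesin ChIA-PET study generator with planted ground truth.

Emulates, at desk scale, the data a multi-cell-type cohesin ChIA-PET study
produces: disjoint anchor regions with log-normal ChIP efficiencies,
candidate anchor pairs inside the (10 kb, 5 Mb) span window, a designated
subset of true contact loops with power-law distance decay, negative-
binomially dispersed per-sample PET counts with planted cell-type and
group effects, convergently oriented CTCF motifs at loop anchors,
degree-biased enhancer placement, chromatin-state tracks, loop-coupled
gene expression, intragenic promoter-to-gene-body loops coupled to exon
counts, and GWAS SNP panels with planted anchor-overlap enrichment.

Every stage draws from named substreams of one master seed, so full
regeneration under the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import FeatureTrack
from .io import SampleSheet
from .loopcall import AnchorSet

GROUPS = ("blood", "embryonic", "solid")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults are desk-scale: 2 chromosomes x 20 Mb, 400 anchors, 5,000 true
    loops, 6 cell types (2 per group) x 2 replicates, 500k PETs per sample.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_anchors: int = 400
    anchor_width: int = 2000
    n_true_loops: int = 5000
    n_cell_types_per_group: int = 2
    n_replicates: int = 2
    library_depth: int = 500_000
    decay_exponent: float = 1.0        # alpha in d**-alpha
    nb_dispersion: float = 0.01        # phi; var = mu + phi * mu^2
    background_rate: float = 0.05      # candidate-pair weight relative to true loops
    efficiency_sigma: float = 0.5      # log-normal sigma of anchor efficiency
    frac_variable: float = 0.10
    frac_group_specific: float = 0.04  # per group
    effect_size: float = 3.0           # multiplicative fold in target cells
    motif_convergent_frac: float = 0.72
    motif_loop_frac: float = 0.8
    double_motif_anchor_frac: float = 0.05
    expr_coupling: float = 0.8         # beta in [0, 1]
    exon_coupling: float = 0.8         # gamma in [0, 1]
    gwas_planted_frac: float = 0.5
    n_genes: int = 300
    n_gwas_clusters: int = 1100
    min_span: int = 10_000
    max_span: int = 5_000_000
    exclusive_loop_anchors: bool = False  # true loops claim dedicated anchors

    def __post_init__(self):
        for name in ("frac_variable", "frac_group_specific", "motif_convergent_frac",
                     "motif_loop_frac", "expr_coupling", "exon_coupling",
                     "gwas_planted_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def cell_types(self) -> list:
        return [f"{g}{k}" for g in GROUPS for k in range(1, self.n_cell_types_per_group + 1)]

    def streams(self) -> dict:
        names = ["anchors", "loops", "truth", "motifs", "counts", "genes",
                 "expression", "enhancers", "states", "exons", "gwas", "pets"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TruthTables:
    loops: pd.DataFrame        # per true loop: variable, target_cell, group
    genes: pd.DataFrame        # per gene: class, target_cell, coupled_loop
    exon_pairs: pd.DataFrame   # gene_id, exon_index, loop_id, body_anchor
    snps: pd.DataFrame         # study_id, planted flag per cluster lead


@dataclass
class SyntheticDataset:
    config: SynthConfig
    anchors: AnchorSet
    candidates: pd.DataFrame   # anchor_a, anchor_b, span, is_true
    sample_sheet: SampleSheet
    counts: pd.DataFrame       # candidates x samples raw PET counts
    motif_track: FeatureTrack
    truth: TruthTables
    annotations: dict = field(default_factory=dict)
    gwas_tables: pd.DataFrame | None = None

    @property
    def true_loops(self) -> pd.DataFrame:
        return self.candidates[self.candidates["is_true"]]

    @property
    def true_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.truth.loops.index]


# ---------------------------------------------------------------------------
# anchors, candidates, true loops, motifs
# ---------------------------------------------------------------------------

def _chrom_names(config) -> list:
    return [f"chr{i+1}" for i in range(config.n_chroms)]


def generate_anchors_and_loops(config: SynthConfig, rngs: dict | None = None):
    """Anchors on a jittered grid, all in-window candidate pairs, and a
    distance-decay-weighted true-loop subset.

    Returns ``(anchors, candidates)`` where candidates carry columns
    anchor_a / anchor_b / span / is_true.
    """
    rngs = rngs or config.streams()
    rng = rngs["anchors"]
    per_chrom = np.full(config.n_chroms, config.n_anchors // config.n_chroms)
    per_chrom[: config.n_anchors % config.n_chroms] += 1
    rows = []
    for chrom, m in zip(_chrom_names(config), per_chrom):
        spacing = config.chrom_length / (m + 1)
        if spacing <= config.anchor_width * 2:
            raise ValueError(
                f"chromosome too short for {m} anchors of width {config.anchor_width}")
        centres = (np.arange(1, m + 1) * spacing
                   + rng.uniform(-0.25, 0.25, size=m) * spacing).astype(np.int64)
        half = config.anchor_width // 2
        for c in centres:
            rows.append((chrom, int(c - half), int(c + half)))
    track = FeatureTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    efficiency = rng.lognormal(mean=0.0, sigma=config.efficiency_sigma, size=len(track))
    anchors = AnchorSet(track, efficiency=efficiency)

    mids = anchors.midpoints
    chroms = anchors.chroms
    a_list, b_list = [], []
    for chrom in np.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        m = mids[idx]
        for ii in range(len(idx)):
            lo = np.searchsorted(m, m[ii] + config.min_span, side="right")
            hi = np.searchsorted(m, m[ii] + config.max_span, side="left")
            a_list.append(np.full(hi - lo, idx[ii]))
            b_list.append(idx[lo:hi])
    anchor_a = np.concatenate(a_list)
    anchor_b = np.concatenate(b_list)
    span = mids[anchor_b] - mids[anchor_a]
    candidates = pd.DataFrame({"anchor_a": anchor_a, "anchor_b": anchor_b, "span": span})

    loop_rng = rngs["loops"]
    n_true = min(config.n_true_loops, len(candidates))
    w = span.astype(float) ** -config.decay_exponent
    is_true = np.zeros(len(candidates), dtype=bool)
    if config.exclusive_loop_anchors:
        # decay-weighted greedy matching: each anchor hosts at most one loop
        order = loop_rng.choice(len(candidates), size=len(candidates),
                                replace=False, p=w / w.sum())
        used = np.zeros(config.n_anchors, dtype=bool)
        taken = 0
        for ci in order:
            a, b = anchor_a[ci], anchor_b[ci]
            if used[a] or used[b]:
                continue
            used[a] = used[b] = True
            is_true[ci] = True
            taken += 1
            if taken >= n_true:
                break
    else:
        pick = loop_rng.choice(len(candidates), size=n_true, replace=False, p=w / w.sum())
        is_true[pick] = True
    candidates["is_true"] = is_true
    return anchors, candidates


def plant_loop_truth(config: SynthConfig, candidates: pd.DataFrame,
                     rngs: dict | None = None) -> pd.DataFrame:
    """Assign variable / group-specific flags to true loops.

    Exactly round(frac_variable * n_true) loops get a target cell type
    (balanced across cells) and round(frac_group_specific * n_true) loops
    per group get a group flag; the sets are disjoint.
    """
    rngs = rngs or config.streams()
    rng = rngs["truth"]
    true_ids = candidates.index[candidates["is_true"]].to_numpy()
    n_true = len(true_ids)
    n_var = int(round(config.frac_variable * n_true))
    n_grp = int(round(config.frac_group_specific * n_true))
    perm = rng.permutation(true_ids)
    var_ids = perm[:n_var]
    cells = config.cell_types
    target_cell = np.array([cells[i % len(cells)] for i in range(n_var)], dtype=object)
    cursor = n_var
    group_of = {}
    for g in GROUPS:
        for lid in perm[cursor: cursor + n_grp]:
            group_of[lid] = g
        cursor += n_grp
    flags = pd.DataFrame(index=pd.Index(true_ids, name="loop_id"))
    flags["variable"] = flags.index.isin(var_ids)
    tc = pd.Series("", index=flags.index, dtype=object)
    tc.loc[var_ids] = target_cell
    flags["target_cell"] = tc
    flags["group"] = pd.Series(group_of, dtype=object).reindex(flags.index).fillna("")
    return flags.sort_index()


def plant_ctcf_motifs(config: SynthConfig, anchors: AnchorSet,
                      candidates: pd.DataFrame, rngs: dict | None = None):
    """Place CTCF motifs at true-loop anchors with planted orientations.

    Loops are visited in a seeded random order; a loop receives motifs only
    if both its anchors are still motif-free, so every two-motif loop has an
    independently drawn orientation: convergent (+/-) with probability
    ``motif_convergent_frac``, else uniform among the other three.  A
    fraction of leftover anchors receives two motifs (excluded downstream).
    """
    rngs = rngs or config.streams()
    rng = rngs["motifs"]
    true_loops = candidates[candidates["is_true"]]
    # visit loops with low-degree anchors first: motifs planted at anchors
    # used by a single loop cannot create incidental two-motif loops with
    # mixed provenance
    deg = np.zeros(len(anchors), dtype=np.int64)
    for col in ("anchor_a", "anchor_b"):
        np.add.at(deg, true_loops[col].to_numpy(), 1)
    max_deg = np.maximum(deg[true_loops["anchor_a"].to_numpy()],
                         deg[true_loops["anchor_b"].to_numpy()])
    jitter = rng.uniform(size=len(true_loops))
    order = true_loops.index.to_numpy()[np.lexsort((jitter, max_deg))]
    anchor_used = np.zeros(len(anchors), dtype=bool)
    adf = anchors.track.df
    motif_rows = []
    orientation = {}

    def motif_at(anchor_id: int, strand: str):
        s = int(adf.at[anchor_id, "start"])
        e = int(adf.at[anchor_id, "end"])
        mid = (s + e) // 2
        motif_rows.append((adf.at[anchor_id, "chrom"], mid - 10, mid + 9, strand, "CTCF", 0.0))

    categories = ("convergent", "divergent", "tandem_plus", "tandem_minus")
    strand_pairs = {"convergent": ("+", "-"), "divergent": ("-", "+"),
                    "tandem_plus": ("+", "+"), "tandem_minus": ("-", "-")}
    c = config.motif_convergent_frac
    probs = np.array([c, (1 - c) / 3, (1 - c) / 3, (1 - c) / 3])
    for lid in order:
        a = int(true_loops.at[lid, "anchor_a"])
        b = int(true_loops.at[lid, "anchor_b"])
        if anchor_used[a] or anchor_used[b]:
            continue
        if rng.uniform() > config.motif_loop_frac:
            continue
        cat = categories[rng.choice(4, p=probs)]
        sa, sb = strand_pairs[cat]
        motif_at(a, sa)
        motif_at(b, sb)
        anchor_used[a] = anchor_used[b] = True
        orientation[lid] = cat
    free = np.nonzero(~anchor_used)[0]
    n_double = int(round(config.double_motif_anchor_frac * len(free)))
    if n_double:
        for aid in rng.choice(free, size=n_double, replace=False):
            motif_at(int(aid), "+")
            motif_at(int(aid), "-")
    track = FeatureTrack(
        pd.DataFrame(motif_rows, columns=["chrom", "start", "end", "strand", "label", "score"]),
        name="CTCF",
    )
    return track, pd.Series(orientation, name="orientation")


# ---------------------------------------------------------------------------
# sample sheet and PET counts
# ---------------------------------------------------------------------------

def make_sample_sheet(config: SynthConfig) -> SampleSheet:
    rows = []
    batch = 0
    for ct in config.cell_types:
        group = next(g for g in GROUPS if ct.startswith(g))
        for r in range(1, config.n_replicates + 1):
            rows.append({
                "sample_id": f"{ct}_r{r}", "cell_type": ct, "replicate": r,
                "group": group, "batch": f"b{(batch % 3) + 1}",
                "depth": config.library_depth,
            })
            batch += 1
    return SampleSheet(pd.DataFrame(rows))


def generate_pet_counts(
    config: SynthConfig,
    anchors: AnchorSet,
    candidates: pd.DataFrame,
    loop_truth: pd.DataFrame,
    sample_sheet: SampleSheet,
    rngs: dict | None = None,
) -> pd.DataFrame:
    """Negative-binomial PET counts for every candidate pair and sample.

    The expected count is depth * w_l * m_{l,cell} / sum_l(w_l * m_{l,cell})
    with w_l = span^-alpha * e_i * e_j * (1 for true loops, background_rate
    otherwise) and m the planted effect multiplier (effect_size for a
    variable loop in its target cell or a group loop in its group's cells).
    Replicates share the expectation.
    """
    rngs = rngs or config.streams()
    rng = rngs["counts"]
    eff = anchors.efficiency
    w = (
        candidates["span"].to_numpy(dtype=float) ** -config.decay_exponent
        * eff[candidates["anchor_a"].to_numpy()]
        * eff[candidates["anchor_b"].to_numpy()]
        * np.where(candidates["is_true"].to_numpy(), 1.0, config.background_rate)
    )
    cell_mult = {}
    for ct in config.cell_types:
        m = np.ones(len(candidates))
        var_rows = loop_truth.index[(loop_truth["target_cell"] == ct)]
        m[candidates.index.get_indexer(var_rows)] = config.effect_size
        group = next(g for g in GROUPS if ct.startswith(g))
        grp_rows = loop_truth.index[loop_truth["group"] == group]
        m[candidates.index.get_indexer(grp_rows)] = config.effect_size
        cell_mult[ct] = m
    cols = {}
    for row in sample_sheet.df.itertuples(index=False):
        m = cell_mult[row.cell_type]
        mu = row.depth * (w * m) / (w * m).sum()
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            cols[row.sample_id] = rng.negative_binomial(r, p)
        else:
            cols[row.sample_id] = rng.poisson(mu)
    return pd.DataFrame(cols, index=candidates.index)


def emit_pet_bedpe(
    config: SynthConfig,
    anchors: AnchorSet,
    candidates: pd.DataFrame,
    counts_column: pd.Series,
    rng: np.random.Generator,
    read_len: int = 100,
) -> pd.DataFrame:
    """Materialize one sample's counts as BEDPE PET endpoint records.

    Endpoint intervals are placed uniformly, fully inside their anchors, so
    re-tabulation against the same anchor set reproduces the counts exactly.
    """
    adf = anchors.track.df
    nz = counts_column[counts_column > 0]
    rows_a, rows_b = [], []
    for lid, k in nz.items():
        a = int(candidates.at[lid, "anchor_a"])
        b = int(candidates.at[lid, "anchor_b"])
        for aid, bucket in ((a, rows_a), (b, rows_b)):
            s = int(adf.at[aid, "start"])
            e = int(adf.at[aid, "end"])
            starts = rng.integers(s, max(e - read_len, s + 1), size=int(k))
            bucket.append((adf.at[aid, "chrom"], starts))
    recs = []
    i = 0
    for (ca, sa), (cb, sb) in zip(rows_a, rows_b):
        for x, y in zip(sa, sb):
            recs.append((ca, int(x), int(x) + read_len, cb, int(y), int(y) + read_len,
                         f"PET{i}", 1, "+", "-"))
            i += 1
    from .io import BEDPE_COLUMNS

    return pd.DataFrame(recs, columns=BEDPE_COLUMNS)


# ---------------------------------------------------------------------------
# regulatory annotations: genes, expression, enhancers, states, exons
# ---------------------------------------------------------------------------

def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def generate_regulatory_annotations(
    config: SynthConfig,
    anchors: AnchorSet,
    candidates: pd.DataFrame,
    loop_truth: pd.DataFrame,
    sample_sheet: SampleSheet,
    counts: pd.DataFrame,
    rngs: dict | None = None,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Gene models, expression, enhancers, states, TF motifs, exon counts.

    Returns ``(annotations, gene_truth, exon_pair_truth)``.  Couplings:
    expression of loop-coupled genes follows the loop's normalized contact
    frequency with weight ``expr_coupling``; counts of planted exons follow
    their gene-body anchor strength with weight ``exon_coupling``;
    cell-type-specific genes and enhancers sit at the anchors of loops
    planted for the same cell.
    """
    from .exprlink import GeneModel

    rngs = rngs or config.streams()
    g_rng = rngs["genes"]
    e_rng = rngs["expression"]
    enh_rng = rngs["enhancers"]
    st_rng = rngs["states"]
    ex_rng = rngs["exons"]

    adf = anchors.track.df
    mids = anchors.midpoints
    chroms = anchors.chroms
    cells = config.cell_types
    samples = sample_sheet.df
    true_loops = candidates[candidates["is_true"]]

    # per-(loop, cell) mean count to drive couplings (replicates averaged)
    true_counts = counts.loc[loop_truth.index]
    cell_means = {}
    for ct in cells:
        ids = sample_sheet.samples_of_cell(ct)
        cell_means[ct] = true_counts[ids].mean(axis=1)
    loop_cell = pd.DataFrame(cell_means)          # loops x cells
    loop_z = pd.DataFrame(_zscore_rows(np.log1p(loop_cell.to_numpy())),
                          index=loop_cell.index, columns=loop_cell.columns)

    # --- gene placement -----------------------------------------------------
    n = config.n_genes
    n_coupled = int(round(0.40 * n))
    n_intra = int(round(0.15 * n))
    n_hk = int(round(0.20 * n))
    n_spec = int(round(0.10 * n))
    gene_rows = []
    gene_truth_rows = []
    exon_pair_rows = []

    # loops suitable for gene planting: moderate span, TSS at anchor_a.
    # prefer promoter anchors with low loop degree, as real promoters have,
    # so the promoter map points mostly at the coupled loop
    deg = np.zeros(len(anchors), dtype=np.int64)
    for col in ("anchor_a", "anchor_b"):
        np.add.at(deg, true_loops[col].to_numpy(), 1)

    def by_low_degree(ids):
        ids = np.asarray(ids)
        jitter = g_rng.uniform(size=len(ids))
        a_deg = deg[true_loops.loc[ids, "anchor_a"].to_numpy()]
        return ids[np.lexsort((jitter, a_deg))]

    spans = true_loops["span"]
    intra_pool = by_low_degree(
        true_loops.index[(spans > 20_000) & (spans < 150_000)].to_numpy())
    coupled_pool = by_low_degree(
        [lid for lid in loop_truth.index if lid not in set(intra_pool[:n_intra])])
    coupled_ids = list(coupled_pool[: min(n_coupled, len(coupled_pool))])

    def add_gene(gid, chrom, strand, start, end, exons, biotype="protein_coding"):
        gene_rows.append(GeneModel(gid, chrom, strand, int(start), int(end),
                                   exons, biotype))

    gi = 0
    chrom_len = config.chrom_length
    # expression-coupled genes at true-loop promoter anchors
    for lid in coupled_ids:
        a = int(true_loops.at[lid, "anchor_a"])
        chrom = chroms[a]
        tss = int(mids[a])
        length = int(g_rng.integers(30_000, 120_000))
        start, end = tss, min(tss + length, chrom_len - 1)
        exons = _make_exons(start, end, g_rng)
        add_gene(f"G{gi:04d}", chrom, "+", start, end, exons)
        gene_truth_rows.append((f"G{gi:04d}", "coupled", "", lid))
        gi += 1

    # intragenic-loop genes: promoter at anchor_a, planted exon near anchor_b
    used_intra = []
    for lid in intra_pool[:n_intra]:
        a = int(true_loops.at[lid, "anchor_a"])
        b = int(true_loops.at[lid, "anchor_b"])
        chrom = chroms[a]
        tss = int(mids[a])
        b_end = int(adf.at[b, "end"])
        planted_fp = b_end + 1000          # upstream window [fp-5000, fp) covers anchor b
        end = min(planted_fp + 60_000, chrom_len - 1)
        exons = [(tss, tss + 300)]
        # filler middle exons well before the anchor, outside the 20 kb exclusion
        filler_lo = tss + 5_000
        filler_hi = int(adf.at[b, "start"]) - 25_000
        if filler_hi - filler_lo > 2_000:
            for k in range(2):
                s = int(g_rng.integers(filler_lo, filler_hi - 400))
                exons.append((s, s + 300))
        exons.append((planted_fp, planted_fp + 300))
        # control exons downstream, > 20 kb past the anchor centre
        ctrl = planted_fp + 25_000
        if ctrl + 400 < end:
            exons.append((ctrl, ctrl + 300))
        exons.append((end - 300, end))
        exons = sorted(set(exons))
        add_gene(f"G{gi:04d}", chrom, "+", tss, end, exons)
        planted_idx = exons.index((planted_fp, planted_fp + 300))
        gene_truth_rows.append((f"G{gi:04d}", "intragenic", "", lid))
        exon_pair_rows.append((f"G{gi:04d}", planted_idx, lid, b))
        used_intra.append(lid)
        gi += 1

    # cell-type-specific genes at the anchors of cell-planted variable loops
    var_by_cell = {ct: loop_truth.index[(loop_truth["target_cell"] == ct)].to_numpy()
                   for ct in cells}
    spec_cells = [cells[i % len(cells)] for i in range(n_spec)]
    var_pool_sorted = {ct: by_low_degree(var_by_cell[ct]) if len(var_by_cell[ct]) else var_by_cell[ct]
                       for ct in cells}
    for k, ct in enumerate(spec_cells):
        pool = var_pool_sorted[ct]
        if len(pool) == 0:
            break
        lid = int(pool[(k // len(cells)) % len(pool)])
        a = int(true_loops.at[lid, "anchor_a"])
        chrom = chroms[a]
        tss = int(mids[a]) + 200
        end = min(tss + int(g_rng.integers(20_000, 60_000)), chrom_len - 1)
        exons = _make_exons(tss, end, g_rng)
        add_gene(f"G{gi:04d}", chrom, "+", tss, end, exons)
        gene_truth_rows.append((f"G{gi:04d}", "cell_specific", ct, lid))
        gi += 1

    # housekeeping + filler genes in open space
    n_rest = n - gi
    for k in range(n_rest):
        chrom = _chrom_names(config)[int(g_rng.integers(config.n_chroms))]
        tss = int(g_rng.integers(100_000, chrom_len - 200_000))
        strand = "+" if g_rng.uniform() < 0.5 else "-"
        length = int(g_rng.integers(20_000, 80_000))
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length, tss
        exons = _make_exons(start, end, g_rng)
        cls = "housekeeping" if k < n_hk else "filler"
        add_gene(f"G{gi:04d}", chrom, strand, start, end, exons)
        gene_truth_rows.append((f"G{gi:04d}", cls, "", -1))
        gi += 1

    genes = gene_rows
    gene_truth = pd.DataFrame(gene_truth_rows,
                              columns=["gene_id", "class", "target_cell", "coupled_loop"]
                              ).set_index("gene_id")

    # --- expression ---------------------------------------------------------
    beta = config.expr_coupling
    expr = {}
    base = pd.Series(e_rng.lognormal(2.0, 0.8, size=len(genes)),
                     index=[g.gene_id for g in genes])
    noise_g = {gid: e_rng.normal(size=len(cells)) for gid in gene_truth.index}
    for si, row in enumerate(samples.itertuples(index=False)):
        vals = np.empty(len(genes))
        ct = row.cell_type
        ci = cells.index(ct)
        for k, g in enumerate(genes):
            gid = g.gene_id
            cls = gene_truth.at[gid, "class"]
            if cls in ("coupled", "intragenic"):
                lid = gene_truth.at[gid, "coupled_loop"]
                z = float(loop_z.at[lid, ct])
                signal = beta * z + (1 - beta) * noise_g[gid][ci]
                vals[k] = base[gid] * np.exp(0.8 * signal)
            elif cls == "housekeeping":
                vals[k] = 5.0 + base[gid]
            elif cls == "cell_specific":
                vals[k] = 50.0 + base[gid] if gene_truth.at[gid, "target_cell"] == ct else 0.2
            else:
                vals[k] = base[gid] * np.exp(0.5 * noise_g[gid][ci])
        rep_noise = e_rng.normal(0, 0.05, size=len(genes))
        expr[row.sample_id] = vals * np.exp(rep_noise)
    expression = pd.DataFrame(expr, index=[g.gene_id for g in genes])

    # --- enhancers (H3K27ac peaks) and signal -------------------------------
    deg = np.zeros(len(anchors), dtype=np.int64)
    for col in ("anchor_a", "anchor_b"):
        np.add.at(deg, true_loops[col].to_numpy(), 1)
    p_enh = np.clip(0.05 + 0.03 * deg, 0.0, 0.9)
    has_enh = enh_rng.uniform(size=len(anchors)) < p_enh
    # anchors of cell-planted loops always get an enhancer (the specific one)
    spec_anchor_cell = {}
    for ct in cells:
        for lid in var_by_cell[ct]:
            b = int(true_loops.at[lid, "anchor_b"])
            has_enh[b] = True
            spec_anchor_cell.setdefault(b, ct)
    enh_rows = []
    enh_cell = []
    for aid in np.nonzero(has_enh)[0]:
        s = int(adf.at[aid, "start"])
        e = int(adf.at[aid, "end"])
        enh_rows.append((chroms[aid], s + 200, e - 200, ".", f"ENH_{len(enh_rows)}", 0.0))
        enh_cell.append(spec_anchor_cell.get(aid, ""))
    enhancer_track = FeatureTrack(
        pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "strand", "label", "score"]),
        name="H3K27ac")
    enh_ids = enhancer_track.df["label"].tolist()
    # the track is re-sorted on construction; recover per-row cell tags
    tag_by_label = {r[4]: t for r, t in zip(enh_rows, enh_cell)}
    enh_target = [tag_by_label[l] for l in enh_ids]
    sig = {}
    for row in samples.itertuples(index=False):
        v = enh_rng.lognormal(1.0, 0.3, size=len(enh_ids))
        boost = np.array([5.0 if t == row.cell_type else 1.0 for t in enh_target])
        sig[row.sample_id] = v * boost
    enhancer_signal = pd.DataFrame(sig, index=enh_ids)

    # --- chromatin state tracks per cell type -------------------------------
    from .enrichment import CHROMATIN_STATES

    state_tracks = {}
    seg = 25_000
    state_p = np.array([0.03, 0.02, 0.10, 0.05, 0.02, 0.05, 0.03, 0.70])
    for ct in cells:
        rows = []
        for chrom in _chrom_names(config):
            starts = np.arange(0, config.chrom_length, seg)
            labels = st_rng.choice(len(CHROMATIN_STATES), size=len(starts), p=state_p)
            for s, li in zip(starts, labels):
                rows.append((chrom, int(s), int(min(s + seg, config.chrom_length)),
                             ".", CHROMATIN_STATES[li], 0.0))
        # explicit ENH segments at this cell's planted loop anchors
        for lid in var_by_cell[ct]:
            b = int(true_loops.at[lid, "anchor_b"])
            rows.append((chroms[b], int(adf.at[b, "start"]), int(adf.at[b, "end"]),
                         ".", "ENH", 0.0))
        # TSS segments at gene promoters
        for g in genes:
            lo = max(g.tss - 500, 0)
            rows.append((g.chrom, lo, g.tss + 500, ".", "TSS", 0.0))
        state_tracks[ct] = FeatureTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label", "score"]))

    # --- group TF motif tracks ----------------------------------------------
    tf_rng = rngs["motifs"]
    motif_tracks = {}
    grp_loops = {g: loop_truth.index[loop_truth["group"] == g].to_numpy() for g in GROUPS}
    grp_anchor = {g: set() for g in GROUPS}
    for g in GROUPS:
        for lid in grp_loops[g]:
            grp_anchor[g].add(int(true_loops.at[lid, "anchor_a"]))
            grp_anchor[g].add(int(true_loops.at[lid, "anchor_b"]))
    for g, tf in (("blood", "TF_BLOOD"), ("embryonic", "TF_EMB")):
        rows = []
        for aid in range(len(anchors)):
            p_hit = 0.6 if aid in grp_anchor[g] else 0.1
            if tf_rng.uniform() < p_hit:
                mid = int(mids[aid])
                rows.append((chroms[aid], mid - 8, mid + 8,
                             "+" if tf_rng.uniform() < 0.5 else "-", tf, 0.0))
        motif_tracks[tf] = FeatureTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label", "score"]),
            name=tf)
    rows = []
    for aid in range(len(anchors)):
        if tf_rng.uniform() < 0.15:
            mid = int(mids[aid])
            rows.append((chroms[aid], mid - 8, mid + 8,
                         "+" if tf_rng.uniform() < 0.5 else "-", "TF_NULL", 0.0))
    motif_tracks["TF_NULL"] = FeatureTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label", "score"]),
        name="TF_NULL")

    # --- exon counts coupled to anchor strength -----------------------------
    gamma = config.exon_coupling
    anchor_strength = anchor_count_matrix(true_loops, counts.loc[loop_truth.index],
                                          n_anchors=len(anchors))
    az = pd.DataFrame(_zscore_rows(np.log1p(anchor_strength.to_numpy())),
                      index=anchor_strength.index, columns=anchor_strength.columns)
    exon_rows = {}
    due = {}
    planted_pairs = {(r[0], r[1]): r[3] for r in exon_pair_rows}
    for g in genes:
        gbase = float(e_rng.lognormal(3.0, 0.5))
        for ei in range(len(g.exons)):
            exon_id = f"{g.gene_id}:{ei}"
            body = planted_pairs.get((g.gene_id, ei))
            vals = np.empty(len(samples))
            eps = ex_rng.normal(size=len(samples))
            for si, row in enumerate(samples.itertuples(index=False)):
                if body is not None:
                    z = float(az.at[body, row.sample_id])
                    vals[si] = gbase * np.exp(0.8 * (gamma * z + (1 - gamma) * eps[si]))
                else:
                    vals[si] = gbase * np.exp(0.3 * eps[si])
            exon_rows[exon_id] = vals
            due[exon_id] = body is not None or ex_rng.uniform() < 0.10
    exon_counts = pd.DataFrame.from_dict(exon_rows, orient="index",
                                         columns=samples["sample_id"].tolist())
    due_flags = pd.Series(due, name="due_flag")

    # --- CAGE track over a few filler middle exons --------------------------
    cage_rows = []
    filler_genes = [g for g in genes
                    if gene_truth.at[g.gene_id, "class"] == "filler" and len(g.exons) > 2]
    for g in filler_genes[:10]:
        s, e = g.exons[1]
        cage_rows.append((g.chrom, s, e))
    cage_track = FeatureTrack(pd.DataFrame(cage_rows, columns=["chrom", "start", "end"]),
                              name="CAGE")

    exon_pairs = pd.DataFrame(exon_pair_rows,
                              columns=["gene_id", "exon_index", "loop_id", "body_anchor"])
    annotations = {
        "genes": genes,
        "expression": expression,
        "enhancer_track": enhancer_track,
        "enhancer_signal": enhancer_signal,
        "state_tracks": state_tracks,
        "tf_motif_tracks": motif_tracks,
        "exon_counts": exon_counts,
        "due_flags": due_flags,
        "cage_track": cage_track,
        "anchor_strength": anchor_strength,
    }
    return annotations, gene_truth, exon_pairs


def _make_exons(start: int, end: int, rng) -> list:
    n_ex = int(rng.integers(3, 7))
    span = end - start
    if span < 2000 * n_ex:
        n_ex = max(3, span // 2000)
    pos = np.linspace(start, end - 300, n_ex).astype(int)
    return [(int(p), int(p) + 300) for p in pos]


def anchor_count_matrix(loops: pd.DataFrame, counts: pd.DataFrame,
                        n_anchors: int) -> pd.DataFrame:
    """Per-sample anchor strength: summed PET counts of loops touching it."""
    out = np.zeros((n_anchors, counts.shape[1]))
    a = loops.loc[counts.index, "anchor_a"].to_numpy()
    b = loops.loc[counts.index, "anchor_b"].to_numpy()
    X = counts.to_numpy()
    np.add.at(out, a, X)
    np.add.at(out, b, X)
    return pd.DataFrame(out, index=pd.RangeIndex(n_anchors), columns=counts.columns)


# ---------------------------------------------------------------------------
# GWAS panels
# ---------------------------------------------------------------------------

def generate_gwas_panel(
    config: SynthConfig,
    anchors: AnchorSet,
    blood_loop_ids,
    candidates: pd.DataFrame,
    rngs: dict | None = None,
    study_ids=("planted", "null"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP tables for one planted-enrichment study and one null study.

    Cluster leads carry the minimum p within their LD cluster.  In the
    planted study a ``gwas_planted_frac`` share of the 50 most significant
    pruned leads is relocated inside blood-specific loop anchors; the null
    study places all clusters uniformly.
    """
    rngs = rngs or config.streams()
    rng = rngs["gwas"]
    adf = anchors.track.df
    blood_anchor_ids = sorted({int(candidates.at[l, c])
                               for l in blood_loop_ids for c in ("anchor_a", "anchor_b")})
    chrom_names = _chrom_names(config)
    rows = []
    truth_rows = []
    for study in study_ids:
        n_clusters = config.n_gwas_clusters
        lead_p = np.empty(n_clusters)
        n_gw = 60
        lead_p[:n_gw] = 10.0 ** -rng.uniform(7.5, 12, size=n_gw)
        lead_p[n_gw:] = rng.uniform(1e-6, 1.0, size=n_clusters - n_gw)
        order = np.argsort(lead_p, kind="mergesort")
        planted_flag = np.zeros(n_clusters, dtype=bool)
        if study == "planted":
            top50 = order[:50]
            chosen = rng.uniform(size=50) < config.gwas_planted_frac
            planted_flag[top50[chosen]] = True
        sizes = rng.integers(1, 11, size=n_clusters)
        for ci in range(n_clusters):
            if planted_flag[ci]:
                aid = int(rng.choice(blood_anchor_ids))
                chrom = adf.at[aid, "chrom"]
                lead_pos = int(rng.integers(adf.at[aid, "start"], adf.at[aid, "end"]))
            else:
                chrom = chrom_names[int(rng.integers(config.n_chroms))]
                lead_pos = int(rng.integers(10_000, config.chrom_length - 10_000))
            cid = f"{study}_c{ci}"
            rows.append((study, f"{cid}_lead", chrom, lead_pos, float(lead_p[ci]), cid, 1.0))
            for k in range(int(sizes[ci]) - 1):
                pos = int(np.clip(lead_pos + rng.integers(-25_000, 25_000),
                                  0, config.chrom_length - 1))
                pv = float(min(1.0, lead_p[ci] * rng.uniform(1.5, 1e3)))
                r2 = float(rng.uniform(0.5, 1.0))
                rows.append((study, f"{cid}_s{k}", chrom, pos, pv, cid, r2))
            truth_rows.append((study, cid, bool(planted_flag[ci])))
    snp_df = pd.DataFrame(rows, columns=["study_id", "snp_id", "chrom", "pos",
                                         "p_value", "ld_cluster", "r2_to_lead"])
    truth = pd.DataFrame(truth_rows, columns=["study_id", "ld_cluster", "planted"])
    return snp_df, truth


# ---------------------------------------------------------------------------
# one-call generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig, with_annotations: bool = True,
                     with_gwas: bool = True) -> SyntheticDataset:
    """Generate the full synthetic study under one master seed."""
    rngs = config.streams()
    anchors, candidates = generate_anchors_and_loops(config, rngs)
    loop_truth = plant_loop_truth(config, candidates, rngs)
    motif_track, orientation = plant_ctcf_motifs(config, anchors, candidates, rngs)
    sheet = make_sample_sheet(config)
    counts = generate_pet_counts(config, anchors, candidates, loop_truth, sheet, rngs)
    loop_truth = loop_truth.join(orientation)
    loop_truth["orientation"] = loop_truth["orientation"].fillna("")
    annotations = {}
    gene_truth = pd.DataFrame()
    exon_pairs = pd.DataFrame()
    if with_annotations:
        annotations, gene_truth, exon_pairs = generate_regulatory_annotations(
            config, anchors, candidates, loop_truth, sheet, counts, rngs)
    gwas_tables = None
    snp_truth = pd.DataFrame()
    if with_gwas:
        blood_ids = loop_truth.index[loop_truth["group"] == "blood"]
        gwas_tables, snp_truth = generate_gwas_panel(config, anchors, blood_ids,
                                                     candidates, rngs)
    truth = TruthTables(loops=loop_truth, genes=gene_truth,
                        exon_pairs=exon_pairs, snps=snp_truth)
    return SyntheticDataset(config=config, anchors=anchors, candidates=candidates,
                            sample_sheet=sheet, counts=counts, motif_track=motif_track,
                            truth=truth, annotations=annotations, gwas_tables=gwas_tables)
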