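"""Stage orchestration: run the analysis end to end from one config.

Each stage reads the files earlier stages wrote under ``outdir``, writes its
outputs atomically (temp file + rename), and records inputs, parameters and
output checksums in ``manifest.json``.  Stages in order: simulate, anchors,
tabulate, score, normalize, variability, specificity, enrich, exprlink,
splicing, gwas, report.  All randomness derives from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import exprlink as xl
from . import gwas as gw
from . import io as lio
from . import loopstats as ls
from . import specificity as sp
from .intervals import FeatureTrack
from .loopcall import (
    AnchorSet, build_anchor_set, build_interaction_matrix, ctcf_orientation_summary,
    downsample_pets, score_loops, tabulate_pets,
)
from .synth import SynthConfig, anchor_count_matrix, generate_dataset

STAGES = ["simulate", "anchors", "tabulate", "score", "normalize", "variability",
          "specificity", "enrich", "exprlink", "splicing", "gwas", "report"]


DEFAULT_PARAMS = {
    "extension_bp": 500,
    "min_span": 10_000,
    "max_span": 5_000_000,
    "downsample_cap": 2_250_000,
    "min_pets": 4,
    "n_distance_bins": 50,
    "call_fdr": 0.01,
    "variability_fdr": 0.10,
    "variability_method": "lmm_lrt",
    "top_frac": 0.10,
    "gene_top_frac": 0.20,
    "min_cell": 5,
    "n_shuffles": 100,
    "n_perm": 200,
}


@dataclasses.dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    synth: dict = dataclasses.field(default_factory=dict)
    params: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(seed=self.seed, **self.synth)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"seed": config.seed, "stages": {}}

    def path(self, name: str) -> Path:
        return self.out / name

    def write_df(self, df: pd.DataFrame, name: str, index_label=None):
        tmp = self.path(name + ".tmp")
        if index_label is not None:
            df.to_csv(tmp, sep="\t", index_label=index_label)
        else:
            df.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, self.path(name))
        return self.path(name)

    def write_track(self, track: FeatureTrack, name: str, dialect="bed6"):
        tmp = self.path(name + ".tmp")
        lio.write_intervals(track, tmp, dialect=dialect)
        os.replace(tmp, self.path(name))
        return self.path(name)

    def write_json(self, obj: dict, name: str):
        tmp = self.path(name + ".tmp")
        tmp.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
        os.replace(tmp, self.path(name))
        return self.path(name)

    def record(self, stage: str, inputs: list, outputs: list, params: dict):
        def rel(p):
            p = Path(p)
            try:
                return str(p.relative_to(self.out))
            except ValueError:
                return str(p)

        self.manifest["stages"][stage] = {
            "inputs": [rel(p) for p in inputs],
            "params": {k: params[k] for k in sorted(params)},
            "outputs": {Path(p).name: _checksum(Path(p)) for p in outputs},
        }
        tmp = self.manifest_path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        os.replace(tmp, self.manifest_path)

    def require(self, *names: str) -> list:
        paths = [self.path(n) for n in names]
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"missing upstream output(s): {', '.join(missing)}")
        return paths


def _sample_ids(run: _Run) -> list:
    return lio.SampleSheet.read(run.path("samples.tsv")).sample_ids


# --------------------------------------------------------------------------- stages

def stage_simulate(run: _Run) -> list:
    cfg = run.config.synth_config()
    ds = generate_dataset(cfg)
    outputs = []
    rngs = cfg.streams()
    pet_rng = rngs["pets"]
    ext = run.config.params["extension_bp"]
    # per-sample peak calls: anchors shrunk by the extension the anchor
    # builder will re-apply
    peaks = ds.anchors.track.df.copy()
    peaks["start"] += ext
    peaks["end"] -= ext
    peak_track = FeatureTrack(peaks)
    from .synth import emit_pet_bedpe

    for sid in ds.sample_sheet.sample_ids:
        outputs.append(run.write_track(peak_track, f"peaks_{sid}.bed", dialect="bed3"))
        pets = emit_pet_bedpe(cfg, ds.anchors, ds.candidates, ds.counts[sid], pet_rng)
        tmp = run.path(f"pets_{sid}.bedpe.tmp")
        lio.write_bedpe(pets, tmp)
        os.replace(tmp, run.path(f"pets_{sid}.bedpe"))
        outputs.append(run.path(f"pets_{sid}.bedpe"))
    ds.sample_sheet.write(run.path("samples.tsv"))
    outputs.append(run.path("samples.tsv"))
    outputs.append(run.write_track(ds.motif_track, "ctcf_motifs.bed"))
    outputs.append(run.write_df(ds.truth.loops, "truth_loops.tsv", index_label="loop_id"))
    ann = ds.annotations
    if ann:
        gene_rows = []
        for g in ann["genes"]:
            for (s, e) in g.exons:
                gene_rows.append((g.gene_id, g.chrom, g.strand, g.start, g.end, s, e, g.biotype))
        gene_df = pd.DataFrame(gene_rows, columns=lio.GENE_TABLE_COLUMNS)
        outputs.append(run.write_df(gene_df, "genes.tsv"))
        outputs.append(run.write_df(ann["expression"], "expression.tsv", index_label="gene_id"))
        outputs.append(run.write_track(ann["enhancer_track"], "enhancers.bed"))
        outputs.append(run.write_df(ann["enhancer_signal"], "enhancer_signal.tsv",
                                    index_label="enhancer_id"))
        for ct, track in ann["state_tracks"].items():
            outputs.append(run.write_track(track, f"states_{ct}.bed", dialect="state_bed"))
        for tf, track in ann["tf_motif_tracks"].items():
            outputs.append(run.write_track(track, f"motifs_{tf}.bed"))
        outputs.append(run.write_df(ann["exon_counts"], "exon_counts.tsv", index_label="exon_id"))
        outputs.append(run.write_df(ann["due_flags"].to_frame(), "due_flags.tsv",
                                    index_label="exon_id"))
        outputs.append(run.write_track(ann["cage_track"], "cage.bed", dialect="bed3"))
        outputs.append(run.write_df(ds.truth.genes, "truth_genes.tsv", index_label="gene_id"))
        outputs.append(run.write_df(ds.truth.exon_pairs, "truth_exon_pairs.tsv"))
    if ds.gwas_tables is not None:
        tmp = run.path("gwas_snps.tsv.tmp")
        lio.write_snp_table(ds.gwas_tables, tmp)
        os.replace(tmp, run.path("gwas_snps.tsv"))
        outputs.append(run.path("gwas_snps.tsv"))
    run.record("simulate", [], outputs,
               {"seed": run.config.seed, **{f"synth.{k}": v for k, v in run.config.synth.items()}})
    return outputs


def stage_anchors(run: _Run) -> list:
    run.require("samples.tsv")
    sids = _sample_ids(run)
    peak_paths = [run.require(f"peaks_{s}.bed")[0] for s in sids]
    tracks = [lio.read_intervals(p, "bed3") for p in peak_paths]
    blacklist_path = run.path("blacklist.bed")
    blacklist = (lio.read_intervals(blacklist_path, "bed3")
                 if blacklist_path.exists() else None)
    anchors = build_anchor_set(tracks, extension_bp=run.config.params["extension_bp"],
                               blacklist=blacklist)
    out = run.write_track(anchors.to_bed(), "anchors.bed")
    run.record("anchors", peak_paths, [out],
               {"extension_bp": run.config.params["extension_bp"]})
    return [out]


def _load_anchors(run: _Run) -> AnchorSet:
    track = lio.read_intervals(run.require("anchors.bed")[0], "bed6")
    eff = track.df["score"].to_numpy(dtype=float)
    return AnchorSet(FeatureTrack(track.df.assign(score=0.0)),
                     efficiency=eff if eff.sum() > 0 else None)


def stage_tabulate(run: _Run) -> list:
    anchors = _load_anchors(run)
    sids = _sample_ids(run)
    p = run.config.params
    cols = {}
    endpoint_total = np.zeros(len(anchors))
    for i, sid in enumerate(sids):
        pets = lio.read_intervals(run.require(f"pets_{sid}.bedpe")[0], "bedpe")
        pets = downsample_pets(pets, cap=p["downsample_cap"], seed=run.config.seed + i)
        counts, endpoints = tabulate_pets(pets, anchors, min_span=p["min_span"],
                                          max_span=p["max_span"])
        cols[sid] = counts
        endpoint_total += endpoints
    mat = build_interaction_matrix(cols, anchors)
    flat = mat.reset_index()
    flat.insert(0, "loop_id", [f"{a}_{b}" for a, b in zip(flat["anchor_a"], flat["anchor_b"])])
    out1 = run.write_df(flat, "counts.tsv")
    bed = anchors.track.df.copy()
    bed["label"] = [f"anchor_{i}" for i in range(len(bed))]
    bed["score"] = endpoint_total
    out2 = run.write_track(FeatureTrack(bed), "anchors.bed")
    run.record("tabulate", [run.path("anchors.bed")], [out1, out2],
               {k: p[k] for k in ("downsample_cap", "min_span", "max_span")})
    return [out1, out2]


def _load_counts(run: _Run) -> pd.DataFrame:
    df = pd.read_csv(run.require("counts.tsv")[0], sep="\t")
    df = df.set_index(["anchor_a", "anchor_b"]).drop(columns=["loop_id"])
    return df


def stage_score(run: _Run) -> list:
    anchors = _load_anchors(run)
    mat = _load_counts(run)
    p = run.config.params
    pairs = mat.index.to_frame(index=False)
    pairs["count"] = mat.sum(axis=1).to_numpy()
    scores = score_loops(pairs, anchors, n_distance_bins=p["n_distance_bins"],
                         fdr=p["call_fdr"])
    out1 = run.write_df(scores, "loop_scores.tsv")
    called = scores[scores["called"]]
    motif_path = run.path("ctcf_motifs.bed")
    outputs = [out1]
    if motif_path.exists():
        summary = ctcf_orientation_summary(called, anchors,
                                           lio.read_intervals(motif_path, "motif_bed"))
        outputs.append(run.write_json(summary, "ctcf_orientation.json"))
    run.record("score", [run.path("counts.tsv")], outputs,
               {k: p[k] for k in ("n_distance_bins", "call_fdr")})
    return outputs


def _called_counts(run: _Run) -> pd.DataFrame:
    mat = _load_counts(run)
    scores = pd.read_csv(run.require("loop_scores.tsv")[0], sep="\t")
    called = scores[scores["called"]]
    idx = pd.MultiIndex.from_frame(called[["anchor_a", "anchor_b"]])
    return mat.loc[mat.index.intersection(idx)]


def stage_normalize(run: _Run) -> list:
    p = run.config.params
    mat = _called_counts(run)
    mat = ls.filter_testable(mat, min_pets=p["min_pets"])
    mat = mat.loc[~ls.zero_variance_rows(mat)]
    norm = ls.normalize_matrix(mat)
    flat = norm.reset_index()
    flat.insert(0, "loop_id", [f"{a}_{b}" for a, b in zip(flat["anchor_a"], flat["anchor_b"])])
    out = run.write_df(flat, "normalized.tsv")
    flat_raw = mat.reset_index()
    flat_raw.insert(0, "loop_id",
                    [f"{a}_{b}" for a, b in zip(flat_raw["anchor_a"], flat_raw["anchor_b"])])
    out2 = run.write_df(flat_raw, "testable_counts.tsv")
    run.record("normalize", [run.path("counts.tsv")], [out, out2],
               {"min_pets": p["min_pets"]})
    return [out, out2]


def _read_loop_matrix(run: _Run, name: str) -> pd.DataFrame:
    df = pd.read_csv(run.require(name)[0], sep="\t")
    return df.set_index(["anchor_a", "anchor_b"]).drop(columns=["loop_id"])


def stage_variability(run: _Run) -> list:
    p = run.config.params
    norm = _read_loop_matrix(run, "normalized.tsv")
    raw = _read_loop_matrix(run, "testable_counts.tsv")
    sheet = lio.SampleSheet.read(run.require("samples.tsv")[0])
    weights = ls.voom_weights(raw, sheet)
    res = ls.test_variability(norm, sheet, weights, method=p["variability_method"],
                              fdr=p["variability_fdr"])
    out = run.write_df(res.table, "variability.tsv", index_label="loop")
    var_df = res.variable_ids.to_frame(index=False)
    out2 = run.write_df(var_df, "variable_loops.tsv")
    static = ls.static_sets(raw, res.variable_ids, mode="score_ranked")
    out3 = run.write_df(static.to_frame(index=False), "static_loops.tsv")
    run.record("variability", [run.path("normalized.tsv")], [out, out2, out3],
               {"method": p["variability_method"], "fdr": p["variability_fdr"]})
    return [out, out2, out3]


def stage_specificity(run: _Run) -> list:
    p = run.config.params
    norm = _read_loop_matrix(run, "normalized.tsv")
    sheet = lio.SampleSheet.read(run.require("samples.tsv")[0])
    outputs = []
    rows = []
    for ct in sheet.cell_types:
        s = sp.celltype_specific(norm, sheet, ct, top_frac=p["top_frac"])
        for m in s.members:
            rows.append({"target": ct, "kind": "cell_type", "anchor_a": m[0], "anchor_b": m[1]})
    for g, s in sp.group_specific(norm, sheet, top_frac=p["top_frac"]).items():
        for m in s.members:
            rows.append({"target": g, "kind": "group", "anchor_a": m[0], "anchor_b": m[1]})
    out = run.write_df(pd.DataFrame(rows), "specific_loops.tsv")
    outputs.append(out)
    run.record("specificity", [run.path("normalized.tsv")], outputs,
               {"top_frac": p["top_frac"]})
    return outputs


def _specific_sets(run: _Run) -> pd.DataFrame:
    return pd.read_csv(run.require("specific_loops.tsv")[0], sep="\t")


def stage_enrich(run: _Run) -> list:
    p = run.config.params
    anchors = _load_anchors(run)
    norm = _read_loop_matrix(run, "normalized.tsv")
    loops = norm.index.to_frame(index=False)
    loops.index = pd.MultiIndex.from_frame(loops[["anchor_a", "anchor_b"]])
    spec = _specific_sets(run)
    sheet = lio.SampleSheet.read(run.require("samples.tsv")[0])
    outputs = []
    enh_path = run.path("enhancers.bed")
    if enh_path.exists():
        features = {"enhancer": lio.read_intervals(enh_path, "bed6")}
        genes = xl.genes_from_table(lio.read_gene_table(run.path("genes.tsv")))
        features["promoter"] = xl.promoter_track(genes)
        prof = enr.connectivity_profile(loops, anchors, features)
        outputs.append(run.write_df(prof, "connectivity_enrichment.tsv"))
    state_results = []
    for ct in sheet.cell_types:
        spath = run.path(f"states_{ct}.bed")
        if not spath.exists():
            continue
        members = spec[(spec["target"] == ct) & (spec["kind"] == "cell_type")]
        member_idx = pd.MultiIndex.from_frame(members[["anchor_a", "anchor_b"]])
        res = enr.state_enrichment(member_idx, loops, anchors,
                                   lio.read_intervals(spath, "state_bed"), cell=ct)
        state_results.extend(res["results"])
    if state_results:
        from statsmodels.stats.multitest import multipletests

        df = enr.results_frame(state_results)
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        outputs.append(run.write_df(df, "state_enrichment.tsv"))
    motif_tracks = {}
    for f in sorted(run.out.glob("motifs_*.bed")):
        tf = f.stem.replace("motifs_", "")
        motif_tracks[tf] = lio.read_intervals(f, "motif_bed")
    if motif_tracks:
        for g in sorted(spec.loc[spec["kind"] == "group", "target"].unique()):
            members = spec[(spec["target"] == g) & (spec["kind"] == "group")]
            member_idx = pd.MultiIndex.from_frame(members[["anchor_a", "anchor_b"]])
            df = enr.motif_enrichment(member_idx, loops, anchors, motif_tracks,
                                      min_cell=p["min_cell"])
            outputs.append(run.write_df(df, f"tf_enrichment_{g}.tsv"))
    run.record("enrich", [run.path("specific_loops.tsv")], outputs,
               {"min_cell": p["min_cell"]})
    return outputs


def stage_exprlink(run: _Run) -> list:
    p = run.config.params
    anchors = _load_anchors(run)
    norm = _read_loop_matrix(run, "normalized.tsv")
    genes = xl.genes_from_table(lio.read_gene_table(run.require("genes.tsv")[0]))
    expr = pd.read_csv(run.require("expression.tsv")[0], sep="\t", index_col=0)
    sheet = lio.SampleSheet.read(run.require("samples.tsv")[0])
    loops = norm.index.to_frame(index=False)
    loops.index = norm.index
    mapping = xl.map_loops_to_genes(loops, anchors, genes, scheme="promoter")
    res = xl.loop_expression_correlation(norm, expr, mapping, sheet,
                                         n_shuffles=p["n_shuffles"], seed=run.config.seed)
    out = run.write_json({
        "n_pairs": len(res["pairs"]),
        "real_mean_abs_rho": res["real_mean_abs_rho"],
        "null_mean_abs_rho": res["null_mean_abs_rho"],
        "sign_test_odds_ratio": res["sign_test"].odds_ratio,
        "sign_test_p": res["sign_test"].p,
    }, "loop_expression.json")
    pairs = res["pairs"].copy()
    pairs["loop_id"] = [f"{a}_{b}" for a, b in pairs["loop_id"]]
    out2 = run.write_df(pairs, "loop_gene_pairs.tsv")
    run.record("exprlink", [run.path("normalized.tsv")], [out, out2],
               {"n_shuffles": p["n_shuffles"]})
    return [out, out2]


def stage_splicing(run: _Run) -> list:
    anchors = _load_anchors(run)
    genes = xl.genes_from_table(lio.read_gene_table(run.require("genes.tsv")[0]))
    cage = lio.read_intervals(run.require("cage.bed")[0], "bed3")
    exon_counts = pd.read_csv(run.require("exon_counts.tsv")[0], sep="\t", index_col=0)
    due = pd.read_csv(run.require("due_flags.tsv")[0], sep="\t", index_col=0)["due_flag"]
    raw = _read_loop_matrix(run, "testable_counts.tsv")
    loops = raw.index.to_frame(index=False)
    loops.index = raw.index
    intra = xl.find_intragenic_loops(genes, loops, anchors, cage)
    astr = anchor_count_matrix(loops, raw, n_anchors=len(anchors))
    res = xl.exon_loop_correlation(exon_counts, astr, intra, genes, anchors,
                                   due_flags=due, n_perm=run.config.params["n_shuffles"],
                                   seed=run.config.seed)
    out = run.write_json({
        "n_intragenic_loops": len(intra),
        "n_real_pairs": res["n_real_pairs"],
        "n_control_pairs": res["n_control_pairs"],
        "mean_real_r": float(np.nanmean(res["real_r"])) if len(res["real_r"]) else None,
        "perm_mean_r_p95": (float(np.nanpercentile(res["perm_mean_r"], 95))
                            if np.isfinite(res["perm_mean_r"]).any() else None),
    }, "splicing.json")
    out2 = run.write_df(intra.assign(loop_id=[f"{a}_{b}" for a, b in intra["loop_id"]]),
                        "intragenic_loops.tsv")
    run.record("splicing", [run.path("exon_counts.tsv")], [out, out2], {})
    return [out, out2]


def stage_gwas(run: _Run) -> list:
    p = run.config.params
    anchors = _load_anchors(run)
    snps = lio.read_snp_table(run.require("gwas_snps.tsv")[0])
    spec = _specific_sets(run)
    blood = spec[(spec["kind"] == "group") & (spec["target"] == "blood")]
    aids = sorted(set(blood["anchor_a"]) | set(blood["anchor_b"]))
    if not aids:
        raise ValueError("no blood-specific loop anchors available for GWAS stage")
    regions = FeatureTrack(anchors.track.df.iloc[aids].reset_index(drop=True))
    pruned = gw.prune_and_expand(snps)
    rows = []
    for study in sorted(pruned["study_id"].unique()):
        sub = pruned[pruned["study_id"] == study]
        res = gw.binned_rank_enrichment(sub, regions, n_perm=p["n_perm"],
                                        seed=run.config.seed)
        rows.append({"study_id": study, "top_bin_fold": res["top_bin_fold"],
                     "empirical_p": res["empirical_p"], "base_frac": res["base_frac"]})
    out = run.write_df(pd.DataFrame(rows), "gwas_enrichment.tsv")
    run.record("gwas", [run.path("gwas_snps.tsv")], [out], {"n_perm": p["n_perm"]})
    return [out]


def stage_report(run: _Run) -> list:
    rows = []

    def count_lines(name, header=True):
        path = run.path(name)
        if not path.exists():
            return None
        n = sum(1 for _ in open(path))
        return n - (1 if header else 0)

    rows.append(("anchors", count_lines("anchors.bed", header=False)))
    rows.append(("candidate_loops", count_lines("counts.tsv")))
    rows.append(("called_loops", None))
    scores_path = run.path("loop_scores.tsv")
    if scores_path.exists():
        sc = pd.read_csv(scores_path, sep="\t")
        rows[-1] = ("called_loops", int(sc["called"].sum()))
    rows.append(("testable_loops", count_lines("normalized.tsv")))
    rows.append(("variable_loops", count_lines("variable_loops.tsv")))
    spec_path = run.path("specific_loops.tsv")
    if spec_path.exists():
        spec = pd.read_csv(spec_path, sep="\t")
        for (kind, target), sub in spec.groupby(["kind", "target"]):
            rows.append((f"specific_{kind}_{target}", len(sub)))
    df = pd.DataFrame([(k, v) for k, v in rows if v is not None],
                      columns=["quantity", "count"])
    out = run.write_df(df, "report.tsv")
    run.record("report", [], [out], {})
    return [out]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "anchors": stage_anchors, "tabulate": stage_tabulate,
    "score": stage_score, "normalize": stage_normalize, "variability": stage_variability,
    "specificity": stage_specificity, "enrich": stage_enrich, "exprlink": stage_exprlink,
    "splicing": stage_splicing, "gwas": stage_gwas, "report": stage_report,
}


def run_stage(stage_name: str, config: RunConfig) -> list:
    """Run one named stage; raises if its upstream outputs are missing."""
    if stage_name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; choose from {STAGES}")
    return _STAGE_FUNCS[stage_name](_Run(config))


def run_all(config: RunConfig, stages=None, dry_run: bool = False) -> list:
    """Run the stages in dependency order; halts naming a failing stage."""
    stages = list(stages or STAGES)
    bad = [s for s in stages if s not in _STAGE_FUNCS]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    if dry_run:
        return stages
    written = []
    for s in stages:
        try:
            written.extend(run_stage(s, config))
        except Exception as exc:
            raise RuntimeError(f"stage {s!r} failed: {exc}") from exc
    return written
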