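import numpy as np
import pandas as pd
import pytest

from loopscape import exprlink as xl
from loopscape.loopcall import AnchorSet

from conftest import track_from_tuples
from test_loopstats import sheet_for


def anchors_at(*centres, width=2_000):
    rows = [("chr1", c - width // 2, c + width // 2) for c in centres]
    return AnchorSet(track_from_tuples(rows))


def gene(gid, tss, end, strand="+", exons=None, biotype="protein_coding"):
    if strand == "+":
        start = tss
        exons = exons or [(start, start + 300), ((start + end) // 2, (start + end) // 2 + 300),
                          (end - 300, end)]
        return xl.GeneModel(gid, "chr1", strand, start, end, exons, biotype)
    exons = exons or [(end - 300 - (end - tss) // 2, (end - (end - tss) // 2)),
                      (tss - 300, tss)]
    return xl.GeneModel(gid, "chr1", strand, end, tss, exons, biotype)


class TestGeneModel:
    def test_tss_is_strand_aware(self):
        g = xl.GeneModel("g", "chr1", "+", 100, 5_000, [(100, 400)])
        assert g.tss == 100
        g = xl.GeneModel("g", "chr1", "-", 100, 5_000, [(100, 400)])
        assert g.tss == 5_000

    def test_exon_outside_body_rejected(self):
        with pytest.raises(ValueError):
            xl.GeneModel("g", "chr1", "+", 100, 5_000, [(50, 400)])

    def test_promoter_track_strand_aware(self):
        gp = xl.GeneModel("gp", "chr1", "+", 10_000, 20_000, [(10_000, 10_300)])
        gm = xl.GeneModel("gm", "chr1", "-", 10_000, 20_000, [(10_000, 10_300)])
        track = xl.promoter_track([gp, gm], upstream_bp=500)
        by_label = {iv.label: iv for iv in track}
        assert by_label["gp"].start == 9_500
        assert by_label["gm"].end == 20_500


class TestMapSchemes:
    def setup_method(self):
        # one loop chr1: anchors centred at 50,000 and 150,000
        self.anchors = anchors_at(50_000, 150_000, 400_000)
        self.loops = pd.DataFrame({"anchor_a": [0], "anchor_b": [1]}, index=[0])

    def test_promoter_rule_within_1kb(self):
        near = gene("near", 51_500, 90_000)       # 500 bp from anchor edge
        far = gene("far", 53_000, 90_000)         # 2 kb away
        m = xl.map_loops_to_genes(self.loops, self.anchors, [near, far],
                                  scheme="promoter")
        assert set(m["gene_id"]) == {"near"}

    def test_contained_rule_needs_distance_from_anchors(self):
        inside = gene("inside", 70_000, 120_000)  # TSS 19 kb from anchor a
        at_anchor = gene("at_anchor", 51_200, 120_000)
        m = xl.map_loops_to_genes(self.loops, self.anchors, [inside, at_anchor],
                                  scheme="contained")
        assert set(m["gene_id"]) == {"inside"}
        m2 = xl.map_loops_to_genes(self.loops, self.anchors, [inside, at_anchor],
                                   scheme="promoter")
        assert "inside" not in set(m2["gene_id"])

    def test_all_rule_includes_partial_orf_overlap(self):
        spans = gene("spans", 40_000, 60_000)     # overlaps the loop interval
        outside = gene("outside", 300_000, 350_000)
        m = xl.map_loops_to_genes(self.loops, self.anchors, [spans, outside],
                                  scheme="all")
        assert set(m["gene_id"]) == {"spans"}

    def test_promoter_enhancer_needs_far_end_peak(self):
        g = gene("g", 50_500, 90_000)
        with_enh = track_from_tuples([("chr1", 149_800, 150_200)])
        without = track_from_tuples([("chr1", 900_000, 900_400)])
        m1 = xl.map_loops_to_genes(self.loops, self.anchors, [g], with_enh,
                                   scheme="promoter_enhancer")
        m2 = xl.map_loops_to_genes(self.loops, self.anchors, [g], without,
                                   scheme="promoter_enhancer")
        assert len(m1) == 1 and len(m2) == 0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            xl.map_loops_to_genes(self.loops, self.anchors, [], scheme="bogus")

    def test_emitted_promoter_pairs_satisfy_predicate(self, small_ds, small_norm):
        Mf, _ = small_norm
        loops = small_ds.true_loops.loc[Mf.index]
        genes = small_ds.annotations["genes"]
        m = xl.map_loops_to_genes(loops, small_ds.anchors, genes, scheme="promoter")
        by_id = {g.gene_id: g for g in genes}
        adf = small_ds.anchors.track.df
        for row in m.sample(min(len(m), 50), random_state=0).itertuples(index=False):
            g = by_id[row.gene_id]
            ok = False
            for col in ("anchor_a", "anchor_b"):
                aid = loops.at[row.loop_id, col]
                s, e = adf.at[aid, "start"], adf.at[aid, "end"]
                d = 0 if s <= g.tss < e else (s - g.tss if g.tss < s else g.tss - e + 1)
                ok = ok or d <= 1000
            assert ok


class TestLoopExpressionCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        sheet = sheet_for(["c1", "c2", "c3", "c4", "c5", "c6"],
                          groups=["blood"] * 2 + ["embryonic"] * 2 + ["solid"] * 2)
        rng = np.random.default_rng(0)
        normM = pd.DataFrame(rng.uniform(0, 1000, size=(5, 12)),
                             index=[f"L{i}" for i in range(5)],
                             columns=sheet.sample_ids)
        expr = pd.DataFrame(np.sqrt(normM.to_numpy()) + 2,
                            index=[f"G{i}" for i in range(5)],
                            columns=sheet.sample_ids)
        mapping = pd.DataFrame({"loop_id": [f"L{i}" for i in range(5)],
                                "gene_id": [f"G{i}" for i in range(5)]})
        res = xl.loop_expression_correlation(normM, expr, mapping, sheet,
                                             n_shuffles=5, seed=0,
                                             average_by_cell_type=False)
        assert np.allclose(res["pairs"]["rho"], 1.0)

    def test_shuffle_preserves_per_loop_multiplicity(self):
        # the null permutes genes across mapping slots, so each loop keeps its
        # number of genes; verify via the internal pairing arrays staying fixed
        sheet = sheet_for([f"c{i}" for i in range(6)],
                          groups=["blood"] * 2 + ["embryonic"] * 2 + ["solid"] * 2)
        rng = np.random.default_rng(1)
        normM = pd.DataFrame(rng.uniform(0, 1000, size=(10, 12)),
                             index=[f"L{i}" for i in range(10)], columns=sheet.sample_ids)
        expr = pd.DataFrame(rng.uniform(1, 50, size=(8, 12)),
                            index=[f"G{i}" for i in range(8)], columns=sheet.sample_ids)
        mapping = pd.DataFrame({
            "loop_id": ["L0", "L0", "L0", "L1", "L2"],
            "gene_id": ["G0", "G1", "G2", "G3", "G4"],
        })
        res = xl.loop_expression_correlation(normM, expr, mapping, sheet,
                                             n_shuffles=20, seed=1)
        assert res["pairs"]["loop_id"].value_counts()["L0"] == 3

    def test_too_few_shared_cell_types_rejected(self):
        sheet = sheet_for(["c1", "c2"], groups=["blood", "solid"])
        M = pd.DataFrame(np.random.default_rng(2).uniform(size=(3, 4)),
                         columns=sheet.sample_ids)
        with pytest.raises(ValueError, match="shared cell types"):
            xl.loop_expression_correlation(M, M.copy(), pd.DataFrame({
                "loop_id": [0], "gene_id": [0]}), sheet)


class TestIntragenic:
    def setup_method(self):
        # promoter anchor at 100,000; gene-body anchor at 140,000
        self.anchors = anchors_at(100_000, 140_000)
        self.loops = pd.DataFrame({"anchor_a": [0], "anchor_b": [1]}, index=[7])

    def make_gene(self, exon3_fp=142_000, n_exons=4, biotype="protein_coding"):
        tss = 100_000
        exons = [(tss, tss + 300), (tss + 20_000, tss + 20_300)]
        exons.append((exon3_fp, exon3_fp + 300))
        exons.append((tss + 90_000, tss + 90_300))
        return xl.GeneModel("g1", "chr1", "+", tss, tss + 95_000,
                            exons[:n_exons], biotype)

    def test_qualifying_loop_found_with_exon_recorded(self):
        g = self.make_gene(exon3_fp=142_000)  # window [137,000, 142,000) hits anchor b
        out = xl.find_intragenic_loops([g], self.loops, self.anchors)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["loop_id"] == 7 and row["gene_id"] == "g1"
        assert row["body_anchor"] == 1 and row["exon_index"] == 2

    def test_anchor_outside_upstream_window_excluded(self):
        g = self.make_gene(exon3_fp=147_000)  # window starts at 142,000 > anchor end
        out = xl.find_intragenic_loops([g], self.loops, self.anchors)
        assert len(out) == 0

    def test_gene_without_middle_exon_excluded(self):
        g = self.make_gene(n_exons=2)
        assert len(xl.find_intragenic_loops([g], self.loops, self.anchors)) == 0

    def test_non_coding_gene_excluded(self):
        g = self.make_gene(biotype="lncRNA")
        assert len(xl.find_intragenic_loops([g], self.loops, self.anchors)) == 0

    def test_cage_overlapping_exon_removed(self):
        g = self.make_gene(exon3_fp=142_000)
        cage = track_from_tuples([("chr1", 142_100, 142_200)])
        assert len(xl.find_intragenic_loops([g], self.loops, self.anchors, cage)) == 0


class TestExonLoopCorrelation:
    def build(self, rng, coupled=True):
        anchors = anchors_at(100_000, 140_000)
        loops = pd.DataFrame({"anchor_a": [0], "anchor_b": [1]}, index=[7])
        g = xl.GeneModel("g1", "chr1", "+", 100_000, 200_000, [
            (100_000, 100_300),
            (141_000, 141_300),   # within 5 kb of anchor 5' boundary (139,000)
            (150_000, 150_300),   # 9.0 kb from anchor centre -> excluded control
            (190_000, 190_300),   # 50 kb away -> valid control
        ])
        samples = [f"s{i}" for i in range(8)]
        anchor_counts = pd.DataFrame(
            rng.uniform(10, 100, size=(2, 8)), index=[0, 1], columns=samples)
        exon_ids = [f"g1:{i}" for i in range(4)]
        E = pd.DataFrame(rng.uniform(5, 50, size=(4, 8)), index=exon_ids,
                         columns=samples)
        if coupled:
            E.loc["g1:1"] = anchor_counts.loc[1] * 2 + 1
        intra = pd.DataFrame({"loop_id": [7], "gene_id": ["g1"], "exon_index": [1],
                              "body_anchor": [1]})
        return E, anchor_counts, intra, [g], anchors

    def test_real_pair_and_exclusion_rule(self):
        rng = np.random.default_rng(3)
        E, A, intra, genes, anchors = self.build(rng)
        res = xl.exon_loop_correlation(E, A, intra, genes, anchors, n_perm=10, seed=0)
        assert res["n_real_pairs"] == 1
        # exon at 150,000 is within 20 kb of the anchor centre: not a control
        assert res["n_control_pairs"] == 2  # exons 0 (promoter) and 3 (distal)
        assert res["real_r"][0] == pytest.approx(1.0)

    def test_due_restriction(self):
        rng = np.random.default_rng(4)
        E, A, intra, genes, anchors = self.build(rng)
        due = pd.Series(False, index=E.index)
        res = xl.exon_loop_correlation(E, A, intra, genes, anchors, due_flags=due,
                                       n_perm=5, seed=0)
        assert res["n_real_pairs"] == 0


class TestDoseResponse:
    def test_bins_and_tests(self):
        rng = np.random.default_rng(5)
        n = 300
        counts = rng.integers(0, 6, size=n)
        expr = 10 + 5 * np.minimum(counts, 3) + rng.normal(0, 1, size=n)
        rec = pd.DataFrame({"n_linked_enhancers": counts, "expression": expr})
        res = xl.enhancer_dose_response(rec)
        med = res["medians"]
        assert med["1"] < med["2"] < med["3+"]
        assert (res["tests"]["p"] < 0.05).all()
        assert (res["table"]["n_linked_enhancers"] >= 1).all()


class TestCoexpression:
    def test_planted_same_loop_coexpression(self):
        rng = np.random.default_rng(6)
        anchors = anchors_at(100_000, 600_000, 1_100_000, 1_600_000)
        loops = pd.DataFrame({"anchor_a": [0, 2], "anchor_b": [1, 3]}, index=[0, 1])
        genes = []
        # two genes inside loop 0, two genes on the same chrom not in a loop
        for i, (s, e) in enumerate([(150_000, 250_000), (300_000, 400_000),
                                    (2_000_000, 2_100_000), (2_400_000, 2_500_000)]):
            genes.append(xl.GeneModel(f"g{i}", "chr1", "+", s, e, [(s, s + 300)]))
        samples = [f"s{i}" for i in range(6)]
        shared = rng.normal(size=6)
        expr = pd.DataFrame(rng.normal(size=(4, 6)) * 0.2, columns=samples,
                            index=[g.gene_id for g in genes])
        expr.iloc[0] += shared
        expr.iloc[1] += shared
        expr += 10
        out = xl.coexpression_in_loops(genes, loops, anchors, variable_loops=[],
                                       expression=expr)
        same = out[out["category"] == "same_loop"]["median_rho"]
        ctrl = out[out["category"] == "not_same_loop"]["median_rho"]
        assert same.iloc[0] > ctrl.max()
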