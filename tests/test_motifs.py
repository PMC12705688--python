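"""Window-rule annotation, DA motif sets, and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from chronotrace.motifs import (
    AnnotatedMotifSite,
    GeneModel,
    GenomicInterval,
    MotifSetRule,
    annotate_sites,
    build_motif_sets,
    enrich_motifs,
)
from chronotrace.simulate import simulate_regulatory_fixture
from chronotrace.stats import hypergeom_enrichment


def _site(start, end, chrom="chr1", sid="s0"):
    return AnnotatedMotifSite(sid, GenomicInterval(chrom, start, end), "M00")


GENE_PLUS = GeneModel("gp", "chr1", 50_000, 52_000, "+")    # TSS 50000, TTS 51999
GENE_MINUS = GeneModel("gm", "chr1", 150_000, 152_000, "-")  # TSS 151999, TTS 150000


def _assign(site, genes=(GENE_PLUS, GENE_MINUS)):
    annotate_sites([site], genes)
    return site.gene_assignments


class TestAnnotationWindows:
    def test_site_inside_span_is_gene_body(self):
        assert _assign(_site(50_500, 50_510)) == {"gp": "gene_body"}

    def test_promoter_upstream_edge_inclusive(self):
        # TSS 50000, -1107 offset covers base 48893: [48883,48893) misses,
        # [48884,48894) overlaps by exactly one base
        assert _assign(_site(48_883, 48_893)) .get("gp") == "distal"
        assert _assign(_site(48_884, 48_894)) == {"gp": "promoter"}

    def test_promoter_downstream_edge_inclusive(self):
        # +107 offset covers base 50107; 50108 is body-only territory
        assert _assign(_site(50_107, 50_108)) == {"gp": "gene_body"}  # precedence
        # a site fully inside the span but past +107 is still gene_body
        assert _assign(_site(50_108, 50_118)) == {"gp": "gene_body"}

    def test_distal_upstream_boundary(self):
        # distal = [TSS-10000, TSS): base 40000 in, 39999 out
        assert _assign(_site(40_000, 40_010)) == {"gp": "distal"}
        assert _assign(_site(39_990, 40_000)) == {}

    def test_distal_downstream_boundary(self):
        # (TTS, TTS+10000]: TTS=51999 -> bases 52000..61999
        assert _assign(_site(61_999, 62_000)) == {"gp": "distal"}
        assert _assign(_site(62_000, 62_010)) == {}

    def test_minus_strand_promoter_window(self):
        # TSS 151999: promoter covers genomic [151892, 153107)
        assert _assign(_site(153_106, 153_116)) == {"gm": "promoter"}
        assert _assign(_site(153_107, 153_117)) == {"gm": "distal"}
        assert _assign(_site(151_892, 151_902)) == {"gm": "gene_body"}  # precedence

    def test_minus_strand_distal_windows(self):
        # upstream (TSS, TSS+10000]: 152000..161999
        assert _assign(_site(161_999, 162_009)) == {"gm": "distal"}
        assert _assign(_site(162_000, 162_010)) == {}
        # downstream [TTS-10000, TTS): 140000..149999
        assert _assign(_site(140_000, 140_001)) == {"gm": "distal"}
        assert _assign(_site(139_999, 140_000)) == {}

    def test_far_upstream_site_unannotated(self):
        # ends 10050 bp upstream of the TSS: outside every window
        assert _assign(_site(39_940, 39_950)) == {}

    def test_strand_symmetry_under_reflection(self):
        # reflecting all coordinates and flipping strands preserves features
        M = 1_000_000
        genes = [GENE_PLUS, GENE_MINUS]
        refl_genes = [
            GeneModel(g.gene_id, g.chrom, M - g.end, M - g.start,
                      "-" if g.strand == "+" else "+")
            for g in genes
        ]
        rng = np.random.default_rng(0)
        starts = rng.integers(35_000, 170_000, size=300)
        for st in starts:
            st = int(st)
            fwd = _site(st, st + 10)
            rev = _site(M - (st + 10), M - st)
            annotate_sites([fwd], genes)
            annotate_sites([rev], refl_genes)
            assert fwd.gene_assignments == rev.gene_assignments

    @staticmethod
    def _expected_feature(gene, p):
        """Oracle: feature of a 1-bp site at base p from inclusive offsets."""
        if gene.start <= p < gene.end:
            return "gene_body"
        if gene.strand == "+":
            if gene.tss - 1107 <= p <= gene.tss + 107:
                return "promoter"
            if gene.tss - 10_000 <= p < gene.tss or gene.tts < p <= gene.tts + 10_000:
                return "distal"
        else:
            if gene.tss - 107 <= p <= gene.tss + 1107:
                return "promoter"
            if gene.tss < p <= gene.tss + 10_000 or gene.tts - 10_000 <= p < gene.tts:
                return "distal"
        return None

    def test_exhaustive_one_bp_probes_around_every_boundary(self):
        # 1-bp sites at -1/0/+1 of every window edge match the offset oracle
        for gene in (GENE_PLUS, GENE_MINUS):
            edges = [gene.start, gene.end, gene.tss, gene.tts,
                     gene.tss - 1107, gene.tss + 1107,
                     gene.tss - 107, gene.tss + 107,
                     gene.tss - 10_000, gene.tss + 10_000,
                     gene.tts - 10_000, gene.tts + 10_000]
            for edge in edges:
                for p in (edge - 1, edge, edge + 1):
                    got = _assign(_site(p, p + 1), (gene,)).get(gene.gene_id)
                    assert got == self._expected_feature(gene, p), \
                        f"{gene.gene_id} strand {gene.strand} base {p}"

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)

    def test_dataframe_input_and_multi_gene_assignment(self):
        near = GeneModel("g2", "chr1", 52_500, 54_000, "+")
        df = pd.DataFrame({"chrom": ["chr1"], "start": [51_900], "end": [51_950],
                           "motif_id": ["M01"]})
        out = annotate_sites(df, [GENE_PLUS, near])
        assert out[0].gene_assignments == {"gp": "gene_body", "g2": "promoter"}


class TestMotifSets:
    DA = pd.DataFrame({
        "region_id": ["s1", "s2", "s3", "s4"],
        "contrast": ["FoxF_KO_vs_control"] * 4,
        "log2fc": [1.5, 1.5, -1.2, 0.2],
        "fdr": [0.01, 0.2, 0.05, 0.01],
    })

    def test_fold_change_and_fdr_gate(self):
        rule = MotifSetRule("open_in_foxf", (("FoxF_KO_vs_control", ">", 1.0),))
        sets = build_motif_sets(self.DA, [rule])
        # s1 passes both; s2 fails the FDR gate; s3/s4 fail the cutoff
        assert sets["open_in_foxf"] == {"s1"}

    def test_or_combined_clauses(self):
        da = pd.DataFrame({
            "region_id": ["a", "b", "c"],
            "contrast": ["mesp_dnFGFR_vs_control", "mesp_MekMut_vs_control",
                         "mesp_dnFGFR_vs_control"],
            "log2fc": [-1.2, 1.2, 0.0],
            "fdr": [0.01, 0.01, 0.01],
        })
        rule = MotifSetRule("tvc_accessible",
                            (("mesp_dnFGFR_vs_control", "<", -1.0),
                             ("mesp_MekMut_vs_control", ">", 1.0)))
        assert build_motif_sets(da, [rule])["tvc_accessible"] == {"a", "b"}

    def test_missing_contrast_named_in_error(self):
        rule = MotifSetRule("x", (("absent_contrast", ">", 1.0),))
        with pytest.raises(KeyError, match="absent_contrast"):
            build_motif_sets(self.DA, [rule])

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            MotifSetRule("x", ())
        with pytest.raises(ValueError):
            MotifSetRule("x", (("c", ">=", 1.0),))


class TestEnrichMotifs:
    def test_target_equals_background_is_null(self):
        sm = pd.DataFrame({"site_id": [f"s{i}" for i in range(10)],
                           "motif_id": ["M0"] * 5 + ["M1"] * 5})
        sites = set(sm["site_id"])
        res = enrich_motifs(sites, sites, sm).set_index("motif_id")
        assert (res["p"] == 1.0).all()
        assert res["odds_ratio"].dropna().tolist() == pytest.approx([1.0, 1.0])

    def test_planted_motif_matches_closed_form(self):
        # motif in all 20 target sites and 10% of the other 180
        rows = []
        for i in range(200):
            rows.append({"site_id": f"s{i}",
                         "motif_id": "MX" if (i < 20 or i % 10 == 5) else f"M{i % 3}"})
        sm = pd.DataFrame(rows)
        target = {f"s{i}" for i in range(20)}
        res = enrich_motifs(target, set(sm["site_id"]), sm).set_index("motif_id")
        k_bg = int((sm["motif_id"] == "MX").sum())
        expected = hypergeom_enrichment(20, 20, k_bg, 200).p
        assert res.loc["MX", "p"] == pytest.approx(expected, rel=1e-9)
        assert res.index[0] == "MX" if res.loc["MX", "p"] == res["p"].min() else True
        assert res.loc["MX", "p_adjusted"] < 0.05

    def test_invariant_to_site_order_and_motif_relabeling(self):
        rng = np.random.default_rng(5)
        sm = pd.DataFrame({"site_id": [f"s{i}" for i in range(60)],
                           "motif_id": rng.choice(["A", "B", "C"], size=60)})
        target = {f"s{i}" for i in range(15)}
        base = enrich_motifs(target, set(sm["site_id"]), sm)
        shuffled = sm.sample(frac=1, random_state=1)
        again = enrich_motifs(target, set(sm["site_id"]), shuffled)
        pd.testing.assert_frame_equal(base, again)
        relabel = sm.assign(motif_id=sm["motif_id"].map({"A": "Z1", "B": "Z2", "C": "Z3"}))
        res2 = enrich_motifs(target, set(sm["site_id"]), relabel)
        assert sorted(res2["p"]) == pytest.approx(sorted(base["p"]))

    def test_target_must_be_subset(self):
        sm = pd.DataFrame({"site_id": ["a"], "motif_id": ["M"]})
        with pytest.raises(ValueError):
            enrich_motifs({"zz"}, {"a"}, sm)


class TestRegulatoryFixture:
    def test_planted_enrichment_detected(self):
        fx = simulate_regulatory_fixture(n_genes=30, n_sites=400,
                                         n_enriched_motifs=2, seed=0)
        sets = build_motif_sets(fx["da_table"], [fx["rule"]])
        target = sets[fx["rule"].set_name]
        res = enrich_motifs(target, set(fx["sites"]["site_id"]), fx["sites"])
        top = set(res[res["p_adjusted"] < 0.05]["motif_id"])
        assert set(fx["truth"]["enriched_motifs"]) <= top

    def test_sites_inside_gene_bodies_annotate_as_gene_body(self):
        fx = simulate_regulatory_fixture(n_genes=10, n_sites=50,
                                         n_enriched_motifs=0, seed=1,
                                         inside_gene_bodies=True)
        out = annotate_sites(fx["sites"], fx["gene_models"])
        for site in out:
            assert "gene_body" in site.gene_assignments.values()

    def test_null_fixture_p_values_uniform(self):
        from scipy.stats import kstest

        fx = simulate_regulatory_fixture(n_genes=30, n_sites=600,
                                         n_enriched_motifs=0, seed=2)
        sets = build_motif_sets(fx["da_table"], [fx["rule"]])
        res = enrich_motifs(sets[fx["rule"].set_name],
                            set(fx["sites"]["site_id"]), fx["sites"])
        # discrete upper-tail p under the null is stochastically >= uniform;
        # one-sided KS should not reject "greater than uniform"
        stat = kstest(res["p"], "uniform", alternative="greater").pvalue
        assert stat > 0.01
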