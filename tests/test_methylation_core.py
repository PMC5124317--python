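import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylscape import methylation_core as mc
from methylscape.io_formats import CytosineRecord, GeneModel, GenomicInterval

from conftest import cg_site, make_track


def test_site_fraction():
    def rec(m, u):
        return CytosineRecord("c1", 1, "+", m, u, "CG", "CGA")
    assert mc.site_fraction(rec(5, 5)) == 0.5
    assert mc.site_fraction(rec(0, 10)) == 0.0
    assert mc.site_fraction(rec(0, 0)) is None


class TestGlobalLevel:
    def test_mean_of_fractions(self):
        track = make_track([cg_site("c1", 1, 10, 0), cg_site("c1", 5, 0, 10),
                            cg_site("c1", 9, 5, 5)])
        assert mc.global_level(track, ("CG",))["CG"] == pytest.approx(0.5)

    def test_estimators_agree_on_symmetric_coverage(self):
        track = make_track([cg_site("c1", 1, 9, 1), cg_site("c1", 5, 1, 9)])
        for estimator in ("mean_of_fractions", "weighted"):
            assert mc.global_level(track, ("CG",), estimator)["CG"] == \
                pytest.approx(0.5)

    def test_estimators_differ_under_unequal_coverage(self):
        track = make_track([cg_site("c1", 1, 90, 10), cg_site("c1", 5, 1, 9)])
        mof = mc.global_level(track, ("CG",), "mean_of_fractions")["CG"]
        weighted = mc.global_level(track, ("CG",), "weighted")["CG"]
        assert mof == pytest.approx(0.5)
        assert weighted == pytest.approx(91 / 110)

    def test_uncovered_context_is_undefined(self):
        track = make_track([cg_site("c1", 1, 3, 1)])
        levels = mc.global_level(track, ("CG", "CHH"))
        assert levels["CHH"] is None and levels["CG"] == pytest.approx(0.75)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30))
    def test_estimator_equality_under_equal_coverage(self, meths):
        cov = 20
        rows = [cg_site("c1", i + 1, m, cov - m) for i, m in enumerate(meths)]
        track = make_track(rows)
        mof = mc.global_level(track, ("CG",), "mean_of_fractions")["CG"]
        weighted = mc.global_level(track, ("CG",), "weighted")["CG"]
        assert mof == pytest.approx(weighted)

    def test_coverage_filter_excludes_shallow_sites(self):
        track = make_track([cg_site("c1", 1, 1, 0), cg_site("c1", 5, 0, 6)],
                           min_coverage=5)
        assert track.n_covered("CG") == 1
        assert mc.global_level(track, ("CG",))["CG"] == 0.0

    def test_duplicate_records_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_track([cg_site("c1", 1, 1, 1), cg_site("c1", 1, 2, 2)])


class TestFeatureMethylation:
    def test_uniform_track(self):
        track = make_track([cg_site("c1", p, 9, 1) for p in range(1, 50, 5)])
        fm = mc.feature_methylation(track, [GenomicInterval("c1", 0, 50)],
                                    "gene_body", feature_id="g1")
        assert fm.fraction_methylation == pytest.approx(0.9)
        assert fm.n_sites_covered == 10

    def test_empty_interval_set_undefined(self):
        track = make_track([cg_site("c1", 1, 1, 1)])
        fm = mc.feature_methylation(track, [], "intergenic")
        assert fm.fraction_methylation is None and fm.n_sites_covered == 0

    def test_exon_intron_body_hand_arithmetic(self):
        # exon sites at fractions {1.0, 1.0}, intron site at 0.0
        track = make_track([cg_site("c1", 1, 5, 0), cg_site("c1", 30, 5, 0),
                            cg_site("c1", 15, 0, 5)])
        exon = [GenomicInterval("c1", 0, 10), GenomicInterval("c1", 25, 35)]
        intron = [GenomicInterval("c1", 10, 25)]
        body = [GenomicInterval("c1", 0, 35)]
        assert mc.feature_methylation(track, exon, "exon").fraction_methylation \
            == pytest.approx(1.0)
        assert mc.feature_methylation(track, intron, "intron"
                                      ).fraction_methylation == pytest.approx(0.0)
        assert mc.feature_methylation(track, body, "gene_body"
                                      ).fraction_methylation == pytest.approx(2 / 3)

    def test_partition_reconstitutes_weighted_global(self):
        rng = np.random.default_rng(0)
        rows = [cg_site("c1", p, int(m), int(u)) for p, m, u in zip(
            range(1, 400, 4), rng.integers(0, 30, 100),
            rng.integers(1, 30, 100))]
        track = make_track(rows)
        cuts = [0, 57, 130, 260, 400]
        total_m = total_t = 0
        for a, b in zip(cuts, cuts[1:]):
            meth, tot = mc.region_sites(track, [GenomicInterval("c1", a, b)])
            total_m += meth.sum()
            total_t += tot.sum()
        assert total_m / total_t == pytest.approx(
            mc.global_level(track, ("CG",), "weighted")["CG"])


def uniform_gene_track(fractions, start=100, spacing=10, strand="+",
                       contig="c1", contig_len=10_000):
    """A gene covering evenly spaced CpGs with the given site fractions."""
    rows = []
    for i, f in enumerate(fractions):
        m = int(round(f * 10))
        rows.append(cg_site(contig, start + i * spacing + 1, m, 10 - m))
    end = start + len(fractions) * spacing
    gene = GeneModel("g1", GenomicInterval(contig, start, end, strand),
                     exons=[GenomicInterval(contig, start, end, strand)])
    return make_track(rows), gene


class TestMetagene:
    def test_uniform_track_flat_profile(self):
        track, gene = uniform_gene_track([0.5] * 40)
        prof = mc.metagene_profile(track, [gene], n_body_bins=8, flank_bp=0)
        assert np.allclose(prof["mean_fraction"], 0.5)

    def test_increasing_fractions_monotone_bins(self):
        track, gene = uniform_gene_track(np.linspace(0, 1, 40))
        prof = mc.metagene_profile(track, [gene], n_body_bins=8, flank_bp=0)
        vals = prof["mean_fraction"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)

    def test_minus_strand_gene_mirrors_plus_twin(self):
        fr = np.linspace(0.1, 0.9, 30)
        L = 5_000
        rows = []
        for i, f in enumerate(fr):
            m = int(round(f * 10))
            pos_plus = 100 + i * 10          # 0-based
            rows.append(cg_site("p", pos_plus + 1, m, 10 - m))
            rows.append(cg_site("m", L - 1 - pos_plus + 1, m, 10 - m))
        end = 100 + len(fr) * 10
        gene_p = GeneModel("gp", GenomicInterval("p", 100, end, "+"),
                           exons=[GenomicInterval("p", 100, end, "+")])
        gene_m = GeneModel("gm", GenomicInterval("m", L - end, L - 100, "-"),
                           exons=[GenomicInterval("m", L - end, L - 100, "-")])
        track = make_track(rows)
        prof_p = mc.metagene_profile(track, [gene_p], n_body_bins=6,
                                     flank_bp=0)
        prof_m = mc.metagene_profile(track, [gene_m], n_body_bins=6,
                                     flank_bp=0)
        np.testing.assert_allclose(prof_p["mean_fraction"],
                                   prof_m["mean_fraction"])

    def test_flank_truncated_at_contig_edge(self):
        track, gene = uniform_gene_track([0.5] * 10, start=100)
        prof = mc.metagene_profile(track, [gene], n_body_bins=4,
                                   flank_bp=500, flank_bin_bp=100,
                                   contig_lengths={"c1": 250})
        assert len(prof) == 4 + 2 * 5  # bins exist; edge bins just lack data

    def test_gene_flanks_strandedness(self):
        g = GeneModel("g", GenomicInterval("c1", 1000, 2000, "-"))
        up, down = mc.gene_flanks(g, 500)
        assert (up.start, up.end) == (2000, 2500)
        assert (down.start, down.end) == (500, 1000)


class TestHistogram:
    def test_two_bins(self):
        track = make_track([cg_site("c1", 1, 0, 5), cg_site("c1", 3, 0, 5),
                            cg_site("c1", 5, 5, 0), cg_site("c1", 7, 5, 0)])
        assert mc.site_level_histogram(track, "CG", 2).tolist() == [2, 2]

    def test_empty_track_all_zero(self):
        track = make_track([("c1", 1, "+", 0, 0, "CG", "CGA")], min_coverage=1)
        assert mc.site_level_histogram(track, "CG", 5).sum() == 0

    def test_sums_to_covered_sites(self, tiny_sim):
        _, manifest = tiny_sim
        track = mc.MethylationTrack.from_report(
            manifest["paths"]["report_replete"])
        hist = mc.site_level_histogram(track, "CG", 20)
        assert hist.sum() == track.n_covered("CG")

    def test_simulated_histogram_is_bimodal(self, tiny_sim):
        _, manifest = tiny_sim
        track = mc.MethylationTrack.from_report(
            manifest["paths"]["report_replete"])
        hist = mc.site_level_histogram(track, "CG", 20)
        assert mc.bimodality_index(hist) > 0.3
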