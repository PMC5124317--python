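import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylscape import genemodels as gm
from methylscape.io_formats import GeneModel, GenomicInterval, write_fasta


def gene(gid, start, end, strand="+", contig="c1", cds=None):
    iv = GenomicInterval(contig, start, end, strand)
    cds_ivals = [GenomicInterval(contig, s, e, strand) for s, e in (cds or [])]
    return GeneModel(gid, iv, exons=[iv], cds=cds_ivals or [iv])


def fpkm_table(values):
    return pd.DataFrame({"s1": values}, index=list(values.keys())) \
        if isinstance(values, dict) else values


class TestHighConfidenceModels:
    def test_hand_evaluation_of_both_rules(self):
        a = [gene("a1", 0, 100), gene("a2", 200, 300), gene("a3", 400, 500)]
        b = [gene("b1", 50, 150), gene("b2", 250, 350)]
        fpkm = pd.DataFrame({"s1": [2.0, 0.0, 3.0]}, index=["a1", "a2", "a3"])
        selected, report = gm.high_confidence_models(a, b, fpkm)
        assert [g.gene_id for g in selected] == ["a1"]
        assert report["n_removed_no_overlap"] == 1
        assert report["n_removed_zero_fpkm"] == 1

    def test_empty_predictor_b_selects_nothing(self):
        a = [gene("a1", 0, 100)]
        selected, _ = gm.high_confidence_models(
            a, [], pd.DataFrame({"s1": [1.0]}, index=["a1"]))
        assert selected == []

    def test_identity_with_positive_fpkm_selects_all(self):
        a = [gene("a1", 0, 100), gene("a2", 200, 300)]
        fpkm = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a1", "a2"])
        selected, _ = gm.high_confidence_models(a, list(a), fpkm)
        assert [g.gene_id for g in selected] == ["a1", "a2"]

    def test_strand_must_match(self):
        a = [gene("a1", 0, 100, "+")]
        b = [gene("b1", 0, 100, "-")]
        selected, report = gm.high_confidence_models(
            a, b, pd.DataFrame({"s1": [1.0]}, index=["a1"]))
        assert selected == [] and report["n_removed_no_overlap"] == 1

    def test_missing_fpkm_treated_as_zero(self):
        a = [gene("a1", 0, 100)]
        selected, report = gm.high_confidence_models(
            a, list(a), pd.DataFrame({"s1": []}, dtype=float))
        assert selected == []
        assert report["n_missing_fpkm"] == 1

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 15),
                              st.floats(0, 5)), min_size=1, max_size=8),
           st.lists(st.tuples(st.integers(0, 40), st.integers(1, 15)),
                    min_size=0, max_size=8),
           st.tuples(st.integers(0, 40), st.integers(1, 15)))
    def test_selection_monotone_in_b_and_fpkm(self, a_spec, b_spec, extra_b):
        a = [gene(f"a{i}", s * 10, s * 10 + w * 10)
             for i, (s, w, _) in enumerate(a_spec)]
        fpkm = pd.DataFrame({"s1": [f for _, _, f in a_spec]},
                            index=[g.gene_id for g in a])
        b = [gene(f"b{i}", s * 10, s * 10 + w * 10)
             for i, (s, w) in enumerate(b_spec)]
        sel_before, _ = gm.high_confidence_models(a, b, fpkm)
        grown = b + [gene("bx", extra_b[0] * 10,
                          extra_b[0] * 10 + extra_b[1] * 10)]
        sel_after, _ = gm.high_confidence_models(a, grown, fpkm)
        assert {g.gene_id for g in sel_before} <= {g.gene_id for g in sel_after}
        # zeroing any FPKM row never grows the selection
        if len(a):
            zeroed = fpkm.copy()
            zeroed.iloc[0] = 0.0
            sel_zero, _ = gm.high_confidence_models(a, b, zeroed)
            assert {g.gene_id for g in sel_zero} <= \
                {g.gene_id for g in sel_before}


class TestGenomeStats:
    def write_genome(self, tmp_path, length=1000, contig="c1"):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=length))
        path = tmp_path / "g.fa"
        write_fasta({contig: seq}, path)
        return path

    def test_forced_arithmetic(self, tmp_path):
        fa = self.write_genome(tmp_path)
        g = gene("g1", 100, 700, cds=[(100, 700)])
        stats = gm.genome_stats([g], fa)
        assert stats.percent_coding_dna == pytest.approx(60.0)
        assert stats.gene_density == pytest.approx(1000.0)
        assert stats.mean_model_length == 600.0
        assert stats.mean_exons_per_gene == 1.0

    def test_overlapping_cds_counted_once(self, tmp_path):
        fa = self.write_genome(tmp_path)
        g1 = gene("g1", 0, 100, cds=[(0, 100)])
        g2 = gene("g2", 50, 150, cds=[(50, 150)])
        stats = gm.genome_stats([g1, g2], fa)
        assert stats.percent_coding_dna == pytest.approx(15.0)  # 150 of 1000

    def test_zero_genes_is_na_safe(self, tmp_path):
        fa = self.write_genome(tmp_path)
        stats = gm.genome_stats([], fa)
        assert stats.n_models == 0
        assert stats.mean_model_length == 0.0
        assert stats.percent_coding_dna == 0.0

    def test_gene_beyond_contig_named_in_error(self, tmp_path):
        fa = self.write_genome(tmp_path)
        with pytest.raises(ValueError, match="gRunaway"):
            gm.genome_stats([gene("gRunaway", 900, 1100)], fa)

    def test_intron_exon_count_relation(self, tmp_path):
        fa = self.write_genome(tmp_path, length=2000)
        iv = GenomicInterval("c1", 0, 1000)
        g = GeneModel("g1", iv,
                      exons=[GenomicInterval("c1", 0, 200),
                             GenomicInterval("c1", 400, 600),
                             GenomicInterval("c1", 800, 1000)],
                      cds=[GenomicInterval("c1", 0, 200)])
        stats = gm.genome_stats([g], fa)
        assert stats.mean_exons_per_gene == 3.0
        assert stats.mean_introns_per_gene == 2.0
        assert stats.mean_intron_length == 200.0

    def test_simulator_truth_recovered(self, tiny_sim, tiny_run):
        profile, manifest = tiny_sim
        _, _, out, summary = tiny_run
        # consensus selection recovers exactly the placed (non-decoy) genes
        assert summary["models"]["n_selected"] == \
            manifest["counts"]["n_genes_real"]
        stats = summary["genome_stats"]
        assert stats["total_models"] == manifest["counts"]["n_genes_real"]
        expected_density = manifest["counts"]["n_genes_real"] / (
            manifest["counts"]["genome_length"] / 1e6)
        assert stats["gene_density_per_mbp"] == pytest.approx(expected_density)
        assert stats["gc_content"] == pytest.approx(profile.gc_content,
                                                    abs=0.01)
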