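import numpy as np
import pandas as pd
import pytest

from methylscape import gene_status as gs
from methylscape.io_formats import GeneModel, GenomicInterval

from conftest import cg_site, make_track


class TestClassifyGene:
    def test_basic_calls(self):
        assert gs.classify_gene(0.9, 10) == "methylated"
        assert gs.classify_gene(0.1, 10) == "unmethylated"

    def test_insufficient_sites_is_undetermined_regardless_of_fraction(self):
        assert gs.classify_gene(0.99, 3) == "undetermined"
        assert gs.classify_gene(0.01, 4) == "undetermined"

    def test_tie_goes_up(self):
        assert gs.classify_gene(0.5, 10) == "methylated"


def toy_statuses():
    return pd.DataFrame({
        "fraction": [0.8, 1.0, 0.0, 0.1, 0.7],
        "n_sites": [10, 10, 10, 10, 2],
        "status": ["methylated", "methylated", "unmethylated", "unmethylated",
                   "undetermined"],
        "sum_fpkm": [4.0, 8.0, 1000.0, 2000.0, 1.0],
        "mean_fpkm": [2.0, 4.0, 500.0, 1000.0, 0.5],
    }, index=[f"g{i}" for i in range(5)])


class TestClassSummary:
    def test_hand_arithmetic(self):
        summary = gs.class_summary(toy_statuses())
        assert summary.loc["methylated", "proportion"] == pytest.approx(0.5)
        assert summary.loc["unmethylated", "proportion"] == pytest.approx(0.5)
        assert summary.loc["methylated", "mean_fraction"] == pytest.approx(0.9)
        assert summary.loc["unmethylated", "mean_fraction"] == pytest.approx(0.05)
        assert summary.loc["methylated", "mean_fpkm"] == pytest.approx(3.0)

    def test_counts_partition_all_genes(self):
        summary = gs.class_summary(toy_statuses())
        assert summary["n_genes"].sum() == 5

    def test_all_methylated(self):
        statuses = toy_statuses().iloc[:2]
        summary = gs.class_summary(statuses)
        assert summary.loc["methylated", "proportion"] == 1.0

    def test_no_determined_genes_is_error(self):
        statuses = toy_statuses().iloc[[4]]
        with pytest.raises(ValueError, match="determined"):
            gs.class_summary(statuses)


def paired_tracks(fractions, invert=False):
    rows_a, rows_b = [], []
    for i, f in enumerate(fractions):
        m = int(round(f * 10))
        rows_a.append(cg_site("c1", i * 10 + 1, m, 10 - m))
        mb = 10 - m if invert else m
        rows_b.append(cg_site("c1", i * 10 + 1, mb, 10 - mb))
    return make_track(rows_a), make_track(rows_b)


def genes_over(fractions, genes_of=10):
    out = []
    n = len(fractions) // genes_of
    for k in range(n):
        a, b = k * genes_of * 10, (k + 1) * genes_of * 10
        out.append(GeneModel(f"g{k}", GenomicInterval("c1", a, b, "+")))
    return out


class TestConditionCorrelation:
    fr = list(np.linspace(0.05, 0.95, 60))

    def test_identical_tracks_give_unit_correlation(self):
        ta, tb = paired_tracks(self.fr)
        res = gs.condition_correlation(ta, tb, genes=genes_over(self.fr))
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_sitewise_inversion_gives_minus_one(self):
        ta, tb = paired_tracks(self.fr, invert=True)
        res = gs.condition_correlation(ta, tb, genes=genes_over(self.fr))
        assert res["pearson_r"] == pytest.approx(-1.0)

    def test_symmetric_in_tracks(self):
        rng = np.random.default_rng(1)
        fr2 = rng.random(60)
        ta, _ = paired_tracks(self.fr)
        tb, _ = paired_tracks(list(fr2))
        genes = genes_over(self.fr)
        r_ab = gs.condition_correlation(ta, tb, genes=genes)["pearson_r"]
        r_ba = gs.condition_correlation(tb, ta, genes=genes)["pearson_r"]
        assert r_ab == pytest.approx(r_ba)

    def test_window_unit(self):
        ta, tb = paired_tracks(self.fr)
        res = gs.condition_correlation(ta, tb, unit="window", window=100)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["n_units"] >= 3

    def test_too_few_shared_units_is_error(self):
        ta, tb = paired_tracks(self.fr[:10])
        with pytest.raises(ValueError, match=">= 3"):
            gs.condition_correlation(ta, tb, genes=genes_over(self.fr[:10]))


def status_frame(calls):
    return pd.DataFrame({"status": calls},
                        index=[f"g{i}" for i in range(len(calls))])


class TestSharedOrthologStatus:
    def test_hand_count(self):
        a = pd.DataFrame({"status": ["methylated", "methylated"]},
                         index=["a", "b"])
        b = pd.DataFrame({"status": ["methylated", "unmethylated"]},
                         index=["x", "y"])
        pairs = pd.DataFrame({"gene_a": ["a", "b"], "gene_b": ["x", "y"]})
        counts = gs.shared_ortholog_status(a, b, pairs)
        assert counts["both_methylated"] == 1
        assert counts["either_methylated"] == 2
        assert counts["neither"] == 0

    def test_empty_pair_table(self):
        counts = gs.shared_ortholog_status(
            status_frame(["methylated"]), status_frame(["methylated"]),
            pd.DataFrame(columns=["gene_a", "gene_b"]))
        assert counts["n_pairs_used"] == 0 and counts["both_methylated"] == 0

    def test_identity_pairs_count_methylated_genes(self):
        calls = ["methylated", "unmethylated", "methylated", "unmethylated"]
        table = status_frame(calls)
        pairs = pd.DataFrame({"gene_a": table.index, "gene_b": table.index})
        counts = gs.shared_ortholog_status(table, table, pairs)
        assert counts["both_methylated"] == 2

    def test_dangling_ids_excluded_and_counted(self):
        a = status_frame(["methylated"])
        b = status_frame(["methylated"])
        pairs = pd.DataFrame({"gene_a": ["g0", "ghost"],
                              "gene_b": ["g0", "g0"]})
        counts = gs.shared_ortholog_status(a, b, pairs)
        assert counts["n_dangling"] == 1 and counts["n_pairs_used"] == 1


class TestStatusRecovery:
    def test_classification_recovers_simulated_truth(self, tiny_run):
        profile, manifest, out, summary = tiny_run
        truth = pd.read_csv(manifest["paths"]["gene_truth"], sep="\t",
                            index_col=0)
        statuses = pd.read_csv(out / "status_replete.tsv", sep="\t",
                               index_col=0)
        merged = truth.join(statuses, how="inner")
        det = merged[(merged["status"] != "undetermined")
                     & (~merged["is_decoy"])]
        agree = (det["status"] == det["status_truth"]).mean()
        assert agree >= 0.99
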