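import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from methylscape import synthetic_data as sd
from methylscape.io_formats import read_bed


def file_hashes(directory):
    out = {}
    for p in sorted(Path(directory).iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestExpectedSummaries:
    def test_default_profile_calibration(self):
        exp = sd.expected_summaries(sd.ccryptica_profile())
        assert exp["global_cg_level"] == pytest.approx(0.61, abs=0.005)
        assert exp["repeat_fraction"] == pytest.approx(0.528)
        assert exp["p_methylated_gene"] == pytest.approx(0.23)
        assert exp["mean_fpkm_methylated"] == pytest.approx(492, rel=0.01)
        assert exp["mean_fpkm_unmethylated"] == pytest.approx(4470, rel=0.01)
        assert exp["p_methylated_given_low_fpkm"] == pytest.approx(0.947,
                                                                   abs=0.005)

    def test_symmetric_profile_gives_half(self):
        prof = sd.ccryptica_profile(mu_hyper=0.5, mu_meth_gene=0.5,
                                    mu_unmeth_gene=0.5,
                                    mu_hypo_intergenic=0.5)
        assert sd.expected_summaries(prof)["global_cg_level"] == pytest.approx(0.5)

    def test_no_hyper_domains_degenerates_to_hypo_mixture(self):
        prof = sd.ccryptica_profile(hyper_domain_fraction=0.0)
        exp = sd.expected_summaries(prof)
        g = prof.genic_fraction_within_hypo
        expected = g * prof.mu_unmeth_gene + (1 - g) * prof.mu_hypo_intergenic
        assert exp["global_cg_level"] == pytest.approx(expected)
        assert exp["repeat_fraction"] == 0.0

    def test_lognormal_mean_formula(self):
        assert sd.lognormal_mean(6.6, 1.9) == pytest.approx(
            np.exp(6.6 + 1.9 ** 2 / 2))


class TestProfileValidation:
    @pytest.mark.parametrize("field,value", [
        ("hyper_domain_fraction", 1.4),
        ("mu_hyper", 0.0),
        ("coverage_mean", -1.0),
        ("gc_content", -0.1),
    ])
    def test_invalid_profile_rejected_before_any_file(self, tmp_path, field, value):
        prof = dataclasses.replace(sd.ccryptica_profile(), **{field: value})
        out = tmp_path / "never"
        with pytest.raises(ValueError):
            sd.simulate(prof, out)
        assert not out.exists()

    def test_with_n_genes_scales_genome(self):
        prof = sd.ccryptica_profile().with_n_genes(5000)
        # expected-count formula inverted: ~45 Mbp for the default geometry
        assert prof.genome_length == pytest.approx(45.3e6, rel=0.02)


class TestSimulationOutputs:
    def test_same_seed_byte_identical(self, tmp_path):
        prof = sd.ccryptica_profile(seed=3, n_contigs=1, contig_length=60_000)
        sd.simulate(prof, tmp_path / "a")
        sd.simulate(prof, tmp_path / "b")
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_domain_truth_tiles_each_contig(self, tiny_sim):
        profile, manifest = tiny_sim
        domains = read_bed(manifest["paths"]["domains_truth"])
        by_contig = {}
        for iv in domains:
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        assert len(by_contig) == profile.n_contigs
        for intervals in by_contig.values():
            intervals.sort()
            assert intervals[0][0] == 0
            assert intervals[-1][1] == profile.contig_length
            for (_, e), (s, _) in zip(intervals, intervals[1:]):
                assert s == e  # no gaps, no overlaps

    def test_truth_levels_shared_between_conditions(self, tiny_sim):
        profile, manifest = tiny_sim
        truth = pd.read_csv(manifest["paths"]["site_truth"], sep="\t")
        for cond in ("replete", "deplete"):
            rep = pd.read_csv(manifest["paths"][f"report_{cond}"], sep="\t",
                              header=None,
                              names=["contig", "pos", "strand", "m", "u",
                                     "context", "tri"])
            merged = truth.merge(rep, on=["contig", "pos", "strand"])
            assert len(merged) == len(truth)
            cov = merged["m"] + merged["u"]
            well = merged[(cov >= 20) & (merged["context_x"] == "CG")]
            frac = well["m"] / (well["m"] + well["u"])
            # counts are binomial draws around the one shared truth
            r = np.corrcoef(frac, well["true_level"])[0, 1]
            assert r > 0.95

    def test_repeat_fraction_matches_closed_form(self, tiny_sim):
        profile, manifest = tiny_sim
        expected = sd.expected_summaries(profile)["repeat_fraction"]
        assert manifest["counts"]["repeat_fraction"] == pytest.approx(
            expected, abs=0.05)

    def test_degenerate_profile_without_hyper_domains(self, tmp_path):
        prof = sd.ccryptica_profile(seed=2, n_contigs=1, contig_length=50_000,
                                    hyper_domain_fraction=0.0)
        manifest = sd.simulate(prof, tmp_path)
        domains = read_bed(manifest["paths"]["domains_truth"])
        assert len(domains) == 1 and len(domains[0]) == 50_000
        assert manifest["counts"]["repeat_bases"] == 0
        assert manifest["counts"]["n_genes_methylated_truth"] == 0

    def test_gene_count_tracks_request(self, tmp_path):
        prof = sd.ccryptica_profile(seed=4, contig_length=200_000
                                    ).with_n_genes(200)
        manifest = sd.simulate(prof, tmp_path, contexts=("CG",))
        assert manifest["counts"]["n_genes_real"] == pytest.approx(200, rel=0.15)

    def test_predictor_structure_fractions(self, tiny_sim):
        profile, manifest = tiny_sim
        c = manifest["counts"]
        n_a = c["n_predictor_a"]
        assert c["n_decoys"] / n_a == pytest.approx(profile.frac_a_only,
                                                    abs=0.05)
        assert c["n_zero_fpkm"] / n_a == pytest.approx(profile.frac_zero_fpkm,
                                                       abs=0.05)
        assert c["n_predictor_b"] == c["n_genes_real"]

    def test_manifest_json_round_trips(self, tiny_sim):
        _, manifest = tiny_sim
        on_disk = json.loads(
            (manifest["paths"]["genome"].parent / "manifest.json").read_text())
        assert on_disk["counts"] == manifest["counts"]
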