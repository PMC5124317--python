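import json

import pandas as pd
import pytest

from methylscape import pipeline
from methylscape import synthetic_data as sd
from methylscape.methylation_core import MethylationTrack


def make_track(rows, min_coverage=1):
    """Build a MethylationTrack from (contig, pos, strand, meth, unmeth,
    context, trinucleotide) tuples."""
    frame = pd.DataFrame(rows, columns=[
        "contig", "pos", "strand", "count_meth", "count_unmeth",
        "context", "trinucleotide"])
    return MethylationTrack(frame, min_coverage=min_coverage)


def cg_site(contig, pos, meth, unmeth, strand="+"):
    return (contig, pos, strand, meth, unmeth, "CG", "CGA")


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """Two-contig 300-kb dataset, all contexts, with per-site truth levels."""
    out = tmp_path_factory.mktemp("tiny_sim")
    profile = sd.ccryptica_profile(seed=5, n_contigs=2, contig_length=150_000)
    manifest = sd.simulate(profile, out, write_site_truth=True)
    return profile, manifest


@pytest.fixture(scope="session")
def tiny_run(tiny_sim, tmp_path_factory):
    profile, manifest = tiny_sim
    out = tmp_path_factory.mktemp("tiny_run")
    cfg = pipeline.RunConfig.from_manifest(
        manifest["paths"]["genome"].parent / "manifest.json",
        out_dir=str(out), n_permutations=200, seed=7)
    return profile, manifest, out, pipeline.run_all(cfg)


@pytest.fixture(scope="session")
def sim_5mb(tmp_path_factory):
    """Default-profile 5-Mbp genome, all contexts (the genome-scale study)."""
    out = tmp_path_factory.mktemp("sim5mb")
    profile = sd.ccryptica_profile(seed=1)
    manifest = sd.simulate(profile, out)
    return profile, manifest


@pytest.fixture(scope="session")
def run_5mb(sim_5mb, tmp_path_factory):
    profile, manifest = sim_5mb
    out = tmp_path_factory.mktemp("run5mb")
    cfg = pipeline.RunConfig.from_manifest(
        manifest["paths"]["genome"].parent / "manifest.json",
        out_dir=str(out), n_permutations=200, seed=1)
    return profile, manifest, out, pipeline.run_all(cfg)


@pytest.fixture(scope="session")
def sim_5k(tmp_path_factory):
    """Default profile scaled to ~5000 gene models, CG-context reports."""
    out = tmp_path_factory.mktemp("sim5k")
    profile = sd.ccryptica_profile(seed=1).with_n_genes(5000)
    manifest = sd.simulate(profile, out, contexts=("CG",))
    return profile, manifest


@pytest.fixture(scope="session")
def run_5k(sim_5k, tmp_path_factory):
    profile, manifest = sim_5k
    out = tmp_path_factory.mktemp("run5k")
    cfg = pipeline.RunConfig.from_manifest(
        manifest["paths"]["genome"].parent / "manifest.json",
        out_dir=str(out), n_permutations=200, seed=1)
    return profile, manifest, out, pipeline.run_all(cfg)


def load_manifest(manifest, key):
    return manifest["paths"][key]


def read_summary(out_dir):
    with open(out_dir / "summary.json") as fh:
        return json.load(fh)
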