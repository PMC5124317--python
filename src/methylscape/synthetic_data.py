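"""Seeded generator for a complete toy methylome dataset.

The generator emulates the large-scale architecture of a repeat-rich,
heavily methylated diatom genome: contigs tile into alternating
hypermethylated and hypomethylated domains (hyper domains repeat-dense, up
to ~30 kb long), genes sit mostly in the hypomethylated territory, a minority
of genes are themselves methylated and live inside hyper domains, per-site
methylation levels are Beta-distributed around class means (so the per-site
histogram is bimodal), read counts are binomial at Poisson coverage, and
expression is drawn from methylation-status-conditional lognormal mixtures.

Everything a run produces — genome FASTA, two predictor GFF3s, repeat BED,
two-condition cytosine reports, FPKM/taxonomy/ortholog tables, truth tables —
is written to one output directory under a JSON manifest.  Identical seeds
give byte-identical outputs.

The companion :func:`expected_summaries` returns the closed-form expectations
implied by a profile (global CG level, class means, repeat fraction,
conditional methylation probability at low FPKM, ...) and is the calibration
oracle the default profile was tuned against.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_fasta,
    write_gff3_genes,
)

# per-base class codes used while painting contigs
_HYPO_INTERGENIC, _HYPER_INTERGENIC, _METH_GENE, _UNMETH_GENE = 0, 1, 2, 3
_BASES = np.array(["A", "C", "G", "T"])
_A, _C, _G, _T = 0, 1, 2, 3

CONDITIONS = ("replete", "deplete")


@dataclass(frozen=True)
class SimProfile:
    """Full parameter set of the synthetic methylome generator.

    The defaults are the ``ccryptica`` profile: a calibration for which the
    closed-form expectations (:func:`expected_summaries`) reproduce the
    headline summaries of a heavily methylated centric diatom genome —
    ~61% global CG level, 23% methylated genes with class mean methylation
    88% vs 7%, class mean FPKM ~490 vs ~4470, ~53% repeat coverage, and
    ~95% methylated genes among genes below 10 FPKM.
    """

    seed: int = 0
    n_contigs: int = 10
    contig_length: int = 500_000
    gc_content: float = 0.43

    # domain architecture
    hyper_domain_fraction: float = 0.66
    domain_length_mean: float = 15_000.0
    domain_length_max: float = 30_000.0
    domain_length_min: float = 2_000.0
    repeat_coverage_within_hyper: float = 0.80
    repeat_chunk: int = 1_000

    # gene placement
    genic_fraction_within_hypo: float = 0.50
    p_methylated_gene: float = 0.23
    gene_length_mean: float = 2_000.0
    exon_number_mean: float = 3.0

    # site-level methylation (Beta means, shared concentration)
    mu_hyper: float = 0.90
    mu_meth_gene: float = 0.88
    mu_unmeth_gene: float = 0.07
    mu_hypo_intergenic: float = 0.03
    beta_concentration: float = 50.0
    chg_level: float = 0.03
    chh_level: float = 0.03
    coverage_mean: float = 30.0

    # expression (status-conditional lognormal mixtures, FPKM units)
    fpkm_meth_weights: tuple[float, ...] = (0.8, 0.2)
    fpkm_meth_meanlog: tuple[float, ...] = (0.5, 7.3)
    fpkm_meth_sdlog: tuple[float, ...] = (1.5, 1.0)
    fpkm_unmeth_meanlog: float = 6.6
    fpkm_unmeth_sdlog: float = 1.9
    n_samples_per_condition: int = 2
    sample_noise_sdlog: float = 0.05

    # taxonomy: (group, genome weight, P(methylated | group))
    taxonomy_groups: tuple[tuple[str, float, float], ...] = (
        ("diatom", 0.62, 0.1521),
        ("unknown", 0.20, 0.5405),
        ("opisthokont", 0.05, 0.1530),
        ("bacteria", 0.05, 0.1530),
        ("sar_excluding_diatoms", 0.04, 0.1530),
        ("archaeplastida", 0.04, 0.1530),
    )

    # predictor structure
    frac_a_only: float = 0.2      # predictor-A models lacking a B overlap
    frac_zero_fpkm: float = 0.1   # models with sum FPKM exactly 0
    boundary_jitter: int = 100    # bp jitter of predictor-B spans

    # cross-species ortholog emulation
    n_ortholog_pairs: int = 200
    p_meth_species_b: float = 0.05

    @property
    def genome_length(self) -> int:
        return self.n_contigs * self.contig_length

    def validate(self) -> None:
        fractions = {
            "gc_content": self.gc_content,
            "hyper_domain_fraction": self.hyper_domain_fraction,
            "repeat_coverage_within_hyper": self.repeat_coverage_within_hyper,
            "genic_fraction_within_hypo": self.genic_fraction_within_hypo,
            "p_methylated_gene": self.p_methylated_gene,
            "frac_a_only": self.frac_a_only,
            "frac_zero_fpkm": self.frac_zero_fpkm,
            "p_meth_species_b": self.p_meth_species_b,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("mu_hyper", "mu_meth_gene", "mu_unmeth_gene",
                     "mu_hypo_intergenic", "chg_level", "chh_level"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")
        if self.n_contigs < 1 or self.contig_length < 1000:
            raise ValueError("genome too small to simulate")
        if not math.isclose(sum(w for _, w, _ in self.taxonomy_groups), 1.0,
                            abs_tol=1e-6):
            raise ValueError("taxonomy group weights must sum to 1")
        if len(self.fpkm_meth_weights) != len(self.fpkm_meth_meanlog) or \
                len(self.fpkm_meth_weights) != len(self.fpkm_meth_sdlog):
            raise ValueError("methylated-FPKM mixture parameter lengths differ")
        if not math.isclose(sum(self.fpkm_meth_weights), 1.0, abs_tol=1e-6):
            raise ValueError("methylated-FPKM mixture weights must sum to 1")

    def with_n_genes(self, n_genes: int, contig_length: int | None = None
                     ) -> "SimProfile":
        """Scale the genome so ~``n_genes`` gene models are placed.

        Expected gene count is ``G * (1-h) * g / L / (1-p)`` with G the genome
        length, h the hyper fraction, g the genic fraction of hypo territory,
        L the mean gene length and p the methylated-gene share; this inverts
        that relation.
        """
        h, g, p = (self.hyper_domain_fraction, self.genic_fraction_within_hypo,
                   self.p_methylated_gene)
        if h >= 1.0 or g <= 0.0:
            raise ValueError("profile places no genes; cannot scale")
        genome = n_genes * (1.0 - p) * self.gene_length_mean / ((1.0 - h) * g)
        clen = contig_length or self.contig_length
        n_contigs = max(1, int(round(genome / clen)))
        return dataclasses.replace(self, n_contigs=n_contigs, contig_length=clen)


def ccryptica_profile(**overrides) -> SimProfile:
    """The default calibrated profile (see :class:`SimProfile`)."""
    return dataclasses.replace(SimProfile(), **overrides)


# ---------------------------------------------------------------------------
# closed-form expectations (the calibration oracle)
# ---------------------------------------------------------------------------

def lognormal_mean(meanlog: float, sdlog: float) -> float:
    return math.exp(meanlog + sdlog ** 2 / 2.0)


def _hyper_genic_share(profile: SimProfile) -> float:
    """Expected share of hyper-domain territory occupied by (methylated) genes."""
    h, g, p = (profile.hyper_domain_fraction, profile.genic_fraction_within_hypo,
               profile.p_methylated_gene)
    if h == 0.0 or p == 1.0:
        return 0.0
    return (1.0 - h) * g * p / ((1.0 - p) * h)


def expected_summaries(profile: SimProfile, low_fpkm_max: float = 10.0) -> dict:
    """Pure-arithmetic expectations implied by a profile.

    The global CG level decomposes over territory classes: hyper domains at
    ``mu_hyper`` (minus the genic share valued at ``mu_meth_gene``) and hypo
    domains split between unmethylated gene bodies and hypo intergenic
    background.  Lognormal means are ``exp(meanlog + sdlog^2 / 2)``; the
    conditional probability of being methylated at low FPKM follows from
    Bayes' rule on the two status-conditional FPKM distributions.
    """
    profile.validate()
    h = profile.hyper_domain_fraction
    g = profile.genic_fraction_within_hypo
    p = profile.p_methylated_gene if h > 0 else 0.0
    f_gh = _hyper_genic_share(profile)
    hyper_mean = (1.0 - f_gh) * profile.mu_hyper + f_gh * profile.mu_meth_gene
    hypo_mean = (g * profile.mu_unmeth_gene
                 + (1.0 - g) * profile.mu_hypo_intergenic)
    global_cg = h * hyper_mean + (1.0 - h) * hypo_mean

    mean_fpkm_meth = sum(
        w * lognormal_mean(m, s)
        for w, m, s in zip(profile.fpkm_meth_weights, profile.fpkm_meth_meanlog,
                           profile.fpkm_meth_sdlog)
    )
    mean_fpkm_unmeth = lognormal_mean(profile.fpkm_unmeth_meanlog,
                                      profile.fpkm_unmeth_sdlog)

    log_t = math.log(low_fpkm_max) if low_fpkm_max > 0 else -math.inf
    p_low_meth = sum(
        w * stats.norm.cdf((log_t - m) / s)
        for w, m, s in zip(profile.fpkm_meth_weights, profile.fpkm_meth_meanlog,
                           profile.fpkm_meth_sdlog)
    )
    p_low_unmeth = stats.norm.cdf(
        (log_t - profile.fpkm_unmeth_meanlog) / profile.fpkm_unmeth_sdlog)
    denom = p * p_low_meth + (1.0 - p) * p_low_unmeth
    p_meth_given_low = p * p_low_meth / denom if denom > 0 else float("nan")

    return {
        "global_cg_level": global_cg,
        "global_chg_level": profile.chg_level,
        "global_chh_level": profile.chh_level,
        "p_methylated_gene": p,
        "class_mean_methylated": profile.mu_meth_gene,
        "class_mean_unmethylated": profile.mu_unmeth_gene,
        "mean_fpkm_methylated": mean_fpkm_meth,
        "mean_fpkm_unmethylated": mean_fpkm_unmeth,
        "repeat_fraction": h * profile.repeat_coverage_within_hyper,
        "p_low_fpkm_given_methylated": p_low_meth,
        "p_low_fpkm_given_unmethylated": p_low_unmeth,
        "p_methylated_given_low_fpkm": p_meth_given_low,
    }


# ---------------------------------------------------------------------------
# simulation internals
# ---------------------------------------------------------------------------

def _domain_lengths_params(mean: float, maximum: float, minimum: float
                           ) -> tuple[float, float]:
    """Uniform bounds with the requested mean, within [minimum, maximum].

    Domains are kb-scale blocks; the floor keeps sub-window slivers out of
    the truth tiling.  When the mean itself sits below the floor the length
    collapses to the constant mean.
    """
    if mean <= minimum:
        return mean, mean
    lo = max(0.0, 2.0 * mean - maximum, minimum)
    hi = 2.0 * mean - lo
    return lo, hi


def _tile_domains(rng: np.random.Generator, length: int, profile: SimProfile
                  ) -> list[tuple[int, int, str]]:
    """Alternating hyper/hypo domains tiling ``[0, length)`` exactly."""
    h = profile.hyper_domain_fraction
    if h == 0.0:
        return [(0, length, "hypo")]
    if h == 1.0:
        return [(0, length, "hyper")]
    mu_hyper = 2.0 * h * profile.domain_length_mean
    mu_hypo = 2.0 * (1.0 - h) * profile.domain_length_mean
    lo_hi = {
        "hyper": _domain_lengths_params(mu_hyper, profile.domain_length_max,
                                        profile.domain_length_min),
        "hypo": _domain_lengths_params(mu_hypo, profile.domain_length_max,
                                       profile.domain_length_min),
    }
    label = "hyper" if rng.random() < h else "hypo"
    pos = 0
    out = []
    while pos < length:
        lo, hi = lo_hi[label]
        dlen = max(1, int(round(rng.uniform(lo, hi))))
        end = min(pos + dlen, length)
        out.append((pos, end, label))
        pos = end
        label = "hypo" if label == "hyper" else "hyper"
    return out


def _place_repeats(rng: np.random.Generator, domains, profile: SimProfile
                   ) -> list[tuple[int, int]]:
    """Repeat blocks covering ~``repeat_coverage_within_hyper`` of hyper domains."""
    chunk = profile.repeat_chunk
    r = profile.repeat_coverage_within_hyper
    repeats = []
    for start, end, label in domains:
        if label != "hyper" or r == 0.0:
            continue
        edges = list(range(start, end, chunk)) + [end]
        keep = rng.random(len(edges) - 1) < r
        cur = None
        for (a, b), k in zip(zip(edges, edges[1:]), keep):
            if k:
                if cur is not None and cur[1] == a:
                    cur = (cur[0], b)
                else:
                    if cur is not None:
                        repeats.append(cur)
                    cur = (a, b)
            else:
                if cur is not None:
                    repeats.append(cur)
                    cur = None
        if cur is not None:
            repeats.append(cur)
    return repeats


def _gene_structure(rng: np.random.Generator, contig: str, start: int,
                    glen: int, strand: str, gene_id: str, source: str,
                    exon_number_mean: float = 3.0) -> GeneModel:
    """Random exon/intron structure; exons double as CDS in this toy genome."""
    n_exons = 1 + rng.poisson(max(0.0, exon_number_mean - 1.0))
    n_parts = 2 * n_exons - 1
    if n_parts == 1 or glen < 2 * n_parts:
        exons = [GenomicInterval(contig, start, start + glen, strand)]
    else:
        w = rng.dirichlet(np.ones(n_parts))
        lens = np.maximum(1, np.floor(w * glen).astype(int))
        lens[-1] = glen - int(lens[:-1].sum())
        if lens[-1] < 1:  # redistribute into the last exon
            deficit = 1 - int(lens[-1])
            lens[-1] = 1
            lens[0] = max(1, int(lens[0]) - deficit)
            total = int(lens.sum())
            lens[0] += glen - total
        exons = []
        pos = start
        for i, seg in enumerate(lens):
            if i % 2 == 0:
                exons.append(GenomicInterval(contig, pos, pos + int(seg), strand))
            pos += int(seg)
    interval = GenomicInterval(contig, start, start + glen, strand)
    return GeneModel(gene_id=gene_id, interval=interval, exons=exons,
                     cds=list(exons), source=source)


def _sample_fpkm_base(rng: np.random.Generator, methylated: bool,
                      profile: SimProfile) -> float:
    if methylated:
        k = rng.choice(len(profile.fpkm_meth_weights),
                       p=np.asarray(profile.fpkm_meth_weights))
        return float(rng.lognormal(profile.fpkm_meth_meanlog[k],
                                   profile.fpkm_meth_sdlog[k]))
    return float(rng.lognormal(profile.fpkm_unmeth_meanlog,
                               profile.fpkm_unmeth_sdlog))


def _beta_by_class(rng: np.random.Generator, cls: np.ndarray,
                   means: dict[int, float], conc: float) -> np.ndarray:
    """Per-site Beta(mean, concentration) levels, class-indexed."""
    level = np.empty(cls.shape[0], dtype=np.float64)
    for code in sorted(means):
        mask = cls == code
        n = int(mask.sum())
        if n:
            a = means[code] * conc
            b = (1.0 - means[code]) * conc
            level[mask] = rng.beta(a, b, size=n)
    return level


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate(profile: SimProfile, out_dir: str | Path,
             contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
             write_site_truth: bool = False) -> dict:
    """Generate the full dataset under ``profile`` and write it to ``out_dir``.

    Two cytosine reports (conditions ``replete`` / ``deplete``) are drawn from
    one shared per-site truth: true levels are sampled once, counts are
    sampled independently per condition.  ``contexts`` restricts which
    cytosine contexts are emitted in the reports (the genome itself is
    unchanged).  Returns the manifest dictionary (also written as JSON).
    """
    profile.validate()
    for c in contexts:
        if c not in ("CG", "CHG", "CHH"):
            raise ValueError(f"unknown context {c!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(profile.seed)

    gc = profile.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    conc = profile.beta_concentration
    class_means = {
        _HYPO_INTERGENIC: profile.mu_hypo_intergenic,
        _HYPER_INTERGENIC: profile.mu_hyper,
        _METH_GENE: profile.mu_meth_gene,
        _UNMETH_GENE: profile.mu_unmeth_gene,
    }

    sequences: dict[str, str] = {}
    domain_rows = []          # (contig, start, end, label)
    repeat_rows = []          # (contig, start, end)
    genes: list[GeneModel] = []
    gene_truth_rows = []      # per real gene
    per_contig: dict[str, dict] = {}
    hyper_domains_by_contig: dict[str, list[tuple[int, int]]] = {}

    contig_names = [f"ctg{i + 1:03d}" for i in range(profile.n_contigs)]
    gene_counter = 0

    for contig in contig_names:
        L = profile.contig_length
        codes = rng.choice(4, size=L, p=base_p).astype(np.uint8)
        cls = np.zeros(L, dtype=np.uint8)

        domains = _tile_domains(rng, L, profile)
        hyper_domains = [(a, b) for a, b, lab in domains if lab == "hyper"]
        hyper_domains_by_contig[contig] = hyper_domains
        for a, b, lab in domains:
            domain_rows.append((contig, a, b, lab))
            if lab == "hyper":
                cls[a:b] = _HYPER_INTERGENIC

        for a, b in _place_repeats(rng, domains, profile):
            repeat_rows.append((contig, a, b))

        # unmethylated genes fill hypo domains at the genic coverage fraction
        g = profile.genic_fraction_within_hypo
        if g > 0:
            gap_mean = profile.gene_length_mean * (1.0 - g) / g if g < 1 else 0.0
            for a, b, lab in domains:
                if lab != "hypo":
                    continue
                pos = a  # genes first, gaps after: keeps realized coverage ~g
                while True:
                    glen = int(rng.uniform(0.5, 1.5) * profile.gene_length_mean)
                    if pos + glen > b:
                        break
                    gene_counter += 1
                    gid = f"g{gene_counter:05d}"
                    strand = "+" if rng.random() < 0.5 else "-"
                    gm = _gene_structure(rng, contig, pos, glen, strand, gid,
                                         "predictorA", profile.exon_number_mean)
                    genes.append(gm)
                    cls[pos:pos + glen] = _UNMETH_GENE
                    gene_truth_rows.append(
                        dict(gene_id=gid, contig=contig, start=pos,
                             end=pos + glen, strand=strand,
                             status_truth="unmethylated", domain="hypo"))
                    pos += glen
                    pos += int(rng.exponential(gap_mean)) if gap_mean > 0 else 0

        per_contig[contig] = {"codes": codes, "cls": cls}

    # methylated genes: p_methylated_gene of all genes, inside hyper domains
    n_unmeth = gene_counter
    p = profile.p_methylated_gene
    all_hyper = [(c, a, b) for c in contig_names
                 for a, b in hyper_domains_by_contig[c]]
    n_meth = int(round(n_unmeth * p / (1.0 - p))) if (p < 1.0 and all_hyper) else 0
    if all_hyper and n_meth > 0:
        weights = np.array([b - a for _, a, b in all_hyper], dtype=float)
        weights /= weights.sum()
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
        placed = 0
        attempts = 0
        while placed < n_meth and attempts < 200 * n_meth:
            attempts += 1
            k = rng.choice(len(all_hyper), p=weights)
            contig, a, b = all_hyper[k]
            glen = int(rng.uniform(0.5, 1.5) * profile.gene_length_mean)
            if b - a <= glen:
                continue
            start = int(rng.integers(a, b - glen))
            if any(start < e and s < start + glen for s, e in occupied[contig]):
                continue
            occupied[contig].append((start, start + glen))
            gene_counter += 1
            gid = f"g{gene_counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            gm = _gene_structure(rng, contig, start, glen, strand, gid,
                                 "predictorA", profile.exon_number_mean)
            genes.append(gm)
            per_contig[contig]["cls"][start:start + glen] = _METH_GENE
            gene_truth_rows.append(
                dict(gene_id=gid, contig=contig, start=start, end=start + glen,
                     strand=strand, status_truth="methylated", domain="hyper"))
            placed += 1

    genes.sort(key=lambda m: (m.contig, m.interval.start))
    truth = pd.DataFrame(gene_truth_rows).set_index("gene_id") if gene_truth_rows \
        else pd.DataFrame(columns=["contig", "start", "end", "strand",
                                   "status_truth", "domain"])
    n_real = len(genes)

    # ---- per-site truth and two-condition counts -------------------------
    cond_frames = {cond: [] for cond in CONDITIONS}
    truth_frames = []
    for contig in contig_names:
        codes = per_contig[contig]["codes"]
        cls = per_contig[contig]["cls"]
        L = codes.shape[0]
        site_pos = []      # 0-based position of the C on the forward axis
        site_strand = []
        site_level = []
        site_context = []
        site_tri = []

        is_c = codes == _C
        is_g = codes == _G

        # forward-strand cytosines with a determinate trinucleotide
        fwd = np.flatnonzero(is_c[: L - 2])
        nxt, third = codes[fwd + 1], codes[fwd + 2]
        fwd_cg = fwd[nxt == _G]
        fwd_chg = fwd[(nxt != _G) & (third == _G)]
        fwd_chh = fwd[(nxt != _G) & (third != _G)]

        # reverse-strand cytosines are forward-strand Gs (reading 3'<-5')
        rev = np.flatnonzero(is_g)
        rev = rev[rev >= 2]
        prv, prv2 = codes[rev - 1], codes[rev - 2]
        rev_cg = rev[prv == _C]
        rev_chg = rev[(prv != _C) & (prv2 == _C)]
        rev_chh = rev[(prv != _C) & (prv2 != _C)]

        def tri_fwd(idx):
            return np.char.add(np.char.add(_BASES[codes[idx]],
                                           _BASES[codes[idx + 1]]),
                               _BASES[codes[idx + 2]])

        def tri_rev(idx):
            comp = np.array([3, 2, 1, 0], dtype=np.uint8)
            return np.char.add(np.char.add(_BASES[comp[codes[idx]]],
                                           _BASES[comp[codes[idx - 1]]]),
                               _BASES[comp[codes[idx - 2]]])

        if "CG" in contexts:
            # symmetric CpG: one truth level per dyad, shared by both strands
            dyads = fwd_cg[fwd_cg + 1 < L]
            dyad_level = _beta_by_class(rng, cls[dyads], class_means, conc)
            site_pos.append(dyads)
            site_strand.append(np.full(dyads.shape[0], "+"))
            site_level.append(dyad_level)
            site_context.append(np.full(dyads.shape[0], "CG"))
            site_tri.append(tri_fwd(dyads))
            partner = dyads + 1
            keep = partner >= 2
            site_pos.append(partner[keep])
            site_strand.append(np.full(int(keep.sum()), "-"))
            site_level.append(dyad_level[keep])
            site_context.append(np.full(int(keep.sum()), "CG"))
            site_tri.append(tri_rev(partner[keep]))

        for ctx, idx_f, idx_r, mu in (
            ("CHG", fwd_chg, rev_chg, profile.chg_level),
            ("CHH", fwd_chh, rev_chh, profile.chh_level),
        ):
            if ctx not in contexts:
                continue
            a, b = mu * conc, (1.0 - mu) * conc
            for idx, strand, tri_fn in ((idx_f, "+", tri_fwd),
                                        (idx_r, "-", tri_rev)):
                lev = rng.beta(a, b, size=idx.shape[0])
                site_pos.append(idx)
                site_strand.append(np.full(idx.shape[0], strand))
                site_level.append(lev)
                site_context.append(np.full(idx.shape[0], ctx))
                site_tri.append(tri_fn(idx))

        if not site_pos:
            continue
        pos0 = np.concatenate(site_pos)
        strand_arr = np.concatenate(site_strand)
        level = np.concatenate(site_level)
        ctx_arr = np.concatenate(site_context)
        tri_arr = np.concatenate(site_tri)
        order = np.lexsort((strand_arr, pos0))
        pos0, strand_arr, level = pos0[order], strand_arr[order], level[order]
        ctx_arr, tri_arr = ctx_arr[order], tri_arr[order]

        for cond in CONDITIONS:
            cov = rng.poisson(profile.coverage_mean, size=pos0.shape[0])
            meth = rng.binomial(cov, level)
            cond_frames[cond].append(pd.DataFrame({
                "contig": contig,
                "pos": pos0 + 1,
                "strand": strand_arr,
                "count_meth": meth,
                "count_unmeth": cov - meth,
                "context": ctx_arr,
                "trinucleotide": tri_arr,
            }))
        if write_site_truth:
            truth_frames.append(pd.DataFrame({
                "contig": contig, "pos": pos0 + 1, "strand": strand_arr,
                "context": ctx_arr, "true_level": np.round(level, 8),
            }))

    # ---- decoy models, predictor sets ------------------------------------
    # A-only decoys (misscall emulation): short, intergenic, no B overlap;
    # zero-FPKM models are drawn from the decoys first.
    n_decoy = int(round(n_real * profile.frac_a_only / (1.0 - profile.frac_a_only))) \
        if profile.frac_a_only < 1.0 else 0
    gene_starts = {c: np.array(sorted(
        [g.interval.start for g in genes if g.contig == c])) for c in contig_names}
    gene_ends = {c: np.array(sorted(
        [g.interval.end for g in genes if g.contig == c])) for c in contig_names}
    decoys: list[GeneModel] = []
    attempts = 0
    while len(decoys) < n_decoy and attempts < 200 * max(1, n_decoy):
        attempts += 1
        contig = contig_names[int(rng.integers(len(contig_names)))]
        glen = int(rng.uniform(300, 800))
        start = int(rng.integers(0, profile.contig_length - glen))
        # reject if within jitter range of a real gene, so decoys can never
        # overlap a (jittered) predictor-B span
        margin = profile.boundary_jitter
        ends = gene_ends[contig]
        starts = gene_starts[contig]
        k = np.searchsorted(ends, start - margin, side="right")
        if k < starts.shape[0] and starts[k] < start + glen + margin:
            continue
        gene_counter += 1
        gid = f"g{gene_counter:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        decoys.append(_gene_structure(rng, contig, start, glen, strand, gid,
                                      "predictorA"))

    predictor_a = sorted(genes + decoys,
                         key=lambda m: (m.contig, m.interval.start))

    n_zero = int(round(profile.frac_zero_fpkm * len(predictor_a)))
    decoy_ids = [d.gene_id for d in decoys]
    zero_ids = set(decoy_ids[:n_zero])
    if n_zero > len(decoy_ids):  # spill over onto real genes if decoys run out
        spill = n_zero - len(decoy_ids)
        real_ids = [g.gene_id for g in genes]
        pick = rng.choice(len(real_ids), size=spill, replace=False)
        zero_ids |= {real_ids[i] for i in sorted(pick)}

    # predictor B: jittered spans of real genes only
    predictor_b = []
    for i, gm in enumerate(genes):
        j1 = int(rng.integers(-profile.boundary_jitter, profile.boundary_jitter + 1))
        j2 = int(rng.integers(-profile.boundary_jitter, profile.boundary_jitter + 1))
        s = max(0, gm.interval.start + j1)
        e = min(profile.contig_length, gm.interval.end + j2)
        if e - s < 50:
            s, e = gm.interval.start, gm.interval.end
        iv = GenomicInterval(gm.contig, s, e, gm.strand)
        predictor_b.append(GeneModel(gene_id=f"m{i + 1:05d}", interval=iv,
                                     exons=[iv], cds=[iv], source="predictorB"))

    # ---- FPKM table -------------------------------------------------------
    sample_names = [f"{cond}_r{i + 1}" for cond in CONDITIONS
                    for i in range(profile.n_samples_per_condition)]
    fpkm_rows = {}
    status_by_id = dict(zip(truth.index, truth["status_truth"])) if n_real else {}
    base_fpkm = {}
    for gm in predictor_a:
        gid = gm.gene_id
        if gid in zero_ids:
            base = 0.0
        elif gid in status_by_id:
            base = _sample_fpkm_base(rng, status_by_id[gid] == "methylated",
                                     profile)
        else:  # decoy with residual low expression
            base = float(rng.lognormal(0.5, 1.5))
        base_fpkm[gid] = base
        noise = np.exp(rng.normal(0.0, profile.sample_noise_sdlog,
                                  size=len(sample_names)))
        fpkm_rows[gid] = np.round(base * noise, 4)
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index",
                                  columns=sample_names)
    fpkm.index.name = "gene_id"

    # ---- taxonomy ---------------------------------------------------------
    groups = [t[0] for t in profile.taxonomy_groups]
    w = np.array([t[1] for t in profile.taxonomy_groups])
    q = np.array([t[2] for t in profile.taxonomy_groups])
    p_given_m = w * q
    p_given_m = p_given_m / p_given_m.sum() if p_given_m.sum() > 0 else w
    p_given_u = w * (1.0 - q)
    p_given_u = p_given_u / p_given_u.sum()
    tax_rows = []
    for gid in truth.index:
        probs = p_given_m if status_by_id[gid] == "methylated" else p_given_u
        tax_rows.append((gid, groups[int(rng.choice(len(groups), p=probs))]))
    taxonomy = pd.DataFrame(tax_rows, columns=["gene_id", "group"])

    # ---- cross-species ortholog emulation ---------------------------------
    n_pairs = min(profile.n_ortholog_pairs, n_real)
    if n_pairs > 0:
        pick = np.sort(rng.choice(n_real, size=n_pairs, replace=False))
        a_ids = [truth.index[i] for i in pick]
        b_ids = [f"tb{i + 1:04d}" for i in range(n_pairs)]
        b_status = np.where(rng.random(n_pairs) < profile.p_meth_species_b,
                            "methylated", "unmethylated")
        pairs = pd.DataFrame({"gene_a": a_ids, "gene_b": b_ids})
        species_b = pd.DataFrame({"gene_id": b_ids, "status": b_status})
    else:
        pairs = pd.DataFrame(columns=["gene_a", "gene_b"])
        species_b = pd.DataFrame(columns=["gene_id", "status"])

    # ---- write everything -------------------------------------------------
    for contig in contig_names:
        codes = per_contig[contig]["codes"]
        sequences[contig] = np.array([65, 67, 71, 84], dtype=np.uint8)[
            codes].tobytes().decode("ascii")

    paths = {
        "genome": out / "genome.fa",
        "predictor_a": out / "genes_predictorA.gff3",
        "predictor_b": out / "genes_predictorB.gff3",
        "repeats": out / "repeats.bed",
        "domains_truth": out / "domains_truth.bed",
        "fpkm": out / "fpkm.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "ortholog_pairs": out / "ortholog_pairs.tsv",
        "species_b_status": out / "speciesB_status.tsv",
        "gene_truth": out / "gene_truth.tsv",
    }
    for cond in CONDITIONS:
        paths[f"report_{cond}"] = out / f"meth_{cond}.CX.tsv"

    write_fasta(sequences, paths["genome"])
    write_gff3_genes(predictor_a, paths["predictor_a"])
    write_gff3_genes(predictor_b, paths["predictor_b"])
    write_bed([GenomicInterval(c, a, b) for c, a, b in repeat_rows],
              paths["repeats"])
    write_bed([GenomicInterval(c, a, b) for c, a, b, _ in domain_rows],
              paths["domains_truth"],
              names=[lab for _, _, _, lab in domain_rows])
    for cond in CONDITIONS:
        frame = pd.concat(cond_frames[cond], ignore_index=True) if \
            cond_frames[cond] else pd.DataFrame(columns=[
                "contig", "pos", "strand", "count_meth", "count_unmeth",
                "context", "trinucleotide"])
        frame.to_csv(paths[f"report_{cond}"], sep="\t", header=False,
                     index=False)
    fpkm.to_csv(paths["fpkm"], sep="\t")
    taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    pairs.to_csv(paths["ortholog_pairs"], sep="\t", index=False)
    species_b.to_csv(paths["species_b_status"], sep="\t", index=False)

    truth_out = truth.copy()
    truth_out["is_decoy"] = False
    if decoys:
        decoy_truth = pd.DataFrame({
            "contig": [d.contig for d in decoys],
            "start": [d.interval.start for d in decoys],
            "end": [d.interval.end for d in decoys],
            "strand": [d.strand for d in decoys],
            "status_truth": "decoy",
            "domain": "any",
            "is_decoy": True,
        }, index=pd.Index([d.gene_id for d in decoys], name="gene_id"))
        truth_out = pd.concat([truth_out, decoy_truth])
    truth_out["sum_fpkm_zero"] = [gid in zero_ids for gid in truth_out.index]
    truth_out["base_fpkm"] = [round(base_fpkm.get(g, 0.0), 4)
                              for g in truth_out.index]
    truth_out.sort_index().to_csv(paths["gene_truth"], sep="\t")

    if write_site_truth:
        truth_sites = pd.concat(truth_frames, ignore_index=True) if \
            truth_frames else pd.DataFrame()
        paths["site_truth"] = out / "site_truth.tsv"
        truth_sites.to_csv(paths["site_truth"], sep="\t", index=False)

    genome_len = profile.genome_length
    repeat_bases = sum(b - a for _, a, b in repeat_rows)
    manifest = {
        "seed": profile.seed,
        "profile": dataclasses.asdict(profile),
        "contexts_emitted": list(contexts),
        "conditions": list(CONDITIONS),
        "paths": {k: v.name for k, v in paths.items()},  # relative to out_dir
        "counts": {
            "genome_length": genome_len,
            "n_contigs": profile.n_contigs,
            "n_genes_real": n_real,
            "n_genes_methylated_truth": int(
                (truth["status_truth"] == "methylated").sum()) if n_real else 0,
            "n_decoys": len(decoys),
            "n_predictor_a": len(predictor_a),
            "n_predictor_b": len(predictor_b),
            "n_zero_fpkm": len(zero_ids),
            "repeat_bases": int(repeat_bases),
            "repeat_fraction": repeat_bases / genome_len,
            "n_ortholog_pairs": int(len(pairs)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["paths"] = paths  # absolute in-memory, relative on disk
    return manifest
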