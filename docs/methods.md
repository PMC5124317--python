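# Methods

## The methylome model

The package targets WGBS methylomes with a near-binary large-scale
architecture: long hypermethylated blocks dominated by repeats alternating
with hypomethylated, gene-rich territory.  All statistics are built from
per-cytosine counts `(m, u)`; a site's level is `m/(m+u)` and a site is
*covered* when `m+u >= min_coverage` (default 5 reads — standard WGBS
practice; the exact threshold used for the reference organism is not
published, so it is exposed as configuration).  Two regional estimators are
carried side by side: the per-cytosine average ("mean of fractions", the
default, matching how per-cytosine levels are usually averaged) and the
coverage-weighted level `sum(m)/sum(m+u)`.  They coincide exactly under
equal coverage, which the test suite asserts as an identity.

CpG records are kept per strand; the two strands of a dyad are never pooled
implicitly (pooling changes coverage, so it must be an explicit choice).
Site inclusion in a feature is strand-agnostic.

## The synthetic-data generator

`methylscape.synthetic_data.simulate` emulates the study conditions the
analysis assumes; its defaults (`SimProfile`, the `ccryptica` profile) are
fixed by closed-form calibration, not by fitting:

* **Sequence** — i.i.d. bases at GC = 0.43; cytosine contexts are read off
  the generated sequence, so context proportions follow GC content and the
  parsers are exercised with genuine trinucleotides.
* **Domains** — each contig tiles into alternating hyper/hypo domains.
  Lengths are uniform with means `2h·15 kb` (hyper) and `2(1−h)·15 kb`
  (hypo), h = 0.66, truncated at 30 kb (the scale of the largest observed
  blocks) with a 2-kb floor: domains are kb-scale blocks and sub-window
  slivers are not part of the architecture being emulated.  The truth
  tiling is exact — no gaps, no overlaps.
* **Repeats** — 1-kb chunks of hyper domains are marked repeat with
  probability 0.80, then merged, so the expected repeat fraction of the
  genome is `0.66 × 0.80 = 0.528`.
* **Genes** — unmethylated genes (lengths uniform around a 2-kb mean,
  1 + Poisson(2) exons) pack hypo domains to 50% coverage via exponential
  gaps; methylated genes (23% of all genes) are placed uniformly inside
  hyper domains.  Gene bodies override the domain background class.
* **Site levels** — per-site true levels are Beta-distributed around the
  class mean (hyper intergenic 0.90, methylated gene 0.88, unmethylated
  gene 0.07, hypo intergenic 0.03; concentration 50), which produces the
  bimodal per-site histogram the analysis expects.  CG dyads share one
  truth level across strands (symmetric CpG methylation); CHG/CHH levels
  (mean 0.03) are drawn independently per strand.
* **Counts** — truth levels are drawn once; each condition then draws
  coverage ~ Poisson(30) and methylated reads ~ Binomial(coverage, level)
  independently.  The two condition reports therefore share one methylome,
  and per-gene levels correlate near 1 between conditions by construction.
* **Expression** — FPKM is drawn per gene conditional on status:
  methylated `0.8·LogN(0.5, 1.5) + 0.2·LogN(7.3, 1.0)` (mean ≈ 492),
  unmethylated `LogN(6.6, 1.9)` (mean ≈ 4470).  Four samples (two per
  condition) replicate the gene value with mild lognormal noise
  (sdlog 0.05), so thresholds on the per-gene mean stay at their
  closed-form probabilities.
* **Predictor structure** — predictor B re-reports each placed gene with
  ±100 bp span jitter; 20% of predictor-A models are short intergenic
  decoys placed at least the jitter width away from any real gene (so they
  can never gain a B overlap), and the zero-FPKM fraction (10% of A models)
  is drawn from the decoys first, mirroring fragmented unsupported
  misscalls.  The consensus filter therefore recovers exactly the placed
  genes, which keeps the status/expression couplings of the analysed set at
  their closed forms.
* **Taxonomy** — each gene's group is drawn conditional on its true status
  via Bayes' rule from genome weights and per-group methylation
  propensities (defaults: a dominant methylation-depleted "diatom" group at
  weight 0.62, a methylation-enriched "unknown" group at weight 0.20, four
  minor groups at the baseline propensity).
* **Cross-species emulation** — an ortholog pair table maps a sample of
  genes to a second species whose status table is mostly unmethylated
  (5%), for exercising the shared-status contingency operation.

Identical seeds give byte-identical output files (paths inside the manifest
are relative for this reason).

### Closed-form calibration (`expected_summaries`)

With h the hyper fraction, g the genic fraction of hypo territory and p the
methylated-gene share, the genic share of hyper territory is
`f = (1−h)·g·p / ((1−p)·h)` and the expected global CG level is

    E[CG] = h·[(1−f)·0.90 + f·0.88] + (1−h)·[g·0.07 + (1−g)·0.03] = 0.610

for the defaults.  Lognormal means are `exp(meanlog + sdlog²/2)`; the
probability that a methylated gene falls at or below 10 FPKM is 0.708, an
unmethylated gene 0.012, giving
`P(methylated | FPKM ≤ 10) = 0.23·0.708 / (0.23·0.708 + 0.77·0.012) = 0.947`.
These expectations are the oracle the default constants were chosen
against, and the Monte-Carlo convergence of the simulator to them is
asserted by the acceptance tests.

### What the generator does not emulate

Read-level artefacts (incomplete bisulfite conversion, mapping bias, SNPs),
replicate-level biological variance, isoform structure, chromosome-scale
organisation, and any real sequence composition beyond GC content.  Passing
tests demonstrate that the pipeline's estimators recover known generative
truth at realistic coverage and genome scale; they do not validate
methylation calling or alignment, which are upstream of this package.

## Analysis conventions and numerical choices

* **Status call** — gene-body CG fraction ≥ 0.5 over ≥ 5 covered CpGs is
  methylated; exactly 0.5 goes up (documented tie-break).  On well-separated
  data (class means ~0.88 vs ~0.07) any mid-range threshold yields the same
  calls, which is why a published threshold is not needed for recovery.
* **Condition averaging** — quantities described as averaged between
  conditions are computed per condition and combined as the arithmetic
  mean; every per-condition value is also reported.
* **Class means** — reported as means of per-gene fractions (not
  coverage-weighted); medians are reported alongside, and no outlier
  removal is applied.
* **Between-condition correlation** — the comparison unit is not uniquely
  defined by a single published number, so gene-unit and 1-kb-window
  Pearson r are reported side by side.
* **Segmentation** — 1-kb non-overlapping windows, hyper at window mean
  ≥ 0.5, minimum 3 covered sites per window; sparse windows inherit the
  previous label (so sparse gaps never split a domain), and leading/trailing
  sparse windows count as uncovered territory.  A two-state thresholded
  scan is used instead of an HMM because the targeted structure is
  near-binary and the simple method admits exact oracle tests; an HMM is an
  extension point.  End-of-contig windows may be short and are kept.
* **Populations** — i: mean FPKM ≤ 10; iii: methylated and mean FPKM ≥ 100;
  ii: unmethylated above 10.  Population i takes precedence over iii
  because it is defined by expression alone.  The iii cut-off of 100 FPKM
  is a configuration default (the reference range is only loosely bounded).
* **Enrichment** — determined genes only, in both numerator and
  denominator; the gene-count-weighted mean of enrichments is identically
  zero, which the tests assert as an algebraic identity.  The permutation
  test (label shuffling, add-one two-sided p-value) is this package's
  addition.
* **Consensus models** — overlap means ≥ 1 bp same-strand genomic-span
  overlap by default (CDS-level and minimum-fraction overlap are flags);
  "non-zero FPKM" means sum across samples > 0 exactly, no epsilon.
  Percent coding DNA uses CDS bases by default (exon mode available),
  unioned so overlapping genes count each base once.
* **Degenerate inputs** — zero-coverage sites are retained at parse time
  and excluded by the coverage filter; empty contexts, empty interval sets
  and zero-gene assemblies yield undefined/zero values rather than errors;
  flanks truncate at contig edges.

## Problem sizes

The bundled studies use a 5-Mbp genome (all contexts; ~460k covered CpGs)
for genome-level statistics and a ~45-Mbp genome scaled to ~5000 gene
models for gene-level statistics, the latter emitting CG-context records
only, since CHG/CHH sites do not enter gene-body CG classification and the
CG statistics are unchanged.  At these sizes every recovered statistic sits
within a couple of points of its closed form while the whole acceptance run
completes in minutes on one CPU.

## Known limitations

The generator's independence assumptions (i.i.d. sequence, independent
per-site Beta draws) understate the spatial autocorrelation of real
methylomes within a class; domain boundaries are sharper than biology.  The
segmentation carries labels across long uncovered stretches rather than
declaring them unknown.  Permutation p-values are exchangeability-based and
ignore gene-length or coverage confounding between taxonomic groups.
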