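"""End-to-end orchestration: config, stage sequencing, summary report.

``run_all`` executes consensus-model selection, per-condition methylation
statistics, gene classification, domain segmentation, expression
integration, taxonomic enrichment and the ortholog comparison, writes every
stage's table under the output directory, and returns one JSON-serialisable
summary holding the headline statistics.  All randomness (the permutation
test) flows from the single config seed, so a rerun on the same inputs is
byte-identical.

Quantities the analysis convention averages "between both experimental
conditions" (global levels, the methylated-gene proportion, class means,
population shares) are reported per condition and as the arithmetic mean of
the two condition runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import (enrichment, expression_integration, gene_status, genemodels,
               methylation_core, segmentation)
from .io_formats import (read_bed, read_fpkm_table, read_gff3_genes,
                         read_ortholog_pairs, read_taxonomy_table, write_bed)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths to all inputs plus per-stage parameters (module defaults)."""

    genome: str = ""
    predictor_a: str = ""
    predictor_b: str = ""
    repeats: str = ""
    fpkm: str = ""
    taxonomy: str = ""
    ortholog_pairs: str = ""
    species_b_status: str = ""
    reports: dict = field(default_factory=dict)   # condition -> CX report path
    out_dir: str = "methylscape_out"

    min_coverage: int = 5
    min_sites: int = 5
    status_threshold: float = 0.5
    contexts: tuple = ("CG", "CHG", "CHH")
    window: int = 1000
    t_hyper: float = 0.5
    min_sites_per_window: int = 3
    merge_gap: int = 1
    low_fpkm_max: float = 10.0
    high_fpkm_min: float = 100.0
    n_permutations: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.contexts, list):
            cfg.contexts = tuple(cfg.contexts)
        return cfg

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, **overrides) -> "RunConfig":
        """Build a config from a simulator manifest (paths filled in)."""
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        base = Path(manifest_path).parent
        paths = {k: str(v if Path(v).is_absolute() else base / v)
                 for k, v in manifest["paths"].items()}
        reports = {cond: paths[f"report_{cond}"]
                   for cond in manifest["conditions"]}
        cfg = cls(
            genome=paths["genome"],
            predictor_a=paths["predictor_a"],
            predictor_b=paths["predictor_b"],
            repeats=paths["repeats"],
            fpkm=paths["fpkm"],
            taxonomy=paths["taxonomy"],
            ortholog_pairs=paths["ortholog_pairs"],
            species_b_status=paths["species_b_status"],
            reports=reports,
            contexts=tuple(manifest.get("contexts_emitted",
                                        ("CG", "CHG", "CHH"))),
        )
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["contexts"] = list(self.contexts)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> None:
        required = {
            "genome": self.genome, "predictor_a": self.predictor_a,
            "predictor_b": self.predictor_b, "fpkm": self.fpkm,
        }
        for name, value in required.items():
            if not value or not Path(value).exists():
                raise FileNotFoundError(f"config input '{name}' missing: {value!r}")
        if not self.reports:
            raise ValueError("config has no cytosine reports")
        for cond, path in self.reports.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"cytosine report for condition '{cond}' missing: {path!r}")


def _mean_defined(values) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else None


def run_all(config: RunConfig) -> dict:
    """Execute every stage; write stage TSVs and a JSON summary; return it."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- inputs -----------------------------------------------------------
    current = stage("load-inputs")
    try:
        genes_a = read_gff3_genes(config.predictor_a, source="predictorA")
        genes_b = read_gff3_genes(config.predictor_b, source="predictorB")
        fpkm = read_fpkm_table(config.fpkm)
        repeats = read_bed(config.repeats) if config.repeats and \
            Path(config.repeats).exists() else []
        fasta = Fasta(config.genome)
        contig_lengths = {name: len(fasta[name]) for name in fasta.keys()}
        logger.info("read %d predictor-A models, %d predictor-B models",
                    len(genes_a), len(genes_b))
    except Exception as exc:
        raise StageError(current, exc) from exc

    # ---- consensus models -------------------------------------------------
    current = stage("models")
    try:
        hc_genes, model_report = genemodels.high_confidence_models(
            genes_a, genes_b, fpkm)
        gstats = genemodels.genome_stats(hc_genes, config.genome)
        gstats.to_frame().to_csv(out / "genome_stats.tsv", sep="\t")
        logger.info("high-confidence models: %d of %d",
                    model_report["n_selected"], model_report["n_input"])
    except Exception as exc:
        raise StageError(current, exc) from exc

    conditions = sorted(config.reports)
    per_condition: dict[str, dict] = {}
    tracks: dict[str, methylation_core.MethylationTrack] = {}

    for cond in conditions:
        # ---- methylation --------------------------------------------------
        current = stage(f"methylation[{cond}]")
        try:
            track = methylation_core.MethylationTrack.from_report(
                config.reports[cond], min_coverage=config.min_coverage,
                name=cond)
            tracks[cond] = track
            levels_mof = methylation_core.global_level(
                track, config.contexts, "mean_of_fractions")
            levels_w = methylation_core.global_level(
                track, config.contexts, "weighted")
            logger.info("%s: %d covered CG sites", cond, track.n_covered("CG"))
        except Exception as exc:
            raise StageError(current, exc) from exc

        # ---- classify -----------------------------------------------------
        current = stage(f"classify[{cond}]")
        try:
            statuses = gene_status.status_table(
                track, hc_genes, fpkm, min_sites=config.min_sites,
                threshold=config.status_threshold)
            statuses.to_csv(out / f"status_{cond}.tsv", sep="\t")
            summary = gene_status.class_summary(statuses)
            summary.to_csv(out / f"class_summary_{cond}.tsv", sep="\t")
        except Exception as exc:
            raise StageError(current, exc) from exc

        # ---- segment ------------------------------------------------------
        current = stage(f"segment[{cond}]")
        try:
            segs = segmentation.segment_domains(
                track, window=config.window, t_hyper=config.t_hyper,
                min_sites_per_window=config.min_sites_per_window,
                merge_gap=config.merge_gap, contig_lengths=contig_lengths)
            segs = segmentation.annotate_segments(segs, repeats, hc_genes)
            write_bed([s.interval for s in segs],
                      out / f"domains_{cond}.bed",
                      names=[s.label for s in segs],
                      scores=[s.mean_fraction for s in segs])
            hyper = [s for s in segs if s.label == "hyper"]
            hypo = [s for s in segs if s.label == "hypo"]
            seg_summary = {
                "n_segments": len(segs),
                "n_hyper": len(hyper),
                "n_hypo": len(hypo),
                "max_hyper_length": max((len(s) for s in hyper), default=0),
                "mean_repeat_overlap_hyper": _mean_defined(
                    [s.repeat_overlap_fraction for s in hyper]),
                "mean_repeat_overlap_hypo": _mean_defined(
                    [s.repeat_overlap_fraction for s in hypo]),
                "genes_in_hyper": sum(s.n_genes_contained for s in hyper),
                "genes_in_hypo": sum(s.n_genes_contained for s in hypo),
            }
        except Exception as exc:
            raise StageError(current, exc) from exc

        # ---- integrate expression ----------------------------------------
        current = stage(f"integrate-expression[{cond}]")
        try:
            parts = expression_integration.partition_populations(
                statuses, low_fpkm_max=config.low_fpkm_max,
                high_fpkm_min=config.high_fpkm_min)
            parts["summary"].to_csv(out / f"populations_{cond}.tsv", sep="\t")
            scatter = expression_integration.methylation_expression_scatter(
                statuses)
            scatter["table"].to_csv(out / f"scatter_{cond}.tsv", sep="\t")
        except Exception as exc:
            raise StageError(current, exc) from exc

        # ---- enrichment ---------------------------------------------------
        enrich_summary = None
        if config.taxonomy and Path(config.taxonomy).exists():
            current = stage(f"enrich[{cond}]")
            try:
                taxonomy = read_taxonomy_table(config.taxonomy)
                enr = enrichment.taxon_enrichment(
                    statuses, taxonomy, n_permutations=config.n_permutations,
                    seed=config.seed)
                table = enrichment.enrichment_table(enr)
                table.to_csv(out / f"enrichment_{cond}.tsv", sep="\t")
                enrich_summary = {
                    row.group: {"enrichment": row.enrichment,
                                "p_perm": row.p_perm,
                                "n_genes": row.n_genes_in_group}
                    for row in enr
                }
            except Exception as exc:
                raise StageError(current, exc) from exc

        per_condition[cond] = {
            "global_level_mean_of_fractions": levels_mof,
            "global_level_weighted": levels_w,
            "n_covered_cg": track.n_covered("CG"),
            "statuses": statuses,
            "proportion_methylated": float(
                summary.loc["methylated", "proportion"]),
            "class_mean_fraction": {
                "methylated": summary.loc["methylated", "mean_fraction"],
                "unmethylated": summary.loc["unmethylated", "mean_fraction"],
            },
            "class_mean_fpkm": {
                "methylated": summary.loc["methylated", "mean_fpkm"],
                "unmethylated": summary.loc["unmethylated", "mean_fpkm"],
            },
            "n_undetermined": int(summary.loc["undetermined", "n_genes"]),
            "segmentation": seg_summary,
            "populations": parts["summary"].to_dict(orient="index"),
            "scatter": {"pearson_r": scatter["pearson_r"],
                        "spearman_rho": scatter["spearman_rho"]},
            "enrichment": enrich_summary,
        }

    # ---- condition comparison --------------------------------------------
    comparison = None
    if len(conditions) >= 2:
        current = stage("compare-conditions")
        try:
            a, b = conditions[0], conditions[1]
            by_gene = gene_status.condition_correlation(
                tracks[a], tracks[b], genes=hc_genes, unit="gene")
            by_window = gene_status.condition_correlation(
                tracks[a], tracks[b], unit="window", window=config.window)
            comparison = {
                "conditions": [a, b],
                "pearson_r_gene": by_gene["pearson_r"],
                "n_genes_compared": by_gene["n_units"],
                "pearson_r_window": by_window["pearson_r"],
                "n_windows_compared": by_window["n_units"],
            }
        except Exception as exc:
            raise StageError(current, exc) from exc

    # ---- cross-species ortholog status ------------------------------------
    ortholog = None
    if config.ortholog_pairs and Path(config.ortholog_pairs).exists() \
            and config.species_b_status and Path(config.species_b_status).exists():
        current = stage("ortholog-status")
        try:
            pairs = read_ortholog_pairs(config.ortholog_pairs)
            species_b = pd.read_csv(config.species_b_status, sep="\t",
                                    index_col=0)
            ortholog = gene_status.shared_ortholog_status(
                per_condition[conditions[0]]["statuses"], species_b, pairs)
        except Exception as exc:
            raise StageError(current, exc) from exc

    # ---- assemble summary --------------------------------------------------
    def across(getter):
        return _mean_defined([getter(per_condition[c]) for c in conditions])

    summary_json = {
        "conditions": conditions,
        "seed": config.seed,
        "global_cg_mean_of_fractions": across(
            lambda d: d["global_level_mean_of_fractions"].get("CG")),
        "global_cg_weighted": across(
            lambda d: d["global_level_weighted"].get("CG")),
        "global_chg_mean_of_fractions": across(
            lambda d: d["global_level_mean_of_fractions"].get("CHG")),
        "global_chh_mean_of_fractions": across(
            lambda d: d["global_level_mean_of_fractions"].get("CHH")),
        "proportion_methylated_genes": across(
            lambda d: d["proportion_methylated"]),
        "class_mean_fraction_methylated": across(
            lambda d: d["class_mean_fraction"]["methylated"]),
        "class_mean_fraction_unmethylated": across(
            lambda d: d["class_mean_fraction"]["unmethylated"]),
        "class_mean_fpkm_methylated": across(
            lambda d: d["class_mean_fpkm"]["methylated"]),
        "class_mean_fpkm_unmethylated": across(
            lambda d: d["class_mean_fpkm"]["unmethylated"]),
        "percent_methylated_population_i": across(
            lambda d: d["populations"]["i_lowFPKM"]["percent_methylated"]),
        "condition_comparison": comparison,
        "ortholog_status": ortholog,
        "models": model_report,
        "genome_stats": {k: (float(v) if np.isfinite(v) else None)
                         for k, v in gstats.to_frame()["value"].items()},
        "per_condition": {
            c: {k: v for k, v in d.items() if k != "statuses"}
            for c, d in per_condition.items()
        },
    }

    def sanitize(obj):
        if isinstance(obj, dict):
            return {str(k): sanitize(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [sanitize(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating, float)):
            return float(obj) if np.isfinite(obj) else None
        return obj

    summary_json = sanitize(summary_json)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)
    return summary_json
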