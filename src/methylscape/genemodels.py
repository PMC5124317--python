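"""Consensus gene-model selection and genome statistics.

High-confidence models are the predictor-A models that (a) overlap some
predictor-B model's genomic span by at least one base on the same strand and
(b) have a positive FPKM sum across all samples (exactly zero is excluded;
no epsilon, mirroring "sum FPKM = 0.00" unsupported models).  Selection is
monotone: adding B models can only grow it, zeroing FPKM rows can only
shrink it.

Genome statistics treat coding bases as a genome fraction: CDS intervals are
unioned across genes and strands so an overlapping base counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .io_formats import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeStats:
    n_models: int
    percent_coding_dna: float
    gene_density: float            # genes / Mbp
    mean_model_length: float       # bp
    mean_exons_per_gene: float
    mean_exon_length: float        # bp
    mean_introns_per_gene: float
    mean_intron_length: float      # bp
    gc_content: float              # fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": [
                self.n_models, self.percent_coding_dna, self.gene_density,
                self.mean_model_length, self.mean_exons_per_gene,
                self.mean_exon_length, self.mean_introns_per_gene,
                self.mean_intron_length, self.gc_content,
            ]},
            index=[
                "total_models", "percent_coding_dna", "gene_density_per_mbp",
                "mean_model_length_bp", "mean_exons_per_gene",
                "mean_exon_length_bp", "mean_introns_per_gene",
                "mean_intron_length_bp", "gc_content",
            ],
        )


def high_confidence_models(predictor_a: Sequence[GeneModel],
                           predictor_b: Sequence[GeneModel],
                           fpkm: pd.DataFrame,
                           use_cds_overlap: bool = False,
                           min_overlap_fraction: float = 0.0
                           ) -> tuple[list[GeneModel], dict]:
    """Select predictor-A models supported by a B overlap and expression.

    Returns (selected models, report) where the report counts how many
    models each criterion removed.  Genes missing from the FPKM table count
    as FPKM 0 (with a warning count).  ``use_cds_overlap`` tests CDS
    intervals instead of genomic spans; ``min_overlap_fraction`` requires the
    overlap to cover that fraction of the A model's span.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for b in predictor_b:
        ivals = b.cds if (use_cds_overlap and b.cds) else [b.interval]
        for iv in ivals:
            trees.setdefault((iv.contig, iv.strand), IntervalTree()
                             ).addi(iv.start, iv.end)

    selected = []
    n_no_overlap = n_zero_fpkm = n_missing_fpkm = 0
    for g in predictor_a:
        ivals = g.cds if (use_cds_overlap and g.cds) else [g.interval]
        overlap_bases = 0
        for iv in ivals:
            tree = trees.get((iv.contig, iv.strand))
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                overlap_bases += min(hit.end, iv.end) - max(hit.begin, iv.start)
        needed = max(1, int(np.ceil(min_overlap_fraction * len(g.interval))))
        has_overlap = overlap_bases >= needed
        if not has_overlap:
            n_no_overlap += 1
            continue
        if g.gene_id not in fpkm.index:
            n_missing_fpkm += 1
            total_fpkm = 0.0
        else:
            total_fpkm = float(fpkm.loc[g.gene_id].sum())
        if total_fpkm > 0.0:
            selected.append(g)
        else:
            n_zero_fpkm += 1
    if n_missing_fpkm:
        logger.warning("%d predictor-A models missing from FPKM table "
                       "(treated as FPKM 0)", n_missing_fpkm)
    report = {
        "n_input": len(predictor_a),
        "n_selected": len(selected),
        "n_removed_no_overlap": n_no_overlap,
        "n_removed_zero_fpkm": n_zero_fpkm,
        "n_missing_fpkm": n_missing_fpkm,
    }
    return selected, report


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total


def genome_stats(genes: Sequence[GeneModel], genome_fasta: str | Path,
                 coding_from: str = "cds") -> GenomeStats:
    """Table-style genome statistics for a gene set against an assembly.

    ``coding_from`` is 'cds' (default) or 'exon': which intervals count as
    coding bases.  Coding bases are strand-collapsed and unioned so each
    genomic position counts once.  A gene extending beyond its contig raises
    an error naming the gene.  With zero genes all means are reported as 0.
    """
    fasta = Fasta(str(genome_fasta))
    contig_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    assembly_length = sum(contig_lengths.values())

    gc = at = 0
    for name in fasta.keys():
        seq = np.frombuffer(str(fasta[name][:]).upper().encode(), dtype=np.uint8)
        gc += int(np.isin(seq, np.frombuffer(b"GC", dtype=np.uint8)).sum())
        at += int(np.isin(seq, np.frombuffer(b"AT", dtype=np.uint8)).sum())
    gc_content = gc / (gc + at) if (gc + at) else float("nan")

    coding: dict[str, list[tuple[int, int]]] = {}
    exon_lengths, intron_lengths = [], []
    n_exons = n_introns = 0
    model_lengths = []
    for g in genes:
        clen = contig_lengths.get(g.contig)
        if clen is None:
            raise ValueError(f"gene {g.gene_id}: contig {g.contig} not in assembly")
        if g.interval.end > clen:
            raise ValueError(
                f"gene {g.gene_id} extends past the end of {g.contig} "
                f"({g.interval.end} > {clen})")
        model_lengths.append(len(g.interval))
        source = g.cds if coding_from == "cds" else g.exons
        for iv in source:
            coding.setdefault(g.contig, []).append((iv.start, iv.end))
        exon_lengths.extend(len(e) for e in g.exons)
        n_exons += len(g.exons)
        introns = g.introns
        intron_lengths.extend(len(i) for i in introns)
        n_introns += len(introns)

    coding_bases = sum(_union_length(v) for v in coding.values())
    n = len(genes)
    return GenomeStats(
        n_models=n,
        percent_coding_dna=100.0 * coding_bases / assembly_length,
        gene_density=n / (assembly_length / 1e6),
        mean_model_length=float(np.mean(model_lengths)) if n else 0.0,
        mean_exons_per_gene=n_exons / n if n else 0.0,
        mean_exon_length=float(np.mean(exon_lengths)) if exon_lengths else 0.0,
        mean_introns_per_gene=n_introns / n if n else 0.0,
        mean_intron_length=float(np.mean(intron_lengths)) if intron_lengths
        else 0.0,
        gc_content=gc_content,
    )
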