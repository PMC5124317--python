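"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (``[start, end)``), the BED
convention.  GFF3 columns (1-based inclusive) and cytosine-report positions
(1-based) are converted exactly once, at the parse/serialize boundary.

Cytosine reports follow the Bismark "CX report" dialect: one tab-delimited
line per cytosine, no header, columns ::

    contig  pos(1-based)  strand(+/-)  count_meth  count_unmeth  context  trinucleotide

with context in {CG, CHG, CHH} (H = A, C or T).  Records are kept per strand;
nothing in this module ever pools the two strands of a CpG dyad.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a contig; strand '.', '+' or '-'."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def context_of(trinucleotide: str) -> str | None:
    """Methylation context implied by a trinucleotide (first base C).

    Returns None when the trinucleotide is ambiguous (contains N) or does not
    start with C.
    """
    t = trinucleotide.upper()
    if len(t) != 3 or t[0] != "C" or "N" in t:
        return None
    if t[1] == "G":
        return "CG"
    if t[2] == "G":
        return "CHG"
    return "CHH"


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's per-strand methylated / unmethylated read counts."""

    contig: str
    pos: int  # 1-based, position of the C on its own strand
    strand: str
    count_meth: int
    count_unmeth: int
    context: str
    trinucleotide: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("negative read count")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        implied = context_of(self.trinucleotide)
        if implied is not None and implied != self.context:
            raise ValueError(
                f"context {self.context} inconsistent with trinucleotide "
                f"{self.trinucleotide}"
            )

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass
class GeneModel:
    """A gene with exon/CDS intervals; introns are the gaps between exons.

    Multi-transcript genes are represented by the union of their exons (and
    of their CDS) so that all statistics are per gene, not per isoform.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    source: str = "."

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds = sorted(self.cds, key=lambda c: c.start)
        prev_end = None
        for e in self.exons:
            if e.contig != self.interval.contig or e.strand != self.interval.strand:
                raise ValueError(f"{self.gene_id}: exon on wrong contig/strand")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(
                    f"{self.gene_id}: exon [{e.start},{e.end}) outside gene span "
                    f"[{self.interval.start},{self.interval.end})"
                )
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e.end

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.contig, a.end, b.start, self.strand)
                )
        return out

    @property
    def length(self) -> int:
        return len(self.interval)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path) -> Iterator[CytosineRecord]:
    """Stream records from a CX-style cytosine report, in file order.

    Raises FormatError (with the 1-based line number) on a wrong column
    count, negative counts, an unknown context token, or a context that
    contradicts its trinucleotide.  Zero-coverage records are retained;
    coverage filtering is a downstream concern.
    """
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"expected 7 columns, got {len(parts)}", line=i)
            contig, pos, strand, cm, cu, context, trinuc = parts
            try:
                rec = CytosineRecord(
                    contig=contig,
                    pos=int(pos),
                    strand=strand,
                    count_meth=int(cm),
                    count_unmeth=int(cu),
                    context=context,
                    trinucleotide=trinuc,
                )
            except ValueError as exc:
                raise FormatError(str(exc), line=i) from exc
            yield rec


_REPORT_COLUMNS = [
    "contig", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide",
]


def read_cytosine_report_frame(path: str | Path) -> pd.DataFrame:
    """Vectorised cytosine-report reader (same dialect, same validation).

    Used for genome-scale tracks; `read_cytosine_report` is the record-level
    equivalent.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_REPORT_COLUMNS,
            dtype={
                "contig": str,
                "pos": np.int64,
                "strand": str,
                "count_meth": np.int64,
                "count_unmeth": np.int64,
                "context": str,
                "trinucleotide": str,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(str(exc)) from exc
    if df.shape[1] != 7:
        raise FormatError(f"expected 7 columns, got {df.shape[1]}")
    nulls = df.isna().any(axis=1)
    if nulls.any():
        raise FormatError("expected 7 columns",
                          line=int(np.argmax(nulls.to_numpy())) + 1)
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        bad = int(np.argmax((df["count_meth"] < 0) | (df["count_unmeth"] < 0)).item()) + 1
        raise FormatError("negative read count", line=bad)
    if not df["context"].isin(CONTEXTS).all():
        bad = int(np.argmax(~df["context"].isin(CONTEXTS).to_numpy())) + 1
        raise FormatError(f"unknown context token {df['context'].iloc[bad - 1]!r}", line=bad)
    # context/trinucleotide consistency (N-containing trinucleotides pass)
    tri = df["trinucleotide"].str.upper()
    second_g = tri.str[1] == "G"
    third_g = tri.str[2] == "G"
    implied = np.where(second_g, "CG", np.where(third_g, "CHG", "CHH"))
    determinate = tri.str.len().eq(3) & tri.str[0].eq("C") & ~tri.str.contains("N")
    mismatch = determinate.to_numpy() & (implied != df["context"].to_numpy())
    if mismatch.any():
        bad = int(np.argmax(mismatch)) + 1
        raise FormatError(
            f"context {df['context'].iloc[bad - 1]} inconsistent with "
            f"trinucleotide {df['trinucleotide'].iloc[bad - 1]}",
            line=bad,
        )
    return df


def write_cytosine_report(records: Iterable[CytosineRecord] | pd.DataFrame,
                          path: str | Path) -> None:
    """Write a CX-style cytosine report (tab-delimited, no header)."""
    if isinstance(records, pd.DataFrame):
        records[_REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
        return
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig}\t{r.pos}\t{r.strand}\t{r.count_meth}\t"
                f"{r.count_unmeth}\t{r.context}\t{r.trinucleotide}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly overlapping intervals (same contig/strand)."""
    if not ivals:
        return []
    ivals = sorted(ivals, key=lambda i: i.start)
    merged = [ivals[0]]
    for iv in ivals[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = dataclasses.replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def read_gff3_genes(path: str | Path, source: str = ".") -> list[GeneModel]:
    """Parse gene models from GFF3 (gene / mRNA / exon / CDS, ID/Parent linked).

    Multi-mRNA genes collapse to the union of their exons and the union of
    their CDS.  A feature whose Parent cannot be resolved raises FormatError
    naming the orphan.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_ids = set()
    gene_feats = {}
    for g in db.features_of_type("gene"):
        gene_feats[g.id] = g
        gene_ids.add(g.id)

    mrna_to_gene = {}
    for m in db.features_of_type("mRNA"):
        parents = m.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            raise FormatError(f"orphan mRNA feature {m.id!r}: unknown Parent {parents}")
        mrna_to_gene[m.id] = parents[0]

    exons: dict[str, list[GenomicInterval]] = {gid: [] for gid in gene_ids}
    cds: dict[str, list[GenomicInterval]] = {gid: [] for gid in gene_ids}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            gid = None
            for p in parents:
                if p in mrna_to_gene:
                    gid = mrna_to_gene[p]
                    break
                if p in gene_ids:
                    gid = p
                    break
            if gid is None:
                raise FormatError(
                    f"orphan {ftype} feature at {f.seqid}:{f.start}-{f.end}: "
                    f"unresolved Parent {parents}"
                )
            store[gid].append(
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
            )

    models = []
    for gid, g in gene_feats.items():
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        gene_exons = _merge_intervals(exons[gid]) or [interval]
        models.append(
            GeneModel(
                gene_id=gid,
                interval=interval,
                exons=gene_exons,
                cds=_merge_intervals(cds[gid]),
                source=source if source != "." else (g.source or "."),
            )
        )
    models.sort(key=lambda m: (m.contig, m.interval.start, m.gene_id))
    return models


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialise gene models as GFF3 (one mRNA per gene, exon+CDS children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            src = g.source if g.source != "." else "methylscape"
            iv = g.interval
            fh.write(
                f"{iv.contig}\t{src}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{iv.contig}\t{src}\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.contig}\t{src}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={mid}\n"
                )
            for c in g.cds:
                fh.write(
                    f"{c.contig}\t{src}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t0\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# BED and tabular inputs
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, as on disk)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED requires >= 3 columns", line=i)
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            try:
                out.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
                )
            except ValueError as exc:
                raise FormatError(str(exc), line=i) from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.contig, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(names[i] if names is not None else ".")
                cols.append(f"{scores[i]:.6g}" if scores is not None else "0")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_fpkm_table(path: str | Path) -> pd.DataFrame:
    """Genes x samples FPKM table (TSV, first column gene id, header row).

    Raises FormatError on negative FPKM or duplicate gene ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in FPKM table")
    if (df.to_numpy(dtype=float) < 0).any():
        raise FormatError("negative FPKM value")
    return df.astype(float)


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Gene -> taxonomic group table (TSV: gene_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if "gene_id" not in df.columns or "group" not in df.columns:
        raise FormatError("taxonomy table requires columns gene_id, group")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r} in taxonomy table")
    return df[["gene_id", "group"]]


def read_ortholog_pairs(path: str | Path) -> pd.DataFrame:
    """Ortholog pair table (TSV: gene_a, gene_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if df.shape[1] < 2:
        raise FormatError("ortholog pair table requires two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return df


def read_table(path: str | Path, schema: str):
    """Schema-dispatched tabular reader (fpkm | taxonomy | ortholog_pairs | bed)."""
    readers = {
        "fpkm": read_fpkm_table,
        "taxonomy": read_taxonomy_table,
        "ortholog_pairs": read_ortholog_pairs,
        "bed": read_bed,
    }
    try:
        reader = readers[schema]
    except KeyError:
        raise ValueError(f"unknown table schema {schema!r}") from None
    return reader(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
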