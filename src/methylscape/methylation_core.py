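"""Per-site, per-context and per-feature methylation statistics.

Two estimators of a regional methylation level are carried everywhere:

``mean_of_fractions``
    the unweighted average of per-site fractions ``m / (m + u)`` over covered
    sites (the default; the per-cytosine average a browser track shows), and
``weighted``
    the coverage-weighted level ``sum(m) / sum(m + u)``.

The two agree exactly when every site has equal coverage.  "Covered" always
means coverage at or above the track's ``min_coverage`` threshold (default 5
reads, standard WGBS practice).  Site inclusion in a feature is
strand-agnostic: both strands' cytosines inside the interval count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, CytosineRecord, GeneModel, GenomicInterval, \
    read_cytosine_report_frame

logger = logging.getLogger(__name__)

REGION_KINDS = ("gene_body", "exon", "intron", "upstream500", "downstream500",
                "intergenic", "repeat")


def site_fraction(record: CytosineRecord) -> float | None:
    """Per-site methylation fraction; None (undefined) at zero coverage."""
    cov = record.count_meth + record.count_unmeth
    if cov == 0:
        return None
    return record.count_meth / cov


@dataclass(frozen=True)
class FeatureMethylation:
    """Methylation summary of one feature's territory in one context."""

    feature_id: str
    region_kind: str
    context: str
    n_sites_covered: int
    fraction_methylation: float | None      # mean of per-site fractions
    weighted_level: float | None = None     # sum(meth) / sum(total)
    median_fraction: float | None = None


class MethylationTrack:
    """Indexed per-cytosine counts for one condition.

    Holds the full report (zero-coverage records included) and exposes
    per-contig, per-context sorted position/count arrays for covered sites.
    At most one record may exist per (contig, pos, strand).
    """

    def __init__(self, frame: pd.DataFrame, min_coverage: int = 5,
                 name: str = "track"):
        if frame.duplicated(subset=["contig", "pos", "strand"]).any():
            dup = frame[frame.duplicated(subset=["contig", "pos", "strand"])]
            raise ValueError(
                f"duplicate cytosine record at {dup['contig'].iloc[0]}:"
                f"{dup['pos'].iloc[0]}{dup['strand'].iloc[0]}"
            )
        self.frame = frame
        self.min_coverage = int(min_coverage)
        self.name = name
        self._index: dict[str, dict[str, tuple]] = {}

    @classmethod
    def from_report(cls, path: str | Path, min_coverage: int = 5,
                    name: str | None = None) -> "MethylationTrack":
        frame = read_cytosine_report_frame(path)
        return cls(frame, min_coverage=min_coverage,
                   name=name or Path(path).stem)

    @property
    def contigs(self) -> list[str]:
        return sorted(self.frame["contig"].unique())

    def _context_index(self, context: str) -> dict[str, tuple]:
        """contig -> (pos0 sorted, meth, total) over covered sites."""
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        if context in self._index:
            return self._index[context]
        sub = self.frame[self.frame["context"] == context]
        total = (sub["count_meth"] + sub["count_unmeth"]).to_numpy()
        covered = total >= self.min_coverage
        sub = sub.loc[covered]
        total = total[covered]
        index: dict[str, tuple] = {}
        meth_all = sub["count_meth"].to_numpy()
        pos_all = sub["pos"].to_numpy() - 1  # to 0-based
        contig_all = sub["contig"].to_numpy()
        for contig in np.unique(contig_all):
            m = contig_all == contig
            pos0, meth, tot = pos_all[m], meth_all[m], total[m]
            order = np.argsort(pos0, kind="stable")
            index[str(contig)] = (pos0[order], meth[order], tot[order])
        self._index[context] = index
        return index

    def covered_sites(self, context: str, contig: str | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pos0, meth, total) arrays of covered sites, one contig or all."""
        idx = self._context_index(context)
        if contig is not None:
            return idx.get(contig, (np.array([], dtype=np.int64),) * 3)
        if not idx:
            empty = np.array([], dtype=np.int64)
            return empty, empty, empty
        parts = [idx[c] for c in sorted(idx)]
        return tuple(np.concatenate([p[i] for p in parts]) for i in range(3))

    def sites_in(self, contig: str, start: int, end: int, context: str
                 ) -> tuple[np.ndarray, np.ndarray]:
        """(meth, total) of covered sites with 0-based position in [start, end)."""
        pos0, meth, tot = self.covered_sites(context, contig)
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return meth[lo:hi], tot[lo:hi]

    def n_covered(self, context: str) -> int:
        pos0, _, _ = self.covered_sites(context)
        return int(pos0.shape[0])


# ---------------------------------------------------------------------------
# global and regional levels
# ---------------------------------------------------------------------------

def _level(meth: np.ndarray, total: np.ndarray, estimator: str) -> float | None:
    if meth.shape[0] == 0:
        return None
    if estimator == "mean_of_fractions":
        return float(np.mean(meth / total))
    if estimator == "weighted":
        return float(meth.sum() / total.sum())
    raise ValueError(f"unknown estimator {estimator!r}")


def global_level(track: MethylationTrack,
                 contexts: Sequence[str] = CONTEXTS,
                 estimator: str = "mean_of_fractions") -> dict[str, float | None]:
    """Genome-wide level per context plus a pooled value over the contexts.

    A context with no covered site yields None (and a logged warning).
    """
    out: dict[str, float | None] = {}
    pooled_m, pooled_t = [], []
    for context in contexts:
        _, meth, tot = track.covered_sites(context)
        value = _level(meth, tot, estimator)
        if value is None:
            logger.warning("no covered %s sites in %s", context, track.name)
        out[context] = value
        pooled_m.append(meth)
        pooled_t.append(tot)
    out["pooled"] = _level(np.concatenate(pooled_m), np.concatenate(pooled_t),
                           estimator) if pooled_m else None
    return out


def region_sites(track: MethylationTrack, intervals: Iterable[GenomicInterval],
                 context: str = "CG") -> tuple[np.ndarray, np.ndarray]:
    """Concatenated (meth, total) over covered sites in a set of intervals."""
    ms, ts = [], []
    for iv in intervals:
        m, t = track.sites_in(iv.contig, iv.start, iv.end, context)
        ms.append(m)
        ts.append(t)
    if not ms:
        e = np.array([], dtype=np.int64)
        return e, e
    return np.concatenate(ms), np.concatenate(ts)


def feature_methylation(track: MethylationTrack,
                        intervals: Sequence[GenomicInterval],
                        region_kind: str, context: str = "CG",
                        feature_id: str = "") -> FeatureMethylation:
    """Mean-of-fractions level over covered sites inside ``intervals``.

    Zero covered sites gives an undefined (None) fraction, never an error.
    """
    meth, tot = region_sites(track, intervals, context)
    n = int(meth.shape[0])
    frac = meth / tot if n else None
    return FeatureMethylation(
        feature_id=feature_id,
        region_kind=region_kind,
        context=context,
        n_sites_covered=n,
        fraction_methylation=float(np.mean(frac)) if n else None,
        weighted_level=float(meth.sum() / tot.sum()) if n else None,
        median_fraction=float(np.median(frac)) if n else None,
    )


def gene_flanks(gene: GeneModel, flank_bp: int = 500,
                contig_length: int | None = None
                ) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """(upstream, downstream) flanks of a gene on its own strand.

    Flanks extending past the contig edge are truncated; a fully truncated
    flank is None.
    """
    iv = gene.interval
    left = (max(0, iv.start - flank_bp), iv.start)
    right_end = iv.end + flank_bp
    if contig_length is not None:
        right_end = min(contig_length, right_end)
    right = (iv.end, right_end)

    def mk(bounds):
        s, e = bounds
        return GenomicInterval(iv.contig, s, e, iv.strand) if e > s else None

    if iv.strand == "-":
        return mk(right), mk(left)
    return mk(left), mk(right)


def gene_feature_table(track: MethylationTrack, genes: Sequence[GeneModel],
                       context: str = "CG", flank_bp: int = 500,
                       contig_lengths: dict[str, int] | None = None
                       ) -> pd.DataFrame:
    """Per-gene methylation by feature: body, exon, intron, both flanks.

    Returns one row per gene with ``<kind>_fraction`` (mean of per-site
    fractions, NaN when no covered site) and ``<kind>_n`` columns.
    """
    rows = []
    for g in genes:
        clen = contig_lengths.get(g.contig) if contig_lengths else None
        up, down = gene_flanks(g, flank_bp, clen)
        regions = {
            "body": [g.interval],
            "exon": g.exons,
            "intron": g.introns,
            "upstream500": [up] if up else [],
            "downstream500": [down] if down else [],
        }
        row: dict = {"gene_id": g.gene_id}
        for kind, ivals in regions.items():
            meth, tot = region_sites(track, ivals, context)
            n = int(meth.shape[0])
            row[f"{kind}_fraction"] = float(np.mean(meth / tot)) if n else np.nan
            row[f"{kind}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

def metagene_profile(track: MethylationTrack, genes: Sequence[GeneModel],
                     n_body_bins: int = 20, flank_bp: int = 500,
                     flank_bin_bp: int = 100, context: str = "CG",
                     contig_lengths: dict[str, int] | None = None
                     ) -> pd.DataFrame:
    """Average methylation across genes in 5'->3' orientation.

    Each gene body is rescaled to ``n_body_bins`` bins; flanks use fixed
    ``flank_bin_bp`` windows.  Minus-strand genes are reversed so bin 0 is
    always the 5' end.  A bin's value is the mean over genes of the per-gene
    bin mean; genes with no covered site in a bin are skipped for that bin.

    Returns a DataFrame with columns bin_kind ('upstream'/'body'/'downstream'),
    bin_index, mean_fraction, n_genes.
    """
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    n_flank_bins = max(0, flank_bp // flank_bin_bp) if flank_bp > 0 else 0
    total_bins = n_body_bins + 2 * n_flank_bins
    sums = np.zeros(total_bins)
    counts = np.zeros(total_bins, dtype=np.int64)

    for g in genes:
        iv = g.interval
        clen = contig_lengths.get(g.contig) if contig_lengths else None
        pos0, meth, tot = track.covered_sites(context, g.contig)
        span_start = iv.start - flank_bp
        span_end = iv.end + flank_bp
        lo = np.searchsorted(pos0, max(0, span_start), side="left")
        hi = np.searchsorted(pos0, span_end if clen is None
                             else min(clen, span_end), side="left")
        if lo == hi:
            continue
        p = pos0[lo:hi]
        frac = meth[lo:hi] / tot[lo:hi]

        # signed 5'->3' coordinate: bin index in [0, total_bins)
        bins = np.empty(p.shape[0], dtype=np.int64)
        in_body = (p >= iv.start) & (p < iv.end)
        upstream = p < iv.start
        downstream = p >= iv.end
        body_rel = np.clip(((p - iv.start) * n_body_bins) // max(1, len(iv)),
                           0, n_body_bins - 1)
        up_rel = (iv.start - 1 - p[upstream]) // flank_bin_bp if flank_bin_bp else 0
        down_rel = (p[downstream] - iv.end) // flank_bin_bp if flank_bin_bp else 0
        bins[in_body] = n_flank_bins + body_rel[in_body]
        bins[upstream] = n_flank_bins - 1 - up_rel
        bins[downstream] = n_flank_bins + n_body_bins + down_rel
        if iv.strand == "-":
            bins = total_bins - 1 - bins
        valid = (bins >= 0) & (bins < total_bins)
        bins, frac = bins[valid], frac[valid]
        if bins.shape[0] == 0:
            continue
        gene_sum = np.bincount(bins, weights=frac, minlength=total_bins)
        gene_n = np.bincount(bins, minlength=total_bins)
        occupied = gene_n > 0
        sums[occupied] += gene_sum[occupied] / gene_n[occupied]
        counts[occupied] += 1

    kinds = (["upstream"] * n_flank_bins + ["body"] * n_body_bins
             + ["downstream"] * n_flank_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_kind": kinds,
        "bin_index": np.arange(total_bins),
        "mean_fraction": mean,
        "n_genes": counts,
    })


# ---------------------------------------------------------------------------
# site-level histogram
# ---------------------------------------------------------------------------

def site_level_histogram(track: MethylationTrack, context: str = "CG",
                         n_bins: int = 20) -> np.ndarray:
    """Histogram counts of per-site fractions over [0, 1]; sums to n covered."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _, meth, tot = track.covered_sites(context)
    if meth.shape[0] == 0:
        return np.zeros(n_bins, dtype=np.int64)
    counts, _ = np.histogram(meth / tot, bins=n_bins, range=(0.0, 1.0))
    return counts.astype(np.int64)


def bimodality_index(hist: np.ndarray) -> float:
    """Extreme-bin mass minus central-bin mass, each over a fifth of the range.

    Positive values indicate the bimodal extremes-heavy shape expected of a
    per-site methylation-level histogram.
    """
    n = hist.shape[0]
    k = max(1, n // 5)
    total = hist.sum()
    if total == 0:
        return 0.0
    extreme = hist[:k].sum() + hist[-k:].sum()
    mid = n // 2
    central = hist[mid - k // 2: mid - k // 2 + k].sum() * 2
    return float((extreme - central) / total)


def site_fractions_bedgraph(track: MethylationTrack, path: str | Path,
                            context: str = "CG") -> None:
    """Write covered-site fractions as bedGraph (one base per record)."""
    with open(path, "w") as fh:
        for contig in track.contigs:
            pos0, meth, tot = track.covered_sites(context, contig)
            for p, m, t in zip(pos0, meth, tot):
                fh.write(f"{contig}\t{p}\t{p + 1}\t{m / t:.4f}\n")
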