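"""Two-state methylation-domain segmentation and repeat/gene annotation.

Contigs are scanned in fixed windows; a window with enough covered CpGs is
labelled *hyper* when its mean-of-fractions level reaches ``t_hyper`` and
*hypo* otherwise.  Data-sparse windows (fewer than ``min_sites_per_window``
covered sites) carry the previous label, so sparse gaps up to ``merge_gap``
windows never split a domain; longer sparse runs are carried too, keeping the
segmentation a tiling of covered territory.  Sparse windows before the first
(or after the last) data-bearing window are uncovered territory and excluded.
Runs of same-label windows merge into :class:`DomainSegment` blocks.

A thresholded scan rather than an HMM: the domain structure this targets is
near-binary (high plateaus vs near-zero troughs), where the simple method is
exact and trivially testable; an HMM remains an extension point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval
from .methylation_core import MethylationTrack

HYPER, HYPO = "hyper", "hypo"


@dataclass(frozen=True)
class DomainSegment:
    interval: GenomicInterval
    label: str                      # 'hyper' | 'hypo'
    mean_fraction: float
    n_sites: int
    repeat_overlap_fraction: float = 0.0
    n_genes_contained: int = 0

    def __len__(self) -> int:
        return len(self.interval)


def _window_stats(pos0: np.ndarray, frac: np.ndarray, window: int,
                  n_windows: int, offset: int) -> tuple[np.ndarray, np.ndarray]:
    widx = (pos0 - offset) // window
    n = np.bincount(widx, minlength=n_windows)
    s = np.bincount(widx, weights=frac, minlength=n_windows)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return mean, n


def segment_domains(track: MethylationTrack, window: int = 1000,
                    t_hyper: float = 0.5, min_sites_per_window: int = 3,
                    merge_gap: int = 1, context: str = "CG",
                    contig_lengths: dict[str, int] | None = None
                    ) -> list[DomainSegment]:
    """Partition each contig into alternating hyper/hypo domains.

    Windows at contig ends may be short; they are kept.  An empty track
    yields an empty segmentation.  Output is sorted by contig then start and
    independent of contig processing order.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    segments: list[DomainSegment] = []
    for contig in sorted(track.contigs):
        pos0, meth, tot = track.covered_sites(context, contig)
        if pos0.shape[0] == 0:
            continue
        frac = meth / tot
        clen = (contig_lengths or {}).get(contig, int(pos0[-1]) + 1)
        n_windows = int(np.ceil(clen / window))
        mean, n = _window_stats(pos0, frac, window, n_windows, 0)

        dense = n >= min_sites_per_window
        if not dense.any():
            continue
        first, last = int(np.argmax(dense)), int(
            len(dense) - 1 - np.argmax(dense[::-1]))

        labels = np.empty(n_windows, dtype=object)
        labels[dense] = np.where(mean[dense] >= t_hyper, HYPER, HYPO)
        # interior sparse windows inherit the previous dense label
        current = labels[first]
        for i in range(first, last + 1):
            if dense[i]:
                current = labels[i]
            else:
                labels[i] = current

        # merge same-label runs into segments
        run_start = first
        for i in range(first + 1, last + 2):
            if i > last or labels[i] != labels[run_start]:
                seg_start = run_start * window
                seg_end = min((i - 1 + 1) * window, clen)
                in_run = slice(run_start, i)
                n_run = int(n[in_run].sum())
                lo = np.searchsorted(pos0, seg_start, side="left")
                hi = np.searchsorted(pos0, seg_end, side="left")
                mean_frac = float(frac[lo:hi].mean()) if hi > lo else float("nan")
                segments.append(DomainSegment(
                    interval=GenomicInterval(contig, seg_start, seg_end),
                    label=labels[run_start],
                    mean_fraction=mean_frac,
                    n_sites=n_run,
                ))
                run_start = i
    segments.sort(key=lambda s: (s.interval.contig, s.interval.start))
    return segments


def annotate_segments(segments: Sequence[DomainSegment],
                      repeats: Sequence[GenomicInterval],
                      genes: Sequence[GeneModel] | None = None
                      ) -> list[DomainSegment]:
    """Fill repeat_overlap_fraction (overlapped bases / segment length) and
    n_genes_contained (gene midpoint inside the segment)."""
    repeat_trees: dict[str, IntervalTree] = {}
    for r in repeats:
        repeat_trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)
    gene_mids: dict[str, np.ndarray] = {}
    if genes:
        by_contig: dict[str, list[float]] = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g.interval.midpoint)
        gene_mids = {c: np.sort(np.array(v)) for c, v in by_contig.items()}

    out = []
    for seg in segments:
        iv = seg.interval
        overlap = 0
        tree = repeat_trees.get(iv.contig)
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                overlap += min(hit.end, iv.end) - max(hit.begin, iv.start)
        n_genes = 0
        mids = gene_mids.get(iv.contig)
        if mids is not None:
            n_genes = int(np.searchsorted(mids, iv.end)
                          - np.searchsorted(mids, iv.start))
        out.append(replace(seg,
                           repeat_overlap_fraction=overlap / len(iv),
                           n_genes_contained=n_genes))
    return out


def boundary_recovery(segments: Sequence[DomainSegment],
                      truth: Sequence[tuple[str, int, int, str]],
                      window: int = 1000) -> float:
    """Share of true domain edges recovered within one window.

    ``truth`` rows are (contig, start, end, label); interior edges only
    (contig ends are forced boundaries in both).
    """
    recovered_by_contig: dict[str, np.ndarray] = {}
    for seg in segments:
        recovered_by_contig.setdefault(seg.interval.contig, [])
    tmp: dict[str, list[int]] = {}
    for seg in segments:
        tmp.setdefault(seg.interval.contig, []).extend(
            [seg.interval.start, seg.interval.end])
    recovered_by_contig = {c: np.unique(np.array(v)) for c, v in tmp.items()}

    edge_set: set[tuple[str, int]] = set()
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end, _ in truth:
        by_contig.setdefault(contig, []).append((start, end))
    for contig, doms in by_contig.items():
        doms.sort()
        lo = min(s for s, _ in doms)
        hi = max(e for _, e in doms)
        for s, e in doms:
            for edge in (s, e):
                if lo < edge < hi:
                    edge_set.add((contig, edge))
    true_edges = sorted(edge_set)
    if not true_edges:
        return float("nan")
    n_hit = 0
    for contig, edge in true_edges:
        rec = recovered_by_contig.get(contig)
        if rec is None or rec.shape[0] == 0:
            continue
        nearest = rec[np.argmin(np.abs(rec - edge))]
        if abs(int(nearest) - edge) <= window:
            n_hit += 1
    return n_hit / len(true_edges)
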