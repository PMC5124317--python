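"""Gene methylation-status calls and cross-condition / cross-species comparison.

A gene is called *methylated* when its gene-body CG fraction (mean of
per-site fractions over covered CpGs) reaches the status threshold, and
*unmethylated* below it; genes with fewer covered CpGs than ``min_sites``
are *undetermined*.  A fraction exactly at the threshold is methylated (the
tie goes up).  On well-separated data — class means near 0.9 vs 0.07 — any
mid-range threshold gives the same calls; 0.5 is the default and both knobs
are exposed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .methylation_core import MethylationTrack, gene_feature_table

logger = logging.getLogger(__name__)

METHYLATED, UNMETHYLATED, UNDETERMINED = "methylated", "unmethylated", "undetermined"


def classify_gene(body_fraction: float, n_sites_covered: int,
                  min_sites: int = 5, threshold: float = 0.5) -> str:
    """Status of one gene from its body CG fraction and covered-site count."""
    if n_sites_covered < min_sites:
        return UNDETERMINED
    if not np.isfinite(body_fraction):
        return UNDETERMINED
    return METHYLATED if body_fraction >= threshold else UNMETHYLATED


def status_table(track: MethylationTrack, genes: Sequence[GeneModel],
                 fpkm: pd.DataFrame | None = None, min_sites: int = 5,
                 threshold: float = 0.5, context: str = "CG") -> pd.DataFrame:
    """Per-gene summary: body CG fraction, covered sites, status call, FPKM.

    Columns: fraction, n_sites, status, sum_fpkm, mean_fpkm.  Genes absent
    from the FPKM table get NaN expression (with a logged count).
    """
    feats = gene_feature_table(track, genes, context=context)
    out = pd.DataFrame({
        "fraction": feats["body_fraction"],
        "n_sites": feats["body_n"],
    })
    out["status"] = [
        classify_gene(f, n, min_sites=min_sites, threshold=threshold)
        for f, n in zip(out["fraction"].fillna(np.nan), out["n_sites"])
    ]
    if fpkm is not None:
        missing = out.index.difference(fpkm.index)
        if len(missing):
            logger.warning("%d genes missing from FPKM table", len(missing))
        aligned = fpkm.reindex(out.index)
        out["sum_fpkm"] = aligned.sum(axis=1, skipna=False)
        out["mean_fpkm"] = aligned.mean(axis=1, skipna=False)
    else:
        out["sum_fpkm"] = np.nan
        out["mean_fpkm"] = np.nan
    return out


def class_summary(statuses: pd.DataFrame) -> pd.DataFrame:
    """Per-class count, share of determined genes, mean fraction, mean FPKM.

    Proportions are over determined genes only.  Raises ValueError when no
    gene has a determined status.
    """
    determined = statuses[statuses["status"] != UNDETERMINED]
    if determined.empty:
        raise ValueError("no determined genes")
    rows = []
    for status in (METHYLATED, UNMETHYLATED):
        sub = determined[determined["status"] == status]
        rows.append({
            "status": status,
            "n_genes": len(sub),
            "proportion": len(sub) / len(determined),
            "mean_fraction": float(sub["fraction"].mean()) if len(sub) else np.nan,
            "median_fraction": float(sub["fraction"].median()) if len(sub) else np.nan,
            "mean_fpkm": float(sub["mean_fpkm"].mean()) if len(sub) else np.nan,
            "mean_sum_fpkm": float(sub["sum_fpkm"].mean()) if len(sub) else np.nan,
        })
    rows.append({
        "status": UNDETERMINED,
        "n_genes": int((statuses["status"] == UNDETERMINED).sum()),
        "proportion": np.nan,
        "mean_fraction": np.nan,
        "median_fraction": np.nan,
        "mean_fpkm": np.nan,
        "mean_sum_fpkm": np.nan,
    })
    return pd.DataFrame(rows).set_index("status")


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def _window_fractions(track: MethylationTrack, window: int, context: str
                      ) -> pd.Series:
    """Mean-of-fractions per fixed tiling window, indexed (contig, window_i)."""
    chunks = {}
    for contig in track.contigs:
        pos0, meth, tot = track.covered_sites(context, contig)
        if pos0.shape[0] == 0:
            continue
        widx = pos0 // window
        frac = meth / tot
        s = pd.Series(frac).groupby(widx).mean()
        for wi, v in s.items():
            chunks[(contig, int(wi))] = v
    return pd.Series(chunks, dtype=float)


def condition_correlation(track_a: MethylationTrack, track_b: MethylationTrack,
                          genes: Sequence[GeneModel] | None = None,
                          unit: str = "gene", window: int = 1000,
                          context: str = "CG") -> dict:
    """Pearson correlation of per-unit methylation between two conditions.

    ``unit`` is 'gene' (per-gene body fractions; requires ``genes``) or
    'window' (fixed tiling windows of ``window`` bp).  Units with an
    undefined fraction in either condition are excluded and counted.
    Returns dict with r, n_units, n_excluded and the paired table.
    """
    if unit == "gene":
        if genes is None:
            raise ValueError("gene unit requires gene models")
        fa = gene_feature_table(track_a, genes, context=context)["body_fraction"]
        fb = gene_feature_table(track_b, genes, context=context)["body_fraction"]
    elif unit == "window":
        fa = _window_fractions(track_a, window, context)
        fb = _window_fractions(track_b, window, context)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    paired = pd.DataFrame({"a": fa, "b": fb})
    n_total = len(paired)
    paired = paired.dropna()
    if len(paired) < 3:
        raise ValueError(
            f"need >= 3 units with coverage in both conditions, got {len(paired)}")
    r, _ = stats.pearsonr(paired["a"], paired["b"])
    return {
        "pearson_r": float(r),
        "n_units": len(paired),
        "n_excluded": n_total - len(paired),
        "unit": unit,
        "paired": paired,
    }


# ---------------------------------------------------------------------------
# cross-species ortholog comparison
# ---------------------------------------------------------------------------

def shared_ortholog_status(status_a: pd.DataFrame, status_b: pd.DataFrame,
                           pairs: pd.DataFrame) -> dict:
    """Contingency counts of methylation status over ortholog pairs.

    ``status_a`` / ``status_b`` need a ``status`` column indexed by gene id;
    ``pairs`` has columns gene_a, gene_b.  Pairs whose genes are missing from
    either table are excluded (with a warning) and counted; pairs with an
    undetermined status on either side are likewise excluded.
    """
    counts = {"both_methylated": 0, "either_methylated": 0, "neither": 0,
              "n_pairs_used": 0, "n_dangling": 0, "n_undetermined": 0}
    for _, row in pairs.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        if a not in status_a.index or b not in status_b.index:
            counts["n_dangling"] += 1
            continue
        sa, sb = status_a.loc[a, "status"], status_b.loc[b, "status"]
        if UNDETERMINED in (sa, sb):
            counts["n_undetermined"] += 1
            continue
        counts["n_pairs_used"] += 1
        ma, mb = sa == METHYLATED, sb == METHYLATED
        if ma and mb:
            counts["both_methylated"] += 1
            counts["either_methylated"] += 1
        elif ma or mb:
            counts["either_methylated"] += 1
        else:
            counts["neither"] += 1
    if counts["n_dangling"]:
        logger.warning("%d ortholog pairs referenced unknown genes",
                       counts["n_dangling"])
    return counts
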