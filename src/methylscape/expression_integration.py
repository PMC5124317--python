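"""Joining methylation status with expression.

Determined genes partition into three populations (plus a remainder):

* ``i_lowFPKM`` — mean FPKM in [0, ``low_fpkm_max``], regardless of status
  (a population defined by expression alone, almost entirely methylated);
* ``iii_expressed_methylated`` — methylated with mean FPKM at or above
  ``high_fpkm_min``;
* ``ii_expressed_unmethylated`` — unmethylated above ``low_fpkm_max``;
* ``other`` — the remainder (methylated, mid-range FPKM).

Population i takes precedence over iii when both match, since i is defined
by expression alone.  Gene FPKM is the mean across all samples; the sum
across samples is retained for the consensus filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gene_status import METHYLATED, UNDETERMINED

logger = logging.getLogger(__name__)

POPULATIONS = ("i_lowFPKM", "ii_expressed_unmethylated",
               "iii_expressed_methylated", "other")


@dataclass
class PopulationPartition:
    label: str
    gene_ids: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.gene_ids)


def partition_populations(statuses: pd.DataFrame,
                          low_fpkm_max: float = 10.0,
                          high_fpkm_min: float = 100.0) -> dict:
    """Assign each determined gene to one population; summarise each.

    ``statuses`` is a status table (columns fraction, status, mean_fpkm,
    sum_fpkm).  Genes with no FPKM (NaN mean) are excluded with a warning
    count.  Returns a dict with per-population members and a summary frame
    (count, mean FPKM, % methylated).
    """
    det = statuses[statuses["status"] != UNDETERMINED].copy()
    n_missing = int(det["mean_fpkm"].isna().sum())
    if n_missing:
        logger.warning("%d determined genes lack FPKM; excluded", n_missing)
    det = det.dropna(subset=["mean_fpkm"])

    meth = det["status"] == METHYLATED
    low = det["mean_fpkm"] <= low_fpkm_max
    high = det["mean_fpkm"] >= high_fpkm_min

    label = pd.Series("other", index=det.index, dtype=object)
    label[~meth & ~low] = "ii_expressed_unmethylated"
    label[meth & high] = "iii_expressed_methylated"
    label[low] = "i_lowFPKM"  # precedence: i beats iii

    rows = []
    members = {}
    for pop in POPULATIONS:
        ids = det.index[label == pop]
        sub = det.loc[ids]
        members[pop] = PopulationPartition(pop, list(ids))
        rows.append({
            "population": pop,
            "n_genes": len(ids),
            "mean_fpkm": float(sub["mean_fpkm"].mean()) if len(ids) else np.nan,
            "percent_methylated": float(
                100.0 * (sub["status"] == METHYLATED).mean()) if len(ids)
                else np.nan,
        })
    return {
        "assignments": label,
        "members": members,
        "summary": pd.DataFrame(rows).set_index("population"),
        "n_missing_fpkm": n_missing,
    }


def methylation_expression_scatter(statuses: pd.DataFrame) -> dict:
    """Per-gene (fraction, mean FPKM) table with Pearson/Spearman coefficients.

    Coefficients are NaN (reported as undefined) when either column is
    constant.  The expected relationship is non-linear and bimodal, so weak
    linear correlation is the norm, not a defect.
    """
    det = statuses[statuses["status"] != UNDETERMINED].dropna(
        subset=["fraction", "mean_fpkm"])
    table = det[["fraction", "mean_fpkm"]].copy()
    if len(table) < 2 or table["fraction"].nunique() < 2 \
            or table["mean_fpkm"].nunique() < 2:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(table["fraction"],
                                       table["mean_fpkm"])[0])
        spearman = float(stats.spearmanr(table["fraction"],
                                         table["mean_fpkm"])[0])
    return {"table": table, "pearson_r": pearson, "spearman_rho": spearman}
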