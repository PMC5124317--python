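"""Static figures: site-level histogram, metagene profile, status scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_site_histogram(hist: np.ndarray, path: str | Path,
                        title: str = "Per-site CG methylation levels") -> None:
    edges = np.linspace(0, 1, hist.shape[0] + 1)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(edges[:-1], hist, width=np.diff(edges), align="edge",
           color="#4477aa", edgecolor="white")
    ax.set_xlabel("fraction methylation")
    ax.set_ylabel("covered sites")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metagene(profile: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    ax.plot(profile["bin_index"], profile["mean_fraction"], color="#4477aa")
    body = profile[profile["bin_kind"] == "body"]
    if not body.empty:
        ax.axvspan(body["bin_index"].min(), body["bin_index"].max(),
                   color="#dddddd", alpha=0.5, label="gene body")
        ax.legend(frameon=False)
    ax.set_xlabel("bin (5' → 3')")
    ax.set_ylabel("mean fraction methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_expression_scatter(table: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.8))
    ax.scatter(np.log10(table["mean_fpkm"] + 1), table["fraction"],
               s=6, alpha=0.4, color="#4477aa", linewidths=0)
    ax.set_xlabel("log10(mean FPKM + 1)")
    ax.set_ylabel("gene-body fraction methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
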