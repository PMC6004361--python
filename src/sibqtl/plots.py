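"""Figure helpers: Manhattan plot and phenotype frequency distribution."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan_plot(
    scan_table: pd.DataFrame,
    path: str,
    title: str = "",
    thresholds: tuple[float, ...] = (0.05, 0.1),
) -> None:
    """-log10(p) per site with uniform x spacing in site (gene) order."""
    tab = scan_table[scan_table.testable]
    x = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.scatter(x, tab.neg_log10_p, s=14, c="steelblue")
    for thr, style in zip(thresholds, ("--", ":")):
        ax.axhline(-np.log10(thr), color="firebrick", ls=style, lw=0.8,
                   label=f"p = {thr}")
    ax.set_xticks(x)
    ax.set_xticklabels(tab.site_id, rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def phenotype_histogram(
    phen: pd.DataFrame,
    path: str,
    bins: int = 40,
) -> None:
    """Side-by-side weight and length frequency distributions."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, col, unit in zip(axes, ("weight_g", "length_mm"), ("g", "mm")):
        ax.hist(phen[col], bins=bins, color="lightsteelblue", edgecolor="grey")
        ax.set_xlabel(f"{col.split('_')[0]} ({unit})")
        ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
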