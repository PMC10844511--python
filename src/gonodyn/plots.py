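"""Optional figure exports (headless; Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gonodyn.dynamics import (
    CLASS_FEG,
    CLASS_MEG,
    CLASS_NONSIG,
    CLASS_SHARED,
    MechanismSummary,
    mechanism_percentages,
)

_CLASS_COLORS = {
    CLASS_MEG: "#2166ac",   # blue
    CLASS_FEG: "#b2182b",   # red
    CLASS_SHARED: "#999999",  # grey
    CLASS_NONSIG: "#dddddd",
}


def fc_plane_scatter(points: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Female FC on X, male FC on Y; MEG blue, FEG red, shared grey."""
    fig, ax = plt.subplots(figsize=(5, 5))
    shown = points[points["class"] != CLASS_NONSIG]
    for cls in (CLASS_SHARED, CLASS_FEG, CLASS_MEG):
        sub = shown[shown["class"] == cls]
        ax.scatter(
            sub["fc_female"],
            sub["fc_male"],
            s=6,
            alpha=0.6,
            color=_CLASS_COLORS[cls],
            label=f"{cls} (n={len(sub)})",
            linewidths=0,
        )
    ax.axhline(0, color="black", lw=0.5)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_xlabel("log2 FC female (T2 vs T1)")
    ax.set_ylabel("log2 FC male (T2 vs T1)")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mechanism_bars(summaries: dict[str, MechanismSummary], path: str | Path) -> None:
    """Diverging bars of up-/down-regulated percentages per sex and species."""
    species = list(summaries)
    fig, ax = plt.subplots(figsize=(7, 0.8 + 0.8 * len(species)))
    y = np.arange(len(species))
    for i, sp in enumerate(species):
        pct = mechanism_percentages(summaries[sp])
        ax.barh(y[i] + 0.2, pct["feg_up_pct"], height=0.35, color="#b2182b")
        ax.barh(y[i] + 0.2, -pct["feg_down_pct"], height=0.35, color="#b2182b", alpha=0.5)
        ax.barh(y[i] - 0.2, pct["meg_up_pct"], height=0.35, color="#2166ac")
        ax.barh(y[i] - 0.2, -pct["meg_down_pct"], height=0.35, color="#2166ac", alpha=0.5)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_yticks(y, species)
    ax.set_xlabel("% downregulated  |  % upregulated")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def panel_scatter(panel_report: pd.DataFrame, path: str | Path) -> None:
    """One FC-plane panel per key gene, species points colored by class."""
    genes = list(dict.fromkeys(panel_report["gene"]))
    ncol = 3
    nrow = int(np.ceil(len(genes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for k, gene in enumerate(genes):
        ax = axes[k // ncol][k % ncol]
        sub = panel_report[panel_report["gene"] == gene]
        for _, row in sub.iterrows():
            if pd.isna(row["fc_female"]) or pd.isna(row["fc_male"]):
                continue
            color = _CLASS_COLORS.get(row["class"], "#999999")
            filled = bool(row["significant"])
            ax.scatter(
                row["fc_female"],
                row["fc_male"],
                s=40,
                facecolors=color if filled else "none",
                edgecolors=color,
            )
        ax.axhline(0, color="black", lw=0.5)
        ax.axvline(0, color="black", lw=0.5)
        ax.set_title(gene, fontsize=9)
    for k in range(len(genes), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.supxlabel("log2 FC female")
    fig.supylabel("log2 FC male")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enrichment_bars(conserved: pd.DataFrame, path: str | Path, side: str = "feg") -> None:
    """Per-pathway bars of the per-species gene ratios for one side."""
    ratio_cols = [c for c in conserved.columns if c.startswith(f"{side}_ratio_")]
    fig, ax = plt.subplots(figsize=(7, 0.6 + 0.5 * max(len(conserved), 1)))
    y = np.arange(len(conserved))
    width = 0.8 / max(len(ratio_cols), 1)
    for j, col in enumerate(ratio_cols):
        ax.barh(
            y + j * width,
            conserved[col].fillna(0.0),
            height=width,
            label=col.replace(f"{side}_ratio_", ""),
        )
    ax.set_yticks(y + 0.4, conserved["set_id"])
    ax.set_xlabel("gene ratio")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
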