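"""Manhattan-style and heatmap renders of scan and genotype output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["manhattan", "genotype_matrix_plot", "pool_state_plot"]

_STATE_VALUES = {"FIXED_REF": 0, "SEGREGATING": 1, "FIXED_ALT": 2,
                 "MISSING": np.nan}


def manhattan(windows, out_path: str | Path, value_col: str = "z",
              cutoff: float | None = None, title: str = "") -> None:
    """Z scores of windowed statistics along the genome, one colour per
    chromosome, with an optional horizontal cutoff line."""
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, chrom in enumerate(windows["chrom"].unique()):
        sub = windows[windows["chrom"] == chrom]
        x = (sub["start"] + sub["end"]) / 2 + offset
        ax.scatter(x, sub[value_col], s=4,
                   color="tab:blue" if i % 2 == 0 else "tab:orange")
        ticks.append(offset + sub["end"].max() / 2)
        labels.append(str(chrom))
        offset += sub["end"].max()
    if cutoff is not None:
        ax.axhline(cutoff, color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(value_col)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def genotype_matrix_plot(matrix, out_path: str | Path) -> None:
    """Line-origin genotype heatmap: yellow homozygous wild-type,
    orange heterozygous, red homozygous Fayoumi, white missing."""
    from matplotlib.colors import ListedColormap

    codes = matrix.codes.astype(float).T  # individuals x markers
    codes[codes == -1] = np.nan
    cmap = ListedColormap(["gold", "orange", "firebrick"])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(codes, aspect="auto", cmap=cmap, vmin=0, vmax=2,
              interpolation="nearest")
    ax.set_xlabel("marker")
    ax.set_ylabel("individual")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def pool_state_plot(states, pools: list[str], out_path: str | Path) -> None:
    """Fixed/segregating heatmap of pools (rows) by variants (cols)."""
    mat = np.array([[_STATE_VALUES[v] for v in states[p]] for p in pools],
                   dtype=float)
    fig, ax = plt.subplots(figsize=(10, 0.5 + 0.4 * len(pools)))
    ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0, vmax=2,
              interpolation="nearest")
    ax.set_yticks(range(len(pools)), pools)
    ax.set_xlabel("variant")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
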