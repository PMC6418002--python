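"""Figures: pan/core accumulation boxplot, genome dotplot, per-node dN/dS bars."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .clustering_pangenome import AccumulationCurve
from .structural_features import MatchSegment


def accumulation_boxplot(curve: AccumulationCurve, path: str | Path) -> None:
    """Pan and core cluster counts vs number of genomes, whiskers at extremes."""
    fig, ax = plt.subplots(figsize=(6, 4))
    gs = sorted(curve.pan)
    ax.boxplot(
        [curve.pan[g] for g in gs],
        positions=[g - 0.15 for g in gs],
        widths=0.25,
        whis=(0, 100),
        patch_artist=True,
        boxprops={"facecolor": "#4878a8"},
    )
    ax.boxplot(
        [curve.core[g] for g in gs],
        positions=[g + 0.15 for g in gs],
        widths=0.25,
        whis=(0, 100),
        patch_artist=True,
        boxprops={"facecolor": "white"},
    )
    ax.set_xticks(gs)
    ax.set_xticklabels(gs)
    ax.set_xlabel("number of genomes")
    ax.set_ylabel("protein clusters")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def dotplot(segments: Sequence[MatchSegment], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for s in segments:
        color = "black" if s.orientation == "direct" else "red"
        ax.plot([s.a_start, s.a_end], [s.b_start, s.b_end][:: 1 if s.orientation == "direct" else -1], color=color, lw=0.8)
    ax.set_xlabel("genome A (bp)")
    ax.set_ylabel("genome B (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def dnds_bars(node_table: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(
        [str(n) for n in node_table["node"]],
        node_table["mean_omega"],
        yerr=node_table["sd_omega"],
        capsize=3,
        color="#4878a8",
    )
    ax.axhline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("creation node")
    ax.set_ylabel("mean dN/dS")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
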