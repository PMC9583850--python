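"""Figures: per-strain mean-log-GFP histogram grid, scatter heatmaps,
per-cluster GFP densities and OD growth scatter plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .circuit_model import GATE_NAMES, INPUT_PAIRS
from .gating import EventTable, WellSummary
from .plate_reader import PlateReaderRecord
from .scatter_analysis import GFPDensityComparison


def histogram_grid(
    summaries: Sequence[WellSummary], threshold: float, path: str | Path
) -> None:
    """Per-strain histograms of replicate mean log10 GFP, colored by the
    intended output (orange high / blue low), with the threshold line."""
    fig, axes = plt.subplots(4, 6, figsize=(16, 9), sharex=True)
    by_strain: dict[str, list[float]] = {}
    expected: dict[str, int] = {}
    for s in summaries:
        if s.retained and s.strain is not None and not s.strain.is_control:
            by_strain.setdefault(s.strain_label, []).append(s.mean_log_gfp)
            expected[s.strain_label] = s.strain.expected_output
    for col, gate in enumerate(GATE_NAMES):
        for row, (a, b) in enumerate(INPUT_PAIRS):
            label = f"{gate}{a}{b}"
            ax = axes[row, col]
            vals = by_strain.get(label, [])
            if vals:
                color = "tab:orange" if expected.get(label) else "tab:blue"
                ax.hist(vals, bins=20, color=color)
            ax.axvline(threshold, color="red", linestyle="--", linewidth=1)
            ax.set_title(label, fontsize=8)
    fig.supxlabel("mean log10 GFP per replicate (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def scatter_heatmap(events: EventTable, path: str | Path, bins: int = 150) -> None:
    """2D log-log histogram of FSC_A vs SSC_A."""
    x = np.log10(np.maximum(events.data["FSC_A"], 1.0))
    y = np.log10(np.maximum(events.data["SSC_A"], 1.0))
    fig, ax = plt.subplots(figsize=(5, 4))
    h = ax.hist2d(x, y, bins=bins, cmap="viridis")
    fig.colorbar(h[3], ax=ax, label="events")
    ax.set_xlabel("log10 FSC_A (a.u.)")
    ax.set_ylabel("log10 SSC_A (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def cluster_gfp_densities(cmp: GFPDensityComparison, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, name in ((cmp.density_cluster1, "cluster 1"), (cmp.density_cluster2, "cluster 2")):
        if curve is not None:
            ax.plot(cmp.grid, curve, label=name)
    ax.set_xlabel("log10 GFP (a.u.)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def od_scatter(records: Sequence[PlateReaderRecord], path: str | Path) -> None:
    """Initial vs final OD over all wells."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        [r.initial_od for r in records],
        [r.final_od for r in records],
        s=6,
        alpha=0.4,
    )
    ax.set_xlabel("initial OD (post-recovery)")
    ax.set_ylabel("final OD (at measurement)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
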