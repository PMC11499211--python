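"""Optional PNG renderings of pipeline artifacts.

Plots are derivatives of the exported TSV tables: network graphs (node area
proportional to occurrence count, arrow width proportional to transition
weight), 6x6 transition heat maps on a white-to-red scale, and per-phase
centrality z-score trajectories across postpartum days.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .centrality import centrality_table
from .ethogram import GROUPS
from .transitions import NODE_ORDER, PHASES, build_group_network

_ANGLES = 2 * np.pi * np.arange(len(NODE_ORDER)) / len(NODE_ORDER)
_POS = np.column_stack([np.cos(_ANGLES), np.sin(_ANGLES)])
_METRICS = ("in_strength", "out_strength", "betweenness")
_GROUP_COLOR = {"CTRL": "black", "LBN": "magenta"}


def _plot_network(net, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    w = net.weights
    wmax = w.max() if w.max() > 0 else 1.0
    for i in range(len(NODE_ORDER)):
        for j in range(len(NODE_ORDER)):
            if w[i, j] <= 0:
                continue
            ax.annotate(
                "",
                xy=_POS[j] * 0.85,
                xytext=_POS[i] * 0.85,
                arrowprops=dict(
                    arrowstyle="-|>",
                    lw=0.5 + 3.0 * w[i, j] / wmax,
                    color="steelblue",
                    alpha=0.7,
                    connectionstyle="arc3,rad=0.12",
                ),
            )
    sizes = 120 + 900 * net.node_sizes / max(net.node_sizes.max(), 1.0)
    ax.scatter(_POS[:, 0], _POS[:, 1], s=sizes, c="orange", zorder=3, edgecolors="k")
    for i, code in enumerate(NODE_ORDER):
        ax.annotate(code, _POS[i] * 1.18, ha="center", va="center", fontsize=9)
    ax.set_title(f"{net.group} {net.phase} PPD {net.ppd} (n={net.n_dams})", fontsize=10)
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_heatmap(net, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(net.weights, cmap="Reds", vmin=0)
    ax.set_xticks(range(len(NODE_ORDER)), NODE_ORDER, rotation=45, fontsize=8)
    ax.set_yticks(range(len(NODE_ORDER)), NODE_ORDER, fontsize=8)
    ax.set_xlabel("to")
    ax.set_ylabel("from")
    ax.set_title(f"{net.group} {net.phase} PPD {net.ppd}", fontsize=10)
    fig.colorbar(im, ax=ax, label="transition weight")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_centrality_curves(tables, phase: str, mode: str, path: Path) -> None:
    fig, axes = plt.subplots(
        len(_METRICS), len(NODE_ORDER), figsize=(14, 7), sharex=True, sharey=True
    )
    for mi, metric in enumerate(_METRICS):
        for ni, code in enumerate(NODE_ORDER):
            ax = axes[mi, ni]
            for group, frame in tables.items():
                sel = frame[(frame["metric"] == metric) & (frame["code"] == code)]
                ax.plot(sel["ppd"], sel["z"], color=_GROUP_COLOR.get(group, "gray"),
                        marker="o", ms=2.5, lw=1, label=group)
            ax.axhline(0, color="0.8", lw=0.5)
            if mi == 0:
                ax.set_title(code, fontsize=9)
            if ni == 0:
                ax.set_ylabel(f"{metric}\n(z)", fontsize=8)
    axes[0, 0].legend(fontsize=7)
    fig.suptitle(f"Centrality z-scores, {phase} phase ({mode} betweenness)")
    fig.supxlabel("postpartum day")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_run_plots(dataset, out: Path, config) -> None:
    plots = Path(out) / "plots"
    plots.mkdir(exist_ok=True)
    groups = [g for g in GROUPS if dataset.dam_ids(g)]
    ppds = dataset.ppds()
    for phase in PHASES:
        tables = {}
        for group in groups:
            frames = []
            for ppd in ppds:
                net = build_group_network(dataset, group, phase, ppd,
                                          l_policy=config.l_policy)
                slug = f"{group}_{phase}_ppd{ppd}"
                _plot_network(net, plots / f"network_{slug}.png")
                _plot_heatmap(net, plots / f"heatmap_{slug}.png")
                frames.append(centrality_table(net, mode=config.betweenness_mode))
            import pandas as pd

            tables[group] = pd.concat(frames, ignore_index=True)
        _plot_centrality_curves(
            tables, phase, config.betweenness_mode, plots / f"centrality_{phase}.png"
        )
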