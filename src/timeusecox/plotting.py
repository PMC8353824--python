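"""Figures for the reallocation analyses (matplotlib, headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .reallocation import ReallocationCurve, TernaryGrid

__all__ = [
    "plot_curves",
    "plot_comparison",
    "plot_scenarios",
    "plot_ternary",
]


def plot_curves(curves, ref_values: dict | None = None, path=None):
    """Multi-panel dose-response curves with pointwise 95% CI bands."""
    n = len(curves)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.4), squeeze=False)
    for ax, curve in zip(axes[0], curves):
        df = curve.frame()
        ax.plot(df["minutes"], df["hr"], color="C0")
        ax.fill_between(df["minutes"], df["lo"], df["hi"], color="C0", alpha=0.25)
        ax.axhline(1.0, ls=":", color="grey")
        if ref_values and curve.scenario in ref_values:
            ax.axvline(ref_values[curve.scenario], ls="--", color="grey", lw=0.8)
        ax.set_xlabel(f"{curve.scenario} (min/day)")
        ax.set_ylabel("HR vs referent")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_comparison(table, path=None):
    """Dot plot of standard vs compositional HRs per destination behavior."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    offsets = {"compositional": -0.12, "standard": 0.12}
    parts = list(dict.fromkeys(table["to_part"]))
    for model, grp in table.groupby("model"):
        y = [parts.index(p) + offsets[model] for p in grp["to_part"]]
        ax.errorbar(
            grp["hr"],
            y,
            xerr=[grp["hr"] - grp["lo"], grp["hi"] - grp["hr"]],
            fmt="o",
            capsize=3,
            label=model,
        )
    ax.axvline(1.0, ls=":", color="grey")
    ax.set_yticks(range(len(parts)), parts)
    ax.set_xlabel("HR for 30 min/day out of SB")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_scenarios(frame, path=None):
    """Bar-with-error chart of the predefined scenario HRs."""
    fig, ax = plt.subplots(figsize=(6, 3.4))
    x = np.arange(len(frame))
    ax.bar(x, frame["hr"], color="C0", alpha=0.8)
    ax.errorbar(
        x,
        frame["hr"],
        yerr=[frame["hr"] - frame["lo"], frame["hi"] - frame["hr"]],
        fmt="none",
        ecolor="k",
        capsize=3,
    )
    ax.axhline(1.0, ls=":", color="grey")
    ax.set_xticks(x, [s.split(":")[0] for s in frame["scenario"]])
    ax.set_ylabel("HR vs referent")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def _barycentric_xy(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project 3-part shares to 2-D ternary coordinates."""
    shares = nodes / nodes.sum(axis=1, keepdims=True)
    x = shares[:, 1] + 0.5 * shares[:, 2]
    y = np.sqrt(3) / 2 * shares[:, 2]
    return x, y


def plot_ternary(grid: TernaryGrid, path=None):
    """Ternary heatmap of HRs over the three free behaviors."""
    fig, ax = plt.subplots(figsize=(4.6, 4.2))
    x, y = _barycentric_xy(grid.nodes)
    hrs = np.array([e.hr for e in grid.estimates])
    sc = ax.scatter(x, y, c=np.log2(hrs), cmap="RdBu_r", s=14, marker="h")
    fig.colorbar(sc, ax=ax, label="log2 HR vs referent")
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=0.8)
    labels = grid.free_parts
    ax.text(-0.03, -0.05, labels[0], ha="right")
    ax.text(1.03, -0.05, labels[1], ha="left")
    ax.text(0.5, np.sqrt(3) / 2 + 0.04, labels[2], ha="center")
    ax.set_title(f"{grid.fixed_part} fixed at {100 * grid.fixed_proportion:.1f}%")
    ax.set_axis_off()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
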