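"""Minimal figure regeneration from the analysis CSV outputs.

Each function takes the DataFrame written by the corresponding analysis
and renders a plain matplotlib figure — ribbons for posterior bands,
one panel per metric. Styling is intentionally spartan; the CSVs are the
primary interface.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_series(df: pd.DataFrame, path: str | Path, logy: bool = False) -> None:
    """Panel per metric: mean line with the lo/hi ribbon over years."""
    plt = _pyplot()
    metrics = list(dict.fromkeys(df["metric"]))
    fig, axes = plt.subplots(len(metrics), 1, figsize=(7, 2.4 * len(metrics)),
                             sharex=True, squeeze=False)
    for ax, metric in zip(axes[:, 0], metrics):
        sub = df[df["metric"] == metric]
        ax.fill_between(sub["year"], sub["lo"], sub["hi"], alpha=0.3,
                        color="grey")
        ax.plot(sub["year"], sub["mean"], color="black")
        ax.set_ylabel(metric)
        if logy and (sub["mean"] > 0).all():
            ax.set_yscale("log")
    axes[-1, 0].set_xlabel("year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ablation(df: pd.DataFrame, path: str | Path) -> None:
    """Relative-difference ribbons per ablated dispersal mode."""
    plt = _pyplot()
    metrics = list(dict.fromkeys(df["metric"]))
    fig, axes = plt.subplots(len(metrics), 1, figsize=(7, 2.8 * len(metrics)),
                             sharex=True, squeeze=False)
    colors = {"no_LD": "tab:red", "no_SD": "tab:blue"}
    for ax, metric in zip(axes[:, 0], metrics):
        for mode, sub in df[df["metric"] == metric].groupby("mode"):
            c = colors.get(mode, "grey")
            ax.fill_between(sub["year"], sub["lo"], sub["hi"], alpha=0.25,
                            color=c)
            ax.plot(sub["year"], sub["mean"], color=c, label=mode)
        ax.axhline(0.0, lw=0.5, color="black")
        ax.set_ylabel(f"relative diff. ({metric})")
        ax.legend(frameon=False)
    axes[-1, 0].set_xlabel("year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fecundity_curve(df: pd.DataFrame, path: str | Path) -> None:
    """Posterior scaled fecundity f(k)/M per age with its 95% band."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(df["age"], df["lo"], df["hi"], alpha=0.3, color="grey")
    ax.plot(df["age"], df["mean"], color="black")
    ax.set_xlabel("plant age (years)")
    ax.set_ylabel("fecundity / M")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
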