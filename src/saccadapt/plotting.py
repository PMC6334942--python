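"""Figures for the adaptation analysis (time-courses, latencies, process gains)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .preprocessing import smooth_by_block  # noqa: E402

CONDITION_COLORS = {"down": "tab:green", "up": "tab:red", "none": "0.4"}


def plot_timecourse(trials, value_col: str = "gain", window: int = 6, ax=None):
    """Cohort-average smoothed gain time-course per saccade type and order."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    sm = smooth_by_block(trials, value_col, window=window)
    for (styp, order), grp in sm.groupby(["saccade_type", "direction_order"]):
        mean = grp.groupby("trial")[f"{value_col}_smooth"].mean()
        ax.plot(mean.index, mean.values, label=f"{styp} {order}", lw=1.2)
    for edge in np.cumsum([48, 96, 96])[:3]:
        ax.axvline(edge + 0.5, color="0.8", lw=0.8, zorder=0)
    ax.axhline(1.0, color="0.8", lw=0.8, zorder=0)
    ax.set(xlabel="trial", ylabel=value_col, title="Adaptation time-course")
    ax.legend(fontsize=8)
    return ax


def plot_latencies(latency_table, ax=None):
    """Condition means of saccade latency with 95% CIs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(latency_table))
    ax.bar(
        x,
        latency_table["mean"],
        yerr=latency_table["ci_halfwidth"],
        color=[CONDITION_COLORS.get(g, "0.5") for g in latency_table["gain_direction"]],
    )
    labels = [
        f"{r.saccade_type}\n{r.gain_direction}" for r in latency_table.itertuples()
    ]
    ax.set_xticks(x, labels, fontsize=8)
    ax.set(ylabel="latency (ms)", title="Saccade latencies (block 2)")
    return ax


def plot_process_gains(fits, ax=None):
    """Per-participant fast/slow process gains by condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = [
        (s, d) for s in ("reactive", "scanning") for d in ("down", "up")
    ]
    for j, proc in enumerate(("gamma_fast", "gamma_slow")):
        for i, (styp, gdir) in enumerate(order):
            vals = fits[(fits["saccade_type"] == styp) & (fits["gain_direction"] == gdir)][proc]
            x = i + j * (len(order) + 1)
            ax.scatter(np.full(len(vals), x), vals, s=10, alpha=0.6)
            ax.scatter([x], [vals.mean()], marker="_", s=300, color="k")
    ticks = [f"{s[:4]}/{d}" for s, d in order]
    ax.set_xticks(
        list(range(len(order))) + [len(order) + 1 + i for i in range(len(order))],
        ticks * 2,
        fontsize=7,
        rotation=45,
    )
    ax.set(ylabel="process gain", title="fast (left) and slow (right) process gains")
    return ax


def plot_awareness(aware_series, ax=None):
    """Running-average 'seen' proportion across the session per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for label, series in aware_series.items():
        ax.plot(np.arange(1, len(series) + 1), series, label=label, lw=1.0)
    ax.set(xlabel="trial", ylabel="p(seen)", ylim=(0, 1), title="Displacement awareness")
    ax.legend(fontsize=7)
    return ax


def report_figures(trials, fits, aware, out_dir) -> list:
    """Render and save the report's figures; returns the file paths."""
    from .stats_reporting import latency_summary

    paths = []
    specs = [
        ("timecourse", lambda ax: plot_timecourse(trials, ax=ax)),
        ("latencies", lambda ax: plot_latencies(latency_summary(trials), ax=ax)),
        ("process_gains", lambda ax: plot_process_gains(fits, ax=ax)),
        ("awareness", lambda ax: plot_awareness(aware["series"], ax=ax)),
    ]
    for name, draw in specs:
        fig, ax = plt.subplots(figsize=(8, 4))
        draw(ax)
        path = f"{out_dir}/{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
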