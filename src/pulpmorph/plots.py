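"""Plotting: parameter histograms with Gaussian overlays, scattergrams,
and the comparative regression-line figure.

All functions draw on a supplied or fresh matplotlib Axes and return it;
``write_report_plots`` renders the standard figure set of a study report.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .regression import RegressionFit, evaluate_line
from .stats import DescriptiveStats, Histogram, gaussian_overlay

__all__ = ["plot_histogram", "plot_scattergram", "plot_regression_lines", "write_report_plots"]

_PARAM_LABEL = {
    "area": "A (um$^2$)",
    "perimeter": "P (um)",
    "form_factor": "FF",
}


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_histogram(hist: Histogram, stats: DescriptiveStats | None = None, ax=None, title: str = ""):
    """Bar histogram of one parameter with its matched-Gaussian overlay."""
    ax = _get_ax(ax)
    ax.bar(hist.centers, hist.counts, width=hist.class_width * 0.95, color="#9db8d9", edgecolor="#3a5a88")
    if stats is not None:
        curve = gaussian_overlay(stats, hist)
        if curve is not None:
            ax.plot(hist.centers, curve, color="#b03030", lw=1.5)
    ax.set_xlabel(_PARAM_LABEL.get(hist.parameter, hist.parameter))
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    return ax


def plot_scattergram(
    areas, perimeters, fit: RegressionFit | None = None, ax=None,
    xlim=None, ylim=None, title: str = "",
):
    """P-versus-A scatter with the fitted regression line.

    Pass common ``xlim``/``ylim`` across groups to make the group
    scattergrams directly comparable.
    """
    ax = _get_ax(ax)
    ax.plot(areas, perimeters, ".", ms=3, alpha=0.5, color="#3a5a88")
    if fit is not None:
        xs = np.linspace(min(areas), max(areas), 2)
        ax.plot(xs, [evaluate_line(fit, x) for x in xs], color="#b03030", lw=1.5,
                label=f"P = {fit.slope:.4f} A + {fit.intercept:.4f} (r = {fit.correlation:.4f})")
        ax.legend(fontsize=8)
    if xlim:
        ax.set_xlim(*xlim)
    if ylim:
        ax.set_ylim(*ylim)
    ax.set_xlabel(_PARAM_LABEL["area"])
    ax.set_ylabel(_PARAM_LABEL["perimeter"])
    if title:
        ax.set_title(title)
    return ax


def plot_regression_lines(fits: dict[str, RegressionFit], area_range=(0.0, 70.0), ax=None):
    """Comparative plot of the group regression lines on one axes."""
    ax = _get_ax(ax)
    styles = ["--", "-", "-."]
    xs = np.linspace(*area_range, 2)
    for (label, fit), ls in zip(fits.items(), styles):
        ax.plot(xs, [evaluate_line(fit, x) for x in xs], ls, label=f"group {label}")
    ax.set_xlabel(_PARAM_LABEL["area"])
    ax.set_ylabel(_PARAM_LABEL["perimeter"])
    ax.legend()
    return ax


def write_report_plots(report, out_dir: str | Path) -> Path:
    """Render the standard figures of a study report to PNG files."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gs = report.group_stats.set_index(["group", "parameter"])
    for (group, param), sub in report.histograms.groupby(["group", "parameter"], sort=False):
        edges = np.append(sub["edge_low"].to_numpy(), sub["edge_high"].iloc[-1])
        hist = Histogram(
            parameter=param,
            class_width=float(edges[1] - edges[0]),
            edges=edges,
            counts=sub["count"].to_numpy(),
            n=int(gs.loc[(group, param), "n"]),
            out_of_range=int(sub["out_of_range"].iloc[0]),
        )
        row = gs.loc[(group, param)]
        stats = DescriptiveStats(int(row["n"]), row["mean"], row["sd"], row["min"], row["max"])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        plot_histogram(hist, stats, ax=ax, title=f"group {group}")
        fig.tight_layout()
        fig.savefig(out / f"hist_{group}_{param}.png", dpi=110)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    plot_regression_lines(report.regressions, ax=ax)
    fig.tight_layout()
    fig.savefig(out / "regression_lines.png", dpi=110)
    plt.close(fig)
    return out
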