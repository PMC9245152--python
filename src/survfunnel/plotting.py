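"""Funnel-plot rendering.

Each center is a point at (effective sample size, O/E); the control-limit
curves narrow toward the target line O/E = 1 as precision grows. Colors
follow the multiplicity-adjusted classification. Geometry is consistent
with the table by construction: a center lies outside the curves exactly
when |Z| exceeds the corresponding normal quantile.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .engine import funnel_limits  # noqa: E402

__all__ = ["render_funnel"]

_COLORS = {"under": "#c0392b", "over": "#1e8449", "target": "#566573"}


def render_funnel(
    results: pd.DataFrame,
    out=None,
    ax=None,
    logx: bool = False,
    labels: str = "none",
    ylabel: str = "Excess mortality (O/E)",
    grid_size: int = 200,
):
    """Render a funnel plot from a center-results table.

    ``results`` is the output of :func:`survfunnel.center_summary` (or the
    follow-up analogue); its ``attrs`` carry p0 and the alpha levels.
    ``labels`` is one of ``none``, ``flagged`` (adjusted-level outliers
    only) or ``all``. Writes to ``out`` (PNG/SVG by extension) when given;
    returns the matplotlib Axes.
    """
    tested = results[results["tested"]]
    if tested.empty:
        raise ValueError("no testable centers to plot")
    p0 = results.attrs["p0"]
    alpha = results.attrs.get("alpha", 0.05)
    alpha_adj = results.attrs.get("alpha_adjusted")

    if ax is None:
        _, ax = plt.subplots(figsize=(7.5, 5))
    lo, hi = tested["ess"].min(), tested["ess"].max()
    grid = np.geomspace(max(lo * 0.8, 1e-6), hi * 1.1, grid_size)
    lim = funnel_limits(grid, p0, alpha, alpha_adj)
    ax.plot(grid, lim["upper"], "-", color="k", lw=1, label=f"{1-alpha:.0%} limits")
    ax.plot(grid, lim["lower"], "-", color="k", lw=1)
    if alpha_adj is not None:
        ax.plot(
            grid, lim["upper_adj"], "--", color="k", lw=1,
            label=f"adjusted ({alpha_adj:.2g})",
        )
        ax.plot(grid, lim["lower_adj"], "--", color="k", lw=1)
    ax.axhline(1.0, color="#888888", lw=0.8)

    colors = [_COLORS.get(c, "#566573") for c in tested["class_alpha_adj"]]
    ax.scatter(tested["ess"], tested["oe_ratio"], s=18, c=colors, zorder=3)
    if labels != "none":
        for _, row in tested.iterrows():
            if labels == "all" or row["class_alpha_adj"] != "target":
                ax.annotate(
                    str(row["center"]), (row["ess"], row["oe_ratio"]),
                    fontsize=7, xytext=(2, 2), textcoords="offset points",
                )
    if logx:
        ax.set_xscale("log")
    ax.set_ylim(bottom=min(0.0, float(tested["oe_ratio"].min()) - 0.1))
    ax.set_xlabel("Effective sample size")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
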