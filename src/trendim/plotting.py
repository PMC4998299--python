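"""Color-coded diagnostic plots.

Both views scatter the paired changes (dRM, dTM) with one fixed color per
classification category: uninterpretable blue, noninterchangeable red,
gray zone orange, interchangeable green.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .comparators import RADIAL_LOA_THRESHOLD_DEG, to_polar
from .core import CATEGORY_COLORS, Category

__all__ = ["plot_four_quadrant", "plot_polar"]

_LEGEND_ORDER = [
    Category.UNINTERPRETABLE,
    Category.NONINTERCHANGEABLE,
    Category.GRAY_ZONE,
    Category.INTERCHANGEABLE,
]


def _per_category(table: pd.DataFrame):
    for cat in _LEGEND_ORDER:
        sub = table[table["category"] == cat.value]
        yield cat, CATEGORY_COLORS[cat], sub


def plot_four_quadrant(classified: pd.DataFrame, ax=None, title: str | None = None):
    """Four-quadrant scatter of classified changes with the line of identity.

    ``classified`` is the table from :func:`trendim.core.classify_series`
    (columns delta_rm, delta_tm, category).  Returns the figure.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    if classified.empty:
        warnings.warn("no changes to plot", UserWarning, stacklevel=2)
    for cat, color, sub in _per_category(classified):
        if len(sub):
            ax.scatter(sub["delta_rm"], sub["delta_tm"], s=18, color=color,
                       label=cat.value, alpha=0.8)
    lim = 1.0
    if len(classified):
        lim = 1.1 * max(
            classified["delta_rm"].abs().max(), classified["delta_tm"].abs().max(), 1e-9
        )
    ax.plot([-lim, lim], [-lim, lim], color="0.4", lw=0.8, label="identity")
    ax.axhline(0, color="0.7", lw=0.6)
    ax.axvline(0, color="0.7", lw=0.6)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel(r"$\Delta$RM (units)")
    ax.set_ylabel(r"$\Delta$TM (units)")
    ax.set_aspect("equal")
    ax.legend(fontsize=7, loc="upper left")
    if title:
        ax.set_title(title)
    return fig


def plot_polar(
    classified: pd.DataFrame,
    exclusion_radius: float = 0.0,
    ax=None,
    title: str | None = None,
):
    """Polar scatter of classified changes with +/-30 degree reference rays.

    Zero-magnitude changes and changes inside the exclusion radius are
    dropped with a warning.  Returns the figure.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"projection": "polar"})
    else:
        fig = ax.figure
    n_dropped = 0
    plotted = 0
    for cat, color, sub in _per_category(classified):
        thetas, radii = [], []
        for _, row in sub.iterrows():
            if row["delta_rm"] == 0 and row["delta_tm"] == 0:
                n_dropped += 1
                continue
            p = to_polar((row["delta_rm"], row["delta_tm"]))
            if p.radius < exclusion_radius:
                n_dropped += 1
                continue
            thetas.append(np.deg2rad(p.angle))
            radii.append(p.radius)
        if thetas:
            ax.scatter(thetas, radii, s=18, color=color, label=cat.value, alpha=0.8)
            plotted += len(thetas)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} change(s) excluded from the polar plot "
            "(zero vector or inside the exclusion radius)",
            UserWarning,
            stacklevel=2,
        )
    if plotted == 0:
        warnings.warn("no changes to plot", UserWarning, stacklevel=2)
    rmax = ax.get_rmax() if plotted else 1.0
    for sign in (+1, -1):
        ax.plot(
            [0, np.deg2rad(sign * RADIAL_LOA_THRESHOLD_DEG)], [0, rmax],
            color="0.4", lw=0.8, ls="--",
        )
    ax.set_thetamin(-90)
    ax.set_thetamax(90)
    ax.set_theta_zero_location("E")
    ax.legend(fontsize=7, loc="lower left", bbox_to_anchor=(0.0, -0.15))
    if title:
        ax.set_title(title)
    return fig
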