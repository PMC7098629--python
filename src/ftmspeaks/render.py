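"""Static rendering of :class:`~ftmspeaks.plotdata.PlotData` to PNG/SVG.

Rendering is deterministic: rows are drawn in table order, no randomness is
used, and SVG output is stripped of timestamps and salted hash ids so the
same PlotData always produces byte-identical files.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "ftmspeaks"

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classes import ClassBoundarySet
from .plotdata import PlotData

__all__ = ["render"]

_SCATTER_KINDS = {"van_krevelen", "kendrick", "scatter"}


def _draw_scatter(ax, pd_obj: PlotData) -> None:
    df = pd_obj.data
    include = pd_obj.include if pd_obj.include is not None else pd.Series(True, index=df.index)
    shown = df[include.to_numpy()]
    hidden = df[~include.to_numpy()]
    if len(hidden):
        ax.scatter(hidden[pd_obj.x], hidden[pd_obj.y], s=6, c="0.85", label="_deselected")
    color = pd_obj.color_by
    if color is None or color not in shown.columns:
        ax.scatter(shown[pd_obj.x], shown[pd_obj.y], s=8)
    elif pd.api.types.is_numeric_dtype(shown[color]):
        sc = ax.scatter(shown[pd_obj.x], shown[pd_obj.y], s=8, c=shown[color],
                        cmap="viridis")
        plt.colorbar(sc, ax=ax, label=color)
    else:
        for i, (lab, grp) in enumerate(shown.groupby(color, sort=True)):
            ax.scatter(grp[pd_obj.x], grp[pd_obj.y], s=8, label=str(lab))
        ax.legend(fontsize=7)


def _draw_boundaries(ax, boundary_set: ClassBoundarySet) -> None:
    for rule in boundary_set.rules:
        ax.add_patch(
            plt.Rectangle(
                (rule.oc_min, rule.hc_min),
                rule.oc_max - rule.oc_min,
                rule.hc_max - rule.hc_min,
                fill=False, edgecolor="0.4", linewidth=0.7,
            )
        )
        ax.annotate(rule.label, (rule.oc_min, rule.hc_max), fontsize=6,
                    va="top", color="0.3")


def render(plot_data: PlotData, path: str, options: dict | None = None) -> str:
    """Write ``plot_data`` to ``path`` (format from the extension).

    Options: ``title``, ``figsize``, ``boundary_set`` (a
    :class:`ClassBoundarySet` overlaid on van Krevelen plots).
    """
    opts = options or {}
    if plot_data.data.empty:
        raise ValueError("refusing to render empty plot data")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"output directory does not exist: {parent}")

    fig, ax = plt.subplots(figsize=opts.get("figsize", (5, 4)))
    try:
        if plot_data.kind in _SCATTER_KINDS:
            _draw_scatter(ax, plot_data)
            if plot_data.kind == "van_krevelen" and opts.get("boundary_set") is not None:
                _draw_boundaries(ax, opts["boundary_set"])
        elif plot_data.kind == "density":
            for lab, grp in plot_data.data.groupby("curve", sort=True):
                level = grp["level"].iloc[0]
                ax.plot(grp["x"], grp["density"], label=str(lab),
                        linewidth=2.0 if level == "group" else 1.0)
            ax.legend(fontsize=7)
        elif plot_data.kind == "summary_bar":
            df = plot_data.data
            ax.bar(range(len(df)), df["n_observed"])
            ax.set_xticks(range(len(df)), df["sample"], rotation=90, fontsize=6)
        elif plot_data.kind == "summary_box":
            df = plot_data.data
            stats_list = [
                {
                    "med": r["median"], "q1": r["q1"], "q3": r["q3"],
                    "whislo": r["whisker_low"], "whishi": r["whisker_high"],
                    "label": str(r["sample"]), "fliers": [],
                }
                for _, r in df.iterrows()
            ]
            ax.bxp(stats_list, showfliers=False)
            ax.tick_params(axis="x", rotation=90, labelsize=6)
        ax.set_xlabel(plot_data.axis_labels.get("x", plot_data.x))
        ax.set_ylabel(plot_data.axis_labels.get("y", plot_data.y))
        if opts.get("title"):
            ax.set_title(opts["title"])
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if path.endswith(".svg") else None)
    finally:
        plt.close(fig)
    return path
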