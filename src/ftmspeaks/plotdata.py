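"""Tidy plot-data tables behind every figure type, plus cognostics.

Every figure the package can draw is backed by a :class:`PlotData` object —
a plain table of points or curves plus axis/color metadata — built by a pure
function of its dataset (double invocation returns identical tables).  The
separation lets users re-plot with their own tooling, and makes figures
testable without rendering.

Cognostics are per-subset summary statistics (peak counts, composition-class
proportions, means of selected properties) used to sort and filter a grid of
small-multiple plots; :func:`cognostics` recomputes them directly from the
subset so they are always consistent with the data shown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calc import elemental_composition_class, _counts_from_row
from .compare import GroupComparison, GroupSummary
from .dataset import PeakDataset

__all__ = [
    "PlotData",
    "CognosticsRow",
    "van_krevelen_data",
    "kendrick_data",
    "density_data",
    "scatter_data",
    "summary_plot",
    "cognostics",
]

PLOT_KINDS = ("van_krevelen", "kendrick", "density", "scatter", "summary_bar", "summary_box")


@dataclass
class PlotData:
    """A figure's backing table plus the metadata needed to draw it."""

    kind: str
    data: pd.DataFrame
    x: str
    y: str
    color_by: str | None = None
    group_labels: tuple[str, ...] = ()
    axis_labels: dict = field(default_factory=dict)
    #: optional boolean mask over rows: False rows are drawn deselected/hidden
    include: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")


@dataclass
class CognosticsRow:
    """Summary metrics for one data subset (a sample or a group)."""

    label: str
    metrics: dict

    def as_dict(self) -> dict:
        return {"label": self.label, **self.metrics}


# ------------------------------------------------------------ scatter plots

def _eligible_points(dataset: PeakDataset, xcol: str, ycol: str) -> pd.DataFrame:
    for c in (xcol, ycol):
        if c not in dataset.annotation.columns:
            raise ValueError(
                f"annotation column {c!r} not computed; run compound_calcs first"
            )
    ann = dataset.annotation
    mask = dataset.formula_assigned & ann[xcol].notna() & ann[ycol].notna()
    out = pd.DataFrame(
        {"peak_id": dataset.peak_ids[mask], xcol: ann.loc[mask, xcol].to_numpy(),
         ycol: ann.loc[mask, ycol].to_numpy()}
    )
    return out.reset_index(drop=True)


def _attach_color(df: pd.DataFrame, dataset: PeakDataset, color_by: str | None) -> None:
    if color_by is None:
        return
    if color_by not in dataset.annotation.columns:
        raise ValueError(f"color variable {color_by!r} not in annotation")
    df[color_by] = dataset.annotation.loc[df["peak_id"], color_by].to_numpy()


def _scatter_from_source(source, xcol: str, ycol: str, color_by: str | None,
                         kind: str, axis_labels: dict) -> PlotData:
    """Shared builder for van Krevelen / Kendrick scatter over the three
    accepted sources: a dataset, a group summary, or a group comparison."""
    if isinstance(source, PeakDataset):
        df = _eligible_points(source, xcol, ycol)
        _attach_color(df, source, color_by)
        return PlotData(kind=kind, data=df, x=xcol, y=ycol, color_by=color_by,
                        axis_labels=axis_labels)
    if isinstance(source, GroupSummary):
        ds = source.dataset
        if ds is None:
            raise ValueError("group summary lost its dataset reference")
        fn = color_by or "n_present"
        if fn not in source.functions:
            raise ValueError(f"summary function {fn!r} not in group summary")
        df = _eligible_points(ds, xcol, ycol)
        for g in source.group_sizes:
            df[f"{g}:{fn}"] = source.column(g, fn).loc[df["peak_id"]].to_numpy()
        return PlotData(kind=kind, data=df, x=xcol, y=ycol, color_by=fn,
                        group_labels=tuple(source.group_sizes),
                        axis_labels=axis_labels)
    if isinstance(source, GroupComparison):
        ds = source.dataset
        if ds is None:
            raise ValueError("group comparison lost its dataset reference")
        df = _eligible_points(ds, xcol, ycol)
        df["verdict"] = source.table.loc[df["peak_id"], "verdict"].to_numpy()
        include = ~df["verdict"].isin(["observed_in_both", "observed_in_neither"])
        return PlotData(kind=kind, data=df, x=xcol, y=ycol, color_by="verdict",
                        group_labels=(source.group1, source.group2),
                        include=include, axis_labels=axis_labels)
    raise TypeError(f"unsupported source type {type(source).__name__}")


def van_krevelen_data(source, color_by: str | None = None) -> PlotData:
    """H:C vs O:C scatter: one point per formula-assigned, non-isotope peak.

    ``source`` may be a dataset (color by any annotation column), a
    :class:`GroupSummary` (color by per-group presence counts) or a
    :class:`GroupComparison` (color by uniqueness verdict, with the
    both/neither verdicts marked deselected).
    """
    return _scatter_from_source(
        source, "oc", "hc", color_by, "van_krevelen",
        {"x": "O:C ratio", "y": "H:C ratio"},
    )


def kendrick_data(source, color_by: str | None = None) -> PlotData:
    """Kendrick defect vs Kendrick mass scatter for eligible peaks."""
    return _scatter_from_source(
        source, "kendrick_mass", "kendrick_defect", color_by, "kendrick",
        {"x": "Kendrick mass", "y": "Kendrick mass defect"},
    )


def scatter_data(dataset: PeakDataset, xvar: str, yvar: str,
                 color_by: str | None = None) -> PlotData:
    """Generic scatter of two computed per-peak variables (pairwise dropna)."""
    df = _eligible_points(dataset, xvar, yvar)
    _attach_color(df, dataset, color_by)
    return PlotData(kind="scatter", data=df, x=xvar, y=yvar, color_by=color_by,
                    axis_labels={"x": xvar, "y": yvar})


# ------------------------------------------------------------ density plots

def _kde_curve(values: np.ndarray, bandwidth: float | str = "silverman",
               gridsize: int = 256) -> pd.DataFrame:
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    h = kde.factor * values.std(ddof=1) if values.std(ddof=1) > 0 else 1.0
    lo, hi = values.min() - 4 * h, values.max() + 4 * h
    grid = np.linspace(lo, hi, gridsize)
    return pd.DataFrame({"x": grid, "density": kde(grid)})


def density_data(
    dataset: PeakDataset,
    variable: str,
    samples: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    include_group_curve: bool = False,
    bandwidth: float | str = "silverman",
    histogram_bins: int = 30,
) -> PlotData:
    """Kernel density curves (and histogram bins) of a chemical property.

    For each selected sample the curve is estimated over the variable's
    non-missing values among peaks observed in that sample (Gaussian kernel,
    normal-reference bandwidth by default).  With ``include_group_curve`` a
    pooled curve over each selected group's member samples is overlaid.
    Curves are density-normalized, as are the histogram bins in
    ``meta["histogram"]``.
    """
    if variable not in dataset.annotation.columns:
        raise ValueError(f"variable {variable!r} not computed")
    values = pd.to_numeric(dataset.annotation[variable], errors="coerce")
    if values.notna().sum() == 0:
        raise TypeError(f"variable {variable!r} has no numeric values")

    if groups is not None and dataset.group_map is None:
        raise ValueError("groups requested but none designated")
    sel_samples: list[str]
    if samples is not None:
        sel_samples = list(samples)
    elif groups is not None:
        sel_samples = [s for s in dataset.sample_ids
                       if dataset.group_map[s] in set(groups)]
    else:
        sel_samples = list(dataset.sample_ids)

    curves = []
    hists = []
    presence = dataset.presence

    def add_curve(label: str, level: str, vals: np.ndarray) -> None:
        if len(vals) < 2:
            return
        c = _kde_curve(vals, bandwidth)
        c.insert(0, "curve", label)
        c.insert(1, "level", level)
        curves.append(c)
        dens, edges = np.histogram(vals, bins=histogram_bins, density=True)
        hists.append(pd.DataFrame({
            "curve": label, "bin_left": edges[:-1], "bin_right": edges[1:],
            "density": dens,
        }))

    for s in sel_samples:
        vals = values[presence[s] & values.notna()].to_numpy(dtype=float)
        add_curve(s, "sample", vals)
    if include_group_curve:
        if dataset.group_map is None:
            raise ValueError("group curve requested but no groups designated")
        gsel = set(groups) if groups is not None else set(dataset.groups)
        for g, members in dataset.groups.items():
            if g not in gsel:
                continue
            pooled = np.concatenate([
                values[presence[s] & values.notna()].to_numpy(dtype=float)
                for s in members if s in sel_samples or samples is None
            ]) if members else np.array([])
            add_curve(g, "group", pooled)

    if not curves:
        raise ValueError("no curve has at least two observations")
    return PlotData(
        kind="density",
        data=pd.concat(curves, ignore_index=True),
        x="x",
        y="density",
        color_by="curve",
        axis_labels={"x": variable, "y": "density"},
        meta={"variable": variable, "histogram": pd.concat(hists, ignore_index=True)},
    )


# ------------------------------------------------------- dataset summaries

def summary_plot(dataset: PeakDataset) -> PlotData:
    """Dataset-level summary figure data (bars on the presence scale,
    boxplot statistics otherwise); see ``PeakDataset.summary_plot_data``."""
    df = dataset.summary_plot_data()
    kind = "summary_bar" if dataset.scale == "presence_absence" else "summary_box"
    y = "n_observed" if kind == "summary_bar" else "median"
    return PlotData(kind=kind, data=df, x="sample", y=y, color_by="group",
                    axis_labels={"x": "sample"})


# ----------------------------------------------------------------- cognostics

#: Properties averaged per display kind (when present in the annotation).
_KIND_MEANS = {
    "van_krevelen": ("oc", "hc", "nosc", "ai_mod"),
    "kendrick": ("kendrick_mass", "kendrick_defect"),
    "density": ("nosc", "ai_mod", "kendrick_defect"),
}


def cognostics(dataset: PeakDataset, display_kind: str = "van_krevelen",
               label: str | None = None) -> CognosticsRow:
    """Summary metrics of one dataset subset, recomputed from its tables.

    Always includes the peak and formula-assigned counts and the proportion
    of each elemental-composition class among assigned peaks; adds means of
    the display-kind-relevant properties that have been computed.
    """
    if display_kind not in _KIND_MEANS:
        raise ValueError(f"unknown display kind {display_kind!r}")
    if dataset.n_peaks == 0:
        raise ValueError("empty subset")
    metrics: dict = {
        "n_peaks": dataset.n_peaks,
        "n_formula_assigned": int(dataset.formula_assigned.sum()),
    }
    eligible = dataset.formula_assigned
    if eligible.any():
        ann = dataset.annotation
        comps = [
            elemental_composition_class(_counts_from_row(ann.loc[pid]))
            for pid in ann.index[eligible]
        ]
        counts = pd.Series(comps).value_counts()
        for comp, n in sorted(counts.items()):
            metrics[f"prop_{comp}"] = n / len(comps)
    for col in _KIND_MEANS[display_kind]:
        if col in dataset.annotation.columns:
            vals = pd.to_numeric(dataset.annotation[col], errors="coerce").dropna()
            metrics[f"mean_{col}"] = float(vals.mean()) if len(vals) else math.nan
    return CognosticsRow(label=label or "all", metrics=metrics)
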