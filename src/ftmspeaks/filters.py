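"""Declarative peak and sample filters with preview-before-apply.

A filter is built once as an immutable :class:`FilterSpec`, previewed against
a dataset (:func:`preview_filter` returns counts and plot-ready preview data
without touching the dataset), and applied with :func:`apply_filter`, which
removes rows consistently from the intensity matrix and the annotation table
and appends the spec and its report to the provenance log.

Supported kinds
---------------
mass
    keep peaks whose observed mass lies in ``[min_mass, max_mass]`` (closed).
molecule
    keep peaks observed (positive, non-missing intensity) in at least
    ``min_num`` samples.
formula
    keep peaks with an assigned molecular formula (isotope-flagged peaks are
    not counted as assigned).
emeta
    keep peaks whose value in an annotation column is in a category list or a
    closed numeric range; rows missing in that column are removed.
sample_subset
    keep the listed samples (or groups, once groups are designated) instead
    of filtering peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PeakDataset

__all__ = ["FilterSpec", "FilterReport", "make_filter", "preview_filter", "apply_filter"]

KINDS = ("mass", "molecule", "formula", "emeta", "sample_subset")

#: Default width (Da) of the mass-preview histogram bins; cosmetic only.
DEFAULT_MASS_BIN_WIDTH = 50.0


@dataclass(frozen=True)
class FilterSpec:
    """An immutable, validated filter; build via :func:`make_filter`."""

    kind: str
    params: tuple[tuple[str, Any], ...]

    def __getitem__(self, key: str) -> Any:
        return dict(self.params)[key]

    def get(self, key: str, default: Any = None) -> Any:
        return dict(self.params).get(key, default)

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v!r}" for k, v in self.params)
        return f"{self.kind}({inner})"


@dataclass
class FilterReport:
    """Counts (and kind-specific preview data) for a filter on a dataset."""

    spec: FilterSpec
    n_peaks_before: int
    n_peaks_after: int
    n_removed: int
    preview: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "filter": self.spec.describe(),
            "n_peaks_before": self.n_peaks_before,
            "n_peaks_after": self.n_peaks_after,
            "n_removed": self.n_removed,
            **{k: v for k, v in self.preview.items() if not isinstance(v, pd.DataFrame)},
        }


def _freeze(value: Any) -> Any:
    if isinstance(value, (list, tuple, set)):
        return tuple(value)
    return value


def make_filter(kind: str, **parameters: Any) -> FilterSpec:
    """Validate parameters for ``kind`` and return an immutable spec."""
    if kind not in KINDS:
        raise ValueError(f"unknown filter kind {kind!r}; choose from {KINDS}")
    p = dict(parameters)
    if kind == "mass":
        lo, hi = p.get("min_mass"), p.get("max_mass")
        if lo is None or hi is None:
            raise ValueError("mass filter needs min_mass and max_mass")
        if not lo < hi:
            raise ValueError(f"min_mass must be < max_mass (got {lo}, {hi})")
    elif kind == "molecule":
        k = p.get("min_num")
        if k is None or int(k) != k or k < 1:
            raise ValueError(f"molecule filter needs integer min_num >= 1 (got {k})")
    elif kind == "formula":
        extra = set(p)
        if extra:
            raise ValueError(f"formula filter takes no parameters (got {sorted(extra)})")
    elif kind == "emeta":
        if "column" not in p:
            raise ValueError("emeta filter needs a column")
        has_cat = "categories" in p
        has_range = "min" in p or "max" in p
        if has_cat == has_range:
            raise ValueError("emeta filter needs categories OR a numeric min/max range")
        if has_range:
            lo, hi = p.get("min"), p.get("max")
            if lo is None or hi is None:
                raise ValueError("emeta numeric filter needs both min and max")
            if not lo <= hi:
                raise ValueError(f"emeta range inverted ({lo} > {hi})")
    elif kind == "sample_subset":
        if ("samples" in p) == ("groups" in p):
            raise ValueError("sample_subset needs samples OR groups")
    return FilterSpec(kind=kind, params=tuple(sorted((k, _freeze(v)) for k, v in p.items())))


# --------------------------------------------------------------- evaluation

def _retained_peaks(spec: FilterSpec, ds: PeakDataset) -> pd.Series:
    """Boolean keep-mask over peaks (all True for sample_subset)."""
    if spec.kind == "mass":
        m = ds.masses
        return (m >= spec["min_mass"]) & (m <= spec["max_mass"]) & m.notna()
    if spec.kind == "molecule":
        return ds.presence.sum(axis=1) >= spec["min_num"]
    if spec.kind == "formula":
        return ds.formula_assigned
    if spec.kind == "emeta":
        col = spec["column"]
        if col not in ds.annotation.columns:
            raise KeyError(f"annotation column {col!r} not found")
        values = ds.annotation[col]
        if "categories" in dict(spec.params):
            cats = set(spec["categories"])
            return values.notna() & values.isin(cats)
        numeric = pd.to_numeric(values, errors="coerce")
        if values.notna().any() and numeric.notna().sum() == 0:
            raise TypeError(f"numeric range filter on non-numeric column {col!r}")
        return numeric.notna() & (numeric >= spec["min"]) & (numeric <= spec["max"])
    # sample_subset keeps every peak
    return pd.Series(True, index=ds.peak_ids)


def _retained_samples(spec: FilterSpec, ds: PeakDataset) -> list[str]:
    if spec.get("samples") is not None:
        wanted = list(spec["samples"])
        unknown = [s for s in wanted if s not in set(ds.sample_ids)]
        if unknown:
            raise KeyError(f"unknown samples {unknown}")
        return [s for s in ds.sample_ids if s in set(wanted)]
    if ds.group_map is None:
        raise ValueError("sample_subset by group requires groups to be designated first")
    wanted_groups = set(spec["groups"])
    unknown = wanted_groups - set(ds.groups)
    if unknown:
        raise KeyError(f"unknown groups {sorted(unknown)}")
    return [s for s in ds.sample_ids if ds.group_map[s] in wanted_groups]


def preview_filter(spec: FilterSpec, dataset: PeakDataset) -> FilterReport:
    """Counts retained/removed plus kind-specific preview data; no mutation.

    The mass preview carries a histogram of peak counts per mass window with
    retained/removed split per peak; the molecule preview carries, for every
    k in 1..n_samples, the number of peaks observed in at least k samples.
    """
    n_before = dataset.n_peaks
    preview: dict = {}
    if spec.kind == "sample_subset":
        kept_samples = _retained_samples(spec, dataset)
        preview["n_samples_before"] = dataset.n_samples
        preview["n_samples_after"] = len(kept_samples)
        preview["samples_kept"] = kept_samples
        n_after = n_before
    else:
        mask = _retained_peaks(spec, dataset)
        n_after = int(mask.sum())
        if spec.kind == "mass":
            m = dataset.masses.dropna()
            if len(m):
                width = DEFAULT_MASS_BIN_WIDTH
                lo = np.floor(m.min() / width) * width
                hi = np.ceil(m.max() / width) * width
                edges = np.arange(lo, hi + width, width)
                kept = m[mask.reindex(m.index)]
                removed = m[~mask.reindex(m.index)]
                kept_counts, _ = np.histogram(kept, bins=edges)
                removed_counts, _ = np.histogram(removed, bins=edges)
                preview["histogram"] = pd.DataFrame(
                    {
                        "bin_left": edges[:-1],
                        "bin_right": edges[1:],
                        "n_retained": kept_counts,
                        "n_removed": removed_counts,
                    }
                )
        elif spec.kind == "molecule":
            counts = dataset.presence.sum(axis=1)
            ks = np.arange(1, dataset.n_samples + 1)
            preview["min_num_curve"] = pd.DataFrame(
                {"min_num": ks, "n_retained": [(counts >= k).sum() for k in ks]}
            )
    return FilterReport(
        spec=spec,
        n_peaks_before=n_before,
        n_peaks_after=n_after,
        n_removed=n_before - n_after,
        preview=preview,
    )


def apply_filter(spec: FilterSpec, dataset: PeakDataset) -> PeakDataset:
    """Apply a filter, returning a new dataset; rejects emptying filters.

    Retained counts always equal the preview's.  ``sample_subset`` removes
    sample columns and metadata rows instead of peaks; intensities are never
    renormalized.
    """
    report = preview_filter(spec, dataset)
    if spec.kind == "sample_subset":
        kept = report.preview["samples_kept"]
        if not kept:
            raise ValueError(f"filter {spec.describe()} would remove every sample")
        new = dataset._replace(
            intensities=dataset.intensities[kept],
            sample_table=dataset.sample_table.loc[kept],
            group_map=None if dataset.group_map is None
            else {s: dataset.group_map[s] for s in kept},
            _raw=dataset._raw[kept],
        )
    else:
        if report.n_peaks_after == 0:
            raise ValueError(
                f"filter {spec.describe()} would remove all "
                f"{report.n_peaks_before} peaks"
            )
        mask = _retained_peaks(spec, dataset)
        new = dataset._replace(
            intensities=dataset.intensities.loc[mask],
            annotation=dataset.annotation.loc[mask],
            _raw=dataset._raw.loc[mask],
        )
    new.provenance.append(
        f"apply_filter:{spec.describe()} kept {report.n_peaks_after}/{report.n_peaks_before}"
    )
    return new
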