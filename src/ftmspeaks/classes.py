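"""Compound classification from van Krevelen (O:C, H:C) boundary sets.

A boundary set is an ordered list of rectangular windows in the O:C x H:C
plane, each labelled with a biochemical compound class (lipid, protein,
carbohydrate, lignin, tannin, ...).  Rule order defines precedence where
windows overlap; a point outside every window is classed "Other".  Three
reconstructed default sets (``bs1``/``bs2``/``bs3``) ship as an editable YAML
config; users can load their own file with the same schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .calc import CALC_COLUMNS, compound_calcs
from .dataset import PeakDataset

__all__ = [
    "BoundaryRule",
    "ClassBoundarySet",
    "load_boundary_sets",
    "get_boundary_set",
    "assign_compound_class",
    "assign_class",
]

OTHER_LABEL = "Other"


@dataclass(frozen=True)
class BoundaryRule:
    label: str
    oc_min: float
    oc_max: float
    hc_min: float
    hc_max: float
    #: optional extra predicates: annotation column -> (min, max), closed.
    extra: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.oc_min > self.oc_max or self.hc_min > self.hc_max:
            raise ValueError(f"rule {self.label!r}: min bound exceeds max bound")

    def contains(self, oc: float, hc: float,
                 extra_values: Mapping[str, float] | None = None) -> bool:
        if not (self.oc_min <= oc <= self.oc_max and self.hc_min <= hc <= self.hc_max):
            return False
        for col, lo, hi in self.extra:
            v = None if extra_values is None else extra_values.get(col)
            if v is None or pd.isna(v) or not lo <= v <= hi:
                return False
        return True


@dataclass(frozen=True)
class ClassBoundarySet:
    name: str
    rules: tuple[BoundaryRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"boundary set {self.name!r} has no rules")


def _rules_from_config(name: str, entries: Sequence[Mapping]) -> ClassBoundarySet:
    rules = []
    for e in entries:
        try:
            extra = tuple(
                (col, float(lo), float(hi)) for col, (lo, hi) in (e.get("extra") or {}).items()
            )
            rules.append(
                BoundaryRule(
                    label=str(e["label"]),
                    oc_min=float(e["oc"][0]), oc_max=float(e["oc"][1]),
                    hc_min=float(e["hc"][0]), hc_max=float(e["hc"][1]),
                    extra=extra,
                )
            )
        except (KeyError, TypeError, IndexError) as err:
            raise ValueError(f"malformed boundary rule in set {name!r}: {e!r}") from err
    return ClassBoundarySet(name=name, rules=tuple(rules))


def load_boundary_sets(path: str | None = None) -> dict[str, ClassBoundarySet]:
    """Load boundary sets from a YAML file (bundled defaults when no path)."""
    if path is None:
        text = resources.files("ftmspeaks.data").joinpath("boundary_sets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("boundary set file must map set names to rule lists")
    return {name: _rules_from_config(name, entries) for name, entries in cfg.items()}


def get_boundary_set(name: str, path: str | None = None) -> ClassBoundarySet:
    sets = load_boundary_sets(path)
    if name not in sets:
        raise KeyError(f"unknown boundary set {name!r}; available: {sorted(sets)}")
    return sets[name]


def assign_compound_class(oc: float, hc: float, boundary_set: ClassBoundarySet,
                          extra_values: Mapping[str, float] | None = None) -> str:
    """Class label of a single (O:C, H:C) point under a boundary set.

    The first rule (in precedence order) whose window contains the point
    wins; ``"Other"`` when no rule matches.
    """
    if pd.isna(oc) or pd.isna(hc):
        raise ValueError("oc and hc must be defined")
    for rule in boundary_set.rules:
        if rule.contains(oc, hc, extra_values):
            return rule.label
    return OTHER_LABEL


def assign_class(dataset: PeakDataset,
                 boundary_set: ClassBoundarySet | str = "bs1") -> PeakDataset:
    """Add a per-peak compound-class column ``class_<set name>``.

    Element ratios are computed first if absent.  Formula-less and
    isotope-flagged peaks get a missing class.
    """
    if isinstance(boundary_set, str):
        boundary_set = get_boundary_set(boundary_set)
    ds = dataset
    if "oc" not in ds.annotation.columns or "hc" not in ds.annotation.columns:
        ds = compound_calcs(ds, ["calc_element_ratios"])
    ann = ds.annotation.copy()
    eligible = ds.formula_assigned
    labels = []
    for pid in ann.index:
        if not bool(eligible.loc[pid]) or pd.isna(ann.at[pid, "oc"]) or pd.isna(ann.at[pid, "hc"]):
            labels.append(None)
        else:
            row = ann.loc[pid]
            labels.append(
                assign_compound_class(row["oc"], row["hc"], boundary_set, row)
            )
    ann[f"class_{boundary_set.name}"] = labels
    new = ds._replace(annotation=ann)
    new.provenance.append(f"assign_class:{boundary_set.name}")
    return new
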