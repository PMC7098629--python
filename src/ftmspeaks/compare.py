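"""Group-level presence summaries and qualitative two-group comparison.

FT-MS peak lists are usually compared qualitatively: a compound is either
observed in a sample or it is not.  Given designated sample groups this
module computes per-peak presence counts and proportions per group
(:func:`summarize_groups`) and decides, for two chosen groups, which peaks
are unique to each (:func:`compare_groups`).  Uniqueness can be called by
simple count/proportion thresholds or by a formal test of association
between observation pattern and group membership — the likelihood-ratio
G-test on the 2x2 present/absent x group table.

The G-test used here is the plain likelihood ratio statistic
``G = 2 sum O ln(O/E)`` (no Williams or Yates correction, ``0 ln 0 := 0``)
referred to a chi-square distribution with one degree of freedom.  With
degenerate margins (a peak present, or absent, in every sample of both
groups) there is nothing to test: G = 0, p = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PeakDataset

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize_groups",
    "gtest_2x2",
    "compare_groups",
    "VERDICTS",
]

SUMMARY_FUNCTIONS = ("n_present", "prop_present")
METHODS = ("gtest", "nsamps", "prop")
VERDICTS = ("unique_to_g1", "unique_to_g2", "observed_in_both", "observed_in_neither")


@dataclass
class GroupSummary:
    """Per-peak, per-group presence summaries.

    ``data`` has one column per group per summary function, named
    ``"<group>:<function>"``, indexed by peak id.
    """

    data: pd.DataFrame
    group_sizes: dict[str, int]
    functions: tuple[str, ...]
    dataset: PeakDataset | None = None

    def column(self, group: str, function: str) -> pd.Series:
        return self.data[f"{group}:{function}"]


@dataclass
class GroupComparison:
    """Per-peak uniqueness verdicts for a two-group comparison.

    ``table`` is indexed by peak id with columns ``n_present_g1``,
    ``prop_present_g1`` (ditto g2), ``g_statistic``/``p_value`` for the gtest
    method, and ``verdict`` in :data:`VERDICTS`.
    """

    table: pd.DataFrame
    group1: str
    group2: str
    method: str
    thresholds: dict
    dataset: PeakDataset | None = None

    @property
    def verdicts(self) -> pd.Series:
        return self.table["verdict"]


def summarize_groups(
    dataset: PeakDataset,
    summary_functions: Sequence[str] = SUMMARY_FUNCTIONS,
) -> GroupSummary:
    """Per-group presence count and/or proportion for every peak."""
    if dataset.group_map is None:
        raise ValueError("groups must be designated before summarizing groups")
    funcs = tuple(summary_functions)
    for f in funcs:
        if f not in SUMMARY_FUNCTIONS:
            raise ValueError(f"unknown summary function {f!r}; choose from {SUMMARY_FUNCTIONS}")
    if not funcs:
        raise ValueError("at least one summary function required")
    presence = dataset.presence
    groups = dataset.groups
    cols: dict[str, pd.Series] = {}
    for g, members in groups.items():
        n = presence[members].sum(axis=1).astype(int)
        if "n_present" in funcs:
            cols[f"{g}:n_present"] = n
        if "prop_present" in funcs:
            cols[f"{g}:prop_present"] = n / len(members)
    return GroupSummary(
        data=pd.DataFrame(cols, index=dataset.peak_ids),
        group_sizes={g: len(m) for g, m in groups.items()},
        functions=funcs,
        dataset=dataset,
    )


def gtest_2x2(n1_present: int, n1_total: int,
              n2_present: int, n2_total: int) -> tuple[float, float]:
    """G statistic and chi-square(1) p-value for a 2x2 presence table.

    Rows are groups, columns present/absent; expected counts come from the
    independence model on the margins.  Observed zeros contribute nothing to
    the sum.  Degenerate margins (the peak present in all samples of both
    groups, or absent from all) give G = 0, p = 1.
    """
    if n1_total < 1 or n2_total < 1:
        raise ValueError("group totals must be >= 1")
    if not (0 <= n1_present <= n1_total and 0 <= n2_present <= n2_total):
        raise ValueError("present counts must lie in [0, total]")
    obs = np.array(
        [
            [n1_present, n1_total - n1_present],
            [n2_present, n2_total - n2_present],
        ],
        dtype=float,
    )
    col_tot = obs.sum(axis=0)
    if col_tot[0] == 0 or col_tot[1] == 0:
        return 0.0, 1.0
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), col_tot) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    g = max(g, 0.0)
    return float(g), float(stats.chi2.sf(g, df=1))


def _gtest_vectorized(n1: np.ndarray, t1: int, n2: np.ndarray, t2: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    obs = np.stack([n1, t1 - n1, n2, t2 - n2], axis=1).astype(float)  # (k, 4)
    present = n1 + n2
    absent = (t1 - n1) + (t2 - n2)
    n = float(t1 + t2)
    e = np.stack(
        [t1 * present, t1 * absent, t2 * present, t2 * absent], axis=1
    ) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / e), 0.0)
    g = np.clip(2.0 * terms.sum(axis=1), 0.0, None)
    degenerate = (present == 0) | (absent == 0)
    g[degenerate] = 0.0
    p = stats.chi2.sf(g, df=1)
    p[degenerate] = 1.0
    return g, p


def compare_groups(
    dataset: PeakDataset,
    group1: str,
    group2: str,
    method: str = "gtest",
    *,
    presence_prop: float | None = None,
    presence_n: int | None = None,
    pvalue: float = 0.05,
    absence_prop: float | None = None,
    absence_n: int | None = None,
    adjust: str | None = None,
) -> GroupComparison:
    """Decide which peaks are unique to each of two groups.

    Presence in a group is declared when the peak's observed proportion
    strictly exceeds ``presence_prop`` (default 0.5, i.e. "more than half
    the samples") or, alternatively, when its count is at least
    ``presence_n``.  A peak present in both groups is ``observed_in_both``;
    in neither, ``observed_in_neither``.  A peak present in exactly one
    group is unique to it when the chosen method's absence criterion holds
    for the other group:

    * ``gtest`` — the G-test p-value is below ``pvalue``;
    * ``nsamps`` — the other group's count is at most ``absence_n``;
    * ``prop`` — the other group's proportion is at most ``absence_prop``;

    otherwise it falls back to ``observed_in_both``.  ``adjust="bh"``
    applies a Benjamini-Hochberg correction to the G-test p-values before
    thresholding (off by default).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if dataset.group_map is None:
        raise ValueError("groups must be designated before comparing groups")
    groups = dataset.groups
    for g in (group1, group2):
        if g not in groups:
            raise KeyError(f"unknown group {g!r}; available: {sorted(groups)}")
    if group1 == group2:
        raise ValueError("two distinct groups required")
    if presence_prop is not None and presence_n is not None:
        raise ValueError("give presence_prop or presence_n, not both")
    if presence_prop is None and presence_n is None:
        presence_prop = 0.5
    if presence_prop is not None and not 0 <= presence_prop < 1:
        raise ValueError(f"presence_prop must be in [0, 1), got {presence_prop}")
    if not 0 < pvalue <= 1:
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    if method == "nsamps" and absence_n is None:
        absence_n = 0
    if method == "prop" and absence_prop is None:
        absence_prop = 0.0

    m1, m2 = groups[group1], groups[group2]
    t1, t2 = len(m1), len(m2)
    if presence_n is not None and not 1 <= presence_n <= max(t1, t2):
        raise ValueError(f"presence_n out of range (got {presence_n})")
    presence = dataset.presence
    n1 = presence[m1].sum(axis=1).to_numpy(dtype=int)
    n2 = presence[m2].sum(axis=1).to_numpy(dtype=int)
    p1, p2 = n1 / t1, n2 / t2

    if presence_prop is not None:
        present1, present2 = p1 > presence_prop, p2 > presence_prop
    else:
        present1, present2 = n1 >= presence_n, n2 >= presence_n

    table = pd.DataFrame(
        {
            "n_present_g1": n1,
            "prop_present_g1": p1,
            "n_present_g2": n2,
            "prop_present_g2": p2,
        },
        index=dataset.peak_ids,
    )
    thresholds: dict = {
        "presence_prop": presence_prop,
        "presence_n": presence_n,
    }

    if method == "gtest":
        g, p = _gtest_vectorized(n1, t1, n2, t2)
        table["g_statistic"] = g
        if adjust == "bh":
            p = _benjamini_hochberg(p)
        elif adjust is not None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        table["p_value"] = p
        other_absent_1 = p < pvalue  # significance criterion, shared by both directions
        other_absent_2 = other_absent_1
        thresholds["pvalue"] = pvalue
        thresholds["adjust"] = adjust
    elif method == "nsamps":
        if not 0 <= absence_n:
            raise ValueError(f"absence_n must be >= 0, got {absence_n}")
        other_absent_1 = n2 <= absence_n  # for unique_to_g1
        other_absent_2 = n1 <= absence_n
        thresholds["absence_n"] = absence_n
    else:
        if not 0 <= absence_prop <= 1:
            raise ValueError(f"absence_prop must be in [0, 1], got {absence_prop}")
        other_absent_1 = p2 <= absence_prop
        other_absent_2 = p1 <= absence_prop
        thresholds["absence_prop"] = absence_prop

    verdict = np.where(
        present1 & present2,
        "observed_in_both",
        np.where(
            ~present1 & ~present2,
            "observed_in_neither",
            np.where(
                present1 & other_absent_1,
                "unique_to_g1",
                np.where(present2 & other_absent_2, "unique_to_g2", "observed_in_both"),
            ),
        ),
    )
    table["verdict"] = verdict
    return GroupComparison(
        table=table,
        group1=group1,
        group2=group2,
        method=method,
        thresholds=thresholds,
        dataset=dataset,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out
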