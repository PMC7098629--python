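"""The three-table peak dataset and its core operations.

An FT-MS peak-level study is carried as three aligned tables:

* a peak x sample intensity matrix (one row per observed mass),
* a sample metadata table (one row per sample, arbitrary covariates),
* a peak annotation table (molecular formula or element counts, isotope flag,
  and any computed chemical properties).

:class:`PeakDataset` bundles the three with the current intensity scale, an
optional sample -> group assignment, and an append-only provenance log.  An
intensity of zero and a missing cell both mean "peak not observed in this
sample"; internally both are normalized to a single absent sentinel (0 on the
intensity and presence/absence scales, NaN on log scales).  The raw intensity
matrix is always retained so scale transforms never compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ELEMENTS
from .formula import ElementCounts, parse_formula, write_formula

__all__ = [
    "PeakDataset",
    "DatasetSummary",
    "build_dataset",
    "transform_scale",
    "set_groups",
    "summarize_dataset",
    "summary_plot_data",
    "SCALES",
]

SCALES = ("intensity", "log2", "log10", "ln", "presence_absence")
_LOG_FUNCS = {"log2": np.log2, "log10": np.log10, "ln": np.log}

#: Values of an isotope-flag column treated as truthy when no explicit symbol
#: is declared.
_DEFAULT_TRUTHY = {"1", "yes", "true", "y", "t"}


@dataclass
class DatasetSummary:
    """Headline counts of a :class:`PeakDataset`."""

    n_samples: int
    n_peaks: int
    n_assigned_formulae: int
    pct_missing: float
    per_group_n: dict[str, int] | None = None

    def __str__(self) -> str:
        lines = [
            f"{'Samples':<22}{self.n_samples}",
            f"{'Peaks':<22}{self.n_peaks}",
            f"{'Assigned formulae':<22}{self.n_assigned_formulae}",
            f"{'Missing values (%)':<22}{self.pct_missing:.2f}",
        ]
        if self.per_group_n is not None:
            for g, n in self.per_group_n.items():
                lines.append(f"{'  group ' + g:<22}{n}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "n_peaks": self.n_peaks,
            "n_assigned_formulae": self.n_assigned_formulae,
            "pct_missing": self.pct_missing,
        }
        if self.per_group_n is not None:
            d["per_group_n"] = dict(self.per_group_n)
        return d


@dataclass
class PeakDataset:
    """Validated peak x sample dataset with annotation and sample metadata.

    Do not construct directly; use :func:`build_dataset`, which validates the
    three tables and normalizes formulas.  All transforming operations return a
    new object and append one provenance entry.
    """

    intensities: pd.DataFrame            # index peak_id, columns sample_id, current scale
    sample_table: pd.DataFrame           # index sample_id
    annotation: pd.DataFrame             # index peak_id
    scale: str = "intensity"
    group_map: dict[str, str] | None = None
    provenance: list[str] = field(default_factory=list)
    _raw: pd.DataFrame | None = None     # original intensity matrix (absent = 0)

    # ---------------------------------------------------------------- basics
    def __post_init__(self) -> None:
        if self._raw is None:
            self._raw = self.intensities.copy()

    @property
    def peak_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def raw(self) -> pd.DataFrame:
        """Original intensity matrix (absent cells are 0)."""
        return self._raw

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean observed/not-observed matrix derived from raw intensities."""
        return self._raw > 0

    @property
    def masses(self) -> pd.Series:
        """Observed mass per peak (Da); NaN where no mass is known."""
        return self.annotation["mass"]

    @property
    def formula_assigned(self) -> pd.Series:
        """True for peaks with a formula and no isotope flag.

        Isotopic peaks duplicate the chemistry of their monoisotopic parent,
        so they are excluded from formula-based calculators, class assignment
        and the formula-assigned count even when a formula string is present.
        """
        has_formula = self.annotation["formula"].notna()
        return has_formula & ~self.annotation["isotope"]

    @property
    def groups(self) -> dict[str, list[str]]:
        """Mapping group label -> member sample ids (empty if no groups set)."""
        if self.group_map is None:
            return {}
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.group_map[s], []).append(s)
        return out

    def _replace(self, **kw) -> "PeakDataset":
        base = dict(
            intensities=self.intensities,
            sample_table=self.sample_table,
            annotation=self.annotation,
            scale=self.scale,
            group_map=None if self.group_map is None else dict(self.group_map),
            provenance=list(self.provenance),
            _raw=self._raw,
        )
        base.update(kw)
        return PeakDataset(**base)

    # ------------------------------------------------------------ operations
    def transform_scale(self, target_scale: str) -> "PeakDataset":
        """Re-express intensities on ``target_scale``.

        Only a dataset on the intensity scale may be transformed (the raw
        matrix is retained, so revert by transforming the original object).
        On log scales absent cells become NaN; on the presence/absence scale
        observed cells become 1 and absent cells 0.
        """
        if target_scale not in SCALES:
            raise ValueError(f"unsupported scale {target_scale!r}; choose from {SCALES}")
        if self.scale != "intensity":
            raise ValueError(
                f"can only transform from the intensity scale (current: {self.scale!r})"
            )
        if target_scale == "intensity":
            mat = self._raw.copy()
        elif target_scale == "presence_absence":
            mat = (self._raw > 0).astype(float)
        else:
            fn = _LOG_FUNCS[target_scale]
            mat = self._raw.where(self._raw > 0)
            mat = pd.DataFrame(
                fn(mat.to_numpy(dtype=float)), index=mat.index, columns=mat.columns
            )
        new = self._replace(intensities=mat, scale=target_scale)
        new.provenance.append(f"transform_scale:{target_scale}")
        return new

    def set_groups(self, main_effect_columns: Sequence[str] | str) -> "PeakDataset":
        """Assign each sample to a group from one or two sample-table columns.

        With two main effects the group label is ``"<v1>_<v2>"``; distinct
        effect-value combinations that collide onto one label are rejected.
        """
        if isinstance(main_effect_columns, str):
            cols = [main_effect_columns]
        else:
            cols = list(main_effect_columns)
        if not 1 <= len(cols) <= 2:
            raise ValueError("1 or 2 main effect columns required")
        for c in cols:
            if c not in self.sample_table.columns:
                raise KeyError(f"main effect column {c!r} not in sample table")
        sub = self.sample_table[cols]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"samples with missing main-effect values: {bad}")
        tuples = [tuple(str(v) for v in row) for row in sub.itertuples(index=False)]
        labels = ["_".join(t) for t in tuples]
        seen: dict[str, tuple] = {}
        for t, lab in zip(tuples, labels):
            if lab in seen and seen[lab] != t:
                raise ValueError(
                    f"group label collision: {seen[lab]} and {t} both map to {lab!r}"
                )
            seen[lab] = t
        gmap = dict(zip(sub.index, labels))
        new = self._replace(group_map=gmap)
        new.provenance.append(f"set_groups:{','.join(cols)}")
        return new

    def summarize(self) -> DatasetSummary:
        """Counts of samples, peaks, assigned formulae and percent missing.

        A cell is missing when the peak was not observed in the sample: zero
        or absent intensity on the intensity and presence/absence scales, NaN
        on log scales (identical sets by construction).
        """
        n_cells = self.n_peaks * self.n_samples
        n_absent = int((~self.presence).to_numpy().sum())
        pct = 100.0 * n_absent / n_cells if n_cells else 0.0
        per_group = None
        if self.group_map is not None:
            per_group = {g: len(m) for g, m in self.groups.items()}
        return DatasetSummary(
            n_samples=self.n_samples,
            n_peaks=self.n_peaks,
            n_assigned_formulae=int(self.formula_assigned.sum()),
            pct_missing=pct,
            per_group_n=per_group,
        )

    def summary_plot_data(self) -> pd.DataFrame:
        """Per-sample table backing the dataset-level summary plot.

        On the presence/absence scale, one row per sample with the observed
        peak count (bar chart).  On intensity or log scales, per-sample
        boxplot statistics (quartiles and 1.5 IQR whiskers) over observed
        values.  When groups are set, samples of one group are contiguous and
        each row carries its group label.
        """
        order = list(self.sample_ids)
        if self.group_map is not None:
            pos = {s: i for i, s in enumerate(order)}
            order.sort(key=lambda s: (self.group_map[s], pos[s]))
        rows = []
        for s in order:
            group = self.group_map[s] if self.group_map else None
            if self.scale == "presence_absence":
                rows.append(
                    {"sample": s, "group": group, "n_observed": int(self.presence[s].sum())}
                )
            else:
                col = self.intensities[s]
                vals = col[self.presence[s]].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    q1 = med = q3 = lo = hi = math.nan
                else:
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    iqr = q3 - q1
                    lo = float(vals[vals >= q1 - 1.5 * iqr].min())
                    hi = float(vals[vals <= q3 + 1.5 * iqr].max())
                rows.append(
                    {
                        "sample": s,
                        "group": group,
                        "q1": q1,
                        "median": med,
                        "q3": q3,
                        "whisker_low": lo,
                        "whisker_high": hi,
                        "n_observed": int(self.presence[s].sum()),
                    }
                )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------- building

def _normalize_isotope(ann: pd.DataFrame, isotope_col: str | None,
                       isotope_symbol: str | None) -> pd.Series:
    if isotope_col is None:
        return pd.Series(False, index=ann.index)
    if isotope_col not in ann.columns:
        raise KeyError(f"isotope column {isotope_col!r} not in annotation table")
    col = ann[isotope_col]
    if isotope_symbol is not None:
        return col.astype(str).str.strip() == str(isotope_symbol)
    def truthy(v) -> bool:
        if pd.isna(v):
            return False
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in _DEFAULT_TRUTHY
    return col.map(truthy)


def build_dataset(
    peak_table: pd.DataFrame,
    sample_table: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    peak_id: str,
    sample_id: str,
    formula: str | None = None,
    elements: Mapping[str, str] | None = None,
    isotope: str | None = None,
    isotope_symbol: str | None = None,
    mass: str | None = None,
) -> PeakDataset:
    """Validate and assemble the three tables into a :class:`PeakDataset`.

    Parameters
    ----------
    peak_table
        Peak x sample intensities; one ``peak_id`` column plus one numeric
        column per sample.  Zero or missing means not observed.
    sample_table
        One row per sample; ``sample_id`` values must equal the peak-table
        sample columns as a set.
    annotation
        One row per peak keyed by ``peak_id``, carrying either a formula
        string column (named by ``formula``) or element-count columns (the
        ``elements`` mapping, e.g. ``{"C": "C", "H": "H", ...}``).  When only
        counts are supplied canonical formula strings are synthesized; when
        only strings are supplied the counts are parsed out.  Supplying both
        cross-checks them.
    isotope, isotope_symbol
        Optional annotation column flagging isotopic peaks, with the symbol
        that means "is an isotope" (any common truthy marker by default).
    mass
        Optional annotation column with the observed mass; by default the
        peak identifier is interpreted as the mass where possible.
    """
    if formula is None and elements is None:
        raise ValueError("need a formula column or element-count columns")

    pt = peak_table.copy()
    if peak_id not in pt.columns:
        raise KeyError(f"peak id column {peak_id!r} not in peak table")
    ids = pt[peak_id]
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate peak ids: {dup}")
    pt = pt.set_index(peak_id)
    if pt.shape[1] < 1:
        raise ValueError("peak table needs at least one sample column")

    st = sample_table.copy()
    if sample_id not in st.columns:
        raise KeyError(f"sample id column {sample_id!r} not in sample table")
    if st[sample_id].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    st = st.set_index(sample_id)
    if set(st.index) != set(pt.columns):
        raise ValueError(
            "sample ids do not match peak-table columns: "
            f"only in sample table {sorted(set(st.index) - set(pt.columns))}, "
            f"only in peak table {sorted(set(pt.columns) - set(st.index))}"
        )
    st = st.loc[pt.columns]

    ann = annotation.copy()
    if peak_id not in ann.columns:
        raise KeyError(f"peak id column {peak_id!r} not in annotation table")
    if ann[peak_id].duplicated().any():
        raise ValueError("duplicate peak ids in annotation table")
    ann = ann.set_index(peak_id)
    if set(ann.index) != set(pt.index):
        raise ValueError(
            "annotation peak ids do not match peak table: "
            f"only in annotation {sorted(set(ann.index) - set(pt.index))[:5]}, "
            f"only in peak table {sorted(set(pt.index) - set(ann.index))[:5]}"
        )
    ann = ann.loc[pt.index]

    # intensities: numeric, non-negative; missing normalized to 0 (absent)
    mat = pt.apply(pd.to_numeric, errors="coerce")
    bad_numeric = pt.notna() & mat.isna()
    if bad_numeric.any().any():
        rows = pt.index[bad_numeric.any(axis=1)].tolist()[:5]
        raise ValueError(f"non-numeric intensities for peaks {rows}")
    neg = mat < 0
    if neg.any().any():
        rows = pt.index[neg.any(axis=1)].tolist()
        raise ValueError(f"negative intensities for peaks {rows}")
    mat = mat.fillna(0.0).astype(float)

    iso = _normalize_isotope(ann, isotope, isotope_symbol)

    # formulas / element counts: parse or synthesize, cross-check when both
    parsed: list[ElementCounts | None] = []
    if formula is not None:
        if formula not in ann.columns:
            raise KeyError(f"formula column {formula!r} not in annotation table")
        raw_formula = ann[formula]
        for pid, v in raw_formula.items():
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                parsed.append(None)
                continue
            try:
                parsed.append(parse_formula(str(v)))
            except ValueError as e:
                raise ValueError(f"peak {pid}: {e}") from None
    if elements is not None:
        for el in ("C", "H"):
            if el not in elements:
                raise ValueError(f"element column mapping must include {el!r}")
        counts_list: list[ElementCounts | None] = []
        for i, pid in enumerate(ann.index):
            vals = {}
            missing = False
            for el in ELEMENTS:
                col = elements.get(el)
                if col is None:
                    vals[el] = 0
                    continue
                if col not in ann.columns:
                    raise KeyError(f"element column {col!r} not in annotation table")
                v = ann[col].iloc[i]
                if pd.isna(v):
                    v = 0
                if float(v) != int(v) or int(v) < 0:
                    raise ValueError(f"peak {pid}: element count {el}={v!r} invalid")
                vals[el] = int(v)
            if vals["C"] == 0 and vals["H"] == 0 and all(v == 0 for v in vals.values()):
                counts_list.append(None)  # no assignment for this peak
            else:
                counts_list.append(ElementCounts(**vals))
        if formula is not None:
            for pid, a, b in zip(ann.index, parsed, counts_list):
                if (a is None) != (b is None) or (a is not None and a != b):
                    raise ValueError(
                        f"peak {pid}: formula string and element counts disagree "
                        f"({a} vs {b})"
                    )
        else:
            parsed = counts_list

    for pid, c in zip(ann.index, parsed):
        if c is not None and (c.C < 1 or c.H < 1):
            raise ValueError(f"peak {pid}: assigned formula must have C >= 1 and H >= 1")

    norm = pd.DataFrame(index=ann.index)
    norm["formula"] = [None if c is None else write_formula(c) for c in parsed]
    for el in ELEMENTS:
        norm[el] = [np.nan if c is None else getattr(c, el) for c in parsed]
    norm["isotope"] = iso.to_numpy()
    if mass is not None:
        if mass not in ann.columns:
            raise KeyError(f"mass column {mass!r} not in annotation table")
        norm["mass"] = pd.to_numeric(ann[mass], errors="coerce")
    else:
        norm["mass"] = pd.to_numeric(pd.Series(ann.index, index=ann.index), errors="coerce")

    # carry extra user annotation columns (covariates) through untouched
    reserved = {formula, isotope, mass} | set(
        (elements or {}).values()
    )
    for col in ann.columns:
        if col not in reserved and col not in norm.columns:
            norm[col] = ann[col]

    ds = PeakDataset(
        intensities=mat, sample_table=st, annotation=norm, scale="intensity"
    )
    ds.provenance.append(f"build_dataset:{len(mat)}x{mat.shape[1]}")
    return ds


# --------------------------------------------------- functional counterparts

def transform_scale(dataset: PeakDataset, target_scale: str) -> PeakDataset:
    return dataset.transform_scale(target_scale)


def set_groups(dataset: PeakDataset, main_effect_columns: Sequence[str] | str) -> PeakDataset:
    return dataset.set_groups(main_effect_columns)


def summarize_dataset(dataset: PeakDataset) -> DatasetSummary:
    return dataset.summarize()


def summary_plot_data(dataset: PeakDataset) -> pd.DataFrame:
    return dataset.summary_plot_data()
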