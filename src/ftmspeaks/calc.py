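"""Chemical property calculations from molecular formulas.

Every quantity here is a pure function of the element counts (and, for the
Kendrick quantities, the observed mass):

* elemental ratios O:C, H:C, N:C, P:C and N:P,
* Kendrick mass and defect for a chosen repeating base unit,
* nominal oxidation state of carbon (NOSC),
* Cox Gibbs free energy of the carbon oxidation half reaction,
* aromaticity index (AI) and its modified form which discounts half the
  oxygen as carboxyl-like,
* double bond equivalents (DBE) and DBE minus oxygen.

Scalar functions take :class:`~ftmspeaks.formula.ElementCounts`;
:func:`compound_calcs` applies them column-wise to a dataset, leaving cells
missing (never zero) for peaks without a usable formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_VALENCES,
    ELEMENTS,
    GIBBS_INTERCEPT,
    GIBBS_SLOPE,
    KENDRICK_BASES,
)
from .dataset import PeakDataset
from .formula import ElementCounts

__all__ = [
    "KendrickValues",
    "element_ratios",
    "kendrick",
    "nosc",
    "gibbs_cox",
    "aromaticity",
    "dbe",
    "elemental_composition_class",
    "compound_calcs",
    "CALC_NAMES",
]


@dataclass(frozen=True)
class KendrickValues:
    base: str
    kendrick_mass: float
    kendrick_defect: float


def element_ratios(counts: ElementCounts) -> dict[str, float]:
    """O:C, H:C, N:C, P:C and N:P ratios; N:P is missing (NaN) when P = 0."""
    if counts.C < 1:
        raise ValueError("element ratios require C >= 1")
    return {
        "oc": counts.O / counts.C,
        "hc": counts.H / counts.C,
        "nc": counts.N / counts.C,
        "pc": counts.P / counts.C,
        "np": counts.N / counts.P if counts.P > 0 else math.nan,
    }


def kendrick(mass: float, base: str = "CH2", convention: str = "ceil") -> KendrickValues:
    """Kendrick mass and defect of an observed mass for a repeating base unit.

    The mass axis is rescaled so the base unit (CH2 by default) has exactly
    its nominal integer mass; members of a homologous series built from that
    unit then share a common fractional remainder, the Kendrick defect.

    ``convention="ceil"`` defines the defect as ``ceil(KM) - KM`` (in
    ``[0, 1)``); ``convention="round"`` uses ``round(KM) - KM`` (in
    ``[-0.5, 0.5]``).  Both appear in the literature.
    """
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if base not in KENDRICK_BASES:
        raise ValueError(f"unknown Kendrick base {base!r}; choose from {sorted(KENDRICK_BASES)}")
    nominal, exact = KENDRICK_BASES[base]
    km = mass * nominal / exact
    if convention == "ceil":
        # guard against float noise pushing an exactly-integer KM just above
        # its integer, which would flip the defect from ~0 to ~1
        kd = math.ceil(round(km, 9)) - km
        if kd < 0:
            kd = 0.0
    elif convention == "round":
        kd = round(km) - km
    else:
        raise ValueError(f"unknown Kendrick defect convention {convention!r}")
    return KendrickValues(base=base, kendrick_mass=km, kendrick_defect=kd)


def nosc(counts: ElementCounts) -> float:
    """Nominal oxidation state of carbon.

    NOSC = 4 - (4C + H - 3N - 2O + 5P - 2S) / C, ranging from -4 (methane)
    to +4 (CO2).  Higher values indicate more oxidized carbon.
    """
    if counts.C < 1:
        raise ValueError("NOSC requires C >= 1")
    z = 4 * counts.C + counts.H - 3 * counts.N - 2 * counts.O + 5 * counts.P - 2 * counts.S
    return 4.0 - z / counts.C


def gibbs_cox(counts: ElementCounts) -> float:
    """Standard-state Gibbs free energy of the carbon oxidation half reaction.

    Linear in NOSC: 60.3 - 28.5 * NOSC, in kJ per mol C.  More reduced
    compounds (lower NOSC) yield more energy on oxidation.
    """
    return GIBBS_INTERCEPT + GIBBS_SLOPE * nosc(counts)


def aromaticity(counts: ElementCounts) -> tuple[float, float]:
    """Aromaticity index (AI) and modified AI.

    AI     = (1 + C - O - S - 0.5 H) / (C - O - S - N - P)
    AI_mod = (1 + C - 0.5 O - S - 0.5 H) / (C - 0.5 O - S - N - P)

    A non-positive numerator or denominator means no aromatic character can
    be inferred; such values are clamped to 0 so the index is never negative.
    """
    if counts.C < 1:
        raise ValueError("aromaticity requires C >= 1")
    C, H, N, O, S, P = counts.C, counts.H, counts.N, counts.O, counts.S, counts.P

    def _ai(o_weight: float) -> float:
        num = 1 + C - o_weight * O - S - 0.5 * H
        den = C - o_weight * O - S - N - P
        if num <= 0 or den <= 0:
            return 0.0
        return num / den

    return _ai(1.0), _ai(0.5)


def dbe(counts: ElementCounts,
        valences: Mapping[str, int] | None = None) -> tuple[float, float]:
    """Double bond equivalents and DBE minus oxygen.

    DBE = 1 + sum_e n_e (v_e - 2) / 2 over all elements, which with the
    default covalences (C=4, H=1, N=3, P=3; O=S=2 contribute nothing)
    reduces to 1 + C - H/2 + N/2 + P/2.  DBE-O subtracts the oxygen count
    as a crude correction for carboxyl/carbonyl double bonds.
    """
    if counts.C < 1:
        raise ValueError("DBE requires C >= 1")
    v = dict(DEFAULT_VALENCES)
    if valences:
        for el, val in valences.items():
            if el not in v:
                raise ValueError(f"unknown element {el!r} in valences")
            if val < 0:
                raise ValueError(f"negative valence for {el!r}")
            v[el] = val
    d = 1 + sum(getattr(counts, el) * (v[el] - 2) for el in ELEMENTS) / 2
    return d, d - counts.O


def elemental_composition_class(counts: ElementCounts) -> str:
    """Elemental-composition class: present element symbols in C,H,N,O,S,P order."""
    return "".join(el for el in ("C", "H", "N", "O", "S", "P") if getattr(counts, el) > 0)


# ------------------------------------------------------------- dataset level

#: Calculator registry; names follow the field's conventional function names.
CALC_NAMES = (
    "calc_element_ratios",
    "calc_kendrick",
    "calc_nosc",
    "calc_gibbs",
    "calc_aroma",
    "calc_dbe",
)

#: Columns produced by each calculator.
CALC_COLUMNS = {
    "calc_element_ratios": ("oc", "hc", "nc", "pc", "np"),
    "calc_kendrick": ("kendrick_mass", "kendrick_defect"),
    "calc_nosc": ("nosc",),
    "calc_gibbs": ("gibbs_cox",),
    "calc_aroma": ("ai", "ai_mod"),
    "calc_dbe": ("dbe", "dbe_o"),
}


def _counts_from_row(row: pd.Series) -> ElementCounts:
    return ElementCounts(**{el: int(row[el]) for el in ELEMENTS})


def compound_calcs(
    dataset: PeakDataset,
    calc_names: Sequence[str],
    *,
    kendrick_base: str = "CH2",
    kendrick_convention: str = "ceil",
    valences: Mapping[str, int] | None = None,
) -> PeakDataset:
    """Append the requested chemical-property columns to the annotation table.

    Peaks without an assigned formula, and isotope-flagged peaks, get missing
    cells (never zero).  Recomputing an already-present property overwrites
    it, so the operation is idempotent.
    """
    for name in calc_names:
        if name not in CALC_NAMES:
            raise ValueError(f"unknown calculation {name!r}; choose from {CALC_NAMES}")
    if not calc_names:
        return dataset

    ann = dataset.annotation.copy()
    eligible = dataset.formula_assigned
    new_cols: dict[str, list[float]] = {
        col: [] for name in calc_names for col in CALC_COLUMNS[name]
    }
    for pid in ann.index:
        ok = bool(eligible.loc[pid])
        row = ann.loc[pid]
        counts = _counts_from_row(row) if ok else None
        for name in calc_names:
            cols = CALC_COLUMNS[name]
            if not ok:
                for c in cols:
                    new_cols[c].append(math.nan)
                continue
            if name == "calc_element_ratios":
                r = element_ratios(counts)
                for c in cols:
                    new_cols[c].append(r[c])
            elif name == "calc_kendrick":
                m = row["mass"]
                if pd.isna(m) or m <= 0:
                    new_cols["kendrick_mass"].append(math.nan)
                    new_cols["kendrick_defect"].append(math.nan)
                else:
                    kv = kendrick(float(m), base=kendrick_base,
                                  convention=kendrick_convention)
                    new_cols["kendrick_mass"].append(kv.kendrick_mass)
                    new_cols["kendrick_defect"].append(kv.kendrick_defect)
            elif name == "calc_nosc":
                new_cols["nosc"].append(nosc(counts))
            elif name == "calc_gibbs":
                new_cols["gibbs_cox"].append(gibbs_cox(counts))
            elif name == "calc_aroma":
                ai, ai_mod = aromaticity(counts)
                new_cols["ai"].append(ai)
                new_cols["ai_mod"].append(ai_mod)
            elif name == "calc_dbe":
                d, do = dbe(counts, valences)
                new_cols["dbe"].append(d)
                new_cols["dbe_o"].append(do)
    for c, vals in new_cols.items():
        ann[c] = vals

    new = dataset._replace(annotation=ann)
    new.provenance.append(f"compound_calcs:{','.join(calc_names)}")
    return new


def assign_elemental_composition(dataset: PeakDataset) -> PeakDataset:
    """Add an ``el_comp`` column with the elemental-composition class."""
    ann = dataset.annotation.copy()
    eligible = dataset.formula_assigned
    ann["el_comp"] = [
        elemental_composition_class(_counts_from_row(ann.loc[pid]))
        if bool(eligible.loc[pid]) else None
        for pid in ann.index
    ]
    new = dataset._replace(annotation=ann)
    new.provenance.append("assign_elemental_composition")
    return new
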