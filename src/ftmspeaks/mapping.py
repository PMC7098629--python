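"""Formula-keyed mapping of peaks to compounds, reactions and pathways.

FT-MS peaks carry molecular formulas, not structures, so identification is
necessarily ambiguous: a peak maps to every database compound sharing its
canonical formula (possibly none, possibly many).  The database is a simple
database-agnostic three-relation schema the user supplies as delimited
tables — no reference database content is bundled:

* ``compounds``: compound_id, formula
* ``reactions``: reaction_id, compound_id
* ``pathways``:  pathway_id, reaction_id

Formulas are canonicalized on load so string dialect differences (element
order, implicit 1s) never break the join.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .dataset import PeakDataset
from .formula import parse_formula, write_formula

__all__ = [
    "CompoundDB",
    "load_compound_db",
    "map_peaks_to_compounds",
    "map_compounds_to_reactions",
    "map_reactions_to_pathways",
    "PeakCompoundMapping",
]


def _canonical(f: str) -> str:
    try:
        return write_formula(parse_formula(str(f)))
    except ValueError:
        # formulas outside the CHONSP dialect are kept verbatim; they can
        # never match a peak formula, which is always canonical
        return str(f).strip()


@dataclass(frozen=True)
class CompoundDB:
    """Three-relation compound/reaction/pathway database."""

    compounds: pd.DataFrame  # compound_id, formula (canonical)
    reactions: pd.DataFrame  # reaction_id, compound_id
    pathways: pd.DataFrame   # pathway_id, reaction_id

    def __post_init__(self) -> None:
        # canonicalize compound formulas however the object was built
        comp = self.compounds.copy()
        if "formula" in comp.columns:
            comp["formula"] = comp["formula"].map(_canonical)
        object.__setattr__(self, "compounds", comp)
        for name, df, cols in (
            ("compounds", self.compounds, ("compound_id", "formula")),
            ("reactions", self.reactions, ("reaction_id", "compound_id")),
            ("pathways", self.pathways, ("pathway_id", "reaction_id")),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")
        bad_c = set(self.reactions["compound_id"]) - set(self.compounds["compound_id"])
        if bad_c:
            raise ValueError(f"reactions reference unknown compounds: {sorted(bad_c)[:5]}")
        bad_r = set(self.pathways["reaction_id"]) - set(self.reactions["reaction_id"])
        if bad_r:
            raise ValueError(f"pathways reference unknown reactions: {sorted(bad_r)[:5]}")


def load_compound_db(directory: str, sep: str = "\t") -> CompoundDB:
    """Load ``compounds``, ``reactions`` and ``pathways`` tables from a directory.

    Files are ``compounds.tsv``, ``reactions.tsv`` and ``pathways.tsv`` (or
    ``.csv`` with ``sep=","``).  Compound formulas are canonicalized.
    """
    ext = "csv" if sep == "," else "tsv"
    frames = {}
    for name in ("compounds", "reactions", "pathways"):
        path = os.path.join(directory, f"{name}.{ext}")
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        frames[name] = pd.read_csv(path, sep=sep)
    comp = frames["compounds"].copy()
    if "formula" not in comp.columns:
        raise ValueError("compounds table missing formula column")
    comp["formula"] = comp["formula"].map(_canonical)
    return CompoundDB(compounds=comp, reactions=frames["reactions"], pathways=frames["pathways"])


@dataclass
class PeakCompoundMapping:
    """Peak -> compound join result with the unmapped remainder."""

    table: pd.DataFrame        # peak_id, formula, compound_id
    unmapped: list             # peak ids with a formula but no db match

    @property
    def n_mapped_peaks(self) -> int:
        return self.table["peak_id"].nunique()


def map_peaks_to_compounds(dataset: PeakDataset, db: CompoundDB) -> PeakCompoundMapping:
    """Join formula-assigned peaks to db compounds on the canonical formula.

    One output row per (peak, compound) pair; peaks may map to zero, one or
    many compounds.  Isotope-flagged peaks are not mapped.
    """
    eligible = dataset.formula_assigned
    peaks = pd.DataFrame(
        {
            "peak_id": dataset.peak_ids[eligible],
            "formula": dataset.annotation.loc[eligible, "formula"].to_numpy(),
        }
    )
    merged = peaks.merge(
        db.compounds[["compound_id", "formula"]], on="formula", how="left"
    )
    mapped = (
        merged.dropna(subset=["compound_id"])
        .sort_values(["peak_id", "compound_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    unmapped = sorted(set(peaks["peak_id"]) - set(mapped["peak_id"]), key=str)
    return PeakCompoundMapping(table=mapped, unmapped=unmapped)


def map_compounds_to_reactions(mapping: PeakCompoundMapping, db: CompoundDB) -> pd.DataFrame:
    """Extend a peak->compound mapping to reactions.

    Returns one row per (peak, compound, reaction); empty input gives an
    empty table, never an error.
    """
    if mapping.table.empty:
        return pd.DataFrame(columns=["peak_id", "formula", "compound_id", "reaction_id"])
    out = mapping.table.merge(db.reactions, on="compound_id", how="inner")
    return (
        out.sort_values(["peak_id", "compound_id", "reaction_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def map_reactions_to_pathways(reaction_table: pd.DataFrame, db: CompoundDB
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extend a reaction mapping to pathways, with per-pathway peak counts.

    Returns ``(rows, pathway_counts)`` where ``rows`` has one row per
    (peak, compound, reaction, pathway) and ``pathway_counts`` counts the
    distinct peaks and compounds per pathway.
    """
    cols = ["peak_id", "formula", "compound_id", "reaction_id", "pathway_id"]
    if reaction_table.empty:
        return (
            pd.DataFrame(columns=cols),
            pd.DataFrame(columns=["pathway_id", "n_peaks", "n_compounds"]),
        )
    rows = reaction_table.merge(db.pathways, on="reaction_id", how="inner")
    rows = rows.sort_values(cols[:1] + ["pathway_id"], kind="mergesort").reset_index(drop=True)
    counts = (
        rows.groupby("pathway_id")
        .agg(n_peaks=("peak_id", "nunique"), n_compounds=("compound_id", "nunique"))
        .reset_index()
        .sort_values("pathway_id", kind="mergesort")
        .reset_index(drop=True)
    )
    return rows, counts
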