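"""Reading and writing the study file formats.

Input is always a processed peak x sample study: three tables (intensities,
sample metadata, peak annotation) supplied as delimited text files, as
sheets of one spreadsheet workbook, or — as in typical formula-assignment
tool exports — a single combined sheet holding masses, per-sample
intensities and element counts side by side.  Which columns play which role
is declared in a small YAML/JSON config rather than guessed.

Config keys
-----------
``peak_id``, ``sample_id`` (required); ``formula`` or ``elements`` (mapping
element symbol -> column); optional ``isotope`` (``{column, symbol}``),
``mass``, ``sample_columns`` (for combined single-sheet layouts) and
``sheets`` (``{e_data, f_data, e_meta}`` sheet names for workbooks).
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Any, Mapping

import pandas as pd
import yaml

from .dataset import PeakDataset, build_dataset

__all__ = [
    "load_config",
    "read_study_tables",
    "read_dataset",
    "write_outputs",
]

_TABLE_NAMES = ("e_data", "f_data", "e_meta")


def load_config(source: str | Mapping) -> dict:
    """Load and validate a column-role config from a mapping or YAML/JSON file."""
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh.read())
    for key in ("peak_id", "sample_id"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    if "formula" not in cfg and "elements" not in cfg:
        raise ValueError("config needs a formula column or an elements mapping")
    return cfg


def _read_delimited(path: str) -> pd.DataFrame:
    # sniff comma/tab unless the extension already says
    if path.endswith(".tsv"):
        return pd.read_csv(path, sep="\t")
    if path.endswith(".csv"):
        return pd.read_csv(path)
    return pd.read_csv(path, sep=None, engine="python")


def _check_columns(df: pd.DataFrame, wanted: list[str], where: str) -> None:
    missing = [c for c in wanted if c and c not in df.columns]
    if missing:
        raise ValueError(f"{where}: declared columns not found: {missing}")


def read_study_tables(
    source: str | Mapping[str, str], config: str | Mapping
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Read the three study tables from files or a workbook.

    ``source`` may be a mapping ``{e_data: path, f_data: path, e_meta: path}``,
    a directory containing files of those names (csv/tsv), a multi-sheet
    ``.xlsx`` workbook, or a single-sheet workbook/file with the combined
    layout (then ``config`` must name the annotation columns; every other
    non-key column is treated as a sample, and a minimal sample table is
    synthesized unless ``sample_columns`` narrows the choice).

    Returns ``(e_data, f_data, e_meta, config)`` ready for
    :func:`~ftmspeaks.dataset.build_dataset`.
    """
    cfg = load_config(config)
    peak_id, sample_id = cfg["peak_id"], cfg["sample_id"]

    tables: dict[str, pd.DataFrame] = {}
    if isinstance(source, Mapping):
        for name in _TABLE_NAMES:
            if name not in source:
                raise ValueError(f"source mapping missing {name!r}")
            tables[name] = _read_delimited(source[name])
    elif os.path.isdir(source):
        for name in _TABLE_NAMES:
            for ext in ("csv", "tsv", "txt"):
                p = os.path.join(source, f"{name}.{ext}")
                if os.path.exists(p):
                    tables[name] = _read_delimited(p)
                    break
            else:
                raise FileNotFoundError(f"no {name}.csv/.tsv/.txt in {source}")
    elif str(source).endswith((".xlsx", ".xls")):
        sheets = pd.read_excel(source, sheet_name=None)
        names = cfg.get("sheets", {})
        resolved = {}
        for name in _TABLE_NAMES:
            wanted = names.get(name, name)
            if wanted in sheets:
                resolved[name] = sheets[wanted]
        if len(resolved) == 3:
            tables = resolved
        elif len(sheets) == 1:
            tables = _split_combined(next(iter(sheets.values())), cfg)
        else:
            raise ValueError(
                f"workbook sheets {sorted(sheets)} do not match expected "
                f"{_TABLE_NAMES}; declare names under config['sheets']"
            )
    else:
        # single combined delimited file
        tables = _split_combined(_read_delimited(source), cfg)

    e_data, f_data, e_meta = tables["e_data"], tables["f_data"], tables["e_meta"]
    _check_columns(e_data, [peak_id], "e_data")
    _check_columns(f_data, [sample_id], "f_data")
    ann_cols = [peak_id]
    if "formula" in cfg:
        ann_cols.append(cfg["formula"])
    ann_cols += list(cfg.get("elements", {}).values())
    if cfg.get("isotope"):
        ann_cols.append(cfg["isotope"]["column"])
    if cfg.get("mass"):
        ann_cols.append(cfg["mass"])
    _check_columns(e_meta, ann_cols, "e_meta")
    return e_data, f_data, e_meta, cfg


def _split_combined(df: pd.DataFrame, cfg: dict) -> dict[str, pd.DataFrame]:
    """Split a combined single-sheet layout into the three tables."""
    peak_id, sample_id = cfg["peak_id"], cfg["sample_id"]
    if peak_id not in df.columns:
        raise ValueError(f"combined table: peak id column {peak_id!r} not found")
    ann_cols = [peak_id]
    if "formula" in cfg and cfg["formula"] in df.columns:
        ann_cols.append(cfg["formula"])
    for col in cfg.get("elements", {}).values():
        if col in df.columns:
            ann_cols.append(col)
    if cfg.get("isotope") and cfg["isotope"]["column"] in df.columns:
        ann_cols.append(cfg["isotope"]["column"])
    if cfg.get("mass") and cfg["mass"] in df.columns:
        ann_cols.append(cfg["mass"])
    if "sample_columns" in cfg:
        sample_cols = list(cfg["sample_columns"])
        _check_columns(df, sample_cols, "combined table")
    else:
        sample_cols = [c for c in df.columns if c not in ann_cols]
    if not sample_cols:
        raise ValueError("combined table: no sample columns left after annotation columns")
    return {
        "e_data": df[[peak_id] + sample_cols],
        "f_data": pd.DataFrame({sample_id: sample_cols}),
        "e_meta": df[ann_cols],
    }


def read_dataset(source, config) -> PeakDataset:
    """Read the three tables and assemble a validated dataset."""
    e_data, f_data, e_meta, cfg = read_study_tables(source, config)
    iso = cfg.get("isotope") or {}
    return build_dataset(
        e_data, f_data, e_meta,
        peak_id=cfg["peak_id"],
        sample_id=cfg["sample_id"],
        formula=cfg.get("formula"),
        elements=cfg.get("elements"),
        isotope=iso.get("column"),
        isotope_symbol=iso.get("symbol"),
        mass=cfg.get("mass"),
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "as_dict"):
            return _jsonable(obj.as_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_outputs(obj, path: str, format: str | None = None) -> list[str]:
    """Write tables, datasets or reports to disk; returns the paths written.

    * ``PeakDataset`` -> a directory of ``e_data``/``f_data``/``e_meta``
      delimited files plus a ``config.yaml``, or a 3-sheet workbook when
      ``format="xlsx"``; the output re-reads losslessly with
      :func:`read_dataset`.
    * ``DataFrame`` -> csv/tsv/xlsx chosen from ``format`` or the extension.
    * anything else (reports, summaries, dicts) -> JSON.
    """
    if isinstance(obj, PeakDataset):
        e_data = obj.intensities.reset_index(names="peak_id")
        f_data = obj.sample_table.reset_index(names="sample_id")
        e_meta = obj.annotation.reset_index(names="peak_id")
        cfg = {
            "peak_id": "peak_id",
            "sample_id": "sample_id",
            "formula": "formula",
            "isotope": {"column": "isotope", "symbol": "True"},
            "mass": "mass",
        }
        if format == "xlsx" or str(path).endswith(".xlsx"):
            with pd.ExcelWriter(path) as xw:
                e_data.to_excel(xw, sheet_name="e_data", index=False)
                f_data.to_excel(xw, sheet_name="f_data", index=False)
                e_meta.to_excel(xw, sheet_name="e_meta", index=False)
            return [path]
        os.makedirs(path, exist_ok=True)
        sep = "\t" if format == "tsv" else ","
        ext = "tsv" if format == "tsv" else "csv"
        written = []
        for name, df in (("e_data", e_data), ("f_data", f_data), ("e_meta", e_meta)):
            p = os.path.join(path, f"{name}.{ext}")
            df.to_csv(p, sep=sep, index=False)
            written.append(p)
        cfg_path = os.path.join(path, "config.yaml")
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(cfg, fh)
        return written + [cfg_path]

    if isinstance(obj, pd.DataFrame):
        fmt = format or os.path.splitext(path)[1].lstrip(".") or "csv"
        if fmt == "xlsx":
            obj.to_excel(path, index=False)
        else:
            obj.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)
        return [path]

    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, default=str)
        fh.write("\n")
    return [path]
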