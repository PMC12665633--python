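"""Shared data model and table I/O for mesocosm experiments.

The canonical on-disk layout is a directory of tidy CSV files, one table per
file (``tanks.csv``, ``chemistry.csv``, ``amphipods.csv``, ``tadpoles.csv``,
``algae_counts.csv``, ``chlorophyll.csv``, ``stress.csv``).  A supplementary
spreadsheet layout is supported through a sheet-mapping configuration because
published workbooks rarely share a fixed schema.

Concentration conventions: every tank carries its nominal diquat
concentration and its treatment-group mean measured 1-h concentration
(``initial_measured_conc``); analyses use the measured group mean by default.
Below-detection chemistry values are stored at the detection limit with a
censoring flag, never as zero, so downstream steps choose their own handling.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_SCHEMAS",
    "Dataset",
    "ValidationReport",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "write_results",
]

#: mandatory columns per table
TABLE_SCHEMAS: dict[str, list[str]] = {
    "tanks": ["tank_id", "block", "nominal_conc", "initial_measured_conc"],
    "chemistry": ["tank_id", "day", "analyte", "value", "below_detection", "detection_limit"],
    "amphipods": ["tank_id", "cage_id", "week", "n_atrisk", "n_alive", "n_juveniles", "wet_mass_mg"],
    "tadpoles": ["tank_id", "tadpole_id", "survived", "gosner_stage", "days_elapsed",
                 "wet_mass_g", "liver_mass_g", "sex"],
    "algae": ["tank_id", "day", "taxon", "count", "biomass_mg_m3"],
    "chlorophyll": ["tank_id", "day", "chl_a_ug_L"],
    "stress": ["tank_id", "hne_ug_g", "protein_carbonyl_nmol_mg"],
}

_FILENAMES = {
    "tanks": "tanks.csv",
    "chemistry": "chemistry.csv",
    "amphipods": "amphipods.csv",
    "tadpoles": "tadpoles.csv",
    "algae": "algae_counts.csv",
    "chlorophyll": "chlorophyll.csv",
    "stress": "stress.csv",
}

#: default nominal treatment levels (µg/L diquat)
DEFAULT_NOMINAL_LEVELS = (0.0, 74.0, 147.0, 291.0, 579.0, 1153.0)

#: reporting detection limit for diquat in water (µg/L)
DETECTION_LIMIT_UG_L = 5.0


class SchemaError(ValueError):
    """A mandatory column is missing or a table cannot be parsed."""


@dataclass
class Dataset:
    """Container of tidy experiment tables keyed by ``tank_id``."""

    tanks: pd.DataFrame
    chemistry: pd.DataFrame
    amphipods: pd.DataFrame
    tadpoles: pd.DataFrame
    algae: pd.DataFrame
    chlorophyll: pd.DataFrame
    stress: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    def conc_for_tank(self, which: str = "initial_measured_conc") -> pd.Series:
        """Concentration label per tank (measured group mean by default)."""
        return self.tanks.set_index("tank_id")[which]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_records: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_SCHEMAS[name]})


def _check_columns(name: str, df: pd.DataFrame) -> None:
    missing = [c for c in TABLE_SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{name}' is missing mandatory column(s): {', '.join(missing)}")


def read_dataset(path: str | Path, layout: str = "csv_dir",
                 sheet_map: Mapping[str, str] | str | Path | None = None) -> Dataset:
    """Read an experiment dataset from disk.

    Parameters
    ----------
    path:
        Directory of CSV tables (``layout="csv_dir"``) or an XLSX workbook
        (``layout="supplementary_xlsx"``).
    layout:
        Named schema of the on-disk layout.
    sheet_map:
        For the XLSX layout, mapping of table name -> sheet name (or a path
        to a JSON file holding that mapping).  Tables absent from the map are
        returned empty with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("csv_dir", "supplementary_xlsx"):
        raise ValueError(f"unknown layout {layout!r}")

    tables: dict[str, pd.DataFrame] = {}
    warnings: list[str] = []
    if layout == "csv_dir":
        for name, fname in _FILENAMES.items():
            f = path / fname
            if f.exists():
                df = pd.read_csv(f)
                if df.empty and not df.columns.tolist():
                    df = _empty_table(name)
            else:
                df = _empty_table(name)
                warnings.append(f"missing table file {fname}; using empty {name} table")
            _check_columns(name, df)
            tables[name] = df
    else:
        if isinstance(sheet_map, (str, Path)):
            sheet_map = json.loads(Path(sheet_map).read_text())
        sheet_map = dict(sheet_map or {})
        for name in TABLE_SCHEMAS:
            if name in sheet_map:
                df = pd.read_excel(path, sheet_name=sheet_map[name])
                _check_columns(name, df)
            else:
                df = _empty_table(name)
                warnings.append(f"no sheet mapped for table {name}; using empty table")
            tables[name] = df

    for name in ("amphipods", "tadpoles", "algae", "chemistry"):
        if tables[name].empty:
            warnings.append(f"table '{name}' is empty")

    ds = Dataset(**tables, warnings=warnings)
    _coerce_types(ds)
    return ds


def _coerce_types(ds: Dataset) -> None:
    numeric = {
        "tanks": ["nominal_conc", "initial_measured_conc"],
        "chemistry": ["day", "value", "detection_limit"],
        "amphipods": ["week", "n_atrisk", "n_alive", "n_juveniles", "wet_mass_mg"],
        "tadpoles": ["gosner_stage", "days_elapsed", "wet_mass_g", "liver_mass_g"],
        "algae": ["day", "count", "biomass_mg_m3"],
        "chlorophyll": ["day", "chl_a_ug_L"],
        "stress": ["hne_ug_g", "protein_carbonyl_nmol_mg"],
    }
    for name, cols in numeric.items():
        df = getattr(ds, name)
        for c in cols:
            if not df.empty:
                df[c] = pd.to_numeric(df[c], errors="coerce")
    if not ds.chemistry.empty:
        ds.chemistry["below_detection"] = ds.chemistry["below_detection"].astype(bool)
    if not ds.tadpoles.empty:
        ds.tadpoles["survived"] = ds.tadpoles["survived"].astype(bool)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, str]:
    """Write all tables as tidy CSVs. Returns ``{table: filename}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in ds.tables().items():
        f = out_dir / _FILENAMES[name]
        df.to_csv(f, index=False)
        written[name] = f.name
    return written


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Apply all type invariants. Violations are data, not exceptions."""
    rep = ValidationReport()
    rep.warnings.extend(ds.warnings)
    for name, df in ds.tables().items():
        rep.n_records[name] = len(df)

    tk = ds.tanks
    if tk.empty:
        rep.errors.append("tanks: table is empty")
        return rep
    if tk["tank_id"].duplicated().any():
        dup = tk.loc[tk["tank_id"].duplicated(), "tank_id"].tolist()
        rep.errors.append(f"tanks: duplicate tank_id rows: {dup}")
    if (tk["nominal_conc"] < 0).any():
        rep.errors.append("tanks: negative nominal_conc")
    n_levels = tk["nominal_conc"].nunique()
    if n_levels != 6:
        rep.warnings.append(f"tanks: expected 6 treatment levels, found {n_levels}")
    known = set(tk["tank_id"])

    def _fk(name: str, df: pd.DataFrame) -> None:
        if df.empty:
            return
        bad = sorted(set(df["tank_id"]) - known)
        if bad:
            rep.errors.append(f"{name}: tank_id not in tanks table: {bad}")

    for name in ("chemistry", "amphipods", "tadpoles", "algae", "chlorophyll", "stress"):
        _fk(name, getattr(ds, name))

    am = ds.amphipods
    if not am.empty:
        bad = am["n_alive"] > am["n_atrisk"]
        for idx in am.index[bad]:
            rep.errors.append(f"amphipods: row {idx}: alive>at_risk")
        for col in ("n_atrisk", "n_alive", "n_juveniles"):
            if (am[col].dropna() < 0).any():
                rep.errors.append(f"amphipods: negative {col}")
    td = ds.tadpoles
    if not td.empty:
        for col in ("wet_mass_g", "liver_mass_g"):
            if (td[col].dropna() < 0).any():
                rep.errors.append(f"tadpoles: negative {col}")
        bad_sex = set(td["sex"].dropna()) - {"F", "M", "unknown"}
        if bad_sex:
            rep.errors.append(f"tadpoles: unexpected sex categories {sorted(bad_sex)}")
    ch = ds.chemistry
    if not ch.empty:
        if (ch["value"].dropna() < 0).any():
            rep.errors.append("chemistry: negative value")
        cen = ch["below_detection"].astype(bool)
        mismatch = cen & (ch["value"] != ch["detection_limit"])
        if mismatch.any():
            rep.errors.append("chemistry: below_detection rows must carry value = detection_limit")
    al = ds.algae
    if not al.empty and (al["count"].dropna() < 0).any():
        rep.errors.append("algae: negative count")
    return rep


def _versions() -> dict[str, str]:
    import scipy
    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def write_results(bundle: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: Mapping | None = None, seed: int | None = None) -> dict:
    """Write result tables as TSVs plus a JSON run manifest.

    Numeric output uses ``repr``-round-trippable formatting so re-running with
    identical config and seeds reproduces byte-identical tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": {}, "seed": seed, "versions": _versions()}
    if config is not None:
        cfg_json = json.dumps(config, sort_keys=True, default=str)
        manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    for name, df in bundle.items():
        fname = f"{name}.tsv"
        f = out_dir / fname
        df.to_csv(f, sep="\t", index=False, float_format="%.10g")
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        manifest["tables"][name] = {"file": fname, "sha256": digest, "n_rows": len(df)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
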