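"""Reading, validation and writing of the inventory tables.

Four delimited text tables make up a dataset bundle:

``plots``    plot_id, ecoregion_id, slope, altitude, temp_seasonality,
             precip_seasonality, area_ha
``stems``    plot_id, subplot (1-9), species_id, dbh (cm), height (m)
``soil``     plot_id, layer_index (1-5), top_cm, bottom_cm, gravel_frac,
             bulk_density (g/cm^3), organic_c (g/kg), thickness (cm)
``species``  species_id, strategy {EcM, AM, dual, other}, seral_status
             {pioneer, climax, neither}, eight leaf traits (Cmass, Nmass,
             Pmass, Kmass, LA, SLA, LMA, LDMC; missing cells allowed)

Comma is the default delimiter; tab is accepted. Units are fixed at the
schema level - no auto-detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TRAIT_NAMES
from .errors import ReferentialIntegrityError, SchemaError

log = logging.getLogger("mycoforest")

STRATEGIES = {"EcM", "AM", "dual", "other"}
SERAL_STATUSES = {"pioneer", "climax", "neither"}

#: required columns per table (traits may be missing-valued but must exist)
SCHEMAS: dict[str, list[str]] = {
    "plots": ["plot_id", "ecoregion_id", "slope", "altitude",
              "temp_seasonality", "precip_seasonality", "area_ha"],
    "stems": ["plot_id", "subplot", "species_id", "dbh", "height"],
    "soil": ["plot_id", "layer_index", "top_cm", "bottom_cm",
             "gravel_frac", "bulk_density", "organic_c", "thickness"],
    "species": ["species_id", "strategy", "seral_status", *TRAIT_NAMES],
}

_NUMERIC = {
    "plots": ["slope", "altitude", "temp_seasonality", "precip_seasonality", "area_ha"],
    "stems": ["subplot", "dbh", "height"],
    "soil": ["layer_index", "top_cm", "bottom_cm", "gravel_frac",
             "bulk_density", "organic_c", "thickness"],
    "species": list(TRAIT_NAMES),
}


@dataclass
class ValidationReport:
    """Collected validation problems; empty means the bundle is clean."""

    problems: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.problems.append(msg)

    @property
    def ok(self) -> bool:
        return not self.problems

    def raise_if_failed(self) -> None:
        if self.problems:
            raise SchemaError("validation failed:\n" + "\n".join(self.problems))


@dataclass
class Dataset:
    """In-memory bundle of the four inventory tables."""

    plots: pd.DataFrame
    stems: pd.DataFrame
    soil: pd.DataFrame
    species: pd.DataFrame

    def copy(self) -> "Dataset":
        return Dataset(self.plots.copy(), self.stems.copy(),
                       self.soil.copy(), self.species.copy())


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing required column(s): {missing}")


def _coerce_numeric(df: pd.DataFrame, table: str, report: ValidationReport) -> pd.DataFrame:
    df = df.copy()
    for col in _NUMERIC[table]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            report.add(f"{table}.{col}: {int(newly_bad.sum())} non-numeric value(s)")
        df[col] = coerced
    return df


def validate_dataset(ds: Dataset, gravel_percent: bool = False) -> ValidationReport:
    """Check bounds, layer geometry and referential integrity.

    With ``gravel_percent`` the soil gravel column is interpreted as 0-100
    and divided by 100 in place before the [0, 1] bound is enforced.
    """
    report = ValidationReport()
    if gravel_percent:
        ds.soil["gravel_frac"] = ds.soil["gravel_frac"] / 100.0

    s = ds.stems
    if ((s["dbh"] <= 0) | s["dbh"].isna()).any():
        report.add("stems.dbh: non-positive or missing values")
    if ((s["height"] <= 0) | s["height"].isna()).any():
        report.add("stems.height: non-positive or missing values")
    if (~s["subplot"].isin(range(1, 10))).any():
        report.add("stems.subplot: values outside 1..9")

    unknown = set(s["species_id"]) - set(ds.species["species_id"])
    if unknown:
        raise ReferentialIntegrityError(
            f"stems reference unknown species_id(s): {sorted(unknown)[:10]}"
        )

    bad_strat = set(ds.species["strategy"]) - STRATEGIES
    if bad_strat:
        report.add(f"species.strategy: unknown categories {sorted(bad_strat)}")
    bad_seral = set(ds.species["seral_status"]) - SERAL_STATUSES
    if bad_seral:
        report.add(f"species.seral_status: unknown categories {sorted(bad_seral)}")
    for t in TRAIT_NAMES:
        if (ds.species[t] <= 0).any():
            report.add(f"species.{t}: non-positive trait values")

    so = ds.soil
    if ((so["gravel_frac"] < 0) | (so["gravel_frac"] > 1)).any():
        report.add("soil.gravel_frac: values outside [0, 1]")
    if (so["bulk_density"] <= 0).any():
        report.add("soil.bulk_density: non-positive values")
    if (so["organic_c"] < 0).any():
        report.add("soil.organic_c: negative values")
    thick = so["bottom_cm"] - so["top_cm"]
    if ((thick <= 0) | ((so["thickness"] - thick).abs() > 1e-6)).any():
        report.add("soil: thickness must equal bottom_cm - top_cm and be > 0")
    for plot_id, grp in so.sort_values("top_cm").groupby("plot_id"):
        g = grp.drop_duplicates("layer_index")
        if (g["top_cm"].to_numpy()[1:] < g["bottom_cm"].to_numpy()[:-1]).any():
            report.add(f"soil: overlapping layers in plot {plot_id}")

    if (ds.plots["area_ha"] <= 0).any():
        report.add("plots.area_ha: non-positive values")
    return report


def read_tables(paths: dict[str, str | Path] | str | Path, *, sep: str | None = None,
                gravel_percent: bool = False, strict: bool = True) -> Dataset:
    """Read and validate a dataset bundle.

    ``paths`` is either a directory containing plots/stems/soil/species CSVs
    or a mapping table-name -> path. ``sep=None`` sniffs comma vs tab from
    the header line.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {t: base / f"{t}.csv" for t in SCHEMAS}
    frames = {}
    report = ValidationReport()
    for table in SCHEMAS:
        path = Path(paths[table])
        if not path.exists():
            raise SchemaError(f"missing input file for table {table!r}: {path}")
        use_sep = sep
        if use_sep is None:
            header = path.open().readline()
            use_sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=use_sep)
        _check_columns(df, table)
        frames[table] = _coerce_numeric(df, table, report)
        log.info("read %s: %d rows", path.name, len(df))
    ds = Dataset(**frames)
    vrep = validate_dataset(ds, gravel_percent=gravel_percent)
    report.problems.extend(vrep.problems)
    if strict:
        report.raise_if_failed()
    return ds


def write_tables(ds: Dataset, out_dir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write the bundle as four delimited text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for table in SCHEMAS:
        df: pd.DataFrame = getattr(ds, table)
        path = out / f"{table}.csv"
        df.to_csv(path, sep=sep, index=False)
        written[table] = path
        log.info("wrote %s: %d rows", path.name, len(df))
    return written


def apply_stem_filter(stems: pd.DataFrame, min_dbh: float = 3.0) -> pd.DataFrame:
    """Keep only stems with DBH >= 3 cm (the inventory inclusion rule)."""
    kept = stems[stems["dbh"] >= min_dbh]
    log.info("stem filter (dbh >= %g cm): removed %d of %d stems",
             min_dbh, len(stems) - len(kept), len(stems))
    return kept


def apply_strategy_exclusion(stems: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Restrict stems to EcM/AM/dual species for the dominance calculation.

    Species with other strategies (ericoid, non-mycorrhizal) are excluded
    from the dominance numerator and denominator only; by default their
    stems still count toward tree carbon and richness.
    """
    strat = stems["species_id"].map(species.set_index("species_id")["strategy"])
    kept = stems[strat.isin(["EcM", "AM", "dual"])]
    n_removed = len(stems) - len(kept)
    log.info("strategy exclusion: removed %d stem(s) of other strategies", n_removed)
    if len(kept) == 0 and len(stems) > 0:
        log.warning("strategy exclusion removed every stem; dominance is undefined")
    return kept
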