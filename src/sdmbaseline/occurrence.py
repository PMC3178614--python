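"""Presence-only occurrence records: loading, quality filtering, grid snapping.

Records follow Darwin-Core-style fields (species, decimal coordinates,
coordinate uncertainty in meters, collection year, voucher flag).  The
quality filters mirror common museum-record practice for distribution
modelling: drop records whose georeferencing error radius exceeds the grid
resolution (default 1 km), records collected before the climate-normal era
(default 1950), and, optionally, records without a preserved voucher
specimen.  Records with an unknown year or unknown uncertainty fail the
corresponding rule: precision or temporal congruence cannot be certified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layers import GridSpec, RegionMask

__all__ = [
    "OccurrenceSet",
    "CellOccurrences",
    "SpeciesPool",
    "FilterReport",
    "DEFAULT_SCHEMA",
    "load_occurrences",
    "filter_records",
    "snap_and_deduplicate",
    "assemble_species_pool",
]

#: Default column map: internal field -> source column name.
DEFAULT_SCHEMA: dict[str, str] = {
    "species_id": "species",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "uncertainty_m": "coordinateUncertaintyInMeters",
    "year": "year",
    "vouchered": "vouchered",
    "source_id": "source_id",
}

_REQUIRED = ("species_id", "lat", "lon")

_COLUMNS = ["species_id", "lon", "lat", "uncertainty_m", "year", "vouchered", "source_id"]


class SchemaError(ValueError):
    """A mapped column is absent from the source table."""


@dataclass
class OccurrenceSet:
    """Ordered occurrence records plus an append-only provenance log.

    ``records`` is a DataFrame with columns species_id, lon, lat,
    uncertainty_m (meters, NaN = unknown), year (nullable integer),
    vouchered (bool), source_id.
    """

    records: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    def with_log_entry(self, records: pd.DataFrame, entry: dict) -> "OccurrenceSet":
        return OccurrenceSet(records, self.log + [entry])

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class CellOccurrences:
    """A species' presences collapsed to unique grid cells."""

    species_id: str
    cell_ids: frozenset[int]
    n_records_raw: int

    def __post_init__(self) -> None:
        if len(self.cell_ids) > self.n_records_raw:
            raise ValueError("more unique cells than raw records")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class FilterReport:
    """Counts of records removed by each quality rule.

    Rules are applied conjunctively; each record is charged to every rule
    it violates, so counts may sum to more than ``n_removed``.
    """

    n_input: int
    n_retained: int
    removed_uncertainty: int
    removed_year: int
    removed_unvouchered: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "removed_uncertainty": self.removed_uncertainty,
            "removed_year": self.removed_year,
            "removed_unvouchered": self.removed_unvouchered,
        }


def _normalize_species(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.replace(r"\s+", " ", regex=True).str.casefold()


def load_occurrences(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> OccurrenceSet:
    """Read a delimited occurrence table into an :class:`OccurrenceSet`.

    ``schema`` maps internal field names to source column names (defaults
    to Darwin-Core-ish names, :data:`DEFAULT_SCHEMA`).  Rows whose
    coordinates cannot be parsed or fall outside valid lon/lat ranges are
    dropped and counted in the provenance log.  A missing mandatory column
    raises :class:`SchemaError`; an empty file yields an empty set with a
    warning.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema field(s): {sorted(unknown)}")
        colmap.update(schema)

    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty:
        warnings.warn(f"{path}: no occurrence rows", stacklevel=2)

    # fall back to internal field names so package-written CSVs round-trip
    for fld in _COLUMNS:
        if colmap[fld] not in raw.columns and fld in raw.columns:
            colmap[fld] = fld
    for fld in _REQUIRED:
        if colmap[fld] not in raw.columns:
            raise SchemaError(f"mandatory column {colmap[fld]!r} (field {fld}) not found")

    df = pd.DataFrame(index=raw.index)
    df["species_id"] = _normalize_species(raw[colmap["species_id"]])
    df["lon"] = pd.to_numeric(raw[colmap["lon"]], errors="coerce")
    df["lat"] = pd.to_numeric(raw[colmap["lat"]], errors="coerce")
    for fld, dtype in (("uncertainty_m", float), ("year", "Int64")):
        col = colmap[fld]
        if col in raw.columns:
            df[fld] = pd.to_numeric(raw[col], errors="coerce")
            if dtype == "Int64":
                df[fld] = df[fld].round().astype("Int64")
        else:
            df[fld] = pd.Series([np.nan] * len(raw), dtype="float64" if dtype is float else "Int64")
    if colmap["vouchered"] in raw.columns:
        df["vouchered"] = (
            raw[colmap["vouchered"]].astype(str).str.strip().str.lower()
            .isin(("1", "true", "t", "yes", "y"))
        )
    else:
        df["vouchered"] = True
    df["source_id"] = (
        raw[colmap["source_id"]] if colmap["source_id"] in raw.columns else ""
    )

    bad_coord = (
        df["lon"].isna() | df["lat"].isna()
        | (df["lon"] < -180) | (df["lon"] > 180)
        | (df["lat"] < -90) | (df["lat"] > 90)
    )
    n_bad = int(bad_coord.sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} row(s) with unparseable or "
                      "out-of-range coordinates", stacklevel=2)
    if (df.loc[~bad_coord, "uncertainty_m"] < 0).any():
        raise ValueError("negative coordinate uncertainty encountered")
    records = df.loc[~bad_coord].reset_index(drop=True)
    log = [{"op": "load", "path": str(path), "n_rows": len(raw),
            "n_loaded": len(records), "n_dropped_bad_coordinates": n_bad}]
    return OccurrenceSet(records, log)


def filter_records(
    occ: OccurrenceSet,
    max_uncertainty_km: float = 1.0,
    min_year: int = 1950,
    vouchered_only: bool = True,
) -> tuple[OccurrenceSet, FilterReport]:
    """Apply the three record-quality rules and report per-rule removals.

    A record is retained iff its uncertainty radius is known and at most
    ``max_uncertainty_km`` * 1000 m, its collection year is known and at
    least ``min_year``, and (when ``vouchered_only``) it is vouchered.
    The rules commute, and the filter is idempotent.
    """
    if not max_uncertainty_km > 0:
        raise ValueError("max_uncertainty_km must be positive")
    df = occ.records
    ok_unc = df["uncertainty_m"].notna() & (df["uncertainty_m"] <= max_uncertainty_km * 1000.0)
    ok_year = df["year"].notna() & (df["year"] >= min_year)
    ok_vouch = df["vouchered"].astype(bool) if vouchered_only else pd.Series(True, index=df.index)
    keep = ok_unc & ok_year.fillna(False).astype(bool) & ok_vouch
    report = FilterReport(
        n_input=len(df),
        n_retained=int(keep.sum()),
        removed_uncertainty=int((~ok_unc).sum()),
        removed_year=int((~ok_year.fillna(False).astype(bool)).sum()),
        removed_unvouchered=int((~ok_vouch).sum()),
    )
    entry = {"op": "filter", "max_uncertainty_km": max_uncertainty_km,
             "min_year": min_year, "vouchered_only": vouchered_only,
             **report.as_dict()}
    return occ.with_log_entry(df.loc[keep].reset_index(drop=True), entry), report


def snap_and_deduplicate(occ: OccurrenceSet, grid: GridSpec) -> dict[str, CellOccurrences]:
    """Snap records to grid cells and collapse duplicates within a cell.

    Returns a mapping species_id -> :class:`CellOccurrences`.  Records
    outside the grid are dropped with a warning, never silently.
    """
    df = occ.records
    row, col = grid.rowcol_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    row = np.atleast_1d(row)
    col = np.atleast_1d(col)
    inside = row >= 0
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} record(s) fall outside the analysis grid and "
                      "were dropped", stacklevel=2)
    cells = np.asarray(grid.cell_id(row, col))
    out: dict[str, CellOccurrences] = {}
    sub = pd.DataFrame({"species_id": df["species_id"].to_numpy()[inside],
                        "cell": cells[inside]})
    for sp, grp in sub.groupby("species_id", sort=True):
        out[str(sp)] = CellOccurrences(
            species_id=str(sp),
            cell_ids=frozenset(int(c) for c in grp["cell"].unique()),
            n_records_raw=len(grp),
        )
    return out


ELIGIBLE_HABITATS = frozenset({"freshwater", "freshwater-estuarine"})

#: Minimum unique occupied cells for a species to be modelled.
MIN_UNIQUE_CELLS = 10


@dataclass
class SpeciesPool:
    """Candidate species for modelling: in-basin, eligible habitat class."""

    entries: pd.DataFrame  # columns: species_id, native, habitat_class, in_basin

    @property
    def members(self) -> list[str]:
        m = self.entries
        return sorted(m.loc[m["in_basin"], "species_id"])

    def is_native(self, species_id: str) -> bool:
        row = self.entries.loc[self.entries["species_id"] == species_id]
        if row.empty:
            raise KeyError(species_id)
        return bool(row["native"].iloc[0])


def assemble_species_pool(
    occ: OccurrenceSet,
    basin_mask: RegionMask,
    habitat_table: Mapping[str, str],
    native_table: Mapping[str, bool],
) -> SpeciesPool:
    """Build the basin species pool from records and habitat classes.

    A species enters the pool iff it has at least one record inside
    ``basin_mask`` and its habitat class is freshwater or
    freshwater-estuarine (marine and strictly estuarine species are
    excluded).  Non-native species are included, flagged.  Species missing
    from ``habitat_table`` are excluded with a warning.
    """
    habitat = { _norm(k): v for k, v in habitat_table.items() }
    native = { _norm(k): bool(v) for k, v in native_table.items() }
    df = occ.records
    row, col = basin_mask.grid.rowcol_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    row = np.atleast_1d(row)
    col = np.atleast_1d(col)
    inside_grid = row >= 0
    in_basin = np.zeros(len(df), dtype=bool)
    in_basin[inside_grid] = basin_mask.values[row[inside_grid], col[inside_grid]]

    rows = []
    for sp in sorted(df["species_id"].unique()):
        sp = str(sp)
        if sp not in habitat:
            warnings.warn(f"species {sp!r} has no habitat classification; excluded",
                          stacklevel=2)
            continue
        hab = habitat[sp]
        has_basin_record = bool(in_basin[(df["species_id"] == sp).to_numpy()].any())
        rows.append({
            "species_id": sp,
            "native": native.get(sp, True),
            "habitat_class": hab,
            "in_basin": has_basin_record and hab in ELIGIBLE_HABITATS,
        })
    return SpeciesPool(pd.DataFrame(rows, columns=["species_id", "native",
                                                   "habitat_class", "in_basin"]))


def _norm(name: str) -> str:
    return " ".join(str(name).split()).casefold()
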