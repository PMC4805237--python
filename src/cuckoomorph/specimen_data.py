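"""Specimen measurement tables: schema, I/O, taxon-to-region mapping, filtering.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per museum specimen and the columns in :data:`COLUMNS`.  A row records three
bill measurements in mm (length from the anterior edge of the nares to the
tip, width and depth at the nares, to 0.1 mm) and four ordinal ventral color
scores (chin, breast, belly, vent) on a configurable darkness scale
(default 0 = lightest ... 5 = darkest).  Quality-control marks accumulate in a
semicolon-joined ``flags`` column; values are never imputed — downstream
stages apply explicit complete-case filtering via :func:`complete_cases`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Geographic regions, ordered clockwise around the Caribbean basin.
REGIONS = (
    "florida_bahamas",
    "greater_antilles",
    "antigua_barbuda",
    "lesser_antilles",
    "south_america",
    "middle_america",
)

#: The twelve named subspecies and the region each occupies.
TAXON_REGION_MAP: dict[str, str] = {
    "maynardi": "florida_bahamas",       # Florida, Bahamas
    "caymanensis": "greater_antilles",   # Cayman Islands
    "nesiotes": "greater_antilles",
    "teres": "greater_antilles",         # Greater Antilles except Jamaica/Cuba
    "rileyi": "antigua_barbuda",         # Barbuda, Antigua
    "dominicae": "lesser_antilles",      # Montserrat, Guadeloupe, Dominica
    "vincentis": "lesser_antilles",      # Martinique, St. Lucia, St. Vincent
    "grenadensis": "lesser_antilles",    # Grenada, Grenadines
    "minor": "south_america",            # northern South America
    "continentalis": "middle_america",   # Caribbean slope of Middle America
    "palloris": "middle_america",        # Pacific slope of Middle America
    "abbotti": "middle_america",         # Providencia, San Andres
}

SUBSPECIES = tuple(TAXON_REGION_MAP)

#: Museum series size per subspecies (274 specimens in total).
SPECIMEN_COUNTS: dict[str, int] = {
    "abbotti": 10,
    "caymanensis": 25,
    "continentalis": 18,
    "dominicae": 27,
    "grenadensis": 21,
    "maynardi": 32,
    "minor": 8,
    "nesiotes": 30,
    "palloris": 30,
    "rileyi": 23,
    "teres": 27,
    "vincentis": 23,
}

BILL_TRAITS = ("bill_length_mm", "bill_width_mm", "bill_depth_mm")
COLOR_TRAITS = ("color_chin", "color_breast", "color_belly", "color_vent")

#: Bill measurements above this are treated as recording errors (mm).
BILL_SANITY_CAP_MM = 50.0

#: Default ordinal support for color scores (inclusive).
DEFAULT_COLOR_RANGE = (0, 5)

COLUMNS = (
    "specimen_id",
    "repository",
    "subspecies",
    "region",
    "locale",
    "sex",
    "collection_date",
    *BILL_TRAITS,
    *COLOR_TRAITS,
    "flags",
)

REQUIRED_COLUMNS = ("specimen_id", "subspecies", *BILL_TRAITS)

SEXES = ("male", "female", "unknown")


class SchemaError(ValueError):
    """A required column is absent (after applying the column mapping)."""


class EmptyInputError(ValueError):
    """The input table holds no specimen rows."""


class UnknownSubspeciesError(KeyError):
    """A subspecies label is not one of the twelve named forms."""


@dataclass
class SpecimenRecord:
    """One museum specimen.

    ``bill_*`` fields are mm; ``color_*`` fields are ordinal darkness scores.
    Missing numeric values are ``None``; QC marks accumulate in ``flags``.
    """

    specimen_id: str
    subspecies: str
    repository: str = ""
    region: str = ""
    locale: str = ""
    sex: str = "unknown"
    collection_date: date | None = None
    bill_length_mm: float | None = None
    bill_width_mm: float | None = None
    bill_depth_mm: float | None = None
    color_chin: int | None = None
    color_breast: int | None = None
    color_belly: int | None = None
    color_vent: int | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.region and self.subspecies in TAXON_REGION_MAP:
            self.region = TAXON_REGION_MAP[self.subspecies]


def assign_region(subspecies: str, mapping: Mapping[str, str] | None = None) -> str:
    """Return the geographic region of a named subspecies.

    Total and deterministic over the twelve names; unknown names raise
    :class:`UnknownSubspeciesError` listing the valid labels.
    """
    mapping = TAXON_REGION_MAP if mapping is None else mapping
    try:
        return mapping[subspecies]
    except KeyError:
        raise UnknownSubspeciesError(
            f"unknown subspecies {subspecies!r}; valid names: {sorted(mapping)}"
        ) from None


def _parse_float(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        return np.nan


def _parse_ordinal(value) -> float:
    x = _parse_float(value)
    if np.isnan(x) or x != round(x):
        return np.nan if np.isnan(x) else x  # non-integral handled by range check
    return float(int(round(x)))


def read_specimens(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    color_range: tuple[int, int] = DEFAULT_COLOR_RANGE,
) -> pd.DataFrame:
    """Read a specimen CSV into the canonical table.

    Parameters
    ----------
    path
        CSV file with a header row, one specimen per row.
    schema
        Optional mapping from canonical column names (:data:`COLUMNS`) to the
        names used in the file, for ingesting third-party tables.
    color_range
        Inclusive ordinal support for the color scores.

    Row count is preserved: unparseable numeric cells become missing values
    with a QC flag rather than dropping the row.  Out-of-range bill
    measurements (non-positive or above :data:`BILL_SANITY_CAP_MM`) and color
    scores outside ``color_range`` are flagged and set missing.  The region
    column is derived from the subspecies label when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if raw.empty:
        raise EmptyInputError(f"{path} holds no specimen rows")

    n = len(raw)
    out = pd.DataFrame(index=raw.index)
    flags: list[set[str]] = [set() for _ in range(n)]

    for col in ("specimen_id", "repository", "subspecies", "region", "locale", "sex"):
        out[col] = raw[col].astype(str).str.strip() if col in raw.columns else ""
    out["sex"] = out["sex"].str.lower().where(out["sex"].str.lower().isin(SEXES), "unknown")

    # region from subspecies where not supplied
    derived = out["subspecies"].map(TAXON_REGION_MAP).fillna("")
    out["region"] = out["region"].where(out["region"].isin(REGIONS), derived)

    if "collection_date" in raw.columns:
        out["collection_date"] = _parse_dates(raw["collection_date"])
    else:
        out["collection_date"] = pd.NaT

    for col in BILL_TRAITS:
        vals = raw[col].map(_parse_float).astype(float)
        bad_parse = vals.isna() & (raw[col].astype(str).str.strip() != "")
        out_of_range = vals.notna() & ~((vals > 0) & (vals < BILL_SANITY_CAP_MM))
        for i in np.flatnonzero(bad_parse.to_numpy()):
            flags[i].add(f"unparseable:{col}")
        for i in np.flatnonzero(out_of_range.to_numpy()):
            flags[i].add(f"out_of_range:{col}")
        out[col] = vals.where(~out_of_range).round(1)

    lo, hi = color_range
    for col in COLOR_TRAITS:
        if col not in raw.columns:
            out[col] = np.nan
            continue
        vals = raw[col].map(_parse_ordinal).astype(float)
        bad_parse = vals.isna() & (raw[col].astype(str).str.strip() != "")
        out_of_range = vals.notna() & ~vals.between(lo, hi)
        for i in np.flatnonzero(bad_parse.to_numpy()):
            flags[i].add(f"unparseable:{col}")
        for i in np.flatnonzero(out_of_range.to_numpy()):
            flags[i].add(f"out_of_range:{col}")
        out[col] = vals.where(~out_of_range)

    out["flags"] = [";".join(sorted(f)) for f in flags]
    logger.info("read %d specimens from %s (%d flagged)", n, path, sum(bool(f) for f in flags))
    return out[list(COLUMNS)]


def _parse_dates(col: pd.Series) -> pd.Series:
    """Permissive date parsing: ISO dates or bare years; anything else NaT."""
    s = col.astype(str).str.strip()
    parsed = pd.to_datetime(s, errors="coerce", format="mixed")
    year_only = parsed.isna() & s.str.fullmatch(r"\d{4}")
    parsed.loc[year_only] = pd.to_datetime(s[year_only] + "-01-01")
    return parsed


def write_specimens(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical table as UTF-8 CSV (round-trips with read_specimens)."""
    df = table.copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"]).dt.strftime("%Y-%m-%d")
    for col in BILL_TRAITS:
        df[col] = df[col].round(1)
    df.to_csv(path, index=False, encoding="utf-8")


def complete_cases(
    table: pd.DataFrame, traits: Sequence[str]
) -> tuple[pd.DataFrame, dict]:
    """Keep rows with all named traits present; report who was dropped and why.

    An empty ``traits`` list is a vacuous filter.  An empty result is a
    logged warning, not an error.
    """
    unknown = [t for t in traits if t not in table.columns]
    if unknown:
        raise KeyError(f"unknown trait column(s): {unknown}")
    if not traits:
        return table.copy(), {"n_in": len(table), "n_kept": len(table), "dropped": []}
    mask = table[list(traits)].notna().all(axis=1)
    dropped = [
        (row.specimen_id, [t for t in traits if pd.isna(getattr(row, t))])
        for row in table[~mask].itertuples()
    ]
    kept = table[mask].copy()
    report = {"n_in": len(table), "n_kept": len(kept), "dropped": dropped}
    logger.info("complete_cases on %s: kept %d of %d", list(traits), len(kept), len(table))
    if kept.empty:
        logger.warning("complete_cases removed every row")
    return kept, report


def records(table: pd.DataFrame) -> list[SpecimenRecord]:
    """Materialize table rows as :class:`SpecimenRecord` objects."""
    out = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        cd = d.pop("collection_date", None)
        d["collection_date"] = None if pd.isna(cd) else pd.Timestamp(cd).date()
        d["flags"] = set(filter(None, str(d.get("flags", "") or "").split(";")))
        for k in BILL_TRAITS + COLOR_TRAITS:
            if pd.isna(d.get(k)):
                d[k] = None
        out.append(SpecimenRecord(**d))
    return out


def validate_taxon_region_map(mapping: Mapping[str, str] | None = None) -> None:
    """Assert the structural invariants of a taxon-to-region mapping."""
    mapping = TAXON_REGION_MAP if mapping is None else mapping
    if len(mapping) != 12:
        raise ValueError(f"expected 12 subspecies, got {len(mapping)}")
    uncovered = set(REGIONS) - set(mapping.values())
    if uncovered:
        raise ValueError(f"regions with no subspecies: {sorted(uncovered)}")


def region_counts(table: pd.DataFrame) -> pd.Series:
    """Specimens per region (a partition: sums match per-subspecies counts)."""
    return table["region"].value_counts().reindex(REGIONS, fill_value=0)
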