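"""Read, validate and filter CMS-style facility location tables.

The expected dialect is a plain-text delimited table (comma or tab,
auto-detected) with a header naming a provider-category column and the
coordinate columns ``g_lon`` / ``g_lat``.  Category codes: IRF (inpatient
rehabilitation facility), NH (nursing home), hh_care (home health care),
acute_care (acute care hospital), crit_care (critical access hospital),
hospice, LTCH (long-term care hospital).

Rows with missing or invalid coordinates or unknown category codes are
dropped with a logged warning and counted in the table's provenance.
Coordinates are taken as-is (no re-geocoding); duplicate rows are kept,
since distinct certifications can share an address.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .core import CATEGORIES, LabeledPointSet

logger = logging.getLogger(__name__)

#: Contiguous-US fallback bounding box (used when no state column exists).
CONTIGUOUS_BBOX = {"lon": (-125.0, -66.0), "lat": (24.5, 49.5)}

#: State/territory codes excluded from the contiguous-US subset.
NON_CONTIGUOUS_CODES = frozenset({"AK", "HI", "PR", "VI", "GU", "AS", "MP"})


@dataclass(frozen=True)
class DialectConfig:
    """Column names and delimiter of a facility table."""

    category_col: str = "type"
    lon_col: str = "g_lon"
    lat_col: str = "g_lat"
    state_col: str = "state"  # optional in the file
    id_col: str = "provider_id"  # optional in the file
    sep: str | None = None  # None = auto-detect comma/tab
    categories: tuple[str, ...] = CATEGORIES


@dataclass
class FacilityTable:
    """A validated facility table plus row-accounting provenance.

    ``df`` has canonical columns ``category``, ``lon``, ``lat`` and, when
    present in the source, ``state`` and ``provider_id``.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def census(self) -> dict[str, int]:
        return self.df["category"].value_counts().sort_index().to_dict()

    def to_labeled_point_set(self) -> LabeledPointSet:
        return LabeledPointSet(
            self.df["lon"].to_numpy(float),
            self.df["lat"].to_numpy(float),
            self.df["category"].to_numpy(str),
        )

    def _derive(self, df: pd.DataFrame, **prov) -> "FacilityTable":
        new_prov = dict(self.provenance)
        new_prov.update(prov)
        return FacilityTable(df.reset_index(drop=True), new_prov)


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;|").delimiter
    except csv.Error:
        return ","


def read_facilities(path, dialect: DialectConfig | None = None) -> FacilityTable:
    """Read and validate a facility table.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    the mandatory category/longitude/latitude columns are absent.
    """
    dialect = dialect or DialectConfig()
    path = Path(path)
    sep = dialect.sep or _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [
        c for c in (dialect.category_col, dialect.lon_col, dialect.lat_col)
        if c not in raw.columns
    ]
    if missing:
        raise ValueError(f"{path}: mandatory column(s) missing: {missing}")

    df = pd.DataFrame(
        {
            "category": raw[dialect.category_col].str.strip(),
            "lon": pd.to_numeric(raw[dialect.lon_col], errors="coerce"),
            "lat": pd.to_numeric(raw[dialect.lat_col], errors="coerce"),
        }
    )
    for src, dst in ((dialect.state_col, "state"), (dialect.id_col, "provider_id")):
        if src in raw.columns:
            df[dst] = raw[src].str.strip()

    bad_coord = (
        df["lon"].isna() | df["lat"].isna()
        | (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
    )
    bad_cat = ~df["category"].isin(dialect.categories)
    keep = ~(bad_coord | bad_cat)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d row(s) (%d invalid coordinates, %d unknown category)",
            path, n_dropped, int(bad_coord.sum()), int((bad_cat & ~bad_coord).sum()),
        )
    return FacilityTable(
        df[keep].reset_index(drop=True),
        provenance={
            "source": str(path),
            "n_read": len(raw),
            "n_kept": int(keep.sum()),
            "n_dropped_invalid_coordinates": int(bad_coord.sum()),
            "n_dropped_unknown_category": int((bad_cat & ~bad_coord).sum()),
        },
    )


def write_facilities(
    table: FacilityTable, path, dialect: DialectConfig | None = None
) -> None:
    """Write a facility table back out in the S1-style dialect."""
    dialect = dialect or DialectConfig()
    out = pd.DataFrame(
        {
            dialect.category_col: table.df["category"],
            dialect.lon_col: table.df["lon"],
            dialect.lat_col: table.df["lat"],
        }
    )
    if "state" in table.df.columns:
        out[dialect.state_col] = table.df["state"]
    if "provider_id" in table.df.columns:
        out[dialect.id_col] = table.df["provider_id"]
    out.to_csv(path, sep=dialect.sep or ",", index=False)


def filter_contiguous(table: FacilityTable) -> FacilityTable:
    """Keep contiguous-US records (AK, HI and territories excluded).

    Uses the state column when present; otherwise falls back to the
    contiguous-US bounding box.  Idempotent.
    """
    df = table.df
    if "state" in df.columns and df["state"].str.len().gt(0).any():
        keep = ~df["state"].str.upper().isin(NON_CONTIGUOUS_CODES)
        rule = "state-code"
    else:
        (lo_lon, hi_lon), (lo_lat, hi_lat) = (
            CONTIGUOUS_BBOX["lon"], CONTIGUOUS_BBOX["lat"],
        )
        keep = (
            df["lon"].between(lo_lon, hi_lon) & df["lat"].between(lo_lat, hi_lat)
        )
        rule = "bounding-box"
    n_excl = int((~keep).sum())
    if n_excl:
        logger.info("contiguous filter (%s): excluded %d record(s)", rule, n_excl)
    return table._derive(
        df[keep], contiguous_rule=rule, n_excluded_non_contiguous=n_excl
    )


def filter_state(
    table: FacilityTable,
    state: str | None = None,
    polygon: shapely.Geometry | None = None,
) -> FacilityTable:
    """Select the records of one state, by two-letter code or by polygon.

    A polygon (shapely geometry in lon/lat) is required when the table has
    no state column; point-in-polygon membership then defines the subset.
    """
    df = table.df
    if state is not None and "state" in df.columns:
        keep = df["state"].str.upper() == state.upper()
        rule = f"state-code:{state.upper()}"
    elif polygon is not None:
        keep = shapely.contains_xy(
            polygon, df["lon"].to_numpy(float), df["lat"].to_numpy(float)
        )
        keep = pd.Series(keep, index=df.index)
        rule = "polygon"
    else:
        raise ValueError(
            "state filtering needs a state column (with a state code) or a polygon"
        )
    return table._derive(
        df[keep], state_rule=rule, n_state_records=int(keep.sum())
    )


def to_geojson(table: FacilityTable, properties: pd.DataFrame | None = None) -> dict:
    """A GeoJSON FeatureCollection of the facility points.

    ``properties`` (optional, aligned on row position) adds per-feature
    attributes such as local CLQ values and classes.
    """
    feats = []
    for i, row in table.df.reset_index(drop=True).iterrows():
        props = {"category": row["category"]}
        if "state" in table.df.columns:
            props["state"] = row["state"]
        if properties is not None:
            props.update({k: _json_safe(v) for k, v in properties.iloc[i].items()})
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["lon"]), float(row["lat"])],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def _json_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
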