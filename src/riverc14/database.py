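"""Ingest, validation and harmonization of the river radiocarbon database.

The database holds one row per radiocarbon measurement of river DIC, CO2 or
CH4: F14C with its analytical uncertainty, collection date, coordinates,
catchment area, and raw HydroATLAS lithology/biome codes. This module
validates rows against the schema, back-fills F14C/Delta14C/age from one
another, collapses locations repeat-sampled more than four times within a
calendar year to a single averaged record, and attaches the catchment-size,
lithology and biome classifications used in the grouped analyses.

Every input row is accounted for: the ingest metadata records kept,
collapsed-away and dropped rows (with reasons), and the three counts always
sum to the input count.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import isotope
from .atmosphere import AtmosphericRecord, normalize
from .isotope import MODERN, f14c_to_age, age_equivalent_offset

__all__ = [
    "COMPOUNDS",
    "SIZE_CLASSES",
    "LITHOLOGY_MAP",
    "BIOME_MAP",
    "IngestError",
    "SizeClass",
    "GroupSummary",
    "PairedOffsetResult",
    "ObservationSet",
    "ingest",
    "collapse_repeats",
    "classify_size",
    "simplify_lithology",
    "simplify_biome",
    "summarize",
    "paired_offset",
    "group_test",
]

COMPOUNDS = ("DIC", "CO2", "CH4")

#: Exponential catchment-size classes, labelled by their upper decade (km2);
#: "0-10" is closed at 10, the others are left-open decades, ">100,000" maps
#: to the "1000000" class.
SIZE_CLASSES = ("0-10", "100", "1000", "10000", "100000", "1000000")
_SIZE_EDGES = (10.0, 100.0, 1000.0, 10000.0, 100000.0)

#: HydroATLAS lithology code -> 3-class simplification.
LITHOLOGY_MAP: dict[str, str] = {
    "MT": "metamorphic",
    "VB": "igneous",
    "PB": "igneous",
    "VA": "igneous",
    "PA": "igneous",
    "VI": "igneous",
    "PY": "igneous",
    "PI": "igneous",
    "SU": "sedimentary",
    "SS": "sedimentary",
    "SM": "sedimentary",
    "SC": "sedimentary",
    "ND": "excluded",
    "IG": "excluded",
}

#: HydroATLAS biome code -> 8-class simplification (code 15 is the polar
#: desert extension used for Antarctic samples).
BIOME_MAP: dict[int, str] = {
    8: "temperate grasslands and shrublands",
    7: "tropical grasslands and shrublands",
    9: "tropical grasslands and shrublands",
    5: "temperate conifer and boreal forests",
    6: "temperate conifer and boreal forests",
    1: "tropical broadleaf and conifer forests",
    2: "tropical broadleaf and conifer forests",
    3: "tropical broadleaf and conifer forests",
    4: "temperate and mediterranean broadleaf mixed forest",
    12: "temperate and mediterranean broadleaf mixed forest",
    11: "tundra",
    10: "montane grass and shrubs",
    13: "deserts",
    15: "deserts",
}

_CANONICAL_COLUMNS = [
    "site_id",
    "year",
    "date",
    "compound",
    "f14c",
    "sigma_f14c",
    "delta14c",
    "age_14c",
    "latitude",
    "longitude",
    "coord_flag",
    "uncertainty_flag",
    "catchment_area_km2",
    "area_is_estimated",
    "water_type",
    "ph",
    "temperature_c",
    "lithology_raw",
    "biome_raw",
]

_MANDATORY = ("site_id", "year", "compound")


class IngestError(ValueError):
    """Unreadable file or missing mandatory columns."""


@dataclass(frozen=True)
class SizeClass:
    binary: str  # "small" (<=10 km2) or "large"
    exponential: str  # one of SIZE_CLASSES


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    median: float
    fraction_above_one: float


@dataclass(frozen=True)
class PairedOffsetResult:
    n_pairs: int
    mean_offset: float
    max_offset: float
    offsets: tuple[float, ...]
    age_equivalents: tuple[float, ...]


@dataclass
class ObservationSet:
    """Harmonized observation table plus ingest/collapse provenance.

    ``data`` uses the canonical column names; ``metadata`` carries the
    source path, row counts and the dropped/collapsed row log.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_size(area_km2: float) -> SizeClass:
    """Binary and exponential catchment-size classes.

    Small means area <= 10 km2 (the HydroATLAS basin resolution limit);
    exponential classes are left-open decades labelled by their upper bound,
    with everything above 100,000 km2 in the "1000000" class.
    """
    if not np.isfinite(area_km2) or area_km2 <= 0:
        raise ValueError(f"catchment area must be positive, got {area_km2}")
    idx = int(np.searchsorted(_SIZE_EDGES, area_km2, side="left"))
    exponential = SIZE_CLASSES[idx]
    return SizeClass(
        binary="small" if area_km2 <= 10.0 else "large", exponential=exponential
    )


def simplify_lithology(code: str) -> str:
    """Map a HydroATLAS lithology code to sedimentary/igneous/metamorphic.

    No-data and ice-covered reaches ("ND", "IG") and unrecognized codes are
    "excluded" (unknown codes with a warning) so they drop out of
    lithology-grouped analyses without leaving the database.
    """
    key = str(code).strip().upper()
    if key not in LITHOLOGY_MAP:
        warnings.warn(f"unknown lithology code {code!r}; excluded", stacklevel=2)
        return "excluded"
    return LITHOLOGY_MAP[key]


def simplify_biome(code: int) -> str:
    """Map a HydroATLAS biome code (1-13, 15) to the 8-class scheme."""
    try:
        key = int(code)
    except (TypeError, ValueError):
        key = -1
    if key not in BIOME_MAP:
        warnings.warn(f"unknown biome code {code!r}; unclassified", stacklevel=2)
        return "unclassified"
    return BIOME_MAP[key]


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def _current_year() -> int:
    return _dt.date.today().year


def _validate_row(row: pd.Series) -> str | None:
    """Return a drop reason, or None if the row is valid."""
    if pd.isna(row.get("site_id")) or str(row.get("site_id")).strip() == "":
        return "missing site_id"
    compound = str(row.get("compound")).strip()
    if compound not in COMPOUNDS:
        return f"compound {compound!r} not in {COMPOUNDS}"
    year = row.get("year")
    if pd.isna(year):
        return "missing year"
    year = float(year)
    if not (1950 <= year <= _current_year()):
        return f"year {year:g} outside 1950-present"
    date = row.get("date")
    if isinstance(date, str) and date.strip():
        try:
            parsed = _dt.date.fromisoformat(date.strip())
        except ValueError:
            return f"unparseable date {date!r}"
        if parsed.year != int(year):
            return f"date {date!r} conflicts with year {year:g}"
    f14c = row.get("f14c")
    delta = row.get("delta14c")
    if pd.isna(f14c) and pd.isna(delta):
        return "no F14C or Delta14C"
    if pd.notna(f14c) and float(f14c) <= 0:
        return f"non-positive F14C {f14c}"
    if pd.notna(delta) and float(delta) <= -1000:
        return f"Delta14C {delta} <= -1000"
    sigma = row.get("sigma_f14c")
    if pd.notna(sigma) and float(sigma) < 0:
        return "negative sigma_f14c"
    lat, lon = row.get("latitude"), row.get("longitude")
    if pd.notna(lat) and not -90 <= float(lat) <= 90:
        return f"latitude {lat} out of range"
    if pd.notna(lon) and not -180 <= float(lon) <= 180:
        return f"longitude {lon} out of range"
    for flag, nmax in (("coord_flag", 3), ("uncertainty_flag", 2)):
        v = row.get(flag)
        if pd.notna(v) and int(v) not in range(1, nmax + 1):
            return f"{flag} {v} not in 1-{nmax}"
    area = row.get("catchment_area_km2")
    if pd.notna(area) and float(area) <= 0:
        return f"non-positive catchment area {area}"
    return None


def ingest(
    csv_path: str | Path,
    column_map: Mapping[str, str] | None = None,
    classify: bool = True,
) -> ObservationSet:
    """Read and validate an observations CSV into an :class:`ObservationSet`.

    ``column_map`` maps canonical field names to the CSV's column names
    (identity by default). Rows violating the schema are dropped and
    logged, never silently discarded. F14C is back-filled from Delta14C
    (and vice versa) and conventional ages recomputed; when ``classify``
    is true the size/lithology/biome class columns are attached.
    """
    path = Path(csv_path)
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc

    column_map = dict(column_map or {})
    rename = {
        column_map.get(canon, canon): canon
        for canon in _CANONICAL_COLUMNS
        if column_map.get(canon, canon) in raw.columns
    }
    df = raw.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing or not ({"f14c", "delta14c"} & set(df.columns)):
        missing += [] if {"f14c", "delta14c"} & set(df.columns) else ["f14c"]
        raise IngestError(f"missing mandatory columns: {missing}")
    for canon in _CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = np.nan
    df = df[_CANONICAL_COLUMNS]

    dropped: list[tuple[int, str]] = []
    keep_mask = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        reason = _validate_row(row)
        if reason is not None:
            dropped.append((i, reason))
            keep_mask[i] = False
    df = df.loc[keep_mask].reset_index(drop=True)

    # back-fill F14C <-> Delta14C, recompute conventional ages
    need_f = df["f14c"].isna() & df["delta14c"].notna()
    if need_f.any():
        df.loc[need_f, "f14c"] = isotope.delta14c_to_f14c(
            df.loc[need_f, "delta14c"].astype(float).to_numpy(),
            df.loc[need_f, "year"].astype(float).to_numpy(),
        )
    df["delta14c"] = isotope.f14c_to_delta14c(
        df["f14c"].astype(float).to_numpy(), df["year"].astype(float).to_numpy()
    )
    f = df["f14c"].astype(float).to_numpy()
    with np.errstate(invalid="ignore"):
        age = -isotope.LIBBY_MEAN_LIFE * np.log(f)
    df["age_14c"] = np.where(f > 1.0, np.nan, age)
    df["modern"] = f > 1.0
    df["year"] = df["year"].astype(int)
    df["compound"] = df["compound"].astype(str).str.strip()

    if classify:
        _attach_classes(df)

    meta = {
        "source": str(path),
        "n_input": len(raw),
        "n_kept": len(df),
        "n_dropped": len(dropped),
        "dropped": dropped,
    }
    return ObservationSet(data=df, metadata=meta)


def _attach_classes(df: pd.DataFrame) -> None:
    area = df["catchment_area_km2"].astype(float)
    has_area = area.notna() & (area > 0)
    df["size_binary"] = pd.Series(
        np.where(has_area, np.where(area <= 10.0, "small", "large"), None),
        index=df.index,
        dtype=object,
    )
    expo = pd.Series([None] * len(df), index=df.index, dtype=object)
    if has_area.any():
        idx = np.searchsorted(_SIZE_EDGES, area[has_area].to_numpy(), side="left")
        expo.loc[has_area] = [SIZE_CLASSES[i] for i in idx]
    df["size_class"] = expo
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["lithology_class"] = [
            simplify_lithology(c) if pd.notna(c) else None
            for c in df["lithology_raw"]
        ]
        df["biome_class"] = [
            simplify_biome(c) if pd.notna(c) else None for c in df["biome_raw"]
        ]


# ---------------------------------------------------------------------------
# repeat collapsing
# ---------------------------------------------------------------------------

def collapse_repeats(obs: ObservationSet) -> ObservationSet:
    """Average locations repeat-sampled more than four times in a year.

    Groups on (site_id, calendar year, compound) — compounds are analysed
    separately throughout. A group of n > 4 replicates becomes a single
    record: F14C is the arithmetic mean; the new uncertainty is the larger
    of the standard error of the replicate F14C values and the quadrature
    (root-mean-square) mean of the replicate analytical sigmas; Delta14C
    and the conventional age are recomputed from the mean. Groups of <= 4
    pass through unchanged. Idempotent, and never increases the row count.
    """
    df = obs.data
    if len(df) == 0:
        return ObservationSet(df.copy(), dict(obs.metadata, collapsed_groups=0))

    key = ["site_id", "year", "compound"]
    counts = df.groupby(key)["f14c"].transform("size")
    passthrough = df[counts <= 4]
    to_collapse = df[counts > 4]

    collapsed_rows = []
    n_groups = 0
    for (site, year, compound), grp in to_collapse.groupby(key):
        n_groups += 1
        row = grp.iloc[0].copy()
        fvals = grp["f14c"].astype(float)
        mean_f = fvals.mean()
        sem = fvals.std(ddof=1) / np.sqrt(len(grp))
        sigmas = grp["sigma_f14c"].astype(float).dropna()
        rms_sigma = float(np.sqrt(np.mean(sigmas**2))) if len(sigmas) else 0.0
        row["f14c"] = mean_f
        row["sigma_f14c"] = max(sem, rms_sigma)
        row["delta14c"] = isotope.f14c_to_delta14c(mean_f, float(year))
        age = f14c_to_age(mean_f)
        row["age_14c"] = np.nan if age is MODERN else age
        row["modern"] = mean_f > 1.0
        if "date" in row.index:
            row["date"] = np.nan  # an annual average has no single date
        collapsed_rows.append(row)

    out = pd.concat(
        [passthrough] + ([pd.DataFrame(collapsed_rows)] if collapsed_rows else []),
        ignore_index=True,
    )
    out = out.sort_values(key, kind="stable").reset_index(drop=True)
    meta = dict(obs.metadata)
    meta["collapsed_groups"] = n_groups
    meta["rows_removed_by_collapse"] = len(df) - len(out)
    meta["n_kept"] = len(out)
    return ObservationSet(out, meta)


# ---------------------------------------------------------------------------
# summaries and pairing
# ---------------------------------------------------------------------------

_GROUP_COLUMNS = {
    "compound": "compound",
    "lithology": "lithology_class",
    "biome": "biome_class",
    "size_class": "size_class",
    "size_binary": "size_binary",
}


def summarize(
    obs: ObservationSet,
    group_by: str = "none",
    normalized: bool = False,
    record: AtmosphericRecord | None = None,
) -> list[GroupSummary]:
    """Per-group n, mean, sd (n-1), median and fraction of values > 1.

    When ``normalized`` is true, values are F14C_atm ratios computed
    against ``record``; Antarctic/no-data reaches ("excluded" lithology)
    are omitted from lithology groupings. Groups are ordered by label.
    """
    df = obs.data
    if normalized:
        if record is None:
            raise ValueError("normalized summaries need an atmospheric record")
        values = np.array(
            [
                normalize(float(f), record, int(y)).f14c_atm
                for f, y in zip(df["f14c"], df["year"])
            ]
        )
    else:
        values = df["f14c"].astype(float).to_numpy()

    if group_by == "none":
        labels = pd.Series(["all"] * len(df), index=df.index)
    else:
        col = _GROUP_COLUMNS.get(group_by)
        if col is None:
            raise ValueError(f"unknown group_by {group_by!r}")
        labels = df[col]
        if group_by == "lithology":
            labels = labels.where(labels != "excluded", None)

    out = []
    series = pd.Series(values, index=df.index)
    for label in sorted(x for x in labels.dropna().unique()):
        vals = series[labels == label].to_numpy()
        out.append(
            GroupSummary(
                group=str(label),
                n=len(vals),
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                median=float(np.median(vals)),
                fraction_above_one=float(np.mean(vals > 1.0)),
            )
        )
    return out


def paired_offset(obs: ObservationSet) -> PairedOffsetResult | None:
    """|F14C(DIC) - F14C(CO2)| over same-site, same-date pairs.

    Pairs are matched on (site_id, date); rows without a date fall back to
    the calendar year. Each offset is also expressed as a conventional-age
    difference. Returns None when no pairs exist.
    """
    df = obs.data
    key = df["date"].where(
        df["date"].notna() & (df["date"].astype(str).str.strip() != ""),
        df["year"].astype(str),
    )
    offsets, ages = [], []
    for (_, _), grp in df.groupby([df["site_id"], key]):
        dic = grp[grp["compound"] == "DIC"]["f14c"].astype(float)
        co2 = grp[grp["compound"] == "CO2"]["f14c"].astype(float)
        if len(dic) and len(co2):
            a, b = dic.mean(), co2.mean()
            offsets.append(abs(a - b))
            ages.append(age_equivalent_offset(a, b))
    if not offsets:
        return None
    return PairedOffsetResult(
        n_pairs=len(offsets),
        mean_offset=float(np.mean(offsets)),
        max_offset=float(np.max(offsets)),
        offsets=tuple(offsets),
        age_equivalents=tuple(ages),
    )


def group_test(
    obs: ObservationSet,
    group_by: str,
    normalized: bool = False,
    record: AtmosphericRecord | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis test across the groups of ``group_by``.

    Thin convenience over :func:`scipy.stats.kruskal`; returns
    (statistic, p-value).
    """
    df = obs.data
    col = _GROUP_COLUMNS[group_by]
    if normalized:
        if record is None:
            raise ValueError("normalized test needs an atmospheric record")
        vals = np.array(
            [
                normalize(float(f), record, int(y)).f14c_atm
                for f, y in zip(df["f14c"], df["year"])
            ]
        )
    else:
        vals = df["f14c"].astype(float).to_numpy()
    series = pd.Series(vals, index=df.index)
    groups = [
        series[df[col] == g].to_numpy()
        for g in df[col].dropna().unique()
        if g != "excluded"
    ]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)
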