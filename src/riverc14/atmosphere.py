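"""Annual atmospheric 14CO2 record: extension past the last measured year
and normalization of sample F14C to the atmosphere of the collection year.

The bomb curve (atmospheric F14C, ~0.97 before 1955, peaking near 1.9 in
1964, relaxing back toward 1 since) dominates the raw variability of river
radiocarbon measurements. Dividing a sample's F14C by the atmospheric value
of its collection year (the "F14C_atm" ratio) removes this signal so that
samples collected decades apart are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isotope import RadiocarbonValue

__all__ = [
    "AtmosphericRecord",
    "NormalizedValue",
    "TrendFit",
    "InsufficientRecordError",
    "YearOutOfRangeError",
    "extend_record",
    "normalize",
    "trend_f14c_atm",
]

_EXTRAP_BASE_YEARS = (2014, 2015, 2016, 2017, 2018, 2019)


class InsufficientRecordError(ValueError):
    """Record lacks the years needed for an operation."""


class YearOutOfRangeError(KeyError):
    """Sample year outside the (possibly extended) record."""


@dataclass(frozen=True)
class NormalizedValue:
    """A sample F14C divided by the atmospheric F14C of its year."""

    f14c_atm: float
    source_year: int
    record_provenance: str


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


class AtmosphericRecord:
    """Annual atmospheric 14CO2 F14C series with per-year provenance.

    Years must be contiguous and strictly increasing; values positive.
    Provenance is ``"measured"`` or ``"extrapolated"``; extrapolated years
    always follow the last measured one.
    """

    def __init__(
        self,
        years: Sequence[int],
        f14c_values: Sequence[float],
        provenance: Sequence[str] | None = None,
    ) -> None:
        years = np.asarray(years, dtype=int)
        values = np.asarray(f14c_values, dtype=float)
        if years.size == 0 or years.size != values.size:
            raise ValueError("years and f14c_values must be equal-length, non-empty")
        if not np.all(np.diff(years) == 1):
            raise ValueError("years must be contiguous and strictly increasing")
        if not np.all(values > 0):
            raise ValueError("all atmospheric F14C values must be > 0")
        if provenance is None:
            provenance = ["measured"] * years.size
        provenance = list(provenance)
        if len(provenance) != years.size:
            raise ValueError("provenance length mismatch")
        bad = set(provenance) - {"measured", "extrapolated"}
        if bad:
            raise ValueError(f"unknown provenance tags: {bad}")
        meas = [y for y, p in zip(years, provenance) if p == "measured"]
        extr = [y for y, p in zip(years, provenance) if p == "extrapolated"]
        if extr and meas and min(extr) <= max(meas):
            raise ValueError("extrapolated years must follow the last measured year")
        self.years = years
        self.f14c_values = values
        self.provenance = provenance

    # -- lookup ----------------------------------------------------------
    def __contains__(self, year: int) -> bool:
        return self.years[0] <= year <= self.years[-1]

    def value_at(self, year: int) -> float:
        if year not in self:
            raise YearOutOfRangeError(
                f"year {year} outside record {self.years[0]}-{self.years[-1]}"
            )
        return float(self.f14c_values[int(year) - int(self.years[0])])

    def provenance_at(self, year: int) -> str:
        if year not in self:
            raise YearOutOfRangeError(str(year))
        return self.provenance[int(year) - int(self.years[0])]

    @property
    def last_measured_year(self) -> int:
        meas = [y for y, p in zip(self.years, self.provenance) if p == "measured"]
        if not meas:
            raise InsufficientRecordError("record has no measured years")
        return int(max(meas))

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "AtmosphericRecord":
        """Read ``year,f14c[,sigma][,provenance]`` (header required).

        Sub-annual series (repeated years) are averaged to annual means
        before use, since normalization is to the collection *year*.
        """
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "year" not in cols or "f14c" not in cols:
            raise ValueError("record CSV must have 'year' and 'f14c' columns")
        df["_year"] = np.floor(df[cols["year"]].astype(float)).astype(int)
        annual = df.groupby("_year")[cols["f14c"]].mean()
        prov = None
        if "provenance" in cols:
            prov = df.groupby("_year")[cols["provenance"]].first().tolist()
        return cls(annual.index.to_numpy(), annual.to_numpy(), prov)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "year": self.years,
                "f14c": self.f14c_values,
                "provenance": self.provenance,
            }
        ).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "f14c": self.f14c_values,
                "provenance": self.provenance,
            }
        )


def extend_record(record: AtmosphericRecord, through_year: int) -> AtmosphericRecord:
    """Extend a record past its last measured year on the 2014-2019 trend.

    An OLS line is fitted to the record's six annual values for 2014-2019
    and evaluated for every missing year up to ``through_year``; appended
    years are tagged ``"extrapolated"``. Idempotent: re-extending to the
    same year returns an identical record.
    """
    missing = [y for y in _EXTRAP_BASE_YEARS if y not in record]
    if missing:
        raise InsufficientRecordError(
            f"extension needs measured 2014-2019; missing {missing}"
        )
    last = record.years[-1]
    if through_year <= last:
        return record
    base_years = np.array(_EXTRAP_BASE_YEARS, dtype=float)
    base_vals = np.array([record.value_at(int(y)) for y in base_years])
    slope, intercept = np.polyfit(base_years, base_vals, 1)
    new_years = np.arange(last + 1, through_year + 1)
    new_vals = slope * new_years + intercept
    if np.any(new_vals <= 0):
        raise InsufficientRecordError(
            "extrapolated atmospheric F14C would be non-positive"
        )
    return AtmosphericRecord(
        np.concatenate([record.years, new_years]),
        np.concatenate([record.f14c_values, new_vals]),
        list(record.provenance) + ["extrapolated"] * new_years.size,
    )


def normalize(
    sample: RadiocarbonValue | float,
    record: AtmosphericRecord,
    year: int | None = None,
) -> NormalizedValue:
    """F14C_atm = F14C_sample / F14C_atmosphere(collection year).

    A year outside the record raises :class:`YearOutOfRangeError`; values
    are never silently clamped to the record edge.
    """
    if isinstance(sample, RadiocarbonValue):
        f14c = sample.f14c
        year = int(sample.year_collected)
    else:
        if year is None:
            raise ValueError("year required when sample is a bare float")
        f14c = float(sample)
    atm = record.value_at(year)
    return NormalizedValue(
        f14c_atm=f14c / atm,
        source_year=year,
        record_provenance=record.provenance_at(year),
    )


def trend_f14c_atm(
    years: Iterable[float], values: Iterable[float]
) -> TrendFit:
    """OLS trend of normalized F14C against collection year.

    Returns slope, intercept, R^2 and the two-sided p-value of the
    slope's t-test.
    """
    years = np.asarray(list(years), dtype=float)
    values = np.asarray(list(values), dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must be equal length")
    if np.unique(years).size < 3:
        raise ValueError("trend fit needs >= 3 distinct years")
    res = stats.linregress(years, values)
    return TrendFit(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        p_value=res.pvalue,
        stderr=res.stderr,
    )
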