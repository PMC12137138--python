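"""Radiocarbon unit conversions and conventional-age arithmetic.

Radiocarbon content is carried as F14C (fraction modern): sample activity
normalized to the 1950 oxalic-acid standard. Two decay constants appear, by
long-standing convention:

* the *true* decay constant, ``1/8267`` per year, used when converting
  between F14C and the decay-corrected Delta14C (per mil) for a sample
  collected in year ``y``;
* the Libby mean life, ``8033`` years, used for the *conventional*
  radiocarbon age ``-8033 * ln(F14C)``.

Samples with F14C > 1 carry bomb-derived carbon fixed after 1955; no
conventional age exists for them and they are reported as "modern".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "LAMBDA_TRUE",
    "LIBBY_MEAN_LIFE",
    "REFERENCE_YEAR",
    "MODERN",
    "InvalidMeasurementError",
    "RadiocarbonValue",
    "f14c_to_age",
    "age_to_f14c",
    "age_sigma",
    "age_equivalent_offset",
    "f14c_to_delta14c",
    "delta14c_to_f14c",
]

#: True radiocarbon decay constant (1/yr), for Delta14C decay correction.
LAMBDA_TRUE = 1.0 / 8267.0

#: Libby mean life (yr), for conventional radiocarbon ages.
LIBBY_MEAN_LIFE = 8033.0

#: Reference year of the fraction-modern scale.
REFERENCE_YEAR = 1950


class InvalidMeasurementError(ValueError):
    """A radiocarbon quantity outside its physical domain."""


class _Modern:
    """Sentinel for samples with F14C > 1 (no conventional age)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "MODERN"

    def __str__(self) -> str:
        return "modern"


MODERN = _Modern()

AgeOrModern = Union[float, _Modern]


def _check_positive(f14c: float, name: str = "f14c") -> None:
    if not np.all(np.asarray(f14c) > 0):
        raise InvalidMeasurementError(f"{name} must be > 0, got {f14c!r}")


def f14c_to_age(f14c: float) -> AgeOrModern:
    """Conventional radiocarbon age in years BP, or :data:`MODERN`.

    ``-8033 * ln(F14C)`` for F14C <= 1. Bomb-influenced samples
    (F14C > 1) have no conventional age and return the modern sentinel,
    never a negative number.
    """
    _check_positive(f14c)
    if f14c > 1.0:
        return MODERN
    return -LIBBY_MEAN_LIFE * math.log(f14c)


def age_to_f14c(age: float, mean_life: float = LIBBY_MEAN_LIFE) -> float:
    """Inverse of :func:`f14c_to_age`; also used with the true mean life
    (8,267 yr) to assign F14C to a carbon pool of known age."""
    return math.exp(-age / mean_life)


def age_sigma(f14c: float, sigma_f14c: float) -> float:
    """First-order (delta-method) age uncertainty: ``8033 * sigma / F``."""
    _check_positive(f14c)
    if sigma_f14c < 0:
        raise InvalidMeasurementError("sigma_f14c must be >= 0")
    return LIBBY_MEAN_LIFE * sigma_f14c / f14c


def age_equivalent_offset(f14c_a: float, f14c_b: float) -> float:
    """Absolute conventional-age difference between two F14C values.

    ``|8033 * (ln a - ln b)|`` — defined for any positive pair, including
    values above 1, so paired measurements (e.g. DIC vs CO2 at one site)
    can be expressed on the age scale: 1.0 vs 0.98 is 162 14C years.
    """
    _check_positive(f14c_a, "f14c_a")
    _check_positive(f14c_b, "f14c_b")
    return abs(LIBBY_MEAN_LIFE * (math.log(f14c_a) - math.log(f14c_b)))


def _warn_year(year: float) -> None:
    if year < REFERENCE_YEAR or year > 2030:
        warnings.warn(
            f"collection year {year} outside 1950-2030; decay correction "
            "extrapolated",
            stacklevel=3,
        )


def f14c_to_delta14c(f14c, year):
    """Delta14C (per mil) of a sample collected in ``year``.

    ``1000 * (F14C * exp(-lambda*(y-1950)) - 1)`` with lambda = 1/8267/yr.
    Accepts scalars or arrays.
    """
    f14c = np.asarray(f14c, dtype=float)
    _check_positive(f14c)
    year = np.asarray(year, dtype=float)
    for y in np.atleast_1d(year):
        _warn_year(y)
    out = 1000.0 * (f14c * np.exp(-LAMBDA_TRUE * (year - REFERENCE_YEAR)) - 1.0)
    return out.item() if out.ndim == 0 else out


def delta14c_to_f14c(delta14c, year):
    """F14C from Delta14C (per mil) and collection year (inverse of
    :func:`f14c_to_delta14c`)."""
    delta14c = np.asarray(delta14c, dtype=float)
    if not np.all(delta14c > -1000.0):
        raise InvalidMeasurementError(
            "delta14c <= -1000 per mil implies non-positive F14C"
        )
    year = np.asarray(year, dtype=float)
    for y in np.atleast_1d(year):
        _warn_year(y)
    out = (delta14c / 1000.0 + 1.0) * np.exp(LAMBDA_TRUE * (year - REFERENCE_YEAR))
    return out.item() if out.ndim == 0 else out


@dataclass
class RadiocarbonValue:
    """One measurement's isotopic state.

    Derived fields (``delta14c``, ``age_14c``) are filled in from ``f14c``
    and ``year_collected`` when not supplied. ``age_14c`` is ``None`` and
    ``modern`` is True whenever F14C > 1.
    """

    f14c: float
    year_collected: float
    sigma_f14c: float | None = None
    delta14c: float | None = field(default=None)
    age_14c: float | None = field(default=None)

    def __post_init__(self) -> None:
        _check_positive(self.f14c)
        if self.sigma_f14c is not None and self.sigma_f14c < 0:
            raise InvalidMeasurementError("sigma_f14c must be >= 0")
        expected_delta = f14c_to_delta14c(self.f14c, self.year_collected)
        if self.delta14c is None:
            self.delta14c = expected_delta
        elif abs(self.delta14c - expected_delta) > 1e-9 * max(
            1.0, abs(expected_delta)
        ):
            raise InvalidMeasurementError(
                f"delta14c={self.delta14c} inconsistent with f14c={self.f14c} "
                f"at year {self.year_collected} (expected {expected_delta:.6f})"
            )
        age = f14c_to_age(self.f14c)
        self.age_14c = None if age is MODERN else age

    @classmethod
    def from_delta14c(
        cls, delta14c: float, year: float, sigma_f14c: float | None = None
    ) -> "RadiocarbonValue":
        return cls(
            f14c=delta14c_to_f14c(delta14c, year),
            year_collected=year,
            sigma_f14c=sigma_f14c,
        )

    @property
    def modern(self) -> bool:
        return self.f14c > 1.0

    @property
    def sigma_age(self) -> float | None:
        if self.sigma_f14c is None or self.modern:
            return None
        return age_sigma(self.f14c, self.sigma_f14c)
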