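"""Units of measurement for model constants and attributes.

A :class:`Unit` is an exponent vector over five base dimensions --
length, time, amount, mass and volume -- together with a scale factor
relating it to the canonical unit of that dimension combination
(metre, second, mole, kilogram, litre).  Composition multiplies scale
factors and adds exponent vectors; conversion is only defined between
units with identical exponent vectors.  Numeric literals are rescaled
to canonical units during type checking, so the simulator core only
ever sees canonical magnitudes.

Volume is deliberately its own base dimension (litre family); cubic
lengths stay in the length dimension and do not interconvert with
litres.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Tuple

__all__ = ["Unit", "UnitError", "DIMENSIONLESS", "PER_SECOND", "lookup_unit", "is_unit_name"]

#: order of the base-dimension exponent vector
DIMENSIONS = ("length", "time", "amount", "mass", "volume")


class UnitError(ValueError):
    """Raised on incompatible-dimension arithmetic or unknown units."""


def _vec(**kw: int) -> Tuple[int, ...]:
    return tuple(kw.get(d, 0) for d in DIMENSIONS)


@dataclass(frozen=True)
class Unit:
    """Exponent vector over base dimensions plus scale to canonical."""

    dims: Tuple[int, ...] = _vec()
    scale: float = 1.0

    # -- algebra ---------------------------------------------------------
    def __mul__(self, other: "Unit") -> "Unit":
        return Unit(tuple(a + b for a, b in zip(self.dims, other.dims)),
                    self.scale * other.scale)

    def __truediv__(self, other: "Unit") -> "Unit":
        return Unit(tuple(a - b for a, b in zip(self.dims, other.dims)),
                    self.scale / other.scale)

    def __pow__(self, n: int) -> "Unit":
        return Unit(tuple(a * n for a in self.dims), self.scale ** n)

    def inverse(self) -> "Unit":
        return DIMENSIONLESS / self

    # -- predicates ------------------------------------------------------
    @property
    def is_dimensionless(self) -> bool:
        return all(d == 0 for d in self.dims)

    def same_dims(self, other: "Unit") -> bool:
        return self.dims == other.dims

    def is_per_time(self) -> bool:
        return self.dims == _vec(time=-1)

    # -- conversion ------------------------------------------------------
    def to_canonical(self, value: float) -> float:
        """Express *value* (given in this unit) in canonical units."""
        return value * self.scale

    def convert(self, value: float, target: "Unit") -> float:
        if not self.same_dims(target):
            raise UnitError(
                f"cannot convert between dimensions {self.dims} and {target.dims}")
        return value * self.scale / target.scale

    def dim_str(self) -> str:
        if self.is_dimensionless:
            return "1"
        num, den = [], []
        for name, e in zip(DIMENSIONS, self.dims):
            if e > 0:
                num.append(name if e == 1 else f"{name}^{e}")
            elif e < 0:
                den.append(name if e == -1 else f"{name}^{-e}")
        out = "*".join(num) if num else "1"
        if den:
            out += "/" + "*".join(den)
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Unit({self.dim_str()}, scale={self.scale:g})"


DIMENSIONLESS = Unit()

_LENGTH = _vec(length=1)
_TIME = _vec(time=1)
_AMOUNT = _vec(amount=1)
_MASS = _vec(mass=1)
_VOLUME = _vec(volume=1)

# Symbol and long-name table.  Scales are relative to the canonical
# units metre / second / mole / kilogram / litre.
_UNIT_TABLE = {
    # length (canonical: metre)
    "m": Unit(_LENGTH, 1.0), "meter": Unit(_LENGTH, 1.0), "metre": Unit(_LENGTH, 1.0),
    "dm": Unit(_LENGTH, 1e-1),
    "cm": Unit(_LENGTH, 1e-2), "centimeter": Unit(_LENGTH, 1e-2),
    "mm": Unit(_LENGTH, 1e-3), "millimeter": Unit(_LENGTH, 1e-3),
    "um": Unit(_LENGTH, 1e-6), "micrometer": Unit(_LENGTH, 1e-6),
    "nm": Unit(_LENGTH, 1e-9), "nanometer": Unit(_LENGTH, 1e-9),
    # time (canonical: second)
    "s": Unit(_TIME, 1.0), "sec": Unit(_TIME, 1.0), "second": Unit(_TIME, 1.0),
    "ms": Unit(_TIME, 1e-3), "millisecond": Unit(_TIME, 1e-3),
    "min": Unit(_TIME, 60.0), "minute": Unit(_TIME, 60.0),
    "h": Unit(_TIME, 3600.0), "hour": Unit(_TIME, 3600.0),
    "d": Unit(_TIME, 86400.0), "day": Unit(_TIME, 86400.0),
    # amount (canonical: mole)
    "mol": Unit(_AMOUNT, 1.0), "mole": Unit(_AMOUNT, 1.0),
    "mmol": Unit(_AMOUNT, 1e-3),
    "umol": Unit(_AMOUNT, 1e-6),
    "nmol": Unit(_AMOUNT, 1e-9),
    # mass (canonical: kilogram)
    "kg": Unit(_MASS, 1.0), "kilogram": Unit(_MASS, 1.0),
    "g": Unit(_MASS, 1e-3), "gram": Unit(_MASS, 1e-3),
    "mg": Unit(_MASS, 1e-6),
    "ug": Unit(_MASS, 1e-9),
    "ng": Unit(_MASS, 1e-12),
    # volume (canonical: litre)
    "L": Unit(_VOLUME, 1.0), "l": Unit(_VOLUME, 1.0), "liter": Unit(_VOLUME, 1.0),
    "litre": Unit(_VOLUME, 1.0),
    "mL": Unit(_VOLUME, 1e-3), "ml": Unit(_VOLUME, 1e-3),
    "uL": Unit(_VOLUME, 1e-6), "ul": Unit(_VOLUME, 1e-6),
    "nL": Unit(_VOLUME, 1e-9),
    "fL": Unit(_VOLUME, 1e-15),
}

PER_SECOND = Unit(_vec(time=-1), 1.0)


def is_unit_name(name: str) -> bool:
    return name in _UNIT_TABLE


def lookup_unit(name: str) -> Unit:
    try:
        return _UNIT_TABLE[name]
    except KeyError:
        raise UnitError(f"unknown unit {name!r}") from None


def exact_scale(name: str) -> Fraction:
    """Scale of a named unit as an exact fraction (testing helper)."""
    return Fraction(str(_UNIT_TABLE[name].scale))
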