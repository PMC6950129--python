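"""Lead isotope fingerprints: ratio triples and abundance vectors.

Natural lead is composed of four stable isotopes (²⁰⁴Pb, ²⁰⁶Pb, ²⁰⁷Pb,
²⁰⁸Pb).  A source or sample "fingerprint" can be written either as the
four mass fractions (an :class:`AbundanceVector`, components summing to 1)
or, as mass spectrometers report it, as three independent isotope ratios
(a :class:`RatioTriple`).  Two ratio parameterizations are supported:

``CHAIN_204``
    the chained ratios (²⁰⁴Pb/²⁰⁶Pb, ²⁰⁶Pb/²⁰⁷Pb, ²⁰⁷Pb/²⁰⁸Pb) — the
    parameterization in which the two-source closed-form solution is
    written;
``REF_204``
    the ²⁰⁴Pb-referenced ratios (²⁰⁸Pb/²⁰⁴Pb, ²⁰⁷Pb/²⁰⁴Pb, ²⁰⁶Pb/²⁰⁴Pb)
    — the conventional geochemical reporting style, and the one the
    bundled case-study table actually carries.

Both are bijective reductions of the abundance vector on strictly
positive ratios, so conversions round-trip exactly (to ~1e-15 relative;
the guaranteed tolerance is 1e-12).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import FingerprintError

__all__ = [
    "Parameterization",
    "RatioTriple",
    "AbundanceVector",
    "abundances_from_ratios",
    "ratios_from_abundances",
    "convert",
    "gobeil_projection",
]

#: Tolerance for closure (sum-to-one) and round-trip identities.
ROUND_TRIP_RTOL = 1e-12


class Parameterization(enum.Enum):
    """Which three ratios a :class:`RatioTriple` carries."""

    CHAIN_204 = "chain204"  # (204/206, 206/207, 207/208)
    REF_204 = "ref204"      # (208/204, 207/204, 206/204)

    @property
    def ratio_names(self) -> tuple[str, str, str]:
        if self is Parameterization.CHAIN_204:
            return ("204Pb/206Pb", "206Pb/207Pb", "207Pb/208Pb")
        return ("208Pb/204Pb", "207Pb/204Pb", "206Pb/204Pb")


def _check_positive_finite(value: float, field: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise FingerprintError(f"ratio {field!r} must be finite, got {value!r}")
    if value <= 0:
        raise FingerprintError(f"ratio {field!r} must be strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class RatioTriple:
    """Three lead isotope ratios plus the tag saying which ratios they are."""

    r1: float
    r2: float
    r3: float
    param: Parameterization = Parameterization.REF_204

    def __post_init__(self) -> None:
        names = self.param.ratio_names
        object.__setattr__(self, "r1", _check_positive_finite(self.r1, names[0]))
        object.__setattr__(self, "r2", _check_positive_finite(self.r2, names[1]))
        object.__setattr__(self, "r3", _check_positive_finite(self.r3, names[2]))
        if not isinstance(self.param, Parameterization):
            raise FingerprintError(f"unknown parameterization {self.param!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r1, self.r2, self.r3)


@dataclass(frozen=True)
class AbundanceVector:
    """Mass fractions of the four stable lead isotopes; closure: sum = 1."""

    x204: float
    x206: float
    x207: float
    x208: float

    def __post_init__(self) -> None:
        for field in ("x204", "x206", "x207", "x208"):
            v = float(getattr(self, field))
            if not math.isfinite(v) or v <= 0:
                raise FingerprintError(
                    f"abundance {field!r} must be a finite positive fraction, got {v!r}"
                )
            object.__setattr__(self, field, v)
        total = self.x204 + self.x206 + self.x207 + self.x208
        if abs(total - 1.0) > ROUND_TRIP_RTOL:
            raise FingerprintError(
                f"abundances must sum to 1 (closure), got {total!r}"
            )

    def as_array(self) -> np.ndarray:
        """Components in mass-number order (204, 206, 207, 208)."""
        return np.array([self.x204, self.x206, self.x207, self.x208])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "AbundanceVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise FingerprintError(f"expected 4 abundance components, got shape {x.shape}")
        return cls(x204=x[0], x206=x[1], x207=x[2], x208=x[3])


def abundances_from_ratios(ratios: RatioTriple) -> AbundanceVector:
    """Invert a ratio triple to the four-isotope abundance vector.

    The three ratios fix the relative masses of the four isotopes up to a
    common scale; the closure constraint (fractions sum to 1) removes the
    scale.  For ``REF_204`` ratios (r208, r207, r206) the un-normalized
    masses per unit ²⁰⁴Pb are (1, r206, r207, r208); for ``CHAIN_204``
    ratios (y1, y2, y3) the masses per unit ²⁰⁸Pb are
    (y1·y2·y3, y2·y3, y3, 1).
    """
    r1, r2, r3 = ratios.as_tuple()
    if ratios.param is Parameterization.REF_204:
        m = np.array([1.0, r3, r2, r1])  # (204, 206, 207, 208)
    else:  # CHAIN_204
        m = np.array([r1 * r2 * r3, r2 * r3, r3, 1.0])
    return AbundanceVector.from_array(m / m.sum())


def ratios_from_abundances(x: AbundanceVector, param: Parameterization) -> RatioTriple:
    """Reduce an abundance vector to three ratios in the requested style."""
    if param is Parameterization.REF_204:
        return RatioTriple(x.x208 / x.x204, x.x207 / x.x204, x.x206 / x.x204, param)
    return RatioTriple(x.x204 / x.x206, x.x206 / x.x207, x.x207 / x.x208, param)


def convert(ratios: RatioTriple, param: Parameterization) -> RatioTriple:
    """Re-express a ratio triple in another parameterization (bijective)."""
    if ratios.param is param:
        return ratios
    return ratios_from_abundances(abundances_from_ratios(ratios), param)


def gobeil_projection(x: AbundanceVector) -> tuple[float, float]:
    """Project an abundance vector onto the classical tracer-ratio pair.

    Returns ``(R, N)`` with R = ²⁰⁶Pb/²⁰⁷Pb and N = ²⁰⁸Pb/²⁰⁶Pb, the two
    ratios balanced by the classical three-source ratio-balance model.
    """
    return (x.x206 / x.x207, x.x208 / x.x206)
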