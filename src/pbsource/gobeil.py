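"""The classical three-source ratio-balance model and its critique.

The classical apportionment model balances two tracer ratios directly:
with R = ²⁰⁶Pb/²⁰⁷Pb and N = ²⁰⁸Pb/²⁰⁶Pb measured for a sample (Rs, Ns)
and three candidate sources (R1..R3, N1..N3), it solves

    Rs = f1·R1 + f2·R2 + f3·R3
    Ns = f1·N1 + f2·N2 + f3·N3
    f1 + f2 + f3 = 1.

The trouble is that ratios of masses do not mix linearly under mass
balance: a true mixture satisfies Rs = Σf·x206 / Σf·x207, not
Σf·(x206/x207).  The two coincide for the R-equation only when the
sources share the same ²⁰⁷Pb abundance, and for the N-equation only when
they share the same ²⁰⁶Pb abundance — and when both hold, the three
source fingerprints collapse and the system turns singular.  So on
physically mixed samples the ratio-balance fractions carry a systematic
deviation that grows with the spread of the sources' ²⁰⁶Pb/²⁰⁷Pb
abundances.  :func:`compare_models` quantifies that deviation against
the mass-balance solver on any chosen mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import FingerprintError, UnidentifiableError
from .fingerprints import (
    AbundanceVector,
    RatioTriple,
    abundances_from_ratios,
    gobeil_projection,
)
from .mass_balance import ApportionResult, SourceSet, solve_mass_balance
from .synthetic import forward_mix

__all__ = [
    "GobeilFingerprint",
    "ModelComparison",
    "solve_gobeil",
    "compare_models",
]


@dataclass(frozen=True)
class GobeilFingerprint:
    """The (R, N) = (²⁰⁶Pb/²⁰⁷Pb, ²⁰⁸Pb/²⁰⁶Pb) tracer-ratio pair."""

    R: float
    N: float

    def __post_init__(self) -> None:
        for field in ("R", "N"):
            v = float(getattr(self, field))
            if not math.isfinite(v) or v <= 0:
                raise FingerprintError(
                    f"Gobeil ratio {field!r} must be finite and positive, got {v!r}"
                )
            object.__setattr__(self, field, v)

    @classmethod
    def from_abundances(cls, x: AbundanceVector) -> "GobeilFingerprint":
        return cls(*gobeil_projection(x))

    @classmethod
    def from_ratio_triple(cls, ratios: RatioTriple) -> "GobeilFingerprint":
        return cls.from_abundances(abundances_from_ratios(ratios))


def solve_gobeil(
    sources: tuple[GobeilFingerprint, GobeilFingerprint, GobeilFingerprint],
    sample: GobeilFingerprint,
) -> np.ndarray:
    """Solve the classical three-source ratio-balance system exactly.

    Returns the three weights (which may be negative).  The model is
    defined for exactly three sources; collinear (R, N) fingerprints make
    the 3×3 matrix singular.
    """
    if len(sources) != 3:
        raise UnidentifiableError(
            f"the ratio-balance model takes exactly 3 sources, got {len(sources)}"
        )
    A = np.array(
        [
            [s.R for s in sources],
            [s.N for s in sources],
            [1.0, 1.0, 1.0],
        ]
    )
    b = np.array([sample.R, sample.N, 1.0])
    try:
        f = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise UnidentifiableError(
            "source (R, N) fingerprints are collinear; the ratio-balance "
            "system is singular"
        ) from exc
    return f


@dataclass(frozen=True)
class ModelComparison:
    """Both models' fractions for one synthetic mixture.

    ``deviation`` holds the ratio-balance fractions minus the
    mass-balance ones per source; ``max_abs_deviation`` is its infinity
    norm — a scale-free measure of how far the classical model strays
    from mass consistency on this mixture.
    """

    true_fractions: np.ndarray
    mass_balance: ApportionResult
    gobeil_fractions: np.ndarray

    @property
    def deviation(self) -> np.ndarray:
        return self.gobeil_fractions - self.mass_balance.fractions

    @property
    def max_abs_deviation(self) -> float:
        return float(np.abs(self.deviation).max())


def compare_models(sources: SourceSet, true_fractions) -> ModelComparison:
    """Mix three sources by mass balance, then solve with both models.

    The mixture is generated by the forward mass-balance model, so the
    mass-balance solver recovers ``true_fractions`` to solver precision;
    the ratio-balance solution deviates unless the sources' ²⁰⁶Pb and
    ²⁰⁷Pb abundances coincide.
    """
    if sources.n != 3:
        raise UnidentifiableError(
            f"model comparison is defined for 3 sources, got {sources.n}"
        )
    f_true = np.asarray(true_fractions, dtype=float)
    sample = forward_mix(sources, f_true, sample_id="comparison")
    mb = solve_mass_balance(sources, sample)
    gobeil_sources = tuple(
        GobeilFingerprint.from_ratio_triple(fp) for fp in sources.fingerprints
    )
    gobeil_sample = GobeilFingerprint.from_ratio_triple(sample.fingerprint)
    fg = solve_gobeil(gobeil_sources, gobeil_sample)
    return ModelComparison(
        true_fractions=f_true, mass_balance=mb, gobeil_fractions=fg
    )
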