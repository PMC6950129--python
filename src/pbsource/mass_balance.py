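"""Mass-balance unmixing of lead pollution sources.

The model: a contaminated sample's lead is a mass-weighted mixture of the
lead of n end-member sources.  Because lead isotopes do not fractionate
measurably in transport, each source contributes its own fixed isotope
composition, so for every isotope j ∈ {204, 206, 207, 208}

    x_j(sample) = Σ_i f_i · x_j(source i),          Σ_i f_i = 1,

where x_j are mass abundances and f_i is the fraction of the sample's
total lead contributed by source i (its *contribution rate*).  Counting
unknowns and equations in the underlying per-isotope mass formulation
(5n unknowns, 4n+4 equations) shows the system is solvable for up to
four sources and under-determined beyond that — with lead isotopes alone
no more than four sources can be apportioned.

Three solvers are provided and cross-check one another:

* :func:`solve_mass_balance` — the reduced abundance-mixing system
  (constrained least squares; exact on consistent data);
* :func:`solve_full_system` — the literal per-isotope-mass linear system,
  kept as an independently coded oracle;
* :func:`solve_two_source_closed_form` — the printed algebraic solution
  for the two-source case.

Fractions are deliberately *not* constrained to be non-negative: a
negative fraction is a diagnostic that the sample lies outside the
simplex spanned by the proposed sources, i.e. that an unmodeled source
contributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    DegenerateSourceError,
    FingerprintError,
    IllConditionedWarning,
    UnidentifiableError,
)
from .fingerprints import (
    AbundanceVector,
    Parameterization,
    RatioTriple,
    abundances_from_ratios,
    convert,
)

__all__ = [
    "SourceSet",
    "MixtureSample",
    "ApportionResult",
    "FullSystemSolution",
    "SystemSpec",
    "BatchApportionment",
    "system_dimensions",
    "solve_mass_balance",
    "solve_full_system",
    "solve_two_source_closed_form",
    "batch_apportion",
]

#: Pairwise-distance threshold below which two sources count as identical.
DEGENERACY_ATOL = 1e-10
#: Relative singular-value threshold for exact rank deficiency.
RANK_DEFICIENCY_RTOL = 1e-12
#: Condition number above which an ill-conditioning warning is emitted.
CONDITION_WARNING_THRESHOLD = 1e10


@dataclass(frozen=True)
class SourceSet:
    """An ordered collection of named end-member fingerprints."""

    names: tuple[str, ...]
    fingerprints: tuple[RatioTriple, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.fingerprints):
            raise FingerprintError("names and fingerprints must have equal length")
        if len(self.names) < 2:
            raise FingerprintError("a SourceSet needs at least two sources")
        if len(set(self.names)) != len(self.names):
            raise FingerprintError(f"source names must be unique, got {self.names!r}")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "fingerprints", tuple(self.fingerprints))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, RatioTriple]]) -> "SourceSet":
        names, fps = zip(*pairs)
        return cls(tuple(names), tuple(fps))

    @property
    def n(self) -> int:
        return len(self.names)

    def abundance_matrix(self) -> np.ndarray:
        """4×n matrix whose columns are the sources' abundance vectors
        (rows in mass-number order 204, 206, 207, 208)."""
        return np.column_stack(
            [abundances_from_ratios(fp).as_array() for fp in self.fingerprints]
        )

    @property
    def degenerate(self) -> bool:
        """True if any two sources have (numerically) identical abundances."""
        X = self.abundance_matrix()
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if np.max(np.abs(X[:, i] - X[:, j])) < DEGENERACY_ATOL:
                    return True
        return False

    def permuted(self, order: Sequence[int]) -> "SourceSet":
        return SourceSet(
            tuple(self.names[i] for i in order),
            tuple(self.fingerprints[i] for i in order),
        )


@dataclass(frozen=True)
class MixtureSample:
    """A contaminated sample: fingerprint plus optional metadata.

    ``concentration`` (total lead, ppm) and ``total_mass`` are metadata
    only — apportionment results are independent of both.
    """

    id: str
    fingerprint: RatioTriple
    concentration: Optional[float] = None
    total_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration < 0:
            raise FingerprintError(
                f"sample {self.id!r}: concentration must be >= 0, got {self.concentration}"
            )
        if self.total_mass <= 0:
            raise FingerprintError(
                f"sample {self.id!r}: total mass must be positive, got {self.total_mass}"
            )

    def abundances(self) -> AbundanceVector:
        return abundances_from_ratios(self.fingerprint)


@dataclass(frozen=True)
class ApportionResult:
    """Per-source contribution fractions with diagnostics.

    ``fractions`` sum to 1 (the normalization is enforced exactly by the
    solver) but individual entries may be negative; ``negative_flags``
    marks those.  ``residuals`` are the four per-isotope balance residuals
    Σ_i f_i x_j(i) − x_j(sample); nonzero residuals mean the sample is not
    an exact mixture of the proposed sources (measurement error or a
    missing source).
    """

    source_names: tuple[str, ...]
    fractions: np.ndarray
    residuals: np.ndarray
    condition_number: float
    method: str
    sample_id: str = ""

    @property
    def negative_flags(self) -> np.ndarray:
        return self.fractions < 0

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.negative_flags))

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residuals))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.source_names, map(float, self.fractions)))


@dataclass(frozen=True)
class FullSystemSolution:
    """Solution of the literal per-isotope mass system.

    ``masses[i, j]`` is the mass of isotope j (order 204, 206, 207, 208)
    that source i contributes to the sample; rows sum to f_i·m.
    """

    source_names: tuple[str, ...]
    masses: np.ndarray
    fractions: np.ndarray
    total_mass: float

    @property
    def source_masses(self) -> np.ndarray:
        return self.masses.sum(axis=1)


@dataclass(frozen=True)
class SystemSpec:
    """Equation/unknown bookkeeping for the n-source mass system."""

    n_sources: int
    n_unknowns: int
    n_equations: int
    solvable: bool
    identifiable: bool


def system_dimensions(n: int) -> SystemSpec:
    """Count unknowns and equations for n sources and judge solvability.

    Per source there are four isotope masses and one fraction (5n
    unknowns).  Equations: one mass-sum per source (n), three ratio
    constraints per source (3n), three ratio constraints on the mixture
    (3), and the fraction normalization (1) — 4n+4 in total.  Equations
    keep pace with unknowns only up to n = 4, where the system is exactly
    determined; from n = 5 on it is under-determined and the fractions
    are unidentifiable.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise UnidentifiableError(f"number of sources must be an integer, got {n!r}")
    if n < 2:
        raise UnidentifiableError(f"need at least 2 sources, got {n}")
    n = int(n)
    solvable = n <= 4
    return SystemSpec(
        n_sources=n,
        n_unknowns=5 * n,
        n_equations=4 * n + 4,
        solvable=solvable,
        identifiable=solvable,
    )


def _check_solvable(n: int) -> None:
    spec = system_dimensions(n)
    if not spec.solvable:
        raise UnidentifiableError(
            f"{n} sources give {spec.n_unknowns} unknowns but only "
            f"{spec.n_equations} equations; the mixing fractions are not "
            "identifiable from lead isotopes alone for more than 4 sources"
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < RANK_DEFICIENCY_RTOL * s[0]:
        raise DegenerateSourceError(
            f"end-member fingerprints {tuple(names)!r} are collinear "
            "(rank-deficient design matrix); apportionment is not unique"
        )


def solve_mass_balance(sources: SourceSet, sample: MixtureSample) -> ApportionResult:
    """Apportion a sample among 2–4 sources by isotope mass balance.

    The per-isotope mass system reduces to the abundance-mixing system
    Σ_i f_i x_j(i) = x_j(sample) with Σ_i f_i = 1.  The normalization is
    enforced exactly by eliminating the last fraction; the four isotope
    balances are then solved by least squares, which returns the exact
    solution whenever the sample is a true mixture of the sources (for
    n = 4 the system is exactly determined) and the least-squares
    compromise, with nonzero residuals, otherwise.
    """
    _check_solvable(sources.n)
    if sources.degenerate:
        raise DegenerateSourceError(
            "two or more sources have identical fingerprints; remove duplicates"
        )
    X = sources.abundance_matrix()
    _check_rank(X, sources.names)
    b = sample.abundances().as_array()

    # eliminate f_n = 1 - sum(f_1..f_{n-1}); same constrained LS problem
    # whichever column is eliminated
    B = X[:, :-1] - X[:, -1:]
    rhs = b - X[:, -1]
    _check_rank(B, sources.names)
    cond = float(np.linalg.cond(B))
    if cond > CONDITION_WARNING_THRESHOLD:
        warnings.warn(
            f"design matrix condition number {cond:.3g} exceeds "
            f"{CONDITION_WARNING_THRESHOLD:.0e}; fractions may be unstable",
            IllConditionedWarning,
            stacklevel=2,
        )
    f_head, *_ = np.linalg.lstsq(B, rhs, rcond=None)
    fractions = np.append(f_head, 1.0 - f_head.sum())
    residuals = X @ fractions - b
    return ApportionResult(
        source_names=sources.names,
        fractions=fractions,
        residuals=residuals,
        condition_number=cond,
        method="mass_balance",
        sample_id=sample.id,
    )


def solve_full_system(sources: SourceSet, sample: MixtureSample) -> FullSystemSolution:
    """Solve the literal per-isotope mass system (the 4n+4 equations).

    Unknowns are the 4n per-source isotope masses m_i^j and the n
    fractions f_i.  Equations: f_i·m = Σ_j m_i^j per source; the three
    chained ratio constraints per source; the three chained ratio
    constraints on the summed mixture masses; and Σ f_i = 1.  Kept as an
    independently coded oracle for :func:`solve_mass_balance` — it never
    forms abundance vectors.
    """
    _check_solvable(sources.n)
    if sources.degenerate:
        raise DegenerateSourceError(
            "two or more sources have identical fingerprints; remove duplicates"
        )
    n = sources.n
    m_total = sample.total_mass
    # unknown vector: [m_1^204, m_1^206, m_1^207, m_1^208, ..., f_1..f_n]
    n_unknowns = 5 * n
    rows: list[np.ndarray] = []
    rhs: list[float] = []

    def mass_idx(i: int, j: int) -> int:
        return 4 * i + j

    def frac_idx(i: int) -> int:
        return 4 * n + i

    # mass-sum equations: f_i * m - sum_j m_i^j = 0
    for i in range(n):
        row = np.zeros(n_unknowns)
        row[frac_idx(i)] = m_total
        row[mass_idx(i, 0):mass_idx(i, 0) + 4] = -1.0
        rows.append(row)
        rhs.append(0.0)

    # per-source chained ratio constraints: m^204 = k1 m^206, etc.
    for i, fp in enumerate(sources.fingerprints):
        k1, k2, k3 = convert(fp, Parameterization.CHAIN_204).as_tuple()
        for (num, den, k) in ((0, 1, k1), (1, 2, k2), (2, 3, k3)):
            row = np.zeros(n_unknowns)
            row[mass_idx(i, num)] = 1.0
            row[mass_idx(i, den)] = -k
            rows.append(row)
            rhs.append(0.0)

    # mixture chained ratio constraints on summed masses
    k7, k8, k9 = convert(sample.fingerprint, Parameterization.CHAIN_204).as_tuple()
    for (num, den, k) in ((0, 1, k7), (1, 2, k8), (2, 3, k9)):
        row = np.zeros(n_unknowns)
        for i in range(n):
            row[mass_idx(i, num)] = 1.0
            row[mass_idx(i, den)] = -k
        rows.append(row)
        rhs.append(0.0)

    # normalization
    row = np.zeros(n_unknowns)
    row[4 * n:] = 1.0
    rows.append(row)
    rhs.append(1.0)

    A = np.vstack(rows)
    assert A.shape == (4 * n + 4, 5 * n)
    solution, *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
    masses = solution[: 4 * n].reshape(n, 4)
    fractions = solution[4 * n:]
    return FullSystemSolution(
        source_names=sources.names,
        masses=masses,
        fractions=fractions,
        total_mass=m_total,
    )


def solve_two_source_closed_form(
    fa: RatioTriple, fb: RatioTriple, fp: RatioTriple
) -> tuple[float, float]:
    """Two-source contribution rates by the printed closed-form solution.

    With the chained ratios k1..k3 of source A, k4..k6 of source B and
    k7..k9 of the sample (k1 = ²⁰⁴Pb/²⁰⁶Pb, k2 = ²⁰⁶Pb/²⁰⁷Pb,
    k3 = ²⁰⁷Pb/²⁰⁸Pb, likewise per set):

        fA = (k1k2k3 + k2k3 + k3 + 1)(k7k8k9 − k4k5k6) / D
        fB = (k4k5k6 + k5k6 + k6 + 1)(k1k2k3 − k7k8k9) / D

    with D the sum of the two numerators, so fA + fB = 1.  The products
    k1k2k3 etc. are the sources' ²⁰⁴Pb/²⁰⁸Pb ratios; if A and B share
    that ratio the denominator vanishes and the pair cannot be separated.
    """
    k1, k2, k3 = convert(fa, Parameterization.CHAIN_204).as_tuple()
    k4, k5, k6 = convert(fb, Parameterization.CHAIN_204).as_tuple()
    k7, k8, k9 = convert(fp, Parameterization.CHAIN_204).as_tuple()
    prod_a, prod_b = k1 * k2 * k3, k4 * k5 * k6
    if abs(prod_a - prod_b) <= RANK_DEFICIENCY_RTOL * max(abs(prod_a), abs(prod_b)):
        raise UnidentifiableError(
            "sources share the same 204Pb/208Pb ratio product "
            "(k1k2k3 = k4k5k6), so the closed-form denominator vanishes for "
            "any consistent mixture; the two sources cannot be separated"
        )
    num_a = (prod_a + k2 * k3 + k3 + 1.0) * (k7 * k8 * k9 - prod_b)
    num_b = (prod_b + k5 * k6 + k6 + 1.0) * (prod_a - k7 * k8 * k9)
    denom = num_a + num_b
    if denom == 0.0:
        raise UnidentifiableError(
            "closed form denominator is zero; the two sources cannot be "
            "separated for this sample"
        )
    return (num_a / denom, num_b / denom)


@dataclass(frozen=True)
class BatchApportionment:
    """Results of apportioning a batch of samples against one source set.

    ``mean_valid_fractions`` averages the fractions of the samples whose
    fractions are all non-negative (the physically interpretable ones),
    mirroring the usual reporting convention of excluding samples flagged
    as influenced by unmodeled sources.
    """

    source_names: tuple[str, ...]
    results: tuple[ApportionResult, ...]
    errors: dict[str, Exception] = field(default_factory=dict)

    @property
    def valid_results(self) -> tuple[ApportionResult, ...]:
        return tuple(r for r in self.results if not r.has_negative)

    @property
    def invalid_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.results if r.has_negative)

    @property
    def mean_valid_fractions(self) -> Optional[np.ndarray]:
        valid = self.valid_results
        if not valid:
            return None
        return np.mean([r.fractions for r in valid], axis=0)


def batch_apportion(
    sources: SourceSet, samples: Sequence[MixtureSample]
) -> BatchApportionment:
    """Apportion every sample; collect per-sample errors instead of failing."""
    results: list[ApportionResult] = []
    errors: dict[str, Exception] = {}
    for sample in samples:
        try:
            results.append(solve_mass_balance(sources, sample))
        except Exception as exc:  # collected, not fatal to the batch
            errors[sample.id] = exc
    return BatchApportionment(
        source_names=sources.names, results=tuple(results), errors=errors
    )
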