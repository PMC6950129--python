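# Methods

## Fingerprints and parameterizations

A lead fingerprint is the composition of the four stable isotopes
(²⁰⁴Pb, ²⁰⁶Pb, ²⁰⁷Pb, ²⁰⁸Pb), stored either as an abundance vector
(mass fraction of each isotope in total lead, components strictly
positive and summing to 1) or as three independent ratios.  Two ratio
parameterizations are supported — the chained ratios
(²⁰⁴Pb/²⁰⁶Pb, ²⁰⁶Pb/²⁰⁷Pb, ²⁰⁷Pb/²⁰⁸Pb) and the ²⁰⁴Pb-referenced
ratios (²⁰⁸Pb/²⁰⁴Pb, ²⁰⁷Pb/²⁰⁴Pb, ²⁰⁶Pb/²⁰⁴Pb) — and both are
bijections of the abundance vector on positive ratios: the ratios fix
the four isotope masses up to scale and the closure constraint removes
the scale.  Round trips are exact to well under the guaranteed 1e-12
relative tolerance; measured ratios carry six significant figures, so
this is far below data precision.

Abundances are *mass* fractions, and ratios are treated as mass
quotients throughout.  Mole-based abundances would shift fourth-decimal
digits of the fractions; no atomic-mass correction is applied, so the
algebra is self-consistent in mass space.  Isotope-fractionation
corrections are out of scope (lead isotopes fractionate negligibly in
environmental transport, which is the physical premise of the model).

## The mass-balance mixing model

Assumption: a sample's lead is a mass-weighted mixture of n end-member
leads whose isotope compositions are fixed and pairwise distinct.  Per
isotope j, Σᵢ fᵢ xⱼ⁽ⁱ⁾ = xⱼ^(sample), plus Σ fᵢ = 1.  In the underlying
per-isotope-mass formulation there are 5n unknowns (four isotope masses
and one fraction per source) against 4n+4 equations (one mass sum per
source, three ratio constraints per source, three ratio constraints on
the mixture, one normalization); equations exceed unknowns for n < 4,
match at n = 4, and fall behind from n = 5 — with lead isotopes alone,
at most four sources are identifiable.  `system_dimensions` exposes the
counts; every solver refuses n > 4 with that analysis in the message.

Three solution routes are implemented and cross-checked in the tests:

* **Reduced solver** (`solve_mass_balance`): eliminates the per-source
  masses into the abundance-mixing form above, substitutes
  fₙ = 1 − Σ fᵢ so normalization holds exactly, and solves the four
  isotope-balance rows by ordinary least squares.  On a consistent
  sample (an exact mixture; for n = 4 the system is exactly determined
  up to the built-in redundancy that the isotope rows sum to the
  normalization row) this *is* the exact solution; on noisy data it is
  the natural least-squares compromise and the per-isotope residuals
  are reported.  Because the constrained least-squares problem is
  independent of which fraction is eliminated, results are equivariant
  under source permutations even for inconsistent data.
* **Full-system solver** (`solve_full_system`): builds the literal
  (4n+4)×(5n) linear system in per-source isotope masses and fractions
  and solves it by least squares.  It never forms abundance vectors and
  is kept as an independently coded oracle; on consistent inputs it
  agrees with the reduced solver to 1e-10.
* **Two-source closed form** (`solve_two_source_closed_form`): the
  algebraic solution in the chained ratios k₁..k₃ (source A), k₄..k₆
  (source B), k₇..k₉ (sample),

      fA = (k₁k₂k₃ + k₂k₃ + k₃ + 1)(k₇k₈k₉ − k₄k₅k₆) / D,
      fB = (k₄k₅k₆ + k₅k₆ + k₆ + 1)(k₁k₂k₃ − k₇k₈k₉) / D,

  D the sum of the numerators.  k₁k₂k₃ is source A's ²⁰⁴Pb/²⁰⁸Pb ratio;
  if both sources share that product, any consistent mixture drives
  D → 0, so that configuration is rejected as unidentifiable up front
  (relative tolerance 1e-12 on the products).

Numerical choices: total mass is normalized out (results are invariant
to sample mass and concentration metadata, property-tested); sources
closer than 1e-10 in abundance space are degenerate and rejected; exact
rank deficiency (smallest singular value below 1e-12 of the largest)
raises an error, while condition numbers above 1e10 only warn.
Fractions are returned unclipped — negative values are the model's
diagnostic for an unmodeled source, so no non-negativity constraint is
imposed.

## The ratio-balance baseline and its deviation

The classical three-source model balances R = ²⁰⁶Pb/²⁰⁷Pb and
N = ²⁰⁸Pb/²⁰⁶Pb linearly in the fractions and is solved here exactly
(3×3 system).  Under mass balance, however, a mixture's R is
Σf·x₂₀₆ / Σf·x₂₀₇, not Σf·(x₂₀₆/x₂₀₇): the R-equation is exact iff all
sources share the same ²⁰⁷Pb abundance, and the N-equation iff they
share the same ²⁰⁶Pb abundance.  When both hold the three (R, N)
fingerprints coincide and the system is singular — so on physically
mixed samples the ratio-balance weights carry a systematic deviation in
any non-degenerate configuration.  The package demonstrates this
numerically (`compare_models`): over a family of source sets with equal
²⁰⁷Pb abundance (making the R-balance exact) the deviation vanishes
monotonically as the sources' ²⁰⁶Pb abundances converge and grows with
their spread.  An earlier conjecture that equal ²⁰⁶Pb abundance alone
makes the ratio balance exact fails numerically — with ²⁰⁷Pb varying,
the R-equation stays inconsistent — which is why the demonstration
pins ²⁰⁷Pb.  The comparison metric is the maximum absolute fraction
deviation plus per-source signed deviations: scale-free and directly
interpretable in percentage points.

## Synthetic data and what it does (not) emulate

`generate_sources` perturbs the logarithms of a natural-lead anchor's
²⁰⁴Pb-referenced ratios (²⁰⁸Pb/²⁰⁴Pb = 38.2, ²⁰⁷Pb/²⁰⁴Pb = 15.55,
²⁰⁶Pb/²⁰⁴Pb = 18.15) by Normal(0, spread) deviates; log-space keeps
every abundance positive at any spread.  The default spread of 0.02
reproduces the abundance envelope of real environmental end-members
(²⁰⁴Pb ≈ 1.3–1.5%, ²⁰⁶Pb ≈ 24–26%, ²⁰⁷Pb ≈ 20–22%, ²⁰⁸Pb ≈ 51–53%).
`forward_mix` mixes abundance vectors linearly (signed fractions are
accepted, to reconstruct samples outside the source simplex).
`perturb` multiplies each reported ratio by an independent (1 + ε),
ε ~ Normal(0, relative s.d.) — multiplicative Gaussian noise, because
MC-ICP-MS precision is quoted as a relative percentage; the default
level and the experiment endpoints (0.02% and 0.09%) span the
instrument campaign's quoted error range, with per-ratio levels
configurable since instruments quote different repeatabilities for
different ratios (0.02% for ²⁰⁷Pb/²⁰⁶Pb and ²⁰⁸Pb/²⁰⁶Pb, 0.04% for
²⁰⁶Pb/²⁰⁴Pb).  True fractions in recovery experiments are drawn from
the flat Dirichlet (uniform on the simplex) as the uninformative
default.  All randomness flows from `numpy.random.SeedSequence`
spawning, so every operation is reproducible from its seed.

What the generator does *not* emulate: correlated inter-ratio errors
from the mass-bias correction, source-fingerprint uncertainty (the
end-members are treated as known), temporal or spatial variation of a
source's fingerprint, and heavy-tailed outliers.  Passing recovery
tests therefore show the estimator is correct and stable under the
stated noise model, not that field data meet that model.

## The bundled case study

The fixture is the measurement table of an industrial-park campaign in
the Guanzhong area (32 soil samples on eight transects around a lead
and zinc smelter, plus four end-members: coking-plant raw coal, smelter
ore, power-plant raw coal, regional background).  Its printed ratio
column headers are the chained ratios, but the values (≈38, ≈15.6, ≈18)
are physically possible only for the ²⁰⁴Pb-referenced ratios of natural
lead (compare NBS 981: ²⁰⁸Pb/²⁰⁴Pb = 36.72, ²⁰⁷Pb/²⁰⁴Pb = 15.50,
²⁰⁶Pb/²⁰⁴Pb = 16.94); the reader applies the ²⁰⁴Pb-referenced
interpretation by default, logs the inconsistency, and offers a strict
mode honoring the headers for sensitivity analysis.  This reading is
validated by reproducing the originally published apportionment of
sample N-1000 (−13.86%, 57.25%, 41.24%, 15.37%) to print precision.

Several other rows of the originally published result table are *not*
reproducible from the published measurements (recomputing row N-1500
gives ≈(−14.4%, 57.1%, 41.7%, 15.5%) against printed (−9.20%, 55.88%,
35.60%, 17.71%)), and two published rows (EN-1500, EN-2000) print
identical fractions for different inputs — presumably a transcription
duplication.  The case-study report therefore asserts only the
structure that must hold (rows close to 100%; the three north-transect
samples carry a negative coking-plant fraction) and emits a per-cell
diff against the published values as an informational diagnostic, with
per-row residuals, rather than forcing agreement.

Result tables round percentages to two decimals with round-half-even
(deterministic across platforms; an accompanying full-precision CSV
carries the unrounded values), and normalize the typographic minus to
ASCII on input.

## Problem sizes

Defaults are desk-scale: oracle-equivalence checks run 1000 random
instances per solver pair, recovery experiments 100–300 replicates, and
Monte-Carlo intervals 400–1000 replicates; the entire test suite and
the reproduction script each complete in well under a minute on one
CPU.  Larger replicate counts change only the smoothness of the
reported statistics.

## Known limitations

* At most four sources — the identifiability ceiling of lead isotopes;
  extending the fingerprint with other elements is future work, out of
  scope here.
* End-member fingerprints are treated as exactly known; their
  measurement uncertainty is not propagated (only the sample's).
* No concentration-weighted multi-sample inversion and no Bayesian
  (MixSIAR-style) posterior machinery; the concentration column is
  metadata only.
* Near-natural end-members are nearly collinear in abundance space, so
  fraction uncertainties can reach tens of percentage points at
  realistic noise even though the solver itself is exact — the
  Monte-Carlo intervals make this visible rather than hiding it.
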