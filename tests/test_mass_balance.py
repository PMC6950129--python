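"""Mass-balance solvers: dimensions, exact recovery, oracle agreement."""

import numpy as np
import pytest

import pbsource as pb
from tests.conftest import random_source_set

REF = pb.Parameterization.REF_204

# Published contribution rates for soil sample N-1000 (percent).
N1000_PUBLISHED_PCT = (-13.86, 57.25, 41.24, 15.37)


class TestSystemDimensions:
    @pytest.mark.parametrize(
        "n, unknowns, equations, solvable",
        [(2, 10, 12, True), (3, 15, 16, True), (4, 20, 20, True),
         (5, 25, 24, False), (6, 30, 28, False)],
    )
    def test_counts_and_solvability(self, n, unknowns, equations, solvable):
        spec = pb.system_dimensions(n)
        assert (spec.n_unknowns, spec.n_equations) == (unknowns, equations)
        assert spec.solvable is solvable
        assert spec.identifiable is solvable

    @pytest.mark.parametrize("bad", [1, 0, -3, 2.5])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(pb.UnidentifiableError):
            pb.system_dimensions(bad)

    def test_exactly_determined_at_four_sources(self):
        crossover = [n for n in range(2, 8)
                     if pb.system_dimensions(n).n_equations
                     == pb.system_dimensions(n).n_unknowns]
        assert crossover == [4]


class TestSolveMassBalance:
    def test_case_study_sample_n1000_matches_published_rates(self, case_inputs):
        sources, samples = case_inputs
        sample = next(s for s in samples if s.id == "N-1000")
        result = pb.solve_mass_balance(sources, sample)
        np.testing.assert_allclose(100 * result.fractions, N1000_PUBLISHED_PCT, atol=0.1)
        assert result.negative_flags.tolist() == [True, False, False, False]
        assert result.fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_sample_at_a_source_vertex_gets_unit_fraction(self, rng):
        sources = random_source_set(rng, 4)
        sample = pb.MixtureSample("vertex", sources.fingerprints[1])
        result = pb.solve_mass_balance(sources, sample)
        np.testing.assert_allclose(result.fractions, [0, 1, 0, 0], atol=1e-10)

    def test_noiseless_forward_mixture_recovered_exactly(self, rng):
        sources = random_source_set(rng, 3)
        sample = pb.forward_mix(sources, [0.5, 0.3, 0.2])
        result = pb.solve_mass_balance(sources, sample)
        np.testing.assert_allclose(result.fractions, [0.5, 0.3, 0.2], atol=1e-10)
        assert result.residual_norm < 1e-12

    def test_permutation_equivariance_even_for_inconsistent_samples(self, rng):
        sources = random_source_set(rng, 4)
        # a perturbed mixture is NOT an exact mixture: the least-squares
        # compromise must still not depend on source ordering
        sample = pb.perturb(
            pb.forward_mix(sources, [0.4, 0.3, 0.2, 0.1]),
            pb.NoiseModel(relative_sd=0.0009, seed=7),
        )
        base = pb.solve_mass_balance(sources, sample)
        order = [2, 0, 3, 1]
        permuted = pb.solve_mass_balance(sources.permuted(order), sample)
        np.testing.assert_allclose(
            permuted.fractions, base.fractions[order], atol=1e-9
        )

    def test_scale_invariance_in_mass_and_concentration(self, case_inputs):
        sources, samples = case_inputs
        s = samples[0]
        heavy = pb.MixtureSample(s.id, s.fingerprint, concentration=999.0, total_mass=5.0)
        a = pb.solve_mass_balance(sources, s)
        b = pb.solve_mass_balance(sources, heavy)
        np.testing.assert_allclose(a.fractions, b.fractions, atol=1e-14)

    def test_five_sources_refused_with_dimension_analysis(self, rng):
        sources = random_source_set(rng, 5)
        sample = pb.MixtureSample("x", sources.fingerprints[0])
        with pytest.raises(pb.UnidentifiableError, match="25 unknowns"):
            pb.solve_mass_balance(sources, sample)

    def test_duplicate_sources_raise_degeneracy_error(self):
        fp = pb.RatioTriple(38.2, 15.55, 18.15, REF)
        sources = pb.SourceSet(("a", "b"), (fp, fp))
        assert sources.degenerate
        with pytest.raises(pb.DegenerateSourceError):
            pb.solve_mass_balance(sources, pb.MixtureSample("x", fp))


class TestSolveFullSystem:
    def test_even_split_of_two_sources_halves_each_source_abundance(self, rng):
        sources = random_source_set(rng, 2)
        sample = pb.forward_mix(sources, [0.5, 0.5])
        sol = pb.solve_full_system(sources, sample)
        np.testing.assert_allclose(sol.fractions, [0.5, 0.5], atol=1e-10)
        X = sources.abundance_matrix()
        np.testing.assert_allclose(sol.masses, 0.5 * X.T, atol=1e-10)

    def test_agrees_with_reduced_solver_on_case_study_sample(self, case_inputs):
        sources, samples = case_inputs
        sample = next(s for s in samples if s.id == "N-1000")
        full = pb.solve_full_system(sources, sample)
        reduced = pb.solve_mass_balance(sources, sample)
        np.testing.assert_allclose(full.fractions, reduced.fractions, atol=1e-10)

    def test_total_mass_scales_masses_not_fractions(self, rng):
        sources = random_source_set(rng, 3)
        mix = pb.forward_mix(sources, [0.2, 0.5, 0.3])
        m1 = pb.solve_full_system(sources, mix)
        m2 = pb.solve_full_system(
            sources, pb.MixtureSample(mix.id, mix.fingerprint, total_mass=2.0)
        )
        np.testing.assert_allclose(m2.masses, 2.0 * m1.masses, atol=1e-9)
        np.testing.assert_allclose(m2.fractions, m1.fractions, atol=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_satisfies_every_equation_on_consistent_data(self, rng, n):
        sources = random_source_set(rng, n)
        f_true = rng.dirichlet(np.ones(n))
        sample = pb.forward_mix(sources, f_true)
        sol = pb.solve_full_system(sources, sample)
        # mass-sum and normalization equations
        np.testing.assert_allclose(
            sol.masses.sum(axis=1), sol.fractions * sample.total_mass, atol=1e-10
        )
        assert sol.fractions.sum() == pytest.approx(1.0, abs=1e-10)
        # per-source and mixture chained-ratio equations
        chain = pb.Parameterization.CHAIN_204
        for i, fp in enumerate(sources.fingerprints):
            k1, k2, k3 = pb.convert(fp, chain).as_tuple()
            m = sol.masses[i]
            assert m[0] == pytest.approx(k1 * m[1], abs=1e-10)
            assert m[1] == pytest.approx(k2 * m[2], abs=1e-10)
            assert m[2] == pytest.approx(k3 * m[3], abs=1e-10)
        k7, k8, k9 = pb.convert(sample.fingerprint, chain).as_tuple()
        tot = sol.masses.sum(axis=0)
        assert tot[0] == pytest.approx(k7 * tot[1], abs=1e-10)
        assert tot[1] == pytest.approx(k8 * tot[2], abs=1e-10)
        assert tot[2] == pytest.approx(k9 * tot[3], abs=1e-10)


class TestTwoSourceClosedForm:
    def test_sample_equal_to_source_a_gives_unit_fraction(self, rng):
        sources = random_source_set(rng, 2)
        fa, fb = pb.solve_two_source_closed_form(
            sources.fingerprints[0], sources.fingerprints[1], sources.fingerprints[0]
        )
        assert fa == pytest.approx(1.0, abs=1e-10)
        assert fb == pytest.approx(0.0, abs=1e-10)

    def test_forward_mixture_fractions_recovered(self, rng):
        sources = random_source_set(rng, 2)
        sample = pb.forward_mix(sources, [0.3, 0.7])
        fa, fb = pb.solve_two_source_closed_form(
            sources.fingerprints[0], sources.fingerprints[1], sample.fingerprint
        )
        assert fa == pytest.approx(0.3, abs=1e-10)
        assert fa + fb == pytest.approx(1.0, abs=1e-12)

    def test_identical_204_208_ratio_products_raise(self):
        # same 204Pb/208Pb product (k1k2k3 = k4k5k6 = 0.0288) but
        # different intermediate ratios: any consistent mixture makes the
        # closed-form denominator vanish
        chain = pb.Parameterization.CHAIN_204
        fa = pb.RatioTriple(0.06, 1.2, 0.4, chain)
        fb = pb.RatioTriple(0.08, 0.9, 0.4, chain)
        sources = pb.SourceSet(("a", "b"), (fa, fb))
        sample = pb.forward_mix(sources, [0.5, 0.5], param=chain)
        with pytest.raises(pb.UnidentifiableError):
            pb.solve_two_source_closed_form(fa, fb, sample.fingerprint)


class TestSolverEquivalences:
    """The three independently coded solution routes agree."""

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_full_system_equals_reduced_solver(self, rng, n):
        for _ in range(50):
            sources = random_source_set(rng, n)
            sample = pb.forward_mix(sources, rng.dirichlet(np.ones(n)))
            full = pb.solve_full_system(sources, sample)
            reduced = pb.solve_mass_balance(sources, sample)
            np.testing.assert_allclose(full.fractions, reduced.fractions, atol=1e-10)

    def test_closed_form_equals_reduced_solver_for_two_sources(self, rng):
        for _ in range(100):
            sources = random_source_set(rng, 2)
            sample = pb.forward_mix(sources, rng.dirichlet(np.ones(2)))
            fa, fb = pb.solve_two_source_closed_form(
                sources.fingerprints[0], sources.fingerprints[1], sample.fingerprint
            )
            reduced = pb.solve_mass_balance(sources, sample)
            np.testing.assert_allclose([fa, fb], reduced.fractions, atol=1e-10)


class TestBatchApportion:
    def test_case_study_batch_flags_the_three_north_samples(self, case_inputs):
        sources, samples = case_inputs
        batch = pb.batch_apportion(sources, samples)
        assert len(batch.results) == 32
        assert not batch.errors
        for sid in ("N-1000", "N-1500", "N-2000"):
            assert sid in batch.invalid_ids
        assert all(
            abs(r.fractions.sum() - 1.0) < 1e-10 for r in batch.results
        )

    def test_empty_sample_list_gives_empty_batch(self, case_sources):
        batch = pb.batch_apportion(case_sources, [])
        assert batch.results == ()
        assert batch.mean_valid_fractions is None

    def test_repeated_sample_gives_identical_rows(self, case_inputs):
        sources, samples = case_inputs
        batch = pb.batch_apportion(sources, [samples[0], samples[0]])
        np.testing.assert_array_equal(
            batch.results[0].fractions, batch.results[1].fractions
        )

    def test_per_sample_errors_collected_not_fatal(self, case_inputs):
        sources, samples = case_inputs
        bad = pb.MixtureSample("bad", sources.fingerprints[0])
        degenerate_sources = pb.SourceSet(
            ("a", "b"), (sources.fingerprints[0], sources.fingerprints[0])
        )
        batch = pb.batch_apportion(degenerate_sources, [bad])
        assert batch.results == ()
        assert isinstance(batch.errors["bad"], pb.DegenerateSourceError)

    def test_mean_excludes_samples_with_negative_fractions(self, case_inputs):
        sources, samples = case_inputs
        batch = pb.batch_apportion(sources, samples)
        valid = [r.fractions for r in batch.results if not r.has_negative]
        np.testing.assert_allclose(
            batch.mean_valid_fractions, np.mean(valid, axis=0), atol=1e-15
        )
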