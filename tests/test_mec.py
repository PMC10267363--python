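"""Constrained-entropy reweighting: tilt solve, cross entropy, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from metamec import synthetic
from metamec.mec import (FreeEnergyProfile, Metastatistics, constrained_average,
                         cross_entropy_direct, cross_entropy_max, ddg,
                         free_energy_mec, metastat_probability,
                         modulation_weights, profile, solve_lambda)
from metamec.metadyn import KB


def three_state():
    return Metastatistics(np.array([0.0, 1.0, 2.0]), np.array([1.0, -2.0, 0.5]),
                          np.array([0.5, 0.3, 0.2]))


class TestMetastatProbability:
    def test_uniform_multiplicity(self):
        ms = Metastatistics(np.arange(5.0), np.zeros(5))
        np.testing.assert_allclose(metastat_probability(ms), 0.2)

    def test_weighted(self):
        ms = Metastatistics(np.array([0.0, 1.0]), np.zeros(2), np.array([1.0, 3.0]))
        np.testing.assert_allclose(metastat_probability(ms), [0.25, 0.75])

    def test_random_multiplicities_normalised(self):
        rng = np.random.default_rng(3)
        mult = rng.uniform(0, 5, 50)
        ms = Metastatistics(np.arange(50.0), np.zeros(50), mult)
        np.testing.assert_allclose(metastat_probability(ms), mult / mult.sum(),
                                   atol=1e-14)
        assert metastat_probability(ms).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            Metastatistics(np.arange(3.0), np.zeros(3), np.zeros(3))


class TestSolveLambda:
    def test_unconstrained_mean_gives_zero(self):
        ms = three_state()
        s = float(np.dot(metastat_probability(ms), ms.xi))
        assert solve_lambda(ms, s) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_uniform_gives_zero(self):
        ms = Metastatistics(np.array([0.0, 1.0, 2.0]), np.zeros(3))
        assert solve_lambda(ms, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_duality_against_convex_minimisation(self):
        # lambda also minimises ln Z(lam) + lam * s (convex dual)
        ms = three_state()
        s = 0.5
        lam = solve_lambda(ms, s)
        p_t = metastat_probability(ms)

        def dual(l):
            return np.log(np.dot(p_t, np.exp(-l * ms.xi))) + l * s

        res = minimize(lambda v: dual(v[0]), x0=[0.0], tol=1e-14)
        assert lam == pytest.approx(res.x[0], abs=1e-6)

    def test_residual_tolerance(self):
        ms = three_state()
        for s in (0.25, 0.5, 1.2, 1.8):
            lam = solve_lambda(ms, s)
            assert np.dot(modulation_weights(ms, lam), ms.xi) == pytest.approx(
                s, abs=1e-9)

    def test_unreachable_target_rejected(self):
        ms = three_state()
        with pytest.raises(ValueError, match="support"):
            solve_lambda(ms, 2.5)
        with pytest.raises(ValueError, match="support"):
            solve_lambda(ms, 0.0)  # boundary is closed, not open

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.05, 1.95))
    def test_lambda_strictly_decreasing_in_s(self, s):
        ms = three_state()
        eps = 0.02
        if s + eps >= 1.95:
            return
        assert solve_lambda(ms, s + eps) < solve_lambda(ms, s)


class TestModulationWeights:
    def test_lambda_zero_recovers_p_tilde(self):
        ms = three_state()
        np.testing.assert_allclose(modulation_weights(ms, 0.0),
                                   metastat_probability(ms), atol=1e-14)

    def test_hand_arithmetic_two_frames(self):
        ms = Metastatistics(np.array([0.0, 1.0]), np.zeros(2))
        np.testing.assert_allclose(modulation_weights(ms, np.log(3.0)),
                                   [0.75, 0.25], atol=1e-12)

    def test_normalised_for_extreme_lambda(self):
        ms = Metastatistics(np.linspace(0, 500, 100), np.zeros(100))
        for lam in (-50.0, 50.0):
            assert modulation_weights(ms, lam).sum() == pytest.approx(1.0, abs=1e-12)

    def test_infinite_lambda_rejected(self):
        with pytest.raises(ValueError):
            modulation_weights(three_state(), np.inf)


class TestCrossEntropy:
    def test_zero_at_lambda_zero(self):
        ms = three_state()
        s = float(np.dot(metastat_probability(ms), ms.xi))
        assert cross_entropy_max(ms, 0.0, s) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_equals_direct_kl(self):
        ms = three_state()
        for s in (0.3, 0.5, 1.0, 1.7):
            lam = solve_lambda(ms, s)
            assert cross_entropy_max(ms, lam, s) == pytest.approx(
                cross_entropy_direct(ms, lam), abs=1e-9)

    def test_nonpositive_everywhere(self):
        ms = three_state()
        for s in np.linspace(0.1, 1.9, 13):
            lam = solve_lambda(ms, s)
            assert cross_entropy_max(ms, lam, s) <= 1e-12

    def test_mismatched_pair_rejected(self):
        ms = three_state()
        with pytest.raises(ValueError):
            cross_entropy_max(ms, 5.0, 1.8)


class TestConstrainedAverage:
    def test_lambda_zero_plain_mean(self):
        ms = three_state()
        out = constrained_average(ms, 0.0, ms.energy)
        assert out == pytest.approx(float(np.dot(metastat_probability(ms), ms.energy)))

    def test_self_consistency_b_equals_xi(self):
        ms = three_state()
        lam = solve_lambda(ms, 0.7)
        assert constrained_average(ms, lam, ms.xi) == pytest.approx(0.7, abs=1e-9)

    def test_hand_computed_energy_average(self):
        ms = three_state()
        lam = 0.4
        w = np.array([0.5, 0.3, 0.2]) * np.exp(-lam * ms.xi)
        w /= w.sum()
        assert constrained_average(ms, lam, ms.energy) == pytest.approx(
            float(np.dot(w, ms.energy)), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            constrained_average(three_state(), 0.0, np.zeros(5))


class TestBruteForceOracle:
    """Tilted solution vs direct constrained maximisation of the entropy."""

    @pytest.mark.parametrize("seed,n,s", [(0, 6, 2.0), (1, 9, 3.5), (2, 12, 1.3)])
    def test_matches_constrained_optimiser(self, seed, n, s):
        rng = np.random.default_rng(seed)
        xi = np.sort(rng.uniform(0, 5, n))
        mult = rng.uniform(0.2, 2.0, n)
        ms = Metastatistics(xi, np.zeros(n), mult)
        lam = solve_lambda(ms, s)
        p_mec = modulation_weights(ms, lam)
        p_t = metastat_probability(ms)

        def neg_entropy(p):
            return float(np.sum(p * np.log(np.maximum(p, 1e-300) / p_t)))

        res = minimize(
            neg_entropy, x0=p_t, method="SLSQP",
            bounds=[(1e-12, 1.0)] * n,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0},
                         {"type": "eq", "fun": lambda p: np.dot(p, xi) - s}],
            options={"maxiter": 2000, "ftol": 1e-16})
        assert res.success
        np.testing.assert_allclose(p_mec, res.x, atol=1e-7)


class TestFreeEnergy:
    def test_lambda_zero_gives_plain_energy(self):
        ms = three_state()
        s = float(np.dot(metastat_probability(ms), ms.xi))
        sol = free_energy_mec(ms, s, T_eff=300.0)
        assert sol.lam == pytest.approx(0.0, abs=1e-9)
        assert sol.G == pytest.approx(
            float(np.dot(metastat_probability(ms), ms.energy)), abs=1e-6)

    def test_entropic_term_nonnegative(self):
        ms = three_state()
        for s in (0.3, 0.9, 1.6):
            sol = free_energy_mec(ms, s, T_eff=300.0)
            assert -sol.T_eff * KB * sol.cross_entropy >= -1e-12

    def test_recovers_generator_free_energy(self, small_ensemble):
        spec, ms = small_ensemble
        grid = np.arange(4.0, 14.5, 2.0)
        prof = profile(ms, grid, s0=14.0, T_eff=spec.T_eff)
        exact = synthetic.exact_free_energy(spec, grid, 14.0)
        dev = np.abs(prof.G_values - exact)
        assert np.all(dev <= 3 * np.maximum(prof.uncertainty, 1e-3))


class TestProfile:
    def test_reference_only_grid_is_zero(self, small_ensemble):
        _, ms = small_ensemble
        prof = profile(ms, np.array([10.0]), s0=10.0, errors="none")
        assert prof.G_values[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_error_estimate_flagged(self, small_ensemble):
        _, ms = small_ensemble
        prof = profile(ms, np.array([8.0]), s0=12.0, errors="none")
        assert prof.uncertainty is None

    def test_unreachable_points_skipped_with_warning(self, small_ensemble):
        _, ms = small_ensemble
        with pytest.warns(UserWarning, match="unreachable"):
            prof = profile(ms, np.array([8.0, 40.0]), s0=12.0, errors="none")
        assert prof.skipped == [40.0]
        assert prof.s_values.tolist() == [8.0]

    def test_lambda_monotone_on_grid(self, small_ensemble):
        _, ms = small_ensemble
        prof = profile(ms, np.arange(4.0, 15.0), s0=14.0, errors="none")
        assert np.all(np.diff(prof.lam) < 0)


class TestDdg:
    def make_profiles(self, shift=0.0):
        s = np.array([4.0, 14.0])
        ref = FreeEnergyProfile(s, np.array([10.0, 0.0]), 14.0)
        var = FreeEnergyProfile(s, np.array([10.0 + shift, 0.0]), 14.0)
        return ref, var

    def test_identical_profiles_zero(self):
        ref, var = self.make_profiles(0.0)
        assert ddg(var, ref, 4.0, 14.0) == pytest.approx(0.0)

    def test_antisymmetry_under_role_swap(self):
        ref, var = self.make_profiles(3.2)
        assert ddg(var, ref, 4.0, 14.0) == pytest.approx(-ddg(ref, var, 4.0, 14.0))

    def test_recovers_injected_gap(self):
        gap = 5.0
        ref, var = synthetic.make_variant_pair(gap, seed=31, n_frames=50_000)
        msr = synthetic.sample_metastatistics(ref)
        msv = synthetic.sample_metastatistics(var)
        pr = profile(msr, np.array([4.0]), 14.0, errors="none")
        pv = profile(msv, np.array([4.0]), 14.0, errors="none")
        assert ddg(pv, pr, 4.0, 14.0) == pytest.approx(gap, abs=0.5)

    def test_constant_energy_shift_invariance(self):
        ref, _ = synthetic.make_variant_pair(0.0, seed=5, n_frames=5_000)
        ms = synthetic.sample_metastatistics(ref)
        shifted = Metastatistics(ms.xi, ms.energy + 123.4, ms.multiplicity, ms.walker)
        p1 = profile(ms, np.array([4.0]), 14.0, errors="none")
        p2 = profile(shifted, np.array([4.0]), 14.0, errors="none")
        assert ddg(p2, p1, 4.0, 14.0) == pytest.approx(0.0, abs=1e-8)

    def test_missing_grid_point_rejected(self):
        ref, var = self.make_profiles()
        with pytest.raises(ValueError):
            ddg(var, ref, 5.0, 14.0)
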