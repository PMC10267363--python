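"""Well-tempered bias construction, altruistic combination, toy sampling."""

import math

import numpy as np
import pytest

from metamec import metadyn, synthetic
from metamec.metadyn import (KB, BiasGrid, BiasPotential, GaussianHill, Schedule,
                             Stage, WTParams, altruistic_combine,
                             average_bias_final, default_schedule, deposit_hill,
                             evaluate_bias, free_energy_from_bias,
                             interpolate_bias_poly4, reweight_wt, run_toy_walker)


class TestWTParams:
    def test_biasing_factor_20_gives_deltaT_5700(self):
        p = WTParams.from_biasing_factor(300.0, 20.0)
        assert p.deltaT == pytest.approx(5700.0, abs=1e-9)
        assert p.biasing_factor == pytest.approx(20.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            WTParams(T=-1)
        with pytest.raises(ValueError):
            WTParams.from_biasing_factor(300.0, 0.5)


class TestEvaluateBias:
    def test_empty_bias_is_offset(self):
        b = BiasPotential()
        assert evaluate_bias(b, 3.7) == 0.0
        b2 = BiasPotential(additive_offset=2.5)
        assert evaluate_bias(b2, -10.0) == 2.5

    def test_gaussian_peak_and_flank(self):
        b = BiasPotential([GaussianHill(5.0, 1.0, 2.0)])
        assert evaluate_bias(b, 5.0) == pytest.approx(2.0)
        assert evaluate_bias(b, 6.0) == pytest.approx(2.0 * math.exp(-0.5), abs=1e-12)

    def test_grid_cache_matches_hills_on_nodes(self):
        b = BiasPotential([GaussianHill(1.0, 0.5, 2.0), GaussianHill(3.0, 1.5, 1.0)])
        grid = b.to_grid(-2.0, 6.0, 0.1)
        np.testing.assert_allclose(grid.values, evaluate_bias(b, grid.nodes), atol=1e-12)


class TestDepositHill:
    def test_first_hill_height_is_w(self):
        p = WTParams(gaussian_height_w=1.3)
        b = deposit_hill(BiasPotential(), 2.0, p, t=20.0)
        assert b.hills[0].height == pytest.approx(1.3)

    def test_second_hill_tempered_by_first(self):
        p = WTParams(gaussian_height_w=1.0, deltaT=5700.0)
        b = deposit_hill(BiasPotential(), 2.0, p)
        b = deposit_hill(b, 2.0, p)
        expected = 1.0 * math.exp(-1.0 / (KB * 5700.0))
        assert b.hills[1].height == pytest.approx(expected, rel=1e-12)

    def test_untempered_heights_all_w(self):
        p = WTParams(tempered=False, gaussian_height_w=0.7)
        b = BiasPotential()
        for s in (0.0, 0.0, 1.0, 0.0):
            deposit_hill(b, s, p)
        assert all(h.height == pytest.approx(0.7) for h in b.hills)

    def test_heights_nonincreasing_at_revisited_center(self):
        p = WTParams(deltaT=600.0)
        b = BiasPotential()
        heights = []
        for _ in range(10):
            deposit_hill(b, 1.0, p)
            heights.append(b.hills[-1].height)
        assert all(h2 <= h1 + 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_deltaT_zero_rejected_when_tempered(self):
        p = WTParams(deltaT=0.0)
        with pytest.raises(ValueError):
            deposit_hill(BiasPotential(), 0.0, p)


class TestFreeEnergyFromBias:
    def test_zero_at_reference(self):
        b = BiasPotential([GaussianHill(0.0, 1.0, 3.0)])
        p = WTParams()
        assert free_energy_from_bias(b, p, 1.5, 1.5) == pytest.approx(0.0)

    def test_prefactor_from_biasing_factor_20(self):
        # gamma/(gamma-1) = 6000/5700 at T=300, dT=5700
        p = WTParams.from_biasing_factor(300.0, 20.0)
        grid = BiasGrid(np.array([0.0, 1.0]), np.array([0.0, -1.0]))
        # V(s)-V(s0) = -1 kJ/mol -> +6000/5700 kJ/mol
        val = free_energy_from_bias(grid, p, 1.0, 0.0)
        assert val == pytest.approx(6000.0 / 5700.0, rel=1e-12)

    def test_offset_invariance(self):
        p = WTParams()
        b1 = BiasPotential([GaussianHill(0.0, 1.0, 3.0)])
        b2 = BiasPotential([GaussianHill(0.0, 1.0, 3.0)], additive_offset=17.0)
        assert free_energy_from_bias(b1, p, 2.0, 0.5) == pytest.approx(
            free_energy_from_bias(b2, p, 2.0, 0.5), rel=1e-12)

    def test_deltaT_zero_rejected(self):
        with pytest.raises(ValueError):
            free_energy_from_bias(BiasPotential(), WTParams(deltaT=0.0), 1.0, 0.0)


def constant_bias(value, lo=-1.0, hi=1.0):
    return BiasPotential(base=BiasGrid(np.array([lo, hi]), np.array([value, value])))


class TestAltruisticCombine:
    def test_alpha_zero_is_identity(self):
        biases = [BiasPotential([GaussianHill(0.0, 1.0, 1.0)]),
                  BiasPotential([GaussianHill(2.0, 1.0, 2.0)])]
        out = altruistic_combine(biases, alpha=0.0, w_share=1.0)
        s = np.linspace(-3, 5, 50)
        for b_in, b_out in zip(biases, out):
            np.testing.assert_allclose(evaluate_bias(b_out, s), evaluate_bias(b_in, s),
                                       atol=1e-12)

    def test_identical_biases_are_fixed_point(self):
        biases = [constant_bias(3.0) for _ in range(4)]
        out = altruistic_combine(biases, alpha=1.0, w_share=0.0)
        for b in out:
            assert evaluate_bias(b, 0.3) == pytest.approx(3.0)

    def test_hand_evaluated_mixture(self):
        # alpha=1, w=1/2, constants 0 and 2: V_i' = (V_i + mean)/2 = (V_i + 1)/2
        biases = [constant_bias(0.0), constant_bias(2.0)]
        out = altruistic_combine(biases, alpha=1.0, w_share=0.5)
        assert evaluate_bias(out[0], 0.0) == pytest.approx(0.5)
        assert evaluate_bias(out[1], 0.0) == pytest.approx(1.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            altruistic_combine([], 0.5, 0.5)


class TestAverageBias:
    def test_mean_of_constants(self):
        avg = average_bias_final([constant_bias(0.0), constant_bias(4.0)])
        assert evaluate_bias(avg, 0.1) == pytest.approx(2.0)

    def test_many_walkers_match_per_node_oracle(self):
        rng = np.random.default_rng(8)
        nodes = np.linspace(0, 16, 161)
        vals = rng.normal(size=(90, nodes.size))
        biases = [BiasPotential(base=BiasGrid(nodes, v)) for v in vals]
        avg = average_bias_final(biases, spacing=0.1)
        np.testing.assert_allclose(avg(nodes), vals.mean(axis=0), atol=1e-9)


class TestPoly4:
    def test_exact_quartic_reproduced(self):
        coeffs = np.array([0.5, -1.0, 0.3, 0.02, -0.004])
        nodes = np.linspace(0.5, 15.5, 40)
        vals = np.polynomial.polynomial.polyval(nodes, coeffs)
        interp = interpolate_bias_poly4(BiasGrid(nodes, vals), (0.5, 15.5))
        np.testing.assert_allclose(interp.coeffs, coeffs, atol=1e-8)

    def test_c1_continuity_at_boundaries(self):
        rng = np.random.default_rng(2)
        nodes = np.linspace(0.0, 16.0, 80)
        vals = np.sin(nodes) + rng.normal(0, 0.1, nodes.size)
        interp = interpolate_bias_poly4(BiasGrid(nodes, vals), (0.5, 15.5))
        for edge in (0.5, 15.5):
            h = 1e-7
            jump = interp(edge + h) - 2 * interp(edge) + interp(edge - h)
            assert abs(interp(edge + h) - interp(edge - h)) < 1e-5  # value continuous
            assert abs(jump) < 1e-9  # derivative continuous
        # linear outside: second difference far outside is zero
        assert interp(-2.0) - 2 * interp(-3.0) + interp(-4.0) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        nodes = np.linspace(0.5, 15.5, 60)
        truth = 0.1 * (nodes - 8) ** 2
        vals = truth + rng.normal(0, 0.5, nodes.size)
        interp = interpolate_bias_poly4(BiasGrid(nodes, vals), (0.5, 15.5))
        # independent normal-equations solve
        A = np.vander(nodes, 5, increasing=True)
        beta = np.linalg.solve(A.T @ A, A.T @ vals)
        np.testing.assert_allclose(interp.coeffs, beta, rtol=1e-6, atol=1e-8)

    def test_too_few_nodes_rejected(self):
        nodes = np.linspace(0, 16, 40)
        grid = BiasGrid(nodes, np.zeros_like(nodes))
        with pytest.raises(ValueError):
            interpolate_bias_poly4(grid, (7.9, 8.4))


class TestSchedule:
    def test_production_staging_bookkeeping(self):
        sched = default_schedule()
        assert sched.construction_ns == pytest.approx(22.0)
        assert sched.equilibration_ns == pytest.approx(8.0)
        assert sched.pre_collection_ns == pytest.approx(30.0)

    def test_stage_validation(self):
        with pytest.raises(ValueError):
            Stage("x", -1.0)
        with pytest.raises(ValueError):
            Stage("x", 1.0, alpha=1.5)


def short_toy_schedule(build_ps=60.0, collect_ps=40.0, exchange_ps=20.0):
    return Schedule([
        Stage("eq", 10.0, None, None, False),
        Stage("build", build_ps, 1.0, 0.5, True),
        Stage("collect", collect_ps, None, None, False),
    ], exchange_ns=exchange_ps)


class TestToyWalker:
    def test_zero_temperature_stays_at_minimum(self):
        spec = synthetic.ToyLandscapeSpec(barrier=10.0, temperature=1e-12)
        sys = synthetic.make_double_well(spec)
        p = WTParams(T=1e-12, tempered=False, gaussian_height_w=1e-12, tau_G=1e9)
        sched = Schedule([Stage("build", 5.0, 1.0, 1.0, True),
                          Stage("collect", 5.0, None, None, False)], exchange_ns=5.0)
        series, _, _ = run_toy_walker(sys, p, sched, seed=0, ns_to_ps=1.0,
                                      sample_stride_ps=0.1)
        np.testing.assert_allclose(series[0].xi, sys.s_init, atol=1e-6)

    def test_determinism(self):
        spec = synthetic.ToyLandscapeSpec(barrier=8.0)
        sys = synthetic.make_double_well(spec)
        p = WTParams.from_biasing_factor(300.0, 20.0, gaussian_width_delta=0.3,
                                         tau_G=5.0)
        runs = [run_toy_walker(sys, p, short_toy_schedule(), n_walkers=2, seed=42,
                               ns_to_ps=1.0, sample_stride_ps=0.5) for _ in range(2)]
        for s1, s2 in zip(runs[0][0], runs[1][0]):
            np.testing.assert_array_equal(s1.xi, s2.xi)
            np.testing.assert_array_equal(s1.times, s2.times)

    def test_symmetric_double_well_balanced_occupancy(self):
        spec = synthetic.ToyLandscapeSpec(barrier=6.0, half_separation=1.0)
        sys = synthetic.make_double_well(spec)
        p = WTParams.from_biasing_factor(300.0, 20.0, gaussian_width_delta=0.3,
                                         tau_G=2.0)
        sched = Schedule([Stage("build", 400.0, 1.0, 0.5, True),
                          Stage("collect", 600.0, None, None, False)],
                         exchange_ns=100.0)
        series, bias, _ = run_toy_walker(sys, p, sched, seed=9, ns_to_ps=1.0,
                                         sample_stride_ps=0.1)
        w = reweight_wt(series[0], bias, p)
        p_right = float(np.sum(w[series[0].xi > spec.center]))
        assert p_right == pytest.approx(0.5, abs=0.1)


class TestReweight:
    def test_zero_bias_gives_plain_mean(self):
        xi = np.array([0.0, 1.0, 2.0, 3.0])
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        out = reweight_wt(xi, BiasPotential(), WTParams(), obs)
        assert out == pytest.approx(obs.mean())

    def test_constant_bias_cancels(self):
        xi = np.array([0.0, 1.0, 2.0])
        obs = np.array([5.0, 7.0, 9.0])
        out = reweight_wt(xi, constant_bias(42.0, -1, 3), WTParams(), obs)
        assert out == pytest.approx(obs.mean())

    def test_known_double_well_populations(self):
        # reweighting a biased series must restore the Boltzmann ratio
        from scipy.integrate import quad

        spec = synthetic.ToyLandscapeSpec(barrier=10.0, tilt=1.5, half_separation=1.0)
        sys = synthetic.make_double_well(spec)
        p = WTParams.from_biasing_factor(300.0, 20.0, gaussian_width_delta=0.3,
                                         tau_G=2.0)
        sched = Schedule([Stage("build", 600.0, 1.0, 0.5, True),
                          Stage("collect", 600.0, None, None, False)],
                         exchange_ns=150.0)
        series, bias, _ = run_toy_walker(sys, p, sched, seed=13, ns_to_ps=1.0,
                                         sample_stride_ps=0.1)
        w = reweight_wt(series[0], bias, p)
        p_right = float(np.sum(w[series[0].xi > spec.center]))
        beta = 1.0 / (KB * 300.0)
        zr, _ = quad(lambda s: np.exp(-beta * sys.free_energy(s)),
                     spec.center, sys.domain[1])
        zl, _ = quad(lambda s: np.exp(-beta * sys.free_energy(s)),
                     sys.domain[0], spec.center)
        assert p_right == pytest.approx(zr / (zr + zl), abs=0.1)
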