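"""Rayleigh fractionation core: scalar ops, pool simulation, NIE fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import n2opools as n

R_STD = n.R15_AIR_N2


def integrate_instantaneous_fractionation(delta_s0, f, eta, steps=20000):
    """Oracle: Euler integration of d(delta) = (eta/1000)(delta+1000) d ln f."""
    ln_f = np.log(f)
    h = ln_f / steps
    delta = delta_s0
    for _ in range(steps):
        delta += (eta / 1000.0) * (delta + 1000.0) * h
    return delta


def atom_bookkeeping(delta_s0, f_target, eta, steps=4000):
    """Oracle: exact heavy/light atom bookkeeping of substrate and product.

    Consumes total substrate in equal steps; the instantaneous product's
    isotope ratio is alpha times the substrate's.  Returns (delta_substrate,
    delta_cumulative_product) at remaining total fraction f_target.
    """
    alpha = 1.0 + eta / 1000.0
    r0 = R_STD * (1.0 + delta_s0 / 1000.0)
    light, heavy = 1.0 / (1.0 + r0), r0 / (1.0 + r0)
    p_light = p_heavy = 0.0
    dn = (1.0 - f_target) / steps
    for _ in range(steps):
        r_p = alpha * heavy / light
        dl = dn / (1.0 + r_p)
        dh = dn - dl
        light -= dl
        heavy -= dh
        p_light += dl
        p_heavy += dh
    def to_delta(h, l):
        return (h / l / R_STD - 1.0) * 1000.0
    return to_delta(heavy, light), to_delta(p_heavy, p_light)


class TestRayleighDelta:
    def test_no_consumption_is_identity(self):
        assert n.rayleigh_delta(12.3, 1.0, -45.0) == pytest.approx(12.3)

    def test_zero_nie_is_identity(self):
        assert n.rayleigh_delta(10.0, 0.5, 0.0) == pytest.approx(10.0)

    def test_enrichment_value(self):
        assert n.rayleigh_delta(0.0, 0.5, -30.0) == pytest.approx(21.01, abs=0.01)

    @pytest.mark.parametrize("f", [0.05, 0.2, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("eta", [-60.0, -30.0, -5.0, 0.0, 10.0])
    def test_agrees_with_integration_oracle(self, f, eta):
        got = n.rayleigh_delta(5.0, f, eta)
        want = integrate_instantaneous_fractionation(5.0, f, eta)
        assert got == pytest.approx(want, abs=0.01)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            n.rayleigh_delta(0.0, 0.0, -30.0)
        with pytest.raises(ValueError):
            n.rayleigh_delta(0.0, 1.5, -30.0)

    @given(f=st.floats(0.05, 1.0), eta=st.floats(-60.0, -0.1))
    def test_residual_substrate_enriches(self, f, eta):
        assert n.rayleigh_delta(0.0, f, eta) >= -1e-12


class TestFractionSubstrateRemaining:
    def test_no_loss(self):
        assert n.fraction_substrate_remaining(100.0, 0.0) == 1.0

    def test_quarter_consumed(self):
        assert n.fraction_substrate_remaining(100.0, 25.0) == 0.75

    def test_monotone_loss_gives_nonincreasing_f(self):
        loss = np.array([0.0, 1.0, 3.0, 7.0, 7.0, 9.0])
        f = n.fraction_substrate_remaining(10.0, loss)
        assert np.all(np.diff(f) <= 0)

    def test_exhaustion_reports_time(self):
        with pytest.raises(n.SubstrateExhaustedError) as err:
            n.fraction_substrate_remaining(10.0, np.array([0.0, 5.0, 10.0]),
                                           pool_name="pool1_fertiliser",
                                           times=np.array([0.0, 1.0, 2.0]))
        assert err.value.time_days == 2.0
        assert err.value.pool == "pool1_fertiliser"


class TestProducedAndEmitted:
    def test_produced_is_additive(self):
        assert n.delta_n2o_produced(0.0, 0.0) == 0.0
        assert n.delta_n2o_produced(21.0, -30.0) == pytest.approx(-9.0)

    def test_produced_matches_instantaneous_product_in_f_to_1_limit(self):
        # for f -> 1 the exact instantaneous product delta approaches
        # alpha*(delta_S0 + 1000) - 1000 ~= delta_S0 + eta
        d0, eta = 10.0, -30.0
        exact = (1 + eta / 1000.0) * (d0 + 1000.0) - 1000.0
        approx = n.delta_n2o_produced(n.rayleigh_delta(d0, 1.0, eta), eta)
        assert approx == pytest.approx(exact, abs=0.5)

    def test_no_reduction_is_identity(self):
        assert n.delta_n2o_emitted(-30.0, 1.0, -6.0) == pytest.approx(-30.0)

    def test_half_reduced_value(self):
        assert n.delta_n2o_emitted(-30.0, 0.5, -6.0) == pytest.approx(-25.96, abs=0.01)

    def test_total_reduction_rejected(self):
        with pytest.raises(ValueError):
            n.delta_n2o_emitted(-30.0, 0.0, -6.0)

    def test_more_reduction_enriches_emitted(self):
        rs = [1.0, 0.8, 0.5, 0.2]
        deltas = [n.delta_n2o_emitted(-30.0, r, -6.0) for r in rs]
        assert np.all(np.diff(deltas) > 0)

    def test_open_system_variant(self):
        got = n.delta_n2o_emitted(-30.0, 0.5, -6.0, form="open")
        assert got == pytest.approx(-30.0 + 6.0 * 0.5)


class TestMassBalance:
    @pytest.mark.parametrize("eta", [-80.0, -30.0, -5.0])
    @pytest.mark.parametrize("f", [0.3, 0.6, 0.9])
    def test_delta_space_rayleigh_vs_exact_atom_bookkeeping(self, eta, f):
        """The delta-space approximation stays within 0.5 per mil of exact
        isotope mass balance for |delta|, |eta| < 100 per mil."""
        d0 = 10.0
        exact_s, exact_p = atom_bookkeeping(d0, f, eta)
        model_s = n.rayleigh_delta(d0, f, eta)
        assert model_s == pytest.approx(exact_s, abs=0.5)
        # pool mass balance: f*delta_S + (1-f)*delta_cumulative_product = delta_S0
        alpha = 1.0 + eta / 1000.0
        model_p = (d0 + 1000.0) * (1.0 - f**alpha) / (1.0 - f) - 1000.0
        assert model_p == pytest.approx(exact_p, abs=0.5)
        assert f * model_s + (1 - f) * model_p == pytest.approx(d0, abs=1e-9)


def _flux_pair(times, n2o_flux, n2_flux, vessel=None):
    return (n.GasFluxSeries("N2O", times, n2o_flux, vessel),
            n.GasFluxSeries("N2", times, n2_flux, vessel))


def _params(eta_p=-30.0, eta_r=-6.0, n1=25.0, d1=0.0, n2_=27.6, d2=10.0):
    return n.RayleighParameters(
        eta_production=eta_p, eta_reduction=eta_r,
        pools=(n.fertiliser_pool(n1, d1), n.soil_pool(n2_, d2)))


class TestSimulatePool:
    def test_zero_loss_keeps_deltas_constant(self):
        t = np.linspace(0, 5, 6)
        ratio = n.ProductRatioSeries(t, np.ones_like(t))
        params = _params()
        traj = n.simulate_pool(params.pools[0], np.zeros_like(t), ratio, params)
        assert np.allclose(traj.f_substrate, 1.0)
        assert np.allclose(traj.delta_no3_residual, 0.0)
        assert np.allclose(traj.delta_n2o_produced, -30.0)
        assert np.allclose(traj.delta_n2o_emitted, -30.0)  # r=1: no shift

    def test_single_step_equals_composed_scalar_ops(self):
        t = np.array([0.0, 1.0])
        loss = np.array([0.0, 5.0])
        r = np.array([1.0, 0.7])
        params = _params()
        traj = n.simulate_pool(params.pools[0], loss, n.ProductRatioSeries(t, r), params)
        f = n.fraction_substrate_remaining(25.0, 5.0)
        d_res = n.rayleigh_delta(0.0, f, -30.0)
        d_prod = n.delta_n2o_produced(d_res, -30.0)
        d_emit = n.delta_n2o_emitted(d_prod, 0.7, -6.0)
        assert traj.f_substrate[1] == pytest.approx(f)
        assert traj.delta_no3_residual[1] == pytest.approx(d_res)
        assert traj.delta_n2o_produced[1] == pytest.approx(d_prod)
        assert traj.delta_n2o_emitted[1] == pytest.approx(d_emit)

    def test_monotone_loss_without_reduction_monotone_delta(self):
        t = np.linspace(0, 5, 20)
        loss = np.linspace(0, 12, 20)
        ratio = n.ProductRatioSeries(t, np.ones_like(t))
        params = _params()
        traj = n.simulate_pool(params.pools[0], loss, ratio, params)
        assert np.all(np.diff(traj.delta_n2o_emitted) > 0)

    def test_exhaustion_propagates(self):
        t = np.array([0.0, 1.0])
        params = _params(n1=4.0)
        with pytest.raises(n.SubstrateExhaustedError):
            n.simulate_pool(params.pools[0], np.array([0.0, 4.0]),
                            n.ProductRatioSeries(t, np.ones(2)), params)


class TestTwoPool:
    def _setup(self):
        t = np.linspace(0, 10, 121)
        n2o = 3.0 * np.exp(-0.5 * (t - 3) ** 2)
        n2 = 1.5 * np.exp(-0.3 * (t - 5) ** 2)
        return _flux_pair(t, n2o, n2)

    def test_full_mixing_bitwise_equals_one_pool(self):
        n2o, n2 = self._setup()
        params = _params()
        always_pool1 = n.CubicMixingFunction(0.0, 0.0, 0.0, 100.0)
        two = n.simulate_two_pool(params, n2o, n2, always_pool1)
        one = n.simulate_one_pool(params, n2o, n2)
        assert np.array_equal(two.delta_bulk_mixed, one.delta_bulk_mixed)
        assert np.array_equal(two.pool1.f_substrate, one.pool1.f_substrate)

    def test_identical_pools_make_mixing_irrelevant(self):
        n2o, n2 = self._setup()
        pool = n.NitrogenPool("pool1_fertiliser", 30.0, 5.0)
        pool2 = n.NitrogenPool("pool2_soil", 30.0, 5.0)
        params = n.RayleighParameters(-30.0, -6.0, (pool, pool2))
        mixing = n.CubicMixingFunction(0.0, 0.0, 0.0, 50.0)
        traj = n.simulate_two_pool(params, n2o, n2, mixing)
        # each pool of 30 loses half the N, so its f(t) equals that of a
        # single pool of 60 taking the whole loss
        double = n.RayleighParameters(-30.0, -6.0,
                                      (n.NitrogenPool("pool1_fertiliser", 60.0, 5.0), pool2))
        ref = n.simulate_one_pool(double, n2o, n2)
        assert traj.delta_bulk_mixed == pytest.approx(ref.delta_bulk_mixed, abs=1e-9)

    def test_mixed_delta_is_convex_combination(self):
        n2o, n2 = self._setup()
        params = _params()
        mixing = n.CubicMixingFunction(0.01, -0.5, 2.0, 55.0)
        traj = n.simulate_two_pool(params, n2o, n2, mixing)
        lo = np.minimum(traj.pool1.delta_n2o_emitted, traj.pool2.delta_n2o_emitted)
        hi = np.maximum(traj.pool1.delta_n2o_emitted, traj.pool2.delta_n2o_emitted)
        assert np.all(traj.delta_bulk_mixed >= lo - 1e-12)
        assert np.all(traj.delta_bulk_mixed <= hi + 1e-12)

    def test_self_consistency_with_stored_truth(self, clean_experiment):
        sc = clean_experiment.scenario
        for tr in ("1c", "3c"):
            stored = clean_experiment.truth.trajectories[tr]
            redone = n.simulate_two_pool(sc.params[tr],
                                         clean_experiment.truth.fluxes[tr]["N2O"],
                                         clean_experiment.truth.fluxes[tr]["N2"],
                                         sc.mixing[tr])
            assert np.max(np.abs(redone.delta_bulk_mixed
                                 - stored.delta_bulk_mixed)) < 1e-9


class TestFitNIE:
    def test_noise_free_recovery(self, clean_experiment):
        sc = clean_experiment.scenario
        truth = clean_experiment.truth
        for tr in ("1c", "3c"):
            tj = truth.trajectories[tr]
            days = np.asarray(sc.unlabelled_days)
            obs = np.interp(days, tj.times, tj.delta_bulk_mixed)
            res = n.fit_nie(days, obs, truth.fluxes[tr]["N2O"],
                            truth.fluxes[tr]["N2"], sc.mixing[tr],
                            sc.params[tr].pools)
            assert abs(res.params.eta_production - sc.params[tr].eta_production) <= 0.1
            assert abs(res.params.eta_reduction - sc.params[tr].eta_reduction) <= 0.1
            assert res.r_squared == pytest.approx(1.0, abs=1e-9)
            assert res.converged

    def test_delta_s0_can_float(self, clean_experiment):
        sc = clean_experiment.scenario
        truth = clean_experiment.truth
        tj = truth.trajectories["3c"]
        days = np.asarray(sc.unlabelled_days)
        obs = np.interp(days, tj.times, tj.delta_bulk_mixed)
        res = n.fit_nie(days, obs, truth.fluxes["3c"]["N2O"], truth.fluxes["3c"]["N2"],
                        sc.mixing["3c"], sc.params["3c"].pools,
                        free=("eta_production", "eta_reduction",
                              "delta_no3_initial_pool1"))
        assert res.params.pool("pool1_fertiliser").delta_no3_initial == pytest.approx(
            0.0, abs=0.5)

    def test_too_few_observations_rejected(self):
        t = np.linspace(0, 10, 20)
        n2o, n2 = _flux_pair(t, np.full(20, 1.0), np.full(20, 0.5))
        params = _params()
        with pytest.raises(ValueError):
            n.fit_nie([5.0], [0.0], n2o, n2, None, params.pools)
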