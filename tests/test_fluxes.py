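"""Flux conversion, baseline subtraction, integration and product ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import n2opools as n


def molar_volume_oracle_flux(conc_ppm, flow_ml_min, vessel, gas,
                             temp_k=293.15, press_kpa=101.325):
    """Independent dimensional-analysis route via the 22.414 L/mol molar volume."""
    vm_l_mol = 22.414 * (temp_k / 273.15) * (101.325 / press_kpa)
    mol_min = flow_ml_min / 1000.0 / vm_l_mol
    atoms = {"NO": 1, "N2O": 2, "N2": 2, "CO2": 1}[gas]
    mass_g_mol = {"NO": 14.0067, "N2O": 14.0067, "N2": 14.0067, "CO2": 12.011}[gas]
    g_per_day = conc_ppm * 1e-6 * mol_min * atoms * mass_g_mol * 60 * 24
    return g_per_day / 1000.0 / vessel.surface_area_m2 * 1e4


class TestConcentrationToFlux:
    def test_matches_dimensional_oracle(self, vessel_3c):
        got = n.concentration_to_flux(1.0, 30.0, vessel_3c, "N2O")
        oracle = molar_volume_oracle_flux(1.0, 30.0, vessel_3c, "N2O")
        assert got == pytest.approx(oracle, rel=1e-4)
        assert got == pytest.approx(0.10544, abs=1e-4)

    def test_zero_concentration_gives_zero(self, vessel_3c):
        assert n.concentration_to_flux(0.0, 30.0, vessel_3c, "NO") == 0.0

    @pytest.mark.parametrize("gas", ["NO", "N2O", "N2", "CO2"])
    def test_linear_in_concentration_and_flow(self, vessel_3c, gas):
        base = n.concentration_to_flux(1.0, 30.0, vessel_3c, gas)
        assert n.concentration_to_flux(2.0, 30.0, vessel_3c, gas) == pytest.approx(2 * base)
        assert n.concentration_to_flux(1.0, 60.0, vessel_3c, gas) == pytest.approx(2 * base)

    def test_n2o_counts_two_nitrogen_atoms(self, vessel_3c):
        one = n.concentration_to_flux(1.0, 30.0, vessel_3c, "NO")
        two = n.concentration_to_flux(1.0, 30.0, vessel_3c, "N2O")
        assert two == pytest.approx(2 * one)

    def test_errors(self, vessel_3c):
        with pytest.raises(ValueError):
            n.concentration_to_flux(1.0, 0.0, vessel_3c, "N2O")
        with pytest.raises(ValueError):
            n.concentration_to_flux(1.0, 30.0, vessel_3c, "CH4")
        with pytest.raises(ValueError):
            n.concentration_to_flux(-1.0, 30.0, vessel_3c, "N2O")


class TestSubtractBaseline:
    def test_hourly_baseline_converted_to_daily(self):
        series = n.GasFluxSeries("CO2", [0.0, 1.0], [20.0, 20.0])
        out = n.subtract_baseline(series, 0.67)
        assert out.fluxes == pytest.approx([3.92, 3.92])
        assert np.array_equal(out.times, series.times)

    def test_zero_baseline_is_identity(self):
        series = n.GasFluxSeries("CO2", [0.0, 1.0], [5.0, 7.0])
        out = n.subtract_baseline(series, 0.0)
        assert np.array_equal(out.fluxes, series.fluxes)

    def test_baseline_equal_series_zeroes_it(self):
        series = n.GasFluxSeries("CO2", [0.0, 1.0], [24 * 0.67] * 2)
        out = n.subtract_baseline(series, 0.67)
        assert out.fluxes == pytest.approx([0.0, 0.0])

    def test_negative_results_retained_and_flagged(self):
        series = n.GasFluxSeries("CO2", [0.0, 1.0], [1.0, 30.0])
        out = n.subtract_baseline(series, 0.67)
        assert out.fluxes[0] < 0
        assert list(out.negative_mask) == [True, False]


class TestCumulativeEmission:
    def test_constant_flux(self):
        series = n.GasFluxSeries("N2O", [0, 0.5, 1, 2], [1.0] * 4)
        assert n.cumulative_emission(series, 0, 2).total == pytest.approx(2.0)

    def test_linear_ramp_triangle_area(self):
        series = n.GasFluxSeries("N2O", [0, 1, 2], [0.0, 1.0, 2.0])
        assert n.cumulative_emission(series, 0, 2).total == pytest.approx(2.0)

    def test_gamma_pulse_matches_analytic_integral(self):
        # bi-hourly sampling of a smooth pulse: trapezoid error < 0.1 %
        t = np.arange(0, 12 + 1e-9, 2 / 24)
        shape, scale, total = 4.0, 1.0, 7.5
        flux = total * stats.gamma.pdf(t, shape, scale=scale)
        series = n.GasFluxSeries("N2O", t, flux)
        exact = total * (stats.gamma.cdf(10, shape, scale=scale)
                         - stats.gamma.cdf(0, shape, scale=scale))
        got = n.cumulative_emission(series, 0, 10).total
        assert got == pytest.approx(exact, rel=1e-3)

    def test_window_endpoints_interpolated(self):
        series = n.GasFluxSeries("N2O", [0, 2], [0.0, 2.0])
        # over [0.5, 1.5]: integral of f(t)=t is (1.5^2-0.5^2)/2 = 1.0
        assert n.cumulative_emission(series, 0.5, 1.5).total == pytest.approx(1.0)

    @given(split=st.floats(0.1, 1.9))
    def test_additive_over_adjacent_windows(self, split):
        series = n.GasFluxSeries("N2O", [0, 0.7, 1.3, 2], [1.0, 3.0, 0.5, 2.0])
        whole = n.cumulative_emission(series, 0, 2).total
        parts = (n.cumulative_emission(series, 0, split).total
                 + n.cumulative_emission(series, split, 2).total)
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_invariant_to_collinear_point_insertion(self):
        series = n.GasFluxSeries("N2O", [0, 2], [1.0, 3.0])
        dense = n.GasFluxSeries("N2O", [0, 1, 2], [1.0, 2.0, 3.0])
        assert (n.cumulative_emission(series, 0, 2).total
                == pytest.approx(n.cumulative_emission(dense, 0, 2).total, rel=1e-14))

    def test_window_outside_range_errors(self):
        series = n.GasFluxSeries("N2O", [0, 2], [1.0, 1.0])
        with pytest.raises(ValueError):
            n.cumulative_emission(series, -1, 2)
        with pytest.raises(ValueError):
            n.cumulative_emission(series, 1, 1)


class TestTotalDenitrification:
    @staticmethod
    def _cum(gas, total, vessel=None):
        return n.CumulativeEmission(gas, 0.0, 10.0, total, vessel)

    def test_zero(self):
        assert n.total_denitrification(self._cum("NO", 0), self._cum("N2O", 0),
                                       self._cum("N2", 0)) == 0.0

    def test_is_arithmetic_sum(self):
        got = n.total_denitrification(self._cum("NO", 0.0079),
                                      self._cum("N2O", 6.73),
                                      self._cum("N2", 2.88))
        assert got == pytest.approx(9.6179)

    def test_mixed_vessels_rejected(self):
        v1 = n.VesselConfig.from_treatment("a", "1c")
        v2 = n.VesselConfig.from_treatment("b", "3c")
        with pytest.raises(ValueError, match="mixed vessels"):
            n.total_denitrification(self._cum("NO", 1, v1), self._cum("N2O", 1, v2),
                                    self._cum("N2", 1, v1))

    def test_wrong_gas_order_rejected(self):
        with pytest.raises(ValueError):
            n.total_denitrification(self._cum("N2O", 1), self._cum("NO", 1),
                                    self._cum("N2", 1))


class TestProductRatio:
    def test_no_n2_means_ratio_one(self):
        n2o = n.GasFluxSeries("N2O", [0, 1, 2], [1.0, 2.0, 3.0])
        n2 = n.GasFluxSeries("N2", [0, 1, 2], [0.0, 0.0, 0.0])
        r = n.product_ratio(n2o, n2)
        assert np.allclose(r.r_n2o, 1.0)

    def test_equal_fluxes_give_half(self):
        n2o = n.GasFluxSeries("N2O", [0, 1], [2.0, 2.0])
        n2 = n.GasFluxSeries("N2", [0, 1], [2.0, 2.0])
        assert np.allclose(n.product_ratio(n2o, n2).r_n2o, 0.5)

    def test_crossing_series_pointwise(self):
        n2o = n.GasFluxSeries("N2O", [0, 1, 2], [3.0, 2.0, 1.0])
        n2 = n.GasFluxSeries("N2", [0, 1, 2], [1.0, 2.0, 3.0])
        assert n.product_ratio(n2o, n2).r_n2o == pytest.approx([0.75, 0.5, 0.25])

    def test_zero_denominator_flagged_not_filled(self):
        n2o = n.GasFluxSeries("N2O", [0, 1], [0.0, 1.0])
        n2 = n.GasFluxSeries("N2", [0, 1], [0.0, 1.0])
        r = n.product_ratio(n2o, n2)
        assert not r.defined[0] and np.isnan(r.r_n2o[0])
        assert r.defined[1]

    def test_negative_flux_flagged(self):
        n2o = n.GasFluxSeries("N2O", [0, 1], [-0.5, 1.0])
        n2 = n.GasFluxSeries("N2", [0, 1], [1.0, 1.0])
        r = n.product_ratio(n2o, n2)
        assert not r.defined[0]

    @given(seed=st.integers(0, 1000))
    def test_defined_ratios_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, 8))
        t += np.arange(8) * 1e-6  # enforce strict increase
        n2o = n.GasFluxSeries("N2O", t, rng.uniform(0, 5, 8))
        n2 = n.GasFluxSeries("N2", t, rng.uniform(0, 5, 8))
        r = n.product_ratio(n2o, n2)
        ok = r.r_n2o[r.defined]
        assert np.all((ok >= 0) & (ok <= 1))
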