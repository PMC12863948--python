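"""Closed-form excretion model against independent numerical oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from pulsedose import (
    MarkerCurveParams,
    MarkerDose,
    ParamError,
    compartment_masses,
    curve_auc,
    derive_all,
    excretion_concentration,
    excretion_density,
    fecal_output_dm,
    residence_times,
)
from conftest import random_valid_params


def convolution_oracle(t: float, p: MarkerCurveParams) -> float:
    """C(t) by brute-force convolution of Erlang-2(lambda1) with Exp(k2)
    transit densities, scaled by C2/k2.  Independent of the closed form."""
    u = t - p.tau
    if u <= 0:
        return 0.0
    erlang2 = stats.gamma(a=2, scale=1.0 / p.lambda1)
    dens, _ = integrate.quad(
        lambda s: erlang2.pdf(s) * p.k2 * np.exp(-p.k2 * (u - s)), 0.0, u,
        limit=200)
    return (p.c2 / p.k2) * dens


class TestExcretionConcentration:
    def test_zero_at_and_before_delay(self, true_params):
        assert excretion_concentration(12.0, true_params) == 0.0
        assert excretion_concentration(3.0, true_params) == 0.0

    @pytest.mark.parametrize("t", [20.0, 32.0, 50.0, 80.0])
    def test_matches_convolution_oracle(self, t, true_params):
        expected = convolution_oracle(t, true_params)
        got = excretion_concentration(t, true_params)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_frozen_value(self, true_params):
        # oracle value for (t=32, lambda1=0.3, k2=0.05, tau=12, C2=1000)
        assert excretion_concentration(32.0, true_params) == pytest.approx(
            508.33, abs=0.01)

    def test_fast_first_compartment_limit(self):
        """lambda1 -> infinity collapses to a single exponential."""
        p = MarkerCurveParams(1e6, 0.05, 12.0, 1000.0)
        got = excretion_concentration(22.0, p)
        assert got == pytest.approx(1000.0 * np.exp(-0.5), rel=1e-4)

    def test_equal_rates_limit_is_continuous(self):
        k = 0.05
        exact = MarkerCurveParams(k, k, 5.0, 800.0)
        near = MarkerCurveParams(k * (1 + 1e-5), k, 5.0, 800.0)
        t = np.linspace(5.0, 120.0, 40)
        a = excretion_concentration(t, exact)
        b = excretion_concentration(t, near)
        assert np.allclose(a, b, rtol=1e-3)
        # Erlang-3 closed form at equal rates
        u = 30.0
        expected = 800.0 * (k * u) ** 2 / 2 * np.exp(-k * u)
        assert excretion_concentration(5.0 + u, exact) == pytest.approx(expected)

    def test_nonnegative_and_vanishing(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = random_valid_params(rng)
            t = np.linspace(0.0, p.tau + 40.0 / p.k2, 200)
            c = excretion_concentration(t, p)
            assert np.all(c >= 0)
            assert c[-1] < 1e-6 * c.max()

    def test_invalid_params_raise(self):
        with pytest.raises(ParamError):
            MarkerCurveParams(-0.1, 0.05, 1.0, 100.0)
        with pytest.raises(ParamError):
            MarkerCurveParams(0.3, 0.05, -1.0, 100.0)
        with pytest.raises(ParamError):
            excretion_concentration(-1.0, MarkerCurveParams(0.3, 0.05, 1, 100))


class TestAuc:
    def test_closed_form_equals_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_valid_params(rng)
            num, _ = integrate.quad(
                lambda t: excretion_concentration(t, p), 0.0, 2000.0,
                limit=500, points=[p.tau, p.tau + 1 / p.k2])
            assert curve_auc(p) == pytest.approx(num, rel=1e-6)

    def test_independent_of_lambda_and_tau(self):
        a = curve_auc(MarkerCurveParams(0.2, 0.05, 5.0, 1000.0))
        b = curve_auc(MarkerCurveParams(0.8, 0.05, 19.0, 1000.0))
        assert a == b == pytest.approx(20000.0)

    def test_linear_in_c2(self):
        p1 = MarkerCurveParams(0.3, 0.05, 12.0, 1000.0)
        p2 = MarkerCurveParams(0.3, 0.05, 12.0, 2000.0)
        assert curve_auc(p2) == pytest.approx(2 * curve_auc(p1))


class TestFecalOutput:
    def test_dose_dilution_value(self):
        p = MarkerCurveParams(0.33, 0.055, 12.8, 1003.0)
        fo = fecal_output_dm(p, MarkerDose(4540.0))
        # 24 * D / AUC with AUC = C2/k2
        assert fo == pytest.approx(24 * 4540 / curve_auc(p), rel=1e-12)
        assert fo == pytest.approx(5.975, abs=1e-3)

    def test_inverse_in_c2_increasing_in_k2(self):
        d = MarkerDose(4540.0)
        base = fecal_output_dm(MarkerCurveParams(0.3, 0.05, 12, 1000), d)
        half = fecal_output_dm(MarkerCurveParams(0.3, 0.05, 12, 2000), d)
        more = fecal_output_dm(MarkerCurveParams(0.3, 0.06, 12, 1000), d)
        assert half == pytest.approx(base / 2)
        assert more > base


class TestResidenceTimes:
    def test_footnote_formula(self):
        rt = residence_times(MarkerCurveParams(0.33, 0.055, 12.8, 1003.0))
        assert rt.rtg == pytest.approx(37.04, abs=0.01)
        rt2 = residence_times(MarkerCurveParams(0.10, 0.061, 5.5, 1000.0))
        assert rt2.rtg == pytest.approx(20 + 1 / 0.061 + 5.5, rel=1e-12)
        assert rt2.rtg == pytest.approx(41.89, abs=0.01)

    def test_equals_numerical_first_moment(self):
        """Cross-validates the model form: mean excretion time of the
        transit density must equal 2/lambda1 + 1/k2 + tau."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = random_valid_params(rng)
            hi = p.tau + 60.0 / p.k2
            m1, _ = integrate.quad(
                lambda t: t * excretion_density(t, p), 0.0, hi,
                limit=500, points=[p.tau], epsabs=1e-12, epsrel=1e-10)
            assert m1 == pytest.approx(residence_times(p).rtg, rel=1e-5)

    def test_fast_compartment_limit(self):
        rt = residence_times(MarkerCurveParams(1e9, 0.05, 10.0, 500.0))
        assert rt.mcrt2 == pytest.approx(0.0, abs=1e-8)
        assert rt.rtg == pytest.approx(1 / 0.05 + 10.0, rel=1e-8)


class TestCompartmentMasses:
    def test_steady_state_identities(self):
        p = MarkerCurveParams(0.33, 0.055, 12.8, 1003.0)
        d = MarkerDose(4540.0)
        fo_rate = fecal_output_dm(p, d) / 24.0
        m = compartment_masses(p, d, fo_rate)
        assert m.cm2 == pytest.approx(4540 / 1003, rel=1e-12)
        assert m.cm2 == pytest.approx(4.527, abs=1e-3)
        # Little's law: mass = flux x mean residence time
        assert m.cm1 == pytest.approx(fo_rate * 2 / 0.33, rel=1e-12)
        assert m.cm1 == pytest.approx(0.2490 * 2 / 0.33, abs=2e-3)
        assert m.cms == pytest.approx(m.cm1 + m.cm2)
        assert m.cf2 == pytest.approx(fecal_output_dm(p, d), rel=1e-12)

    def test_inconsistent_rate_warns(self):
        p = MarkerCurveParams(0.33, 0.055, 12.8, 1003.0)
        d = MarkerDose(4540.0)
        with pytest.warns(UserWarning, match="inconsistent"):
            m = compartment_masses(p, d, fo_rate=1.0)
        assert np.isfinite(m.cms)


class TestDeriveAll:
    @pytest.mark.parametrize("ash,mult", [(0.212, 0.85), (0.10, 0.90),
                                          (0.15, 0.85)])
    def test_ash_cap(self, ash, mult, dose):
        p = MarkerCurveParams(0.33, 0.055, 12.8, 1003.0)
        d = derive_all(p, dose, ash)
        assert d.om_multiplier == pytest.approx(mult)
        assert d.fo_om == pytest.approx(d.fo_dm * mult)
        assert d.cms_om == pytest.approx(d.cms * mult)

    def test_invariants_random_sweep(self, dose):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = random_valid_params(rng)
            ash = rng.uniform(0.0, 0.4)
            d = derive_all(p, dose, ash)
            assert d.rtg == pytest.approx(d.mcrts + p.tau, rel=1e-12)
            assert d.cms == pytest.approx(d.cm1 + d.cm2, rel=1e-12)
            assert d.cf2 == pytest.approx(d.fo_dm, rel=1e-12)
            assert 0.85 - 1e-12 <= d.om_multiplier <= 1.0
            assert d.fo_om <= d.fo_dm

    def test_bad_ash_raises(self, dose):
        with pytest.raises(ParamError):
            derive_all(MarkerCurveParams(0.3, 0.05, 12, 1000), dose, 1.2)


class TestMarkerDose:
    def test_bolus_accounting(self):
        d = MarkerDose.from_boluses(6, 756.0)
        assert d.total_mg == pytest.approx(4536.0)

    def test_inconsistent_bolus_count_raises(self):
        with pytest.raises(ParamError):
            MarkerDose(total_mg=5000.0, n_boluses=6, per_bolus_mg=756.0)

    def test_nonpositive_raises(self):
        with pytest.raises(ParamError):
            MarkerDose(0.0)
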