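"""Curve fitting: preprocessing rules, multi-start search, deletion ladder."""

import numpy as np
import pytest
from scipy.optimize import golden

from pulsedose import (
    FecalSeries,
    FitConfig,
    FitError,
    MarkerCurveModel,
    MarkerCurveParams,
    MarkerDose,
    excretion_concentration,
    fit_curve,
    initial_start_grid,
    preprocess_series,
    refit_with_deletion,
)
from pulsedose.simulate import SimConfig, make_schedule, simulate_series


def make_series(t, conc, dose_mg=4536.0, background=0.0):
    return FecalSeries.from_arrays(np.asarray(t, float),
                                   np.asarray(conc, float),
                                   MarkerDose(dose_mg),
                                   background_conc=background)


class TestPreprocess:
    def test_background_subtraction_and_clamp(self):
        s = make_series([15, 20, 25, 30, 40, 50], [500, 3, 700, 600, 400, 200],
                        background=6.36)
        out = preprocess_series(s)
        concs = [x.conc for x in out.samples]
        assert concs[0] == pytest.approx(493.64)
        assert concs[1] == 0.0  # clamped, 3 < background

    def test_big_dip_flagged_not_dropped(self):
        """A mid-curve value below 20% of both neighbours is the
        out-of-sequence dip pattern; it must be flagged, not removed."""
        true = MarkerCurveParams(0.3, 0.05, 12.0, 1000.0)
        t = np.linspace(15.0, 85.0, 15)
        conc = excretion_concentration(t, true)
        conc[7] = 0.1 * min(conc[6], conc[8])
        out = preprocess_series(make_series(t, conc))
        flagged = [s for s in out.samples if s.excluded]
        assert len(flagged) == 1
        assert flagged[0].reason == "big_dip"
        assert len(out.samples) == 15

    def test_all_excluded_raises(self):
        s = make_series([10, 20], [1.0, 2.0], background=100.0)
        s.samples[0].excluded = True
        s.samples[1].excluded = True
        with pytest.raises(FitError, match="empty"):
            preprocess_series(s)


class TestStartGrid:
    def test_default_grid_size(self, noiseless_series):
        starts = initial_start_grid(noiseless_series)
        assert len(starts) == 5 * 4 * 3 * 3  # 180

    def test_scaling_to_series(self):
        s = make_series([14.0, 20, 30, 40, 50, 60],
                        [600, 900, 1200, 800, 500, 300])
        starts = initial_start_grid(s)
        c2s = sorted({p.c2 for p in starts})
        assert c2s == [600.0, 1200.0, 1800.0]
        taus = sorted({p.tau for p in starts})
        assert taus == pytest.approx([7.0, 11.2, 14.0])


class TestFitCurve:
    def test_noiseless_identifiability(self, noiseless_series, true_params):
        res = MarkerCurveModel(noiseless_series).fit()
        est = res.params.as_array()
        true = true_params.as_array()
        assert np.all(np.abs(est / true - 1) < 1e-4)
        assert res.converged and res.n_starts == 180
        assert res.mse == pytest.approx(0.0, abs=1e-10)

    def test_no_signal_raises(self):
        s = make_series(np.linspace(1, 10, 8), np.zeros(8))
        with pytest.raises(FitError):
            fit_curve(s)

    def test_too_few_samples(self):
        s = make_series([15, 20, 30, 40], [100, 300, 250, 100])
        with pytest.raises(FitError, match="degrees of freedom"):
            fit_curve(s)

    def test_estimates_respect_bounds_and_flag_cap(self):
        """Data generated beyond the passage-rate cap must pin k2 at the
        cap and flag it rather than exceed it silently."""
        fast = MarkerCurveParams(0.4, 0.08, 10.0, 800.0)
        t = np.linspace(12.0, 80.0, 16)
        s = make_series(t, excretion_concentration(t, fast))
        res = fit_curve(s, FitConfig(k2_cap=0.061))
        assert res.params.k2 <= 0.061 + 1e-12
        assert res.at_k2_bound

    def test_cap_disabled_recovers_fast_passage(self):
        fast = MarkerCurveParams(0.4, 0.08, 10.0, 800.0)
        t = np.linspace(12.0, 80.0, 16)
        s = make_series(t, excretion_concentration(t, fast))
        res = fit_curve(s, FitConfig(k2_cap=None))
        assert res.params.k2 == pytest.approx(0.08, rel=1e-4)
        assert not res.at_k2_bound

    def test_deterministic(self, true_params):
        cfg = SimConfig()
        rng = np.random.default_rng(99)
        sched = make_schedule(cfg, rng)
        series = simulate_series(true_params, sched, cfg, rng)
        a = MarkerCurveModel(preprocess_series(series)).fit()
        series2 = FecalSeries([type(s)(s.t, s.conc) for s in series.samples],
                              series.dose, series.background_conc)
        b = MarkerCurveModel(preprocess_series(series2)).fit()
        assert a.params == b.params
        assert a.sse == b.sse

    def test_zero_residual_deletion_stability(self, noiseless_series,
                                              true_params):
        """Dropping an exactly-fitted point cannot move the optimum."""
        base = MarkerCurveModel(noiseless_series).fit()
        pruned = FecalSeries(list(noiseless_series.samples),
                             noiseless_series.dose)
        pruned.samples[5].excluded = True
        res = MarkerCurveModel(pruned).fit()
        assert np.allclose(res.params.as_array(), base.params.as_array(),
                           rtol=1e-6)

    def test_recovery_improves_as_noise_shrinks(self, true_params):
        """Median |relative error| non-increasing over CV 10% -> 5% -> 2%
        on identical seeds."""
        med = []
        for cv in (0.10, 0.05, 0.02):
            cfg = SimConfig(assay_cv=cv, biological_cv=0.0)
            errs = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                sched = make_schedule(cfg, rng)
                series = simulate_series(true_params, sched, cfg, rng,
                                         background=0.0)
                res = MarkerCurveModel(preprocess_series(series)).fit()
                errs.append(np.abs(res.params.as_array()
                                   / true_params.as_array() - 1))
            med.append(np.median(errs, axis=0))
        med = np.array(med)
        assert np.all(np.diff(med, axis=0) <= 1e-9)


class TestDeletionLadder:
    def _stalled_series(self):
        true = MarkerCurveParams(0.3, 0.05, 12.0, 1000.0)
        t = np.array([15.0, 18, 22, 26, 30, 31.5, 36, 45, 55, 65, 75, 85])
        conc = excretion_concentration(t, true)
        conc[4] = conc[5] = 380.0  # near-identical pair 1.5 h apart, off-curve
        return make_series(t, conc)

    def test_deletes_one_pair_member(self):
        plain = fit_curve(self._stalled_series())
        res = refit_with_deletion(self._stalled_series(),
                                  mse_threshold=plain.mse * 0.8)
        assert res.n_deleted == 1
        assert any("adjacent-similar" in line for line in res.ladder_log)
        assert res.mse < plain.mse * 0.8

    def test_converging_series_skips_ladder(self, noiseless_series):
        res = refit_with_deletion(noiseless_series)
        assert res.n_deleted == 0
        assert res.ladder_log == ["step0: plain fit succeeded"]

    def test_exhausted_ladder_raises_with_log(self):
        plain = fit_curve(self._stalled_series())
        with pytest.raises(FitError) as exc:
            refit_with_deletion(self._stalled_series(),
                                mse_threshold=plain.mse * 1e-6)
        assert exc.value.log  # the escalation log travels with the error
        assert any("exhausted" in line for line in exc.value.log)


class TestDiagnostics:
    def test_peak_time_matches_golden_section(self, noiseless_series,
                                              true_params):
        res = MarkerCurveModel(noiseless_series).fit()
        p = res.params
        t_star = golden(lambda t: -excretion_concentration(float(t), p),
                        brack=(p.tau + 1e-3, p.tau + 20.0), tol=1e-10)
        assert res.peak_time() == pytest.approx(t_star, abs=1e-4)
        assert p.tau < res.peak_time() < p.tau + 40.0

    def test_residual_table_and_summary(self, noiseless_series):
        res = MarkerCurveModel(noiseless_series).fit()
        diag = res.diagnostics()
        assert set(diag.columns) == {"t", "observed", "fitted", "residual"}
        assert np.allclose(diag["residual"], 0.0, atol=1e-6)
        text = res.summary()
        assert "lambda1" in text and "passage rate" in text
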