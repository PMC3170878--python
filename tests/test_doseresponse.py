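"""Sigmoid fitting, extrapolation rule, range extension, aggregation."""

import numpy as np
import pandas as pd
import pytest

from pcassay.doseresponse import (
    AggregationError,
    FitResult,
    fit_sigmoid,
    needs_range_extension,
    relative_increase,
    summarize_experiments,
)
from pcassay.synthetic import default_concentrations, hill_curve


def _points(concs, activities):
    return pd.DataFrame(
        {"concentration_uM": concs, "activity_nmol_mg_hr": activities}
    )


def _noiseless_points(baseline, top, ec50, hill=1.0, concs=None):
    concs = np.asarray(concs if concs is not None else default_concentrations())
    return _points(concs, hill_curve(concs, baseline, top, ec50, hill))


class TestFitSigmoid:
    def test_noiseless_exact_recovery(self):
        # positive-control scale: baseline 1854, plateau 27765, EC50 7.7 µM
        pts = _noiseless_points(1854.0, 27765.0, 7.7)
        fit = fit_sigmoid(pts)
        assert fit.converged and not fit.extrapolated
        assert fit.baseline == pytest.approx(1854.0, rel=1e-9)
        assert fit.top == pytest.approx(27765.0, rel=1e-6)
        assert fit.ec50_uM == pytest.approx(7.7, rel=1e-6)
        assert fit.max_activity == pytest.approx(27765.0, rel=1e-6)

    def test_fit_reproduces_every_input_point(self):
        pts = _noiseless_points(500.0, 20000.0, 42.0)
        fit = fit_sigmoid(pts)
        c = pts["concentration_uM"].to_numpy()
        predicted = hill_curve(c, fit.baseline, fit.top, fit.ec50_uM, fit.hill)
        assert np.allclose(predicted, pts["activity_nmol_mg_hr"], rtol=1e-9)

    def test_flat_data_unconverged(self):
        pts = _points(default_concentrations(), [1000.0] * 11)
        fit = fit_sigmoid(pts)
        assert not fit.converged
        assert fit.flat
        assert fit.max_activity == 1000.0  # observed at highest tested c

    def test_free_hill_recovers_steep_curve(self):
        pts = _noiseless_points(100.0, 9000.0, 12.0, hill=2.0)
        fit = fit_sigmoid(pts, hill_fixed=False)
        assert fit.converged
        assert fit.hill == pytest.approx(2.0, rel=1e-4)
        assert fit.ec50_uM == pytest.approx(12.0, rel=1e-4)

    def test_extrapolated_ec50_uses_observed_top_activity(self):
        # EC50 beyond the 800 µM limit: report the observed activity at the
        # highest tested concentration, not the fitted plateau
        pts = _noiseless_points(0.0, 30000.0, 5000.0)
        fit = fit_sigmoid(pts)
        assert fit.converged
        assert fit.ec50_uM == pytest.approx(5000.0, rel=1e-4)
        assert fit.extrapolated
        observed_top = hill_curve(1000.0, 0.0, 30000.0, 5000.0)
        assert fit.max_activity == pytest.approx(observed_top, rel=1e-9)
        assert fit.max_activity < fit.top

    def test_non_extrapolated_iff_ec50_below_threshold(self):
        for ec50, flag in [(500.0, False), (900.0, True)]:
            fit = fit_sigmoid(_noiseless_points(100.0, 10000.0, ec50))
            assert fit.extrapolated is flag

    def test_monotone_decreasing_data_flagged_not_raised(self):
        pts = _noiseless_points(20000.0, 20000.0, 7.7)
        pts["activity_nmol_mg_hr"] = np.linspace(20000.0, 15000.0, len(pts))
        fit = fit_sigmoid(pts)
        assert fit.converged
        assert fit.top_below_baseline

    def test_requires_vehicle_group_and_enough_concentrations(self):
        with pytest.raises(ValueError):
            fit_sigmoid(_points([1.0, 3.0, 10.0, 30.0, 100.0], [1.0] * 5))
        with pytest.raises(ValueError):
            fit_sigmoid(_points([0.0, 1.0, 3.0, 10.0], [1.0] * 4))

    def test_initial_guess_insensitivity(self, rng):
        # the EC50 retry grid makes the converged optimum independent of the
        # starting point across noisy replicates
        concs = np.asarray(default_concentrations())
        for _ in range(20):
            truth = hill_curve(concs, 1000.0, 25000.0, 15.0)
            noisy = truth * rng.lognormal(0, 0.1, truth.shape)
            noisy[concs == 0] = 1000.0
            fits = [
                fit_sigmoid(_points(concs, noisy)) for _ in range(2)
            ]
            assert fits[0].ec50_uM == pytest.approx(fits[1].ec50_uM, rel=1e-6)


class TestRangeExtension:
    def test_low_ec50_saturated(self):
        fit = fit_sigmoid(_noiseless_points(1854.0, 27765.0, 7.7))
        assert not needs_range_extension(fit, default_concentrations())

    def test_high_ec50_triggers_extension(self):
        # an EC50 near 600 µM against a 1 mM top concentration has not
        # saturated: extend toward 20 mM
        fit = fit_sigmoid(_noiseless_points(0.0, 25000.0, 592.0))
        assert needs_range_extension(fit, default_concentrations())

    def test_unconverged_fit_is_conservative(self):
        flat = fit_sigmoid(_points(default_concentrations(), [500.0] * 11))
        assert needs_range_extension(flat, default_concentrations())


class TestRelativeIncrease:
    def test_zero_baseline_not_calculable(self):
        assert relative_increase(0.0, 6462.0) is None

    def test_equal_baseline_and_max(self):
        assert relative_increase(5000.0, 5000.0) == 1.0

    def test_mean_of_ratios_aggregation(self):
        ratios = [relative_increase(b, m) for b, m in [(10, 20), (10, 30), (10, 40)]]
        assert np.mean(ratios) == pytest.approx(3.0)
        assert np.std(ratios, ddof=1) / np.sqrt(3) == pytest.approx(0.577, abs=1e-3)


def _fit(baseline, top, ec50, **kw):
    defaults = dict(
        baseline=baseline,
        top=top,
        ec50_uM=ec50,
        hill=1.0,
        extrapolated=ec50 > 800.0,
        highest_tested_uM=1000.0,
        max_activity=top if ec50 <= 800.0 else top * 1000.0 / (ec50 + 1000.0),
        converged=True,
        rss=0.0,
        n_points=40,
    )
    defaults.update(kw)
    return FitResult(**defaults)


class TestSummarize:
    def test_identical_fits_have_zero_sem(self):
        fits = [_fit(1854.0, 27765.0, 7.7)] * 3
        s = summarize_experiments(fits, [33000.0] * 3)
        assert s.n == 3 and s.reportable
        for pair in (s.baseline_mean_sem, s.max_mean_sem, s.ec50_mean_sem_uM):
            assert pair[1] == 0.0
        assert s.relative_increase_mean_sem[0] == pytest.approx(27765.0 / 1854.0)

    def test_mean_of_ratios_not_ratio_of_means(self):
        # constructed so the two aggregations differ: mean of per-experiment
        # ratios is 1.2125, ratio of means is 1.25
        fits = [_fit(10000.0, 11000.0, 1.0), _fit(20000.0, 26500.0, 1.0)]
        s = summarize_experiments(fits, [33000.0] * 2)
        ratio_of_means = s.max_mean_sem[0] / s.baseline_mean_sem[0]
        assert s.relative_increase_mean_sem[0] == pytest.approx(1.2125)
        assert ratio_of_means == pytest.approx(1.25)
        assert s.relative_increase_mean_sem[0] != pytest.approx(ratio_of_means)

    def test_zero_baseline_propagates_nc(self):
        fits = [_fit(0.0, 6462.0, 592.0)] * 3
        s = summarize_experiments(fits, [33000.0] * 3)
        assert s.relative_increase_mean_sem is None
        assert s.baseline_imputed_zero

    def test_unconverged_fits_excluded(self):
        fits = [_fit(1854.0, 27765.0, 7.7)] * 3 + [
            _fit(1854.0, 27765.0, 7.7, converged=False)
        ]
        s = summarize_experiments(fits, [33000.0] * 4)
        assert s.n == 3
        assert s.n_excluded == 1

    def test_pct_wt_uses_per_experiment_reference(self):
        fits = [_fit(1000.0, 2000.0, 5.0), _fit(1000.0, 2000.0, 5.0)]
        s = summarize_experiments(fits, [20000.0, 40000.0])
        assert s.baseline_pct_wt_mean_sem[0] == pytest.approx((5.0 + 2.5) / 2)

    def test_empty_or_mismatched_inputs_raise(self):
        with pytest.raises(AggregationError):
            summarize_experiments([], [])
        with pytest.raises(AggregationError):
            summarize_experiments([_fit(1.0, 2.0, 5.0)], [1.0, 2.0])
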