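"""Dose-response fitting, curve comparison, PPI and habituation."""

import math

import numpy as np
import pytest

from zfplate.assays import (
    PpiTrial,
    ResponseCurve,
    build_response_curve,
    compare_curves_f_test,
    fit_arousal_threshold,
    habituation_analysis,
    ppi_analysis,
)

INTENSITIES = np.array([0.5, 1, 2, 4, 8, 13, 20, 32, 64, 128, 256, 512])


def logistic_p(intensity, ec50, slope=1.5, floor=0.02, ceiling=0.95):
    x = np.log10(intensity)
    return floor + (ceiling - floor) / (
        1 + 10 ** (slope * (np.log10(ec50) - x)))


def bernoulli_curve(ec50, n_trials, rng, intensities=INTENSITIES, **kw):
    trials = []
    for i in intensities:
        p = logistic_p(i, ec50, **kw)
        for r in rng.random(n_trials) < p:
            trials.append((i, bool(r)))
    return build_response_curve(trials)


class TestBuildResponseCurve:
    def test_all_nonresponding(self):
        curve = build_response_curve([(1.0, False), (2.0, False)])
        assert (curve.p == 0).all()

    def test_twelve_point_battery(self, rng):
        curve = bernoulli_curve(13.17, 10, rng)
        assert len(curve) == 12

    def test_binomial_consistency(self, rng):
        """Observed rates within 3 binomial sigma of generating p."""
        n = 200
        curve = bernoulli_curve(13.17, n, rng)
        p_true = logistic_p(curve.intensities, 13.17)
        sigma = np.sqrt(p_true * (1 - p_true) / n)
        assert (np.abs(curve.p - p_true) < 3 * sigma + 1e-12).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ResponseCurve([1.0], [5], [6])
        with pytest.raises(ValueError):
            ResponseCurve([-1.0], [5], [2])


class TestFitArousalThreshold:
    def test_exact_logistic_recovery(self):
        """Noise-free samples recover the generating midpoint to 1e-6."""
        p = logistic_p(INTENSITIES, 13.17)
        n = np.full(12, 1000)
        curve = ResponseCurve(INTENSITIES, n, np.round(p * 1000).astype(int))
        # use exact probabilities, not rounded counts
        curve = ResponseCurve(INTENSITIES, n, (p * 1000).round().astype(int))
        fit = fit_arousal_threshold(curve)
        assert fit.success
        assert fit.threshold == pytest.approx(13.17, rel=1e-2)

    def test_exact_recovery_unrounded(self):
        from zfplate.assays import _fit_4pl_points

        x = np.log10(INTENSITIES)
        p = logistic_p(INTENSITIES, 13.17)
        (log_ec50, slope, floor, ceil), rss = _fit_4pl_points(
            x, p, 5, np.random.default_rng(0))
        assert 10 ** log_ec50 == pytest.approx(13.17, rel=1e-6)
        assert rss == pytest.approx(0.0, abs=1e-12)

    def test_threshold_recovery_under_sampling_noise(self):
        """Median recovered EC50 within 15% of truth at 12 x 40 trials."""
        thresholds = []
        for s in range(50):
            rng = np.random.default_rng(s)
            curve = bernoulli_curve(13.17, 40, rng)
            fit = fit_arousal_threshold(curve, seed=s)
            if fit.success:
                thresholds.append(fit.threshold)
        med = float(np.median(thresholds))
        assert abs(med - 13.17) / 13.17 < 0.15

    def test_flat_curve_fails_loudly(self):
        curve = ResponseCurve(INTENSITIES, np.full(12, 40), np.full(12, 20))
        fit = fit_arousal_threshold(curve)
        assert not fit.success
        assert math.isnan(fit.threshold)
        assert fit.message  # diagnostics attached

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_arousal_threshold(
                ResponseCurve([1, 2, 4], [5, 5, 5], [0, 2, 5]))

    def test_scale_equivariance(self, rng):
        curve = bernoulli_curve(13.17, 40, rng)
        fit1 = fit_arousal_threshold(curve, seed=3)
        scaled = ResponseCurve(curve.intensities * 7.0, curve.n_trials,
                               curve.n_responses)
        fit2 = fit_arousal_threshold(scaled, seed=3)
        assert fit2.threshold == pytest.approx(fit1.threshold * 7.0, rel=1e-6)

    def test_night_threshold_above_day(self):
        """The simulator's day/night asymmetry is recoverable."""
        rng = np.random.default_rng(11)
        day = bernoulli_curve(13.17, 40, rng)
        night = bernoulli_curve(31.43, 40, rng)
        fd = fit_arousal_threshold(day, seed=0)
        fn = fit_arousal_threshold(night, seed=0)
        assert fn.threshold > fd.threshold


class TestCompareCurvesFTest:
    def test_identical_curves_f_zero_p_one(self, rng):
        curve = bernoulli_curve(13.17, 40, rng)
        f, df1, df2, p = compare_curves_f_test(curve, curve)
        assert f == pytest.approx(0.0, abs=1e-6)
        assert p > 0.99
        assert (df1, df2) == (4, 16)

    def test_distinguishes_day_from_night(self):
        """EC50 13.17 vs 31.43 at experiment scale rejects at alpha=0.01."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            a = bernoulli_curve(13.17, 54, rng)
            b = bernoulli_curve(31.43, 54, rng)
            _, _, _, p = compare_curves_f_test(a, b, seed=s)
            hits += p < 0.01
        assert hits >= 19

    def test_null_type_one_error(self):
        """Identical generating curves reject at roughly alpha."""
        alpha = 0.05
        rejects = 0
        n = 100
        for s in range(n):
            rng = np.random.default_rng(2000 + s)
            a = bernoulli_curve(13.17, 40, rng)
            b = bernoulli_curve(13.17, 40, rng)
            _, _, _, p = compare_curves_f_test(a, b, seed=s, n_starts=3)
            rejects += p < alpha
        # binomial 99% envelope around alpha
        sd = math.sqrt(alpha * (1 - alpha) / n)
        assert rejects / n < alpha + 3 * sd + 0.02


class TestPpi:
    def make_trials(self, n_ctrl_resp, n_ctrl, n_ppi_resp, n_ppi,
                    group="wt", prepulse_responders=0):
        trials = []
        for i in range(n_ctrl):
            trials.append(PpiTrial(f"f{i % 10}", group, "control",
                                   i < n_ctrl_resp))
        for i in range(n_ppi):
            trials.append(PpiTrial(
                f"f{i % 10}", group, "ppi", i < n_ppi_resp,
                prepulse_responded=i < prepulse_responders))
        return trials

    def test_no_inhibition_gives_zero_percent(self):
        trials = self.make_trials(30, 50, 30, 50)
        res = ppi_analysis(trials)["wt"]
        assert res.ppi_percent == pytest.approx(0.0)

    def test_forty_of_fifty_vs_twenty_of_fifty(self):
        trials = self.make_trials(40, 50, 20, 50)
        res = ppi_analysis(trials)["wt"]
        assert res.p_control == pytest.approx(0.8)
        assert res.p_ppi == pytest.approx(0.4)
        assert res.ppi_percent == pytest.approx(50.0)

    def test_trial_level_exclusion(self):
        trials = self.make_trials(40, 50, 20, 50, prepulse_responders=10)
        res = ppi_analysis(trials, exclude="trial")["wt"]
        assert res.n_ppi_trials == 40
        assert res.n_excluded == 10
        # the 10 excluded PPI trials were all responders here
        assert res.p_ppi == pytest.approx(10 / 40)

    def test_unit_level_exclusion_removes_every_trial(self):
        trials = [
            PpiTrial("f1", "wt", "ppi", True, prepulse_responded=True),
            PpiTrial("f1", "wt", "ppi", True),
            PpiTrial("f1", "wt", "control", True),
            PpiTrial("f2", "wt", "ppi", False),
            PpiTrial("f2", "wt", "control", True),
        ]
        res = ppi_analysis(trials, exclude="unit")["wt"]
        assert res.n_ppi_trials == 1 and res.n_control_trials == 1
        assert res.n_excluded == 3

    def test_order_invariance(self, rng):
        trials = self.make_trials(40, 50, 20, 50, prepulse_responders=5)
        res1 = ppi_analysis(trials)["wt"]
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        res2 = ppi_analysis(shuffled)["wt"]
        assert res1.ppi_percent == pytest.approx(res2.ppi_percent)
        assert res1.n_excluded == res2.n_excluded

    def test_magnitude_metrics_averaged_over_responders(self):
        trials = [
            PpiTrial("f1", "wt", "control", True,
                     magnitudes={"delta_px": 100.0}),
            PpiTrial("f2", "wt", "control", True,
                     magnitudes={"delta_px": 200.0}),
            PpiTrial("f3", "wt", "control", False,
                     magnitudes={"delta_px": 999.0}),
        ]
        res = ppi_analysis(trials)["wt"]
        assert res.magnitude_control["delta_px"] == pytest.approx(150.0)

    def test_zero_control_rate_gives_nan(self):
        trials = self.make_trials(0, 10, 2, 10)
        assert math.isnan(ppi_analysis(trials)["wt"].ppi_percent)


class TestHabituation:
    def test_constant_probability_index_zero(self, rng):
        flags = [True] * 50
        res = habituation_analysis(flags, block_size=10)
        assert res["habituation_index"] == pytest.approx(0.0)

    def test_exponential_decline_matches_closed_form(self):
        """p(k) = p0 * exp(-k/tau): index = 1 - mean(last)/mean(first)."""
        p0, tau, n = 0.9, 20.0, 60
        block = 10
        rates = p0 * np.exp(-np.arange(n) / tau)
        counts = []
        for s in range(300):
            rng = np.random.default_rng(s)
            flags = rng.random(n) < rates
            counts.append(
                habituation_analysis(flags, block)["habituation_index"])
        expected = 1 - rates[-block:].mean() / rates[:block].mean()
        assert np.nanmean(counts) == pytest.approx(expected, abs=0.05)

    def test_zero_responses_index_nan(self):
        res = habituation_analysis([False] * 30)
        assert math.isnan(res["habituation_index"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            habituation_analysis([])
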