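"""Behavioural statistics: standardisation, logistic, peri-blink, block tests."""

import numpy as np
import pytest

from urgepfm import behaviour, synthgen
from urgepfm.behaviour import (
    DegenerateInputError,
    NoRetainedBlinksError,
    PeriBlinkCurve,
)
from urgepfm.synthgen import OKAY, SUPPRESS


def _trace(values, rate=10.0, condition=None):
    values = np.asarray(values, float)
    if condition is None:
        condition = np.full(len(values), OKAY)
    return synthgen.UrgeTrace(rate_hz=rate, values=values, condition=np.asarray(condition))


class TestDownsampleStandardise:
    def test_bin_count(self):
        rng = np.random.default_rng(0)
        z = behaviour.downsample_standardise(_trace(rng.uniform(0, 100, 70)))
        assert z.n_seconds == 7

    def test_groups_standardised_separately(self, schedule, urge_blinks):
        urge, _ = urge_blinks
        z = behaviour.downsample_standardise(urge)
        for g in ("random", "experimental"):
            sel = z.group == g
            assert abs(z.values[sel].mean()) < 1e-9
            assert abs(z.values[sel].std() - 1.0) < 1e-9

    def test_downsampling_is_within_second_mean(self):
        vals = np.concatenate([np.full(10, 10.0 * k) for k in range(5)])
        vals[0:10] = np.arange(10)  # first second averages to 4.5
        z = behaviour.downsample_standardise(_trace(vals))
        # reconstruct the pre-z per-second means and check ordering is kept
        assert z.n_seconds == 5
        assert np.all(np.diff(z.values) > 0)

    def test_standardisation_idempotent(self, urge_blinks):
        urge, _ = urge_blinks
        z = behaviour.downsample_standardise(urge)
        for g in ("random", "experimental"):
            v = z.values[z.group == g]
            again = (v - v.mean()) / v.std()
            np.testing.assert_allclose(again, v, atol=1e-9)

    def test_constant_trace_rejected(self):
        with pytest.raises(DegenerateInputError):
            behaviour.downsample_standardise(_trace(np.full(100, 50.0)))

    def test_uneven_rate_rejected(self):
        with pytest.raises(ValueError):
            behaviour.downsample_standardise(_trace(np.zeros(30) + 1, rate=2.5))


class TestBinarizeBlinks:
    def _blinks(self, onsets, run=100.0):
        onsets = np.asarray(onsets, float)
        return synthgen.BlinkTrain(
            onsets_s=onsets, durations_s=np.full(onsets.shape, 0.2), run_length_s=run
        )

    def test_multiple_blinks_in_second_binarised(self):
        v = behaviour.binarize_blinks(self._blinks([3.1, 3.7]), 10)
        assert v[3] == 1 and v.sum() == 1

    def test_no_blinks_all_zero(self):
        assert behaviour.binarize_blinks(self._blinks([]), 5).sum() == 0

    def test_half_open_bin_convention(self):
        v = behaviour.binarize_blinks(self._blinks([4.0]), 10)
        assert v[4] == 1 and v[3] == 0

    def test_onset_beyond_range_rejected(self):
        with pytest.raises(ValueError):
            behaviour.binarize_blinks(self._blinks([12.0]), 10)


class TestLogistic:
    def test_planted_slope_recovered(self):
        from urgepfm import evaluation

        res = evaluation.logistic_recovery(n_seeds=40)
        assert abs(res["bias"]) < 0.03

    def test_null_association_gives_unit_odds_ratio(self):
        exps, ps = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(3000)
            y = (rng.random(3000) < 0.1).astype(float)
            r = behaviour.blink_urge_logistic(x, y)
            exps.append(r.ExpB)
            ps.append(1.0)  # fit succeeded
        assert np.mean(exps) == pytest.approx(1.0, abs=0.02)

    def test_single_class_outcome_flagged(self):
        with pytest.raises(DegenerateInputError):
            behaviour.blink_urge_logistic(np.random.randn(100), np.zeros(100))

    def test_perfect_separation_flagged(self):
        x = np.linspace(-1, 1, 50)
        y = (x > 0).astype(float)
        with pytest.raises(DegenerateInputError):
            behaviour.blink_urge_logistic(x, y)

    def test_wald_type_I_error_calibrated(self):
        """Under the null the 5%-level Wald test rejects ~5% of the time."""
        rej = 0
        n_sets = 400
        for seed in range(n_sets):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.standard_normal(600)
            y = (rng.random(600) < 0.15).astype(float)
            r = behaviour.blink_urge_logistic(x, y)
            from scipy import stats

            rej += stats.chi2.sf(r.wald, 1) <= 0.05
        assert abs(rej / n_sets - 0.05) < 0.03


class TestPeriBlinkAverage:
    def _setup(self, onsets, n_seconds=420):
        rng = np.random.default_rng(0)
        sched = synthgen.make_block_schedule()
        vals = rng.standard_normal(n_seconds)
        cond = sched.condition_labels(np.arange(n_seconds, dtype=float))
        z = behaviour.StandardisedUrge(
            values=vals,
            condition=cond,
            group=np.where(cond == "Random", "random", "experimental"),
        )
        onsets = np.asarray(onsets, float)
        blinks = synthgen.BlinkTrain(
            onsets_s=onsets, durations_s=np.full(onsets.shape, 0.2), run_length_s=420.0
        )
        return z, blinks, sched

    def test_single_blink_curve_is_raw_window(self):
        z, blinks, sched = self._setup([60.3])  # Okay block at 30-90 s
        curve = behaviour.periblink_average(z, blinks, sched, OKAY)
        assert curve.n_blinks == 1
        np.testing.assert_array_equal(curve.values, z.values[55:66])

    def test_blink_near_block_start_excluded(self):
        z, blinks, sched = self._setup([33.0, 60.0])  # 3 s after Okay onset
        curve = behaviour.periblink_average(z, blinks, sched, OKAY)
        assert curve.n_blinks == 1

    def test_all_blinks_excluded_signals_exclusion(self):
        z, blinks, sched = self._setup([31.0, 88.0, 151.0])
        with pytest.raises(NoRetainedBlinksError):
            behaviour.periblink_average(z, blinks, sched, OKAY)

    def test_window_conservation_against_bruteforce(self, schedule):
        """Retained = total minus the 5 s edge exclusions, counted directly."""
        urge, blinks = synthgen.simulate_urge_and_blinks(schedule, seed=21)
        z = behaviour.downsample_standardise(urge)
        for cond in (OKAY, SUPPRESS):
            expected = 0
            for onset in blinks.onsets_s:
                for b in schedule.blocks_of(cond):
                    if (
                        b.onset_s <= onset < b.end_s
                        and onset - b.onset_s >= 5
                        and b.end_s - onset > 5
                    ):
                        expected += 1
            try:
                curve = behaviour.periblink_average(z, blinks, schedule, cond)
                assert curve.n_blinks == expected
            except NoRetainedBlinksError:
                assert expected == 0


class TestPeriBlinkStats:
    def _curves(self, values_list):
        lags = np.arange(-5.0, 6.0)
        return [
            PeriBlinkCurve(lags=lags, values=np.asarray(v, float), n_blinks=3)
            for v in values_list
        ]

    def test_symmetric_triangle_latency_and_skew(self):
        tri = 5.0 - np.abs(np.arange(-5, 6))
        stats_ = behaviour.periblink_stats(self._curves([tri] * 5))
        np.testing.assert_array_equal(stats_.peak_latency_s, 0.0)
        np.testing.assert_allclose(stats_.skewness, 0.0, atol=1e-12)

    def test_shifted_peak_rejected_by_group_test(self):
        rng = np.random.default_rng(0)
        curves = []
        for _ in range(12):
            v = np.exp(-0.5 * ((np.arange(-5, 6) + 3) / 1.5) ** 2)
            curves.append(v + rng.normal(0, 0.01, 11))
        stats_ = behaviour.periblink_stats(self._curves(curves))
        t = stats_.tests["peak_latency"]
        assert stats_.peak_latency_s.mean() < 0
        assert t.p < 0.01

    def test_gaussian_curve_kurtosis_matches_moment_oracle(self):
        """Discretised Gaussian curves: kurtosis equals direct moment sums."""
        lags = np.arange(-5.0, 6.0)
        sigma = 2.0
        density = np.exp(-0.5 * (lags / sigma) ** 2)
        # independent oracle: raw moment summation on the planted density
        w = density - density.min()
        p = w / w.sum()
        mu = (p * lags).sum()
        var = (p * (lags - mu) ** 2).sum()
        kurt_oracle = (p * (lags - mu) ** 4).sum() / var**2
        rng = np.random.default_rng(5)
        curves = self._curves([density + rng.normal(0, 0.002, 11) for _ in range(40)])
        stats_ = behaviour.periblink_stats(curves)
        assert stats_.kurtosis.mean() == pytest.approx(kurt_oracle, abs=0.05)
        np.testing.assert_allclose(
            stats_.excess_kurtosis, stats_.kurtosis - 3.0, atol=1e-12
        )

    def test_too_few_participants_rejected(self):
        tri = 5.0 - np.abs(np.arange(-5, 6))
        with pytest.raises(ValueError):
            behaviour.periblink_stats(self._curves([tri, tri]))


class TestCurvilinearFit:
    def _curve(self, values):
        return PeriBlinkCurve(
            lags=np.arange(-5.0, 6.0), values=np.asarray(values, float), n_blinks=2
        )

    def test_planted_model_selection(self):
        from urgepfm import evaluation

        res = evaluation.curvilinear_selection(n_seeds=60)
        assert res["quadratic_selection_fraction"] >= 0.95
        assert res["linear_selection_fraction"] >= 0.95
        assert res["quad_coef_within_3se_fraction"] >= 0.95

    def test_exact_quadratic_coefficients(self):
        t = np.arange(-5.0, 6.0)
        fit = behaviour.curvilinear_fit(self._curve(0.9 - 0.04 * t - 0.02 * t**2))
        assert fit.chosen == "quadratic"
        assert fit.quadratic.intercept == pytest.approx(0.9)
        np.testing.assert_allclose(fit.quadratic.coefficients, [-0.04, -0.02], atol=1e-12)

    def test_constant_curve_selects_nothing(self):
        fit = behaviour.curvilinear_fit(self._curve(np.full(11, 0.3)))
        assert fit.chosen is None
        assert fit.linear.adj_r2 == 0.0
        np.testing.assert_allclose(fit.linear.coefficients, 0.0, atol=1e-12)


class TestBlockSummary:
    def _participant(self, okay_blinks_per_min, sup_blinks_per_min, urge_ok, urge_sup, seed):
        rng = np.random.default_rng(seed)
        sched = synthgen.make_block_schedule()
        n = 420
        cond = sched.condition_labels(np.arange(n, dtype=float))
        vals = np.where(cond == SUPPRESS, urge_sup, np.where(cond == OKAY, urge_ok, 5.0))
        vals = np.clip(vals + rng.normal(0, 1.0, n), 0, 100)
        urge = synthgen.UrgeTrace(rate_hz=1.0, values=vals, condition=cond)
        onsets = []
        for b in sched.blocks:
            rate = {OKAY: okay_blinks_per_min, SUPPRESS: sup_blinks_per_min}.get(b.label, 10.0)
            k = rng.poisson(rate * b.duration_s / 60.0)
            onsets.extend(rng.uniform(b.onset_s, b.end_s - 0.01, k))
        onsets = np.sort(np.asarray(onsets))
        blinks = synthgen.BlinkTrain(
            onsets_s=onsets, durations_s=np.full(onsets.shape, 0.2), run_length_s=420.0
        )
        return urge, blinks, sched

    def test_planted_rate_difference_detected(self):
        """6x blink-rate difference over 20 participants: Wilcoxon rejects."""
        reject = 0
        n_seeds = 20
        for seed in range(n_seeds):
            group = [
                self._participant(30.0, 5.0, 20.0, 55.0, 1000 * seed + i)
                for i in range(20)
            ]
            summary = behaviour.block_summary_tests(group)
            reject += summary.blink_test.p <= 0.05
            assert summary.urge_test.p <= 0.05
        assert reject == n_seeds

    def test_identical_conditions_give_null_p(self):
        group = [self._participant(15.0, 15.0, 30.0, 30.0, i) for i in range(6)]
        # force exact equality of the per-participant summaries
        summary = behaviour.block_summary_tests(
            [(u, b, s) for (u, b, s) in group]
        )
        # no systematic direction: one-tailed p should not be small
        assert summary.urge_test.p > 0.05

    def test_blinks_per_minute_arithmetic(self):
        sched = synthgen.make_block_schedule()
        n = 420
        cond = sched.condition_labels(np.arange(n, dtype=float))
        vals = np.where(cond == SUPPRESS, 60.0, 20.0)
        urge = synthgen.UrgeTrace(rate_hz=1.0, values=vals, condition=cond)
        # 2 blinks in the first 60 s Okay block only
        blinks = synthgen.BlinkTrain(
            onsets_s=np.array([40.0, 50.0]),
            durations_s=np.array([0.2, 0.2]),
            run_length_s=420.0,
        )
        other = synthgen.BlinkTrain(
            onsets_s=np.array([40.0]), durations_s=np.array([0.2]), run_length_s=420.0
        )
        summary = behaviour.block_summary_tests(
            [(urge, blinks, sched), (urge, other, sched)]
        )
        # 2 blinks over three 60 s Okay blocks -> 2/3 per minute
        assert summary.blink_rates[OKAY][0] == pytest.approx(2.0 / 3.0)
        # single Okay block with 2 blinks in 60 s would be 2.0/min
        only_first = [
            b for b in blinks.onsets_s if 30.0 <= b < 90.0
        ]
        assert len(only_first) / 1.0 == 2.0

    def test_missing_condition_rejected(self):
        urge, blinks, _ = self._participant(10, 10, 30, 30, 0)
        bad = synthgen.BlockSchedule(
            blocks=(synthgen.Block("Random", 0.0, 420.0),), run_length_s=420.0
        )
        with pytest.raises(ValueError):
            behaviour.block_summary_tests([(urge, blinks, bad), (urge, blinks, bad)])

    def test_too_few_participants_rejected(self):
        p = self._participant(10, 10, 30, 30, 0)
        with pytest.raises(ValueError):
            behaviour.block_summary_tests([p])
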