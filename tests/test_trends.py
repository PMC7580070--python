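import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diatrend._time import DAYS_PER_YEAR
from diatrend.corpus_io import ArticleRecord
from diatrend.synthetic_data import SyntheticSpec, TopicSpec, Trajectory, generate_corpus
from diatrend.trends import (
    era_contrast,
    fit_binomial_trend,
    fit_segmented_trend,
    rank_word_trends,
)


def _logit(p):
    return np.log(p / (1 - p))


class TestFitBinomialTrend:
    def test_two_point_closed_form(self):
        # saturated two-point fit: annualised slope = logit(0.4) - logit(0.2)
        series = ([0.0, DAYS_PER_YEAR], [20000, 40000], [100000, 100000])
        fit = fit_binomial_trend(series)
        assert fit.slope_per_day * DAYS_PER_YEAR == pytest.approx(
            _logit(0.4) - _logit(0.2), abs=1e-6
        )
        assert fit.annual_odds_factor == pytest.approx(8 / 3, rel=1e-6)

    def test_flat_series_factor_one(self):
        series = ([0.0, 400.0, 900.0], [30, 30, 30], [100, 100, 100])
        fit = fit_binomial_trend(series)
        assert fit.annual_odds_factor == pytest.approx(1.0, abs=1e-9)
        assert fit.slope_per_day == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_distinct_dates(self):
        with pytest.raises(ValueError):
            fit_binomial_trend(([5.0, 5.0], [1, 2], [10, 10]))

    def test_all_zero_successes_flagged(self):
        fit = fit_binomial_trend(([0.0, 365.0, 730.0], [0, 0, 0], [50, 50, 50]))
        assert fit.all_zero_flag
        assert np.isnan(fit.ci_low)

    def test_complete_separation_flagged(self):
        fit = fit_binomial_trend(([0.0, 365.0, 730.0, 1095.0], [0, 0, 50, 50], [50, 50, 50, 50]))
        assert fit.separation_flag
        assert np.isnan(fit.ci_low) and np.isnan(fit.ci_high)

    def test_aggregation_sufficiency(self):
        # binomial fit on aggregated counts == Bernoulli fit on per-article rows
        rng = np.random.default_rng(4)
        days = np.repeat([0.0, 500.0, 1200.0, 3000.0], 50)
        p = 1 / (1 + np.exp(-(-1.0 + 0.0005 * days)))
        y = (rng.random(days.size) < p).astype(int)
        fit_disagg = fit_binomial_trend((days, y, np.ones_like(y)))
        agg_days, agg_succ, agg_trials = [], [], []
        for d in np.unique(days):
            m = days == d
            agg_days.append(d)
            agg_succ.append(int(y[m].sum()))
            agg_trials.append(int(m.sum()))
        fit_agg = fit_binomial_trend((agg_days, agg_succ, agg_trials))
        assert fit_agg.slope_per_day == pytest.approx(fit_disagg.slope_per_day, rel=1e-8)
        assert fit_agg.intercept == pytest.approx(fit_disagg.intercept, rel=1e-8)

    def test_time_shift_changes_intercept_only(self):
        series = ([0.0, 400.0, 900.0, 2000.0], [10, 20, 30, 55], [100, 100, 100, 100])
        fit = fit_binomial_trend(series)
        shifted = ([3650.0, 4050.0, 4550.0, 5650.0], [10, 20, 30, 55], [100, 100, 100, 100])
        fit2 = fit_binomial_trend(shifted)
        assert fit2.slope_per_day == pytest.approx(fit.slope_per_day, rel=1e-7)
        assert fit2.intercept != pytest.approx(fit.intercept, abs=1e-3)


def _two_segment_series(rng, break_year=1990.0, pre=1.01, post=1.08, p_ref=0.2,
                        n_per_year=400, years=range(1950, 2011)):
    traj = Trajectory(p_ref=p_ref, ref_year=1950.0, annual_factor=pre,
                      break_year=break_year, post_factor=post)
    dates, succ, trials = [], [], []
    for y in years:
        t = y + 0.5
        p = float(traj.prob_at(t))
        dates.append(dt.date(y, 7, 1))
        succ.append(int(rng.binomial(n_per_year, p)))
        trials.append(n_per_year)
    return dates, succ, trials


class TestFitSegmentedTrend:
    def test_recovers_planted_break_and_matches_grid_oracle(self):
        rng = np.random.default_rng(11)
        series = _two_segment_series(rng)
        fit = fit_segmented_trend(series)
        assert fit.converged
        assert abs(fit.breakpoint_year - 1990.0) < 1.0
        # exhaustive grid-search ML oracle over candidate break dates
        psi_grid = _grid_breakpoint(series)
        assert abs(fit.breakpoint_year - psi_grid) < 0.5
        assert fit.aic < fit.null_model_aic  # break strongly supported

    def test_single_slope_data_prefers_null_by_aic_majority(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            dates, succ, trials = [], [], []
            for y in range(1950, 2011):
                p = 1 / (1 + np.exp(-(-1.0 + 0.01 * (y - 1950))))
                dates.append(dt.date(y, 7, 1))
                succ.append(int(rng.binomial(300, p)))
                trials.append(300)
            fit = fit_segmented_trend((dates, succ, trials))
            if fit.aic > fit.null_model_aic:
                wins += 1
        assert wins >= 3

    def test_equal_slopes_collapse_to_plain_trend(self):
        # deterministic expected counts from a single-slope model
        dates, succ, trials = [], [], []
        for y in range(1950, 2011):
            p = 1 / (1 + np.exp(-(-1.5 + 0.02 * (y - 1950))))
            dates.append(dt.date(y, 7, 1))
            succ.append(int(round(10000 * p)))
            trials.append(10000)
        seg = fit_segmented_trend((dates, succ, trials))
        plain = fit_binomial_trend((dates, succ, trials))
        assert seg.pre_slope_per_day == pytest.approx(plain.slope_per_day, abs=1e-6)
        assert seg.post_slope_per_day == pytest.approx(plain.slope_per_day, abs=1e-6)

    def test_needs_four_distinct_dates(self):
        with pytest.raises(ValueError):
            fit_segmented_trend(([0.0, 1.0, 2.0], [1, 2, 3], [10, 10, 10]))


def _grid_breakpoint(series, coarse_step=1.0, fine_step=0.05):
    """Independent oracle: maximise the binomial log-likelihood over a psi grid."""
    import statsmodels.api as sm

    from diatrend.trends import _as_series

    x_days, succ, trials = _as_series(series)
    x = x_days / DAYS_PER_YEAR
    endog = np.column_stack([succ, trials - succ])

    def llf(psi):
        exog = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        return res.llf

    lo, hi = x.min() + 1.0, x.max() - 1.0
    coarse = np.arange(lo, hi, coarse_step)
    best = coarse[int(np.argmax([llf(p) for p in coarse]))]
    fine = np.arange(best - coarse_step, best + coarse_step, fine_step)
    best = fine[int(np.argmax([llf(p) for p in fine]))]
    return 1948.0 + best


class TestEraContrast:
    def test_closed_form_from_printed_incidences(self):
        # era incidences 0.37 and 0.54 -> OR = (0.54/0.46)/(0.37/0.63) = 2.00
        series = (
            [0.0, DAYS_PER_YEAR * 10],
            [3700, 5400],
            [10000, 10000],
        )
        res = era_contrast(series, era_boundary=DAYS_PER_YEAR * 5)
        expected = (0.54 / 0.46) / (0.37 / 0.63)
        assert res.odds_ratio == pytest.approx(expected, rel=1e-6)
        assert round(res.odds_ratio, 2) == 2.00

    def test_equal_proportions_or_one(self):
        series = ([0.0, 1000.0], [25, 50], [100, 200])
        res = era_contrast(series, era_boundary=500.0)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_empty_era_errors(self):
        with pytest.raises(ValueError):
            era_contrast(([0.0, 10.0], [1, 2], [5, 5]), era_boundary=100.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_matches_contingency_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        days = rng.uniform(0, 2000, size=30)
        trials = rng.integers(20, 100, size=30)
        succ = rng.binomial(trials, 0.3 + 0.2 * (days > 1000))
        res = era_contrast((days, succ, trials), era_boundary=1000.0)
        pre = days < 1000
        a, b = succ[~pre].sum(), (trials - succ)[~pre].sum()
        c, d = succ[pre].sum(), (trials - succ)[pre].sum()
        assert res.odds_ratio == pytest.approx((a / b) / (c / d), rel=1e-6)


class TestRankWordTrends:
    def _graded_corpus(self, factors, seed=0):
        words = {f"word{chr(97 + i)}": Trajectory(p_ref=0.01, annual_factor=f)
                 for i, f in enumerate(factors)}
        spec = SyntheticSpec(
            year_start=1960, year_end=2010, articles_per_year=60,
            tokens_per_article=80,
            topics=[TopicSpec("background", Trajectory(0.5), n_words=30)],
            word_trajectories=words, seed=seed,
        )
        records, _ = generate_corpus(spec)
        return records, list(words)

    def test_planted_rank_order_recovered(self):
        factors = np.round(np.linspace(0.96, 1.05, 8), 4)
        records, words = self._graded_corpus(factors, seed=2)
        fits, pct, ties = rank_word_trends(records, words, focal_word=words[-1])
        fitted = fits.set_index("word").loc[words, "annual_odds_factor"].to_numpy()
        # recovered ordering matches the planted grading
        assert list(np.argsort(fitted)) == list(range(len(words)))
        assert pct == 100.0 and ties == 0

    def test_absent_word_dropped_with_warning(self):
        records, words = self._graded_corpus([1.0, 1.02], seed=3)
        with pytest.warns(UserWarning, match="absent"):
            fits, _, _ = rank_word_trends(records, words + ["zzznotthere"])
        assert set(fits["word"]) == set(words)

    def test_percentile_of_fastest_word_is_100(self):
        records, words = self._graded_corpus([0.99, 1.0, 1.06], seed=4)
        _, pct, _ = rank_word_trends(records, words, focal_word=words[-1])
        assert pct == 100.0
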