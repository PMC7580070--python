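import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diatrend.corpus_io import ArticleRecord
from diatrend.incidence import (
    TopicCatalog,
    article_incidence,
    discretize,
    standardize_probs,
    supertopic_about,
    supertopic_calls,
    topic_incidence,
    word_incidence,
)


class TestStandardize:
    def test_singleton_subset_forced_to_one(self):
        assert standardize_probs([0.3], [0]) == pytest.approx([1.0])

    def test_hand_arithmetic(self):
        out = standardize_probs([0.2, 0.2, 0.6], [0, 1])
        assert out == pytest.approx([0.5, 0.5])

    def test_zero_subset_flagged_as_all_zero(self):
        out = standardize_probs([0.0, 0.0, 1.0], [0, 1])
        assert np.array_equal(out, np.zeros(2))

    @given(
        st.lists(st.floats(0, 10), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_renormalisation(self, probs, data):
        subset = data.draw(
            st.lists(st.integers(0, len(probs) - 1), min_size=1, unique=True)
        )
        out = standardize_probs(probs, subset)
        total = sum(probs[i] for i in subset)
        if total == 0:
            assert np.array_equal(out, np.zeros(len(subset)))
        else:
            assert out == pytest.approx([probs[i] / total for i in subset])
            assert out.sum() == pytest.approx(1.0)


class TestDiscretize:
    def test_boundary_inclusive_at_threshold(self):
        assert discretize(np.array([0.05]))[0]

    def test_just_below_threshold(self):
        assert not discretize(np.array([0.049999]))[0]

    def test_pigeonhole_at_least_one_call(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(20))
        assert discretize(p).any()  # max >= 1/20 > 0.05 cannot fail

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, probs):
        p = np.array(probs)
        low = discretize(p, 0.05).sum()
        high = discretize(p, 0.2).sum()
        assert high <= low


class TestSupertopicAbout:
    def test_full_subset_always_about(self):
        assert supertopic_about([0.2, 0.3, 0.5], members=[0, 1, 2])

    def test_hand_arithmetic_boundary(self):
        # three members each 0.017 of a unit total -> 0.051 >= 0.05
        p = np.array([0.017, 0.017, 0.017, 0.949])
        assert supertopic_about(p / p.sum(), members=[0, 1, 2])

    @given(st.lists(st.floats(0.001, 1), min_size=3, max_size=10), st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_sum_and_compare_oracle(self, probs, data):
        members = data.draw(
            st.lists(st.integers(0, len(probs) - 1), min_size=1, unique=True)
        )
        p = np.array(probs)
        expected = (p[members].sum() / p.sum()) >= 0.05
        assert supertopic_about(p, members=members) == expected
        assert supertopic_calls(p[None, :], members)[0] == expected


def _dates(years):
    return [dt.date(y, 6, 1) for y in years]


class TestTopicIncidence:
    def test_denominator_is_calls_not_papers(self):
        # call-sets {A}, {A,B}, {B}: incidence of A = 2/4
        calls = np.array([[1, 0], [1, 1], [0, 1]], dtype=bool)
        series = topic_incidence(calls, _dates([1950, 1950, 1950]), 0)
        row = series.data.iloc[0]
        assert row["numerator"] == 2 and row["denominator"] == 4
        assert row["incidence"] == pytest.approx(0.5)

    def test_never_called_topic_is_zero(self):
        calls = np.array([[1, 0], [1, 0]], dtype=bool)
        series = topic_incidence(calls, _dates([1950, 1951]), 1)
        assert (series.data["incidence"] == 0).all()

    def test_zero_denominator_year_undefined(self):
        calls = np.array([[0, 0], [1, 0]], dtype=bool)
        series = topic_incidence(calls, _dates([1950, 1951]), 0)
        y1950 = series.data.set_index("year").loc[1950]
        assert np.isnan(y1950["incidence"]) and np.isnan(y1950["ci_low"])

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_tally_and_conserves(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        n, k = 40, 5
        calls = rng.random((n, k)) < 0.3
        years = rng.integers(1950, 1955, size=n)
        dates = _dates(years)
        per_topic = [topic_incidence(calls, dates, j).data for j in range(k)]
        for y in np.unique(years):
            mask = years == y
            den = calls[mask].sum()
            total_inc = 0.0
            for j in range(k):
                row = per_topic[j].set_index("year").loc[y]
                assert row["numerator"] == calls[mask, j].sum()
                assert row["denominator"] == den
                if den > 0:
                    total_inc += row["incidence"]
            if den > 0:
                assert total_inc == pytest.approx(1.0)  # sum_i I_it = 1


class TestArticleIncidence:
    @pytest.mark.parametrize(
        "num,den,printed",
        [(240, 606, 40), (68, 81, 84)],
    )
    def test_printed_proportions(self, num, den, printed):
        flags = np.array([True] * num + [False] * (den - num))
        series = article_incidence(flags, _dates([1948] * den))
        inc = series.data["incidence"].iloc[0]
        assert inc == pytest.approx(num / den)
        assert round(100 * inc) == printed

    def test_all_true_is_identically_one(self):
        flags = np.ones(30, dtype=bool)
        years = [1950] * 10 + [1960] * 10 + [1970] * 10
        series = article_incidence(flags, _dates(years))
        assert (series.data["incidence"] == 1.0).all()

    def test_none_flagged_is_zero(self):
        series = article_incidence(np.zeros(5, dtype=bool), _dates([1950] * 5))
        assert (series.data["incidence"] == 0.0).all()

    def test_wilson_interval_brackets_estimate(self):
        series = article_incidence(
            np.array([True] * 3 + [False] * 7), _dates([1950] * 10)
        )
        row = series.data.iloc[0]
        assert row["ci_low"] <= row["incidence"] <= row["ci_high"]
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(3, 10, method="wilson")
        assert row["ci_low"] == pytest.approx(lo) and row["ci_high"] == pytest.approx(hi)


def _tok_rec(i, year, tokens):
    return ArticleRecord(f"w{i}", f"t{i}", dt.date(year, 2, 1), tokens=tokens)


class TestWordIncidence:
    def test_hand_count(self):
        recs = [_tok_rec(0, 1950, ["women", "men", "women"])]
        series = word_incidence(recs, {"woman", "women"})
        row = series.data.iloc[0]
        assert row["numerator"] == 2 and row["denominator"] == 3

    def test_absent_variants_zero(self):
        recs = [_tok_rec(0, 1950, ["men", "mice"])]
        series = word_incidence(recs, {"women"})
        assert (series.data["incidence"] == 0).all()

    def test_empty_variant_set_errors(self):
        with pytest.raises(ValueError):
            word_incidence([], set())

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_token_tally(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 500)))
        words = ["women", "men", "heart", "trial"]
        recs = [
            _tok_rec(i, int(rng.integers(1950, 1953)), list(rng.choice(words, size=rng.integers(1, 15))))
            for i in range(12)
        ]
        series = word_incidence(recs, {"women"}).data.set_index("year")
        for y in {r.pub_date.year for r in recs}:
            recs_y = [r for r in recs if r.pub_date.year == y]
            num = sum(t == "women" for r in recs_y for t in r.tokens)
            den = sum(len(r.tokens) for r in recs_y)
            assert series.loc[y, "numerator"] == num
            assert series.loc[y, "denominator"] == den


class TestTopicCatalog:
    def test_women_specific_implies_clinical(self):
        import pandas as pd

        bad = pd.DataFrame(
            {
                "label": ["x"],
                "super_topic": ["x"],
                "clinical": [False],
                "women_specific": [True],
            },
            index=pd.Index(["t1"], name="topic_id"),
        )
        with pytest.raises(ValueError):
            TopicCatalog(bad)

    def test_packaged_catalog_valid(self):
        cat = TopicCatalog.packaged()
        assert set(cat.women_specific_ids()) <= set(cat.clinical_ids())
        assert len(cat.supertopic_members("pregnancy")) == 2
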