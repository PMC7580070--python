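"""End-to-end parameter-recovery experiments on synthetic corpora.

Each experiment generates a corpus under the package's study conditions, runs
the full measurement pipeline (incidence or classification, then a trend
model) and returns the fit next to the generating truth, so recovery can be
judged by confidence-interval coverage.  Default trajectory parameters are
the conditions the trend estimates describe: a focal word pair rising by an
annual odds factor of 1.023 from an incidence of ~1/1000 words in 1948; a
gender-lexicon hit rate of 0.40 in 1948 declining at 0.99/year until a break
at 2005.2 and rising at 2.18/year after it; and a women-specific super-topic
call probability of 0.11 in 1948 rising at 1.004/year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .incidence import supertopic_calls, word_incidence
from .subcorpora import GenderLexicon, classify_gender_vocal
from .synthetic_data import (
    SupertopicCall,
    SyntheticSpec,
    TopicSpec,
    Trajectory,
    generate_corpus,
)
from .trends import SegmentedFit, TrendFit, fit_binomial_trend, fit_segmented_trend


@dataclass
class TrendRecovery:
    fit: TrendFit
    true_annual_factor: float
    n_articles: int

    @property
    def covered(self) -> bool:
        return bool(self.fit.ci_low <= self.true_annual_factor <= self.fit.ci_high)


@dataclass
class BreakRecovery:
    fit: SegmentedFit
    true_break_year: float
    true_pre_factor: float
    true_post_factor: float
    n_articles: int

    @property
    def break_error_years(self) -> float:
        return abs(self.fit.breakpoint_year - self.true_break_year)

    @property
    def post_covered(self) -> bool:
        return bool(self.fit.post_ci_low <= self.true_post_factor <= self.fit.post_ci_high)


def word_trend_experiment(
    seed: int,
    articles_per_year: int = 500,
    tokens_per_article: float = 200.0,
    true_factor: float = 1.023,
    p_ref: float = 0.001,
    variants: tuple[str, ...] = ("woman", "women"),
) -> TrendRecovery:
    """Plant a rising focal-word trajectory, measure word incidence, refit.

    The planted per-token probability applies to the variant pair jointly
    (emitted as the plural form); the incidence step counts both variants.
    """
    spec = SyntheticSpec(
        articles_per_year=articles_per_year,
        tokens_per_article=tokens_per_article,
        topics=[TopicSpec("background", Trajectory(0.5), n_words=50)],
        word_trajectories={
            variants[-1]: Trajectory(p_ref=p_ref, annual_factor=true_factor)
        },
        seed=seed,
    )
    records, _ = generate_corpus(spec)
    series = word_incidence(records, set(variants)).trend_series()
    fit = fit_binomial_trend(series)
    return TrendRecovery(fit=fit, true_annual_factor=true_factor, n_articles=len(records))


def vocal_break_experiment(
    seed: int,
    articles_per_year: int = 500,
    tokens_per_article: float = 60.0,
    p_ref: float = 0.40,
    pre_factor: float = 0.99,
    break_year: float = 2005.2,
    post_factor: float = 2.18,
) -> BreakRecovery:
    """Plant a two-segment gender-vocal trajectory, classify, refit the break.

    The segmented model is fitted on per-article Bernoulli outcomes with exact
    publication dates, initialised at the midpoint of the date range.
    """
    traj = Trajectory(
        p_ref=p_ref,
        annual_factor=pre_factor,
        break_year=break_year,
        post_factor=post_factor,
    )
    spec = SyntheticSpec(
        articles_per_year=articles_per_year,
        tokens_per_article=tokens_per_article,
        topics=[TopicSpec("background", Trajectory(0.5), n_words=50)],
        lexicon_trajectory=traj,
        seed=seed,
    )
    records, _ = generate_corpus(spec)
    lex = GenderLexicon()
    flags = np.array([classify_gender_vocal(r.tokens, lex) for r in records])
    dates = [r.pub_date for r in records]
    fit = fit_segmented_trend((dates, flags.astype(int), np.ones(len(flags))))
    return BreakRecovery(
        fit=fit,
        true_break_year=break_year,
        true_pre_factor=pre_factor,
        true_post_factor=post_factor,
        n_articles=len(records),
    )


def supertopic_trend_experiment(
    seed: int,
    articles_per_year: int = 1000,
    true_factor: float = 1.004,
    p_ref: float = 0.11,
) -> TrendRecovery:
    """Plant a women-specific super-topic call trajectory, discretise, refit."""
    topics = [
        TopicSpec("pregnancy", Trajectory(0.15), "womens_health", True, True, n_words=5),
        TopicSpec("contraception", Trajectory(0.05), "womens_health", True, True, n_words=5),
        TopicSpec("cardiology", Trajectory(0.4), "cardiology", True, False, n_words=5),
        TopicSpec("oncology", Trajectory(0.4), "oncology", True, False, n_words=5),
    ]
    spec = SyntheticSpec(
        articles_per_year=articles_per_year,
        topics=topics,
        supertopic_call=SupertopicCall(
            members=("pregnancy", "contraception"),
            trajectory=Trajectory(p_ref=p_ref, annual_factor=true_factor),
        ),
        emit_tokens=False,
        seed=seed,
    )
    records, truth = generate_corpus(spec)
    member_cols = [truth.topic_names.index(m) for m in ("pregnancy", "contraception")]
    calls = supertopic_calls(truth.mixtures, member_cols)
    dates = [r.pub_date for r in records]
    fit = fit_binomial_trend((dates, calls.astype(int), np.ones(len(calls))))
    return TrendRecovery(fit=fit, true_annual_factor=true_factor, n_articles=len(records))
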