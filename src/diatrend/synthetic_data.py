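"""Synthetic diachronic corpora with known ground truth.

The generator emulates the statistical structure the analysis assumes in real
data: per-year article counts; per-article topic mixtures drawn from a
Dirichlet centred on year-specific topic prevalences (softmax of per-topic
logit trajectories); topic-specific word emissions over disjoint signature
vocabularies; independently injected focal-word occurrences whose per-token
probability follows a logistic trajectory; and a gender-lexicon channel whose
per-article hit probability follows a (possibly two-segment) logistic
trajectory.  Trajectories are parameterised on the logit scale, so a planted
"annual odds factor" is exactly the quantity the trend module estimates.

A designated super-topic's article-level call probability can also be planted
directly: the article's about-flag is drawn from the trajectory and the
mixture constructed so its standardised super-topic mass lands on the correct
side of the 0.05 discretisation threshold.

Everything is deterministic given the seed.  Tokens are emitted in count
order within an article (token order carries no signal downstream).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._time import EPOCH, date_of_days, days_to_year
from .corpus_io import DEFAULT_PARSE_WINDOW, ArticleRecord
from .incidence import TopicCatalog

_LEXICON_TERMS = ("woman", "women", "female", "females", "gender", "sex", "sexes")


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class Trajectory:
    """Logistic trajectory: probability at a reference year plus annual odds
    factor(s), with an optional structural break.

    logit p(t) = logit(p_ref) + ln(annual_factor) * (min(t, break) - ref_year)
                              + ln(post_factor)   * max(t - break, 0)
    """

    p_ref: float
    ref_year: float = 1948.0
    annual_factor: float = 1.0
    break_year: float | None = None
    post_factor: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError("p_ref must lie in (0, 1)")
        if self.annual_factor <= 0:
            raise ValueError("annual factors must be positive")
        if (self.break_year is None) != (self.post_factor is None):
            raise ValueError("break_year and post_factor must be given together")
        if self.break_year is not None:
            if self.post_factor <= 0:
                raise ValueError("annual factors must be positive")
            if self.break_year < self.ref_year:
                raise ValueError("break_year must not precede ref_year")

    def logit_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.break_year is None:
            return _logit(self.p_ref) + np.log(self.annual_factor) * (t - self.ref_year)
        pre = np.minimum(t, self.break_year) - self.ref_year
        post = np.maximum(t - self.break_year, 0.0)
        return (
            _logit(self.p_ref)
            + np.log(self.annual_factor) * pre
            + np.log(self.post_factor) * post
        )

    def prob_at(self, t) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logit_at(t)))


@dataclass(frozen=True)
class TopicSpec:
    """One synthetic topic: prevalence trajectory, flags and vocabulary size."""

    name: str
    trajectory: Trajectory = field(default_factory=lambda: Trajectory(p_ref=0.2))
    super_topic: str = ""
    clinical: bool = True
    women_specific: bool = False
    n_words: int = 20

    def __post_init__(self) -> None:
        if self.women_specific and not self.clinical:
            raise ValueError("women_specific topics must be clinical")
        if self.n_words < 1:
            raise ValueError("topics need at least one signature word")


def _default_topics() -> list[TopicSpec]:
    return [
        TopicSpec("pregnancy", Trajectory(0.15), "pregnancy", True, True),
        TopicSpec("contraception", Trajectory(0.05), "contraception", True, True),
        TopicSpec("cardiology", Trajectory(0.30), "cardiology", True, False),
        TopicSpec("psychiatry", Trajectory(0.25), "psychiatry", True, False),
        TopicSpec("oncology", Trajectory(0.25), "oncology", True, False),
    ]


@dataclass(frozen=True)
class SupertopicCall:
    """Directly planted article-level call probability for a super-topic."""

    members: tuple[str, ...]
    trajectory: Trajectory
    called_mass: tuple[float, float] = (0.05, 0.5)  # standardised mass when called
    uncalled_mass: tuple[float, float] = (0.0, 0.0499)


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the desk-scale study conditions."""

    year_start: int = 1948
    year_end: int = 2018
    articles_per_year: int | Mapping[int, int] = 500
    tokens_per_article: float = 200.0
    tokens_dispersion: float | None = None  # None = Poisson; else neg. binomial size
    topics: list[TopicSpec] = field(default_factory=_default_topics)
    doc_topic_concentration: float = 30.0
    topic_word_concentration: float = 0.5
    word_trajectories: dict[str, Trajectory] = field(default_factory=dict)
    lexicon_trajectory: Trajectory | None = None
    lexicon_terms: tuple[str, ...] = _LEXICON_TERMS
    lexicon_topic_coupling: float = 0.0  # extra log-odds of a hit for ws-called articles
    supertopic_call: SupertopicCall | None = None
    emit_tokens: bool = True
    emit_text: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if not self.topics:
            raise ValueError("spec must define at least one topic")
        names = [t.name for t in self.topics]
        if len(set(names)) != len(names):
            raise ValueError("topic names must be unique")


@dataclass
class GroundTruth:
    """Per-article truth emitted alongside the corpus."""

    articles: pd.DataFrame  # article_id, date, year_frac, lexicon_flag, supertopic_flag
    mixtures: np.ndarray  # D x K true topic mixtures
    topic_names: list[str]
    catalog: TopicCatalog
    spec: SyntheticSpec

    def true_calls(self, threshold: float = 0.05) -> np.ndarray:
        """Discrete aboutness calls implied by the true mixtures."""
        return self.mixtures >= threshold

    def lexicon_flags(self) -> np.ndarray:
        return self.articles["lexicon_flag"].to_numpy(dtype=bool)

    def supertopic_flags(self) -> np.ndarray:
        return self.articles["supertopic_flag"].to_numpy(dtype=bool)

    def to_sidecar(self, path) -> None:
        self.articles.to_csv(path, index=False)


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _suffix(i: int) -> str:
    # digit-free suffixes so signature words survive token cleaning
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = _ALPHABET[r] + s
    return s


def topic_vocabulary(topic: TopicSpec) -> list[str]:
    return [f"{topic.name}{_suffix(j)}" for j in range(topic.n_words)]


def _article_dates(spec: SyntheticSpec, rng) -> tuple[np.ndarray, list[dt.date]]:
    """Uniform dates within each year; returns fractional day offsets and dates."""
    day_offsets = []
    for y in range(spec.year_start, spec.year_end + 1):
        n = (
            spec.articles_per_year[y]
            if isinstance(spec.articles_per_year, Mapping)
            else int(spec.articles_per_year)
        )
        start = (dt.date(y, 1, 1) - EPOCH).days
        length = (dt.date(y + 1, 1, 1) - dt.date(y, 1, 1)).days
        day_offsets.append(start + rng.uniform(0.0, length, size=n))
    days = np.sort(np.concatenate(day_offsets))
    dates = [date_of_days(np.floor(d)) for d in days]
    return days, dates


def _catalog_from_topics(topics: Sequence[TopicSpec]) -> TopicCatalog:
    return TopicCatalog(
        pd.DataFrame(
            {
                "label": [t.name for t in topics],
                "super_topic": [t.super_topic or t.name for t in topics],
                "clinical": [t.clinical for t in topics],
                "women_specific": [t.women_specific for t in topics],
            },
            index=pd.Index([t.name for t in topics], name="topic_id"),
        )
    )


def _draw_mixtures(spec: SyntheticSpec, year_frac: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-article Dirichlet mixtures (and supertopic flags when planted)."""
    K = len(spec.topics)
    D = year_frac.size
    logits = np.column_stack([t.trajectory.logit_at(year_frac) for t in spec.topics])
    logits -= logits.max(axis=1, keepdims=True)
    prev = np.exp(logits)
    prev /= prev.sum(axis=1, keepdims=True)

    st_flags = np.zeros(D, dtype=bool)
    if spec.supertopic_call is None:
        shape = np.clip(spec.doc_topic_concentration * prev, 1e-8, None)
        g = rng.gamma(shape)
        mix = g / g.sum(axis=1, keepdims=True)
        return mix, st_flags

    call = spec.supertopic_call
    names = [t.name for t in spec.topics]
    member_idx = np.array([names.index(m) for m in call.members])
    other_idx = np.array([j for j in range(K) if j not in set(member_idx)])
    if other_idx.size == 0:
        raise ValueError("supertopic_call must leave at least one non-member topic")
    p_call = call.trajectory.prob_at(year_frac)
    st_flags = rng.random(D) < p_call
    W = np.where(
        st_flags,
        rng.uniform(call.called_mass[0], call.called_mass[1], size=D),
        rng.uniform(call.uncalled_mass[0], call.uncalled_mass[1], size=D),
    )
    mix = np.zeros((D, K))
    gm = rng.gamma(np.ones((D, member_idx.size)))
    gm /= gm.sum(axis=1, keepdims=True)
    mix[:, member_idx] = gm * W[:, None]
    shape_o = np.clip(spec.doc_topic_concentration * prev[:, other_idx], 1e-8, None)
    go = rng.gamma(shape_o)
    go /= go.sum(axis=1, keepdims=True)
    mix[:, other_idx] = go * (1.0 - W)[:, None]
    return mix, st_flags


def generate_corpus(spec: SyntheticSpec, seed: int | None = None) -> tuple[list[ArticleRecord], GroundTruth]:
    """Generate a dated corpus and its ground truth; deterministic given seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    days, dates = _article_dates(spec, rng)
    year_frac = days_to_year(days)
    D = days.size

    mixtures, st_flags = _draw_mixtures(spec, year_frac, rng)

    lex_flags = np.zeros(D, dtype=bool)
    if spec.lexicon_trajectory is not None:
        logit = spec.lexicon_trajectory.logit_at(year_frac)
        if spec.lexicon_topic_coupling:
            logit = logit + spec.lexicon_topic_coupling * st_flags
        p_lex = 1.0 / (1.0 + np.exp(-logit))
        lex_flags = rng.random(D) < p_lex

    records: list[ArticleRecord] = []
    if spec.emit_tokens:
        vocabs = [np.array(topic_vocabulary(t), dtype=object) for t in spec.topics]
        word_dists = [
            rng.dirichlet(np.full(t.n_words, spec.topic_word_concentration))
            for t in spec.topics
        ]
        traj_words = list(spec.word_trajectories)
        traj_probs = {
            w: spec.word_trajectories[w].prob_at(year_frac) for w in traj_words
        }
        lex_terms = np.array(spec.lexicon_terms, dtype=object)
        if spec.tokens_dispersion is None:
            n_tokens = rng.poisson(spec.tokens_per_article, size=D)
        else:
            size = spec.tokens_dispersion
            n_tokens = rng.negative_binomial(
                size, size / (size + spec.tokens_per_article), size=D
            )
        n_tokens = np.maximum(n_tokens, 1)
        traj_counts = {
            w: rng.binomial(n_tokens, traj_probs[w]) for w in traj_words
        }
        n_lex = np.where(lex_flags, 1 + rng.poisson(1.0, size=D), 0)

        for a in range(D):
            toks: list[str] = []
            for w in traj_words:
                toks.extend([w] * int(traj_counts[w][a]))
            if n_lex[a]:
                toks.extend(rng.choice(lex_terms, size=int(n_lex[a])).tolist())
            n_bg = int(n_tokens[a]) - len(toks)
            if n_bg > 0:
                per_topic = rng.multinomial(n_bg, mixtures[a])
                for j, c in enumerate(per_topic):
                    if c:
                        wc = rng.multinomial(int(c), word_dists[j])
                        nz = wc.nonzero()[0]
                        toks.extend(np.repeat(vocabs[j][nz], wc[nz]).tolist())
            records.append(
                ArticleRecord(
                    article_id=f"a{a:06d}",
                    title=f"synthetic article {a:06d}",
                    pub_date=dates[a],
                    text=" ".join(toks) if spec.emit_text else "",
                    tokens=toks,
                    token_count=len(toks),
                )
            )
    else:
        for a in range(D):
            records.append(
                ArticleRecord(
                    article_id=f"a{a:06d}",
                    title=f"synthetic article {a:06d}",
                    pub_date=dates[a],
                    token_count=1,
                )
            )

    truth = GroundTruth(
        articles=pd.DataFrame(
            {
                "article_id": [r.article_id for r in records],
                "date": dates,
                "year_frac": year_frac,
                "lexicon_flag": lex_flags,
                "supertopic_flag": st_flags,
            }
        ),
        mixtures=mixtures,
        topic_names=[t.name for t in spec.topics],
        catalog=_catalog_from_topics(spec.topics),
        spec=spec,
    )
    return records, truth


@dataclass
class DefectManifest:
    """Labelled planted defects for the corpus-filter fixture."""

    n_total: int
    duplicate_idx: np.ndarray
    short_idx: np.ndarray
    missing_idx: np.ndarray
    parse_outlier_idx: np.ndarray
    outlier_threshold: float  # separates planted normal lengths from outliers
    parse_window: tuple[dt.date, dt.date]

    @property
    def n_defects(self) -> int:
        return (
            len(self.duplicate_idx)
            + len(self.short_idx)
            + len(self.missing_idx)
            + len(self.parse_outlier_idx)
        )

    @property
    def expected_retained(self) -> int:
        return self.n_total - self.n_defects

    def defect_index_union(self) -> set[int]:
        return (
            set(self.duplicate_idx.tolist())
            | set(self.short_idx.tolist())
            | set(self.missing_idx.tolist())
            | set(self.parse_outlier_idx.tolist())
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(int(i), "duplicate_title") for i in self.duplicate_idx]
            + [(int(i), "short") for i in self.short_idx]
            + [(int(i), "missing_dataset") for i in self.missing_idx]
            + [(int(i), "parse_outlier") for i in self.parse_outlier_idx]
        )
        return pd.DataFrame(rows, columns=["index", "defect"])


def planted_defect_manifest(
    n_total: int = 74937,
    n_duplicate: int = 1330,
    n_short: int = 364,
    n_missing_dataset: int = 749,
    n_parse_outlier: int = 628,
    year_start: int = 1948,
    year_end: int = 2018,
    parse_window: tuple[dt.date, dt.date] = DEFAULT_PARSE_WINDOW,
    normal_tokens: tuple[int, int] = (50, 3000),
    outlier_tokens: tuple[int, int] = (50_000, 100_000),
    seed: int = 0,
) -> tuple[list[ArticleRecord], DefectManifest]:
    """Corpus with labelled planted defects, defect classes pairwise disjoint.

    Duplicate-title records copy the title of an earlier clean record; short
    records get sub-``min_tokens`` counts; missing-dataset records lose one or
    both membership flags; parse-window outliers sit inside the window with
    token counts far above every planted normal count.  The manifest reports
    the threshold separating normal from outlier lengths so the filter can be
    run with an explicit length rule.
    """
    n_defects = n_duplicate + n_short + n_missing_dataset + n_parse_outlier
    if n_defects > n_total - 1:
        raise ValueError("overlapping defect requests: counts exceed corpus size")
    rng = np.random.default_rng(seed)

    # Record 0 stays clean so every duplicate has an earlier source.
    chosen = rng.choice(np.arange(1, n_total), size=n_defects, replace=False)
    dup_idx = np.sort(chosen[:n_duplicate])
    short_idx = np.sort(chosen[n_duplicate : n_duplicate + n_short])
    miss_idx = np.sort(
        chosen[n_duplicate + n_short : n_duplicate + n_short + n_missing_dataset]
    )
    out_idx = np.sort(chosen[n_duplicate + n_short + n_missing_dataset :])
    defect_set = set(chosen.tolist())

    start_day = (dt.date(year_start, 1, 1) - EPOCH).days
    end_day = (dt.date(year_end, 7, 18) - EPOCH).days
    days = rng.uniform(start_day, end_day, size=n_total)
    token_counts = rng.integers(normal_tokens[0], normal_tokens[1] + 1, size=n_total)

    w0 = (parse_window[0] - EPOCH).days
    w1 = (parse_window[1] - EPOCH).days
    days[out_idx] = rng.uniform(w0, w1 + 0.999, size=len(out_idx))
    token_counts[out_idx] = rng.integers(
        outlier_tokens[0], outlier_tokens[1] + 1, size=len(out_idx)
    )
    token_counts[short_idx] = rng.integers(1, 50, size=len(short_idx))

    in_wc = np.ones(n_total, dtype=bool)
    in_tp = np.ones(n_total, dtype=bool)
    which = rng.integers(0, 3, size=len(miss_idx))
    in_wc[miss_idx[which != 1]] = False
    in_tp[miss_idx[which != 0]] = False

    clean_sorted = np.array(sorted(set(range(n_total)) - defect_set))
    titles = [f"study of synthetic condition {i:06d}" for i in range(n_total)]
    for v in dup_idx:
        pos = int(np.searchsorted(clean_sorted, v))
        source = int(clean_sorted[rng.integers(0, pos)])
        titles[v] = titles[source]

    records = [
        ArticleRecord(
            article_id=f"a{i:06d}",
            title=titles[i],
            pub_date=date_of_days(np.floor(days[i])),
            token_count=int(token_counts[i]),
            in_wordcount_set=bool(in_wc[i]),
            in_topicprob_set=bool(in_tp[i]),
        )
        for i in range(n_total)
    ]
    manifest = DefectManifest(
        n_total=n_total,
        duplicate_idx=dup_idx,
        short_idx=short_idx,
        missing_idx=miss_idx,
        parse_outlier_idx=out_idx,
        outlier_threshold=float(normal_tokens[1] + outlier_tokens[0]) / 2.0,
        parse_window=parse_window,
    )
    return records, manifest
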