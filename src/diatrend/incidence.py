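"""Discrete "aboutness" calls and incidence time series.

Topic probabilities are first standardised over the set of topics of interest
(e.g. all clinical topics), then discretised: an article is *about* a topic
when its standardised probability is at least 0.05 (inclusive), and about a
super-topic when the summed standardised probabilities of its subsidiary
topics reach the same threshold.  Because an article may be about several
topics, the denominator of a topic's yearly incidence is the total number of
topic calls that year, not the number of articles.  Word incidence is counted
over cleaned tokens against all tokens; article incidence (for article-level
classifiers) is a plain proportion of articles.  All series carry Wilson 95%
score intervals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

DEFAULT_THRESHOLD = 0.05


@dataclass
class TopicCatalog:
    """Topic id -> (label, super_topic, clinical flag, women_specific flag).

    Invariant: every women-specific topic is clinical.
    """

    table: pd.DataFrame  # index: topic_id; columns: label, super_topic, clinical, women_specific

    def __post_init__(self) -> None:
        required = {"label", "super_topic", "clinical", "women_specific"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        bad = self.table[self.table["women_specific"] & ~self.table["clinical"]]
        if len(bad):
            raise ValueError(
                f"women_specific topics must be clinical; offending ids: {list(bad.index)}"
            )

    @classmethod
    def from_csv(cls, path) -> "TopicCatalog":
        df = pd.read_csv(path, dtype={"topic_id": str}).set_index("topic_id")
        for col in ("clinical", "women_specific"):
            df[col] = df[col].astype(bool)
        return cls(df)

    @classmethod
    def packaged(cls) -> "TopicCatalog":
        """The miniature stand-in catalog shipped with the package (synthetic)."""
        from importlib import resources

        ref = resources.files("diatrend.data").joinpath("catalog_synthetic.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    @property
    def topic_ids(self) -> list[str]:
        return list(self.table.index)

    def clinical_ids(self) -> list[str]:
        return list(self.table.index[self.table["clinical"]])

    def women_specific_ids(self) -> list[str]:
        return list(self.table.index[self.table["women_specific"]])

    def supertopic_members(self, super_topic: str) -> list[str]:
        return list(self.table.index[self.table["super_topic"] == super_topic])


@dataclass
class IncidenceSeries:
    """Yearly numerator/denominator series with point estimate and Wilson CI.

    Years with zero denominator are emitted with NaN incidence and no CI.
    """

    data: pd.DataFrame  # columns: year, numerator, denominator, incidence, ci_low, ci_high
    label: str = ""

    def __post_init__(self) -> None:
        d = self.data
        if (d["numerator"] > d["denominator"]).any():
            raise ValueError("numerator exceeds denominator")
        if (d[["numerator", "denominator"]] < 0).to_numpy().any():
            raise ValueError("counts must be non-negative")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def trend_series(self) -> pd.DataFrame:
        """(date, successes, trials) rows for the trend module, mid-year dates."""
        d = self.data[self.data["denominator"] > 0]
        return pd.DataFrame(
            {
                "date": [dt.date(int(y), 7, 1) for y in d["year"]],
                "successes": d["numerator"].to_numpy(),
                "trials": d["denominator"].to_numpy(),
            }
        )


def _make_series(years, num, den, label="") -> IncidenceSeries:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    inc = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    lo = np.full(len(num), np.nan)
    hi = np.full(len(num), np.nan)
    pos = den > 0
    if pos.any():
        lo_p, hi_p = proportion_confint(num[pos], den[pos], alpha=0.05, method="wilson")
        lo[pos] = lo_p
        hi[pos] = hi_p
    return IncidenceSeries(
        pd.DataFrame(
            {
                "year": np.asarray(years, dtype=int),
                "numerator": num.astype(int),
                "denominator": den.astype(int),
                "incidence": inc,
                "ci_low": lo,
                "ci_high": hi,
            }
        ),
        label=label,
    )


def standardize_probs(p_row, subset) -> np.ndarray:
    """Renormalise the probabilities of ``subset`` to sum to one.

    Returns a vector over the subset.  A zero subset sum yields an all-zero
    vector (the article is unclassifiable at this step; callers flag it).
    """
    p_row = np.asarray(p_row, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    if (p_row < 0).any():
        raise ValueError("probabilities must be non-negative")
    sub = p_row[subset]
    total = sub.sum()
    if total == 0:
        return np.zeros(subset.size)
    return sub / total


def discretize(p_std, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean 'about' calls: standardised probability >= threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(p_std, dtype=float) >= threshold


def supertopic_about(p_row, members, threshold: float = DEFAULT_THRESHOLD, subset=None) -> bool:
    """Is the article about the super-topic whose subsidiaries are ``members``?

    ``p_row`` is standardised over ``subset`` (defaults to all entries) and the
    member probabilities summed before thresholding.
    """
    p_row = np.asarray(p_row, dtype=float)
    if subset is None:
        subset = np.arange(p_row.size)
    subset = np.asarray(subset, dtype=int)
    p_std = standardize_probs(p_row, subset)
    pos = {int(t): i for i, t in enumerate(subset)}
    member_pos = [pos[int(m)] for m in members]
    return bool(p_std[member_pos].sum() >= threshold)


def supertopic_calls(p_matrix, members, threshold: float = DEFAULT_THRESHOLD, subset=None) -> np.ndarray:
    """Vectorised :func:`supertopic_about` over a (articles x topics) matrix.

    Rows whose standardisation subset sums to zero yield False (unclassifiable
    articles are never 'about' anything).
    """
    p = np.asarray(p_matrix, dtype=float)
    if subset is None:
        subset = np.arange(p.shape[1])
    subset = np.asarray(subset, dtype=int)
    sub = p[:, subset]
    totals = sub.sum(axis=1)
    pos = {int(t): i for i, t in enumerate(subset)}
    member_pos = [pos[int(m)] for m in members]
    mass = sub[:, member_pos].sum(axis=1)
    out = np.zeros(p.shape[0], dtype=bool)
    ok = totals > 0
    out[ok] = (mass[ok] / totals[ok]) >= threshold
    return out


def _years_of(dates) -> np.ndarray:
    out = np.empty(len(dates), dtype=int)
    for i, d in enumerate(dates):
        out[i] = d.year if hasattr(d, "year") else int(d)
    return out


def topic_incidence(calls, dates, selector, label="") -> IncidenceSeries:
    """Yearly incidence I_it = N_it / N_t of one topic (or super-topic).

    ``calls`` is a (articles x topics-of-interest) boolean matrix of 'about'
    calls.  ``selector`` is either a column index, or a per-article boolean
    vector of pre-computed calls (e.g. super-topic calls).  The denominator is
    the total number of calls across all topics of interest that year — not
    the number of articles, since one article may be about several topics.
    """
    calls = np.asarray(calls, dtype=bool)
    years = _years_of(dates)
    if calls.shape[0] != len(years):
        raise ValueError("calls and dates are not aligned")
    if np.isscalar(selector) or isinstance(selector, (int, np.integer)):
        sel = calls[:, int(selector)]
    else:
        sel = np.asarray(selector, dtype=bool)
        if sel.shape != (calls.shape[0],):
            raise ValueError("selector vector must have one entry per article")
    uy = np.unique(years)
    num = np.array([int(sel[years == y].sum()) for y in uy])
    den = np.array([int(calls[years == y].sum()) for y in uy])
    return _make_series(uy, num, den, label=label)


def article_incidence(flags, dates, label="") -> IncidenceSeries:
    """Yearly proportion of flagged articles among all articles that year."""
    flags = np.asarray(flags, dtype=bool)
    years = _years_of(dates)
    if flags.shape[0] != len(years):
        raise ValueError("flags and dates are not aligned")
    uy = np.unique(years)
    num = np.array([int(flags[years == y].sum()) for y in uy])
    den = np.array([int((years == y).sum()) for y in uy])
    return _make_series(uy, num, den, label=label)


def word_incidence(records, variants, label="") -> IncidenceSeries:
    """Yearly occurrences of any variant relative to all (cleaned) tokens.

    ``records`` is an iterable of objects with ``pub_date`` and ``tokens``;
    ``variants`` a non-empty set of lowercase word forms counted jointly.
    """
    variants = frozenset(variants)
    if not variants:
        raise ValueError("variant set must be non-empty")
    num: dict[int, int] = {}
    den: dict[int, int] = {}
    for rec in records:
        tokens = rec.tokens
        if tokens is None:
            raise ValueError(f"record {rec.article_id} has no token list")
        y = rec.pub_date.year
        den[y] = den.get(y, 0) + len(tokens)
        hits = 0
        for t in tokens:
            if t in variants:
                hits += 1
        num[y] = num.get(y, 0) + hits
    uy = sorted(den)
    return _make_series(
        uy, [num[y] for y in uy], [den[y] for y in uy], label=label
    )
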