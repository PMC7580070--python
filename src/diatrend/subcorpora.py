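"""Article classifiers defining the analysis subcorpora.

Two classifiers: (1) *women-specific health* — the article's probabilities
over clinical topics are collapsed into a women-specific bucket W and an
other-clinical bucket O, the pair standardised by W+O, and the article called
women-specific when the standardised W reaches the 0.05 threshold; (2)
*gender vocal / gender silent* — an article is gender vocal when any raw token
exactly matches a lexicon variant (woman/women, female/females, gender,
sex/sexes), and gender silent otherwise.  The lexicon runs on pre-stopword
tokens so that common words cannot be lost to a stopword list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .incidence import DEFAULT_THRESHOLD, IncidenceSeries, TopicCatalog, article_incidence


@dataclass(frozen=True)
class GenderLexicon:
    """Whole-word, lowercase variant groups for the vocal/silent split."""

    groups: tuple[tuple[str, ...], ...] = (
        ("woman", "women"),
        ("female", "females"),
        ("gender",),
        ("sex", "sexes"),
    )

    def __post_init__(self) -> None:
        if not self.groups or any(not g for g in self.groups):
            raise ValueError("lexicon groups must be non-empty")
        for g in self.groups:
            for term in g:
                if term != term.lower():
                    raise ValueError(f"lexicon terms must be lowercase: {term!r}")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(t for g in self.groups for t in g)


def classify_womens_health(
    p_row,
    catalog: TopicCatalog,
    threshold: float = DEFAULT_THRESHOLD,
    clinical_ids: Sequence[str] | None = None,
) -> bool | None:
    """Women-specific-health call from probabilities over clinical topics.

    ``p_row`` must be aligned to ``clinical_ids`` (defaults to the catalog's
    clinical topics in catalog order).  Returns True/False, or None when both
    buckets are zero (unclassifiable).
    """
    if clinical_ids is None:
        clinical_ids = catalog.clinical_ids()
    p_row = np.asarray(p_row, dtype=float)
    if p_row.size != len(clinical_ids):
        raise ValueError("p_row is not aligned to the clinical topic list")
    ws = set(catalog.women_specific_ids())
    is_ws = np.array([tid in ws for tid in clinical_ids])
    W = float(p_row[is_ws].sum())
    O = float(p_row[~is_ws].sum())
    if W + O == 0:
        return None
    return (W / (W + O)) >= threshold


def classify_gender_vocal(tokens: Iterable[str], lexicon: GenderLexicon | None = None) -> bool:
    """True iff any token exactly matches a lexicon variant (case-insensitive)."""
    if lexicon is None:
        lexicon = GenderLexicon()
    terms = lexicon.terms
    for t in tokens:
        if t.lower() in terms:
            return True
    return False


@dataclass
class SubcorpusReport:
    """Class totals plus the per-year incidence of the positive class."""

    n_positive: int
    n_negative: int
    n_unclassifiable: int
    series: IncidenceSeries

    @property
    def n_classified(self) -> int:
        return self.n_positive + self.n_negative


def subcorpus_report(records, classifier: Callable, label: str = "") -> SubcorpusReport:
    """Apply an article classifier corpus-wide and tally by class and year.

    ``classifier`` maps a record to True/False/None (None = unclassifiable;
    excluded from the series denominator).
    """
    flags: list[bool] = []
    dates = []
    n_un = 0
    for rec in records:
        call = classifier(rec)
        if call is None:
            n_un += 1
            continue
        flags.append(bool(call))
        dates.append(rec.pub_date)
    if flags:
        series = article_incidence(np.array(flags), dates, label=label)
        n_pos = int(np.sum(flags))
    else:
        series = IncidenceSeries(
            pd.DataFrame(
                columns=["year", "numerator", "denominator", "incidence", "ci_low", "ci_high"]
            ).astype({"year": int, "numerator": int, "denominator": int}),
            label=label,
        )
        n_pos = 0
    return SubcorpusReport(
        n_positive=n_pos,
        n_negative=len(flags) - n_pos,
        n_unclassifiable=n_un,
        series=series,
    )


def classifications_frame(records, classifier: Callable, positive: str, negative: str) -> pd.DataFrame:
    """Per-article classification table (article_id, class, year) for export."""
    rows = []
    for rec in records:
        call = classifier(rec)
        cls = "unclassifiable" if call is None else (positive if call else negative)
        rows.append((rec.article_id, cls, rec.pub_date.year))
    return pd.DataFrame(rows, columns=["article_id", "class", "year"])
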