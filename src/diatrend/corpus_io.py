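"""Reading, validating and filtering the dated article corpus.

The corpus is a line-delimited JSON file, one article per line, with fields
``id``, ``title``, ``date`` (ISO 8601), ``text`` and optional dataset-membership
flags ``in_wordcount_set`` / ``in_topicprob_set``.  Filtering applies, in
order: duplicate-title removal, short-article removal, dataset-intersection
removal, and removal of implausibly long articles inside a parse-error window,
with every exclusion accounted for in a :class:`FilterReport`.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_TOKENS = 50
DEFAULT_PARSE_WINDOW = (dt.date(1997, 1, 4), dt.date(1998, 2, 14))
DEFAULT_OUTLIER_PERCENTILE = 99.5


class ConfigurationError(ValueError):
    """Raised for inconsistent filter configuration (e.g. start > end)."""


@dataclass
class ArticleRecord:
    """One dated document with raw text and dataset-membership flags.

    ``token_count`` is a raw whitespace word count until preprocessing runs;
    afterwards it equals the length of the cleaned token list.
    """

    article_id: str
    title: str
    pub_date: dt.date
    text: str = ""
    tokens: list[str] | None = None
    token_count: int = 0
    in_wordcount_set: bool = True
    in_topicprob_set: bool = True

    def __post_init__(self) -> None:
        if self.tokens is not None and self.token_count == 0:
            self.token_count = len(self.tokens)
        elif self.token_count == 0 and self.text:
            self.token_count = len(self.text.split())


@dataclass(frozen=True)
class RecordError:
    """A malformed corpus line, reported rather than silently dropped."""

    line_number: int
    article_id: str | None
    message: str


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_removed_duplicate_title: int
    n_removed_short: int
    n_removed_missing_dataset: int
    n_removed_parse_window: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_duplicate_title
            + self.n_removed_short
            + self.n_removed_missing_dataset
            + self.n_removed_parse_window
        )
        if self.n_retained != self.n_input - removed:
            raise ValueError("FilterReport counts do not reconcile")
        if min(
            self.n_input,
            self.n_removed_duplicate_title,
            self.n_removed_short,
            self.n_removed_missing_dataset,
            self.n_removed_parse_window,
            self.n_retained,
        ) < 0:
            raise ValueError("FilterReport counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [
                    "input",
                    "duplicate_title",
                    "short",
                    "missing_dataset",
                    "parse_window",
                    "retained",
                ],
                "count": [
                    self.n_input,
                    self.n_removed_duplicate_title,
                    self.n_removed_short,
                    self.n_removed_missing_dataset,
                    self.n_removed_parse_window,
                    self.n_retained,
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parse_date(raw: str) -> dt.date:
    return dt.date.fromisoformat(str(raw))


def read_corpus(path) -> tuple[list[ArticleRecord], list[RecordError]]:
    """Read a line-delimited JSON corpus.

    Returns records in file order plus a list of per-record errors
    (unparseable JSON, missing fields, impossible dates).  An empty file
    yields an empty corpus with no errors.
    """
    records: list[ArticleRecord] = []
    errors: list[RecordError] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append(RecordError(lineno, None, f"invalid JSON: {exc}"))
                continue
            rid = obj.get("id")
            missing = [k for k in ("id", "title", "date", "text") if k not in obj]
            if missing:
                errors.append(
                    RecordError(lineno, rid, f"missing fields: {', '.join(missing)}")
                )
                continue
            try:
                pub_date = _parse_date(obj["date"])
            except ValueError as exc:
                errors.append(
                    RecordError(lineno, rid, f"unparseable date {obj['date']!r}: {exc}")
                )
                continue
            records.append(
                ArticleRecord(
                    article_id=str(rid),
                    title=str(obj["title"]),
                    pub_date=pub_date,
                    text=str(obj["text"]),
                    token_count=int(obj.get("token_count", 0)),
                    in_wordcount_set=bool(obj.get("in_wordcount_set", True)),
                    in_topicprob_set=bool(obj.get("in_topicprob_set", True)),
                )
            )
    return records, errors


def write_corpus(records: Iterable[ArticleRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "id": rec.article_id,
                        "title": rec.title,
                        "date": rec.pub_date.isoformat(),
                        "text": rec.text,
                        "token_count": rec.token_count,
                        "in_wordcount_set": rec.in_wordcount_set,
                        "in_topicprob_set": rec.in_topicprob_set,
                    }
                )
                + "\n"
            )


def _normalise_title(title: str) -> str:
    return title.strip().casefold()


def percentile_outlier_rule(
    percentile: float = DEFAULT_OUTLIER_PERCENTILE,
) -> Callable[[np.ndarray], np.ndarray]:
    """Rule flagging token counts strictly above a corpus-wide percentile.

    The percentile is computed over the corpus as it stands when the
    parse-window step runs.
    """

    def rule(token_counts: np.ndarray) -> np.ndarray:
        cutoff = np.percentile(token_counts, percentile)
        return token_counts > cutoff

    return rule


def filter_corpus(
    records: Sequence[ArticleRecord],
    window_start: dt.date | None = None,
    window_end: dt.date | None = None,
    min_tokens: int = DEFAULT_MIN_TOKENS,
    parse_window: tuple[dt.date, dt.date] = DEFAULT_PARSE_WINDOW,
    length_outlier_rule: float | Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[list[ArticleRecord], FilterReport]:
    """Filter a corpus in four sequential steps with full accounting.

    Steps, each counted against the corpus as it stands when it runs:

    1. drop records whose normalised title duplicates an earlier record's
       title (first occurrence kept);
    2. drop records with ``token_count < min_tokens``;
    3. drop records absent from either dataset (both membership flags
       required);
    4. drop records dated inside ``parse_window`` (inclusive) whose length
       triggers ``length_outlier_rule`` — a numeric threshold (token_count
       strictly above it), a callable mapping the step-4 token-count array to
       a boolean mask, or None for the default 99.5th-percentile rule.

    ``window_start``/``window_end`` describe the corpus's nominal date span;
    they are validated (start must not exceed end) but no removal class exists
    for them, so they never drop records.
    """
    if window_start is not None and window_end is not None and window_start > window_end:
        raise ConfigurationError("window_start is after window_end")
    if parse_window[0] > parse_window[1]:
        raise ConfigurationError("parse_window start is after its end")

    n_input = len(records)

    seen: set[str] = set()
    after_dup: list[ArticleRecord] = []
    for rec in records:
        key = _normalise_title(rec.title)
        if key in seen:
            continue
        seen.add(key)
        after_dup.append(rec)
    n_dup = n_input - len(after_dup)

    after_short = [r for r in after_dup if r.token_count >= min_tokens]
    n_short = len(after_dup) - len(after_short)

    after_ds = [r for r in after_short if r.in_wordcount_set and r.in_topicprob_set]
    n_ds = len(after_short) - len(after_ds)

    counts = np.array([r.token_count for r in after_ds], dtype=float)
    in_window = np.array(
        [parse_window[0] <= r.pub_date <= parse_window[1] for r in after_ds],
        dtype=bool,
    )
    if len(after_ds) == 0:
        outlier = np.zeros(0, dtype=bool)
    elif length_outlier_rule is None:
        outlier = percentile_outlier_rule()(counts)
    elif callable(length_outlier_rule):
        outlier = np.asarray(length_outlier_rule(counts), dtype=bool)
    else:
        outlier = counts > float(length_outlier_rule)
    drop = in_window & outlier
    retained = [r for r, d in zip(after_ds, drop) if not d]
    n_window = int(drop.sum())

    report = FilterReport(
        n_input=n_input,
        n_removed_duplicate_title=n_dup,
        n_removed_short=n_short,
        n_removed_missing_dataset=n_ds,
        n_removed_parse_window=n_window,
        n_retained=len(retained),
    )
    return retained, report
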