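"""Tokenisation, word-removal rules and the sparse document-term matrix.

Rules applied before topic modelling: lowercase tokens split on non-word
boundaries with hyphens retained inside tokens; then remove stopwords, tokens
containing any digit, and hyphenated tokens with an empty hyphen-delimited
part.  No stemming, lemmatisation or n-grams.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]*)*")


@dataclass(frozen=True)
class StopwordList:
    """A stopword list with provenance (term count and content hash)."""

    terms: frozenset[str]
    sha256: str
    source: str

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def load_stopwords(path=None) -> StopwordList:
    """Load a plain-text stopword list (one lowercase term per line).

    Without ``path`` the packaged common-English list is used.  The sha256 of
    the raw file is recorded so analyses can state exactly which list ran.
    """
    if path is None:
        ref = resources.files("diatrend.data").joinpath("stopwords.txt")
        raw = ref.read_bytes()
        source = "diatrend.data/stopwords.txt"
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
        source = str(path)
    terms = frozenset(
        line.strip().lower()
        for line in raw.decode("utf-8").splitlines()
        if line.strip()
    )
    return StopwordList(terms=terms, sha256=hashlib.sha256(raw).hexdigest(), source=source)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-word boundaries, keeping internal hyphens.

    Digits survive tokenisation (they are removed by :func:`clean_tokens`);
    edge punctuation is stripped by the token pattern itself.
    """
    return _TOKEN_RE.findall(text.lower())


def _is_degenerate_hyphenation(token: str) -> bool:
    return "-" in token and any(part == "" for part in token.split("-"))


def clean_tokens(tokens: Iterable[str], stopwords) -> list[str]:
    """Apply the three removal rules: stopword, contains-digit, empty hyphen part."""
    sw = stopwords.terms if isinstance(stopwords, StopwordList) else set(stopwords)
    return [
        t
        for t in tokens
        if t not in sw
        and not any(ch.isdigit() for ch in t)
        and not _is_degenerate_hyphenation(t)
    ]


def preprocess_corpus(records, stopwords=None) -> None:
    """Tokenise and clean every record in place, updating ``token_count``."""
    if stopwords is None:
        stopwords = load_stopwords()
    for rec in records:
        rec.tokens = clean_tokens(tokenize(rec.text), stopwords)
        rec.token_count = len(rec.tokens)


@dataclass
class Vocabulary:
    """Dense 0-based term index in lexicographic order, with document frequency."""

    terms: list[str]
    index: dict[str, int]
    doc_freq: np.ndarray

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_token_lists(cls, token_lists: Sequence[Sequence[str]]) -> "Vocabulary":
        terms = sorted({t for toks in token_lists for t in toks})
        index = {t: i for i, t in enumerate(terms)}
        df = np.zeros(len(terms), dtype=int)
        for toks in token_lists:
            for t in set(toks):
                df[index[t]] += 1
        return cls(terms=terms, index=index, doc_freq=df)


@dataclass
class DocTermMatrix:
    """Sparse non-negative integer counts, rows aligned to article ids."""

    counts: sp.csr_matrix
    row_ids: list[str]
    vocabulary: Vocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_token_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def zero_rows(self) -> list[str]:
        """Ids of articles whose cleaned text is empty (flagged, not dropped)."""
        sums = self.row_token_counts()
        return [rid for rid, s in zip(self.row_ids, sums) if s == 0]

    def save(self, prefix: str) -> None:
        """Export as MatrixMarket plus row-id and vocabulary sidecars."""
        from scipy.io import mmwrite

        mmwrite(f"{prefix}.mtx", self.counts)
        with open(f"{prefix}.rows.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.row_ids) + ("\n" if self.row_ids else ""))
        with open(f"{prefix}.vocab.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.vocabulary.terms) + ("\n" if self.vocabulary.terms else ""))


def build_doc_term(records) -> tuple[Vocabulary, DocTermMatrix]:
    """Count cleaned tokens into a sparse document-term matrix.

    Records must have been preprocessed (``tokens`` set).  Term order is
    lexicographic, so the matrix is deterministic for a given corpus.  Rows
    that are all-zero (articles reduced to nothing by cleaning) are retained
    and discoverable via :meth:`DocTermMatrix.zero_rows`.
    """
    token_lists = []
    row_ids = []
    for rec in records:
        if rec.tokens is None:
            raise ValueError(f"record {rec.article_id} has no token list; run preprocessing")
        token_lists.append(rec.tokens)
        row_ids.append(rec.article_id)
    vocab = Vocabulary.from_token_lists(token_lists)
    data, indices, indptr = [], [], [0]
    for toks in token_lists:
        counts: dict[int, int] = {}
        for t in toks:
            j = vocab.index[t]
            counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    mat = sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices, dtype=np.int64), np.array(indptr, dtype=np.int64)),
        shape=(len(token_lists), len(vocab)),
    )
    return vocab, DocTermMatrix(counts=mat, row_ids=row_ids, vocabulary=vocab)
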