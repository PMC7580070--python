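import datetime as dt

import numpy as np
import pytest

from diatrend.corpus_io import ArticleRecord


@pytest.fixture
def tiny_records():
    """Three hand-built articles across two years."""
    return [
        ArticleRecord(
            "a1",
            "Oral contraceptives and thrombosis",
            dt.date(1967, 3, 1),
            text="women were given oral contraceptives",
            tokens=["women", "given", "oral", "contraceptives"],
        ),
        ArticleRecord(
            "a2",
            "Myocardial infarction in men",
            dt.date(1967, 9, 1),
            text="men with myocardial infarction",
            tokens=["men", "myocardial", "infarction"],
        ),
        ArticleRecord(
            "a3",
            "Breast cancer screening",
            dt.date(1988, 6, 1),
            text="screening women for breast cancer",
            tokens=["screening", "women", "breast", "cancer"],
        ),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(i, year=2000, tokens=None, title=None, **kwargs):
    return ArticleRecord(
        article_id=f"r{i:04d}",
        title=title or f"record number {i:04d}",
        pub_date=dt.date(year, 6, 15),
        tokens=tokens,
        **kwargs,
    )
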