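"""Date encoding shared across the package.

Trend models regress on publication *date*, not year.  Dates are encoded as
(fractional) days since 1948-01-01; slopes are annualised with a factor of
365.25 days/year so that "annual odds factor" means exp(slope_per_day * 365.25).
"""

from __future__ import annotations

import datetime as dt

import numpy as np

EPOCH = dt.date(1948, 1, 1)
DAYS_PER_YEAR = 365.25


def to_days(dates) -> np.ndarray:
    """Convert dates to float days since the 1948-01-01 epoch.

    Accepts datetime.date objects, numpy datetime64, ISO strings, or numbers
    (already-encoded day offsets pass through unchanged).
    """
    arr = np.asarray(dates)
    if arr.dtype.kind in "fiu":
        return arr.astype(float)
    if arr.dtype.kind == "M":
        epoch64 = np.datetime64(EPOCH)
        return (arr - epoch64) / np.timedelta64(1, "D")
    flat = np.atleast_1d(arr)
    out = np.empty(flat.shape, dtype=float)
    for i, d in enumerate(flat.ravel()):
        if isinstance(d, str):
            d = dt.date.fromisoformat(d)
        elif isinstance(d, dt.datetime):
            d = d.date()
        out.ravel()[i] = (d - EPOCH).days
    return out.reshape(arr.shape) if arr.shape else out[0] * np.ones(())


def days_to_year(days) -> np.ndarray:
    """Fractional calendar-style year for a day offset (1948.0 = epoch)."""
    return 1948.0 + np.asarray(days, dtype=float) / DAYS_PER_YEAR


def year_to_days(year) -> np.ndarray:
    """Inverse of :func:`days_to_year`."""
    return (np.asarray(year, dtype=float) - 1948.0) * DAYS_PER_YEAR


def date_of_days(days: float) -> dt.date:
    return EPOCH + dt.timedelta(days=float(days))
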