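"""Binomial trend models on publication date.

All models are logistic regressions of a success proportion on publication
date (encoded as days since 1948-01-01, regressed on the year scale for
numerical conditioning).  The headline quantity is the *annual odds factor*
exp(slope_per_day * 365.25): the multiplicative yearly change in the odds of
the modelled event.  Wald 95% intervals throughout.

The segmented model adds a single estimated breakpoint psi: the linear
predictor gains a hinge term (x - psi)+, and psi is estimated by iterative
linearisation — refit with the hinge at the current psi plus a gap indicator
I(x > psi), then update psi by the gap-to-slope ratio gamma/beta2 — until the
update falls below 0.01 day.  The breakpoint's standard error is the delta-
method ratio SE(gamma)/|beta2|.  Model choice against the no-break trend is
by AIC, the segmented model carrying four parameters (two slopes, intercept,
breakpoint).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._time import DAYS_PER_YEAR, date_of_days, days_to_year, to_days

_Z = 1.959963984540054  # normal 97.5% quantile


def _as_series(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce input into (x_days, successes, trials) arrays.

    Accepts a DataFrame with columns date/successes/trials or a 3-tuple of
    array-likes in the same order.
    """
    if isinstance(series, pd.DataFrame):
        dates, succ, trials = series["date"], series["successes"], series["trials"]
    else:
        dates, succ, trials = series
    x = to_days(list(dates) if not isinstance(dates, np.ndarray) else dates)
    succ = np.asarray(succ, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if (succ < 0).any() or (trials < succ).any():
        raise ValueError("need 0 <= successes <= trials")
    return np.asarray(x, dtype=float), succ, trials


def _glm_fit(x_cols: list[np.ndarray], succ: np.ndarray, trials: np.ndarray):
    exog = np.column_stack([np.ones_like(succ)] + x_cols)
    endog = np.column_stack([succ, trials - succ])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-10)


@dataclass
class TrendFit:
    """Plain logistic trend: logit(p) = intercept + slope_per_day * days."""

    intercept: float
    slope_per_day: float
    annual_odds_factor: float
    ci_low: float
    ci_high: float
    se_annual_log_odds: float
    deviance: float
    aic: float
    n_obs: int
    separation_flag: bool = False
    all_zero_flag: bool = False

    @property
    def slope_per_year(self) -> float:
        return self.slope_per_day * DAYS_PER_YEAR


def fit_binomial_trend(series) -> TrendFit:
    """Fit logit(p) ~ publication date by IRLS and annualise the slope.

    Requires at least two distinct dates.  Complete separation is flagged and
    the CI suppressed; an all-zero (or all-one) success series is flagged.
    """
    x_days, succ, trials = _as_series(series)
    if np.unique(x_days).size < 2:
        raise ValueError("need at least two distinct dates")
    x_years = x_days / DAYS_PER_YEAR
    res = _glm_fit([x_years], succ, trials)
    b0, b1 = res.params
    se1 = res.bse[1]
    all_zero = succ.sum() == 0 or (trials - succ).sum() == 0
    separation = bool(not np.isfinite(se1) or se1 > 1e3 or abs(b1) > 1e3)
    if separation or all_zero:
        ci = (np.nan, np.nan)
    else:
        ci = (np.exp(b1 - _Z * se1), np.exp(b1 + _Z * se1))
    return TrendFit(
        intercept=float(b0),
        slope_per_day=float(b1) / DAYS_PER_YEAR,
        annual_odds_factor=float(np.exp(b1)),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        se_annual_log_odds=float(se1),
        deviance=float(res.deviance),
        aic=float(res.aic),
        n_obs=len(succ),
        separation_flag=separation,
        all_zero_flag=bool(all_zero),
    )


@dataclass
class SegmentedFit:
    """Single-breakpoint logistic trend with delta-method CI on the break."""

    breakpoint_days: float
    breakpoint_date: dt.date
    breakpoint_year: float
    psi_se_days: float
    psi_ci_low_year: float
    psi_ci_high_year: float
    pre_slope_per_day: float
    post_slope_per_day: float
    pre_annual_factor: float
    pre_ci_low: float
    pre_ci_high: float
    post_annual_factor: float
    post_ci_low: float
    post_ci_high: float
    aic: float
    null_model_aic: float
    converged: bool
    n_iterations: int
    diagnostics: str = ""


def fit_segmented_trend(series, init_breakpoint=None, max_iter: int = 50,
                        tol_days: float = 0.01) -> SegmentedFit:
    """Estimate a single breakpoint by iterative linearisation.

    ``init_breakpoint`` defaults to the midpoint of the observed date range.
    Non-convergence, or a breakpoint escaping the data range that step-halving
    cannot rescue, is reported with ``converged=False`` and diagnostics rather
    than raised.
    """
    x_days, succ, trials = _as_series(series)
    if np.unique(x_days).size < 4:
        raise ValueError("need at least four distinct dates to place a break")
    x = x_days / DAYS_PER_YEAR
    lo, hi = x.min(), x.max()
    span = hi - lo
    if init_breakpoint is None:
        psi = (lo + hi) / 2.0
    else:
        psi = float(to_days(init_breakpoint)) / DAYS_PER_YEAR
    psi = float(np.clip(psi, lo + 1e-6 * span, hi - 1e-6 * span))
    tol = tol_days / DAYS_PER_YEAR

    converged = False
    diagnostics = ""
    res = None
    n_it = 0
    damp = 1.0
    prev_step = 0.0
    for n_it in range(1, max_iter + 1):
        u = np.maximum(x - psi, 0.0)
        v = (x > psi).astype(float)
        res = _glm_fit([x, u, v], succ, trials)
        b2 = res.params[2]
        gamma = res.params[3]
        if b2 == 0 or not np.isfinite(gamma / b2):
            diagnostics = "degenerate hinge slope"
            break
        step = -gamma / b2  # first-order Taylor of the hinge in psi
        # Damp when the update reverses direction (the iteration otherwise
        # two-cycles once psi sits between adjacent observation dates).
        if step * prev_step < 0:
            damp *= 0.5
        prev_step = step
        step *= damp
        # Step-halve if the update would leave the data range.
        halvings = 0
        while not (lo < psi + step < hi) and halvings < 12:
            step /= 2.0
            halvings += 1
        if not (lo < psi + step < hi):
            diagnostics = "breakpoint escaped the data range"
            break
        psi_new = psi + step
        if abs(psi_new - psi) < tol:
            psi = psi_new
            converged = True
            break
        psi = psi_new

    if res is None:  # pragma: no cover - max_iter >= 1 always fits once
        raise RuntimeError("segmented fit did not run")
    if not converged and not diagnostics:
        diagnostics = f"no convergence in {max_iter} iterations"

    # Final linearised fit at the estimated break.  The gap coefficient is ~0
    # there, but keeping the gap column in the design propagates breakpoint
    # uncertainty into the slope standard errors; the reduced (no-gap) fit is
    # used for the deviance/AIC.
    u = np.maximum(x - psi, 0.0)
    v = (x > psi).astype(float)
    res = _glm_fit([x, u, v], succ, trials)
    se_gamma = res.bse[3]
    b2_lin = res.params[2]
    psi_se_years = float(abs(se_gamma / b2_lin)) if b2_lin != 0 else np.nan

    final = _glm_fit([x, u], succ, trials)
    b0, b1, b2f = final.params
    cov = res.cov_params()
    var_pre = cov[1, 1]
    var_post = cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]
    pre_se = float(np.sqrt(var_pre))
    post_se = float(np.sqrt(max(var_post, 0.0)))
    post_slope = b1 + b2f

    null = _glm_fit([x], succ, trials)

    psi_days = psi * DAYS_PER_YEAR
    return SegmentedFit(
        breakpoint_days=float(psi_days),
        breakpoint_date=date_of_days(psi_days),
        breakpoint_year=float(days_to_year(psi_days)),
        psi_se_days=psi_se_years * DAYS_PER_YEAR,
        psi_ci_low_year=float(days_to_year(psi_days) - _Z * psi_se_years),
        psi_ci_high_year=float(days_to_year(psi_days) + _Z * psi_se_years),
        pre_slope_per_day=float(b1) / DAYS_PER_YEAR,
        post_slope_per_day=float(post_slope) / DAYS_PER_YEAR,
        pre_annual_factor=float(np.exp(b1)),
        pre_ci_low=float(np.exp(b1 - _Z * pre_se)),
        pre_ci_high=float(np.exp(b1 + _Z * pre_se)),
        post_annual_factor=float(np.exp(post_slope)),
        post_ci_low=float(np.exp(post_slope - _Z * post_se)),
        post_ci_high=float(np.exp(post_slope + _Z * post_se)),
        aic=float(final.aic + 2.0),  # + the breakpoint parameter
        null_model_aic=float(null.aic),
        converged=converged,
        n_iterations=n_it,
        diagnostics=diagnostics,
    )


@dataclass
class EraContrast:
    """Odds ratio for a binary era split of the series."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pre: int
    n_post: int


def era_contrast(series, era_boundary) -> EraContrast:
    """Logistic model with a single era indicator (date >= boundary).

    The fitted OR equals the closed-form cross-ratio of the pooled
    per-era proportions.
    """
    x_days, succ, trials = _as_series(series)
    boundary = float(to_days(era_boundary))
    ind = (x_days >= boundary).astype(float)
    n_pre, n_post = int((ind == 0).sum()), int((ind == 1).sum())
    if n_pre == 0 or n_post == 0:
        raise ValueError("both eras need observations")
    res = _glm_fit([ind], succ, trials)
    b1, se1 = res.params[1], res.bse[1]
    return EraContrast(
        odds_ratio=float(np.exp(b1)),
        ci_low=float(np.exp(b1 - _Z * se1)),
        ci_high=float(np.exp(b1 + _Z * se1)),
        p_value=float(res.pvalues[1]),
        n_pre=n_pre,
        n_post=n_post,
    )


def rank_word_trends(records, word_list, focal_word: str | None = None):
    """Batch per-word trend fits plus the focal word's percentile rank.

    One pass over the corpus builds each word's yearly occurrence counts
    against the yearly token totals; each series is fitted with
    :func:`fit_binomial_trend`.  Words never observed in the corpus are
    dropped with a warning.  The percentile rank is the share of the *other*
    fitted words whose slope is strictly below the focal word's; exact slope
    ties are reported alongside.

    Returns ``(fits, percentile, n_ties)``; the last two are None when no
    focal word is given.
    """
    word_list = list(dict.fromkeys(word_list))
    if not word_list:
        raise ValueError("word_list must be non-empty")
    wanted = set(word_list)
    year_tokens: dict[int, int] = {}
    counts: dict[str, dict[int, int]] = {w: {} for w in word_list}
    dates_seen: dict[int, float] = {}
    for rec in records:
        y = rec.pub_date.year
        toks = rec.tokens
        if toks is None:
            raise ValueError(f"record {rec.article_id} has no token list")
        year_tokens[y] = year_tokens.get(y, 0) + len(toks)
        for t in toks:
            if t in wanted:
                c = counts[t]
                c[y] = c.get(y, 0) + 1
    years = sorted(year_tokens)
    mid_dates = [dt.date(y, 7, 1) for y in years]
    rows = []
    for w in word_list:
        total = sum(counts[w].values())
        if total == 0:
            warnings.warn(f"word {w!r} absent from corpus; dropped", stacklevel=2)
            continue
        succ = [counts[w].get(y, 0) for y in years]
        trials = [year_tokens[y] for y in years]
        fit = fit_binomial_trend((mid_dates, succ, trials))
        rows.append(
            {
                "word": w,
                "slope_per_day": fit.slope_per_day,
                "annual_odds_factor": fit.annual_odds_factor,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "n_occurrences": total,
            }
        )
    fits = pd.DataFrame(rows)
    if focal_word is None:
        return fits, None, None
    if focal_word not in set(fits["word"]):
        raise ValueError(f"focal word {focal_word!r} was not fitted")
    focal_slope = float(fits.loc[fits["word"] == focal_word, "slope_per_day"].iloc[0])
    others = fits.loc[fits["word"] != focal_word, "slope_per_day"].to_numpy()
    if others.size == 0:
        return fits, np.nan, 0
    pct = 100.0 * float((others < focal_slope).sum()) / others.size
    n_ties = int((others == focal_slope).sum())
    return fits, pct, n_ties
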