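"""Developmental trajectory modeling of the regional g-ratio index.

Each region's per-subject mean g-ratio index is modeled as a logarithmic
function of age,

    g(age) = alpha * ln(age_days) + intercept,

fit by ordinary least squares (the model is linear in its parameters after
the ln transform, so the closed-form solution is exact). Hemispheric
asymmetry is tested with the extra-sum-of-squares F-test comparing the
dual-curve model (independent left/right fits; 4 parameters) against the
single-curve model (one fit to the pooled data; 2 parameters):

    F = ((RSS_single - RSS_dual)/2) / (RSS_dual/(n_total - 4)),

referred to the F(2, n_total - 4) upper tail. The fitted curve evaluated
at 10,000 days serves as the late-childhood plateau ("asymptotic")
estimate of the g-ratio index, reported half-up-rounded to 2 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .reference import EXTRAPOLATION_AGE_DAYS

log = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (report convention), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LogCurveFit:
    """OLS fit of g on ln(age): slope alpha (per ln-day), intercept, RSS."""

    alpha: float
    intercept: float
    rss: float
    n: int

    def predict(self, age_days):
        age = np.asarray(age_days, dtype=float)
        out = self.alpha * np.log(age) + self.intercept
        return float(out) if out.ndim == 0 else out

    @property
    def equation(self) -> str:
        return f"{self.alpha:+.4g}*ln(age) {self.intercept:+.4g}".replace("+", "", 1)


class DegenerateDesignError(ValueError):
    """All ages identical: the ln(age) design matrix is rank-deficient."""


def fit_log_curve(ages, g_means) -> LogCurveFit:
    """Exact OLS of regional mean g on ln(age in days).

    Requires >= 2 points with >= 2 distinct ages; with exactly two points
    the line interpolates (RSS = 0).
    """
    ages = np.asarray(ages, dtype=float)
    g = np.asarray(g_means, dtype=float)
    if ages.shape != g.shape or ages.ndim != 1:
        raise ValueError("ages and g_means must be equal-length 1-D sequences")
    if ages.size < 2:
        raise ValueError("need at least two points to fit a line")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive (days)")
    if np.unique(ages).size < 2:
        raise DegenerateDesignError("all ages identical; slope not identifiable")
    x = np.log(ages)
    design = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(design, g, rcond=None)
    resid = g - design @ coef
    return LogCurveFit(alpha=float(coef[0]), intercept=float(coef[1]),
                       rss=float(resid @ resid), n=int(ages.size))


@dataclass(frozen=True)
class AsymptoteEstimate:
    """Fitted curve evaluated at the extrapolation age (plateau estimate)."""

    region: str
    hemisphere: str
    value: float          # unrounded prediction
    rounded: float        # half-up to 2 decimals, report convention
    extrapolation_age_days: float = EXTRAPOLATION_AGE_DAYS


def asymptote(fit: LogCurveFit, age_days: float = EXTRAPOLATION_AGE_DAYS,
              region: str = "", hemisphere: str = "") -> AsymptoteEstimate:
    """Extrapolate a fitted trajectory to ``age_days`` (default 10,000)."""
    value = fit.predict(age_days)
    return AsymptoteEstimate(region=region, hemisphere=hemisphere,
                             value=value, rounded=round_half_up(value, 2),
                             extrapolation_age_days=float(age_days))


@dataclass(frozen=True)
class HemisphericTest:
    """Extra-sum-of-squares F-test: dual- vs single-curve hemispheric model."""

    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    single_fit: LogCurveFit
    left_fit: LogCurveFit
    right_fit: LogCurveFit
    degenerate: bool = False  # dual model fits perfectly (RSS_dual = 0)


def hemispheric_f_test(left_ages, left_g, right_ages, right_g) -> HemisphericTest:
    """Test whether independent left/right trajectories are justified.

    The single-curve model pools both hemispheres' points into one OLS fit;
    the nested structure guarantees RSS_single >= RSS_left + RSS_right.
    """
    left_fit = fit_log_curve(left_ages, left_g)
    right_fit = fit_log_curve(right_ages, right_g)
    pooled_ages = np.concatenate([np.asarray(left_ages, dtype=float),
                                  np.asarray(right_ages, dtype=float)])
    pooled_g = np.concatenate([np.asarray(left_g, dtype=float),
                               np.asarray(right_g, dtype=float)])
    single_fit = fit_log_curve(pooled_ages, pooled_g)

    rss_dual = left_fit.rss + right_fit.rss
    rss_single = single_fit.rss
    n_total = left_fit.n + right_fit.n
    df_num, df_den = 2, n_total - 4
    if df_den <= 0:
        raise ValueError("need more than 4 points in total for the F-test")
    # a perfectly fitting dual model leaves only round-off residuals
    tol = 1e-14 * (1.0 + float(pooled_g @ pooled_g))
    if rss_dual <= tol:
        if rss_single > tol:
            log.warning("dual model fits perfectly; F reported as +inf")
            return HemisphericTest(np.inf, 0.0, df_num, df_den,
                                   single_fit, left_fit, right_fit,
                                   degenerate=True)
        return HemisphericTest(0.0, 1.0, df_num, df_den,
                               single_fit, left_fit, right_fit,
                               degenerate=True)
    f_stat = ((rss_single - rss_dual) / df_num) / (rss_dual / df_den)
    f_stat = max(f_stat, 0.0)  # guard tiny negative from round-off
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return HemisphericTest(float(f_stat), p_value, df_num, df_den,
                           single_fit, left_fit, right_fit)


@dataclass
class RegionTrajectories:
    """fit_all_regions output: per-region fits, tests and asymptotes."""

    fits: pd.DataFrame        # region, hemisphere, alpha, intercept, rss, n, f_stat, p_value
    asymptotes: pd.DataFrame  # region, hemisphere, asymptote, asymptote_unrounded


def fit_all_regions(table: pd.DataFrame, parameter: str = "g",
                    extrapolation_age: float = EXTRAPOLATION_AGE_DAYS) -> RegionTrajectories:
    """Fit every region in a tidy region table and test hemispheric asymmetry.

    ``table`` is the long-format regional summary (subject_id, age_days,
    region, hemisphere, parameter, mean, ...). Bilateral regions are fit
    per hemisphere and F-tested; midline regions get a single fit. Regions
    with fewer than 3 subjects are skipped with a warning.
    """
    sub = table[table["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"region table has no rows for parameter {parameter!r}")
    fit_rows, asym_rows = [], []
    for region, grp in sub.groupby("region", sort=False):
        by_hemi = {h: g for h, g in grp.groupby("hemisphere", sort=False)}
        if {"left", "right"} <= set(by_hemi):
            sides = [("left", by_hemi["left"]), ("right", by_hemi["right"])]
            if min(len(g) for _, g in sides) < 3:
                log.warning("region %s: fewer than 3 subjects per side, skipped", region)
                continue
            test = hemispheric_f_test(
                sides[0][1]["age_days"], sides[0][1]["mean"],
                sides[1][1]["age_days"], sides[1][1]["mean"])
            fits = {"left": test.left_fit, "right": test.right_fit}
            for hemi, fit in fits.items():
                fit_rows.append({"region": region, "hemisphere": hemi,
                                 "alpha": fit.alpha, "intercept": fit.intercept,
                                 "rss": fit.rss, "n": fit.n,
                                 "f_stat": test.f_stat, "p_value": test.p_value})
                est = asymptote(fit, extrapolation_age, region, hemi)
                asym_rows.append({"region": region, "hemisphere": hemi,
                                  "asymptote": est.rounded,
                                  "asymptote_unrounded": est.value})
        else:
            hemi, g = next(iter(by_hemi.items()))
            if len(g) < 3:
                log.warning("region %s: fewer than 3 subjects, skipped", region)
                continue
            fit = fit_log_curve(g["age_days"], g["mean"])
            fit_rows.append({"region": region, "hemisphere": hemi,
                             "alpha": fit.alpha, "intercept": fit.intercept,
                             "rss": fit.rss, "n": fit.n,
                             "f_stat": np.nan, "p_value": np.nan})
            est = asymptote(fit, extrapolation_age, region, hemi)
            asym_rows.append({"region": region, "hemisphere": hemi,
                              "asymptote": est.rounded,
                              "asymptote_unrounded": est.value})
    return RegionTrajectories(fits=pd.DataFrame(fit_rows),
                              asymptotes=pd.DataFrame(asym_rows))
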