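"""Age-controlled partial correlations between the g-ratio index and the
volume-fraction parameters it is computed from.

For each region, the Pearson partial correlation between the regional mean
g-ratio index and each of vfm, vff, nu_ic, nu_iso is computed while
controlling for subject age: both variables are residualized on age by
OLS and the residuals are correlated. With one controlling covariate the
statistic converts to Student's t with df = n - 3,

    t = r * sqrt(df) / sqrt(1 - r^2),

tested two-sided at p < 0.05 without multiple-comparison correction.
The partial correlation is invariant to affine rescaling of the covariate,
so age may be entered in days or years interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Parameters paired with g in the association table, in report order.
PARTNER_PARAMETERS = ("vfm", "nu_ic", "nu_iso", "vff")

_RESIDUAL_VAR_FLOOR = 1e-14


class CollinearityError(ValueError):
    """A variable is (numerically) an exact affine function of the covariate."""


@dataclass(frozen=True)
class PartialCorrelationResult:
    r_partial: float
    t_stat: float
    df: int
    p_value: float
    significant: bool
    perfect: bool = False  # |r| = 1: t reported as +/-inf, p = 0


def partial_correlation(x, y, covariate, alpha_level: float = 0.05) -> PartialCorrelationResult:
    """Pearson partial correlation of x and y controlling one covariate.

    Residualizes x and y on (1, covariate) by least squares and correlates
    the residuals. Raises :class:`CollinearityError` when either variable
    has no residual variance left.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y, covariate must be equal-length 1-D sequences")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for df = n - 3 >= 1")
    if np.unique(c).size < 2:
        raise ValueError("covariate must take at least 2 distinct values")

    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    var_x, var_y = float(rx @ rx), float(ry @ ry)
    scale_x = max(float(x @ x), 1.0)
    scale_y = max(float(y @ y), 1.0)
    if var_x <= _RESIDUAL_VAR_FLOOR * scale_x or var_y <= _RESIDUAL_VAR_FLOOR * scale_y:
        raise CollinearityError("zero residual variance after removing the covariate")

    r = float(rx @ ry / np.sqrt(var_x * var_y))
    r = min(1.0, max(-1.0, r))
    df = n - 3
    if abs(r) >= 1.0 - 1e-15:
        return PartialCorrelationResult(r_partial=float(np.sign(r)),
                                        t_stat=float(np.sign(r)) * np.inf,
                                        df=df, p_value=0.0, significant=True,
                                        perfect=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r_partial=r, t_stat=float(t), df=df,
                                    p_value=p, significant=p < alpha_level)


def partial_correlation_matrix_formula(x, y, covariate) -> float:
    """Independent closed form: r_xy.c = (r_xy - r_xc r_yc)/sqrt((1-r_xc^2)(1-r_yc^2)).

    Kept as a cross-check oracle for the residualization implementation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xc = np.corrcoef(x, c)[0, 1]
    r_yc = np.corrcoef(y, c)[0, 1]
    return float((r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc ** 2) * (1 - r_yc ** 2)))


def association_table(table: pd.DataFrame, alpha_level: float = 0.05) -> pd.DataFrame:
    """Per-region partial correlations of g with each partner parameter.

    ``table`` is the tidy regional summary; for every (region, hemisphere)
    the per-subject regional means of g are paired with those of vfm,
    nu_ic, nu_iso and vff, controlling for age. A region where g (or a
    partner) is collinear with age yields a flagged NaN row rather than
    aborting the whole table. No multiple-testing correction is applied.
    """
    required = {"g", *PARTNER_PARAMETERS}
    missing = required - set(table["parameter"].unique())
    if missing:
        raise ValueError(f"region table lacks parameter rows: {sorted(missing)}")

    wide = (table.pivot_table(index=["region", "hemisphere", "subject_id"],
                              columns="parameter", values="mean")
                 .join(table.groupby(["region", "hemisphere", "subject_id"])
                            ["age_days"].first()))
    rows = []
    for (region, hemi), grp in wide.groupby(level=["region", "hemisphere"], sort=False):
        grp = grp.sort_index(level="subject_id")
        age = grp["age_days"].to_numpy()
        g = grp["g"].to_numpy()
        for partner in PARTNER_PARAMETERS:
            base = {"region": region, "hemisphere": hemi, "parameter": partner}
            try:
                res = partial_correlation(g, grp[partner].to_numpy(), age,
                                          alpha_level=alpha_level)
            except (CollinearityError, ValueError):
                rows.append({**base, "r_partial": np.nan, "t_stat": np.nan,
                             "df": len(grp) - 3, "p_value": np.nan,
                             "significant": False, "degenerate": True})
                continue
            rows.append({**base, "r_partial": res.r_partial,
                         "t_stat": res.t_stat, "df": res.df,
                         "p_value": res.p_value,
                         "significant": res.significant,
                         "degenerate": res.perfect})
    return pd.DataFrame(rows)
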