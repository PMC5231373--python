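"""Design-of-experiments inference on stretched-exponential fit parameters.

The experimental design is a balanced full factorial: 5 droplets x 3
geometric magnitudes (area, AR, major diameter) x 2 processes
(elongation, recovery), one fitted curve per cell, 30 observations.  The
questions — does the characteristic relaxation time depend on the
droplet, the magnitude, the process? is deformation reversible? — are
answered with:

* a three-factor additive ANOVA (no interactions, residual df 22) on the
  scalar response lambda_c, with F tests;
* a MANOVA with the Pillai trace on the full (a, b, lambda_c, beta)
  response vector;
* Tukey HSD multiple comparisons between droplets (studentized-range
  distribution, residual mean square from the additive ANOVA);
* boxplot-fence outlier screening and seeded percentile-bootstrap
  confidence intervals for the mean stretching exponent and the mean
  relaxation times per process;
* a through-origin linear regression of lambda_c on droplet diameter
  (the interfacial-tension relation lambda_c = eta_eff * R0 / sigma
  predicts proportionality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FACTORS = ("magnitude", "droplet", "process")
_LEVELS = {"magnitude": 3, "droplet": 5, "process": 2}

__all__ = [
    "BootstrapCI",
    "RegressionFit",
    "validate_factor_table",
    "anova_additive",
    "manova_pillai",
    "tukey_hsd",
    "boxplot_outliers",
    "bootstrap_ci",
    "origin_regression",
    "beta_interval",
    "relaxation_time_intervals",
]


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval for one statistic."""

    statistic: str
    level: float
    lower: float
    upper: float
    n_resamples: int
    seed: int

    def overlaps(self, other: "BootstrapCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


@dataclass(frozen=True)
class RegressionFit:
    """Linear fit of lambda_c on diameter; intercept is None when dropped."""

    slope: float
    intercept: float | None
    r2: float
    intercept_p: float
    slope_ci: tuple[float, float]


def validate_factor_table(table: pd.DataFrame) -> None:
    """Require the balanced 5 x 3 x 2 full factorial (one row per cell)."""
    for f, k in _LEVELS.items():
        if f not in table.columns:
            raise ValueError(f"missing factor column {f!r}")
        if table[f].nunique() != k:
            raise ValueError(f"factor {f!r} must have {k} levels")
    counts = table.groupby(list(FACTORS), observed=True).size()
    if len(counts) != 30 or not (counts == 1).all():
        raise ValueError("unbalanced table: need exactly one observation per "
                         "cell of the 5x3x2 design")


def _additive_decomposition(
    table: pd.DataFrame, response_cols: Sequence[str]
) -> tuple[dict[str, np.ndarray], np.ndarray, dict[str, int], int]:
    """Hypothesis and residual SSCP matrices of the additive model.

    For the balanced design the factors are mutually orthogonal, so each
    hypothesis matrix is the between-levels SSCP of that factor's
    marginal means and the residual SSCP is what remains of the total.
    """
    y = table[list(response_cols)].to_numpy(dtype=float)
    n = len(table)
    grand = y.mean(axis=0)
    fitted = np.tile(grand, (n, 1))
    h_mats: dict[str, np.ndarray] = {}
    df_h: dict[str, int] = {}
    for f in FACTORS:
        h = np.zeros((y.shape[1], y.shape[1]))
        for _, idx in table.groupby(f, observed=True).indices.items():
            d = y[idx].mean(axis=0) - grand
            h += len(idx) * np.outer(d, d)
            fitted[idx] += d
        h_mats[f] = h
        df_h[f] = _LEVELS[f] - 1
    resid = y - fitted
    e_mat = resid.T @ resid
    df_e = n - 1 - sum(df_h.values())
    return h_mats, e_mat, df_h, df_e


def anova_additive(table: pd.DataFrame, response: str = "lambda_c") -> pd.DataFrame:
    """Three-factor additive ANOVA of a scalar response.

    Returns a table with rows Magnitude, Droplet, Process, Residuals and
    columns df, sum_sq, mean_sq, f_value, p_value.  F is the ratio of the
    factor mean square to the residual mean square (df 22); for the
    balanced design each factor sum of squares is the between-levels sum
    sum_l n_l * (mean_l - grand_mean)^2.
    """
    validate_factor_table(table)
    h, e, df_h, df_e = _additive_decomposition(table, [response])
    ms_e = float(e[0, 0]) / df_e
    rows = []
    for f in FACTORS:
        ss = float(h[f][0, 0])
        ms = ss / df_h[f]
        f_val = ms / ms_e if ms_e > 0 else float("nan")
        rows.append({
            "factor": f, "df": df_h[f], "sum_sq": ss, "mean_sq": ms,
            "f_value": f_val,
            "p_value": float(sps.f.sf(f_val, df_h[f], df_e)) if ms_e > 0 else float("nan"),
        })
    rows.append({
        "factor": "residual", "df": df_e, "sum_sq": float(e[0, 0]),
        "mean_sq": ms_e, "f_value": float("nan"), "p_value": float("nan"),
    })
    return pd.DataFrame(rows).set_index("factor")


def manova_pillai(
    table: pd.DataFrame,
    responses: Sequence[str] = ("a", "b", "lambda_c", "beta"),
) -> pd.DataFrame:
    """Additive MANOVA with the Pillai trace for each factor.

    For hypothesis SSCP H and residual SSCP E the Pillai statistic is
    V = trace(H (H + E)^-1); the approximate F uses the standard
    transformation with s = min(df_h, p), m = (|df_h - p| - 1)/2,
    n = (df_e - p - 1)/2:

        F = (2n + s + 1) / (2m + s + 1) * V / (s - V)

    on s(2m + s + 1) and s(2n + s + 1) degrees of freedom.  With a single
    response this reduces exactly to the univariate ANOVA F.
    """
    validate_factor_table(table)
    h_mats, e_mat, df_h, df_e = _additive_decomposition(table, responses)
    p = len(responses)
    rows = []
    for f in FACTORS:
        h = h_mats[f]
        if not np.any(h):  # no between-level variation: Pillai is exactly 0
            rows.append({
                "factor": f, "df": df_h[f], "pillai": 0.0, "approx_f": 0.0,
                "df1": float(min(df_h[f], p)), "df2": float("nan"), "p_value": 1.0,
            })
            continue
        he = h + e_mat
        cond = np.linalg.cond(he)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"singular H+E for factor {f!r} (condition number {cond:.3g})"
            )
        v = float(np.trace(h @ np.linalg.inv(he)))
        s = min(df_h[f], p)
        m = (abs(df_h[f] - p) - 1) / 2.0
        nn = (df_e - p - 1) / 2.0
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        f_val = (2 * nn + s + 1) / (2 * m + s + 1) * v / (s - v)
        rows.append({
            "factor": f, "df": df_h[f], "pillai": v, "approx_f": f_val,
            "df1": df1, "df2": df2,
            "p_value": float(sps.f.sf(f_val, df1, df2)),
        })
    return pd.DataFrame(rows).set_index("factor")


def tukey_hsd(
    table: pd.DataFrame,
    response: str = "lambda_c",
    factor: str = "droplet",
    level: float = 0.95,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons using the additive-model residual.

    For each level pair (i, j), diff = mean_j - mean_i with a
    simultaneous interval diff +- q(level; k, df_e) * sqrt(MS_e / n_group)
    and an adjusted p-value from the studentized-range distribution.  The
    residual mean square comes from :func:`anova_additive` on the same
    table, matching the published intervals' half-width.
    """
    if table[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    aov = anova_additive(table, response)
    ms_e = float(aov.loc["residual", "mean_sq"])
    df_e = int(aov.loc["residual", "df"])
    means = table.groupby(factor, observed=True)[response].mean()
    sizes = table.groupby(factor, observed=True)[response].size()
    if sizes.nunique() != 1:
        raise ValueError("groups must be balanced for Tukey HSD")
    n_group = int(sizes.iloc[0])
    k = len(means)
    se = math.sqrt(ms_e / n_group)
    q_crit = float(sps.studentized_range.ppf(level, k, df_e))
    half = q_crit * se
    levels = list(means.index)
    rows = []
    for i_idx in range(k):
        for j_idx in range(i_idx + 1, k):
            li, lj = levels[i_idx], levels[j_idx]
            diff = float(means[lj] - means[li])
            p_adj = float(sps.studentized_range.sf(abs(diff) / se, k, df_e))
            rows.append({
                "pair": f"{li}-{lj}", "diff": diff,
                "lower": diff - half, "upper": diff + half,
                "p_adj": min(p_adj, 1.0),
            })
    return pd.DataFrame(rows).set_index("pair")


def boxplot_outliers(
    values: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Flag values outside the 1.5-IQR boxplot fences.

    Quartiles use linear interpolation of order statistics at positions
    1 + (n - 1) p.  Returns (outliers, kept, (lower_fence, upper_fence)).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for boxplot fences")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iq = q3 - q1
    lo, hi = q1 - 1.5 * iq, q3 + 1.5 * iq
    out = (x < lo) | (x > hi)
    return x[out], x[~out], (float(lo), float(hi))


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    name: str = "mean",
) -> BootstrapCI:
    """Seeded percentile bootstrap confidence interval.

    ``n_resamples`` with-replacement resamples of the original size; the
    interval is the (alpha/2, 1 - alpha/2) percentile pair of the
    resampled statistic (no parametric assumption).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    if statistic is np.mean:
        boots = x[idx].mean(axis=1)
    else:
        boots = np.apply_along_axis(statistic, 1, x[idx])
    alpha = 1.0 - level
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(
        statistic=name, level=level, lower=float(lo), upper=float(hi),
        n_resamples=n_resamples, seed=seed,
    )


def origin_regression(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> RegressionFit:
    """Regress y on x, dropping the intercept when it is not significant.

    A full line is fitted first and the intercept tested against zero; if
    not significant at ``alpha`` the model is refitted through the origin
    with slope = sum(xy) / sum(x^2) (for lambda_c versus diameter this is
    the proportionality predicted by lambda_c = eta_eff * R0 / sigma).
    R^2 is centred for the full model and uncentred for the
    through-origin one.
    """
    import statsmodels.api as sm

    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length x, y with at least 3 points")
    if float(np.sum(xa**2)) == 0.0:
        raise ValueError("x is identically zero")
    full = sm.OLS(ya, sm.add_constant(xa)).fit()
    p_int = float(full.pvalues[0])
    if math.isnan(p_int):  # zero-residual degenerate fits
        p_int = 0.0 if abs(full.params[0]) > 0 else 1.0
    if p_int < alpha:
        ci = full.conf_int(alpha=0.05)[1]
        return RegressionFit(
            slope=float(full.params[1]), intercept=float(full.params[0]),
            r2=float(full.rsquared), intercept_p=p_int,
            slope_ci=(float(ci[0]), float(ci[1])),
        )
    origin = sm.OLS(ya, xa).fit()
    ci = origin.conf_int(alpha=0.05)[0]
    return RegressionFit(
        slope=float(origin.params[0]), intercept=None,
        r2=float(origin.rsquared), intercept_p=p_int,
        slope_ci=(float(ci[0]), float(ci[1])),
    )


def beta_interval(
    table: pd.DataFrame, n_resamples: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[BootstrapCI, np.ndarray]:
    """Bootstrap CI of the mean stretching exponent after outlier removal.

    Pools the 30 beta values across magnitudes and processes, removes
    boxplot-fence outliers, then bootstraps the mean.  Returns the CI and
    the flagged outliers.
    """
    out, kept, _ = boxplot_outliers(table["beta"].to_numpy())
    ci = bootstrap_ci(kept, n_resamples=n_resamples, level=level, seed=seed,
                      name="mean beta (outliers removed)")
    return ci, out


def relaxation_time_intervals(
    table: pd.DataFrame, n_resamples: int = 1000, level: float = 0.95, seed: int = 0
) -> dict[str, BootstrapCI]:
    """Per-process bootstrap CIs of the mean characteristic time.

    Overlapping elongation and recovery intervals support reversibility
    of the field-induced deformation in terms of lambda_c.
    """
    out = {}
    for i, (proc, g) in enumerate(sorted(table.groupby("process", observed=True))):
        out[proc] = bootstrap_ci(
            g["lambda_c"].to_numpy(), n_resamples=n_resamples, level=level,
            seed=seed + i, name=f"mean lambda_c ({proc})",
        )
    return out
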