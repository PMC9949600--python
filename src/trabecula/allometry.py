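"""Non-phylogenetic comparative statistics.

Log10-log10 regressions with confidence-interval-based allometry calls,
body-size proxy selection, species means, and standardized-major-axis
(SMA) equality-of-slopes tests across groups.

The allometry convention: each metric has an isometric expectation from
dimensional analysis (ratios 0; counts per length -1; lengths 1; areas
2; counts per volume -3; mass against a length 3). A fitted slope is
isometric ("0") when the expectation falls inside the 95% CI, and
positively ("+") or negatively ("-") allometric when it falls outside,
according to whether the slope sits above or below the expectation.

The whole-dataset fits are generalized least squares with independent
errors, i.e. ordinary least squares on log10 data; a correlation
structure can be supplied through ``weights`` hooks upstream (the
phylogenetic version lives in :mod:`trabecula.phylo`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSpec",
    "RegressionResult",
    "SlopeEqualityResult",
    "BUILTIN_METRICS",
    "isometric_slope",
    "fit_loglog",
    "classify_allometry",
    "select_body_size_proxy",
    "species_means",
    "sma_slope",
    "sma_common_slope_test",
]


@dataclass(frozen=True)
class MetricSpec:
    name: str
    units: str
    isometric_slope: float


BUILTIN_METRICS = {
    "bv_tv": MetricSpec("bv_tv", "fraction", 0.0),
    "gc": MetricSpec("gc", "fraction", 0.0),
    "da": MetricSpec("da", "ratio", 0.0),
    "tb_n": MetricSpec("tb_n", "1/mm", -1.0),
    "tb_th": MetricSpec("tb_th", "um", 1.0),
    "csa": MetricSpec("csa", "mm^2", 2.0),
    "conn_d": MetricSpec("conn_d", "1/mm^3", -3.0),
    "mass": MetricSpec("mass", "g", 3.0),
}


def isometric_slope(metric: str) -> float:
    """Isometric expectation for a built-in metric name."""
    return BUILTIN_METRICS[metric].isometric_slope


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    n: int
    allometry_call: str | None = None  # one of "+", "-", "0"

    def __post_init__(self):
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("slope must lie within its own confidence interval")


@dataclass(frozen=True)
class SlopeEqualityResult:
    group_slopes: dict
    common_slope: float
    lr_statistic: float
    p_value: float
    verdict: str  # "equal" | "not equal"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Log-log regression


def fit_loglog(
    x: np.ndarray, y: np.ndarray, ci_level: float = 0.95
) -> RegressionResult:
    """OLS of log10(y) on log10(x) with a t-based CI on the slope.

    Both variables must be strictly positive; the two-sided p-value
    tests slope = 0 with n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    bad = np.nonzero(~((x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)))[0]
    if len(bad):
        raise ValueError(f"nonpositive or missing values at rows {bad.tolist()}")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise ValueError("x has no variance on the log scale")
    n = len(lx)
    sxx = np.sum((lx - lx.mean()) ** 2)
    slope = np.sum((lx - lx.mean()) * (ly - ly.mean())) / sxx
    intercept = ly.mean() - slope * lx.mean()
    resid = ly - intercept - slope * lx
    df = n - 2
    sigma2 = np.sum(resid**2) / df
    se = np.sqrt(sigma2 / sxx)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
    tval = slope / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else 0.0
    syy = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if syy == 0 else 1.0 - np.sum(resid**2) / syy
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        ci_low=float(slope - tcrit * se),
        ci_high=float(slope + tcrit * se),
        p_value=float(p),
        r_squared=float(r2),
        n=n,
    )


def classify_allometry(
    result: RegressionResult | tuple[float, float, float],
    spec: MetricSpec | float,
) -> str:
    """CI-based allometry call.

    "0" when the isometric expectation lies inside [ci_low, ci_high];
    otherwise "+" when the slope exceeds the expectation and "-" when
    it falls below. Accepts either a fitted result or a raw
    (slope, ci_low, ci_high) triple, e.g. printed table values.
    """
    iso = spec.isometric_slope if isinstance(spec, MetricSpec) else float(spec)
    if isinstance(result, RegressionResult):
        slope, lo, hi = result.slope, result.ci_low, result.ci_high
    else:
        slope, lo, hi = result
    if lo <= iso <= hi:
        return "0"
    return "+" if slope > iso else "-"


# ---------------------------------------------------------------------------
# Body-size proxy selection


def select_body_size_proxy(
    measurements: pd.DataFrame,
    mass_column: str = "mass_g",
    candidate_columns: list[str] | None = None,
    position_column: str = "position",
) -> dict:
    """Pick the linear measurement (then position) that best tracks mass.

    Stage 1 regresses log mass on log measurement for every candidate
    column and keeps the highest R^2 (ties go to the first candidate in
    column order, logged). Stage 2 refits the winner within each
    vertebral position and picks the best position the same way. Rows
    with missing mass are dropped with a warning.
    """
    df = measurements
    if candidate_columns is None:
        raise ValueError("candidate_columns must list the measurement columns")
    if len(candidate_columns) < 2:
        raise ValueError("need at least two candidate measurements")
    missing = df[mass_column].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} rows with missing mass")
        df = df[~missing]
    if len(df) < 3:
        raise ValueError("need at least 3 specimens with mass")

    stage1 = {}
    for col in candidate_columns:
        stage1[col] = fit_loglog(df[col].to_numpy(), df[mass_column].to_numpy())
    best_r2 = max(r.r_squared for r in stage1.values())
    winners = [c for c in candidate_columns if stage1[c].r_squared == best_r2]
    if len(winners) > 1:
        logger.info("proxy tie between %s; keeping first in column order", winners)
    measurement = winners[0]

    stage2 = {}
    for pos, grp in df.groupby(position_column, sort=True):
        if len(grp) >= 3:
            stage2[pos] = fit_loglog(
                grp[measurement].to_numpy(), grp[mass_column].to_numpy()
            )
    best_pos_r2 = max(r.r_squared for r in stage2.values())
    pos_winners = [p for p in sorted(stage2) if stage2[p].r_squared == best_pos_r2]
    return {
        "measurement": measurement,
        "position": pos_winners[0],
        "stage1": stage1,
        "stage2": stage2,
    }


# ---------------------------------------------------------------------------
# Species means


def species_means(
    table: pd.DataFrame,
    by: tuple[str, str] = ("taxon", "position"),
    value_columns: list[str] | None = None,
    scale: str = "raw",
) -> pd.DataFrame:
    """Arithmetic species means per (species, position).

    Means are taken on the raw metric scale by default and logs are
    applied downstream (``scale="log"`` switches to mean-of-logs, i.e.
    geometric means on the raw scale; by Jensen's inequality the two
    differ on skewed data, so the choice is explicit and documented).
    Non-numeric grouping metadata that is constant within species
    (clade, ecology, size class, mass) is carried through.
    """
    if value_columns is None:
        value_columns = [
            c
            for c in table.columns
            if c not in by and pd.api.types.is_numeric_dtype(table[c])
        ]
    grouped = table.groupby(list(by), sort=True)
    if scale == "raw":
        means = grouped[value_columns].mean()
    elif scale == "log":
        means = np.power(10.0, grouped[value_columns].agg(lambda v: np.log10(v).mean()))
    else:
        raise ValueError("scale must be 'raw' or 'log'")
    meta_cols = [
        c
        for c in table.columns
        if c not in by and c not in value_columns
        and table.groupby(by[0])[c].nunique().max() == 1
    ]
    out = means.reset_index()
    if meta_cols:
        meta = table.groupby(by[0], sort=True)[meta_cols].first().reset_index()
        out = out.merge(meta, on=by[0], how="left")
    return out


# ---------------------------------------------------------------------------
# SMA equality of slopes


def sma_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized major axis slope on log data: sign(r) * sd(y)/sd(x)."""
    lx, ly = np.log10(np.asarray(x, float)), np.log10(np.asarray(y, float))
    sx, sy = lx.std(ddof=1), ly.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a group")
    r = np.corrcoef(lx, ly)[0, 1]
    return float(np.sign(r) if r != 0 else 1.0) * float(sy / sx)


def _residual_fitted_corr2(lx, ly, b):
    """Squared correlation between residual (y - b x) and fitted (y + b x) axes."""
    res = ly - b * lx
    fit = ly + b * lx
    r = np.corrcoef(res, fit)[0, 1]
    return r * r


def sma_common_slope_test(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> SlopeEqualityResult:
    """Likelihood-ratio test of a common SMA slope across groups.

    For SMA, the residual axis (y - b x) and fitted axis (y + b x) are
    uncorrelated in a group exactly when b is that group's SMA slope.
    The common slope b is estimated by minimizing
    sum_i n_i ln(1 - r_i(b)^2) over b, and the statistic
    -sum_i n_i ln(1 - r_i(b_hat)^2) is referred to chi^2 with
    (groups - 1) degrees of freedom. Identical groups give statistic 0
    and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    logged = {}
    slopes = {}
    for label, (x, y) in groups.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 observations")
        slopes[label] = sma_slope(x, y)
        logged[label] = (np.log10(x), np.log10(y))

    def lr_at(b: float) -> float:
        # -2 log Lambda: zero when every group's residual/fitted axes are
        # uncorrelated at slope b (i.e. b is each group's own SMA slope)
        return -sum(
            n * np.log(max(1.0 - _residual_fitted_corr2(lx, ly, b), 1e-300))
            for (lx, ly), n in ((v, len(v[0])) for v in logged.values())
        )

    lo = min(slopes.values())
    hi = max(slopes.values())
    span = max(hi - lo, 1e-6)
    res = optimize.minimize_scalar(
        lr_at, bounds=(lo - 0.5 * span, hi + 0.5 * span), method="bounded"
    )
    b_hat = float(res.x)
    lr = max(float(res.fun), 0.0)
    df = len(groups) - 1
    p = float(stats.chi2.sf(lr, df))
    return SlopeEqualityResult(
        group_slopes=slopes,
        common_slope=b_hat,
        lr_statistic=lr,
        p_value=p,
        verdict="equal" if p >= alpha else "not equal",
    )
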