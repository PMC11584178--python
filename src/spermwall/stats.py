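"""Statistical layer: directional binomial test and wall-covariate regressions.

Two questions are answered here. First, do sperm turn pro-wall-hook more
often than chance? — an exact one-tailed binomial test of the pro/anti
counts against p = 0.5, with a one-sided 95% Clopper–Pearson lower bound
on the pro proportion. Second, how do the kinetic parameters depend on
wall distance and wall angle? — ordinary least squares of the
log-transformed parameter on the two wall covariates (plus optional group
indicators), which is the fixed-effects reduction of the mixed models used
on real multi-animal data; synthetic data has no animal structure to pool
over, and the quantity of interest is recovery of the fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest


@dataclass(frozen=True)
class DirectionalTestResult:
    """Exact binomial test of pro-wall-hook turning against chance (p = 0.5)."""

    n_pro: int
    n_total: int
    proportion: float
    p_value: float            # one-tailed, alternative: proportion > 0.5
    ci_low: float             # one-sided Clopper–Pearson lower bound
    ci_high: float = 1.0
    conf_level: float = 0.95


def binomial_direction_test(n_pro: int, n_total: int,
                            conf: float = 0.95) -> DirectionalTestResult:
    """Exact one-tailed binomial test with a one-sided Clopper–Pearson bound.

    p-value: P(X >= n_pro | X ~ Binomial(n_total, 0.5)), computed exactly.
    ci_low: the p solving P(X >= n_pro | p) = 1 − conf (0 when n_pro = 0);
    the interval is [ci_low, 1.0].
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_pro <= n_total:
        raise ValueError(f"need 0 <= n_pro <= n_total, got {n_pro}/{n_total}")
    res = binomtest(n_pro, n_total, p=0.5, alternative="greater")
    ci = res.proportion_ci(confidence_level=conf)
    return DirectionalTestResult(
        n_pro=n_pro, n_total=n_total, proportion=n_pro / n_total,
        p_value=float(res.pvalue), ci_low=float(ci.low), ci_high=1.0,
        conf_level=conf)


@dataclass
class KineticsModelFit:
    """OLS fit of one (possibly log-transformed) kinetic parameter."""

    response: str
    transform: Literal["log", "identity"]
    coefficients: dict[str, tuple[float, float, float]]  # name -> (est, se, p)
    covariates: list[str]
    n_obs: int
    n_dropped: int = 0
    degenerate: bool = False
    _result: object = field(default=None, repr=False)

    def coef(self, name: str) -> float:
        return self.coefficients[name][0]

    def se(self, name: str) -> float:
        return self.coefficients[name][1]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, *v) for k, v in self.coefficients.items()],
            columns=["covariate", "estimate", "std_err", "p_value"],
        ).set_index("covariate")


def fit_kinetics_model(table: pd.DataFrame, response: str,
                       transform: Literal["log", "identity"] = "log",
                       covariates: Sequence[str] = ("distance_um", "angle_rad"),
                       ) -> KineticsModelFit:
    """Least-squares fit of transform(response) on covariates plus intercept.

    Rows with undefined (NaN) responses or covariates are dropped and
    counted; under the log transform, non-positive responses become
    undefined before transforming. Refuses rank-deficient designs and
    fits with fewer than 10 usable rows. A zero-variance response is fitted
    anyway but flagged ``degenerate`` (all slopes are then ~0).
    """
    missing = [c for c in (response, *covariates) if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks columns: {missing}")
    df = table[[response, *covariates]].copy()
    y = df[response].astype(float)
    if transform == "log":
        y = y.where(y > 0)  # non-positive -> undefined before the log
        y = np.log(y)
    n_before = len(df)
    df = df.assign(**{response: y}).dropna()
    n_dropped = n_before - len(df)
    if len(df) < 10:
        raise ValueError(f"only {len(df)} usable rows; need >= 10")

    X = sm.add_constant(df[list(covariates)].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient; drop collinear covariates")
    degenerate = bool(np.ptp(df[response].to_numpy()) == 0)
    result = sm.OLS(df[response], X).fit()

    coeffs = {
        name: (float(result.params[name]), float(result.bse[name]),
               float(result.pvalues[name]))
        for name in result.params.index
    }
    return KineticsModelFit(response=response, transform=transform,
                            coefficients=coeffs, covariates=list(covariates),
                            n_obs=int(result.nobs), n_dropped=n_dropped,
                            degenerate=degenerate, _result=result)


PARAM_COLUMNS = ("vcl", "vsl", "lin", "swr")


def fit_all_models(table: pd.DataFrame,
                   covariates: Sequence[str] = ("distance_um", "angle_rad"),
                   transforms: dict[str, str] | None = None,
                   ) -> dict[str, KineticsModelFit]:
    """Fit the four standard models (log VCL/VSL/LIN/SWR on the wall covariates).

    ``transforms`` overrides the per-response transform (default log for
    all four).
    """
    transforms = transforms or {}
    return {p: fit_kinetics_model(table, p, transforms.get(p, "log"), covariates)
            for p in PARAM_COLUMNS}


def compare_groups(params_table: pd.DataFrame, group_label: str) -> pd.DataFrame:
    """Per-group descriptive summary of the four kinetic parameters.

    Returns median, first/third quartile, and n per group for each of VCL,
    VSL, LIN and SWR — the boxplot summaries used for e.g. sperm-train vs
    single-sperm comparisons. Descriptive only; no hypothesis test.
    """
    if group_label not in params_table.columns:
        raise KeyError(f"unknown group label column: {group_label!r}")
    rows = []
    for group, sub in params_table.groupby(group_label, sort=True):
        for p in PARAM_COLUMNS:
            vals = sub[p].dropna().astype(float)
            if len(vals) == 0:
                med = q1 = q3 = float("nan")
            else:
                med, q1, q3 = (float(vals.median()),
                               float(vals.quantile(0.25)),
                               float(vals.quantile(0.75)))
            rows.append(dict(group=group, parameter=p, median=med,
                             q1=q1, q3=q3, iqr=q3 - q1, n=len(vals)))
    return pd.DataFrame(rows)
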