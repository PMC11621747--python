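"""Linear-Gaussian structural causal model for age, migration, conformity, diversity.

A four-variable SCM over standardized country-level measures — average age
``A``, migration rate ``M``, conformity ``C``, cultural diversity ``D`` —
with the fork structure

    A ~ Normal(0, 1)
    M ~ Normal(A * beta_AM, sigma_M)
    C ~ Normal(A * beta_AC, sigma_C)
    D ~ Normal(C * beta_CD + M * beta_MD, sigma_D)

Age confounds the M -> D effect through the backdoor path M <- A -> C -> D;
regressing D on both M and C closes it, so the partial coefficient on M
identifies the causal effect of migration on diversity. The module provides
the simulator, the adjustment regression, the causal contrast between two
migration levels, and conditional-independence checks of the DAG's testable
implications (partial correlation with a Fisher-z test).

Default path coefficients put every marginal variance at 1 so effects read
in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "SCMParams",
    "RegressionFit",
    "CausalContrast",
    "ImplicationReport",
    "simulate_scm",
    "fit_adjustment_regression",
    "causal_contrast_scm",
    "implication_check",
    "implied_covariance",
]

_COLUMNS = ("A", "M", "C", "D")


@dataclass(frozen=True)
class SCMParams:
    """Path coefficients and residual SDs of the linear SCM.

    Defaults give unit marginal variances: Var(M) = beta_AM**2 + sigma_M**2
    etc., with Cov(M, C) = beta_AM * beta_AC by path tracing.
    """

    beta_AM: float = 0.5
    beta_AC: float = 0.5
    beta_CD: float = 0.4
    beta_MD: float = -0.3
    sigma_M: float = math.sqrt(0.75)
    sigma_C: float = math.sqrt(0.75)
    sigma_D: float = math.sqrt(0.81)
    n_units: int = 30

    def __post_init__(self) -> None:
        for name in ("sigma_M", "sigma_C", "sigma_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")

    def without_age_conformity_path(self) -> "SCMParams":
        """Variant in which age does not cause conformity (M and C marginally
        independent): the structure in which no adjustment is needed."""
        return replace(self, beta_AC=0.0)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of D on (M, C) with intercept."""

    coef_M: float
    coef_C: float
    se_M: float
    se_C: float
    intercept: float
    residual_sd: float
    n: int


@dataclass(frozen=True)
class CausalContrast:
    """Expected change in D when migration is set from m0 to m1."""

    estimate: float
    se: float
    m0: float
    m1: float

    def interval(self, level: float = 0.9) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.estimate - z * self.se, self.estimate + z * self.se)


@dataclass(frozen=True)
class ImplicationReport:
    """Fisher-z test of a (conditional) independence implication."""

    x: str
    y: str
    given: tuple[str, ...]
    partial_corr: float
    statistic: float
    p_value: float
    alpha: float
    passed: bool


def simulate_scm(params: SCMParams, seed: int) -> pd.DataFrame:
    """Draw ``params.n_units`` country rows (A, M, C, D) from the SCM."""
    rng = np.random.default_rng(seed)
    n = params.n_units
    a = rng.normal(0.0, 1.0, n)
    m = a * params.beta_AM + rng.normal(0.0, params.sigma_M, n)
    c = a * params.beta_AC + rng.normal(0.0, params.sigma_C, n)
    d = c * params.beta_CD + m * params.beta_MD + rng.normal(0.0, params.sigma_D, n)
    return pd.DataFrame({"A": a, "M": m, "C": c, "D": d})


def implied_covariance(params: SCMParams) -> pd.DataFrame:
    """Population covariance of (A, M, C, D) by path tracing (closed form)."""
    bam, bac = params.beta_AM, params.beta_AC
    bcd, bmd = params.beta_CD, params.beta_MD
    v_a = 1.0
    v_m = bam**2 + params.sigma_M**2
    v_c = bac**2 + params.sigma_C**2
    c_am = bam
    c_ac = bac
    c_mc = bam * bac
    c_ad = bcd * c_ac + bmd * c_am
    c_md = bcd * c_mc + bmd * v_m
    c_cd = bcd * v_c + bmd * c_mc
    v_d = bcd**2 * v_c + bmd**2 * v_m + 2 * bcd * bmd * c_mc + params.sigma_D**2
    cov = np.array(
        [
            [v_a, c_am, c_ac, c_ad],
            [c_am, v_m, c_mc, c_md],
            [c_ac, c_mc, v_c, c_cd],
            [c_ad, c_md, c_cd, v_d],
        ]
    )
    return pd.DataFrame(cov, index=_COLUMNS, columns=_COLUMNS)


def _validate_table(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"country table missing columns {missing}")
    if data[list(_COLUMNS)].isna().any().any():
        raise ValueError("country table contains missing cells")
    return data


def fit_adjustment_regression(data: pd.DataFrame) -> RegressionFit:
    """OLS of D on (M, C) with intercept — the backdoor-adjusted model.

    Standard errors are classical (homoskedastic), matching the generative
    model's constant residual variance.
    """
    data = _validate_table(data)
    n = len(data)
    if n <= 3:
        raise ValueError("need more than 3 units to fit D ~ M + C")
    x = sm.add_constant(data[["M", "C"]].to_numpy())
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient: columns M and C (with intercept) "
            "are collinear"
        )
    res = sm.OLS(data["D"].to_numpy(), x).fit()
    resid_df = max(n - 3, 1)
    return RegressionFit(
        coef_M=float(res.params[1]),
        coef_C=float(res.params[2]),
        se_M=float(res.bse[1]),
        se_C=float(res.bse[2]),
        intercept=float(res.params[0]),
        residual_sd=float(np.sqrt(res.ssr / resid_df)),
        n=n,
    )


def causal_contrast_scm(fit: RegressionFit, m0: float, m1: float) -> CausalContrast:
    """Contrast E[D | do(M=m1)] - E[D | do(M=m0)] from the adjusted fit.

    In the additive model the contrast is (m1 - m0) * coef_M regardless of
    the level of C, so marginalizing over C leaves it unchanged; the SE is
    |m1 - m0| * se_M.
    """
    delta = m1 - m0
    return CausalContrast(
        estimate=delta * fit.coef_M, se=abs(delta) * fit.se_M, m0=m0, m1=m1
    )


def implication_check(
    data: pd.DataFrame,
    x: str,
    y: str,
    given: tuple[str, ...] | list[str] = (),
    alpha: float = 0.05,
) -> ImplicationReport:
    """Test the implication ``x _||_ y | given`` by partial correlation.

    Residualizes x and y on the conditioning set (with intercept), correlates
    the residuals, and applies the Fisher z-transform with effective sample
    size n - |given| - 3. ``passed`` means the independence is *not* rejected
    at ``alpha``.
    """
    data = _validate_table(data)
    given = tuple(given)
    if x in given or y in given:
        raise ValueError("conditioning set must not contain x or y")
    for col in (x, y, *given):
        if col not in data.columns:
            raise ValueError(f"unknown column {col!r}")
    xv = data[x].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    n = len(data)
    if given:
        z = np.column_stack([np.ones(n)] + [data[g].to_numpy(dtype=float) for g in given])
        xv = xv - z @ np.linalg.lstsq(z, xv, rcond=None)[0]
        yv = yv - z @ np.linalg.lstsq(z, yv, rcond=None)[0]
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = min(max(r, -0.9999999), 0.9999999)
    dof = n - len(given) - 3
    if dof <= 0:
        raise ValueError("too few rows for the Fisher-z test")
    zstat = math.atanh(r) * math.sqrt(dof)
    p = 2 * stats.norm.sf(abs(zstat))
    return ImplicationReport(
        x=x,
        y=y,
        given=given,
        partial_corr=r,
        statistic=zstat,
        p_value=float(p),
        alpha=alpha,
        passed=bool(p >= alpha),
    )
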