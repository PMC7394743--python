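"""Group-level statistics: risk-factor regressions, FDR, summary tests.

Each network outcome is regressed on a risk factor (determinant) with
covariate adjustment (centre, age when age is not the determinant, gender,
IQ) by ordinary least squares; slopes are reported as standardized betas
(raw slope x SD(x)/SD(y), the same convention for binary predictors).
Multiple testing is controlled with the Benjamini-Hochberg step-up
procedure; the default family is the set of outcomes tested per
determinant.  Also provided: extreme-quintile contrasts, Welch/pooled
two-sample t from printed summary statistics, and the 2x2 chi-square test
used for cohort-vs-included comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "ModelResult",
    "CollinearityError",
    "log_transform",
    "fit_model",
    "bh_fdr",
    "extreme_quintile_test",
    "summary_ttest",
    "chi2_2x2",
    "run_risk_factor_models",
    "OUTCOME_NAMES",
]

#: the five network outcome measures
OUTCOME_NAMES = ("strength", "diameter", "leaf_fraction",
                 "pcc_dlpfc_left", "pcc_dlpfc_right")

DEFAULT_ADJUSTERS = ("center", "age", "gender", "iq")


class CollinearityError(ValueError):
    """The regression design is collinear; names the aliased columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"collinear design: aliased column(s) {self.aliased}")


@dataclass(frozen=True)
class ModelSpec:
    """One regression model: outcome ~ determinants + adjusters.

    Age is dropped from the adjusters automatically when it appears among
    the determinants.  ``log_transform`` maps variable name -> offset for
    ln(value + offset) applied before fitting.
    """

    outcome: str
    determinants: tuple[str, ...]
    adjusters: tuple[str, ...] = DEFAULT_ADJUSTERS
    log_transform: dict = field(default_factory=dict)

    def effective_adjusters(self) -> tuple[str, ...]:
        return tuple(a for a in self.adjusters if a not in self.determinants)


@dataclass
class ModelResult:
    """Fitted OLS model with standardized coefficients.

    ``beta_std`` and ``p_values`` are keyed by predictor name (determinants
    and adjusters alike); F statistic tests the full model.
    """

    outcome: str
    n_obs: int
    adj_r2: float
    f_value: float
    df_model: int
    df_resid: int
    beta_std: dict
    raw_coef: dict
    p_values: dict
    fdr_p: dict = field(default_factory=dict)


def log_transform(table: pd.DataFrame, variables: dict) -> pd.DataFrame:
    """Natural-log transform the listed columns: x -> ln(x + offset).

    ``variables`` maps column name to offset.  Raises when any value + offset
    is not strictly positive.  Other columns are untouched.
    """
    out = table.copy()
    for name, offset in variables.items():
        x = out[name].to_numpy(float) + float(offset)
        if np.any(x <= 0):
            raise ValueError(
                f"log transform of '{name}': non-positive value with offset {offset}"
            )
        out[name] = np.log(x)
    return out


def normality_screen(table: pd.DataFrame, variables=None,
                     alpha: float = 0.05) -> list[str]:
    """Shapiro-Wilk screen: variables that look non-normal at ``alpha``.

    Advisory only — returns the column names whose distribution rejects
    normality, as candidates for a log transform; nothing is modified.
    """
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    flagged = []
    for name in variables:
        x = table[name].dropna().to_numpy(float)
        if x.size < 3 or np.ptp(x) == 0:
            continue
        if sps.shapiro(x).pvalue < alpha:
            flagged.append(name)
    return flagged


def _check_collinear(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # locate aliased columns via the QR diagonal
        _, R = np.linalg.qr(A)
        d = np.abs(np.diag(R))
        tol = d.max() * max(A.shape) * np.finfo(float).eps
        aliased = [X.columns[j - 1] for j in range(1, A.shape[1]) if d[j] < tol]
        raise CollinearityError(aliased or list(X.columns))


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Ordinary least squares with intercept and standardized betas.

    Complete cases only; standardized beta = raw slope x SD(predictor)/
    SD(outcome) (binary predictors included on the same convention).
    """
    predictors = list(spec.determinants) + list(spec.effective_adjusters())
    cols = [spec.outcome] + predictors
    df = data[cols].dropna()
    if spec.log_transform:
        df = log_transform(df, spec.log_transform)
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValueError(f"n={n} too small for {len(predictors)} predictors")
    X = df[predictors]
    _check_collinear(X)
    y = df[spec.outcome].to_numpy(float)
    fit = sm.OLS(y, sm.add_constant(X.to_numpy(float))).fit()
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise ValueError("outcome has zero variance")
    beta_std, raw, pvals = {}, {}, {}
    for k, name in enumerate(predictors, start=1):
        sd_x = df[name].to_numpy(float).std(ddof=1)
        raw[name] = float(fit.params[k])
        beta_std[name] = float(fit.params[k] * sd_x / sd_y)
        pvals[name] = float(fit.pvalues[k])
    return ModelResult(
        outcome=spec.outcome,
        n_obs=n,
        adj_r2=float(fit.rsquared_adj),
        f_value=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        beta_std=beta_std,
        raw_coef=raw,
        p_values=pvals,
    )


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags.

    adjusted p(i) = min_{j >= i} (m * p(j) / j) over the ascending order,
    capped at 1; rejection requires adjusted p strictly below ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < q


def extreme_quintile_test(values: np.ndarray, outcome: np.ndarray,
                          *, equal_var: bool = False):
    """Two-sample t of the outcome between lowest and highest quintiles.

    Cut points are the 20th and 80th percentiles under the
    linear-interpolation percentile rule; boundary values are assigned to
    the extreme groups inclusively (lowest: value <= P20, highest:
    value >= P80).  Welch's t by default.
    Returns (t, p, n_low, n_high).
    """
    v = np.asarray(values, float)
    y = np.asarray(outcome, float)
    if v.shape != y.shape:
        raise ValueError("values and outcome must align")
    p20, p80 = np.percentile(v, [20, 80])
    low = y[v <= p20]
    high = y[v >= p80]
    if low.size < 2 or high.size < 2:
        raise ValueError(
            f"degenerate quintiles: group sizes {low.size} and {high.size}"
        )
    if high.std(ddof=1) == 0 and low.std(ddof=1) == 0:
        if high.mean() == low.mean():
            return 0.0, 1.0, low.size, high.size
    t, p = sps.ttest_ind(high, low, equal_var=equal_var)
    return float(t), float(p), int(low.size), int(high.size)


def summary_ttest(mean_a: float, sd_a: float, n_a: int,
                  mean_b: float, sd_b: float, n_b: int,
                  *, method: str = "welch") -> tuple[float, float]:
    """Two-sample t (and two-sided p) from summary statistics.

    Welch (unequal variances, Welch-Satterthwaite df) by default; pooled
    variance with df = n_a + n_b - 2 via ``method='pooled'``.  When both
    SDs are zero and the means are equal, t is defined as 0.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be >= 2")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        if mean_a == mean_b:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if method == "welch":
        t = (mean_a - mean_b) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    elif method == "pooled":
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def chi2_2x2(counts, *, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (df = 1).

    ``correction`` enables the Yates continuity correction.  All margins
    must be positive.
    """
    tab = np.asarray(counts)
    if tab.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=correction)
    assert dof == 1
    return float(chi2), float(p)


def run_risk_factor_models(data: pd.DataFrame,
                           determinants,
                           outcomes=OUTCOME_NAMES,
                           adjusters=DEFAULT_ADJUSTERS,
                           *,
                           combined: bool = False,
                           q: float = 0.05,
                           log_vars: dict | None = None) -> pd.DataFrame:
    """Fit the per-risk-factor (or all-combined) models over all outcomes.

    ``data`` holds covariates and outcomes per subject.  In the individual
    mode one model is fitted per (determinant, outcome); in the combined
    mode all determinants enter one model per outcome.  BH-FDR is applied
    per determinant across the outcome family.  Returns a tidy frame with
    one row per (outcome, determinant).
    """
    determinants = list(determinants)
    outcomes = [o for o in outcomes if o in data.columns]
    rows = []
    if combined:
        for out in outcomes:
            spec = ModelSpec(out, tuple(determinants), tuple(adjusters),
                             log_transform=log_vars or {})
            res = fit_model(data, spec)
            for det in determinants:
                rows.append(dict(outcome=out, determinant=det, model="combined",
                                 n=res.n_obs, adj_r2=res.adj_r2,
                                 f_value=res.f_value, df_model=res.df_model,
                                 df_resid=res.df_resid,
                                 beta=res.beta_std[det], p=res.p_values[det]))
    else:
        for det in determinants:
            for out in outcomes:
                spec = ModelSpec(out, (det,), tuple(adjusters),
                                 log_transform=log_vars or {})
                res = fit_model(data, spec)
                rows.append(dict(outcome=out, determinant=det, model="individual",
                                 n=res.n_obs, adj_r2=res.adj_r2,
                                 f_value=res.f_value, df_model=res.df_model,
                                 df_resid=res.df_resid,
                                 beta=res.beta_std[det], p=res.p_values[det]))
    table = pd.DataFrame(rows)
    table["fdr_p"] = np.nan
    table["significant"] = False
    for det, grp in table.groupby("determinant"):
        adj, rej = bh_fdr(grp["p"].to_numpy(), q=q)
        table.loc[grp.index, "fdr_p"] = adj
        table.loc[grp.index, "significant"] = rej
    return table
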