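"""Multiple imputation by chained equations for baseline covariates.

Missing baseline covariates are filled by cycling per-variable prediction
models over the incomplete columns (chained equations), producing ``m``
completed copies of the cohort whose analyses are later combined with
Rubin's rules.  Continuous and ordinal covariates use predictive-mean
matching (PMM): a Bayesian linear regression on screened donor variables
ranks observed cases by predicted value and the imputation is drawn from
the ``k`` nearest observed donors, so imputed values always lie in the
observed support (integer categories stay integer, concentrations stay
positive).  Binary covariates use logistic draws.  Outcome scores are never
imputed; only observed outcome measurements are modeled.

Donor (predictor) variables for each incomplete covariate are screened by
absolute pairwise-complete correlation against a minimal threshold, with
diagnosis group always included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import LongCohort, NEVER_MISSING

__all__ = [
    "ImputationConfig",
    "select_donor_variables",
    "mice_impute",
    "pool_rubin",
    "PooledEstimate",
]


@dataclass
class ImputationConfig:
    """Settings of the chained-equation imputation."""

    m: int = 25
    n_iterations: int = 10
    donor_correlation_threshold: float = 0.05
    k_donors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.donor_correlation_threshold < 0:
            raise ValueError("correlation threshold must be >= 0")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _numeric_frame(baseline: pd.DataFrame) -> pd.DataFrame:
    """Numeric view of the baseline table; 'group' becomes a 0/1 indicator."""
    df = baseline.copy()
    if "group" in df.columns:
        codes = pd.Categorical(df["group"]).codes.astype(float)
        df["group"] = codes
    return df.astype(float)


def select_donor_variables(
    baseline: pd.DataFrame,
    target: str,
    threshold: float = 0.05,
    always_include: Sequence[str] = ("group",),
) -> list[str]:
    """Screen donor variables for imputing ``target``.

    Returns the covariates whose absolute pairwise-complete Pearson
    correlation with the target is at least ``threshold``; diagnosis group
    is always included.  Categorical columns participate through their
    numeric coding.
    """
    if target not in baseline.columns:
        raise KeyError(f"unknown covariate {target!r}")
    num = _numeric_frame(baseline)
    y = num[target]
    if y.notna().sum() == 0:
        raise ValueError(f"covariate {target!r} has no observed values; cannot impute")
    selected: list[str] = []
    for col in num.columns:
        if col == target:
            continue
        if col in always_include:
            selected.append(col)
            continue
        x = num[col]
        both = x.notna() & y.notna()
        if both.sum() < 3 or x[both].std() == 0 or y[both].std() == 0:
            continue
        r = np.corrcoef(x[both], y[both])[0, 1]
        if np.isfinite(r) and abs(r) >= threshold:
            selected.append(col)
    return selected


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw (beta*, and the LS fit) for a normal linear model."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * XtX_inv
    cov = (cov + cov.T) / 2 + 1e-10 * np.eye(p)
    beta_star = rng.multivariate_normal(beta_hat, cov, check_valid="ignore")
    return beta_hat, beta_star


def _pmm_impute_column(
    num: pd.DataFrame, target: str, donors: list[str], miss: np.ndarray,
    k: int, rng: np.random.Generator,
) -> np.ndarray:
    obs = ~miss
    X = np.column_stack([np.ones(len(num)), num[donors].to_numpy()]) if donors else np.ones((len(num), 1))
    y = num[target].to_numpy()
    beta_hat, beta_star = _bayes_linear_draw(X[obs], y[obs], rng)
    pred_obs = X[obs] @ beta_hat
    pred_mis = X[miss] @ beta_star
    y_obs = y[obs]
    out = np.empty(miss.sum())
    kk = min(k, len(y_obs))
    for j, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        cand = np.argpartition(d, kk - 1)[:kk]
        out[j] = y_obs[cand[rng.integers(0, kk)]]
    return out


def _logistic_impute_column(
    num: pd.DataFrame, target: str, donors: list[str], miss: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    import statsmodels.api as sm

    obs = ~miss
    X = np.column_stack([np.ones(len(num)), num[donors].to_numpy()]) if donors else np.ones((len(num), 1))
    y = num[target].to_numpy()
    try:
        res = sm.Logit(y[obs], X[obs]).fit(disp=0, maxiter=50)
        beta = rng.multivariate_normal(res.params, res.cov_params())
    except Exception:
        p0 = y[obs].mean()
        return (rng.uniform(size=miss.sum()) < p0).astype(float)
    eta = X[miss] @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.uniform(size=miss.sum()) < p).astype(float)


def _is_binary(series: pd.Series) -> bool:
    vals = set(series.dropna().unique())
    return vals <= {0.0, 1.0}


def mice_impute(
    cohort: LongCohort, config: ImputationConfig, rng: np.random.Generator | None = None
) -> list[LongCohort]:
    """Produce ``m`` completed copies of the cohort's baseline table.

    Observed values are never altered; only baseline covariates are imputed
    (never outcomes).  Each completed set runs ``n_iterations`` chained
    sweeps over the incomplete columns, visiting the least-missing column
    first.  Convergence is checked programmatically: the imputed-cell chain
    means must drift by less than 5% (relative) over the last 3 sweeps,
    otherwise a warning is attached to the returned sets' attrs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = cohort.baseline
    for col in ("age", "sex", "mmse_bl"):
        if col in base.columns and base[col].isna().any():
            raise ValueError(f"covariate {col!r} must be complete before imputation")
    covcols = [c for c in base.columns if c != "group"]
    n_missing = base[covcols].isna().sum()
    incomplete = [c for c in covcols if n_missing[c] > 0]
    for c in incomplete:
        if base[c].notna().sum() < 10:
            raise ValueError(
                f"covariate {c!r} has fewer than 10 observed values; exclude it instead of imputing"
            )
    if not incomplete:
        return [cohort.copy() for _ in range(config.m)]
    order = sorted(incomplete, key=lambda c: (n_missing[c], c))

    donor_lists = {
        c: select_donor_variables(base, c, config.donor_correlation_threshold)
        for c in incomplete
    }
    masks = {c: base[c].isna().to_numpy() for c in incomplete}

    completed: list[LongCohort] = []
    for _ in range(config.m):
        num = _numeric_frame(base)
        # initialize missing cells with random observed draws
        for c in incomplete:
            obs_vals = num[c].dropna().to_numpy()
            fill = obs_vals[rng.integers(0, len(obs_vals), masks[c].sum())]
            col = num[c].to_numpy()
            col[masks[c]] = fill
            num[c] = col
        trace: dict[str, list[float]] = {c: [] for c in incomplete}
        for _sweep in range(config.n_iterations):
            for c in order:
                donors = [d for d in donor_lists[c] if d != c]
                if _is_binary(base[c]):
                    imputed = _logistic_impute_column(num, c, donors, masks[c], rng)
                else:
                    imputed = _pmm_impute_column(num, c, donors, masks[c], config.k_donors, rng)
                col = num[c].to_numpy()
                col[masks[c]] = imputed
                num[c] = col
                trace[c].append(float(np.mean(imputed)))
        out = cohort.copy()
        for c in incomplete:
            out.baseline[c] = num[c].to_numpy()
        out.baseline.attrs["mice_converged"] = _chains_stable(trace)
        out.baseline.attrs["mice_donors"] = donor_lists
        completed.append(out)
    return completed


def _chains_stable(trace: dict[str, list[float]], tol: float = 0.05) -> bool:
    for c, means in trace.items():
        tail = means[-3:]
        if len(tail) < 2:
            continue
        scale = max(abs(np.mean(tail)), 1e-8)
        if (max(tail) - min(tail)) / scale > tol:
            return False
    return True


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    estimate: np.ndarray
    total_variance: np.ndarray
    within_variance: np.ndarray
    between_variance: np.ndarray
    df: np.ndarray
    names: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimate,
                "se": np.sqrt(self.total_variance),
                "total_variance": self.total_variance,
                "within_variance": self.within_variance,
                "between_variance": self.between_variance,
                "df": self.df,
            },
            index=self.names,
        )


def pool_rubin(estimates, variances, *, dfcom: float = np.inf) -> PooledEstimate:
    """Combine per-imputation estimates and squared SEs by Rubin's rules.

    ``estimates`` and ``variances`` are sequences of dicts (term -> value)
    or aligned arrays.  The pooled estimate is the mean across sets; total
    variance is the mean within-imputation variance plus ``(1 + 1/m)`` times
    the between-imputation variance; degrees of freedom follow the
    Barnard-Rubin small-sample formula when ``dfcom`` is finite, otherwise
    the classical large-sample expression.
    """
    est_df = _to_frame(estimates, "estimates")
    var_df = _to_frame(variances, "variances")
    if list(est_df.columns) != list(var_df.columns):
        raise ValueError("coefficient names differ between estimates and variances")
    m = len(est_df)
    if m < 1:
        raise ValueError("need at least one imputation set")
    qbar = est_df.mean(axis=0).to_numpy()
    w = var_df.mean(axis=0).to_numpy()
    b = est_df.var(axis=0, ddof=1).to_numpy() if m > 1 else np.zeros_like(qbar)
    t = w + (1 + 1 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * b / w
        lam = (1 + 1 / m) * b / t
        df_old = np.where(b > 0, (m - 1) * (1 + 1 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
        if np.isfinite(dfcom):
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = np.where(df_old == np.inf, df_obs, df_old * df_obs / (df_old + df_obs))
        else:
            df = df_old
    return PooledEstimate(
        estimate=qbar,
        total_variance=t,
        within_variance=w,
        between_variance=b,
        df=df,
        names=list(est_df.columns),
    )


def _to_frame(values, what: str) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        return values
    rows = list(values)
    if all(isinstance(r, dict) for r in rows):
        names = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != names:
                if set(r.keys()) != set(names):
                    raise ValueError(f"mismatched coefficient names across {what}")
        return pd.DataFrame([{k: r[k] for k in names} for r in rows], columns=names)
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
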