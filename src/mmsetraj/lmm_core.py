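"""Linear mixed-model machinery for longitudinal cognitive-decline models.

The population model is a random-intercept/random-slope linear mixed model
for a bounded cognitive score (MMSE 0-30 or RAVLT 0-75) measured repeatedly
over follow-up:

    y_ij = x_ij' beta + b0_i + b1_i * t_ij + e_ij

where the fixed design ``x_ij`` contains a cubic polynomial in centered time
t' = t - time_center, baseline covariate main effects, and covariate x t'
interactions (time-varying effects).  Random effects (b0_i, b1_i) follow a
bivariate normal with unstructured 2x2 covariance and multiply raw,
uncentered time; residuals are iid normal.

The portable artifact of model building is the :class:`CoefficientTable`:
named fixed-effect estimates plus the time-centering constant and outcome
bounds.  The published tables for the MCI and mild-dementia groups ship as
JSON fixtures and are loaded with :func:`load_published_coefficients`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TIME_TERMS",
    "ModelTerm",
    "CoefficientTable",
    "DesignBundle",
    "LMMFit",
    "RidgeGroups",
    "ConvergenceError",
    "build_design",
    "fit_reml",
    "estimate_blups",
    "fit_grouped_ridge",
    "default_ridge_groups",
    "evaluate_table",
    "load_published_coefficients",
]

#: Names of the forced cubic time-polynomial terms (centered time).
TIME_TERMS = ("t1", "t2", "t3")

_FIXTURES = {
    "MCI": "coefficients_mci_v1.json",
    "mild_dementia": "coefficients_mild_dementia_v1.json",
}


class ConvergenceError(RuntimeError):
    """REML optimization failed; ``.fit`` carries the best iterate."""

    def __init__(self, message: str, fit: "LMMFit | None" = None):
        super().__init__(message)
        self.fit = fit


@dataclass(frozen=True)
class ModelTerm:
    """One candidate predictor in the fixed-effect structure.

    Parameters
    ----------
    covariate
        Column name in the baseline covariate table (raw scale).
    transform
        ``"identity"`` or ``"log"``; a log-transformed covariate appears in
        the design under the name ``log_<covariate>``.
    role
        ``"constant"`` (main effect only), ``"time_varying"`` (main effect
        plus covariate x centered-time interaction is the candidate; the
        interaction is what makes it time varying) or ``"both"``.
    forced
        Forced terms (main effect) are never removed by backward selection.
    forced_interaction
        If True the interaction is also exempt from removal.
    """

    covariate: str
    transform: str = "identity"
    role: str = "both"
    forced: bool = False
    forced_interaction: bool = False

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.role not in ("constant", "time_varying", "both"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def main_name(self) -> str:
        return f"log_{self.covariate}" if self.transform == "log" else self.covariate

    @property
    def interaction_name(self) -> str:
        return f"{self.main_name}:t"

    def design_names(self) -> list[str]:
        names = [self.main_name]
        if self.role in ("time_varying", "both"):
            names.append(self.interaction_name)
        return names


@dataclass
class CoefficientTable:
    """Named fixed effects of a fitted trajectory model.

    ``entries`` maps term names to coefficient values.  Recognised term
    names: ``intercept``; the centered-time polynomial ``t1``/``t2``/``t3``;
    covariate main effects (e.g. ``age``, ``log_ptau``); and covariate x
    centered-time interactions written ``<main>:t``.
    """

    group: str
    entries: dict[str, float]
    se: dict[str, float] | None = None
    outcome: str = "MMSE"
    bounds: tuple[float, float] = (0.0, 30.0)
    time_center: float = 2.3
    notes: str = ""

    def __post_init__(self):
        if "intercept" not in self.entries:
            raise ValueError("CoefficientTable must contain an 'intercept' entry")
        if not np.isfinite(self.time_center):
            raise ValueError("time_center must be finite")
        for name in self.interaction_terms():
            main = name[:-2]
            if main not in self.entries:
                raise ValueError(
                    f"interaction {name!r} present without main effect {main!r}"
                )

    def interaction_terms(self) -> list[str]:
        return [n for n in self.entries if n.endswith(":t")]

    def main_terms(self) -> list[str]:
        skip = {"intercept", *TIME_TERMS}
        return [n for n in self.entries if n not in skip and not n.endswith(":t")]

    def required_covariates(self) -> list[str]:
        """Main-effect names the table needs values for (transformed scale)."""
        seen: list[str] = []
        for name in self.main_terms():
            if name not in seen:
                seen.append(name)
        for name in self.interaction_terms():
            if name[:-2] not in seen:
                seen.append(name[:-2])
        return seen

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "group": self.group,
            "outcome": self.outcome,
            "bounds": list(self.bounds),
            "time_center": self.time_center,
            "entries": dict(self.entries),
        }
        if self.se is not None:
            d["se"] = dict(self.se)
        if self.notes:
            d["notes"] = self.notes
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientTable":
        return cls(
            group=d["group"],
            entries={k: float(v) for k, v in d["entries"].items()},
            se={k: float(v) for k, v in d.get("se", {}).items()} or None,
            outcome=d.get("outcome", "MMSE"),
            bounds=tuple(d.get("bounds", (0.0, 30.0))),
            time_center=float(d.get("time_center", 2.3)),
            notes=d.get("notes", ""),
        )

    @classmethod
    def from_json(cls, path) -> "CoefficientTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_published_coefficients(group: str) -> CoefficientTable:
    """Load the published backward-selected biomarker model for a group.

    ``group`` is ``"MCI"`` or ``"mild_dementia"``.
    """
    if group not in _FIXTURES:
        raise KeyError(f"no published coefficient fixture for group {group!r}")
    ref = resources.files("mmsetraj.data") / _FIXTURES[group]
    return CoefficientTable.from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# Fixed-effect evaluation shared by the generator, evaluator and predictor
# ---------------------------------------------------------------------------

def _covariate_value(name: str, values: Mapping) -> np.ndarray:
    """Resolve a main-effect term against supplied covariate values.

    A term ``log_x`` may be satisfied either by ``log_x`` directly or by a
    raw ``x`` (log applied here, with a positivity check).
    """
    if name in values:
        return np.asarray(values[name], dtype=float)
    if name.startswith("log_") and name[4:] in values:
        raw = np.asarray(values[name[4:]], dtype=float)
        if np.any(raw <= 0):
            raise ValueError(f"cannot log-transform non-positive values of {name[4:]!r}")
        return np.log(raw)
    raise KeyError(f"missing covariate {name!r} required by the coefficient table")


def evaluate_table(
    table: CoefficientTable,
    covariates: Mapping,
    times,
) -> np.ndarray:
    """Evaluate the fixed-effect trajectory.

    ``covariates`` maps covariate names to scalars (one patient) or arrays
    aligned with ``times`` (per-observation evaluation); ``times`` is in
    years since baseline.  Interactions multiply centered time t' = t -
    time_center, the same centering as the time polynomial.  Values are
    returned unclipped.
    """
    t = np.asarray(times, dtype=float)
    tp = t - table.time_center
    e = table.entries
    const = np.asarray(e["intercept"], dtype=float)
    slope_mod = 0.0
    for name in table.main_terms():
        const = const + e[name] * _covariate_value(name, covariates)
    for name in table.interaction_terms():
        slope_mod = slope_mod + e[name] * _covariate_value(name[:-2], covariates)
    poly = (
        e.get("t1", 0.0) * tp
        + e.get("t2", 0.0) * tp**2
        + e.get("t3", 0.0) * tp**3
    )
    return const + poly + slope_mod * tp


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignBundle:
    """Aligned fixed design, random design and response for one cohort."""

    X: pd.DataFrame              # fixed design, named columns
    y: np.ndarray                # response
    groups: np.ndarray           # subject id per row
    exog_re: np.ndarray          # random design: (1, raw time)
    time: np.ndarray             # raw time in years
    time_center: float
    terms: tuple[ModelTerm, ...]
    outcome: str = "MMSE"
    bounds: tuple[float, float] = (0.0, 30.0)
    group_label: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(pd.unique(self.groups))

    def subset_columns(self, names: Sequence[str]) -> "DesignBundle":
        """Restrict the fixed design to intercept + time polynomial + names."""
        keep = ["intercept", *TIME_TERMS] + [n for n in names if n in self.X.columns]
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise KeyError(f"design has no columns {missing}")
        return DesignBundle(
            X=self.X[keep],
            y=self.y,
            groups=self.groups,
            exog_re=self.exog_re,
            time=self.time,
            time_center=self.time_center,
            terms=self.terms,
            outcome=self.outcome,
            bounds=self.bounds,
            group_label=self.group_label,
        )


def build_design(cohort, terms: Iterable[ModelTerm], time_center: float = 2.3) -> DesignBundle:
    """Assemble the fixed/random design matrices from a long cohort.

    The fixed design contains the intercept, the centered-time cubic
    (t', t'^2, t'^3), covariate main effects (log applied where requested)
    and covariate x t' interactions; the random design per subject is
    (1, raw time).  The response includes the baseline observation.
    Covariates must be complete: run imputation first.
    """
    terms = tuple(terms)
    long = cohort.long
    base = cohort.baseline
    merged = long.join(base, on="subject_id")
    merged = merged[merged["outcome"].notna()].reset_index(drop=True)

    t = merged["time_years"].to_numpy(dtype=float)
    tp = t - time_center
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones_like(t),
        "t1": tp,
        "t2": tp**2,
        "t3": tp**3,
    }
    for term in terms:
        if term.covariate not in merged.columns:
            raise KeyError(f"covariate {term.covariate!r} not in baseline table")
        x = merged[term.covariate].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(
                f"covariate {term.covariate!r} has missing values; impute before fitting"
            )
        if term.transform == "log":
            if np.any(x <= 0):
                raise ValueError(f"non-positive value under log transform of {term.covariate!r}")
            x = np.log(x)
        if term.role in ("constant", "both", "time_varying"):
            cols[term.main_name] = x
        if term.role in ("time_varying", "both"):
            cols[term.interaction_name] = x * tp
    X = pd.DataFrame(cols)
    return DesignBundle(
        X=X,
        y=merged["outcome"].to_numpy(dtype=float),
        groups=merged["subject_id"].to_numpy(),
        exog_re=np.column_stack([np.ones_like(t), t]),
        time=t,
        time_center=time_center,
        terms=terms,
        outcome=cohort.outcome,
        bounds=cohort.bounds,
        group_label=getattr(cohort, "group", ""),
    )


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """A fitted random-intercept/slope model."""

    coefficients: CoefficientTable
    coef_p: dict[str, float]
    re_cov: np.ndarray           # 2x2 covariance of (intercept, slope)
    resid_var: float
    loglik: float
    n_subjects: int
    n_obs: int
    converged: bool = True
    method: str = "reml"
    blups: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients.entries)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        q, r, piv = _qr_pivot(arr)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"singular fixed design; collinear columns: {bad}")


def _qr_pivot(arr):
    from scipy.linalg import qr

    q, r, piv = qr(arr, mode="economic", pivoting=True)
    return q, r, list(piv)


def fit_reml(bundle: DesignBundle, *, raise_on_nonconvergence: bool = True) -> LMMFit:
    """Fit the mixed model by restricted maximum likelihood.

    Variance components (unstructured 2x2 random-effect covariance plus
    residual variance) are optimized by REML; fixed effects are the GLS
    solution at the optimum, with Wald (z-based) standard errors and
    p-values.  Several optimizers are tried in sequence so the result is
    deterministic given the data; failure raises :class:`ConvergenceError`
    carrying the best iterate.
    """
    if bundle.n_subjects < 2:
        raise ValueError("need at least 2 subjects to fit a mixed model")
    _check_rank(bundle.X)
    model = sm.MixedLM(
        bundle.y,
        bundle.X.to_numpy(),
        groups=bundle.groups,
        exog_re=bundle.exog_re,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True, method=["lbfgs", "bfgs", "powell"], maxiter=200)
        names = list(bundle.X.columns)
        entries = dict(zip(names, (float(v) for v in result.fe_params)))
        se = dict(zip(names, (float(v) for v in result.bse_fe)))
        pvals = dict(zip(names, (float(v) for v in result.pvalues[: len(names)])))
    table = CoefficientTable(
        group=bundle.group_label or "fit",
        entries=entries,
        se=se,
        outcome=bundle.outcome,
        bounds=bundle.bounds,
        time_center=bundle.time_center,
    )
    try:
        blups = pd.DataFrame(
            {k: np.asarray(v, dtype=float) for k, v in result.random_effects.items()},
            index=["b0", "b1"],
        ).T
        blups.index.name = "subject_id"
    except (ValueError, np.linalg.LinAlgError):
        # boundary fit with singular random-effect covariance
        blups = None
    fit = LMMFit(
        coefficients=table,
        coef_p=pvals,
        re_cov=np.asarray(result.cov_re, dtype=float),
        resid_var=float(result.scale),
        loglik=float(result.llf),
        n_subjects=bundle.n_subjects,
        n_obs=bundle.n_obs,
        converged=bool(result.converged),
        blups=blups,
    )
    if raise_on_nonconvergence and not fit.converged:
        raise ConvergenceError("REML optimization did not converge", fit=fit)
    return fit


def estimate_blups(fit: LMMFit, subject_ids=None) -> pd.DataFrame:
    """Empirical-Bayes posterior means (b0, b1) for subjects in the fit.

    These shrink each subject's raw intercept/slope residual toward zero by
    the ratio of between- to total variability.
    """
    if fit.blups is None:
        raise ValueError("fit carries no per-subject random-effect estimates")
    if subject_ids is None:
        return fit.blups.copy()
    missing = [s for s in subject_ids if s not in fit.blups.index]
    if missing:
        raise KeyError(f"subjects not in the fitted cohort: {missing}")
    return fit.blups.loc[list(subject_ids)].copy()


# ---------------------------------------------------------------------------
# Grouped ridge
# ---------------------------------------------------------------------------

@dataclass
class RidgeGroups:
    """Term groups sharing a ridge penalty, with per-group weights.

    The four groups mirror a local-shrinkage scheme: the cubic time curve,
    the baseline outcome score, the remaining constant-effect terms, and the
    time-varying (interaction) terms.  The intercept is never penalized.
    """

    groups: dict[str, list[str]]
    lambdas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for g, names in self.groups.items():
            for n in names:
                if n in seen:
                    raise ValueError(f"term {n!r} assigned to more than one ridge group")
                seen.add(n)
        for g, lam in self.lambdas.items():
            if lam < 0:
                raise ValueError(f"negative penalty for group {g!r}")

    def group_of(self, name: str) -> str | None:
        for g, names in self.groups.items():
            if name in names:
                return g
        return None


def default_ridge_groups(column_names: Sequence[str], baseline_outcome: str = "mmse_bl") -> RidgeGroups:
    """Build the standard 4-group shrinkage layout from design columns."""
    groups: dict[str, list[str]] = {
        "time_curve": [],
        "baseline_outcome": [],
        "constant": [],
        "time_varying": [],
    }
    for n in column_names:
        if n == "intercept":
            continue
        if n in TIME_TERMS:
            groups["time_curve"].append(n)
        elif n.endswith(":t"):
            groups["time_varying"].append(n)
        elif n == baseline_outcome:
            groups["baseline_outcome"].append(n)
        else:
            groups["constant"].append(n)
    return RidgeGroups(groups={g: v for g, v in groups.items() if v})


def _marginal_precision_products(bundle: DesignBundle, re_cov: np.ndarray, resid_var: float):
    """Accumulate X'V^-1 X and X'V^-1 y per subject under the marginal model."""
    X = bundle.X.to_numpy()
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    order = pd.Series(range(len(bundle.groups))).groupby(bundle.groups, sort=False).groups
    for _, idx in order.items():
        ii = np.asarray(idx)
        Xi, yi, Zi = X[ii], bundle.y[ii], bundle.exog_re[ii]
        Vi = Zi @ re_cov @ Zi.T + resid_var * np.eye(len(ii))
        Vinv = np.linalg.inv(Vi)
        A += Xi.T @ Vinv @ Xi
        b += Xi.T @ Vinv @ yi
    return A, b


def _standardizer(X: pd.DataFrame):
    mu = X.mean().to_numpy()
    sd = X.std(ddof=0).to_numpy()
    mu[0], sd[0] = 0.0, 1.0  # intercept untouched
    sd[sd == 0] = 1.0
    return mu, sd


def _solve_penalized(A, b, mu, sd, lam_diag):
    """Penalized GLS on standardized columns, returned on the original scale.

    With column standardization x_s = (x - mu)/sd the penalized problem in
    standardized coefficients is (S A S + L) beta_s = S (b - A m) ... solved
    here by transforming A, b directly.
    """
    S = np.diag(sd)
    # original beta = S^-1 beta_s  with intercept absorbing means:
    # x' beta = x_s' beta_s + const  =>  beta_j = beta_s_j / sd_j,
    # beta_0 = beta_s_0 - sum_j beta_s_j mu_j / sd_j
    # Build the linear map M: beta = M beta_s, then solve in beta_s space:
    p = len(b)
    M = np.diag(1.0 / sd)
    M[0, :] = -mu / sd
    M[0, 0] = 1.0
    As = M.T @ A @ M
    bs = M.T @ b
    beta_s = np.linalg.solve(As + np.diag(lam_diag), bs)
    return M @ beta_s


def fit_grouped_ridge(
    bundle: DesignBundle,
    groups: RidgeGroups | None = None,
    lambdas: Mapping[str, float] | None = None,
    *,
    n_grid: int = 10,
    grid_range: tuple[float, float] = (1e-2, 1e4),
    inner_folds: int = 5,
    seed: int = 0,
    base_fit: LMMFit | None = None,
) -> LMMFit:
    """Fit fixed effects under grouped ridge shrinkage.

    Variance components come from an unpenalized REML fit; fixed effects
    solve the penalized GLS problem with penalty sum_g lambda_g ||beta_g||^2
    on internally standardized columns (estimates are returned on the
    original scale; the intercept is unpenalized).  When ``lambdas`` is not
    given, penalties are tuned by subject-level ``inner_folds``-fold
    cross-validated squared prediction error: a shared penalty is chosen on
    a log-spaced grid, then refined one group at a time.
    """
    if np.var(bundle.y) == 0:
        raise ValueError("outcome has zero variance; nothing to fit")
    if groups is None:
        groups = default_ridge_groups(bundle.X.columns)
    if base_fit is None:
        base_fit = fit_reml(bundle, raise_on_nonconvergence=False)
    re_cov, resid_var = base_fit.re_cov, base_fit.resid_var
    names = list(bundle.X.columns)
    mu, sd = _standardizer(bundle.X)
    A, b = _marginal_precision_products(bundle, re_cov, resid_var)

    def lam_diag_for(lams: Mapping[str, float]) -> np.ndarray:
        d = np.zeros(len(names))
        for j, n in enumerate(names):
            g = groups.group_of(n)
            if g is not None:
                d[j] = lams.get(g, 0.0)
        return d

    if lambdas is None:
        lambdas = _tune_lambdas(
            bundle, groups, re_cov, resid_var, mu, sd, lam_diag_for,
            n_grid=n_grid, grid_range=grid_range, inner_folds=inner_folds, seed=seed,
        )
    beta = _solve_penalized(A, b, mu, sd, lam_diag_for(lambdas))
    # approximate sandwich SEs at the chosen penalty
    M = np.diag(1.0 / sd)
    M[0, :] = -mu / sd
    M[0, 0] = 1.0
    As = M.T @ A @ M
    P = np.linalg.inv(As + np.diag(lam_diag_for(lambdas)))
    cov_s = P @ As @ P
    cov = M @ cov_s @ M.T
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    entries = dict(zip(names, map(float, beta)))
    table = CoefficientTable(
        group=bundle.group_label or "fit",
        entries=entries,
        se=dict(zip(names, map(float, se))),
        outcome=bundle.outcome,
        bounds=bundle.bounds,
        time_center=bundle.time_center,
    )
    return LMMFit(
        coefficients=table,
        coef_p={n: float("nan") for n in names},
        re_cov=re_cov,
        resid_var=resid_var,
        loglik=float("nan"),
        n_subjects=bundle.n_subjects,
        n_obs=bundle.n_obs,
        converged=base_fit.converged,
        method=f"ridge({', '.join(f'{g}={v:.3g}' for g, v in lambdas.items())})",
        blups=None,
    )


def _tune_lambdas(bundle, groups, re_cov, resid_var, mu, sd, lam_diag_for,
                  *, n_grid, grid_range, inner_folds, seed) -> dict[str, float]:
    subjects = pd.unique(bundle.groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    fold_of = {subjects[perm[i]]: i % inner_folds for i in range(len(subjects))}
    row_fold = np.array([fold_of[s] for s in bundle.groups])
    X = bundle.X.to_numpy()

    fold_products = []
    for f in range(inner_folds):
        train = row_fold != f
        sub = DesignBundle(
            X=bundle.X[train], y=bundle.y[train], groups=bundle.groups[train],
            exog_re=bundle.exog_re[train], time=bundle.time[train],
            time_center=bundle.time_center, terms=bundle.terms,
        )
        fold_products.append((_marginal_precision_products(sub, re_cov, resid_var), ~train))

    def cv_error(lams: Mapping[str, float]) -> float:
        d = lam_diag_for(lams)
        sse = 0.0
        for (A_f, b_f), test in fold_products:
            beta = _solve_penalized(A_f, b_f, mu, sd, d)
            resid = bundle.y[test] - X[test] @ beta
            sse += float(resid @ resid)
        return sse

    grid = np.geomspace(grid_range[0], grid_range[1], n_grid)
    gnames = list(groups.groups)
    # shared penalty first
    shared = [0.0, *grid]
    best_shared = min(shared, key=lambda v: cv_error({g: v for g in gnames}))
    lams = {g: best_shared for g in gnames}
    # one coordinate-refinement pass per group
    for g in gnames:
        best = min(shared, key=lambda v: cv_error({**lams, g: v}))
        lams[g] = best
    return lams
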