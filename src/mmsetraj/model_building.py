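"""Model construction: tiered candidate sets, stable backward selection,
and pooling of the final fixed-effect structure across imputed data sets.

Three nested candidate tiers reflect what information a memory clinic has
at hand:

* ``base`` -- cubic time curve, age, sex, baseline outcome score (mains and
  linear-time interactions);
* ``biomarker`` -- adds APOE e4 allele count, CSF Abeta1-42 and log pTau,
  and MRI total-brain and hippocampal volume;
* ``full`` -- adds education, depression score, systolic/diastolic blood
  pressure, BMI category and smoking history.

Backward selection iteratively drops the least significant removable term
(Wald p above the threshold), respecting hierarchy (a main effect cannot
leave while its time interaction stays) and keeping the time polynomial,
age and sex mains forced.  Across ``m`` imputed sets a term makes the final
model only if selected in at least a configured fraction of sets; the final
structure is refit on every set and pooled with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .imputation import pool_rubin
from .lmm_core import (
    TIME_TERMS,
    CoefficientTable,
    ConvergenceError,
    LMMFit,
    ModelTerm,
    build_design,
    fit_reml,
)
from .synthetic_cohort import LongCohort

__all__ = [
    "ModelTier",
    "SelectionConfig",
    "tier_terms",
    "backward_select_one",
    "stability_select",
    "stable_terms_from_counts",
    "finalize_model",
    "SelectionAudit",
]

_BASE = [
    ModelTerm("age", role="both", forced=True),
    ModelTerm("sex", role="both", forced=True),
    ModelTerm("mmse_bl", role="both"),
]
_BIOMARKER_EXTRA = [
    ModelTerm("apoe4", role="both"),
    ModelTerm("abeta42", role="both"),
    ModelTerm("ptau", transform="log", role="both"),
    ModelTerm("tbv", role="both"),
    ModelTerm("hcv", role="both"),
]
_FULL_EXTRA = [
    ModelTerm("education", role="both"),
    ModelTerm("gds", role="both"),
    ModelTerm("sbp", role="both"),
    ModelTerm("dbp", role="both"),
    ModelTerm("bmi_cat", role="both"),
    ModelTerm("smoking", role="both"),
]


@dataclass(frozen=True)
class ModelTier:
    """A named nested candidate set of model terms."""

    name: str
    terms: tuple[ModelTerm, ...]

    def __post_init__(self):
        if self.name not in ("base", "biomarker", "full", "custom"):
            raise ValueError(f"unknown tier {self.name!r}")


def tier_terms(name: str, outcome_baseline: str = "mmse_bl") -> ModelTier:
    """Build the candidate term list for a tier.

    ``outcome_baseline`` renames the baseline-score covariate (e.g.
    ``ravlt_bl`` when modeling RAVLT).
    """

    def rename(t: ModelTerm) -> ModelTerm:
        if t.covariate == "mmse_bl" and outcome_baseline != "mmse_bl":
            return ModelTerm(outcome_baseline, t.transform, t.role, t.forced, t.forced_interaction)
        return t

    if name == "base":
        terms = _BASE
    elif name == "biomarker":
        terms = _BASE + _BIOMARKER_EXTRA
    elif name == "full":
        terms = _BASE + _BIOMARKER_EXTRA + _FULL_EXTRA
    else:
        raise ValueError(f"unknown tier {name!r}")
    return ModelTier(name=name, terms=tuple(rename(t) for t in terms))


@dataclass
class SelectionConfig:
    """Backward-selection thresholds."""

    alpha: float = 0.10
    retain_fraction: float = 0.5
    time_center: float = 2.3

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must be in (0, 1]")


def _forced_names(terms: Sequence[ModelTerm]) -> set[str]:
    forced = set(TIME_TERMS) | {"intercept"}
    for t in terms:
        if t.forced:
            forced.add(t.main_name)
        if t.forced_interaction:
            forced.add(t.interaction_name)
    return forced


def _removable(name: str, current: set[str], forced: set[str]) -> bool:
    if name in forced:
        return False
    if not name.endswith(":t") and f"{name}:t" in current:
        return False  # hierarchy: main stays while its interaction remains
    return True


@dataclass
class SelectionAudit:
    """Per-set selection trace for reproducibility review."""

    per_set: list[list[str]] = field(default_factory=list)
    retention_counts: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def backward_select_one(
    cohort: LongCohort,
    tier: ModelTier,
    config: SelectionConfig | None = None,
    *,
    audit: SelectionAudit | None = None,
) -> list[str]:
    """Backward selection on one completed data set.

    Returns the surviving design-term names (covariate mains and
    interactions; the intercept and time polynomial are implicit).  At each
    step the removable term with the largest Wald p-value above ``alpha``
    leaves the model; ties break toward the lexicographically first name.  A
    refit that fails to converge keeps the term under test and is flagged.
    """
    config = config or SelectionConfig()
    bundle = build_design(cohort, tier.terms, config.time_center)
    forced = _forced_names(tier.terms)
    current = {n for n in bundle.X.columns if n not in ("intercept", *TIME_TERMS)}
    frozen: set[str] = set()

    while True:
        sub = bundle.subset_columns(sorted(current))
        try:
            fit = fit_reml(sub)
        except ConvergenceError as err:
            if err.fit is None:
                raise
            fit = err.fit
            if audit is not None:
                audit.flags.append("nonconvergent refit; selection continued on best iterate")
        cand = [
            (fit.coef_p[n], n)
            for n in current
            if n not in frozen and _removable(n, current, forced) and fit.coef_p[n] > config.alpha
        ]
        if not cand:
            break
        cand.sort(key=lambda pn: (-pn[0], pn[1]))
        _, drop = cand[0]
        trial = current - {drop}
        try:
            fit_reml(bundle.subset_columns(sorted(trial)))
        except ConvergenceError:
            frozen.add(drop)  # keep the term, flag, continue with the rest
            if audit is not None:
                audit.flags.append(f"refit without {drop!r} failed to converge; term retained")
            continue
        current = trial
    selected = sorted(current)
    if audit is not None:
        audit.per_set.append(selected)
    return selected


def stability_select(
    cohorts: Sequence[LongCohort],
    tier: ModelTier,
    config: SelectionConfig | None = None,
    *,
    audit: SelectionAudit | None = None,
) -> list[str]:
    """Stable term set across imputed data sets.

    A term enters the final model iff selected in at least
    ``retain_fraction * m`` sets; hierarchy is repaired afterwards by adding
    back any main effect whose interaction survived.
    """
    config = config or SelectionConfig()
    m = len(cohorts)
    if m < 1:
        raise ValueError("need at least one completed data set")
    audit = audit if audit is not None else SelectionAudit()
    counts: dict[str, int] = {}
    for cohort in cohorts:
        sel = backward_select_one(cohort, tier, config, audit=audit)
        for n in sel:
            counts[n] = counts.get(n, 0) + 1
    audit.retention_counts = counts
    return stable_terms_from_counts(counts, m, tier, config)


def stable_terms_from_counts(
    counts: Mapping[str, int], m: int, tier: ModelTier, config: SelectionConfig | None = None
) -> list[str]:
    """Apply the retention rule to per-term selection counts.

    A term is kept iff its count is at least ``retain_fraction * m`` (so 13
    of 25 sets keeps a term at the default half, 12 does not); forced mains
    are always kept and hierarchy is repaired.
    """
    config = config or SelectionConfig()
    final = {n for n, c in counts.items() if c >= config.retain_fraction * m}
    for t in tier.terms:
        if t.forced:
            final.add(t.main_name)
    for n in list(final):
        if n.endswith(":t"):
            final.add(n[:-2])
    return sorted(final)


def finalize_model(
    cohorts: Sequence[LongCohort],
    term_names: Sequence[str],
    tier: ModelTier,
    *,
    time_center: float = 2.3,
    group: str | None = None,
) -> tuple[CoefficientTable, LMMFit]:
    """Refit the final structure on every set and pool with Rubin's rules.

    Returns the pooled :class:`CoefficientTable` (pooled SEs included) and a
    representative :class:`LMMFit` whose random-effect covariance and
    residual variance are the across-set averages.
    """
    if not term_names:
        raise ValueError("final term set is empty")
    fits: list[LMMFit] = []
    ests, vars_ = [], []
    for cohort in cohorts:
        bundle = build_design(cohort, tier.terms, time_center).subset_columns(list(term_names))
        missing = [n for n in term_names if n not in bundle.X.columns]
        if missing:
            raise KeyError(f"terms absent from a completed set: {missing}")
        fit = fit_reml(bundle, raise_on_nonconvergence=False)
        fits.append(fit)
        ests.append(dict(fit.coefficients.entries))
        vars_.append({k: v**2 for k, v in fit.coefficients.se.items()})
    pooled = pool_rubin(ests, vars_)
    entries = dict(zip(pooled.names, map(float, pooled.estimate)))
    se = dict(zip(pooled.names, map(float, np.sqrt(pooled.total_variance))))
    ref = fits[0]
    table = CoefficientTable(
        group=group or ref.coefficients.group,
        entries=entries,
        se=se,
        outcome=ref.coefficients.outcome,
        bounds=ref.coefficients.bounds,
        time_center=time_center,
        notes=f"pooled over {len(cohorts)} imputed data sets; tier={tier.name}",
    )
    re_cov = np.mean([f.re_cov for f in fits], axis=0)
    resid = float(np.mean([f.resid_var for f in fits]))
    pooled_fit = LMMFit(
        coefficients=table,
        coef_p={n: float("nan") for n in pooled.names},
        re_cov=re_cov,
        resid_var=resid,
        loglik=float(np.mean([f.loglik for f in fits])),
        n_subjects=ref.n_subjects,
        n_obs=ref.n_obs,
        converged=all(f.converged for f in fits),
        method="pooled-reml",
        blups=ref.blups,
    )
    return table, pooled_fit
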