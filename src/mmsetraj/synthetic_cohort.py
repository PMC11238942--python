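"""Synthetic longitudinal cohorts of amyloid-positive MCI / mild dementia.

Real memory-clinic data of this kind are not openly deposited, so every
downstream stage (imputation, model fitting, selection, validation) is
exercised on generated cohorts that share the statistical structure the
analysis assumes:

* baseline covariates drawn per-group from published summary distributions
  (normal for most continuous measures, log-normal for CSF pTau, category
  probabilities for discrete measures);
* outcome trajectories following a random-intercept/slope mixed model
  around the fixed-effect curve of a :class:`~mmsetraj.lmm_core.CoefficientTable`
  (by default the published backward-selected biomarker model of the group);
* integer outcomes clipped to the instrument bounds (MMSE 0-30, RAVLT 0-75);
* annual visits with dropout and, afterwards, baseline covariate
  missingness (age, sex, baseline MMSE and diagnosis stay complete).

Covariate codings used throughout the package::

    sex       0 = female, 1 = male
    apoe4     number of APOE e4 alleles (0/1/2)
    abeta42   CSF beta-amyloid 1-42, pg/mL
    ptau      CSF phosphorylated tau, pg/mL (models use its natural log)
    tbv, hcv  MRI total-brain / hippocampal volume, mL
    bmi_cat   0: <25, 1: 25-30, 2: >30 kg/m^2
    smoking   0: never, 1: stopped, 2: current
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lmm_core import CoefficientTable, evaluate_table, load_published_coefficients

__all__ = [
    "CovariateSpec",
    "CohortConfig",
    "LongCohort",
    "ConfigError",
    "default_covariate_params",
    "default_missing_rates",
    "generate_baseline",
    "generate_trajectories",
    "apply_missingness",
    "generate_cohort",
]

#: Covariates that are never set missing (complete in the source registry).
NEVER_MISSING = ("age", "sex", "mmse_bl", "ravlt_bl", "group")


class ConfigError(ValueError):
    """A cohort configuration parameter is invalid."""


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution of one baseline covariate.

    ``kind`` is ``"normal"``, ``"lognormal"`` (mean/sd on the log scale) or
    ``"categorical"`` (``probs`` over the integer codes 0..K-1).
    """

    kind: str
    mean: float = 0.0
    sd: float = 0.0
    probs: tuple[float, ...] = ()
    clip: tuple[float, float] | None = None
    integer: bool = False

    def validate(self, name: str) -> None:
        if self.kind in ("normal", "lognormal"):
            if not np.isfinite(self.mean) or self.sd < 0:
                raise ConfigError(f"covariate {name!r}: invalid mean/sd ({self.mean}, {self.sd})")
        elif self.kind == "categorical":
            p = np.asarray(self.probs, dtype=float)
            if len(p) == 0 or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ConfigError(f"covariate {name!r}: category probabilities must be >=0 and sum to 1")
        else:
            raise ConfigError(f"covariate {name!r}: unknown distribution kind {self.kind!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            x = rng.normal(self.mean, self.sd, n)
        elif self.kind == "lognormal":
            x = np.exp(rng.normal(self.mean, self.sd, n))
        else:
            p = np.asarray(self.probs, dtype=float)
            x = rng.choice(len(p), size=n, p=p / p.sum()).astype(float)
        if self.clip is not None:
            x = np.clip(x, *self.clip)
        if self.integer:
            x = np.round(x)
        return x


def default_covariate_params(group: str) -> dict[str, CovariateSpec]:
    """Per-group baseline covariate distributions.

    Means/SDs and category frequencies follow the published baseline table
    of the study cohort (310 MCI / 651 mild dementia); pTau, which is
    right-skewed, is parameterized log-normally from its median and IQR.
    """
    if group == "MCI":
        return {
            "age": CovariateSpec("normal", 66.0, 7.0, clip=(40, 95)),
            "sex": CovariateSpec("categorical", probs=(0.455, 0.545)),
            "mmse_bl": CovariateSpec("normal", 26.5, 2.3, clip=(0, 30), integer=True),
            "apoe4": CovariateSpec("categorical", probs=(0.224, 0.468, 0.308)),
            "abeta42": CovariateSpec("normal", 789.0, 217.0, clip=(150, 2000)),
            "ptau": CovariateSpec("lognormal", 3.391, 0.432, clip=(5, 250)),
            "tbv": CovariateSpec("normal", 1102.0, 113.0, clip=(700, 1600)),
            "hcv": CovariateSpec("normal", 7.0, 0.9, clip=(3, 12)),
            "education": CovariateSpec("normal", 12.5, 3.1, clip=(6, 22), integer=True),
            "gds": CovariateSpec("normal", 3.0, 2.5, clip=(0, 15), integer=True),
            "sbp": CovariateSpec("normal", 146.0, 19.0, clip=(80, 230)),
            "dbp": CovariateSpec("normal", 84.0, 10.0, clip=(40, 140)),
            "bmi_cat": CovariateSpec("categorical", probs=(0.542, 0.400, 0.058)),
            "smoking": CovariateSpec("categorical", probs=(0.475, 0.352, 0.173)),
        }
    if group == "mild_dementia":
        return {
            "age": CovariateSpec("normal", 65.0, 7.0, clip=(40, 95)),
            "sex": CovariateSpec("categorical", probs=(0.492, 0.508)),
            "mmse_bl": CovariateSpec("normal", 22.3, 3.8, clip=(0, 30), integer=True),
            "apoe4": CovariateSpec("categorical", probs=(0.283, 0.483, 0.234)),
            "abeta42": CovariateSpec("normal", 742.0, 205.0, clip=(150, 2000)),
            "ptau": CovariateSpec("lognormal", 3.512, 0.462, clip=(5, 250)),
            "tbv": CovariateSpec("normal", 1066.0, 106.0, clip=(700, 1600)),
            "hcv": CovariateSpec("normal", 6.6, 0.9, clip=(3, 12)),
            "education": CovariateSpec("normal", 12.0, 2.9, clip=(6, 22), integer=True),
            "gds": CovariateSpec("normal", 2.7, 2.3, clip=(0, 15), integer=True),
            "sbp": CovariateSpec("normal", 148.0, 19.0, clip=(80, 230)),
            "dbp": CovariateSpec("normal", 84.0, 10.0, clip=(40, 140)),
            "bmi_cat": CovariateSpec("categorical", probs=(0.622, 0.303, 0.075)),
            "smoking": CovariateSpec("categorical", probs=(0.508, 0.346, 0.146)),
        }
    raise ConfigError(f"unknown group {group!r}")


def default_missing_rates() -> dict[str, float]:
    """Baseline missingness probabilities per covariate.

    MRI volumetry was unavailable in roughly a quarter of the study cohort
    and CSF in just under a tenth; the clinical covariates show small
    sporadic gaps.  Age, sex, baseline MMSE and diagnosis are complete.
    """
    return {
        "abeta42": 0.09,
        "ptau": 0.09,
        "tbv": 0.26,
        "hcv": 0.26,
        "apoe4": 0.03,
        "education": 0.02,
        "gds": 0.08,
        "sbp": 0.05,
        "dbp": 0.05,
        "bmi_cat": 0.06,
        "smoking": 0.04,
    }


def ravlt_generator_table(group: str) -> CoefficientTable:
    """A synthetic generating model for RAVLT Immediate Recall (0-75).

    No published coefficient table exists for the memory outcome, so this is
    a package-defined generator: decline of a few points per year steepening
    over follow-up, strong tracking of the baseline score, and a modest
    amyloid time-varying effect.  It exists to exercise the pipeline on the
    alternative outcome scale, not to reproduce any fitted model.
    """
    entries = {
        "intercept": 6.0,
        "t1": -2.4,
        "t2": -0.25,
        "t3": 0.015,
        "age": -0.02,
        "sex": 0.5,
        "ravlt_bl": 0.85,
        "abeta42": 0.001,
        "abeta42:t": 0.0012,
        "age:t": -0.01,
    }
    return CoefficientTable(
        group=group,
        entries=entries,
        outcome="RAVLT",
        bounds=(0.0, 75.0),
        time_center=2.3,
        notes="synthetic RAVLT generating model (not a fitted table)",
    )


def ravlt_cohort_config(n_subjects: int, group: str = "MCI", **kwargs) -> "CohortConfig":
    """Cohort configuration for the RAVLT outcome.

    Swaps the baseline score covariate for ``ravlt_bl`` (group-specific mean
    and SD) and uses :func:`ravlt_generator_table` as the generating model.
    """
    params = default_covariate_params(group)
    del params["mmse_bl"]
    if group == "MCI":
        params["ravlt_bl"] = CovariateSpec("normal", 30.2, 7.3, clip=(0, 75), integer=True)
    else:
        params["ravlt_bl"] = CovariateSpec("normal", 22.9, 8.1, clip=(0, 75), integer=True)
    kwargs.setdefault("re_sd_intercept", 5.0)
    kwargs.setdefault("re_sd_slope", 2.0)
    kwargs.setdefault("resid_sd", 3.5)
    return CohortConfig(
        n_subjects=n_subjects,
        group=group,
        covariate_params=params,
        true_coefficients=ravlt_generator_table(group),
        **kwargs,
    )


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_subjects: int
    group: str = "MCI"
    visit_interval_years: float = 1.0
    max_followup_years: float = 5.0
    dropout_hazard_per_year: float = 0.15
    dropout_mode: str = "mcar"            # "mcar" or "outcome" (lower score -> higher hazard)
    covariate_params: dict[str, CovariateSpec] | None = None
    true_coefficients: CoefficientTable | None = None
    re_sd_intercept: float = 2.0
    re_sd_slope: float = 1.0
    re_corr: float = -0.3
    resid_sd: float = 1.5
    missing_rates: Mapping[str, float] | None = None
    visit_jitter: float = 0.1             # uniform +/- jitter on follow-up times, years
    round_outcomes: bool = True           # integer instrument; disable for exactness tests
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.visit_interval_years <= 0 or self.max_followup_years <= 0:
            raise ConfigError("visit interval and max follow-up must be positive")
        for nm in ("re_sd_intercept", "re_sd_slope", "resid_sd"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"{nm} must be >= 0")
        if abs(self.re_corr) > 1:
            raise ConfigError("re_corr must lie in [-1, 1]")
        if not 0 <= self.dropout_hazard_per_year:
            raise ConfigError("dropout hazard must be >= 0")
        if self.dropout_mode not in ("mcar", "outcome"):
            raise ConfigError("dropout_mode must be 'mcar' or 'outcome'")
        if self.covariate_params is None:
            self.covariate_params = default_covariate_params(self.group)
        if self.true_coefficients is None:
            self.true_coefficients = load_published_coefficients(self.group)
        if self.missing_rates is None:
            self.missing_rates = default_missing_rates()
        for name, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigError(f"missing rate for {name!r} must be in [0, 1]")

    @property
    def re_cov(self) -> np.ndarray:
        c = self.re_corr * self.re_sd_intercept * self.re_sd_slope
        return np.array(
            [[self.re_sd_intercept**2, c], [c, self.re_sd_slope**2]]
        )


@dataclass
class LongCohort:
    """Long-format repeated outcomes joined to a baseline covariate table.

    ``long`` holds one row per (subject, visit): subject_id, time_years,
    outcome.  ``baseline`` is indexed by subject_id with one column per
    covariate plus ``group``.
    """

    long: pd.DataFrame
    baseline: pd.DataFrame
    outcome: str = "MMSE"
    bounds: tuple[float, float] = (0.0, 30.0)
    group: str = ""

    def validate(self) -> "LongCohort":
        req = {"subject_id", "time_years", "outcome"}
        if not req <= set(self.long.columns):
            raise ValueError(f"long table missing columns {sorted(req - set(self.long.columns))}")
        if (self.long["time_years"] < 0).any():
            raise ValueError("negative visit times")
        extra = set(self.long["subject_id"]) - set(self.baseline.index)
        if extra:
            raise ValueError(f"subjects in long table absent from baseline table: {sorted(extra)[:5]}")
        g = self.long.groupby("subject_id")["time_years"]
        if not np.allclose(g.min(), 0.0):
            raise ValueError("every subject needs a baseline (time 0) observation")
        if (g.apply(lambda s: s.is_monotonic_increasing and s.is_unique) == False).any():  # noqa: E712
            raise ValueError("visit times must be strictly increasing within subject")
        obs = self.long["outcome"].dropna()
        lo, hi = self.bounds
        if ((obs < lo) | (obs > hi)).any():
            bad = self.long.index[(self.long["outcome"] < lo) | (self.long["outcome"] > hi)][0]
            raise ValueError(f"outcome outside bounds {self.bounds} at long-table row {bad}")
        return self

    @property
    def n_subjects(self) -> int:
        return len(self.baseline)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.baseline.index.to_numpy()

    def copy(self) -> "LongCohort":
        return LongCohort(
            long=self.long.copy(),
            baseline=self.baseline.copy(),
            outcome=self.outcome,
            bounds=self.bounds,
            group=self.group,
        )

    def subset(self, subject_ids) -> "LongCohort":
        ids = list(subject_ids)
        return LongCohort(
            long=self.long[self.long["subject_id"].isin(ids)].reset_index(drop=True),
            baseline=self.baseline.loc[ids],
            outcome=self.outcome,
            bounds=self.bounds,
            group=self.group,
        )

    # -- CSV interchange -------------------------------------------------
    def write(self, directory) -> tuple[Path, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        long_path = d / "cohort_long.csv"
        base_path = d / "cohort_baseline.csv"
        self.long.to_csv(long_path, index=False)
        self.baseline.to_csv(base_path, index=True, index_label="subject_id")
        return long_path, base_path


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_baseline(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the baseline covariate table: one row per subject."""
    n = config.n_subjects
    for name, spec in config.covariate_params.items():
        spec.validate(name)
    ids = [f"s{i:05d}" for i in range(n)]
    data = {"group": [config.group] * n}
    for name, spec in config.covariate_params.items():
        data[name] = spec.draw(n, rng)
    df = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
    return df


def _check_generator_schema(table: CoefficientTable, baseline: pd.DataFrame) -> None:
    cols = set(baseline.columns)
    for name in table.required_covariates():
        if name in cols:
            continue
        if name.startswith("log_") and name[4:] in cols:
            continue
        raise KeyError(
            f"true coefficient table references covariate {name!r} absent from the baseline table"
        )


def generate_trajectories(
    baseline: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> LongCohort:
    """Simulate visit schedules and outcome series for each subject.

    Per subject, (b0, b1) is drawn from the configured bivariate normal and
    the observed score at raw time t is the fixed-effect prediction of the
    true coefficient table plus b0 + b1*t plus residual noise, rounded to an
    integer and clipped to the outcome bounds.  Visits run on the configured
    schedule (small uniform time jitter after baseline) until dropout or the
    maximum follow-up.
    """
    table = config.true_coefficients
    _check_generator_schema(table, baseline)
    lo, hi = table.bounds
    n = len(baseline)
    b = rng.multivariate_normal([0.0, 0.0], config.re_cov, size=n) if n else np.zeros((0, 2))

    interval = config.visit_interval_years
    n_follow = int(np.floor(config.max_followup_years / interval + 1e-9))
    surv_mcar = float(np.exp(-config.dropout_hazard_per_year * interval))

    rows_id, rows_t, rows_y = [], [], []
    cov_rows = baseline.to_dict("index")
    ref_score = (
        float(np.nanmean(baseline["mmse_bl"])) if "mmse_bl" in baseline.columns else (lo + hi) / 2
    )
    for i, sid in enumerate(baseline.index):
        cov = cov_rows[sid]
        times = [0.0]
        for k in range(1, n_follow + 1):
            t = k * interval
            if config.visit_jitter > 0:
                t = t + rng.uniform(-config.visit_jitter, config.visit_jitter)
                t = max(t, times[-1] + 1e-3)
            times.append(t)
        times = np.asarray(times)
        mean = evaluate_table(table, cov, times) + b[i, 0] + b[i, 1] * times
        noise = rng.normal(0.0, config.resid_sd, len(times)) if config.resid_sd > 0 else 0.0
        y = mean + noise
        if config.round_outcomes:
            y = np.round(y)
        y = np.clip(y, lo, hi)
        # dropout: walk the schedule, flip a survival coin before each follow-up
        kept = 1
        for k in range(1, len(times)):
            surv = surv_mcar
            if config.dropout_mode == "outcome":
                # lower current score accelerates dropout
                surv = float(np.exp(-config.dropout_hazard_per_year * interval
                                    * np.exp(0.08 * (ref_score - y[k - 1]))))
            if rng.uniform() > surv:
                break
            kept += 1
        rows_id.extend([sid] * kept)
        rows_t.extend(times[:kept])
        rows_y.extend(y[:kept])

    long = pd.DataFrame(
        {"subject_id": rows_id, "time_years": rows_t, "outcome": np.asarray(rows_y, dtype=float)}
    )
    return LongCohort(
        long=long,
        baseline=baseline,
        outcome=table.outcome,
        bounds=table.bounds,
        group=config.group,
    ).validate()


def apply_missingness(cohort: LongCohort, config: CohortConfig, rng: np.random.Generator) -> LongCohort:
    """Independently blank baseline covariate values at the configured rates.

    Age, sex, baseline outcome score and diagnosis group are never blanked.
    """
    out = cohort.copy()
    n = len(out.baseline)
    for name, rate in config.missing_rates.items():
        if name in NEVER_MISSING or name not in out.baseline.columns or rate == 0:
            continue
        mask = rng.uniform(size=n) < rate
        col = out.baseline[name].astype(float)
        col[mask] = np.nan
        out.baseline[name] = col
    return out


def generate_cohort(config: CohortConfig, *, with_missingness: bool = True) -> LongCohort:
    """Full generation pass: baseline, trajectories, optional missingness.

    Deterministic given ``config`` (all randomness flows from ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    baseline = generate_baseline(config, rng)
    cohort = generate_trajectories(baseline, config, rng)
    if with_missingness:
        cohort = apply_missingness(cohort, config, rng)
    return cohort
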