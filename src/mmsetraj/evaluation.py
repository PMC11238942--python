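"""Out-of-sample evaluation of trajectory models.

Internal validation is subject-level k-fold cross-validation: subjects (not
observations) are partitioned, the chosen model-building method (no
penalization, backward selection, or grouped ridge) is trained on k-1
folds, and held-out subjects are predicted from fixed effects only -- their
random effects are unknowable without peeking at their outcomes.  Reported
metrics are root mean squared error, median absolute deviation of the
prediction errors, and out-of-sample R^2 = 1 - SSE/SST with SST taken
around the held-out outcome mean (so R^2 can be negative).  External
validation applies a frozen coefficient table to a new cohort with the same
metric definitions and no refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm_core import CoefficientTable, build_design, evaluate_table, fit_grouped_ridge, fit_reml
from .model_building import ModelTier, SelectionConfig, backward_select_one, finalize_model
from .synthetic_cohort import LongCohort

__all__ = ["EvalMetrics", "kfold_cv", "external_validate", "predict_cohort"]


@dataclass
class EvalMetrics:
    """Out-of-sample error summary (mean over folds plus fold ranges)."""

    rmse: float
    mad: float
    r2: float
    n_parameters: float
    per_fold: dict[str, list[float]] = field(default_factory=dict)

    def fold_range(self, metric: str) -> tuple[float, float]:
        vals = self.per_fold[metric]
        return (min(vals), max(vals))

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mad": self.mad,
            "r2": self.r2,
            "n_parameters": self.n_parameters,
            "per_fold": self.per_fold,
        }


def predict_cohort(table: CoefficientTable, cohort: LongCohort) -> np.ndarray:
    """Fixed-effect predictions for every observed row of a long cohort."""
    merged = cohort.long.join(cohort.baseline, on="subject_id")
    missing = [
        c for c in table.required_covariates()
        if c not in merged.columns and not (c.startswith("log_") and c[4:] in merged.columns)
    ]
    if missing:
        raise KeyError(f"cohort is missing covariate columns required by the model: {missing}")
    skip = {"group", "subject_id", "time_years", "outcome"}
    cov = {
        c: merged[c].to_numpy(dtype=float)
        for c in cohort.baseline.columns
        if c not in skip
    }
    return evaluate_table(table, cov, merged["time_years"].to_numpy(dtype=float))


def _metrics(observed: np.ndarray, predicted: np.ndarray, sst_mean: float | None = None) -> dict:
    err = observed - predicted
    center = np.mean(observed) if sst_mean is None else sst_mean
    sst = float(np.sum((observed - center) ** 2))
    sse = float(np.sum(err**2))
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mad": float(np.median(np.abs(err))),
        "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
    }


def kfold_cv(
    cohort: LongCohort,
    tier: ModelTier,
    method: str = "backward",
    *,
    k: int = 5,
    seed: int = 0,
    selection: SelectionConfig | None = None,
    time_center: float = 2.3,
    followup_only: bool = False,
    sst_reference: str = "test",
) -> EvalMetrics:
    """Subject-level k-fold cross-validation of one model-building method.

    ``method`` is ``"none"`` (fit the full tier), ``"backward"`` (backward
    selection per training split) or ``"ridge"`` (grouped ridge with
    penalties tuned inside the training split).  ``followup_only`` drops the
    baseline observation from scoring; ``sst_reference`` is ``"test"``
    (default) or ``"train"`` for the mean used in SST.
    """
    if method not in ("none", "backward", "ridge"):
        raise ValueError(f"unknown method {method!r}")
    subjects = cohort.subject_ids
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(subjects)})")
    selection = selection or SelectionConfig(time_center=time_center)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    fold_of = np.empty(len(subjects), dtype=int)
    fold_of[order] = np.arange(len(subjects)) % k

    per_fold: dict[str, list[float]] = {"rmse": [], "mad": [], "r2": [], "n_parameters": []}
    for f in range(k):
        train_ids = subjects[fold_of != f]
        test_ids = subjects[fold_of == f]
        train = cohort.subset(train_ids)
        test = cohort.subset(test_ids)
        if method == "backward":
            sel = backward_select_one(train, tier, selection)
            table, _ = finalize_model([train], sel, tier, time_center=time_center)
        elif method == "ridge":
            bundle = build_design(train, tier.terms, time_center)
            fit = fit_grouped_ridge(bundle, seed=seed)
            table = fit.coefficients
        else:
            bundle = build_design(train, tier.terms, time_center)
            table = fit_reml(bundle, raise_on_nonconvergence=False).coefficients
        pred = predict_cohort(table, test)
        mask = test.long["outcome"].notna().to_numpy()
        if followup_only:
            mask &= test.long["time_years"].to_numpy() > 0
        obs = test.long["outcome"].to_numpy(dtype=float)[mask]
        prd = pred[mask]
        sst_mean = None
        if sst_reference == "train":
            sst_mean = float(train.long["outcome"].dropna().mean())
        m = _metrics(obs, prd, sst_mean)
        for key in ("rmse", "mad", "r2"):
            per_fold[key].append(m[key])
        per_fold["n_parameters"].append(len(table.entries))
    return EvalMetrics(
        rmse=float(np.mean(per_fold["rmse"])),
        mad=float(np.mean(per_fold["mad"])),
        r2=float(np.mean(per_fold["r2"])),
        n_parameters=float(np.mean(per_fold["n_parameters"])),
        per_fold=per_fold,
    )


def external_validate(table: CoefficientTable, cohort: LongCohort, *, followup_only: bool = False) -> EvalMetrics:
    """Apply a frozen coefficient table to an external cohort.

    Fixed-effect predictions only, no refitting; same metric definitions as
    internal cross-validation, computed over all observed rows.
    """
    pred = predict_cohort(table, cohort)
    mask = cohort.long["outcome"].notna().to_numpy()
    if followup_only:
        mask &= cohort.long["time_years"].to_numpy() > 0
    obs = cohort.long["outcome"].to_numpy(dtype=float)[mask]
    m = _metrics(obs, pred[mask])
    return EvalMetrics(
        rmse=m["rmse"],
        mad=m["mad"],
        r2=m["r2"],
        n_parameters=len(table.entries),
        per_fold={"rmse": [m["rmse"]], "mad": [m["mad"]], "r2": [m["r2"]],
                  "n_parameters": [float(len(table.entries))]},
    )
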