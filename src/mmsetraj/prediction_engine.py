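"""Individualized prognosis from a fitted coefficient table.

Given a patient's baseline profile and a :class:`~mmsetraj.lmm_core.CoefficientTable`
this module computes:

* the fixed-effect ("natural") trajectory of the cognitive score over time,
* hypothetical treatment overlays -- a proportional reduction of decline,
  modeled by default as *time dilation* (the treated patient traverses the
  natural trajectory at (1-r) times the speed), alternatively as direct
  scaling of the decline from baseline,
* the time to reach a threshold score (e.g. MMSE 20 marking progression
  from MCI to dementia, 15 marking moderate dementia),
* uncertainty bands around the individual prediction by sampling the
  random-effect distribution, and the percentile a (treated) trajectory
  occupies within that natural variation,
* population percentile fans from per-subject empirical-Bayes predictions.

Predicted values are reported unclipped; values outside the instrument
bounds are flagged so a renderer can omit them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lmm_core import CoefficientTable, LMMFit, estimate_blups, evaluate_table

__all__ = [
    "PatientProfile",
    "TreatmentSpec",
    "TrajectoryResult",
    "BandResult",
    "predict_mean",
    "trajectory_function",
    "apply_treatment",
    "time_to_threshold",
    "simulate_individual_band",
    "population_fan",
    "NOT_REACHED",
]

#: Sentinel returned by :func:`time_to_threshold` when the trajectory never
#: crosses the threshold before the horizon.
NOT_REACHED = math.inf

#: Extrapolation warning boundary: the source data cover roughly 5 years of
#: follow-up; predictions beyond are extrapolations.
DATA_RANGE_YEARS = 5.0


@dataclass
class PatientProfile:
    """One individual's predictor values on the instrument scale.

    ``values`` may carry raw ``ptau`` (pg/mL) or ``log_ptau`` directly; the
    log transform is applied automatically when a table requires it, and the
    conversion is recorded in ``audit``.
    """

    group: str
    values: dict[str, float]
    audit: list[str] = field(default_factory=list)

    def __post_init__(self):
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for {k!r}")
        if "mmse_bl" in self.values and not 0 <= self.values["mmse_bl"] <= 30:
            raise ValueError("baseline MMSE must lie in [0, 30]")

    def resolved_for(self, table: CoefficientTable) -> dict[str, float]:
        """Values keyed by the table's main-term names, transforms applied."""
        out: dict[str, float] = {}
        for name in table.required_covariates():
            if name in self.values:
                out[name] = float(self.values[name])
            elif name.startswith("log_") and name[4:] in self.values:
                raw = float(self.values[name[4:]])
                if raw <= 0:
                    raise ValueError(f"cannot log-transform non-positive {name[4:]!r}")
                out[name] = math.log(raw)
                note = f"{name[4:]} supplied untransformed; applied natural log"
                if note not in self.audit:
                    self.audit.append(note)
            else:
                raise KeyError(f"patient profile is missing covariate {name!r}")
        return out


@dataclass(frozen=True)
class TreatmentSpec:
    """A hypothetical intervention reducing decline by fraction ``r``.

    ``mechanism`` is ``"time_dilation"`` (treated(t) = natural((1-r) t)) or
    ``"decline_scaling"`` (treated(t) = natural(0) - (1-r) * (natural(0) -
    natural(t))).  Both coincide with the natural trajectory at r=0 and at
    t=0; for a linear natural decline they are identical.
    """

    reduction: float
    mechanism: str = "time_dilation"

    def __post_init__(self):
        if not 0 <= self.reduction < 1:
            raise ValueError("reduction must lie in [0, 1)")
        if self.mechanism not in ("time_dilation", "decline_scaling"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass
class TrajectoryResult:
    """Predicted values over a time grid, with out-of-bounds flags."""

    times: np.ndarray
    values: np.ndarray
    bounds: tuple[float, float]
    clipped: np.ndarray = None  # True where the raw value leaves the bounds
    extrapolated: np.ndarray = None  # True beyond the source data range

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-negative and non-decreasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite predicted values")
        lo, hi = self.bounds
        if self.clipped is None:
            self.clipped = (self.values < lo) | (self.values > hi)
        if self.extrapolated is None:
            self.extrapolated = self.times > DATA_RANGE_YEARS

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_years": self.times,
                "predicted": self.values,
                "out_of_bounds": self.clipped,
                "extrapolated": self.extrapolated,
            }
        )


def trajectory_function(table: CoefficientTable, patient: PatientProfile) -> Callable:
    """Natural fixed-effect trajectory as a function of years since baseline."""
    cov = patient.resolved_for(table)

    def natural(t):
        return evaluate_table(table, cov, t)

    return natural


def apply_treatment(natural: Callable, treatment: TreatmentSpec) -> Callable:
    """Overlay a proportional decline-reduction on a trajectory function."""
    r = treatment.reduction
    if treatment.mechanism == "time_dilation":
        def treated(t):
            return natural((1.0 - r) * np.asarray(t, dtype=float))
    else:
        def treated(t):
            t = np.asarray(t, dtype=float)
            y0 = natural(np.zeros_like(t))
            return y0 - (1.0 - r) * (y0 - natural(t))
    return treated


def predict_mean(
    table: CoefficientTable,
    patient: PatientProfile,
    times,
    treatment: TreatmentSpec | None = None,
) -> TrajectoryResult:
    """Fixed-effect trajectory at the requested times (unclipped values)."""
    fn = trajectory_function(table, patient)
    if treatment is not None:
        fn = apply_treatment(fn, treatment)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    return TrajectoryResult(times=t, values=fn(t), bounds=table.bounds)


def time_to_threshold(
    table: CoefficientTable,
    patient: PatientProfile,
    threshold: float,
    treatment: TreatmentSpec | None = None,
    *,
    horizon: float = 20.0,
    tol: float = 1e-4,
) -> float:
    """Years until the predicted trajectory first reaches ``threshold``.

    The first crossing of the (treated) fixed-effect trajectory in
    (0, horizon] is bracketed on a dense grid and refined by root-finding to
    ``tol`` years; :data:`NOT_REACHED` (infinity) is returned when there is
    no crossing before the horizon.  Under time dilation the treated
    crossing time is computed exactly as untreated_time / (1 - r).
    """
    natural = trajectory_function(table, patient)
    if float(natural(0.0)) <= threshold:
        raise ValueError("threshold exceeded at baseline: predicted score at t=0 is already at or below it")
    if treatment is not None and treatment.mechanism == "time_dilation":
        t0 = _first_crossing(natural, threshold, horizon * (1.0 - treatment.reduction), tol)
        return t0 / (1.0 - treatment.reduction) if np.isfinite(t0) else NOT_REACHED
    fn = natural if treatment is None else apply_treatment(natural, treatment)
    return _first_crossing(fn, threshold, horizon, tol)


def _first_crossing(fn: Callable, threshold: float, horizon: float, tol: float) -> float:
    grid = np.linspace(0.0, horizon, max(int(horizon / 0.02), 64) + 1)
    vals = np.asarray(fn(grid), dtype=float) - threshold
    below = np.nonzero(vals <= 0)[0]
    if len(below) == 0:
        return NOT_REACHED
    j = below[0]
    if j == 0:
        return 0.0
    root = brentq(lambda t: float(fn(t)) - threshold, grid[j - 1], grid[j], xtol=tol)
    return float(root)


@dataclass
class BandResult:
    """Pointwise percentile band from random-effect simulation."""

    times: np.ndarray
    mean: np.ndarray
    samples: np.ndarray  # shape (n, len(times)), unclipped
    bounds: tuple[float, float]

    def percentile(self, q) -> np.ndarray:
        return np.percentile(self.samples, q, axis=0)

    def percentile_of(self, values, at_index: int | None = None) -> np.ndarray:
        """Rank of supplied trajectory values within the simulated natural
        distribution, in percent (pointwise, or at one time index)."""
        v = np.asarray(values, dtype=float)
        if at_index is not None:
            s = self.samples[:, at_index]
            return float(100.0 * np.mean(s < v))
        return 100.0 * np.mean(self.samples < v[None, :], axis=0)


def simulate_individual_band(
    table: CoefficientTable,
    re_cov: np.ndarray,
    patient: PatientProfile,
    times,
    *,
    n: int = 1000,
    rng: np.random.Generator | None = None,
    resid_var: float = 0.0,
) -> BandResult:
    """Sample the random-effect distribution around a patient's mean curve.

    Each of ``n`` draws adds b0 + b1*t (raw time) to the fixed-effect
    trajectory; residual noise is excluded by default (the band depicts
    stable between-person variation, not test-retest noise) but can be added
    via ``resid_var``.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    re_cov = np.asarray(re_cov, dtype=float)
    eig = np.linalg.eigvalsh((re_cov + re_cov.T) / 2)
    if eig.min() < -1e-8:
        raise ValueError("random-effect covariance must be positive semidefinite")
    rng = rng or np.random.default_rng(0)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    mean = predict_mean(table, patient, t).values
    b = rng.multivariate_normal([0.0, 0.0], re_cov, size=n)
    samples = mean[None, :] + b[:, [0]] + b[:, [1]] * t[None, :]
    if resid_var > 0:
        samples = samples + rng.normal(0.0, math.sqrt(resid_var), samples.shape)
    return BandResult(times=t, mean=mean, samples=samples, bounds=table.bounds)


def population_fan(
    fit: LMMFit,
    cohort,
    *,
    percentiles: Sequence[float] = (2, 16, 50, 84, 98),
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Empirical percentile curves of per-subject predicted trajectories.

    Each subject's predicted value at time t is the fixed-effect prediction
    from their covariates plus their empirical-Bayes (b0, b1) contribution.
    Values outside the outcome bounds are omitted before taking percentiles,
    mirroring how such fans are displayed.
    """
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    if grid is None:
        grid = np.arange(0.5, 5.01, 0.25)
    table = fit.coefficients
    blups = estimate_blups(fit)
    base = cohort.baseline.loc[blups.index]
    cov = {c: base[c].to_numpy(dtype=float) for c in base.columns if c != "group"}
    lo, hi = table.bounds
    rows = []
    for t in grid:
        vals = (
            evaluate_table(table, cov, np.full(len(base), t))
            + blups["b0"].to_numpy()
            + blups["b1"].to_numpy() * t
        )
        ok = (vals >= lo) & (vals <= hi)
        row = {"time_years": t}
        for q in percentiles:
            row[f"p{int(q)}"] = float(np.percentile(vals[ok], q)) if ok.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
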