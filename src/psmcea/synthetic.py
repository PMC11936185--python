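"""Synthetic trial-like survival data with known ground truth.

Individual patient data for the underlying trial are not public, so every
stage of the pipeline — Kaplan-Meier estimation, figure digitization,
pseudo-data reconstruction, parametric fitting — is exercised on simulated
cohorts: event times drawn by inverse-transform sampling from a known
parametric family, administratively censored at a follow-up horizon, then
stepped through a product-limit estimate and a jittered grid "digitization"
that emulates manual curve extraction.

Default sizes mirror the emulated trial: 230 patients per arm, monthly
digitization to 36 months, 0.01 survival-units of digitization jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .params import ModelParameters, base_deck
from .survival import DigitizedCurve, ParametricSurvival, quantile

__all__ = [
    "SimulatedCohort",
    "simulate_event_times",
    "kaplan_meier",
    "digitize",
    "make_base_deck",
]

log = logging.getLogger(__name__)

DEFAULT_COHORT_SIZE = 230
DEFAULT_GRID_MONTHS = 36
DEFAULT_JITTER_SD = 0.01


@dataclass
class SimulatedCohort:
    """Simulated event/censor times (months) with 1 = event, 0 = censored."""

    times: np.ndarray
    status: np.ndarray
    truth: ParametricSurvival
    censor_horizon: float
    seed: int

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_months": self.times, "status": self.status}).to_csv(
            path, index=False)


def simulate_event_times(
    dist: ParametricSurvival,
    n: int,
    admin_censor: float,
    seed: int = 0,
) -> SimulatedCohort:
    """Inverse-transform sample ``n`` event times; censor at ``admin_censor``.

    For the log-logistic family the quantile is
    t = (u / ((1 - u) * lambda)) ** (1 / gamma) for uniform u.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not admin_censor > 0:
        raise ValueError("admin_censor must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    t = np.asarray(quantile(dist, u), dtype=float)
    status = (t <= admin_censor).astype(int)
    t = np.minimum(t, admin_censor)
    return SimulatedCohort(times=t, status=status, truth=dist,
                           censor_horizon=float(admin_censor), seed=seed)


def kaplan_meier(cohort: SimulatedCohort) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate as a right-continuous step function.

    Returns (times, survival) starting at (0, 1), non-increasing.  An
    all-censored cohort yields a flat curve with a warning.
    """
    if int(cohort.status.sum()) == 0:
        log.warning("all-censored cohort: Kaplan-Meier estimate is flat at 1")
        return (np.array([0.0, cohort.times.max()]), np.array([1.0, 1.0]))
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.times, event_observed=cohort.status)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:  # pragma: no cover - lifelines always anchors at 0
        times = np.insert(times, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
    return times, surv


def _step_eval(step_times: np.ndarray, step_surv: np.ndarray, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(step_times, t, side="right") - 1
    return step_surv[np.clip(idx, 0, step_surv.size - 1)]


def digitize(
    step: tuple[np.ndarray, np.ndarray],
    grid: np.ndarray | None = None,
    jitter_sd: float = DEFAULT_JITTER_SD,
    seed: int = 0,
    label: str = "",
    assumed_cohort_size: int = DEFAULT_COHORT_SIZE,
) -> DigitizedCurve:
    """Sample a KM step function on a grid with digitization-like jitter.

    Gaussian jitter (sd in survival-probability units) is added to each
    grid read-off, clipped to [0, 1]; the curve constructor then repairs
    monotonicity — together emulating manual extraction error from a
    published figure.  ``jitter_sd = 0`` reproduces the step values exactly.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    step_times, step_surv = np.asarray(step[0], float), np.asarray(step[1], float)
    if grid is None:
        grid = np.arange(0.0, min(DEFAULT_GRID_MONTHS, step_times[-1]) + 1e-9, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size and grid[-1] > step_times[-1] + 1e-9:
        raise ValueError("digitization grid extends beyond the curve support")
    s = _step_eval(step_times, step_surv, grid)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        s = np.clip(s + rng.normal(0.0, jitter_sd, s.size), 0.0, 1.0)
    return DigitizedCurve(grid, s, label=label, assumed_cohort_size=assumed_cohort_size)


def make_base_deck() -> ModelParameters:
    """The complete published input deck (survival, costs, utilities)."""
    return base_deck()
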