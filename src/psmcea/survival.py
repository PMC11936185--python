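"""Parametric survival distributions for extrapolating digitized trial curves.

Six families commonly used for survival extrapolation in health-economic
models are supported.  The log-logistic family uses the health-economics
parameterisation ``S(t) = 1 / (1 + lambda * t**gamma)`` with shape ``gamma``
and scale ``lambda`` (units of months**-gamma when time is in months); the
other families use the standard shape/rate or shape/log-scale conventions
documented per family below.

The fitting path mirrors how published Kaplan-Meier figures are actually
used when individual patient data are unavailable: digitized (time,
survival) coordinates are converted into per-interval event counts for an
assumed cohort (a simplified Guyot-style reconstruction), and each family is
fitted by maximum likelihood on the resulting interval-censored counts.
Model selection is by minimum AIC with BIC and parsimony tie-breaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Family",
    "ParametricSurvival",
    "DigitizedCurve",
    "FitResult",
    "StateOccupancy",
    "IntervalCounts",
    "survival_probability",
    "quantile",
    "median_survival",
    "state_occupancy",
    "reconstruct_interval_counts",
    "fit_parametric",
    "select_distribution",
    "rank_fits",
]


class Family(str, Enum):
    """Supported parametric survival families."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"


#: number of free parameters per family (exponential has no shape)
N_PARAMS = {
    Family.EXPONENTIAL: 1,
    Family.WEIBULL: 2,
    Family.GOMPERTZ: 2,
    Family.GAMMA: 2,
    Family.LOGNORMAL: 2,
    Family.LOGLOGISTIC: 2,
}


@dataclass(frozen=True)
class ParametricSurvival:
    """A survival-time distribution used for extrapolation.

    Parameters
    ----------
    family
        One of :class:`Family` (strings accepted).
    shape
        Dimensionless shape parameter: gamma for log-logistic and Weibull,
        the Gompertz rate-of-increase, the gamma-distribution shape, or the
        lognormal sigma.  Ignored (may be ``None``) for the exponential.
    scale
        Family-specific positive scale: lambda for log-logistic / Weibull /
        Gompertz / exponential (a rate), the gamma-distribution rate, or
        exp(mu) for the lognormal.
    time_unit
        Informational label; all shipped parameters are in months.
    """

    family: Family
    shape: float | None
    scale: float
    time_unit: str = "months"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if not (self.scale > 0) or not math.isfinite(self.scale):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if self.family is Family.EXPONENTIAL:
            return
        if self.shape is None or not (self.shape > 0) or not math.isfinite(self.shape):
            raise ValueError(
                f"{self.family.value} requires a positive finite shape, got {self.shape}"
            )

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.family]


def survival_probability(dist: ParametricSurvival, t) -> np.ndarray | float:
    """Evaluate S(t) for a valid distribution; vectorised over ``t``.

    Raises ``ValueError`` for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_probability requires t >= 0")
    g, lam = dist.shape, dist.scale
    with np.errstate(over="ignore", divide="ignore"):
        if dist.family is Family.EXPONENTIAL:
            s = np.exp(-lam * t_arr)
        elif dist.family is Family.WEIBULL:
            s = np.exp(-lam * t_arr**g)
        elif dist.family is Family.GOMPERTZ:
            s = np.exp(-(lam / g) * np.expm1(g * t_arr))
        elif dist.family is Family.GAMMA:
            s = stats.gamma.sf(t_arr, a=g, scale=1.0 / lam)
        elif dist.family is Family.LOGNORMAL:
            s = stats.lognorm.sf(t_arr, s=g, scale=lam)
        elif dist.family is Family.LOGLOGISTIC:
            s = 1.0 / (1.0 + lam * t_arr**g)
        else:  # pragma: no cover
            raise ValueError(f"unknown family {dist.family}")
    s = np.clip(s, 0.0, 1.0)
    return float(s) if np.isscalar(t) or np.ndim(t) == 0 else s


def quantile(dist: ParametricSurvival, p) -> np.ndarray | float:
    """Inverse CDF: the time t with F(t) = p (so S(t) = 1 - p)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr >= 1)):
        raise ValueError("quantile requires p in [0, 1)")
    g, lam = dist.shape, dist.scale
    if dist.family is Family.EXPONENTIAL:
        t = -np.log1p(-p_arr) / lam
    elif dist.family is Family.WEIBULL:
        t = (-np.log1p(-p_arr) / lam) ** (1.0 / g)
    elif dist.family is Family.GOMPERTZ:
        t = np.log1p(-g * np.log1p(-p_arr) / lam) / g
    elif dist.family is Family.GAMMA:
        t = stats.gamma.ppf(p_arr, a=g, scale=1.0 / lam)
    elif dist.family is Family.LOGNORMAL:
        t = stats.lognorm.ppf(p_arr, s=g, scale=lam)
    elif dist.family is Family.LOGLOGISTIC:
        # t = (p / ((1 - p) * lambda)) ** (1 / gamma)
        with np.errstate(divide="ignore"):
            t = (p_arr / ((1.0 - p_arr) * lam)) ** (1.0 / g)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {dist.family}")
    return float(t) if np.ndim(p) == 0 else t


def median_survival(dist: ParametricSurvival) -> float:
    """Smallest t with S(t) = 0.5.

    Closed form for exponential, Weibull and log-logistic; numeric root
    otherwise (bracketed bisection on S(t) - 0.5).
    """
    g, lam = dist.shape, dist.scale
    if dist.family is Family.EXPONENTIAL:
        return math.log(2.0) / lam
    if dist.family is Family.WEIBULL:
        return (math.log(2.0) / lam) ** (1.0 / g)
    if dist.family is Family.LOGLOGISTIC:
        return (1.0 / lam) ** (1.0 / g)
    hi = 1.0
    while survival_probability(dist, hi) > 0.5:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - defensive
            raise RuntimeError("median bracket search failed")
    return float(optimize.brentq(lambda t: survival_probability(dist, t) - 0.5, 0.0, hi, xtol=1e-12))


@dataclass(frozen=True)
class StateOccupancy:
    """Partitioned-survival occupancy: progression-free / progressed / dead."""

    pf: float | np.ndarray
    pd: float | np.ndarray
    dead: float | np.ndarray


def state_occupancy(pfs: ParametricSurvival, os: ParametricSurvival, t) -> StateOccupancy:
    """Partition the cohort at time ``t`` using the PFS and OS curves.

    pf = min(S_pfs, S_os) (standard clipping when the digitized PFS curve
    drifts above OS), pd = S_os - pf, dead = 1 - S_os; the three components
    sum to one by construction.
    """
    s_pfs = survival_probability(pfs, t)
    s_os = survival_probability(os, t)
    pf = np.minimum(s_pfs, s_os)
    pd_ = np.maximum(s_os - pf, 0.0)
    dead = 1.0 - s_os
    return StateOccupancy(pf=pf, pd=pd_, dead=dead)


# ---------------------------------------------------------------------------
# Digitized curves and pseudo-data reconstruction
# ---------------------------------------------------------------------------


@dataclass
class DigitizedCurve:
    """Digitized Kaplan-Meier coordinates: (time in months, survival).

    On construction the points are sorted, a (0, 1) anchor is inserted if
    absent, and survival is repaired to be non-increasing (cumulative
    minimum) — manual digitization frequently produces tiny inversions.
    """

    times: np.ndarray
    survival: np.ndarray
    label: str = ""
    assumed_cohort_size: int = 230
    repaired: bool = field(default=False)

    def __init__(
        self,
        times: Sequence[float],
        survival: Sequence[float],
        label: str = "",
        assumed_cohort_size: int = 230,
    ) -> None:
        t = np.asarray(times, dtype=float)
        s = np.asarray(survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and survival must be 1-D and equal length")
        if np.any(t < 0):
            raise ValueError("digitized times must be >= 0")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if int(assumed_cohort_size) < 1:
            raise ValueError("assumed_cohort_size must be positive")
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if t.size == 0 or t[0] > 0:
            t = np.insert(t, 0, 0.0)
            s = np.insert(s, 0, 1.0)
        else:
            s[0] = 1.0
        repaired = bool(np.any(np.diff(s) > 0))
        s = np.minimum.accumulate(s)
        self.times = t
        self.survival = s
        self.label = label
        self.assumed_cohort_size = int(assumed_cohort_size)
        self.repaired = repaired

    # -- CSV dialect: header `time_months,survival`, one curve per file -----
    @classmethod
    def read_csv(cls, path: str | Path, label: str | None = None, assumed_cohort_size: int = 230) -> "DigitizedCurve":
        df = pd.read_csv(path)
        missing = {"time_months", "survival"} - set(df.columns)
        if missing:
            raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
        return cls(
            df["time_months"].to_numpy(),
            df["survival"].to_numpy(),
            label=label if label is not None else Path(path).stem,
            assumed_cohort_size=assumed_cohort_size,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_months": self.times, "survival": self.survival}).to_csv(path, index=False)


@dataclass(frozen=True)
class IntervalCounts:
    """Reconstructed pseudo-data: events per digitized interval.

    ``table`` has columns t_start, t_end, at_risk, events; ``n_censored``
    patients are administratively censored at ``censor_time`` (the last
    digitized point — no earlier loss to follow-up is assumed because the
    source figures publish no numbers-at-risk).
    """

    table: pd.DataFrame
    n_total: int
    n_censored: int
    censor_time: float


def reconstruct_interval_counts(curve: DigitizedCurve) -> IntervalCounts:
    """Convert survival drops between digitized points into event counts.

    Within each interval [t_i, t_{i+1}) the conditional drop
    (S_i - S_{i+1}) / S_i of the current at-risk cohort is rounded to whole
    events; the residual cohort at the last point is right-censored there.
    """
    if curve.assumed_cohort_size < 10:
        raise ValueError("assumed_cohort_size must be >= 10 for reconstruction")
    if curve.times.size < 2:
        raise ValueError("need at least 2 digitized points")
    n = curve.assumed_cohort_size
    rows = []
    for i in range(curve.times.size - 1):
        s_i, s_next = curve.survival[i], curve.survival[i + 1]
        if n > 0 and s_i > 0:
            events = int(round(n * (s_i - s_next) / s_i))
        else:
            events = 0
        events = min(events, n)
        rows.append((curve.times[i], curve.times[i + 1], n, events))
        n -= events
    table = pd.DataFrame(rows, columns=["t_start", "t_end", "at_risk", "events"])
    return IntervalCounts(
        table=table,
        n_total=curve.assumed_cohort_size,
        n_censored=n,
        censor_time=float(curve.times[-1]),
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting on interval-censored counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one family to one reconstructed curve."""

    distribution: ParametricSurvival
    log_likelihood: float
    aic: float
    bic: float
    n_params: int
    converged: bool = True
    message: str = ""


_TINY = 1e-300


def _interval_loglik(dist: ParametricSurvival, counts: IntervalCounts) -> float:
    tab = counts.table
    s_lo = np.asarray(survival_probability(dist, tab["t_start"].to_numpy()))
    s_hi = np.asarray(survival_probability(dist, tab["t_end"].to_numpy()))
    p_event = np.clip(s_lo - s_hi, _TINY, 1.0)
    ll = float(np.sum(tab["events"].to_numpy() * np.log(p_event)))
    if counts.n_censored > 0:
        s_c = max(float(survival_probability(dist, counts.censor_time)), _TINY)
        ll += counts.n_censored * math.log(s_c)
    return ll


def _scale_from_median(family: Family, shape: float, t50: float) -> float:
    """Solve the scale so that the family's median equals t50 at this shape."""
    ln2 = math.log(2.0)
    if family is Family.EXPONENTIAL:
        return ln2 / t50
    if family is Family.WEIBULL:
        return ln2 / t50**shape
    if family is Family.LOGLOGISTIC:
        return t50**-shape
    if family is Family.GOMPERTZ:
        return shape * ln2 / math.expm1(shape * t50)
    if family is Family.GAMMA:
        return stats.gamma.ppf(0.5, a=shape) / t50
    if family is Family.LOGNORMAL:
        return t50  # scale = exp(mu) = median
    raise ValueError(family)  # pragma: no cover


def _curve_median(curve: DigitizedCurve) -> float:
    """Crude median from the digitized coordinates (for starting values)."""
    s, t = curve.survival, curve.times
    below = np.nonzero(s <= 0.5)[0]
    if below.size == 0:
        return float(t[-1]) * 2.0
    j = below[0]
    if j == 0 or s[j - 1] == s[j]:
        return float(t[j])
    # linear interpolation in survival
    frac = (s[j - 1] - 0.5) / (s[j - 1] - s[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


_SHAPE_GRID = (0.3, 0.6, 1.0, 1.5, 2.0, 3.0, 5.0)


def fit_parametric(curve: DigitizedCurve, family: Family | str) -> FitResult:
    """Maximum-likelihood fit of one family to a digitized curve.

    The curve is first reconstructed into interval-censored counts; the
    interval likelihood is then maximised over log-parameters by
    Nelder-Mead from method-of-moments-style starts (scale solved from the
    curve's median over a grid of candidate shapes).  Non-convergence is
    reported via ``converged=False``, never silently replaced.
    """
    family = Family(family)
    if curve.times.size < 3:
        raise ValueError("need at least 3 digitized points to fit")
    if curve.survival[-1] >= curve.survival[0]:
        raise ValueError("curve must contain a survival drop")
    counts = reconstruct_interval_counts(curve)
    t50 = max(_curve_median(curve), 1e-6)
    k = N_PARAMS[family]

    def build(x: np.ndarray) -> ParametricSurvival | None:
        try:
            if family is Family.EXPONENTIAL:
                return ParametricSurvival(family, None, math.exp(x[0]))
            return ParametricSurvival(family, math.exp(x[0]), math.exp(x[1]))
        except (ValueError, OverflowError):
            return None

    def neg_ll(x: np.ndarray) -> float:
        dist = build(x)
        if dist is None:
            return 1e12
        try:
            return -_interval_loglik(dist, counts)
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            return 1e12

    starts: list[np.ndarray] = []
    if family is Family.EXPONENTIAL:
        starts.append(np.array([math.log(_scale_from_median(family, 1.0, t50))]))
    else:
        for g0 in _SHAPE_GRID:
            try:
                lam0 = _scale_from_median(family, g0, t50)
            except (OverflowError, ValueError):
                continue
            if lam0 > 0 and math.isfinite(lam0):
                starts.append(np.array([math.log(g0), math.log(lam0)]))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
        dist = ParametricSurvival(family, None if k == 1 else 1.0, 1.0)
        return FitResult(dist, float("-inf"), float("inf"), float("inf"), k,
                         converged=False, message="optimization failed from all starts")

    dist = build(best.x)
    ll = -float(best.fun)
    n_eff = counts.n_total
    aic = 2 * k - 2 * ll
    bic = k * math.log(n_eff) - 2 * ll
    return FitResult(dist, ll, aic, bic, k, converged=bool(best.success),
                     message=str(best.message))


def rank_fits(fits: Iterable[FitResult]) -> pd.DataFrame:
    """Ranking table for reporting: one row per family, sorted as selected."""
    rows = []
    for f in fits:
        rows.append({
            "family": f.distribution.family.value,
            "shape": f.distribution.shape,
            "scale": f.distribution.scale,
            "log_likelihood": f.log_likelihood,
            "aic": f.aic,
            "bic": f.bic,
            "n_params": f.n_params,
            "converged": f.converged,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["aic", "bic", "n_params"]).reset_index(drop=True)


def select_distribution(fits: Sequence[FitResult]) -> FitResult:
    """Pick the best fit: minimum AIC, ties by BIC, then fewest parameters."""
    ok = [f for f in fits if f.converged and math.isfinite(f.aic)]
    if not ok:
        raise ValueError("no successful fits to select from")
    return min(ok, key=lambda f: (f.aic, f.bic, f.n_params))
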