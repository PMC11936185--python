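"""One-way (tornado) and probabilistic sensitivity analyses.

The one-way analysis reruns the full deterministic model with each
parameter at its low and high value, all else at base, and ranks parameters
by ICER swing.  The probabilistic analysis draws every uncertain parameter
independently — gamma for costs, beta for probabilities and utilities —
with distributions moment-matched to mean = base and sd = (high - low) /
3.92 (the range read as a 95% interval), runs both arms per draw, and
summarises the incremental (dQALY, dcost) cloud as an acceptability
fraction and a cost-effectiveness acceptability curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import run_base_case
from .params import AE_EVENTS, ModelParameters, with_overrides

__all__ = [
    "ParameterSpec",
    "TornadoRow",
    "PSAResult",
    "default_parameter_specs",
    "one_way_sensitivity",
    "sample_psa_deck",
    "run_psa",
    "ce_acceptability_curve",
]

log = logging.getLogger(__name__)

GAMMA = "gamma"
BETA = "beta"
FIXED = "fixed"


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain input: base value, range, and PSA distribution family.

    ``path`` is the dotted deck entry the spec perturbs (defaults to
    ``name``); ``role`` tags the parameter class (cost, utility,
    probability, incidence, structural) for reporting.
    """

    name: str
    base: float
    low: float
    high: float
    psa_family: str = FIXED
    role: str = "structural"
    path: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.psa_family not in (GAMMA, BETA, FIXED):
            raise ValueError(f"{self.name}: unknown psa_family {self.psa_family}")
        if self.psa_family == BETA and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta-family values must lie in [0, 1]")
        if self.psa_family == GAMMA and self.low < 0:
            raise ValueError(f"{self.name}: gamma-family values must be >= 0")
        if not self.path:
            object.__setattr__(self, "path", self.name)

    @property
    def sd(self) -> float:
        return (self.high - self.low) / 3.92


def _pm25(base: float) -> tuple[float, float]:
    return 0.75 * base, 1.25 * base


def default_parameter_specs(deck: ModelParameters) -> list[ParameterSpec]:
    """The published uncertain-parameter set.

    Every cost/utility row with a printed range enters with that range
    (the printed ranges are +/-25% of base); adverse-event incidences,
    which are published with a beta distribution but no range, enter at
    +/-25%.  Body surface area is sampled gamma (its printed range exceeds
    the unit interval, which a beta variate cannot reach).  Survival-curve
    parameters are deliberately fixed.
    """
    p = deck.prices
    c = deck.care_costs
    specs: list[ParameterSpec] = [
        ParameterSpec("prices.tislelizumab", p["tislelizumab"], 1.34, 2.23, GAMMA, "cost"),
        ParameterSpec("prices.etoposide", p["etoposide"], 0.34, 0.56, GAMMA, "cost"),
        ParameterSpec("prices.cisplatin", p["cisplatin"], 0.17, 0.28, GAMMA, "cost"),
        ParameterSpec("prices.carboplatin", p["carboplatin"], 0.06, 0.11, GAMMA, "cost"),
        ParameterSpec("ae_costs.anaemia", deck.ae_costs["anaemia"], 398.79, 664.65, GAMMA, "cost"),
        ParameterSpec("ae_costs.leukopenia", deck.ae_costs["leukopenia"], 345.94, 576.56, GAMMA, "cost"),
        ParameterSpec("ae_costs.neutropenia", deck.ae_costs["neutropenia"], 63.16, 105.26, GAMMA, "cost"),
        ParameterSpec("ae_costs.thrombocytopenia", deck.ae_costs["thrombocytopenia"], 790.50, 1317.50, GAMMA, "cost"),
        ParameterSpec("care_costs.subsequent_treatment", c.subsequent_treatment, 640.54, 1067.56, GAMMA, "cost"),
        ParameterSpec("care_costs.bsc_per_cycle", c.bsc_per_cycle, 269.64, 449.40, GAMMA, "cost"),
        ParameterSpec("care_costs.followup_per_cycle", c.followup_per_cycle, 41.70, 69.50, GAMMA, "cost"),
        ParameterSpec("care_costs.labs_per_cycle", c.labs_per_cycle, 69.38, 115.63, GAMMA, "cost"),
        ParameterSpec("care_costs.imaging_per_cycle", c.imaging_per_cycle, 79.43, 132.38, GAMMA, "cost"),
        ParameterSpec("utilities.progression_free", deck.utilities.progression_free, 0.50, 0.84, BETA, "utility"),
        ParameterSpec("utilities.progressive", deck.utilities.progressive, 0.35, 0.59, BETA, "utility"),
        ParameterSpec("ae_disutilities.anaemia", deck.ae_disutilities["anaemia"], 0.05, 0.09, BETA, "utility"),
        ParameterSpec("ae_disutilities.neutropenia", deck.ae_disutilities["neutropenia"], 0.15, 0.25, BETA, "utility"),
        ParameterSpec("ae_disutilities.thrombocytopenia", deck.ae_disutilities["thrombocytopenia"], 0.14, 0.24, BETA, "utility"),
        ParameterSpec("ae_disutilities.leukopenia", deck.ae_disutilities["leukopenia"], 0.15, 0.25, BETA, "utility"),
        ParameterSpec("patient.body_surface_area_m2", deck.patient.body_surface_area_m2, 1.29, 2.15, GAMMA, "structural"),
        ParameterSpec("settings.annual_discount_rate", deck.settings.annual_discount_rate, 0.04, 0.06, BETA, "structural"),
        ParameterSpec("regimen.platinum_cisplatin_fraction",
                      deck.regimen.platinum_cisplatin_fraction, 0.25, 0.75, BETA, "probability"),
    ]
    for arm, incs in deck.ae_incidence.items():
        for ev in AE_EVENTS:
            base = incs[ev]
            lo, hi = _pm25(base)
            specs.append(ParameterSpec(
                f"ae_incidence.{arm}.{ev}", base, lo, min(hi, 1.0), BETA, "incidence"))
    return specs


# ---------------------------------------------------------------------------
# One-way sensitivity (tornado)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    icer_low: float
    icer_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_value(deck: ModelParameters) -> float:
    """ICER of a deterministic run; NaN in dominance/degenerate quadrants."""
    res = run_base_case(deck)
    return res.icer if res.icer is not None else float("nan")


def one_way_sensitivity(
    deck: ModelParameters, specs: Iterable[ParameterSpec]
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high, all else base.

    Returns a DataFrame (parameter, icer_low, icer_high, swing) sorted by
    descending swing.  Unknown parameter paths raise ``KeyError``.
    """
    rows = []
    for spec in specs:
        lo = _icer_value(with_overrides(deck, {spec.path: spec.low}))
        hi = _icer_value(with_overrides(deck, {spec.path: spec.high}))
        rows.append(TornadoRow(spec.name, lo, hi))
    df = pd.DataFrame(
        [(r.parameter, r.icer_low, r.icer_high, r.swing) for r in rows],
        columns=["parameter", "icer_low", "icer_high", "swing"],
    )
    return df.sort_values("swing", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _draw_one(spec: ParameterSpec, rng: np.random.Generator) -> float:
    m, s = spec.base, spec.sd
    if spec.psa_family == FIXED or s == 0.0:
        return m
    if spec.psa_family == GAMMA:
        if m <= 0:
            return m
        shape = (m / s) ** 2
        return float(rng.gamma(shape, s**2 / m))
    # beta: moment match; shrink sd if the variance is infeasible on (0,1)
    if not 0.0 < m < 1.0:
        return m
    max_var = m * (1.0 - m)
    if s**2 >= max_var:
        s_new = 0.95 * max_var**0.5
        log.warning("%s: sd %.4g infeasible for beta support, shrunk to %.4g",
                    spec.name, s, s_new)
        s = s_new
    nu = m * (1.0 - m) / s**2 - 1.0
    return float(rng.beta(m * nu, (1.0 - m) * nu))


def sample_psa_deck(
    specs: Sequence[ParameterSpec], rng: np.random.Generator
) -> dict[str, float]:
    """Independent method-of-moments draws, keyed by deck path."""
    return {spec.path: _draw_one(spec, rng) for spec in specs}


@dataclass
class PSAResult:
    """Paired incremental draws from the Monte-Carlo PSA."""

    iterations: int
    seed: int
    wtp: float
    d_cost: np.ndarray
    d_qaly: np.ndarray
    n_failed: int = 0
    draws_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def nmb(self) -> np.ndarray:
        return self.wtp * self.d_qaly - self.d_cost

    @property
    def acceptability(self) -> float:
        """Fraction of draws with non-negative net monetary benefit."""
        return float(np.mean(self.nmb >= 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.d_cost.size),
            "d_cost": self.d_cost,
            "d_qaly": self.d_qaly,
            "nmb": self.nmb,
            "acceptable": self.nmb >= 0.0,
        })


def run_psa(
    deck: ModelParameters,
    specs: Sequence[ParameterSpec],
    iterations: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo PSA: sample a deck per iteration, run both arms.

    Reproducible given ``seed``; a failing draw (e.g. an override that
    breaches a component invariant) is logged and excluded rather than
    aborting the run, keeping the draw-index-to-stream mapping stable.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    d_cost = np.empty(iterations)
    d_qaly = np.empty(iterations)
    ok = np.ones(iterations, dtype=bool)
    for i in range(iterations):
        overrides = sample_psa_deck(specs, rng)
        try:
            res = run_base_case(with_overrides(deck, overrides))
        except (ValueError, KeyError) as e:
            ok[i] = False
            log.warning("PSA draw %d failed and was excluded: %s", i, e)
            continue
        d_cost[i] = res.incremental_cost
        d_qaly[i] = res.incremental_qalys
    n_failed = int((~ok).sum())
    return PSAResult(
        iterations=iterations,
        seed=seed,
        wtp=deck.settings.wtp,
        d_cost=d_cost[ok],
        d_qaly=d_qaly[ok],
        n_failed=n_failed,
    )


def ce_acceptability_curve(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """CEAC: P(cost-effective) over a willingness-to-pay grid.

    For each grid value lambda, the fraction of draws with
    lambda * dQALY - dcost >= 0.  Monotonicity is not forced.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    if psa.d_cost.size == 0:
        raise ValueError("PSA contains no successful draws")
    prob = [float(np.mean(lam * psa.d_qaly - psa.d_cost >= 0.0)) for lam in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})
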