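"""Drug-acquisition and adverse-event cost rules for the two treatment arms.

Dosing follows the trial regimen: four 21-day induction cycles of etoposide
100 mg/m2 (days 1-3) plus a platinum agent (cisplatin 75 mg/m2 or
carboplatin dosed by the Calvert formula to AUC 5, taken as equiprobable),
with 200 mg flat-dose tislelizumab each cycle in the intervention arm and
tislelizumab monotherapy continued as maintenance.  Costs are strictly
per-mg linear (no vial rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "Arm",
    "Phase",
    "PatientProfile",
    "RegimenSpec",
    "AdverseEvent",
    "AdverseEventProfile",
    "MissingPriceError",
    "bsa_dose",
    "calvert_dose",
    "cycle_drug_cost",
    "adverse_event_burden",
]


class Arm(str, Enum):
    TISLELIZUMAB = "tislelizumab"
    CHEMOTHERAPY = "chemotherapy"


class Phase(str, Enum):
    INDUCTION = "induction"
    MAINTENANCE = "maintenance"


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient driving body-size-based dosing.

    ``gfr_ml_min`` is the renal-function input to Calvert carboplatin
    dosing.  Body weight is carried for configuration completeness but no
    shipped dosing rule consumes it.
    """

    body_weight_kg: float = 60.0
    body_surface_area_m2: float = 1.72
    gfr_ml_min: float = 70.0

    def __post_init__(self) -> None:
        for name in ("body_weight_kg", "body_surface_area_m2", "gfr_ml_min"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RegimenSpec:
    """Dosing rules for one arm (doses per 21-day cycle)."""

    arm: Arm
    induction_cycles: int = 4
    tislelizumab_flat_dose_mg: float = 200.0
    etoposide_dose_mg_per_m2: float = 100.0
    etoposide_days: int = 3
    cisplatin_dose_mg_per_m2: float = 75.0
    carboplatin_auc: float = 5.0
    platinum_cisplatin_fraction: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm", Arm(self.arm))
        for name in ("tislelizumab_flat_dose_mg", "etoposide_dose_mg_per_m2",
                     "cisplatin_dose_mg_per_m2", "carboplatin_auc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.platinum_cisplatin_fraction <= 1.0:
            raise ValueError("platinum_cisplatin_fraction must be in [0, 1]")
        if self.induction_cycles < 0:
            raise ValueError("induction_cycles must be >= 0")


class MissingPriceError(KeyError):
    """Raised when a regimen references a drug with no configured price."""

    def __init__(self, drug: str):
        super().__init__(drug)
        self.drug = drug

    def __str__(self) -> str:  # KeyError quotes its arg; keep a clear message
        return f"no unit price configured for drug '{self.drug}'"


def bsa_dose(dose_per_m2: float, profile: PatientProfile) -> float:
    """Body-surface-area dose in mg: dose_per_m2 * BSA."""
    if dose_per_m2 < 0:
        raise ValueError("dose_per_m2 must be >= 0")
    return dose_per_m2 * profile.body_surface_area_m2

def calvert_dose(auc_target: float, profile: PatientProfile) -> float:
    """Carboplatin dose in mg by the Calvert formula: AUC * (GFR + 25)."""
    if auc_target < 0:
        raise ValueError("auc_target must be >= 0")
    return auc_target * (profile.gfr_ml_min + 25.0)


def _price(prices: Mapping[str, float], drug: str) -> float:
    try:
        return prices[drug]
    except KeyError:
        raise MissingPriceError(drug) from None


def cycle_drug_cost(
    spec: RegimenSpec,
    prices: Mapping[str, float],
    profile: PatientProfile,
    phase: Phase | str,
) -> float:
    """Expected drug acquisition cost (USD) for one 21-day cycle.

    Induction: etoposide for ``etoposide_days`` daily BSA doses plus the
    cisplatin-fraction-weighted expected platinum cost, plus flat-dose
    tislelizumab in the intervention arm.  Maintenance: tislelizumab only
    (zero for the chemotherapy arm).
    """
    phase = Phase(phase)
    if phase is Phase.MAINTENANCE and spec.arm is not Arm.TISLELIZUMAB:
        return 0.0
    if spec.arm is Arm.TISLELIZUMAB:
        tis_cost = spec.tislelizumab_flat_dose_mg * _price(prices, "tislelizumab")
        if phase is Phase.MAINTENANCE:
            return tis_cost
    etoposide = (
        spec.etoposide_days
        * bsa_dose(spec.etoposide_dose_mg_per_m2, profile)
        * _price(prices, "etoposide")
    )
    cisplatin = bsa_dose(spec.cisplatin_dose_mg_per_m2, profile) * _price(prices, "cisplatin")
    carboplatin = calvert_dose(spec.carboplatin_auc, profile) * _price(prices, "carboplatin")
    p = spec.platinum_cisplatin_fraction
    platinum = p * cisplatin + (1.0 - p) * carboplatin
    total = etoposide + platinum
    if spec.arm is Arm.TISLELIZUMAB:
        total += tis_cost
    return total


@dataclass(frozen=True)
class AdverseEvent:
    """One grade >=3 adverse event: incidence, management cost, disutility."""

    incidence: float
    cost_per_cycle: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("incidence must be in [0, 1]")
        if self.cost_per_cycle < 0:
            raise ValueError("cost_per_cycle must be >= 0")
        if not 0.0 <= self.disutility <= 1.0:
            raise ValueError("disutility must be in [0, 1]")


@dataclass(frozen=True)
class AdverseEventProfile:
    """Arm-level bundle of grade >=3 adverse events (incidence > 1%)."""

    events: Mapping[str, AdverseEvent] = field(default_factory=dict)


def adverse_event_burden(
    profile: AdverseEventProfile, cycle_length_years: float
) -> tuple[float, float]:
    """One-time adverse-event cost (USD) and QALY loss per model entrant.

    Cost is the incidence-weighted sum of per-cycle management costs; the
    QALY loss applies each disutility for one cycle's duration.  Both are
    charged once at model entry (cycle 0).
    """
    if cycle_length_years < 0:
        raise ValueError("cycle_length_years must be >= 0")
    cost = sum(e.incidence * e.cost_per_cycle for e in profile.events.values())
    qaly_loss = sum(
        e.incidence * e.disutility * cycle_length_years for e in profile.events.values()
    )
    return cost, qaly_loss
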