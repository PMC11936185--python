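"""The model parameter deck: every clinical, cost and utility input.

A :class:`ModelParameters` deck aggregates the survival parameters, dosing
rules, unit prices, adverse-event profiles, state utilities, care costs and
global settings for both arms.  Decks are immutable in spirit: sensitivity
analyses derive perturbed decks through :func:`with_overrides`, which
rebuilds the nested frozen dataclasses (re-running their validation) rather
than mutating in place.

The canonical deck ships as ``data/base_deck.yaml`` and must round-trip
value-identically through :func:`load_parameters` / :func:`save_parameters`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .engine import ArmSchedule, ModelSettings
from .regimens import (
    AdverseEvent,
    AdverseEventProfile,
    Arm,
    PatientProfile,
    Phase,
    RegimenSpec,
    cycle_drug_cost,
)
from .survival import ParametricSurvival

__all__ = [
    "AE_EVENTS",
    "DosingRules",
    "Utilities",
    "CareCosts",
    "SurvivalPair",
    "ModelParameters",
    "ParameterValidationError",
    "base_deck",
    "load_parameters",
    "save_parameters",
    "deck_checksum",
    "resolve",
    "with_overrides",
]

AE_EVENTS = ("anaemia", "leukopenia", "neutropenia", "thrombocytopenia")


class ParameterValidationError(ValueError):
    """Aggregated deck validation failure listing every offending key."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid parameter deck:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass(frozen=True)
class DosingRules:
    """Arm-independent dosing rules; combined with an arm label on demand."""

    induction_cycles: int = 4
    tislelizumab_flat_dose_mg: float = 200.0
    etoposide_dose_mg_per_m2: float = 100.0
    etoposide_days: int = 3
    cisplatin_dose_mg_per_m2: float = 75.0
    carboplatin_auc: float = 5.0
    platinum_cisplatin_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.to_spec(Arm.TISLELIZUMAB)  # delegate validation to RegimenSpec

    def to_spec(self, arm: Arm | str) -> RegimenSpec:
        return RegimenSpec(arm=Arm(arm), **dataclasses.asdict(self))


@dataclass(frozen=True)
class Utilities:
    """Health-state preference weights on the 0 (dead) - 1 (perfect) scale."""

    progression_free: float = 0.67
    progressive: float = 0.47

    def __post_init__(self) -> None:
        for name in ("progression_free", "progressive"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"utilities.{name} must be in [0, 1]")


@dataclass(frozen=True)
class CareCosts:
    """Non-drug direct medical costs (USD)."""

    followup_per_cycle: float = 55.60
    labs_per_cycle: float = 92.50
    imaging_per_cycle: float = 105.90
    bsc_per_cycle: float = 359.52
    subsequent_treatment: float = 854.05

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"care_costs.{f.name} must be >= 0")


@dataclass(frozen=True)
class SurvivalPair:
    """The PFS and OS distributions for one arm."""

    pfs: ParametricSurvival
    os: ParametricSurvival


@dataclass(frozen=True)
class ModelParameters:
    """The full input deck for the partitioned-survival analysis."""

    settings: ModelSettings
    patient: PatientProfile
    prices: Mapping[str, float]
    regimen: DosingRules
    survival: Mapping[str, SurvivalPair]
    ae_incidence: Mapping[str, Mapping[str, float]]
    ae_costs: Mapping[str, float]
    ae_disutilities: Mapping[str, float]
    utilities: Utilities
    care_costs: CareCosts
    subsequent_uptake: Mapping[str, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        errors: list[str] = []
        for arm in (Arm.TISLELIZUMAB.value, Arm.CHEMOTHERAPY.value):
            if arm not in self.survival:
                errors.append(f"survival.{arm}: missing")
            if arm not in self.ae_incidence:
                errors.append(f"ae_incidence.{arm}: missing")
            u = self.subsequent_uptake.get(arm)
            if u is None:
                errors.append(f"subsequent_uptake.{arm}: missing")
            elif not 0.0 <= u <= 1.0:
                errors.append(f"subsequent_uptake.{arm}: {u} not in [0, 1]")
        for drug in ("tislelizumab", "etoposide", "cisplatin", "carboplatin"):
            p = self.prices.get(drug)
            if p is None:
                errors.append(f"prices.{drug}: missing")
            elif p < 0:
                errors.append(f"prices.{drug}: {p} must be >= 0")
        for ev in AE_EVENTS:
            if ev not in self.ae_costs:
                errors.append(f"ae_costs.{ev}: missing")
            if ev not in self.ae_disutilities:
                errors.append(f"ae_disutilities.{ev}: missing")
            for arm, inc in self.ae_incidence.items():
                v = inc.get(ev)
                if v is None:
                    errors.append(f"ae_incidence.{arm}.{ev}: missing")
                elif not 0.0 <= v <= 1.0:
                    errors.append(f"ae_incidence.{arm}.{ev}: {v} not in [0, 1]")
        for ev, c in self.ae_costs.items():
            if c < 0:
                errors.append(f"ae_costs.{ev}: {c} must be >= 0")
        for ev, d in self.ae_disutilities.items():
            if not 0.0 <= d <= 1.0:
                errors.append(f"ae_disutilities.{ev}: {d} not in [0, 1]")
        if errors:
            raise ParameterValidationError(errors)

    # -- assembly helpers ---------------------------------------------------

    def ae_profile(self, arm: Arm | str) -> AdverseEventProfile:
        arm = Arm(arm).value
        return AdverseEventProfile(events={
            ev: AdverseEvent(
                incidence=self.ae_incidence[arm][ev],
                cost_per_cycle=self.ae_costs[ev],
                disutility=self.ae_disutilities[ev],
            )
            for ev in AE_EVENTS
        })

    def regimen_spec(self, arm: Arm | str) -> RegimenSpec:
        return self.regimen.to_spec(arm)

    def drug_cycle_costs(self, arm: Arm | str) -> tuple[float, float]:
        """(induction, maintenance) drug cost per cycle for one arm."""
        spec = self.regimen_spec(arm)
        return (
            cycle_drug_cost(spec, self.prices, self.patient, Phase.INDUCTION),
            cycle_drug_cost(spec, self.prices, self.patient, Phase.MAINTENANCE),
        )

    def schedule(self, arm: Arm | str) -> ArmSchedule:
        arm = Arm(arm)
        pair = self.survival[arm.value]
        return ArmSchedule(
            arm=arm.value,
            pfs=pair.pfs,
            os=pair.os,
            induction_cycles=self.regimen.induction_cycles,
            has_maintenance_drug=arm is Arm.TISLELIZUMAB,
            utility_pf=self.utilities.progression_free,
            utility_pd=self.utilities.progressive,
            followup_cost_per_cycle=self.care_costs.followup_per_cycle,
            labs_cost_per_cycle=self.care_costs.labs_per_cycle,
            imaging_cost_per_cycle=self.care_costs.imaging_per_cycle,
            bsc_cost_per_cycle=self.care_costs.bsc_per_cycle,
            subsequent_treatment_cost=self.care_costs.subsequent_treatment,
            subsequent_uptake=self.subsequent_uptake[arm.value],
        )


def base_deck() -> ModelParameters:
    """The published base-case deck: all survival, cost and utility inputs."""
    ll = "loglogistic"
    return ModelParameters(
        settings=ModelSettings(),
        patient=PatientProfile(),
        prices={"tislelizumab": 1.78, "etoposide": 0.45,
                "cisplatin": 0.22, "carboplatin": 0.086},
        regimen=DosingRules(),
        survival={
            "tislelizumab": SurvivalPair(
                pfs=ParametricSurvival(ll, 1.92, 0.035),
                os=ParametricSurvival(ll, 1.78, 0.0068),
            ),
            "chemotherapy": SurvivalPair(
                pfs=ParametricSurvival(ll, 3.97, 0.0022),
                os=ParametricSurvival(ll, 2.37, 0.0019),
            ),
        },
        ae_incidence={
            "tislelizumab": {"anaemia": 0.16, "leukopenia": 0.11,
                             "neutropenia": 0.56, "thrombocytopenia": 0.19},
            "chemotherapy": {"anaemia": 0.17, "leukopenia": 0.10,
                             "neutropenia": 0.55, "thrombocytopenia": 0.25},
        },
        ae_costs={"anaemia": 531.72, "leukopenia": 461.25,
                  "neutropenia": 84.21, "thrombocytopenia": 1054.00},
        ae_disutilities={"anaemia": 0.073, "leukopenia": 0.20,
                         "neutropenia": 0.20, "thrombocytopenia": 0.19},
        utilities=Utilities(),
        care_costs=CareCosts(),
        subsequent_uptake={"tislelizumab": 0.60, "chemotherapy": 0.74},
        provenance={
            "currency": "USD; RMB costs converted at 1 USD = 7.05 RMB (2023 average)",
            "wtp": "3x 2023 Chinese per-capita GDP",
            "survival_time_unit": "months",
        },
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _deck_to_dict(deck: ModelParameters) -> dict:
    def dist_d(d: ParametricSurvival) -> dict:
        return {"family": d.family.value, "shape": d.shape, "scale": d.scale,
                "time_unit": d.time_unit}

    return {
        "settings": dataclasses.asdict(deck.settings),
        "patient": dataclasses.asdict(deck.patient),
        "prices": dict(deck.prices),
        "regimen": dataclasses.asdict(deck.regimen),
        "survival": {arm: {"pfs": dist_d(p.pfs), "os": dist_d(p.os)}
                     for arm, p in deck.survival.items()},
        "ae_incidence": {a: dict(v) for a, v in deck.ae_incidence.items()},
        "ae_costs": dict(deck.ae_costs),
        "ae_disutilities": dict(deck.ae_disutilities),
        "utilities": dataclasses.asdict(deck.utilities),
        "care_costs": dataclasses.asdict(deck.care_costs),
        "subsequent_uptake": dict(deck.subsequent_uptake),
        "provenance": dict(deck.provenance),
    }


_REQUIRED_KEYS = ("settings", "patient", "prices", "regimen", "survival",
                  "ae_incidence", "ae_costs", "ae_disutilities", "utilities",
                  "care_costs", "subsequent_uptake")


def _deck_from_dict(raw: Mapping[str, Any]) -> ModelParameters:
    errors = [f"{k}: missing section" for k in _REQUIRED_KEYS if k not in raw]
    if errors:
        raise ParameterValidationError(errors)

    parts: dict[str, Any] = {}

    def build(key: str, fn) -> None:
        try:
            parts[key] = fn()
        except ParameterValidationError as e:
            errors.extend(e.errors)
        except (ValueError, TypeError, KeyError) as e:
            errors.append(f"{key}: {e}")

    def dist(key: str, d: Mapping[str, Any]) -> ParametricSurvival:
        try:
            return ParametricSurvival(
                d["family"], d.get("shape"), d["scale"],
                time_unit=d.get("time_unit", "months"))
        except (ValueError, KeyError) as e:
            raise ValueError(f"{key}: {e}") from None

    build("settings", lambda: ModelSettings(**raw["settings"]))
    build("patient", lambda: PatientProfile(**raw["patient"]))
    build("prices", lambda: {k: float(v) for k, v in raw["prices"].items()})
    build("regimen", lambda: DosingRules(**raw["regimen"]))
    build("survival", lambda: {
        arm: SurvivalPair(pfs=dist(f"survival.{arm}.pfs", v["pfs"]),
                          os=dist(f"survival.{arm}.os", v["os"]))
        for arm, v in raw["survival"].items()})
    def checked_incidence() -> dict:
        out = {a: dict(v) for a, v in raw["ae_incidence"].items()}
        bad = [f"ae_incidence.{a}.{ev}: {x} not in [0, 1]"
               for a, v in out.items() for ev, x in v.items()
               if not 0.0 <= x <= 1.0]
        if bad:
            raise ParameterValidationError(bad)
        return out

    build("ae_incidence", checked_incidence)
    build("ae_costs", lambda: dict(raw["ae_costs"]))
    build("ae_disutilities", lambda: dict(raw["ae_disutilities"]))
    build("utilities", lambda: Utilities(**raw["utilities"]))
    build("care_costs", lambda: CareCosts(**raw["care_costs"]))
    build("subsequent_uptake", lambda: dict(raw["subsequent_uptake"]))
    parts["provenance"] = dict(raw.get("provenance", {}))

    if errors:
        raise ParameterValidationError(errors)
    return ModelParameters(**parts)


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load and fully validate a deck; ``None`` loads the shipped base deck.

    Validation is aggregated: every offending key is reported, not just the
    first.
    """
    if path is None:
        text = resources.files("psmcea").joinpath("data/base_deck.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterValidationError(["top level: expected a mapping"])
    return _deck_from_dict(raw)


def save_parameters(deck: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_deck_to_dict(deck), sort_keys=True, default_flow_style=False))


def deck_checksum(deck: ModelParameters) -> str:
    """SHA-256 over the canonical serialisation; changes iff a value does."""
    canon = yaml.safe_dump(_deck_to_dict(deck), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Dotted-path access for sensitivity analyses
# ---------------------------------------------------------------------------


def _get_child(obj: Any, key: str) -> Any:
    if isinstance(obj, Mapping):
        if key not in obj:
            raise KeyError(f"unknown deck entry '{key}'")
        return obj[key]
    if dataclasses.is_dataclass(obj) and hasattr(obj, key):
        return getattr(obj, key)
    raise KeyError(f"unknown deck entry '{key}' on {type(obj).__name__}")


def resolve(deck: ModelParameters, path: str) -> Any:
    """Fetch a deck value by dotted path, e.g. ``prices.tislelizumab``."""
    obj: Any = deck
    for part in path.split("."):
        obj = _get_child(obj, part)
    return obj


def _rebuild(obj: Any, key: str, child: Any) -> Any:
    if isinstance(obj, Mapping):
        new = dict(obj)
        new[key] = child
        return new
    return replace(obj, **{key: child})


def _set_path(obj: Any, parts: list[str], value: Any) -> Any:
    if len(parts) == 1:
        _get_child(obj, parts[0])  # raise KeyError for unknown names
        return _rebuild(obj, parts[0], value)
    child = _get_child(obj, parts[0])
    return _rebuild(obj, parts[0], _set_path(child, parts[1:], value))


def with_overrides(deck: ModelParameters, overrides: Mapping[str, Any]) -> ModelParameters:
    """A new deck with the dotted-path entries replaced.

    Every nested frozen dataclass on a touched path is rebuilt, so all
    component invariants are re-checked; unknown paths raise ``KeyError``
    naming the entry.
    """
    obj: Any = deck
    for path, value in overrides.items():
        obj = _set_path(obj, path.split("."), value)
    return obj
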