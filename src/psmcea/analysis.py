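"""Deck-level convenience layer: run arms and the base-case comparison."""

from __future__ import annotations

from .economics import CEResult, incremental_analysis
from .engine import ArmResult, run_arm
from .params import ModelParameters
from .regimens import Arm

__all__ = ["run_arm_from_deck", "run_base_case"]


def run_arm_from_deck(deck: ModelParameters, arm: Arm | str) -> ArmResult:
    """Assemble one arm from the deck and accrue its discounted totals."""
    arm = Arm(arm)
    induction, maintenance = deck.drug_cycle_costs(arm)
    return run_arm(
        schedule=deck.schedule(arm),
        settings=deck.settings,
        induction_cost=induction,
        maintenance_cost=maintenance,
        ae_profile=deck.ae_profile(arm),
    )


def run_base_case(deck: ModelParameters) -> CEResult:
    """Deterministic base case: tislelizumab + chemo vs chemo alone."""
    tis = run_arm_from_deck(deck, Arm.TISLELIZUMAB)
    chemo = run_arm_from_deck(deck, Arm.CHEMOTHERAPY)
    return incremental_analysis(tis, chemo, wtp=deck.settings.wtp)
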