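"""Incremental cost-effectiveness algebra: ICER, NMB, dominance, decision."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import ArmResult

__all__ = ["CEResult", "incremental_analysis", "net_monetary_benefit"]

#: ICER labels used instead of a ratio in the dominance / degenerate quadrants
DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def net_monetary_benefit(dcost: float, dqaly: float, wtp: float) -> float:
    """NMB = WTP * dQALY - dcost; non-negative iff cost-effective at WTP."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * dqaly - dcost


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is a ratio only when the intervention is more costly and more
    effective (or cheaper and less effective); the dominance quadrants and
    the zero-effect edge carry a label instead.
    """

    intervention: ArmResult
    comparator: ArmResult
    wtp: float
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    icer_label: str
    nmb: float
    cost_effective: bool

    def to_frame(self) -> pd.DataFrame:
        """Single-row table mirroring a base-case results table plus NMB."""
        return pd.DataFrame([{
            "intervention": self.intervention.arm,
            "comparator": self.comparator.arm,
            "cost_intervention": self.intervention.total_cost,
            "qalys_intervention": self.intervention.total_qalys,
            "cost_comparator": self.comparator.total_cost,
            "qalys_comparator": self.comparator.total_qalys,
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "icer": self.icer if self.icer is not None else self.icer_label,
            "nmb": self.nmb,
            "cost_effective": self.cost_effective,
        }])


def incremental_analysis(
    intervention: ArmResult, comparator: ArmResult, wtp: float
) -> CEResult:
    """Compare two arms run under the same settings deck.

    ICER = dcost / dQALY in the trade-off quadrants; "dominant" (cheaper and
    more effective) and "dominated" (costlier and less effective) are
    reported as labels, as is the undefined dQALY = 0 edge.  The decision is
    taken on NMB: cost-effective iff NMB >= 0 at ``wtp``.
    """
    dcost = intervention.total_cost - comparator.total_cost
    dqaly = intervention.total_qalys - comparator.total_qalys
    icer: float | None = None
    label = ""
    if dqaly == 0.0:
        label = UNDEFINED if dcost != 0.0 else ""
    elif dcost <= 0.0 and dqaly > 0.0:
        label = DOMINANT
    elif dcost > 0.0 and dqaly < 0.0:
        label = DOMINATED
    else:
        icer = dcost / dqaly
    nmb = net_monetary_benefit(dcost, dqaly, wtp)
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        wtp=wtp,
        incremental_cost=dcost,
        incremental_qalys=dqaly,
        icer=icer,
        icer_label=label,
        nmb=nmb,
        cost_effective=nmb >= 0.0,
    )
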