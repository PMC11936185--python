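"""End-to-end run: base case, tornado, PSA, exports and a manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np

from .analysis import run_base_case, run_arm_from_deck
from .engine import build_trace
from .params import ModelParameters, deck_checksum
from .regimens import Arm
from .sensitivity import (
    ce_acceptability_curve,
    default_parameter_specs,
    one_way_sensitivity,
    run_psa,
)

__all__ = ["RunManifest", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record for one complete run."""

    package_version: str
    deck_checksum: str
    seed: int
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)
    complete: bool = False

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2))


def _summary_text(ce, psa_acceptability: float) -> str:
    tis, chemo = ce.intervention, ce.comparator
    icer = f"{ce.icer:,.2f}" if ce.icer is not None else ce.icer_label
    lines = [
        "Base-case results (discounted)",
        "=" * 62,
        f"{'Group':<22}{'Cost ($)':>14}{'QALYs':>10}",
        f"{'Tislelizumab group':<22}{tis.total_cost:>14,.2f}{tis.total_qalys:>10.2f}",
        f"{'Chemotherapy group':<22}{chemo.total_cost:>14,.2f}{chemo.total_qalys:>10.2f}",
        "-" * 62,
        f"Incremental cost ($):   {ce.incremental_cost:,.2f}",
        f"Incremental QALYs:      {ce.incremental_qalys:.4f}",
        f"ICER ($/QALY):          {icer}",
        f"NMB at WTP ${ce.wtp:,.2f}: {ce.nmb:,.2f}",
        f"Cost-effective at WTP:  {'yes' if ce.cost_effective else 'no'}",
        f"P(cost-effective), PSA: {psa_acceptability:.2%}",
    ]
    return "\n".join(lines) + "\n"


def run_all(
    deck: ModelParameters,
    seed: int,
    out_dir: str | Path,
    psa_iterations: int = 10_000,
    plots: bool = False,
) -> RunManifest:
    """Execute base case, OWSA and PSA and write every standard output.

    Writes per-arm traces and cost breakdowns, the base-case table, the
    tornado table, per-draw PSA results, the CEAC, a human-readable summary
    and (optionally) the three standard figures; the manifest is written
    last so its presence marks a complete run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        package_version=_pkg_version("psmcea"),
        deck_checksum=deck_checksum(deck),
        seed=seed,
        started=datetime.now(timezone.utc).isoformat(),
    )
    log.info(
        "run configuration: half_cycle_correction=%s, platinum_cisplatin_fraction=%s, "
        "PSA sd rule=(high-low)/3.92, discount=%s/yr",
        deck.settings.half_cycle_correction,
        deck.regimen.platinum_cisplatin_fraction,
        deck.settings.annual_discount_rate,
    )

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.outputs.append(name)
        return path

    # base case -------------------------------------------------------------
    ce = run_base_case(deck)
    for arm in (Arm.TISLELIZUMAB, Arm.CHEMOTHERAPY):
        trace = build_trace(deck.schedule(arm), deck.settings)
        save(f"trace_{arm.value}.csv", lambda p, tr=trace: tr.to_frame().to_csv(p, index=False))
        res = run_arm_from_deck(deck, arm)
        save(f"costs_{arm.value}.csv", lambda p, r=res: _breakdown_csv(r, p))
    save("base_case.csv", lambda p: ce.to_frame().to_csv(p, index=False))

    # sensitivity -----------------------------------------------------------
    specs = default_parameter_specs(deck)
    tornado = one_way_sensitivity(deck, specs)
    save("tornado.csv", lambda p: tornado.to_csv(p, index=False))

    psa = run_psa(deck, specs, iterations=psa_iterations, seed=seed)
    save("psa_draws.csv", lambda p: psa.to_frame().to_csv(p, index=False))
    grid = np.linspace(0.0, 2.0 * deck.settings.wtp, 81)
    ceac = ce_acceptability_curve(psa, grid)
    save("ceac.csv", lambda p: ceac.to_csv(p, index=False))

    save("summary.txt", lambda p: p.write_text(_summary_text(ce, psa.acceptability)))

    if plots:
        from . import plots as _plots

        save("ce_plane.png", lambda p: _plots.plot_ce_plane(psa, p))
        base_icer = ce.icer if ce.icer is not None else float("nan")
        save("tornado.png", lambda p: _plots.plot_tornado(tornado, base_icer, p))
        save("ceac.png", lambda p: _plots.plot_ceac(ceac, deck.settings.wtp, p))

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.complete = True
    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def _breakdown_csv(res, path: Path) -> None:
    import pandas as pd

    rows = [{"category": k, "discounted_cost": v} for k, v in res.cost_breakdown.items()]
    rows.append({"category": "total", "discounted_cost": res.total_cost})
    pd.DataFrame(rows).to_csv(path, index=False)
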