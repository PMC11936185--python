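"""Standard figures: cost-effectiveness plane, tornado diagram, CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .sensitivity import PSAResult

__all__ = ["plot_ce_plane", "plot_tornado", "plot_ceac"]


def plot_ce_plane(psa: PSAResult, path: str | Path) -> None:
    """Incremental cost vs incremental QALY scatter with the WTP ray."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.d_qaly, psa.d_cost, s=4, alpha=0.3, linewidths=0)
    lim = max(abs(psa.d_qaly).max(), 1e-6) * 1.1
    ax.plot([-lim, lim], [-lim * psa.wtp, lim * psa.wtp],
            color="firebrick", lw=1, label=f"WTP ${psa.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.set_title(f"Cost-effectiveness plane ({psa.acceptability:.1%} below WTP ray)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(tornado: pd.DataFrame, base_icer: float, path: str | Path,
                 top: int = 15) -> None:
    """Horizontal tornado bars around the base-case ICER."""
    df = tornado.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    y = range(len(df))
    lo = df[["icer_low", "icer_high"]].min(axis=1)
    hi = df[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(y, hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.axvline(base_icer, color="black", lw=1, label="base-case ICER")
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: pd.DataFrame, wtp: float, path: str | Path) -> None:
    """Probability cost-effective against willingness-to-pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["probability"], lw=1.5)
    ax.axvline(wtp, color="firebrick", lw=1, ls="--", label=f"WTP ${wtp:,.0f}")
    ax.set_xlabel("Willingness-to-pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
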