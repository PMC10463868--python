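"""Thin plotting layer over the analysis outputs (matplotlib).

Each function accepts the corresponding result/frame and an optional
axes; nothing here computes — the CSV outputs are the interface and the
plots just render them.
"""

from __future__ import annotations

import pandas as pd


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ce_plane(psa_result, ax=None):
    """Scatter of PSA (ΔQALY, Δcost) draws with quadrant axes."""
    ax = _ax(ax)
    d = psa_result.deltas
    ax.scatter(d["delta_qaly"], d["delta_cost"], s=8, alpha=0.4)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(f"Incremental QALYs ({psa_result.comparator} − {psa_result.reference})")
    ax.set_ylabel("Incremental cost (USD)")
    return ax


def plot_ceac(ceac_frame: pd.DataFrame, ax=None):
    """Acceptability curves: probability cost-effective vs willingness-to-pay."""
    ax = _ax(ax)
    for strategy, grp in ceac_frame.groupby("strategy"):
        ax.plot(grp["wtp"], grp["probability"], label=str(strategy))
    ax.set_xlabel("Willingness-to-pay (USD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_tornado(tornado_frame: pd.DataFrame, base_outcome: float | None = None, ax=None):
    """Horizontal tornado bars, widest swing on top."""
    ax = _ax(ax)
    df = tornado_frame.iloc[::-1]  # widest on top
    lo = df[["outcome_low", "outcome_high"]].min(axis=1)
    hi = df[["outcome_low", "outcome_high"]].max(axis=1)
    ax.barh(df["param"], hi - lo, left=lo, color="steelblue", alpha=0.8)
    if base_outcome is not None:
        ax.axvline(base_outcome, color="black", lw=0.8)
    ax.set_xlabel("Outcome")
    return ax
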