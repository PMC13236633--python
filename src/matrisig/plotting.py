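"""Basic volcano and Kaplan-Meier exports (matplotlib, non-interactive)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .diffabund import DifferentialResult
from .survival import KMCurve

__all__ = ["volcano_plot", "km_plot"]

_CALL_COLORS = {"up_in_lo": "#2166ac", "up_in_hi": "#b2182b", "unchanged": "#bbbbbb"}


def volcano_plot(diff: DifferentialResult, path=None, ax=None):
    """log2 abundance ratio vs -log10 p, colored by call."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    tab = diff.table
    for call, color in _CALL_COLORS.items():
        sub = tab[tab["call"] == call]
        ax.scatter(
            sub["log2_ratio"], -np.log10(sub["p"]), s=12, c=color, label=call, alpha=0.8
        )
    ax.axhline(-np.log10(diff.alpha), ls="--", lw=0.8, c="k")
    for thr in (diff.up_threshold, diff.down_threshold):
        ax.axvline(np.log2(thr), ls="--", lw=0.8, c="k")
    ax.set_xlabel(f"log2({diff.group_hi} / {diff.group_lo})")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def km_plot(curves: list[KMCurve], path=None, ax=None):
    """Step plot of one or more product-limit survival curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        times = np.concatenate([[0.0], curve.event_times])
        surv = np.concatenate([[1.0], curve.survival])
        ax.step(times, surv, where="post", label=curve.label or None)
        if len(curve.censor_times):
            ax.plot(
                curve.censor_times,
                [curve.survival_at(t) for t in curve.censor_times],
                "|", ms=6, c=ax.lines[-1].get_color(),
            )
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if any(c.label for c in curves):
        ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
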