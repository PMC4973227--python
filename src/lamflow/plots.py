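"""Figure helpers: recurrence plots, scaling curves, group profiles, ROC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_recurrence",
    "plot_scaling_curve",
    "plot_group_profile",
    "plot_roc",
]


def plot_recurrence(structure, path=None, ax=None):
    """Render a recurrence plot (the Theiler band shows as a white stripe
    along the line of identity)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(structure.matrix, cmap="binary", origin="lower",
              interpolation="none")
    ax.set_xlabel("state index j")
    ax.set_ylabel("state index i")
    ax.set_title(f"RAD={structure.rad_pct:.2f}%  w={structure.theiler_w}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_scaling_curve(curve, fit=None, path=None, ax=None):
    """Log-log REC vs RAD with the fitted linear tract overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(curve.rad_solutions, curve.achieved_rec, "o-", label="solved")
    if fit is not None and fit.ok:
        x = np.log10(curve.rad_solutions / 100.0)
        y = fit.slope * x + fit.intercept
        ax.loglog(curve.rad_solutions, 100.0 * 10**y, "--",
                  label=f"slope={fit.slope:.2f}  R²={fit.r_squared:.3f}")
    ax.set_xlabel("RAD (% of max distance)")
    ax.set_ylabel("REC (%)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_group_profile(profile, path=None, ax=None):
    """Median time-course of the chosen statistic per group, one point per bin."""
    if ax is None:
        _, ax = plt.subplots()
    for g, sub in profile.medians.groupby("group"):
        ax.plot(sub["bin_start_h"] + profile.bin_h / 2, sub["median"],
                "o-", label=g)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"median {profile.statistic}")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_roc(roc, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc.fpr, roc.tpr, "-", drawstyle="steps-post",
            label=f"AUC={roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ":", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
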