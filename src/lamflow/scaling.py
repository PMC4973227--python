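"""Preliminary REC-vs-RAD scaling analysis.

Before committing to a fixed recurrence-rate target, the radius is solved
for a ladder of REC targets per epoch.  On a log-log plot the correlation
sum of a well-embedded signal scales as a power law ``REC ∝ RAD^d`` at
small radii, so log10(REC) vs log10(RAD) shows a linear tract; its slope
approximates an effective dimension and its straightness (R²) is a per-
epoch QC statistic for the embedding and the chosen REC operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingSpec, StateVectors, embed
from .rqa import (
    _sorted_valid_distances,
    distance_field,
    solve_radius_for_rec,
)

__all__ = [
    "ScalingCurve",
    "LinearityFit",
    "DEFAULT_REC_TARGETS",
    "scaling_curve",
    "scaling_curve_from_vectors",
    "loglog_linearity",
]

#: REC target ladder (%): the standard probing sequence
DEFAULT_REC_TARGETS = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)

#: REC range (%) of the expected linear tract on the log-log plot
LINEAR_TRACT_REC = (0.05, 2.0)


@dataclass(frozen=True)
class ScalingCurve:
    """Solved radius per REC target for one epoch."""

    rec_targets: np.ndarray      # requested REC (%)
    achieved_rec: np.ndarray     # REC actually attained (%)
    rad_solutions: np.ndarray    # solved radius (% of max distance)
    epoch_id: str = ""


@dataclass(frozen=True)
class LinearityFit:
    """Least-squares fit of log10(REC) on log10(RAD) over the linear tract."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    ok: bool


def scaling_curve_from_vectors(
    vectors: StateVectors | np.ndarray,
    theiler_w: int = 0,
    rec_targets=DEFAULT_REC_TARGETS,
    epoch_id: str = "",
) -> ScalingCurve:
    """Solve the radius for each REC target on one set of state vectors."""
    dist = distance_field(vectors)
    sorted_d = _sorted_valid_distances(dist, theiler_w)
    rads, achieved = [], []
    for target in rec_targets:
        sol = solve_radius_for_rec(dist, target, theiler_w=theiler_w,
                                   _sorted=sorted_d)
        rads.append(sol.rad_pct)
        achieved.append(sol.achieved_rec_pct)
    return ScalingCurve(
        rec_targets=np.asarray(rec_targets, dtype=float),
        achieved_rec=np.asarray(achieved),
        rad_solutions=np.asarray(rads),
        epoch_id=epoch_id,
    )


def scaling_curve(
    samples: np.ndarray,
    spec: EmbeddingSpec,
    rec_targets=DEFAULT_REC_TARGETS,
    epoch_id: str = "",
) -> ScalingCurve:
    """Embed one epoch and trace its REC-vs-RAD scaling curve."""
    vecs = embed(np.asarray(samples, dtype=float), spec)
    return scaling_curve_from_vectors(
        vecs, theiler_w=spec.theiler_w, rec_targets=rec_targets,
        epoch_id=epoch_id,
    )


def loglog_linearity(
    curve: ScalingCurve,
    low_rec: float = LINEAR_TRACT_REC[0],
    high_rec: float = LINEAR_TRACT_REC[1],
) -> LinearityFit:
    """Slope and R² of log10(REC) vs log10(RAD) over [low_rec, high_rec] %.

    Fewer than 3 in-range points is flagged (``ok=False``, NaN fit): no
    meaningful straight-line diagnostic can be formed.
    """
    sel = (
        (curve.rec_targets >= low_rec)
        & (curve.rec_targets <= high_rec)
        & (curve.rad_solutions > 0)
        & (curve.achieved_rec > 0)
    )
    n = int(np.count_nonzero(sel))
    if n < 3:
        return LinearityFit(slope=np.nan, intercept=np.nan,
                            r_squared=np.nan, n_points=n, ok=False)
    x = np.log10(curve.rad_solutions[sel] / 100.0)
    y = np.log10(curve.achieved_rec[sel] / 100.0)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearityFit(slope=float(slope), intercept=float(intercept),
                        r_squared=r2, n_points=n, ok=True)
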