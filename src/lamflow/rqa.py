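"""Recurrence-matrix construction, fixed-recurrence radius solving, and RQA.

The recurrence plot of an embedded epoch marks pairs of state vectors
closer than a radius RAD (Euclidean norm, distances normalized to the
maximum pairwise distance so RAD is a percentage).  Instead of fixing RAD,
the radius is solved per epoch so the recurrence rate REC hits a fixed
target (1% by default), which keeps every epoch's recurrence matrix equally
sparse; the laminarity LAM is then normalized by the solved radius
(LAM/RAD) to undo the bias this constraint introduces.

Statistics
----------
REC   recurrence rate: % of valid (Theiler-excluded) state pairs recurrent.
LAM   fraction of recurrence points lying on vertical lines of length >= 2;
      vertical lines are the signature of laminar (slowly changing) states.
VMAX  length of the longest vertical line.
TT    trapping time: mean vertical line length (lines >= 2).
DET   fraction of recurrence points on diagonal lines of length >= 5;
      diagonal lines are the signature of deterministic dynamics.

The Theiler band ``|i−j| <= w`` (and the line of identity) is excluded from
pair counting and line accounting alike: runs are truncated at the band
boundary, so tangential motion neither inflates REC nor contributes line
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import (
    DEFAULT_EMBEDDING_DIM,
    EmbeddingSpec,
    StateVectors,
    embed,
    select_delay,
)
from .exceptions import DegenerateSeriesError, RadiusSolveError

__all__ = [
    "DistanceField",
    "RecurrenceStructure",
    "RadiusSolution",
    "RQAMeasures",
    "DEFAULT_TARGET_REC_PCT",
    "DEFAULT_V_MIN",
    "DEFAULT_L_MIN",
    "distance_field",
    "recurrence_structure",
    "structure_from_matrix",
    "recurrence_rate",
    "solve_radius_for_rec",
    "laminarity",
    "vmax",
    "trapping_time",
    "determinism",
    "measures_for_epoch",
]

DEFAULT_TARGET_REC_PCT = 1.0
DEFAULT_V_MIN = 2
DEFAULT_L_MIN = 5

#: accepted deviation (percentage points) between achieved and target REC
REC_TOLERANCE_PP = 0.05


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceField:
    """Pairwise Euclidean distances normalized to the maximum distance.

    ``condensed`` is the upper-triangle distance vector (scipy ``pdist``
    layout) divided by ``max_distance``, so entries lie in [0, 1] with at
    least one entry equal to 1.
    """

    condensed: np.ndarray
    n_states: int
    max_distance: float

    def dense(self) -> np.ndarray:
        """Full symmetric normalized distance matrix (zero diagonal)."""
        return squareform(self.condensed)


def distance_field(vectors: StateVectors | np.ndarray) -> DistanceField:
    """Normalized Euclidean distance field of a set of state vectors.

    Raises
    ------
    DegenerateSeriesError
        If all vectors coincide (maximum distance 0: nothing to normalize).
    """
    pts = vectors.vectors if isinstance(vectors, StateVectors) else np.asarray(vectors, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 state vectors")
    d = pdist(pts, metric="euclidean")
    dmax = float(d.max())
    if dmax == 0.0:
        raise DegenerateSeriesError("all state vectors identical: max distance 0")
    return DistanceField(condensed=d / dmax, n_states=n, max_distance=dmax)


def _valid_condensed_mask(n: int, theiler_w: int) -> np.ndarray:
    """Boolean mask over the condensed vector: True where |i−j| > w."""
    mask = np.ones(n * (n - 1) // 2, dtype=bool)
    if theiler_w <= 0:
        return mask
    start = 0
    for i in range(n - 1):
        row = n - 1 - i  # pairs (i, i+1) ... (i, n-1)
        k = min(theiler_w, row)
        mask[start:start + k] = False
        start += row
    return mask


# ---------------------------------------------------------------------------
# recurrence structure and line histograms
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceStructure:
    """Thresholded recurrence matrix plus its line-length bookkeeping.

    ``matrix`` is the full symmetric boolean recurrence indicator with the
    line of identity and the Theiler band already blanked.  ``vertical_hist``
    and ``diagonal_hist`` are run-length histograms: entry ``[v]`` counts
    maximal runs of length v (verticals over all columns of the symmetric
    matrix; diagonals over the upper triangle beyond the Theiler band).
    """

    matrix: np.ndarray
    rad_pct: float
    theiler_w: int
    n_valid_pairs: int
    n_recurrent_pairs: int
    vertical_hist: np.ndarray = field(repr=False)
    diagonal_hist: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def _run_length_hist(flat: np.ndarray, max_len: int) -> np.ndarray:
    """Histogram of maximal True-run lengths in a flat boolean array.

    The caller must separate independent lines (columns/diagonals) with
    False sentinels.
    """
    if not flat.any():
        return np.zeros(max_len + 1, dtype=np.int64)
    padded = np.concatenate(([False], flat, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    return np.bincount(lengths, minlength=max_len + 1).astype(np.int64)


def _vertical_histogram(R: np.ndarray) -> np.ndarray:
    n = R.shape[0]
    # column-major ravel with a separator row so runs never cross columns
    with_sep = np.vstack([R, np.zeros((1, n), dtype=bool)])
    return _run_length_hist(with_sep.ravel(order="F"), n)


def _diagonal_histogram(R: np.ndarray, theiler_w: int) -> np.ndarray:
    n = R.shape[0]
    chunks = []
    sep = np.zeros(1, dtype=bool)
    for k in range(theiler_w + 1, n):
        chunks.append(np.ascontiguousarray(np.diagonal(R, k)))
        chunks.append(sep)
    if not chunks:
        return np.zeros(n + 1, dtype=np.int64)
    return _run_length_hist(np.concatenate(chunks), n)


def structure_from_matrix(R: np.ndarray, rad_pct: float, theiler_w: int
                          ) -> RecurrenceStructure:
    """Build a :class:`RecurrenceStructure` from a boolean recurrence matrix.

    The matrix is symmetrized and the LOI/Theiler band blanked before line
    accounting, so hand-built matrices used in tests obey the same
    conventions as thresholded distance fields.
    """
    R = np.asarray(R, dtype=bool).copy()
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("recurrence matrix must be square")
    R |= R.T
    idx = np.arange(n)
    for k in range(0, theiler_w + 1):
        R[idx[: n - k], idx[: n - k] + k] = False
        R[idx[: n - k] + k, idx[: n - k]] = False
    n_valid = int((n - theiler_w) * (n - theiler_w - 1) // 2) if theiler_w < n else 0
    n_rec = int(np.count_nonzero(np.triu(R)))
    return RecurrenceStructure(
        matrix=R,
        rad_pct=rad_pct,
        theiler_w=theiler_w,
        n_valid_pairs=n_valid,
        n_recurrent_pairs=n_rec,
        vertical_hist=_vertical_histogram(R),
        diagonal_hist=_diagonal_histogram(R, theiler_w),
    )


def recurrence_structure(dist: DistanceField, rad_pct: float, theiler_w: int
                         ) -> RecurrenceStructure:
    """Threshold a distance field at ``rad_pct`` (% of max distance).

    ``R[i, j] = 1`` iff the normalized distance is <= rad_pct/100 and
    ``|i−j| > theiler_w``.
    """
    if not 0.0 < rad_pct <= 100.0:
        raise ValueError("rad_pct must be in (0, 100]")
    n = dist.n_states
    mask = _valid_condensed_mask(n, theiler_w)
    rec = (dist.condensed <= rad_pct / 100.0) & mask
    R = squareform(rec)
    return RecurrenceStructure(
        matrix=R,
        rad_pct=rad_pct,
        theiler_w=theiler_w,
        n_valid_pairs=int(np.count_nonzero(mask)),
        n_recurrent_pairs=int(np.count_nonzero(rec)),
        vertical_hist=_vertical_histogram(R),
        diagonal_hist=_diagonal_histogram(R, theiler_w),
    )


def recurrence_rate(structure: RecurrenceStructure) -> float:
    """REC: percentage of valid state pairs that are recurrent."""
    if structure.n_valid_pairs == 0:
        raise RadiusSolveError(
            "no valid pairs: Theiler window covers the whole matrix"
        )
    return 100.0 * structure.n_recurrent_pairs / structure.n_valid_pairs


# ---------------------------------------------------------------------------
# fixed-REC radius solving
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadiusSolution:
    """Result of the adaptive radius search."""

    rad_pct: float
    achieved_rec_pct: float
    attained: bool  # within REC_TOLERANCE_PP of the target


def _sorted_valid_distances(dist: DistanceField, theiler_w: int) -> np.ndarray:
    mask = _valid_condensed_mask(dist.n_states, theiler_w)
    d = np.sort(dist.condensed[mask])
    if d.size == 0:
        raise RadiusSolveError("Theiler window leaves no valid pairs")
    return d


def solve_radius_for_rec(
    dist: DistanceField,
    target_rec_pct: float = DEFAULT_TARGET_REC_PCT,
    theiler_w: int = 0,
    tol: float = 1e-4,
    _sorted: np.ndarray | None = None,
) -> RadiusSolution:
    """Smallest radius (as % of max distance) whose REC reaches the target.

    The radius enters REC only through the count of valid pairwise
    distances below it, so REC(rad) is a non-decreasing step function; the
    search bisects on the normalized radius until the bracket is narrower
    than ``tol``, then reports the upper end (which is guaranteed to reach
    the target).  When tied distances make REC jump over the target the
    overshoot is accepted and flagged via ``attained=False`` if it exceeds
    0.05 percentage points.
    """
    if not 0.0 < target_rec_pct < 100.0:
        if target_rec_pct == 100.0:
            return RadiusSolution(rad_pct=100.0, achieved_rec_pct=100.0,
                                  attained=True)
        raise ValueError("target_rec_pct must be in (0, 100]")
    d = _sorted_valid_distances(dist, theiler_w) if _sorted is None else _sorted
    n_valid = d.size

    def rec_at(rad: float) -> float:
        return 100.0 * np.searchsorted(d, rad, side="right") / n_valid

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if rec_at(mid) >= target_rec_pct:
            hi = mid
        else:
            lo = mid
    achieved = rec_at(hi)
    return RadiusSolution(
        rad_pct=100.0 * hi,
        achieved_rec_pct=achieved,
        attained=abs(achieved - target_rec_pct) <= REC_TOLERANCE_PP,
    )


# ---------------------------------------------------------------------------
# line-based statistics
# ---------------------------------------------------------------------------

def _weighted_sums(hist: np.ndarray, v_min: int) -> tuple[float, float]:
    lengths = np.arange(hist.size)
    total = float(np.sum(lengths * hist))
    qualifying = float(np.sum(lengths[v_min:] * hist[v_min:]))
    return qualifying, total


def laminarity(structure: RecurrenceStructure, v_min: int = DEFAULT_V_MIN
               ) -> float:
    """LAM: fraction of recurrence points on vertical lines of length >= v_min."""
    qual, total = _weighted_sums(structure.vertical_hist, v_min)
    return qual / total if total > 0 else 0.0


def vmax(structure: RecurrenceStructure) -> int:
    """Length of the longest vertical line (0 if none)."""
    nz = np.flatnonzero(structure.vertical_hist)
    return int(nz[-1]) if nz.size else 0


def trapping_time(structure: RecurrenceStructure, v_min: int = DEFAULT_V_MIN
                  ) -> float:
    """TT: mean length of vertical lines of length >= v_min (0 if none)."""
    hist = structure.vertical_hist
    counts = float(np.sum(hist[v_min:]))
    if counts == 0:
        return 0.0
    lengths = np.arange(hist.size)
    return float(np.sum(lengths[v_min:] * hist[v_min:])) / counts


def determinism(structure: RecurrenceStructure, l_min: int = DEFAULT_L_MIN
                ) -> float:
    """DET: fraction of recurrence points on diagonal lines of length >= l_min.

    Diagonals are counted on the upper triangle beyond the Theiler band;
    by symmetry the fraction equals the full-matrix value.
    """
    qual, total = _weighted_sums(structure.diagonal_hist, l_min)
    return qual / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# per-epoch driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RQAMeasures:
    """Full RQA record for one epoch at the solved radius."""

    rec_pct: float
    lam: float
    vmax: int
    tt: float
    det: float
    rad_pct: float
    lam_over_rad: float
    tau: int
    m: int
    theiler_w: int
    n_states: int
    flags: tuple = ()

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def _null_measures(flags: tuple, m: int, tau: int = 0) -> RQAMeasures:
    nan = float("nan")
    return RQAMeasures(
        rec_pct=nan, lam=nan, vmax=0, tt=nan, det=nan, rad_pct=nan,
        lam_over_rad=nan, tau=tau, m=m, theiler_w=(m - 1) * tau,
        n_states=0, flags=flags,
    )


def measures_for_epoch(
    samples: np.ndarray,
    spec: EmbeddingSpec | None = None,
    target_rec_pct: float = DEFAULT_TARGET_REC_PCT,
    v_min: int = DEFAULT_V_MIN,
    l_min: int = DEFAULT_L_MIN,
    m: int = DEFAULT_EMBEDDING_DIM,
) -> RQAMeasures:
    """End-to-end RQA of one epoch.

    When ``spec`` is omitted the delay is selected per epoch from the first
    local minimum of the mutual information and the dimension defaults to
    12.  Degenerate epochs (constant signal, coincident vectors) yield a
    flagged null record rather than raising, so batch runs stay total.
    """
    x = np.asarray(samples, dtype=float)
    try:
        if spec is None:
            spec = EmbeddingSpec(m=m, tau=select_delay(x))
        vecs = embed(x, spec)
        dist = distance_field(vecs)
    except DegenerateSeriesError:
        return _null_measures(("degenerate",), m=m)
    w = spec.theiler_w
    sorted_d = _sorted_valid_distances(dist, w)
    sol = solve_radius_for_rec(dist, target_rec_pct, theiler_w=w,
                               _sorted=sorted_d)
    structure = recurrence_structure(dist, sol.rad_pct, theiler_w=w)
    lam = laminarity(structure, v_min)
    flags = () if sol.attained else ("rec_target_missed",)
    return RQAMeasures(
        rec_pct=recurrence_rate(structure),
        lam=lam,
        vmax=vmax(structure),
        tt=trapping_time(structure, v_min),
        det=determinism(structure, l_min),
        rad_pct=sol.rad_pct,
        lam_over_rad=lam / sol.rad_pct,
        tau=spec.tau,
        m=spec.m,
        theiler_w=w,
        n_states=dist.n_states,
        flags=flags,
    )
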