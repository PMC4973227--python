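"""Takens time-delay embedding with mutual-information delay selection.

State-space reconstruction from a single observable: the epoch
``x_1 … x_N`` is mapped to vectors ``v_i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ})``
in R^m.  The delay τ is chosen per epoch as the first local minimum of the
time-delayed mutual information, and the Theiler exclusion window — the band
of temporally adjacent state pairs removed from recurrence counting to
suppress tangential motion — is ``(m−1)·τ``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import DegenerateSeriesError, EmbeddingError

__all__ = [
    "EmbeddingSpec",
    "StateVectors",
    "DEFAULT_EMBEDDING_DIM",
    "DEFAULT_MAX_LAG",
    "DEFAULT_MI_BINS",
    "mutual_information_curve",
    "first_local_minimum",
    "select_delay",
    "embed",
    "theiler_window",
]

DEFAULT_EMBEDDING_DIM = 12
DEFAULT_MAX_LAG = 100
DEFAULT_MI_BINS = 16


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding dimension m, delay τ (samples) and Theiler half-width.

    ``theiler_w`` is always ``(m−1)·τ``; it is derived, not free.
    """

    m: int
    tau: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")

    @property
    def theiler_w(self) -> int:
        return (self.m - 1) * self.tau

    @property
    def min_length(self) -> int:
        """Shortest series embeddable with this spec (yields 2 states)."""
        return (self.m - 1) * self.tau + 2


@dataclass(frozen=True)
class StateVectors:
    """Reconstructed state vectors for one epoch.

    ``vectors[i, j] == series[i + j*tau]``; ``n_states = N − (m−1)·τ``.
    """

    vectors: np.ndarray
    spec: EmbeddingSpec

    @property
    def n_states(self) -> int:
        return self.vectors.shape[0]


def theiler_window(spec: EmbeddingSpec) -> int:
    """Theiler exclusion half-width ``(m−1)·τ`` in samples."""
    return spec.theiler_w


def _equiprobable_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each sample to one of ``n_bins`` equal-occupancy bins.

    Rank-based (quantile) binning: invariant under any strictly monotone
    transform of the amplitudes, and robust to the outliers expected in
    raw unfiltered signals.
    """
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def mutual_information_curve(
    series: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    n_bins: int = DEFAULT_MI_BINS,
) -> np.ndarray:
    """Time-delayed mutual information MI(k), k = 1 … max_lag, in bits.

    MI(k) is estimated from the 2-D histogram of ``(x_t, x_{t+k})`` with
    equal-occupancy marginal bins.  Returns an array of length ``max_lag``
    whose entry ``[k-1]`` is MI at lag k.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (mutual information undefined).
    """
    x = np.asarray(series, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size <= max_lag + 1:
        raise ValueError(
            f"series length {x.size} must exceed max_lag+1 = {max_lag + 1}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError("constant series: MI undefined")
    bins = _equiprobable_bins(x, n_bins)
    mi = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        a, b = bins[:-k], bins[k:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins)
        joint = joint.reshape(n_bins, n_bins).astype(float)
        n = joint.sum()
        pxy = joint / n
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        mi[k - 1] = float(
            np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz]))
        )
    # estimator is non-negative up to rounding
    return np.maximum(mi, 0.0)


def first_local_minimum(curve: np.ndarray) -> int:
    """First local minimum of a lag-indexed curve (1-based lags).

    Returns the smallest lag k with ``curve(k−1) > curve(k) <= curve(k+1)``
    (strict fall on the left, non-strict on the right, so the first entry
    of a flat valley wins).  If no interior local minimum exists the
    fallback is the first lag where the curve drops below ``curve(1)/e``;
    failing that too, lag 1 — both fallbacks emit a warning.
    """
    c = np.asarray(curve, dtype=float)
    if c.size < 3:
        raise ValueError("curve must have at least 3 points")
    for i in range(1, c.size - 1):
        if c[i - 1] > c[i] <= c[i + 1]:
            return i + 1  # 1-based lag
    thresh = c[0] / np.e
    below = np.flatnonzero(c < thresh)
    if below.size:
        lag = int(below[0]) + 1
        warnings.warn(
            f"no local MI minimum; falling back to first lag below MI(1)/e "
            f"(lag {lag})",
            stacklevel=2,
        )
        return lag
    warnings.warn(
        "no local MI minimum and no 1/e crossing; falling back to lag 1",
        stacklevel=2,
    )
    return 1


def select_delay(
    series: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    n_bins: int = DEFAULT_MI_BINS,
) -> int:
    """Per-epoch delay: first local minimum of the MI curve (with fallback)."""
    max_lag = min(max_lag, len(series) - 2)
    curve = mutual_information_curve(series, max_lag=max_lag, n_bins=n_bins)
    return first_local_minimum(curve)


def embed(series: np.ndarray, spec: EmbeddingSpec) -> StateVectors:
    """Reconstruct delay vectors ``v_i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ})``."""
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < spec.min_length:
        raise EmbeddingError(
            f"series of length {x.size} too short for m={spec.m}, "
            f"tau={spec.tau}: minimum length is {spec.min_length}"
        )
    if spec.m == 1:
        return StateVectors(vectors=x[:, None].copy(), spec=spec)
    span = (spec.m - 1) * spec.tau + 1
    windows = sliding_window_view(x, span)
    return StateVectors(vectors=windows[:, :: spec.tau].copy(), spec=spec)
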