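"""Nonlinearity validation by nonlinear cross-prediction error (NCPE).

Phase-randomized surrogates are unreliable for signals with strong
periodic components, so nonlinearity is instead evidenced through two
properties of nonlinear deterministic systems:

* determinism — a zeroth-order (locally constant) model fitted on one half
  of an epoch can predict the other half better than chance at short
  horizons (``NCPE-det``);
* time irreversibility — the same model predicts the *time-reversed*
  second half poorly (``NCPE-trev``); for a linear Gaussian process, which
  is statistically time-reversible, the two errors are indistinguishable.

Errors are computed for prediction horizons 1…50 and normalized by the
standard deviation of the predicted dataset, so values above 1 mean
"worse than predicting the mean".  Per epoch the two curve maxima
(``max_det``, ``max_trev``) are retained and compared across epochs with
the Mann-Whitney test; a spectral periodicity screen documents, per epoch,
why surrogate testing was not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import welch
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from .embedding import DEFAULT_EMBEDDING_DIM, EmbeddingSpec, embed, select_delay
from .exceptions import PredictionError
from .groupstats import dunn_test, kruskal_groups

__all__ = [
    "NCPEResult",
    "PeriodicityScreen",
    "DEFAULT_STEPS",
    "DEFAULT_K_NEIGHBORS",
    "periodicity_screen",
    "zeroth_order_predict",
    "ncpe_for_epoch",
    "group_ncpe_tests",
]

DEFAULT_STEPS = 50
DEFAULT_K_NEIGHBORS = 5
DEFAULT_PEAK_FACTOR = 10.0


@dataclass(frozen=True)
class PeriodicityScreen:
    """Spectral screen for strong periodic components."""

    periodic: bool
    peak_freqs_hz: np.ndarray
    factor: float


@dataclass(frozen=True)
class NCPEResult:
    """Normalized cross-prediction error curves for one epoch."""

    steps: np.ndarray       # horizons 1 … H
    ncpe_det: np.ndarray    # second half predicted from the first
    ncpe_trev: np.ndarray   # time-reversed second half, same training set
    tau: int
    m: int

    @property
    def max_det(self) -> float:
        return float(np.max(self.ncpe_det))

    @property
    def max_trev(self) -> float:
        return float(np.max(self.ncpe_trev))


def periodicity_screen(
    samples: np.ndarray,
    rate: float,
    factor: float = DEFAULT_PEAK_FACTOR,
    nperseg: int = 1024,
    median_width: int = 31,
) -> PeriodicityScreen:
    """Flag epochs whose Welch spectrum has narrowband peaks.

    A bin is a peak when its power exceeds ``factor`` times the local
    median of the spectrum (running median over ``median_width`` bins);
    the DC bin is ignored.  Epochs flagged periodic are exactly those for
    which phase-randomized surrogate testing would be untrustworthy.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 256:
        raise ValueError("epoch too short for a spectral screen (< 256)")
    freqs, psd = welch(x, fs=rate, nperseg=min(nperseg, x.size))
    local_med = median_filter(psd, size=median_width, mode="nearest")
    flagged = psd > factor * np.maximum(local_med, np.finfo(float).tiny)
    flagged[0] = False  # DC
    return PeriodicityScreen(
        periodic=bool(flagged.any()),
        peak_freqs_hz=freqs[flagged],
        factor=factor,
    )


def zeroth_order_predict(
    train: np.ndarray,
    target: np.ndarray,
    m: int,
    tau: int,
    steps: int = DEFAULT_STEPS,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    theiler_w: int | None = None,
    target_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-step normalized errors of a zeroth-order (local constant) model.

    Both series are embedded with ``(m, tau)``.  For each target state the
    ``k_neighbors`` nearest train states are found (Euclidean norm in the
    reconstructed space) among train states whose full ``steps``-horizon
    future exists; the h-step prediction is the mean of the neighbours'
    h-step scalar futures.  The step-h error is the RMS prediction error
    over all target states whose own h-step future exists, divided by the
    SD of the target series.

    ``target_positions`` (train-state index units) enables Theiler
    exclusion when train and target overlap in time: candidates within
    ``theiler_w`` of a target state's position are not eligible neighbours
    for that state.

    Raises
    ------
    PredictionError
        If fewer than ``k_neighbors`` eligible train states remain.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    train = np.asarray(train, dtype=float)
    target = np.asarray(target, dtype=float)
    spec = EmbeddingSpec(m=m, tau=tau)
    span = (m - 1) * tau
    train_vecs = embed(train, spec).vectors
    target_vecs = embed(target, spec).vectors
    n_train = train_vecs.shape[0]
    n_target = target_vecs.shape[0]
    n_cand = n_train - steps  # candidates with a full steps-horizon future
    if n_cand < k_neighbors:
        raise PredictionError(
            f"only {max(n_cand, 0)} train states have a {steps}-step future; "
            f"{k_neighbors} neighbours requested"
        )
    sd = float(np.std(target))
    if sd == 0.0:
        raise PredictionError("constant target series: normalization SD is 0")

    dists = cdist(target_vecs, train_vecs[:n_cand])
    if target_positions is not None:
        w = span if theiler_w is None else theiler_w
        pos = np.asarray(target_positions, dtype=float)[:, None]
        cand_idx = np.arange(n_cand)[None, :]
        excluded = np.abs(cand_idx - pos) <= w
        if np.any(np.sum(~excluded, axis=1) < k_neighbors):
            raise PredictionError(
                "Theiler exclusion leaves fewer eligible neighbours than "
                f"k={k_neighbors} for some target state"
            )
        dists[excluded] = np.inf
    # k nearest per target state, found once and reused for every horizon
    nbr = np.argpartition(dists, k_neighbors - 1, axis=1)[:, :k_neighbors]

    errors = np.empty(steps)
    for h in range(1, steps + 1):
        # target states whose own h-step future exists
        valid_t = min(n_target, target.size - span - h)
        if valid_t <= 0:
            errors[h - 1] = np.nan
            continue
        truth = target[span + h: span + h + valid_t]
        futures = train[nbr[:valid_t] + span + h]
        pred = futures.mean(axis=1)
        errors[h - 1] = float(np.sqrt(np.mean((pred - truth) ** 2))) / sd
    return errors


def ncpe_for_epoch(
    samples: np.ndarray,
    m: int = DEFAULT_EMBEDDING_DIM,
    tau: int | None = None,
    steps: int = DEFAULT_STEPS,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> NCPEResult:
    """Both NCPE curves (det and trev) and their maxima for one epoch.

    The epoch is split in two halves and the first half serves as the
    training set for both curves:

    * det — the first half predicts the second half (forward time);
    * trev — the first half predicts the *time-reversed* second half.

    Training set and predicted dataset are thus identical between the two
    cases up to the direction of time, so for a time-reversible (linear
    Gaussian) process the two error curves are exchangeable and their
    maxima equidistributed; training on the full epoch instead would give
    the trev case a larger neighbour pool and bias the comparison even
    under the null.  Train and target are disjoint, so no Theiler
    exclusion is needed.

    The delay defaults to the epoch's MI-derived value, matching the
    embedding used for the recurrence analysis; the dimension defaults
    to 12.
    """
    x = np.asarray(samples, dtype=float)
    if tau is None:
        tau = select_delay(x)
    half = x.size // 2
    det = zeroth_order_predict(
        x[:half], x[half:], m=m, tau=tau, steps=steps,
        k_neighbors=k_neighbors,
    )
    trev = zeroth_order_predict(
        x[:half], x[half:][::-1], m=m, tau=tau, steps=steps,
        k_neighbors=k_neighbors,
    )
    return NCPEResult(
        steps=np.arange(1, steps + 1), ncpe_det=det, ncpe_trev=trev,
        tau=tau, m=m,
    )


def group_ncpe_tests(
    results: pd.DataFrame,
    bin_h: float = 24.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin det-vs-trev Mann-Whitney and across-group Kruskal-Wallis/Dunn.

    ``results`` must carry columns ``group``, ``t_hours``, ``max_det``,
    ``max_trev``.  Returns ``(cells, bins)``: one row per (bin, group) with
    medians and the det-vs-trev Mann-Whitney p, and one row per bin with
    the Kruskal-Wallis p over groups (on max_det) and Dunn pairwise
    p-values (Bonferroni-adjusted) when KW is significant.
    """
    df = results.copy()
    df["bin"] = (df["t_hours"] // bin_h).astype(int)
    cell_rows = []
    for (b, g), sub in df.groupby(["bin", "group"], sort=True):
        det = sub["max_det"].to_numpy()
        trev = sub["max_trev"].to_numpy()
        row = {
            "bin": b, "bin_start_h": b * bin_h, "group": g, "n": len(sub),
            "median_det": float(np.median(det)),
            "median_trev": float(np.median(trev)),
            "mw_p": np.nan, "flag": "",
        }
        if len(sub) >= 2:
            row["mw_p"] = float(
                mannwhitneyu(det, trev, alternative="two-sided").pvalue
            )
        else:
            row["flag"] = "too_few"
        cell_rows.append(row)
    cells = pd.DataFrame(cell_rows)

    bin_rows = []
    for b, sub in df.groupby("bin", sort=True):
        samples = {g: s["max_det"].to_numpy() for g, s in sub.groupby("group")}
        kw_p = kruskal_groups(samples)
        row = {"bin": b, "bin_start_h": b * bin_h, "kw_p": kw_p}
        if np.isfinite(kw_p) and kw_p < alpha:
            for (g1, g2), p in dunn_test(samples).items():
                row[f"dunn_{g1}_vs_{g2}"] = p
        bin_rows.append(row)
    return cells, pd.DataFrame(bin_rows)
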