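"""Seeded synthetic signals and three-group cohorts with controlled intermittency.

The study's recordings are electrocorticograms whose dynamics alternate
irregularly between near-periodic laminar phases and bursts — type-I
intermittency.  No such data are deposited, so this module generates
stand-ins spanning the relevant dynamical range:

* ``generate_intermittent_map`` — a Pomeau–Manneville-type circle map whose
  iterates spend long stretches almost constant (laminar phases) between
  reinjection bursts;
* ``generate_ar_linear`` — a stationary Gaussian autoregressive process, the
  linear-stochastic null against which nonlinearity is judged;
* ``generate_periodic_noise`` — sinusoids plus Gaussian noise, the regime in
  which phase-randomized surrogates are unreliable;
* ``generate_cohort`` — a three-group cohort whose per-epoch dynamics is a
  block-wise mixture of the intermittent map and the AR null with a
  time-varying mixture weight λ(t), emulating treatment groups whose
  intermittency prevalence is persistently high, declining, or persistently
  low over 0–144 h.

Everything is deterministic given the seeds: per-subject and per-epoch
streams are derived from the design seed via ``numpy.random.SeedSequence``
spawn keys, so a cohort regenerates bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .exceptions import LamflowError

__all__ = [
    "SignalRecipe",
    "GroupSpec",
    "CohortDesign",
    "SubjectRecord",
    "Cohort",
    "generate_intermittent_map",
    "generate_ar_linear",
    "generate_periodic_noise",
    "generate_recording",
    "generate_mixture_epoch",
    "generate_cohort",
    "lambda_at",
]

#: iterates discarded before the reported series starts
BURN_IN = 1000

#: length (s) of the alternating dynamics blocks used when mixing
MIX_BLOCK_S = 0.5


# ---------------------------------------------------------------------------
# recipes and designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalRecipe:
    """A reproducible description of one synthetic signal.

    Parameters
    ----------
    kind
        One of ``intermittent_map``, ``ar_linear``, ``periodic_noise``,
        ``mixture``.
    params
        Per-kind parameters (see the generator functions).
    rate
        Sampling rate in samples/s.
    duration
        Duration in seconds; ``duration * rate`` must be a positive integer.
    seed
        Seed for the signal's random stream.
    """

    kind: str
    params: dict
    rate: float = 1000.0
    duration: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration * self.rate
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration*rate must be a positive integer, got {n!r}"
            )
        if self.kind not in {
            "intermittent_map", "ar_linear", "periodic_noise", "mixture"
        }:
            raise ValueError(f"unknown signal kind {self.kind!r}")
        lam = self.params.get("lam")
        if lam is not None and not 0.0 <= lam <= 1.0:
            raise ValueError(f"mixture weight lam must be in [0,1], got {lam}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group of a cohort design.

    ``lam_profile`` is a piecewise-linear intermittency weight over time,
    given as ``[(t_hours, lam), ...]`` with 0 <= lam <= 1; it is interpolated
    linearly and held constant beyond the last knot.
    """

    label: str
    n_subjects: int
    lam_profile: tuple  # tuple of (t_hours, lam) pairs

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        prof = tuple((float(t), float(l)) for t, l in self.lam_profile)
        if not prof:
            raise ValueError("lam_profile must have at least one knot")
        for _, l in prof:
            if not 0.0 <= l <= 1.0:
                raise ValueError(f"lam profile value {l} outside [0,1]")
        if any(prof[i + 1][0] < prof[i][0] for i in range(len(prof) - 1)):
            raise ValueError("lam_profile knots must be time-ordered")
        object.__setattr__(self, "lam_profile", prof)


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic multi-subject study.

    Subjects are sampled on the epoch grid ``t = 0, stride_s, 2*stride_s, …``
    strictly below ``duration_h`` hours; each grid point yields one
    continuous ``epoch_len_s`` segment at ``rate`` whose dynamics mixture
    weight is the group's λ profile evaluated at that time.
    """

    groups: tuple  # tuple of GroupSpec
    epoch_len_s: float = 12.0
    stride_s: float = 300.0
    rate: float = 1000.0
    duration_h: float = 144.0
    seed: int = 0

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        labels = [g.label for g in groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if self.epoch_len_s <= 0 or self.stride_s <= 0:
            raise ValueError("epoch_len_s and stride_s must be positive")
        object.__setattr__(self, "groups", groups)

    @property
    def epoch_times_h(self) -> np.ndarray:
        stride_h = self.stride_s / 3600.0
        n = int(math.ceil(self.duration_h / stride_h - 1e-12))
        return np.arange(n) * stride_h


@dataclass
class SubjectRecord:
    """Per-subject output of :func:`generate_cohort`.

    ``epochs`` maps each grid time (hours) to a continuous raw-rate segment.
    """

    subject_id: str
    group: str
    rate: float
    epoch_times_h: np.ndarray
    epochs: list  # list of 1-D arrays, parallel to epoch_times_h
    first_seizure_h: float | None = None


@dataclass
class Cohort:
    design: CohortDesign
    subjects: list = field(default_factory=list)


def lambda_at(profile: Sequence[tuple], t_hours: float) -> float:
    """Piecewise-linear interpolation of a λ-vs-time profile (clamped)."""
    ts = np.array([p[0] for p in profile], dtype=float)
    ls = np.array([p[1] for p in profile], dtype=float)
    return float(np.interp(t_hours, ts, ls))


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def generate_intermittent_map(
    length: int,
    c: float = 0.2,
    z: float = 2.0,
    seed: int | np.random.Generator = 0,
    burn_in: int = BURN_IN,
) -> np.ndarray:
    """Iterate the Pomeau–Manneville-type map ``x → (x + c·x**z) mod 1``.

    Near the marginally stable fixed point at 0 the increments ``c·x**z``
    are tiny, so the orbit lingers in long near-constant laminar stretches;
    reinjection through the mod-1 wrap produces the irregular alternation
    characteristic of type-I intermittency.  The defaults (c=0.2, z=2) put
    laminar durations in the 10²–10³ sample range, so a 12 s epoch contains
    several laminar phases *and* chaotic bursts rather than a single
    phase; much smaller c stretches one laminar phase over the whole
    epoch.

    Parameters
    ----------
    length
        Number of samples returned (after the burn-in).
    c
        Drift coefficient, > 0.  Smaller c lengthens laminar phases.
    z
        Nonlinearity exponent, > 1.
    seed
        Integer seed or an existing ``numpy`` Generator.
    burn_in
        Iterates discarded before recording starts.

    Returns
    -------
    numpy.ndarray
        Series in [0, 1).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if c <= 0:
        raise ValueError("c must be > 0")
    if z <= 1:
        raise ValueError("z must be > 1")
    rng = np.random.default_rng(seed)
    x = float(rng.uniform(1e-6, 1.0 - 1e-6))
    out = np.empty(length)
    total = burn_in + length
    for i in range(total):
        x = (x + c * x ** z) % 1.0
        if not math.isfinite(x):
            raise LamflowError(
                f"intermittent map diverged at step {i} (c={c}, z={z})"
            )
        if i >= burn_in:
            out[i - burn_in] = x
    return out


def generate_ar_linear(
    length: int,
    coefficients: Sequence[float] = (),
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean Gaussian AR(p) realization.

    ``x_t = sum_i a_i x_{t-i} + eps_t`` with ``eps ~ N(0, noise_sd²)``.
    An empty coefficient list gives white noise.  Coefficients must define
    a stationary process (all roots of ``1 - sum a_i L^i`` outside the unit
    circle); a warm-up of 10·p + 100 samples is discarded so the output is
    effectively stationary.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.size:
        # roots of the AR characteristic polynomial 1 - a1 z - ... - ap z^p
        poly = np.concatenate(([1.0], -coeffs))
        roots = np.roots(poly[::-1])
        if np.any(np.abs(roots) <= 1.0 + 1e-12):
            raise ValueError(
                f"AR coefficients {list(coeffs)} are not stationary"
            )
    rng = np.random.default_rng(seed)
    p = coeffs.size
    warm = 10 * p + 100 if p else 0
    eps = rng.normal(0.0, noise_sd, size=length + warm)
    if not p:
        return eps
    x = lfilter([1.0], np.concatenate(([1.0], -coeffs)), eps)
    return x[warm:]


def generate_periodic_noise(
    length: int,
    freqs_hz: Sequence[float],
    amps: Sequence[float],
    noise_sd: float,
    rate: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sum of sinusoids plus Gaussian noise.

    Frequencies must lie strictly below the Nyquist rate ``rate/2``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    freqs = np.asarray(freqs_hz, dtype=float)
    amps_arr = np.asarray(amps, dtype=float)
    if freqs.shape != amps_arr.shape:
        raise ValueError("freqs_hz and amps must have the same length")
    if np.any(freqs >= rate / 2.0):
        raise ValueError(
            f"frequencies {freqs[freqs >= rate / 2].tolist()} are at or above "
            f"Nyquist ({rate / 2} Hz)"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(length) / rate
    x = np.zeros(length)
    for f, a in zip(freqs, amps_arr):
        x += a * np.sin(2.0 * np.pi * f * t)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=length)
    return x


# ---------------------------------------------------------------------------
# mixtures and cohorts
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and rescale to unit SD; a constant segment maps to zeros."""
    sd = float(np.std(x))
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def generate_mixture_epoch(
    length: int,
    lam: float,
    rate: float,
    seed: int | np.random.Generator = 0,
    block_s: float = MIX_BLOCK_S,
    map_params: dict | None = None,
    ar_params: dict | None = None,
) -> np.ndarray:
    """One epoch of block-wise intermittent/AR mixture dynamics.

    Both components are generated over the whole epoch, standardized to unit
    SD (so λ controls the dynamics, not the variance), and then exposed in
    alternating blocks of ``block_s`` seconds, each block drawn Bernoulli(λ)
    intermittent vs. AR.  Block-wise mixing preserves laminar phases that a
    pointwise weighted sum would destroy.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0,1]")
    rng = np.random.default_rng(seed)
    map_params = {"c": 0.2, "z": 2.0, **(map_params or {})}
    ar_params = {"coefficients": (0.9,), "noise_sd": 1.0, **(ar_params or {})}
    comp_map = _standardize(
        generate_intermittent_map(length, seed=rng, **map_params)
    )
    comp_ar = _standardize(
        generate_ar_linear(length, seed=rng, **ar_params)
    )
    block = max(1, int(round(block_s * rate)))
    n_blocks = int(math.ceil(length / block))
    choose_map = rng.random(n_blocks) < lam
    out = np.empty(length)
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, length)
        out[lo:hi] = comp_map[lo:hi] if choose_map[b] else comp_ar[lo:hi]
    return out


def generate_recording(recipe: SignalRecipe) -> np.ndarray:
    """Generate one continuous recording from a :class:`SignalRecipe`."""
    n = recipe.n_samples
    kind, p = recipe.kind, dict(recipe.params)
    if kind == "intermittent_map":
        return generate_intermittent_map(n, seed=recipe.seed, **p)
    if kind == "ar_linear":
        return generate_ar_linear(n, seed=recipe.seed, **p)
    if kind == "periodic_noise":
        return generate_periodic_noise(n, rate=recipe.rate, seed=recipe.seed, **p)
    if kind == "mixture":
        lam = p.pop("lam", 0.5)
        return generate_mixture_epoch(n, lam, recipe.rate, seed=recipe.seed, **p)
    raise ValueError(f"unknown kind {kind!r}")  # pragma: no cover


def _subject_seed_seq(design_seed: int, group_idx: int, subj_idx: int
                      ) -> np.random.SeedSequence:
    # spawn-key derivation: stable across runs and platforms
    return np.random.SeedSequence(design_seed, spawn_key=(group_idx, subj_idx))


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate a seeded multi-group cohort on the design's epoch grid.

    Each subject's record is a sequence of continuous raw-rate epochs at
    ``t = 0, stride, 2·stride, …`` (strictly below ``duration_h``); the
    dynamics of the epoch at time t is a block mixture with weight λ(t)
    taken from the subject's group profile.  Epoch streams are derived from
    ``SeedSequence(design.seed, spawn_key=(group, subject, epoch))`` so two
    runs of the same design are bit-identical.
    """
    times = design.epoch_times_h
    n = int(round(design.epoch_len_s * design.rate))
    cohort = Cohort(design=design)
    for gi, grp in enumerate(design.groups):
        for si in range(grp.n_subjects):
            epochs = []
            for ei, t in enumerate(times):
                ss = np.random.SeedSequence(
                    design.seed, spawn_key=(gi, si, ei)
                )
                lam = lambda_at(grp.lam_profile, float(t))
                epochs.append(
                    generate_mixture_epoch(
                        n, lam, design.rate, seed=np.random.default_rng(ss)
                    )
                )
            cohort.subjects.append(
                SubjectRecord(
                    subject_id=f"{grp.label}-{si + 1:02d}",
                    group=grp.label,
                    rate=design.rate,
                    epoch_times_h=times.copy(),
                    epochs=epochs,
                )
            )
    return cohort
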