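"""End-to-end study orchestration.

Recordings (real or synthetic) are resampled 1000→400 Hz with no other
pre-processing, cut into 12 s (4800-sample) epochs every 5 minutes up to a
stop bound (144 h, or 1 h before the first seizure), and each epoch gets a
full recurrence analysis at the fixed 1% recurrence-rate operating point.
Per-epoch LAM/RAD values are then binned in 24 h windows, compared across
groups with Kruskal-Wallis + Dunn, and summarized as a per-subject ROC from
72 h on; the NCPE validation stage runs on the same epochs when enabled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import resample_poly
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_curve

from .embedding import DEFAULT_EMBEDDING_DIM
from .groupstats import (
    dunn_test,
    kruskal_groups,
    normality_p,
    significance_symbol,
)
from .ncpe import group_ncpe_tests, ncpe_for_epoch, periodicity_screen
from .rqa import (
    DEFAULT_L_MIN,
    DEFAULT_TARGET_REC_PCT,
    DEFAULT_V_MIN,
    measures_for_epoch,
)
from .synthetic import Cohort, CohortDesign, generate_cohort

__all__ = [
    "Epoch",
    "GroupProfile",
    "ROCResult",
    "StudyConfig",
    "StudyResult",
    "resample_recording",
    "sample_epochs",
    "epochs_from_cohort",
    "analyze_epochs",
    "bin_and_test",
    "roc_from_groups",
    "run_study",
]

RATE_IN_DEFAULT = 1000.0
RATE_OUT_DEFAULT = 400.0
EPOCH_LEN_S_DEFAULT = 12.0
STRIDE_S_DEFAULT = 300.0
SEIZURE_LEAD_H = 1.0  # sampling stops this far ahead of the first seizure


@dataclass
class Epoch:
    """A fixed-length analysis window with its provenance."""

    samples: np.ndarray
    rate: float
    subject_id: str
    group: str
    t_hours: float
    flags: tuple = ()


def resample_recording(
    series: np.ndarray,
    rate_in: float = RATE_IN_DEFAULT,
    rate_out: float = RATE_OUT_DEFAULT,
) -> np.ndarray:
    """Anti-aliased rational-ratio resampling (identity when rates match).

    No other filtering is ever applied: the analysis works on raw
    amplitudes so that nonlinear structure is not distorted.
    """
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("rates must be positive")
    if rate_in == rate_out:
        return np.asarray(series, dtype=float)
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return resample_poly(np.asarray(series, dtype=float),
                         frac.numerator, frac.denominator)


def sample_epochs(
    recording: np.ndarray,
    rate: float,
    subject_id: str = "",
    group: str = "",
    epoch_len_s: float = EPOCH_LEN_S_DEFAULT,
    stride_s: float = STRIDE_S_DEFAULT,
    stop_hours: float | None = None,
    first_seizure_hours: float | None = None,
) -> list[Epoch]:
    """Cut a recording into epochs at ``t = 0, stride, 2·stride, …``.

    Epochs start strictly before the stop bound — the earlier of
    ``stop_hours`` and one hour before ``first_seizure_hours`` — and
    windows that would run past the end of the recording are skipped,
    never padded, so every epoch has exactly ``epoch_len_s · rate``
    samples.
    """
    x = np.asarray(recording, dtype=float)
    n_epoch = int(round(epoch_len_s * rate))
    if x.size < n_epoch:
        raise ValueError("recording shorter than one epoch")
    bounds_h = [x.size / rate / 3600.0]
    if stop_hours is not None:
        bounds_h.append(stop_hours)
    if first_seizure_hours is not None:
        bounds_h.append(first_seizure_hours - SEIZURE_LEAD_H)
    stop_h = min(bounds_h)
    epochs = []
    k = 0
    while True:
        t_s = k * stride_s
        t_h = t_s / 3600.0
        start = int(round(t_s * rate))
        if t_h >= stop_h or start + n_epoch > x.size:
            break
        epochs.append(Epoch(
            samples=x[start:start + n_epoch], rate=rate,
            subject_id=subject_id, group=group, t_hours=t_h,
        ))
        k += 1
    return epochs


def epochs_from_cohort(cohort: Cohort,
                       rate_out: float = RATE_OUT_DEFAULT) -> list[Epoch]:
    """Resample every grid epoch of a synthetic cohort to the analysis rate."""
    out = []
    for subj in cohort.subjects:
        for t, ep in zip(subj.epoch_times_h, subj.epochs):
            out.append(Epoch(
                samples=resample_recording(ep, subj.rate, rate_out),
                rate=rate_out,
                subject_id=subj.subject_id,
                group=subj.group,
                t_hours=float(t),
            ))
    return out


# ---------------------------------------------------------------------------
# batch analysis
# ---------------------------------------------------------------------------

def analyze_epochs(
    epochs: list[Epoch],
    m: int = DEFAULT_EMBEDDING_DIM,
    target_rec_pct: float = DEFAULT_TARGET_REC_PCT,
    v_min: int = DEFAULT_V_MIN,
    l_min: int = DEFAULT_L_MIN,
    run_ncpe: bool = False,
    ncpe_steps: int = 50,
    ncpe_k: int = 5,
) -> pd.DataFrame:
    """Run RQA (and optionally NCPE) over a list of epochs.

    Every epoch produces exactly one row; degenerate or failed epochs are
    flagged rather than dropped, so row accounting is conservative.
    """
    rows = []
    for ep in epochs:
        row = {
            "subject_id": ep.subject_id, "group": ep.group,
            "t_hours": ep.t_hours, "n_samples": len(ep.samples),
        }
        meas = measures_for_epoch(
            ep.samples, target_rec_pct=target_rec_pct,
            v_min=v_min, l_min=l_min, m=m,
        )
        row.update({
            "tau": meas.tau, "rad_pct": meas.rad_pct,
            "rec_pct": meas.rec_pct, "lam": meas.lam,
            "lam_over_rad": meas.lam_over_rad, "vmax": meas.vmax,
            "tt": meas.tt, "det": meas.det,
            "flags": ";".join(meas.flags),
        })
        if run_ncpe and not meas.degenerate:
            res = ncpe_for_epoch(ep.samples, m=m, tau=meas.tau,
                                 steps=ncpe_steps, k_neighbors=ncpe_k)
            screen = periodicity_screen(ep.samples, ep.rate)
            row.update({
                "max_det": res.max_det, "max_trev": res.max_trev,
                "periodic": screen.periodic,
            })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binned group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Per-group, per-24-h-bin medians with nonparametric test results."""

    statistic: str
    bin_h: float
    medians: pd.DataFrame   # one row per (bin, group)
    tests: pd.DataFrame     # one row per bin: KW p, Dunn pairwise, symbols


def bin_and_test(
    results: pd.DataFrame,
    statistic: str = "lam_over_rad",
    bin_h: float = 24.0,
    alpha: float = 0.05,
) -> GroupProfile:
    """Bin epoch-level values in ``bin_h``-hour windows and test across groups.

    Per bin: group medians and a D'Agostino-Pearson normality p (recorded
    for the report, never used to switch tests), a Kruskal-Wallis test
    across groups, and Dunn pairwise comparisons (Bonferroni) only when
    the Kruskal-Wallis p falls below ``alpha``.
    """
    df = results.dropna(subset=[statistic]).copy()
    df["bin"] = (df["t_hours"] // bin_h).astype(int)
    med_rows, test_rows = [], []
    for b, sub in df.groupby("bin", sort=True):
        samples = {}
        for g, s in sub.groupby("group"):
            vals = s[statistic].to_numpy()
            samples[g] = vals
            med_rows.append({
                "bin": b, "bin_start_h": b * bin_h, "group": g,
                "n": vals.size, "median": float(np.median(vals)),
                "normality_p": normality_p(vals),
            })
        kw_p = kruskal_groups(samples)
        trow = {"bin": b, "bin_start_h": b * bin_h, "kw_p": kw_p,
                "kw_symbol": significance_symbol(kw_p)}
        if np.isfinite(kw_p) and kw_p < alpha and len(samples) > 1:
            for (g1, g2), p in dunn_test(samples).items():
                trow[f"dunn_{g1}_vs_{g2}"] = p
                trow[f"sym_{g1}_vs_{g2}"] = significance_symbol(p)
        test_rows.append(trow)
    return GroupProfile(
        statistic=statistic, bin_h=bin_h,
        medians=pd.DataFrame(med_rows), tests=pd.DataFrame(test_rows),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    mw_p: float
    n_pos: int
    n_neg: int
    scores: pd.DataFrame


def roc_from_groups(
    results: pd.DataFrame,
    positive_groups,
    score: str = "lam_over_rad",
    from_hours: float = 72.0,
    per_subject: bool = True,
) -> ROCResult:
    """ROC of a statistic for positive vs. other groups, from ``from_hours`` on.

    By default each subject contributes its median score over t >=
    ``from_hours`` (one observation per subject, avoiding
    pseudo-replication); ``per_subject=False`` pools epochs instead.  The
    AUC is the Mann-Whitney rank statistic U/(n_pos·n_neg), with the
    corresponding two-sided p-value.
    """
    if isinstance(positive_groups, str):
        positive_groups = {positive_groups}
    df = results.dropna(subset=[score])
    df = df[df["t_hours"] >= from_hours]
    if per_subject:
        df = (df.groupby(["subject_id", "group"], as_index=False)[score]
                .median())
    labels = df["group"].isin(positive_groups).to_numpy()
    values = df[score].to_numpy()
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes must be non-empty (n_pos={n_pos}, n_neg={n_neg})"
        )
    mw = mannwhitneyu(values[labels], values[~labels],
                      alternative="two-sided")
    auc = float(mw.statistic) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, values)
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, mw_p=float(mw.pvalue),
                     n_pos=n_pos, n_neg=n_neg, scores=df)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Parameters of one batch run; every field is echoed in the run log."""

    design: CohortDesign | None = None
    input_dir: str | None = None
    rate_out: float = RATE_OUT_DEFAULT
    epoch_len_s: float = EPOCH_LEN_S_DEFAULT
    stride_s: float = STRIDE_S_DEFAULT
    m: int = DEFAULT_EMBEDDING_DIM
    target_rec_pct: float = DEFAULT_TARGET_REC_PCT
    v_min: int = DEFAULT_V_MIN
    l_min: int = DEFAULT_L_MIN
    run_ncpe: bool = False
    ncpe_steps: int = 50
    ncpe_k: int = 5
    bin_h: float = 24.0
    roc_from_hours: float = 72.0
    roc_positive_groups: tuple = ()
    roc_per_subject: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = raw.pop("design", None)
        if design is not None:
            from .synthetic import GroupSpec
            groups = tuple(
                GroupSpec(label=g["label"], n_subjects=g["n_subjects"],
                          lam_profile=tuple(map(tuple, g["lam_profile"])))
                for g in design.pop("groups")
            )
            design = CohortDesign(groups=groups, **design)
        if "roc_positive_groups" in raw:
            raw["roc_positive_groups"] = tuple(raw["roc_positive_groups"])
        return cls(design=design, **raw)


@dataclass
class StudyResult:
    per_epoch: pd.DataFrame
    profile: GroupProfile
    roc: ROCResult | None
    ncpe_cells: pd.DataFrame | None
    ncpe_bins: pd.DataFrame | None
    log: list = field(default_factory=list)


def run_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Run the full pipeline and (optionally) write its result tables.

    Deterministic given the design seed: the same config produces
    byte-identical tables.  Every sampled epoch yields exactly one row
    (result or flagged skip).
    """
    log = [f"config: {dataclasses.asdict(config)}"]
    if config.design is not None:
        cohort = generate_cohort(config.design)
        epochs = epochs_from_cohort(cohort, rate_out=config.rate_out)
        log.append(f"generated cohort: {len(cohort.subjects)} subjects, "
                   f"{len(epochs)} epochs")
    elif config.input_dir is not None:
        from .io import load_recording_csv
        epochs = []
        for path in sorted(Path(config.input_dir).glob("*.csv")):
            try:
                samples, meta = load_recording_csv(path)
            except Exception as exc:  # keep batch total
                log.append(f"ERROR reading {path.name}: {exc}")
                continue
            rate_in = meta.get("rate_hz", RATE_IN_DEFAULT)
            rs = resample_recording(samples, rate_in, config.rate_out)
            epochs.extend(sample_epochs(
                rs, config.rate_out,
                subject_id=meta.get("subject_id", path.stem),
                group=meta.get("group", ""),
                epoch_len_s=config.epoch_len_s, stride_s=config.stride_s,
            ))
        log.append(f"loaded {len(epochs)} epochs from {config.input_dir}")
    else:
        epochs = []
        log.append("no inputs configured: empty run")

    per_epoch = analyze_epochs(
        epochs, m=config.m, target_rec_pct=config.target_rec_pct,
        v_min=config.v_min, l_min=config.l_min, run_ncpe=config.run_ncpe,
        ncpe_steps=config.ncpe_steps, ncpe_k=config.ncpe_k,
    )
    n_flagged = 0
    if len(per_epoch):
        n_flagged = int((per_epoch["flags"] != "").sum())
    log.append(f"epochs sampled={len(epochs)} rows={len(per_epoch)} "
               f"flagged={n_flagged}")

    if len(per_epoch):
        profile = bin_and_test(per_epoch, "lam_over_rad", bin_h=config.bin_h)
    else:
        profile = GroupProfile("lam_over_rad", config.bin_h,
                               pd.DataFrame(), pd.DataFrame())

    roc = None
    if config.roc_positive_groups and len(per_epoch):
        try:
            roc = roc_from_groups(
                per_epoch, set(config.roc_positive_groups),
                from_hours=config.roc_from_hours,
                per_subject=config.roc_per_subject,
            )
            log.append(f"ROC: AUC={roc.auc:.3f} p={roc.mw_p:.3g} "
                       f"(n_pos={roc.n_pos}, n_neg={roc.n_neg})")
        except ValueError as exc:
            log.append(f"ROC skipped: {exc}")

    ncpe_cells = ncpe_bins = None
    if config.run_ncpe and len(per_epoch) and "max_det" in per_epoch:
        ncpe_cells, ncpe_bins = group_ncpe_tests(
            per_epoch.dropna(subset=["max_det"]), bin_h=config.bin_h)

    result = StudyResult(per_epoch=per_epoch, profile=profile, roc=roc,
                         ncpe_cells=ncpe_cells, ncpe_bins=ncpe_bins, log=log)
    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def _write_result(result: StudyResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_epoch.to_csv(out / "per_epoch.tsv", sep="\t", index=False)
    result.profile.medians.to_csv(out / "profile_medians.tsv", sep="\t",
                                  index=False)
    result.profile.tests.to_csv(out / "profile_tests.tsv", sep="\t",
                                index=False)
    if result.roc is not None:
        pd.DataFrame({"fpr": result.roc.fpr, "tpr": result.roc.tpr}).to_csv(
            out / "roc_points.tsv", sep="\t", index=False)
        result.roc.scores.to_csv(out / "roc_scores.tsv", sep="\t",
                                 index=False)
    if result.ncpe_cells is not None:
        result.ncpe_cells.to_csv(out / "ncpe_cells.tsv", sep="\t",
                                 index=False)
        result.ncpe_bins.to_csv(out / "ncpe_bins.tsv", sep="\t", index=False)
    (out / "run.log").write_text("\n".join(result.log) + "\n")
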