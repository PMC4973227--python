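"""Plain-text recording and cohort I/O.

Recordings are stored as CSV with ``#``-prefixed metadata header lines
(``rate_hz``, ``group``, ``subject_id``) followed by one sample per line;
cohorts add an ``index.tsv`` (subject_id, group, file, n_epochs,
duration_h).  Cohort subject files carry a ``t_hours`` column so the
epoch sampling grid survives the round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, CohortDesign, SubjectRecord

__all__ = [
    "save_recording_csv",
    "load_recording_csv",
    "save_cohort",
    "load_cohort",
]


def save_recording_csv(path, samples, rate, subject_id="", group=""):
    """Write one continuous recording (one sample per line, metadata header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={rate}\n")
        fh.write(f"# group={group}\n")
        fh.write(f"# subject_id={subject_id}\n")
        np.savetxt(fh, np.asarray(samples, float), fmt="%.10g")
    return path


def _read_meta(path: Path) -> dict:
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").strip().partition("=")
            meta[key] = val
    return meta


def load_recording_csv(path) -> tuple[np.ndarray, dict]:
    """Read a recording written by :func:`save_recording_csv`."""
    path = Path(path)
    meta = _read_meta(path)
    samples = np.loadtxt(path, comments="#")
    meta["rate_hz"] = float(meta.get("rate_hz", "nan"))
    return np.atleast_1d(samples), meta


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as one CSV per subject plus an index TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        fname = f"{subj.subject_id}.csv"
        path = out_dir / fname
        with path.open("w") as fh:
            fh.write(f"# rate_hz={subj.rate}\n")
            fh.write(f"# group={subj.group}\n")
            fh.write(f"# subject_id={subj.subject_id}\n")
            fh.write("t_hours,value\n")
            for t, ep in zip(subj.epoch_times_h, subj.epochs):
                tcol = np.full(ep.size, float(t))
                np.savetxt(fh, np.column_stack([tcol, ep]),
                           fmt=["%.6f", "%.10g"], delimiter=",")
        rows.append({
            "subject_id": subj.subject_id,
            "group": subj.group,
            "file": fname,
            "n_epochs": len(subj.epochs),
            "duration_h": cohort.design.duration_h,
        })
    pd.DataFrame(rows).to_csv(out_dir / "index.tsv", sep="\t", index=False)
    return out_dir


def load_cohort(in_dir, design: CohortDesign | None = None) -> Cohort:
    """Read a cohort written by :func:`save_cohort`."""
    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "index.tsv", sep="\t")
    cohort = Cohort(design=design)
    for _, row in index.iterrows():
        path = in_dir / row["file"]
        meta = _read_meta(path)
        df = pd.read_csv(path, comment="#")
        times, epochs = [], []
        for t, sub in df.groupby("t_hours", sort=True):
            times.append(float(t))
            epochs.append(sub["value"].to_numpy())
        cohort.subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            rate=float(meta.get("rate_hz", "nan")),
            epoch_times_h=np.asarray(times),
            epochs=epochs,
        ))
    return cohort
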