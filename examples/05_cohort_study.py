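"""Run the full pipeline on a small synthetic three-group cohort.

Groups mimic the study design: one group with persistently high
intermittency weight (lambda = 0.8), one whose weight declines to 0.1 by
72 h, and one persistently low (0.1).  The pipeline computes per-epoch
LAM/RAD, bins it in 24 h windows, tests groups with Kruskal-Wallis + Dunn
and builds a per-subject ROC from 72 h on.

Takes a couple of minutes (72 epochs of full recurrence analysis).
"""

from lamflow import StudyConfig, run_study
from lamflow.synthetic import CohortDesign, GroupSpec

design = CohortDesign(
    groups=(
        GroupSpec("alb", 2, ((0.0, 0.8), (144.0, 0.8))),
        GroupSpec("alb+sjn", 2, ((0.0, 0.8), (72.0, 0.1), (144.0, 0.1))),
        GroupSpec("sham", 2, ((0.0, 0.1), (144.0, 0.1))),
    ),
    epoch_len_s=12.0,
    stride_s=12 * 3600.0,  # one epoch every 12 h keeps the demo quick
    rate=1000.0,
    duration_h=144.0,
    seed=0,
)
config = StudyConfig(design=design, roc_positive_groups=("alb",))
result = run_study(config)

print("median LAM/RAD per group and 24 h bin:")
pivot = result.profile.medians.pivot(index="bin_start_h", columns="group",
                                     values="median")
print(pivot.round(4))
print("\nper-bin Kruskal-Wallis p:")
print(result.profile.tests[["bin_start_h", "kw_p"]].round(4).to_string(index=False))
if result.roc is not None:
    print(f"\nROC (alb vs rest, from 72 h, per-subject medians): "
          f"AUC = {result.roc.auc:.2f}")
print("\nThe high-lambda group keeps elevated LAM/RAD throughout; the")
print("declining group falls to the low group's level after 72 h.")
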