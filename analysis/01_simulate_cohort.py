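"""Simulate the study cohort and record who is in it.

Generates 21 neurotypical (NT) and 20 autistic (ASD) synthetic
participants, each with a template-matching observer (decision noise set
for ~75% double-pass choice consistency), AQ/EQ covariates drawn from
group-specific distributions, one 600-trial reverse-correlation session,
one 80-sentence main task, and facial-EMG epochs for every sentence.

Writes results/participants.csv and a per-group summary of the generator
ground truth; the full dataset can be exported with
`vocalsmile simulate` when the (large) raw traces are needed on disk.
"""

import pandas as pd

from _common import RESULTS, SEED, get_cohort

cohort = get_cohort()
cohort.participants.to_csv(RESULTS / "participants.csv", index=False)

truth = pd.DataFrame([
    {"participant": pid, "group": p.group,
     "decision_noise": p.ground_truth["decision_noise"],
     "filter_strength": p.ground_truth["filter_strength"],
     "relaxation_fraction": p.ground_truth["relaxation_fraction"],
     "n_artifact_trials": len(p.ground_truth["artifact_trials"])}
    for pid, p in cohort.data.items()])
truth.to_csv(RESULTS / "ground_truth_summary.csv", index=False)

print(f"simulated cohort (seed {SEED}): "
      f"{(cohort.participants.group == 'NT').sum()} NT + "
      f"{(cohort.participants.group == 'ASD').sum()} ASD participants")
print(cohort.participants.groupby("group")[["aq", "eq"]].mean().round(1))
print("mean artifact trials per session:",
      round(truth["n_artifact_trials"].mean(), 1), "of 80")
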