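"""Preprocess the facial-EMG epochs into windowed z amplitudes.

Runs the full pipeline (50-250 Hz zero-phase band-pass, robust peak-based
artifact rejection, rectified 300 ms envelope, per-trial baseline
z-normalization, window means) and derives the per-participant ZM_filter
and CS_choice difference scores.

Writes results/rejection_log.csv and results/difference_scores.csv; the
large per-trial amplitude table goes to scratch/amplitudes.csv.
"""

from _common import CONFIG, RESULTS, SCRATCH, get_cohort
from vocalsmile import emg
from vocalsmile.pipeline import cohort_amplitudes

cohort = get_cohort(include_revcorr=False)
amps, rejection = cohort_amplitudes(cohort, CONFIG.pipeline)
amps.to_csv(SCRATCH / "amplitudes.csv", index=False)
rejection.to_csv(RESULTS / "rejection_log.csv", index=False)

diffs = emg.difference_scores(amps)
diffs = diffs.merge(cohort.participants, left_on="participant",
                    right_on="participant_id").drop(columns="participant_id")
diffs.to_csv(RESULTS / "difference_scores.csv", index=False)

by_group = rejection.groupby("group")["rejected_fraction"]
print("trials rejected (mean +/- SD):")
for g, frac in by_group:
    print(f"  {g}: {100 * frac.mean():.0f} +/- {100 * frac.std():.0f} %")
print(f"kept {len(amps) // 2} trials across {len(rejection)} participants")
print("mean difference scores by group:")
print(diffs.groupby("group")[["zm_filter", "cs_choice"]].mean().round(3))
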