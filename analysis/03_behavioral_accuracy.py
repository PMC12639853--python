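"""Perceptual accuracy: chance-level tests, group comparison, Bayes factor.

Computes each participant's accuracy (filter-congruent choices over all
rated trials), tests each group against the 0.5 chance level, compares
the groups with a pooled-variance t-test, and quantifies the evidence
with the default JZS Bayes factor.

Writes results/accuracy.csv and results/behavior_stats.json.
"""

import json

import pandas as pd

from _common import CONFIG, RESULTS, get_cohort
from vocalsmile import behavior, stats

cohort = get_cohort(include_emg=False, include_revcorr=False)

rows = []
for pid, p in cohort.data.items():
    s = behavior.perceptual_accuracy(p.behavior)
    rows.append({"participant": pid, "group": p.group,
                 "accuracy": s.accuracy,
                 "n_trials": s.n_smileF + s.n_unsmileF})
acc = pd.DataFrame(rows)
acc.to_csv(RESULTS / "accuracy.csv", index=False)

out = {}
for g in ("NT", "ASD"):
    vals = acc.loc[acc.group == g, "accuracy"]
    t = behavior.test_above_chance(vals)
    out[f"chance_{g}"] = {"mean": vals.mean(), "t": t.t, "df": t.df, "p": t.p}
    print(f"{g}: mean accuracy {vals.mean():.3f}, "
          f"vs chance t({t.df}) = {t.t:.2f}, p = {t.p:.2g}")

gt = stats.two_sample_t(acc.loc[acc.group == "NT", "accuracy"],
                        acc.loc[acc.group == "ASD", "accuracy"])
bf = stats.jzs_bf_ttest(gt.t, 21, 20, prior_scale=CONFIG.prior_scale)
out["group_comparison"] = {"t": gt.t, "df": gt.df, "p": gt.p,
                           "bf10": bf.bf10,
                           "integration_error": bf.integration_error}
print(f"group difference: t({gt.df}) = {gt.t:.2f}, p = {gt.p:.2g}; "
      f"BF10 = {bf.bf10:.3f} "
      f"({'null favored' if bf.bf10 < 1 else 'effect favored'})")

(RESULTS / "behavior_stats.json").write_text(json.dumps(out, indent=2))
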