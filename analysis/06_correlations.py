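"""Correlations between measures and covariates.

Relates the Kernel Distance to perceptual accuracy (pooled and per
group), accuracy to the AQ/EQ questionnaires, and the two muscular
difference scores (ZM_filter vs. CS_choice) within each group.

Writes results/correlations.csv.
"""

import pandas as pd

from _common import CONFIG, RESULTS, get_cohort
from vocalsmile.pipeline import analyze_cohort

cohort = get_cohort()
results = analyze_cohort(cohort, CONFIG)

rows = [{"comparison": name, "r": res.r, "df": res.df,
         "t": res.t, "p": res.p}
        for name, res in results["correlations"].items()]
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "correlations.csv", index=False)

print(table.round(3).to_string(index=False))
sig = table.loc[table.p < CONFIG.alpha, "comparison"].tolist()
print(f"\nsignificant at alpha={CONFIG.alpha}: {sig or 'none'}")
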