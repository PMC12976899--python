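"""Associate factor scores with clinical metadata.

ANOVA for categorical variables (levels with < 3 samples dropped), OLS
for continuous ones, BH adjustment across variables per factor, Tukey
HSD post-hoc for significant categorical hits.
"""

import pandas as pd

from _common import RESULTS, get_cohort, get_model
from mcprog.association import associate, results_table

_, metadata, *_ = get_cohort()
model = get_model()
meta = metadata.drop(columns=["assay"])

for factor in ("Factor1", "Factor2"):
    res = associate(model.Z[factor], meta)
    tab = results_table(res).round(5)
    tab.to_csv(RESULTS / f"04_associations_{factor}.tsv", sep="\t", index=False)
    print(f"\n=== {factor} ===")
    print(tab.to_string(index=False))
    for r in res:
        if r.posthoc is not None:
            print(f"Tukey HSD for {r.variable}:")
            print(r.posthoc.round(4).to_string(index=False))
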