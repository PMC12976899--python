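"""Relate CLR cell-state composition to the recovered program scores.

Within each cell type, state abundances are CLR-transformed (zeros
multiplicatively replaced) and regressed on the two program-matched
factor scores with an assay random intercept; slope t-scores are BH
adjusted across states per score.
"""

import pandas as pd

from _common import RESULTS, get_cohort, get_model, get_views
from mcprog import composition as comp

cells, *_ = get_cohort()
_, norm = get_views()
model = get_model()

scores = model.Z[["Factor1", "Factor2"]]
frames = []
for ct in sorted(norm.views):
    tab = comp.state_composition_table(
        cells.obs, ct, used_samples=norm.present(ct)
    )
    tab.columns = [f"{ct}/{c}" for c in tab.columns]
    frames.append(tab)
clr_all = pd.concat(frames, axis=1)
res = comp.abundance_vs_scores(clr_all, scores, norm.assay)
res = res.round(4)
res.to_csv(RESULTS / "05_composition_slopes.tsv", sep="\t", index=False)

sig = res[res["p_adj"] < 0.05].sort_values("t", ascending=False)
print("significant compositional shifts (BH < 0.05):")
print(sig.to_string(index=False))
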