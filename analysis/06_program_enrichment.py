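"""Score signatures in the program loadings with the ULM engine.

Derives one-vs-rest cell-state marker signatures (t-statistic weights)
within PT and scores them against the acute-program loadings: injured
states' markers should be enriched (positive t) and reference-state
markers depleted.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, get_cohort, get_model
from mcprog import enrichment as enr

cells, *_ = get_cohort()
model = get_model()
*_, truth = get_cohort()

acute_f = model.Z.corrwith(truth.scores["acute"].reindex(model.Z.index)).abs().idxmax()

rows = []
for ct in ("PT", "TAL"):
    sub = cells[cells.obs["cell_type"] == ct]
    expr = pd.DataFrame(
        np.log1p(np.asarray(sub.X.todense(), dtype=float)),
        index=sub.obs_names,
        columns=sub.var_names,
    )
    markers = enr.state_markers(expr, sub.obs["cell_state"], top_n=100)
    loadings = model.W[ct][acute_f]
    for state, sig in markers.items():
        score = enr.ulm(loadings.rename(acute_f), sig)
        rows.append({"cell_type": ct, "state": state, "t": score.t, "p": score.p})
tab = pd.DataFrame(rows).round(4)
tab.to_csv(RESULTS / "06_marker_enrichment.tsv", sep="\t", index=False)
print(f"cell-state marker enrichment in {acute_f} (acute program) loadings:")
print(tab.to_string(index=False))
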