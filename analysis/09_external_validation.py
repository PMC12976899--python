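"""Project the plasma signature onto platform 2 and validate outcomes.

Name-harmonized projection (column z-scaling, weight winsorization at
q99, L2 normalization, score z-standardization), spline association with
the eGFR-like measure, and piecewise Cox models of the AKI-like outcome,
including the four-group dual-hit stratification.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, SCRATCH, SEED, get_cohort, get_model
from mcprog import biofluid as bf
from mcprog import validation as val

cells, metadata, proteins, outcomes, truth = get_cohort()
model = get_model()
sig = bf.load_signature(SCRATCH / "signature_plasma_acute.json")

proj = val.project_signature(sig, proteins["platform2"].values)
r = np.corrcoef(proj["z"], truth.scores["acute"].reindex(proj.index))[0, 1]
print(f"platform-2 projection vs true acute score: r = {r:.3f}")

fs, fl, lrt, p_lin, curve = val.spline_egfr_model(proj["z"], metadata["egfr"], df=4)
curve.round(3).to_csv(RESULTS / "09_egfr_spline_curve.tsv", sep="\t", index=False)
print(f"spline vs linear eGFR model: LRT {lrt:.2f}, p = {p_lin:.3f}")

sub = outcomes[outcomes["outcome"] == "AKI"].set_index("subject_id").copy()
sub["score"] = proj["z"]
hr, _ = val.piecewise_cox(sub.reset_index().dropna(subset=["score"]), "score", [1.0, 3.0])
hr.round(3).to_csv(RESULTS / "09_piecewise_cox_aki.tsv", sep="\t", index=False)
print("piecewise Cox (AKI-like outcome, per-SD projected score):")
print(hr.to_string(index=False))

# dual-hit groups from projected acute + true-chronic-matched factor
chronic_f = model.Z.corrwith(truth.scores["chronic"].reindex(model.Z.index)).abs().idxmax()
groups = val.dual_hit_groups(proj["z"], model.Z[chronic_f])
counts = groups.value_counts()
counts.rename_axis("group").to_frame("n").to_csv(
    RESULTS / "09_dual_hit_groups.tsv", sep="\t"
)
print("dual-hit group sizes:", counts.to_dict())
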