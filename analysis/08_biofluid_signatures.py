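"""Learn plasma and urine protein surrogates of the acute program.

Proteins are restricted to the factor-model gene space, urine values are
creatinine-normalized, both fluids log2-transformed; LASSO with 3-fold
CV (fold-wise scaling, λ by mean CV Spearman) and 500-draw bootstrap
stability. Writes the CV performance and the 20 most stable proteins.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, SCRATCH, SEED, get_cohort, get_model
from mcprog import biofluid as bf

cells, _, proteins, _, truth = get_cohort()
model = get_model()
gene_space = set().union(*(set(w.index) for w in model.W.values()))
acute_f = model.Z.corrwith(truth.scores["acute"].reindex(model.Z.index)).abs().idxmax()
y = model.Z[acute_f]

perf = []
for fluid in ("plasma", "urine"):
    X = bf.restrict_to_gene_space(bf.preprocess(proteins[fluid]), gene_space)
    sig = bf.fit_lasso_cv(X, y, seed=SEED, fluid=fluid, program="acute")
    sig.stability = bf.bootstrap_stability(X, y, sig.lambda_, B=500, seed=SEED)
    bf.save_signature(sig, SCRATCH / f"signature_{fluid}_acute.json")
    top20 = sig.stability.head(20).round(4)
    top20.to_csv(RESULTS / f"08_stability_{fluid}_top20.tsv", sep="\t", index=False)
    perf.append(
        {
            "fluid": fluid,
            "mean_cv_spearman": round(float(np.mean(sig.cv_spearman)), 4),
            "n_selected": int((sig.coef != 0).sum()),
            "lambda": round(sig.lambda_, 5),
        }
    )
    print(f"{fluid}: CV Spearman {perf[-1]['mean_cv_spearman']}, "
          f"{perf[-1]['n_selected']} proteins selected")
    print(top20.head(5).to_string(index=False))
pd.DataFrame(perf).to_csv(RESULTS / "08_signature_performance.tsv", sep="\t", index=False)
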