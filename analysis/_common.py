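"""Shared cohort/model cache for the numbered analysis drivers.

Every driver operates on the same deterministic synthetic cohort
(seed 1, default study conditions). Bulky intermediates live under
scratch/; small result tables go to results/.
"""

import pickle
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 1

warnings.simplefilter("ignore")
SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(parents=True, exist_ok=True)


def get_cohort():
    cache = SCRATCH / "cohort.pkl"
    if cache.exists():
        with open(cache, "rb") as f:
            return pickle.load(f)
    from mcprog import synthetic_cohort as sc

    cohort = sc.generate_cohort(sc.default_spec(seed=SEED))
    with open(cache, "wb") as f:
        pickle.dump(cohort, f)
    return cohort


def get_views():
    cache = SCRATCH / "views.pkl"
    if cache.exists():
        with open(cache, "rb") as f:
            return pickle.load(f)
    from mcprog import pseudobulk as pb

    cells, *_ = get_cohort()
    views = pb.build_views(cells)
    views = pb.filter_views(views)
    norm = views.copy()
    for v in list(norm.views):
        mask = pb.filter_genes(norm.views[v])
        logn = pb.normalize_log1p(norm.views[v].loc[:, mask])
        norm.views[v] = logn[pb.select_hvgs(logn, norm.assay)]
    with open(cache, "wb") as f:
        pickle.dump((views, norm), f)
    return views, norm


def get_model():
    cache = SCRATCH / "model.pkl"
    if cache.exists():
        with open(cache, "rb") as f:
            return pickle.load(f)
    from mcprog import factor_model as fm

    _, metadata, *_ = get_cohort()
    _, norm = get_views()
    model = fm.fit_mcfa(norm, K=7, seed=SEED)
    model = fm.orient_factors(model, metadata["enrollment"], "DM-R")
    with open(cache, "wb") as f:
        pickle.dump(model, f)
    return model
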