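import warnings

import numpy as np
import pytest

from mcprog import biofluid as bf
from mcprog import factor_model as fm
from mcprog import pseudobulk as pb
from mcprog import synthetic_cohort as sc


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (n=100 samples, 1000 genes)."""
    spec = sc.default_spec(seed=0)
    return sc.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort with a minimal gene space, for composition/outcome tests."""
    spec = sc.default_spec(seed=5, n_genes=20)
    return sc.generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_views(cohort):
    cells, *_ = cohort
    views = pb.build_views(cells)
    views = pb.filter_views(views)
    for v in list(views.views):
        mask = pb.filter_genes(views.views[v])
        logn = pb.normalize_log1p(views.views[v].loc[:, mask])
        views.views[v] = logn[pb.select_hvgs(logn, views.assay)]
    return views


@pytest.fixture(scope="session")
def fitted_model(fitted_views, cohort):
    _, metadata, *_ = cohort
    model = fm.fit_mcfa(fitted_views, K=7, seed=0)
    return fm.orient_factors(model, metadata["enrollment"], "DM-R")


@pytest.fixture(scope="session")
def plasma_signature(cohort):
    """Plasma LASSO surrogate of the true acute score (session-shared)."""
    cells, _, proteins, _, truth = cohort
    gene_space = set(cells.var_names)
    X = bf.restrict_to_gene_space(bf.preprocess(proteins["plasma"]), gene_space)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = bf.fit_lasso_cv(X, truth.scores["acute"], seed=0)
    return sig, X


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
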