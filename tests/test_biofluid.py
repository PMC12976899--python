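"""Protein preprocessing, LASSO CV, bootstrap stability, prediction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mcprog import biofluid as bf
from mcprog.synthetic_cohort import ProteinTable


def _table(values, fluid="plasma", creatinine=None):
    df = pd.DataFrame(values)
    df.index = [f"s{i}" for i in range(len(df))]
    creat = None
    if creatinine is not None:
        creat = pd.Series(creatinine, index=df.index)
    return ProteinTable(values=df, fluid=fluid, creatinine=creat)


class TestPreprocess:
    def test_urine_creatinine_ratio_then_log2(self):
        tab = _table({"p1": [8.0]}, fluid="urine", creatinine=[2.0])
        assert bf.preprocess(tab).iloc[0, 0] == pytest.approx(2.0)  # log2(4)

    def test_plasma_log2(self):
        tab = _table({"p1": [1.0]})
        assert bf.preprocess(tab).iloc[0, 0] == 0.0

    def test_zero_creatinine_rejected(self):
        tab = _table({"p1": [8.0]}, fluid="urine", creatinine=[0.0])
        with pytest.raises(ValueError, match="creatinine"):
            bf.preprocess(tab)

    def test_nonpositive_abundance_names_protein(self):
        tab = _table({"bad": [-1.0], "ok": [2.0]})
        with pytest.raises(ValueError, match="bad"):
            bf.preprocess(tab)


def test_gene_space_restriction():
    df = pd.DataFrame({"G0001": [1.0], "DECOY": [1.0]})
    out = bf.restrict_to_gene_space(df, {"G0001"})
    assert list(out.columns) == ["G0001"]
    with pytest.raises(ValueError):
        bf.restrict_to_gene_space(df, {"OTHER"})


def _orthonormal_design(rng, n=64, p=8):
    """Columns orthogonal with mean 0 and Xs^T Xs = n I after scaling."""
    from scipy.linalg import hadamard

    H = hadamard(n).astype(float)[:, 1 : p + 1]  # mean-zero orthogonal columns
    return H  # entries ±1 -> each column already has sd 1


class TestLassoOracles:
    def test_lambda_max_gives_null_model(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 10)))
        X.index = [f"s{i}" for i in range(30)]
        y = pd.Series(rng.normal(size=30), index=X.index)
        Xs = (X - X.mean()) / X.std(ddof=0)
        lmax = bf.lambda_max(Xs.to_numpy(), y.to_numpy())
        coef, _ = bf._fit_lasso(Xs.to_numpy(), y.to_numpy(), lmax * 1.0001)
        assert np.all(coef == 0)

    def test_soft_threshold_on_orthonormal_design(self, rng):
        X = _orthonormal_design(rng)
        n = X.shape[0]
        beta_true = np.array([2.0, -1.0, 0.5, 0.0, 0.0, 0.0, 0.3, -0.2])
        y = X @ beta_true + rng.normal(0, 0.1, n)
        b_ols = X.T @ (y - y.mean()) / n
        for lam in (0.05, 0.3, 0.8):
            coef, _ = bf._fit_lasso(X, y, lam)
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
            assert np.abs(coef - expected).max() < 1e-8

    def test_kkt_at_cv_solution(self, plasma_signature, cohort):
        sig, X = plasma_signature
        *_, truth = cohort
        assert bf.kkt_violation(sig, X, truth.scores["acute"]) < 1e-6


class TestFitLassoCv:
    def test_fold_scaling_no_leakage(self, rng):
        """Shifting one third of the samples' features (a fold's worth)
        must not change coefficients fitted on the remaining samples."""
        X = pd.DataFrame(rng.normal(size=(30, 5)), index=[f"s{i}" for i in range(30)])
        y = pd.Series(X[0] + rng.normal(0, 0.1, 30), index=X.index)
        train = X.index[:20]
        mu, sd = X.loc[train].mean(), X.loc[train].std(ddof=0)
        Xs = ((X.loc[train] - mu) / sd).to_numpy()
        coef_a, _ = bf._fit_lasso(Xs, y.loc[train].to_numpy(), 0.05)
        X_shifted = X.copy()
        X_shifted.loc[X.index[20:]] += 100.0
        mu2, sd2 = X_shifted.loc[train].mean(), X_shifted.loc[train].std(ddof=0)
        Xs2 = ((X_shifted.loc[train] - mu2) / sd2).to_numpy()
        coef_b, _ = bf._fit_lasso(Xs2, y.loc[train].to_numpy(), 0.05)
        assert np.allclose(coef_a, coef_b)

    def test_support_recovery(self, rng):
        """5 strong effects among 200 proteins are selected in >=80% of seeds."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n, p = 90, 200
            X = pd.DataFrame(r.normal(size=(n, p)), index=[f"s{i}" for i in range(n)])
            w = np.zeros(p)
            w[:5] = [3.0, -3.0, 2.5, 2.5, -2.5]
            y = pd.Series(X.to_numpy() @ w + r.normal(0, 1.0, n), index=X.index)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = bf.fit_lasso_cv(X, y, seed=seed, n_lambdas=25)
            hits += set(range(5)) <= set(
                int(c) for c in sig.support
            )
        assert hits >= 0.8 * n_seeds

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"s{i}" for i in range(30)])
        X["const"] = 1.0
        y = pd.Series(X[0] + rng.normal(0, 0.1, 30), index=X.index)
        with pytest.warns(UserWarning, match="constant"):
            sig = bf.fit_lasso_cv(X, y, seed=0, n_lambdas=10)
        assert "const" not in sig.coef.index

    def test_too_few_samples_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"s{i}" for i in range(5)])
        y = pd.Series(rng.normal(size=5), index=X.index)
        with pytest.raises(ValueError, match="samples"):
            bf.fit_lasso_cv(X, y, k=3)


class TestBootstrapStability:
    def test_b_one_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"s{i}" for i in range(20)])
        y = pd.Series(rng.normal(size=20), index=X.index)
        with pytest.raises(ValueError, match="B >= 2"):
            bf.bootstrap_stability(X, y, 0.1, B=1)

    def test_signal_ranked_above_noise(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 30)), index=[f"s{i}" for i in range(80)])
        y = pd.Series(2.0 * X[0] - 2.0 * X[1] + rng.normal(0, 0.5, 80), index=X.index)
        tab = bf.bootstrap_stability(X, y, 0.05, B=60, seed=0)
        top2 = set(tab["protein"].head(2))
        assert top2 == {0, 1}

    def test_zero_coef_proteins_have_zero_stability(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), index=[f"s{i}" for i in range(40)])
        y = pd.Series(rng.normal(size=40), index=X.index)
        tab = bf.bootstrap_stability(X, y, 10.0, B=20, seed=0)  # huge lambda
        assert (tab["inclusion_freq"] == 0).all()
        assert (tab["stability"] == 0).all()


class TestPredict:
    def test_training_row_reproduces_fit(self, plasma_signature):
        sig, X = plasma_signature
        pred = bf.predict_scores(sig, X.iloc[[0]])
        full = bf.predict_scores(sig, X)
        assert pred.iloc[0] == pytest.approx(full.iloc[0])

    def test_mean_profile_predicts_intercept(self, plasma_signature):
        sig, X = plasma_signature
        mean_row = pd.DataFrame([X.mean()], index=["avg"])
        assert bf.predict_scores(sig, mean_row).iloc[0] == pytest.approx(sig.intercept)

    def test_missing_protein_named(self, plasma_signature):
        sig, X = plasma_signature
        with pytest.raises(ValueError, match=sig.coef.index[0]):
            bf.predict_scores(sig, X.drop(columns=[sig.coef.index[0]]))

    def test_heldout_scores_recovered(self, cohort):
        """Fit on 70 samples, predict 30 held out: Spearman > 0.6."""
        cells, _, proteins, _, truth = cohort
        X = bf.restrict_to_gene_space(
            bf.preprocess(proteins["plasma"]), set(cells.var_names)
        )
        y = truth.scores["acute"]
        train, test = X.index[:70], X.index[70:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = bf.fit_lasso_cv(X.loc[train], y.loc[train], seed=0, n_lambdas=25)
        from scipy import stats

        pred = bf.predict_scores(sig, X.loc[test])
        assert stats.spearmanr(pred, y.loc[test]).statistic > 0.6

    def test_plasma_urine_concordance(self, cohort, plasma_signature):
        """Scores predicted from plasma and urine on the same subjects
        are positively correlated."""
        cells, _, proteins, _, truth = cohort
        sig_p, Xp = plasma_signature
        Xu = bf.restrict_to_gene_space(
            bf.preprocess(proteins["urine"]), set(cells.var_names)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig_u = bf.fit_lasso_cv(
                Xu, truth.scores["acute"], seed=0, fluid="urine", n_lambdas=25
            )
        r = np.corrcoef(
            bf.predict_scores(sig_p, Xp), bf.predict_scores(sig_u, Xu)
        )[0, 1]
        assert r > 0.5


def test_signature_roundtrip_json(tmp_path, plasma_signature):
    sig, _ = plasma_signature
    path = tmp_path / "sig.json"
    bf.save_signature(sig, path)
    loaded = bf.load_signature(path)
    assert loaded.lambda_ == sig.lambda_
    pd.testing.assert_series_equal(loaded.coef, sig.coef, check_names=False)
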