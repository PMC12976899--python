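"""ULM activity scoring, marker derivation, program activity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcprog import enrichment as enr


def _sig(weights: dict, name="sig"):
    return enr.Signature(name, pd.Series(weights, dtype=float))


class TestUlm:
    def test_hand_computed_t(self):
        # y=(2,1,0,1), x=(1,1,0,0): b1=1, SSE=1, df=2, Sxx=1 -> t = sqrt(2)
        y = pd.Series([2.0, 1.0, 0.0, 1.0], index=list("abcd"), name="p")
        sig = _sig({"a": 1.0, "b": 1.0})
        score = enr.ulm(y, sig, min_n=2)
        assert score.t == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_perfect_fit_sentinel(self):
        genes = [f"g{i}" for i in range(10)]
        x = pd.Series([3.0, 1.0, 2.0, 0, 0, 0, 0, 0, 0, 0], index=genes)
        y = 3.0 * x
        score = enr.ulm(y.rename("p"), enr.Signature("s", x[x != 0]), min_n=3)
        assert score.t > 1e6 and score.p < 1e-10

    def test_min_overlap_enforced(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"), name="p")
        with pytest.raises(ValueError, match="overlap"):
            enr.ulm(y, _sig({"a": 1.0}))

    def test_constant_weights_rejected(self):
        y = pd.Series(np.arange(6, dtype=float), index=list("abcdef"), name="p")
        with pytest.raises(ValueError, match="degenerate"):
            enr.ulm(y, _sig({g: 1.0 for g in "abcdef"}), min_n=2)

    def test_matches_pearson_transform(self, rng):
        """ULM t equals r*sqrt(df/(1-r^2)) and brute-force OLS."""
        for _ in range(100):
            n = rng.integers(10, 60)
            y = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)], name="p")
            w = rng.normal(size=n)
            w[rng.random(n) < 0.5] = 0.0
            if (w != 0).sum() < 5 or np.ptp(w) == 0:
                continue
            sig = enr.Signature("s", pd.Series(w, index=y.index))
            t = enr.ulm(y, sig).t
            r = np.corrcoef(y, w)[0, 1]
            assert t == pytest.approx(r * np.sqrt((n - 2) / (1 - r**2)), abs=1e-8)
            X = np.column_stack([np.ones(n), w])
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            resid = y.to_numpy() - X @ beta
            se = np.sqrt(
                resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1]
            )
            assert t == pytest.approx(beta[1] / se, abs=1e-8)

    def test_null_permutations_student_t(self, rng):
        """Under independence the ULM t follows Student-t(df): its
        empirical mean is ~0 and a KS test against t(df) does not reject."""
        n = 40
        w = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        sig = enr.Signature("s", w)
        ts = []
        for _ in range(500):
            y = pd.Series(rng.normal(size=n), index=w.index, name="p")
            ts.append(enr.ulm(y, sig).t)
        assert abs(np.mean(ts)) < 0.15
        assert stats.kstest(ts, "t", args=(n - 2,)).pvalue > 0.01

    def test_scale_and_sign_of_weights(self, rng):
        y = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)], name="p")
        w = pd.Series(rng.normal(size=30), index=y.index)
        t0 = enr.ulm(y, enr.Signature("s", w)).t
        assert enr.ulm(y, enr.Signature("s", 5.0 * w)).t == pytest.approx(t0, abs=1e-10)
        assert enr.ulm(y, enr.Signature("s", -w)).t == pytest.approx(-t0, abs=1e-10)


class TestStateMarkers:
    def _expr(self, rng, n_per=20, n_genes=30):
        genes = [f"g{i}" for i in range(n_genes)]
        a = rng.normal(0, 1, (n_per, n_genes))
        b = rng.normal(0, 1, (n_per, n_genes))
        a[:, 0] += 5.0  # g0 exclusively up in state A
        expr = pd.DataFrame(np.vstack([a, b]), columns=genes)
        expr.index = [f"c{i}" for i in range(2 * n_per)]
        states = pd.Series(["A"] * n_per + ["B"] * n_per, index=expr.index)
        return expr, states

    def test_exclusive_gene_ranked_first(self, rng):
        expr, states = self._expr(rng)
        markers = enr.state_markers(expr, states, top_n=10)
        assert markers["A"].weights.index[0] == "g0"
        assert markers["A"].weights.iloc[0] > 0

    def test_permuted_labels_near_chance_overlap(self, rng):
        expr, states = self._expr(rng, n_per=30, n_genes=200)
        markers = enr.state_markers(expr, states, top_n=20)
        perm = pd.Series(
            rng.permutation(states.to_numpy()), index=states.index
        )
        pmarkers = enr.state_markers(expr, perm, top_n=20)
        overlap = len(
            set(markers["A"].weights.index) & set(pmarkers["A"].weights.index)
        )
        # chance expectation 20*20/200 = 2
        assert overlap <= 8

    def test_topn_capped_with_warning(self, rng):
        expr, states = self._expr(rng, n_genes=10)
        with pytest.warns(UserWarning, match="top_n"):
            markers = enr.state_markers(expr, states, top_n=50)
        assert len(markers["A"].weights) == 10

    def test_small_state_skipped(self, rng):
        expr, states = self._expr(rng)
        states.iloc[:2] = "tiny"
        states.iloc[2:20] = "A"
        with pytest.warns(UserWarning, match="tiny"):
            markers = enr.state_markers(expr, states)
        assert "tiny" not in markers


class TestProgramActivity:
    def test_threshold_strictly_greater(self, rng):
        y = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)], name="p")
        loadings = pd.Series(0.1, index=y.index)  # exactly at threshold
        with pytest.raises(ValueError, match="pass"):
            enr.program_activity(y, loadings, threshold=0.1)

    def test_zero_threshold_equals_plain_ulm(self, rng):
        y = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)], name="p")
        loadings = pd.Series(rng.normal(size=20), index=y.index)
        a = enr.program_activity(y, loadings, threshold=0.0)
        b = enr.ulm(y, enr.Signature("program", loadings))
        assert a.t == pytest.approx(b.t, abs=1e-12)

    def test_reconstructed_profiles_rank_by_score(self, fitted_model, cohort):
        """Higher factor score => higher program activity in the
        reconstructed pseudobulk profile."""
        *_, truth = cohort
        Z = fitted_model.Z
        best = Z.corrwith(truth.scores["acute"].reindex(Z.index)).abs().idxmax()
        v = fitted_model.R2[best].idxmax()
        loadings = fitted_model.W[v][best]
        recon = fitted_model.reconstruction(v)
        order = Z.loc[recon.index, best].sort_values()
        lo, hi = order.index[0], order.index[-1]
        acts = {s: enr.program_activity(recon.loc[s], loadings).t for s in (lo, hi)}
        assert acts[hi] > acts[lo]


def test_gmt_and_regulon_readers(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("SET1\tdesc\tg1\tg2\tg3\nSET2\tdesc\tg4\n")
    sigs = enr.read_gmt(gmt)
    assert sigs[0].name == "SET1" and (sigs[0].weights == 1.0).all()
    reg = tmp_path / "reg.tsv"
    reg.write_text("source\ttarget\tweight\nTF1\tg1\t1.5\nTF1\tg2\t-2.0\n")
    regs = enr.read_regulon_tsv(reg)
    assert regs[0].weights["g2"] == -2.0
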