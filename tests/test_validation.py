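"""Projection, eGFR, splines, PheWAS, Cox models, dual-hit groups."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcprog import validation as val
from mcprog.biofluid import SignatureModel


def _sig(weights: dict) -> SignatureModel:
    idx = pd.Index(list(weights))
    return SignatureModel(
        fluid="plasma",
        program="acute",
        intercept=0.0,
        coef=pd.Series(weights),
        feature_means=pd.Series(0.0, index=idx),
        feature_sds=pd.Series(1.0, index=idx),
        lambda_=0.1,
    )


class TestProjection:
    def test_weight_normalization_hand_case(self, rng):
        sig = _sig({"a": 3.0, "b": -1.0, "c": 0.5})
        panel = pd.DataFrame(
            rng.normal(size=(50, 3)), columns=["a", "b", "c"],
            index=[f"u{i}" for i in range(50)],
        )
        proj = val.project_signature(sig, panel)
        # normalized weights (0.9370, -0.3123, 0.1562); reconstruct from scores
        Z = (panel - panel.mean()) / panel.std(ddof=0)
        expected = Z @ np.array([3.0, -1.0, 0.5]) / np.sqrt(10.25)
        assert np.allclose(proj["raw"], expected, atol=1e-10)
        assert abs(proj["z"].mean()) < 1e-12 and proj["z"].std(ddof=0) == pytest.approx(1.0)

    def test_single_shared_protein(self, rng):
        sig = _sig({"a": -2.0, "zzz": 1.0})
        panel = pd.DataFrame({"a": rng.normal(size=30)}, index=[f"u{i}" for i in range(30)])
        proj = val.project_signature(sig, panel)
        z = (panel["a"] - panel["a"].mean()) / panel["a"].std(ddof=0)
        assert np.allclose(proj["z"], -(z - z.mean()) / z.std(ddof=0), atol=1e-10)

    def test_affine_distortion_invariance(self, rng):
        sig = _sig({f"p{i}": w for i, w in enumerate(rng.normal(size=8))})
        panel = pd.DataFrame(
            rng.normal(size=(40, 8)), columns=[f"p{i}" for i in range(8)],
            index=[f"u{i}" for i in range(40)],
        )
        distorted = panel * rng.uniform(0.5, 3.0, 8) + rng.normal(0, 5, 8)
        a = val.project_signature(sig, panel)
        b = val.project_signature(sig, distorted)
        assert np.allclose(a["z"], b["z"], atol=1e-10)

    def test_empty_intersection_rejected(self, rng):
        sig = _sig({"a": 1.0})
        panel = pd.DataFrame({"b": rng.normal(size=10)})
        with pytest.raises(ValueError, match="shared"):
            val.project_signature(sig, panel)


class TestEgfr:
    def test_published_formula_value(self):
        assert val.egfr_ckdepi2021(1.0, 50, "M") == pytest.approx(91.7, abs=0.2)

    def test_at_kappa_only_age_sex_factors_remain(self):
        out = val.egfr_ckdepi2021(0.7, 40, "F")
        assert out == pytest.approx(142 * 0.9938**40 * 1.012, rel=1e-12)
        out_m = val.egfr_ckdepi2021(0.9, 40, "M")
        assert out_m == pytest.approx(142 * 0.9938**40, rel=1e-12)

    def test_monotone_decreasing_in_creatinine(self):
        grid = np.linspace(0.3, 5.0, 50)
        vals = val.egfr_ckdepi2021(grid, np.full(50, 60.0), np.zeros(50, dtype=int))
        assert np.all(np.diff(vals) < 0)

    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            val.egfr_ckdepi2021(1.0, 50, "X")


class TestSpline:
    def _covars(self, rng, n):
        return pd.DataFrame(
            {"age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n)},
            index=[f"u{i}" for i in range(n)],
        )

    def test_df1_reproduces_linear_ols(self, rng):
        n = 200
        score = pd.Series(rng.normal(size=n), index=[f"u{i}" for i in range(n)])
        egfr = pd.Series(90 - 3 * score + rng.normal(0, 5, n), index=score.index)
        fs, fl, lrt, p, _ = val.spline_egfr_model(score, egfr, df=1)
        assert lrt == 0.0 and p == 1.0
        assert np.allclose(fs.params.to_numpy(), fl.params.to_numpy())

    def test_linear_truth_type_one_error(self, rng):
        n_rep, n = 120, 300
        rejections = 0
        for _ in range(n_rep):
            score = pd.Series(rng.normal(size=n), index=[f"u{i}" for i in range(n)])
            egfr = pd.Series(90 - 3 * score + rng.normal(0, 5, n), index=score.index)
            *_, p, _curve = val.spline_egfr_model(score, egfr, df=4)
            rejections += p < 0.05
        assert 0.01 * n_rep <= rejections <= 0.10 * n_rep

    def test_kink_detected(self, rng):
        n_rep, n = 30, 400
        hits = 0
        for _ in range(n_rep):
            score = pd.Series(rng.normal(size=n), index=[f"u{i}" for i in range(n)])
            egfr = pd.Series(
                90 - 8 * np.maximum(score, 0) + rng.normal(0, 5, n), index=score.index
            )
            *_, p, _curve = val.spline_egfr_model(score, egfr, df=4)
            hits += p < 0.05
        assert hits >= 0.9 * n_rep

    def test_collinear_covariates_rejected(self, rng):
        n = 100
        score = pd.Series(rng.normal(size=n), index=[f"u{i}" for i in range(n)])
        egfr = pd.Series(90 + rng.normal(0, 5, n), index=score.index)
        cov = self._covars(rng, n)
        cov["age2"] = 2 * cov["age"]
        with pytest.raises(ValueError, match="collinear"):
            val.spline_egfr_model(score, egfr, covariates=cov, df=3)


class TestPhewas:
    def test_min_cases_exclusion(self, rng):
        n = 500
        score = pd.Series(rng.normal(size=n), index=[f"u{i}" for i in range(n)])
        phen = pd.DataFrame(
            {
                "rare": np.r_[np.ones(19), np.zeros(n - 19)],
                "common": rng.binomial(1, 0.2, n),
            },
            index=score.index,
        )
        out = val.phewas(score, phen)
        status = out.set_index("phenotype")["status"]
        assert status["rare"] == "excluded_min_cases"
        assert status["common"] == "ok"

    def test_null_phenotype_ci_covers_one(self, rng):
        n_rep, n = 60, 400
        covered = 0
        for _ in range(n_rep):
            score = pd.Series(rng.normal(size=n), index=range(n))
            phen = pd.DataFrame({"y": rng.binomial(1, 0.3, n)}, index=score.index)
            row = val.phewas(score, phen).iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 0.85 * n_rep

    def test_liability_phenotype_ranks_first(self, rng):
        n = 2000
        score = pd.Series(rng.normal(size=n), index=range(n))
        liab = score + rng.normal(0, 0.5, n)
        phen = pd.DataFrame(
            {
                "from_score": (liab > liab.quantile(0.7)).astype(int),
                "unrelated1": rng.binomial(1, 0.3, n),
                "unrelated2": rng.binomial(1, 0.2, n),
            },
            index=score.index,
        )
        out = val.phewas(score, phen)
        assert out.iloc[0]["phenotype"] == "from_score"


def _surv_frame(rng, n=2000, beta=0.5, lam0=0.1, horizon=5.0):
    x = rng.normal(0, 1, n)
    t = rng.exponential(1.0 / (lam0 * np.exp(beta * x)))
    return pd.DataFrame(
        {
            "tstart": 0.0,
            "tstop": np.minimum(t, horizon),
            "event": (t <= horizon).astype(int),
            "score": x,
        }
    )


class TestCox:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        df = _surv_frame(rng)
        df["tstop"] = np.round(df["tstop"], 2).clip(lower=0.01)  # induce ties
        fit = val.cox_ph(df, ["score"])
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[["tstop", "event", "score"]],
                duration_col="tstop",
                event_col="event",
            )
        assert fit.coef["score"] == pytest.approx(cph.params_["score"], abs=1e-6)
        assert fit.se["score"] == pytest.approx(
            cph.standard_errors_["score"], abs=1e-6
        )

    def test_two_group_exponential_closed_form(self, rng):
        """log HR within 2 SE of the log rate ratio of two exponential arms."""
        n = 4000
        g = rng.integers(0, 2, n)
        lam = np.where(g == 1, 0.3, 0.1)
        t = rng.exponential(1.0 / lam)
        df = pd.DataFrame(
            {"tstart": 0.0, "tstop": t, "event": 1, "g": g.astype(float)}
        )
        fit = val.cox_ph(df, ["g"])
        assert abs(fit.coef["g"] - np.log(3.0)) < 2 * fit.se["g"]

    def test_permuted_score_null(self, rng):
        df = _surv_frame(rng, beta=0.5)
        df["score"] = rng.permutation(df["score"].to_numpy())
        hr, _ = val.piecewise_cox(df, "score", [1.0, 2.0])
        assert np.nanmax(np.abs(np.log(hr["hr"]))) < 0.15

    def test_single_interval_equals_plain_fit(self, rng):
        df = _surv_frame(rng, n=1500)
        plain = val.cox_ph(df, ["score"])
        _, piece = val.piecewise_cox(df, "score", [])
        assert abs(piece.coef["score_int0"] - plain.coef["score"]) < 1e-8

    def test_episode_split_preserves_likelihood(self, rng):
        """Splitting at non-event cutpoints leaves the fit unchanged."""
        df = _surv_frame(rng, n=1000)
        plain = val.cox_ph(df, ["score"])
        split = val.episode_split(df, [0.5, 1.5, 3.0])
        refit = val.cox_ph(split, ["score"])
        assert abs(refit.coef["score"] - plain.coef["score"]) < 1e-8
        assert abs(refit.loglik - plain.loglik) < 1e-6

    def test_bad_cutpoints_rejected(self, rng):
        df = _surv_frame(rng, n=100)
        with pytest.raises(ValueError, match="increasing"):
            val.episode_split(df, [2.0, 1.0])

    def test_zero_event_interval_reported_missing(self, rng):
        df = _surv_frame(rng, n=300, lam0=0.02)
        df.loc[df["tstop"] < 1.0, "event"] = 0  # no early events
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hr, _ = val.piecewise_cox(df, "score", [0.5, 1.0])
        assert np.isnan(hr.loc[hr["interval"] == 0, "hr"]).all()


class TestDualHit:
    def test_labels(self):
        acute = pd.Series([-1.0, 1.0, -1.0, 1.0], index=list("abcd"))
        chronic = pd.Series([-1.0, -1.0, 1.0, 1.0], index=list("abcd"))
        g = val.dual_hit_groups(acute, chronic)
        assert list(g) == [
            "Reference", "High Acute Only", "High Chronic Only", "Double Hit",
        ]

    def test_median_ties_go_low(self):
        acute = pd.Series([0.0, 0.0, 1.0], index=list("abc"))
        chronic = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        g = val.dual_hit_groups(acute, chronic)
        # chronic median equals every value -> all "low" on chronic
        assert (g == ["Reference", "Reference", "High Acute Only"]).all()

    def test_group_sizes_track_correlation(self, rng):
        """Independent scores give ~25% per group; strong positive
        correlation enriches Reference and Double Hit."""
        n = 4000
        ind = rng.multivariate_normal([0, 0], [[1, 0], [0, 1]], n)
        cor = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], n)
        for arr, enriched in ((ind, False), (cor, True)):
            a = pd.Series(arr[:, 0], index=range(n))
            c = pd.Series(arr[:, 1], index=range(n))
            frac = val.dual_hit_groups(a, c).value_counts(normalize=True)
            both = frac["Reference"] + frac["Double Hit"]
            if enriched:
                assert both > 0.65
            else:
                assert abs(both - 0.5) < 0.05
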