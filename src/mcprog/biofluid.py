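"""Sparse biofluid protein surrogates of program scores.

Urine protein abundances are normalized to urine creatinine; both fluids
are log2-transformed. Proteins are restricted to those whose gene entered
the factor-model gene space. Program scores are predicted by LASSO
regression — objective (1/2n)·||y − b0 − Xb||² + λ||b||₁ — with a k-fold
cross-validation scheme in which fold scaling uses train-fold means/sds
only, λ is chosen to maximize the mean cross-validated Spearman
correlation, and the final model is refit on the fully scaled data.
Coefficient stability is quantified over bootstrap resamples: inclusion
frequency f, mean m and sd s of the coefficient over all draws, and the
stability statistic f·m/s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from .synthetic_cohort import ProteinTable

__all__ = [
    "SignatureModel",
    "preprocess",
    "restrict_to_gene_space",
    "fit_lasso_cv",
    "stability_statistic",
    "bootstrap_stability",
    "predict_scores",
    "lambda_max",
    "save_signature",
    "load_signature",
]


@dataclass
class SignatureModel:
    fluid: str
    program: str
    intercept: float
    coef: pd.Series  # protein -> coefficient (dense over kept proteins)
    feature_means: pd.Series
    feature_sds: pd.Series
    lambda_: float
    cv_spearman: list[float] = field(default_factory=list)
    stability: pd.DataFrame | None = None

    @property
    def support(self) -> pd.Index:
        return self.coef.index[self.coef != 0]


def preprocess(table: ProteinTable) -> pd.DataFrame:
    """Creatinine-normalize (urine) and log2-transform protein abundances."""
    values = table.values
    if table.fluid == "urine":
        if table.creatinine is None:
            raise ValueError("urine table needs a creatinine series")
        creat = table.creatinine.reindex(values.index)
        if np.any(~np.isfinite(creat)) or np.any(creat <= 0):
            raise ValueError("creatinine must be finite and > 0 for all samples")
        values = values.div(creat, axis=0)
    bad = values.columns[(values <= 0).any(axis=0)]
    if len(bad):
        raise ValueError(f"nonpositive abundance at log2 for protein(s): {list(bad)[:5]}")
    return np.log2(values)


def restrict_to_gene_space(values: pd.DataFrame, gene_space: set[str]) -> pd.DataFrame:
    """Keep proteins whose (gene-named) identifier is in the model gene space."""
    keep = [c for c in values.columns if c in gene_space]
    if not keep:
        raise ValueError("no protein maps into the factor-model gene space")
    return values[keep]


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ with an all-zero LASSO solution: max_j |x_j^T (y-ȳ)| / n."""
    yc = y - y.mean()
    return float(np.max(np.abs(X.T @ yc)) / len(y))


def _scale(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (X - means) / sds


def _fit_lasso(Xs: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    model = Lasso(alpha=lam, fit_intercept=True, tol=1e-12, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    return model.coef_.copy(), float(model.intercept_)


def fit_lasso_cv(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 3,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    fluid: str = "plasma",
    program: str = "acute",
    n_lambdas: int = 50,
) -> SignatureModel:
    """Cross-validated LASSO surrogate of one program score.

    λ grid: ``n_lambdas`` log-spaced values from λ_max down to 1e-3·λ_max
    (computed on the fully standardized data); selection by maximum mean
    per-fold Spearman between predictions and held-out scores.
    """
    common = X.index.intersection(y.dropna().index)
    X = X.loc[common]
    y = y.loc[common]
    n = len(X)
    if n < 3 * k:
        raise ValueError(f"need at least {3 * k} samples for {k}-fold CV, got {n}")
    sds_all = X.std(axis=0, ddof=0)
    const = sds_all.index[sds_all == 0]
    if len(const):
        warnings.warn(f"dropping constant protein column(s): {list(const)[:5]}")
        X = X.drop(columns=const)
    Xn = X.to_numpy(dtype=float)
    yn = y.to_numpy(dtype=float)

    means_all = Xn.mean(axis=0)
    sds_all = Xn.std(axis=0, ddof=0)
    Xs_all = _scale(Xn, means_all, sds_all)
    if lambda_grid is None:
        lmax = lambda_max(Xs_all, yn)
        lambda_grid = np.geomspace(lmax, 1e-3 * lmax, n_lambdas)
    lambda_grid = np.asarray(lambda_grid, float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    cv_rho = np.zeros((k, len(lambda_grid)))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        mu = Xn[train_idx].mean(axis=0)
        sd = Xn[train_idx].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr = _scale(Xn[train_idx], mu, sd)
        Xte = _scale(Xn[test_idx], mu, sd)
        for li, lam in enumerate(lambda_grid):
            coef, b0 = _fit_lasso(Xtr, yn[train_idx], lam)
            pred = b0 + Xte @ coef
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(pred, yn[test_idx]).statistic
            cv_rho[fi, li] = rho if np.isfinite(rho) else 0.0
    mean_rho = cv_rho.mean(axis=0)
    best = int(np.argmax(mean_rho))
    lam = float(lambda_grid[best])
    coef, b0 = _fit_lasso(Xs_all, yn, lam)
    return SignatureModel(
        fluid=fluid,
        program=program,
        intercept=b0,
        coef=pd.Series(coef, index=X.columns),
        feature_means=pd.Series(means_all, index=X.columns),
        feature_sds=pd.Series(sds_all, index=X.columns),
        lambda_=lam,
        cv_spearman=list(cv_rho[:, best]),
    )


def stability_statistic(inclusion_freq, mean_coef, sd_coef):
    """Stability = inclusion frequency x mean coefficient / coefficient sd."""
    f = np.asarray(inclusion_freq, dtype=float)
    m = np.asarray(mean_coef, dtype=float)
    s = np.asarray(sd_coef, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            s > 0,
            f * m / np.where(s > 0, s, 1.0),
            np.where(f > 0, np.sign(m) * np.inf, 0.0),
        )
    return out if out.ndim else float(out)


def bootstrap_stability(
    X: pd.DataFrame,
    y: pd.Series,
    lambda_: float,
    B: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap (with replacement) coefficient stability at fixed λ.

    Per protein: inclusion frequency f (nonzero coefficient), mean m and
    sd s over *all* B draws (zeros included), and stability = f·m/s. A
    degenerate s = 0 with f > 0 yields a signed infinity sentinel that
    ranks first by magnitude.
    """
    if B < 2:
        raise ValueError("bootstrap sd undefined for B < 2; need B >= 2")
    common = X.index.intersection(y.dropna().index)
    Xn = X.loc[common].to_numpy(dtype=float)
    yn = y.loc[common].to_numpy(dtype=float)
    n = len(common)
    rng = np.random.default_rng(seed)
    coefs = np.zeros((B, Xn.shape[1]))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, yb = Xn[idx], yn[idx]
        mu = Xb.mean(axis=0)
        sd = Xb.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        coefs[b], _ = _fit_lasso(_scale(Xb, mu, sd), yb, lambda_)
    f = (coefs != 0).mean(axis=0)
    m = coefs.mean(axis=0)
    s = coefs.std(axis=0, ddof=1)
    stability = stability_statistic(f, m, s)
    out = pd.DataFrame(
        {
            "protein": X.columns,
            "inclusion_freq": f,
            "mean_coef": m,
            "sd_coef": s,
            "stability": stability,
        }
    )
    return out.sort_values(
        "stability", key=lambda c: c.abs(), ascending=False
    ).reset_index(drop=True)


def predict_scores(model: SignatureModel, X_new: pd.DataFrame) -> pd.Series:
    """Predict program scores: standardize with stored training means/sds,
    then b0 + Xb. Missing model proteins raise an error naming them."""
    missing = [p for p in model.coef.index if p not in X_new.columns]
    if missing:
        raise ValueError(f"new data lacks model protein(s): {missing[:10]}")
    Xn = X_new[model.coef.index].to_numpy(dtype=float)
    sds = np.where(model.feature_sds.to_numpy() == 0, 1.0, model.feature_sds.to_numpy())
    Xs = (Xn - model.feature_means.to_numpy()) / sds
    pred = model.intercept + Xs @ model.coef.to_numpy()
    return pd.Series(pred, index=X_new.index, name=f"{model.program}_pred")


def kkt_violation(model: SignatureModel, X: pd.DataFrame, y: pd.Series) -> float:
    """Max KKT residual at the solution on the standardized training data.

    For zero coefficients |x_j^T r| / n must not exceed λ; for nonzero
    ones x_j^T r / n must equal λ·sign(b_j). Returns the largest excess.
    """
    common = X.index.intersection(y.dropna().index)
    Xn = X.loc[common, model.coef.index].to_numpy(dtype=float)
    sds = np.where(model.feature_sds.to_numpy() == 0, 1.0, model.feature_sds.to_numpy())
    Xs = (Xn - model.feature_means.to_numpy()) / sds
    yn = y.loc[common].to_numpy(dtype=float)
    r = yn - model.intercept - Xs @ model.coef.to_numpy()
    g = Xs.T @ r / len(yn)
    b = model.coef.to_numpy()
    viol_zero = np.abs(g[b == 0]) - model.lambda_
    viol_nz = np.abs(g[b != 0] - model.lambda_ * np.sign(b[b != 0]))
    parts = [v for v in (viol_zero, viol_nz) if v.size]
    return float(max(np.max(v) for v in parts)) if parts else 0.0


def save_signature(model: SignatureModel, path: str | Path) -> None:
    payload = {
        "fluid": model.fluid,
        "program": model.program,
        "intercept": model.intercept,
        "lambda": model.lambda_,
        "cv_spearman": model.cv_spearman,
        "proteins": list(model.coef.index),
        "coef": model.coef.to_numpy().tolist(),
        "feature_means": model.feature_means.to_numpy().tolist(),
        "feature_sds": model.feature_sds.to_numpy().tolist(),
    }
    if model.stability is not None:
        payload["stability"] = model.stability.to_dict(orient="list")
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_signature(path: str | Path) -> SignatureModel:
    d = json.loads(Path(path).read_text())
    idx = pd.Index(d["proteins"])
    model = SignatureModel(
        fluid=d["fluid"],
        program=d["program"],
        intercept=d["intercept"],
        coef=pd.Series(d["coef"], index=idx),
        feature_means=pd.Series(d["feature_means"], index=idx),
        feature_sds=pd.Series(d["feature_sds"], index=idx),
        lambda_=d["lambda"],
        cv_spearman=d.get("cv_spearman", []),
    )
    if "stability" in d:
        model.stability = pd.DataFrame(d["stability"])
    return model
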