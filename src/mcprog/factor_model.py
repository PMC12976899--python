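"""Multicellular factor analysis: a multi-view Gaussian factor model.

Each cell-type view contributes a (samples x genes) matrix sharing one
sample index; a sample may be missing from any view. The model is

    x_vsg = sum_k z_sk * w_vgk + eps_vsg,   eps ~ N(0, 1/tau_vg)

with shared per-sample scores ``z_s ~ N(0, I_K)``, per-view gene loadings
``W_v`` and per-view per-gene noise precisions. Maximum likelihood is
obtained by EM over the per-sample missing-view patterns; the marginal
log-likelihood is evaluated exactly every iteration (Woodbury identity)
and asserted monotone. Features are centered per sample group (assay)
before fitting, which removes chemistry offsets the way grouped factor
analysis does.

Gaussian factor analysis is identified only up to an invertible
transform of the factor space. Because multicellular programs load
sparsely on genes while their scores are correlated across patients, the
stacked loadings are rotated to the sparsest axis system with an oblique
promax rotation (varimax start, default); scores are counter-rotated so
the reconstruction is unchanged, and factors are ordered by total
variance explained. Sign is fixed separately by :func:`orient_factors`
so that a designated reference group has the lowest scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .pseudobulk import PseudobulkViews

__all__ = [
    "FactorModel",
    "fit_mcfa",
    "variance_explained",
    "orient_factors",
    "varimax",
    "promax",
    "canonical_correlations",
    "save_model",
    "load_model",
]


@dataclass
class FactorModel:
    Z: pd.DataFrame  # samples x K
    W: dict[str, pd.DataFrame]  # view -> genes x K
    tau: dict[str, pd.Series]  # view -> per-gene noise precision
    R2: pd.DataFrame  # views x K variance-explained fractions
    groups: pd.Series | None  # per-sample assay/group label
    K: int
    loglik_path: list[float] = field(default_factory=list)
    centered: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def factor_names(self) -> list[str]:
        return list(self.Z.columns)

    def reconstruction(self, view: str) -> pd.DataFrame:
        W = self.W[view]
        Z = self.Z.loc[self.centered[view].index] if view in self.centered else self.Z
        return pd.DataFrame(
            Z.to_numpy() @ W.to_numpy().T, index=Z.index, columns=W.index
        )


def _center_per_group(df: pd.DataFrame, groups: pd.Series | None) -> pd.DataFrame:
    if groups is None:
        return df - df.mean(axis=0)
    g = groups.reindex(df.index)
    out = df.copy()
    for label in pd.unique(g.dropna()):
        sel = (g == label).to_numpy()
        out.iloc[sel] = df.iloc[sel] - df.iloc[sel].mean(axis=0)
    return out


def promax(loadings: np.ndarray, power: int = 4) -> np.ndarray:
    """Oblique promax rotation; returns the (non-orthogonal) rotation R.

    Varimax first, then a least-squares fit to the powered-loading target.
    Because program scores are correlated in real cohorts, the oblique
    family is the right one: an orthogonal rotation cannot recover
    correlated factors from the whitened EM solution."""
    R_vm = varimax(loadings)
    Lv = loadings @ R_vm
    target = Lv * np.abs(Lv) ** (power - 1)
    U, *_ = np.linalg.lstsq(Lv, target, rcond=None)
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d[None, :]
    return R_vm @ U


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal rotation maximizing the varimax criterion; returns R."""
    p, k = loadings.shape
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (1.0 / p) * L @ np.diag((L**2).sum(axis=0)))
        )
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return R


def fit_mcfa(
    views: PseudobulkViews,
    K: int = 7,
    groups: pd.Series | None = None,
    max_iter: int = 1000,
    tol: float = 1e-4,
    seed: int = 0,
    rotate: str | bool = "promax",
    tau_max: float = 1e10,
) -> FactorModel:
    """Fit the multi-view factor model by EM.

    ``views.views`` must hold normalized (real-valued) matrices. ``groups``
    defaults to ``views.assay``; features are centered within each group
    per view before fitting. Convergence: relative change of the marginal
    log-likelihood below ``tol``. Deterministic given ``seed``.
    """
    if groups is None:
        groups = views.assay
    samples = list(views.samples)
    N = len(samples)
    if K >= N:
        raise ValueError(f"K={K} must be smaller than the number of samples ({N})")
    sample_pos = {s: i for i, s in enumerate(samples)}

    names = sorted(views.views)
    X: dict[str, np.ndarray] = {}
    idx: dict[str, np.ndarray] = {}
    centered: dict[str, pd.DataFrame] = {}
    for v in names:
        df = views.views[v]
        if not np.all(np.isfinite(df.to_numpy())):
            raise ValueError(f"non-finite values in view {v!r}")
        c = _center_per_group(df, groups)
        centered[v] = c
        X[v] = np.ascontiguousarray(c.to_numpy(), dtype=float)
        idx[v] = np.array([sample_pos[s] for s in df.index])

    obs_views = [[] for _ in range(N)]
    for v in names:
        for i in idx[v]:
            obs_views[i].append(v)
    if any(len(o) == 0 for o in obs_views):
        bad = [samples[i] for i, o in enumerate(obs_views) if not o]
        raise ValueError(f"samples present in no view: {bad}")
    patterns: dict[tuple[str, ...], np.ndarray] = {}
    for i, o in enumerate(obs_views):
        patterns.setdefault(tuple(o), []).append(i)
    patterns = {p: np.array(ids) for p, ids in patterns.items()}

    rng = np.random.default_rng(seed)
    W = {v: rng.normal(0.0, 0.1, size=(X[v].shape[1], K)) for v in names}
    tau = {v: np.ones(X[v].shape[1]) for v in names}

    M_rows = np.zeros((N, K))  # posterior means
    loglik_path: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        # per-view sufficient pieces
        B = np.zeros((N, K))
        quad = np.zeros(N)  # x^T Psi^-1 x
        sum_logtau = np.zeros(N)
        C = {v: (W[v] * tau[v][:, None]).T @ W[v] for v in names}  # K x K
        for v in names:
            B[idx[v]] += (X[v] * tau[v][None, :]) @ W[v]
            quad[idx[v]] += (X[v] ** 2 * tau[v][None, :]).sum(axis=1)
            sum_logtau[idx[v]] += np.log(tau[v]).sum()
        Sigma_of = {}
        logdetM = {}
        for pat, ids in patterns.items():
            M = np.eye(K) + sum(C[v] for v in pat)
            Minv = np.linalg.inv(M)
            Minv = 0.5 * (Minv + Minv.T)
            Sigma_of[pat] = Minv
            sign, ld = np.linalg.slogdet(M)
            logdetM[pat] = ld
            M_rows[ids] = B[ids] @ Minv
        # marginal log-likelihood at current parameters
        ll = 0.0
        D_total = 0.0
        for pat, ids in patterns.items():
            D = sum(X[v].shape[1] for v in pat)
            D_total += D * len(ids)
            ll += -0.5 * (
                D * len(ids) * np.log(2 * np.pi)
                - sum_logtau[ids].sum()
                + logdetM[pat] * len(ids)
                + quad[ids].sum()
                - (B[ids] * M_rows[ids]).sum()
            )
        if loglik_path:
            assert ll >= loglik_path[-1] - 1e-6 * (abs(loglik_path[-1]) + 1.0), (
                "EM objective decreased"
            )
        loglik_path.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll

        # M-step
        pat_of_sample = np.empty(N, dtype=object)
        for pat, ids in patterns.items():
            for i in ids:
                pat_of_sample[i] = pat
        for v in names:
            ids = idx[v]
            Mv = M_rows[ids]
            A = Mv.T @ Mv
            for i in ids:
                A += Sigma_of[pat_of_sample[i]]
            Wv = np.linalg.solve(A, Mv.T @ X[v]).T  # genes x K
            resid = (
                (X[v] ** 2).sum(axis=0)
                - 2.0 * np.einsum("sg,sg->g", X[v], Mv @ Wv.T)
                + np.einsum("gk,gk->g", Wv @ A, Wv)
            )
            n_v = len(ids)
            tau[v] = np.clip(n_v / np.maximum(resid, 1e-12), 1e-12, tau_max)
            W[v] = Wv

    Z = M_rows.copy()
    if rotate and K > 1:
        stacked = np.vstack([W[v] for v in names])
        if rotate == "varimax":
            R = varimax(stacked)
        else:
            R = promax(stacked)
        Z = Z @ np.linalg.inv(R).T
        W = {v: W[v] @ R for v in names}

    model = FactorModel(
        Z=pd.DataFrame(Z, index=samples, columns=[f"Factor{k+1}" for k in range(K)]),
        W={
            v: pd.DataFrame(
                W[v], index=views.views[v].columns, columns=[f"Factor{k+1}" for k in range(K)]
            )
            for v in names
        },
        tau={v: pd.Series(tau[v], index=views.views[v].columns) for v in names},
        R2=pd.DataFrame(),
        groups=None if groups is None else groups.reindex(samples),
        K=K,
        loglik_path=loglik_path,
        centered=centered,
    )
    model.R2 = variance_explained(model)
    # order factors by total variance explained
    order = model.R2.sum(axis=0).sort_values(ascending=False).index
    fnames = [f"Factor{k+1}" for k in range(K)]
    model.Z = model.Z[order]
    model.Z.columns = fnames
    for v in names:
        model.W[v] = model.W[v][order]
        model.W[v].columns = fnames
    model.R2 = model.R2[order]
    model.R2.columns = fnames
    return model


def variance_explained(model: FactorModel, views: PseudobulkViews | None = None) -> pd.DataFrame:
    """Per-view, per-factor variance explained.

    ``R2[v,k] = 1 - ||X_v - z_k w_vk^T||^2 / ||X_v||^2`` over non-missing
    samples of the group-centered data; the single-factor definition makes
    factors comparable. Values are floored at 0 (a factor whose rank-one
    reconstruction increases the residual explains nothing).
    """
    if views is not None:
        centered = {
            v: _center_per_group(views.views[v], model.groups) for v in views.views
        }
    else:
        centered = model.centered
    rows = {}
    for v, Xc in centered.items():
        Xn = Xc.to_numpy()
        ss = (Xn**2).sum()
        Zv = model.Z.loc[Xc.index].to_numpy()
        Wv = model.W[v].to_numpy()
        r2 = np.empty(model.K)
        for k in range(model.K):
            resid = Xn - np.outer(Zv[:, k], Wv[:, k])
            r2[k] = 1.0 - (resid**2).sum() / ss if ss > 0 else 0.0
        rows[v] = np.clip(r2, 0.0, 1.0)
    return pd.DataFrame(rows, index=model.Z.columns).T


def orient_factors(
    model: FactorModel, labels: pd.Series, reference: str
) -> FactorModel:
    """Flip factors so the reference group scores lowest.

    For each factor, if the mean score of reference-labelled samples
    exceeds the mean score of the remaining samples, both the factor's
    scores and all its loadings are negated; the reconstruction Z W^T is
    unchanged.
    """
    labels = labels.reindex(model.Z.index)
    if reference not in set(labels.dropna()):
        raise ValueError(f"unknown reference group {reference!r}")
    ref = (labels == reference).to_numpy()
    Z = model.Z.copy()
    W = {v: w.copy() for v, w in model.W.items()}
    for f in Z.columns:
        if Z.loc[ref, f].mean() > Z.loc[~ref, f].mean():
            Z[f] = -Z[f]
            for v in W:
                W[v][f] = -W[v][f]
    return FactorModel(
        Z=Z, W=W, tau=model.tau, R2=model.R2.copy(), groups=model.groups,
        K=model.K, loglik_path=list(model.loglik_path), centered=model.centered,
    )


def canonical_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical correlations between the column spaces of A and B."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def save_model(model: FactorModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Z", data=model.Z.to_numpy())
        f.create_dataset("samples", data=np.array(model.Z.index, dtype="S"))
        f.create_dataset("factors", data=np.array(model.Z.columns, dtype="S"))
        f.attrs["K"] = model.K
        if model.groups is not None:
            f.create_dataset(
                "groups", data=np.array(model.groups.astype(str).to_numpy(), dtype="S")
            )
        wg = f.create_group("W")
        tg = f.create_group("tau")
        for v in sorted(model.W):
            g = wg.create_group(v)
            g.create_dataset("loadings", data=model.W[v].to_numpy())
            g.create_dataset("genes", data=np.array(model.W[v].index, dtype="S"))
            tg.create_dataset(v, data=model.tau[v].to_numpy())
        f.create_dataset("R2", data=model.R2.to_numpy())
        f.create_dataset("R2_views", data=np.array(model.R2.index, dtype="S"))


def load_model(path) -> FactorModel:
    with h5py.File(path, "r") as f:
        samples = [s.decode() for s in f["samples"][...]]
        factors = [s.decode() for s in f["factors"][...]]
        Z = pd.DataFrame(f["Z"][...], index=samples, columns=factors)
        groups = None
        if "groups" in f:
            groups = pd.Series([s.decode() for s in f["groups"][...]], index=samples)
        W = {}
        tau = {}
        for v, g in f["W"].items():
            genes = [s.decode() for s in g["genes"][...]]
            W[v] = pd.DataFrame(g["loadings"][...], index=genes, columns=factors)
            tau[v] = pd.Series(f["tau"][v][...], index=genes)
        r2_views = [s.decode() for s in f["R2_views"][...]]
        R2 = pd.DataFrame(f["R2"][...], index=r2_views, columns=factors)
        return FactorModel(
            Z=Z, W=W, tau=tau, R2=R2, groups=groups, K=int(f.attrs["K"])
        )
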