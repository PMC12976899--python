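"""Weighted gene-signature activity scoring by univariate linear models.

One engine scores every kind of signature used downstream: hallmark-style
gene sets (binary weights), TF regulons (signed interaction weights),
cell-state markers (one-vs-rest t-statistics as weights), and program
loadings (thresholded at |loading| > 0.1). The activity of a signature in
a molecular profile is the t-statistic of the slope from regressing the
profile values on the signature weights over *all* profile genes (absent
genes carry weight 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

__all__ = [
    "Signature",
    "ActivityScore",
    "ulm",
    "ulm_matrix",
    "state_markers",
    "program_activity",
    "read_gmt",
    "read_regulon_tsv",
]

MIN_N = 5


@dataclass(frozen=True)
class Signature:
    name: str
    weights: pd.Series  # gene -> weight


@dataclass(frozen=True)
class ActivityScore:
    signature: str
    profile: str
    t: float
    p: float


def _ulm_t(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    n = len(y)
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate signature: constant weight vector over the profile")
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    b1 = sxy / sxx
    resid = y - y.mean() - b1 * (x - x.mean())
    dof = n - 2
    sse = (resid**2).sum()
    if sse <= 0:
        return np.inf if b1 > 0 else -np.inf, 0.0
    se = np.sqrt(sse / dof / sxx)
    t = b1 / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(p)


def ulm(profile: pd.Series, signature: Signature, min_n: int = MIN_N) -> ActivityScore:
    """Activity of a weighted signature in one molecular profile."""
    overlap = signature.weights.index.intersection(profile.index)
    n_overlap = int((signature.weights.loc[overlap] != 0).sum())
    if n_overlap < min_n:
        raise ValueError(
            f"signature {signature.name!r}: only {n_overlap} weighted genes overlap "
            f"the profile (min_n={min_n})"
        )
    x = signature.weights.reindex(profile.index).fillna(0.0).to_numpy()
    y = profile.to_numpy(dtype=float)
    t, p = _ulm_t(y, x)
    return ActivityScore(signature.name, str(profile.name), t, p)


def ulm_matrix(
    profiles: pd.DataFrame,
    signatures: list[Signature],
    min_n: int = MIN_N,
    adjust: bool = True,
) -> pd.DataFrame:
    """Activity t-statistics for many profiles x signatures (long format)."""
    rows = []
    for sig in signatures:
        for pid in profiles.index:
            try:
                sc = ulm(profiles.loc[pid], sig, min_n=min_n)
            except ValueError:
                continue
            rows.append({"signature": sig.name, "profile": pid, "t": sc.t, "p": sc.p})
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        finite = np.isfinite(out["p"])
        out["p_adj"] = np.nan
        out.loc[finite, "p_adj"] = bh_adjust(out.loc[finite, "p"].to_numpy())
        out.loc[out["p"] == 0.0, "p_adj"] = 0.0
    return out


def state_markers(
    expr: pd.DataFrame,
    states: pd.Series,
    top_n: int = 200,
    min_cells: int = 3,
) -> dict[str, Signature]:
    """One-vs-rest Welch t marker signatures per cell state.

    ``expr`` holds log-normalized cell x gene values within one cell type.
    Genes are BH-adjusted per state and ranked by (adjusted p ascending,
    t descending, gene id); the top ``top_n`` form the signature with the
    t-statistics as weights.
    """
    states = states.reindex(expr.index)
    counts = states.value_counts()
    usable = counts[counts >= min_cells].index
    skipped = counts[counts < min_cells].index.tolist()
    if skipped:
        warnings.warn(f"skipping state(s) with < {min_cells} cells: {skipped}")
    if len(usable) < 2:
        raise ValueError("need >= 2 states with enough cells")
    if top_n > expr.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds gene count {expr.shape[1]}; using all genes"
        )
        top_n = expr.shape[1]
    out: dict[str, Signature] = {}
    X = expr.to_numpy(dtype=float)
    for state in usable:
        in_mask = (states == state).to_numpy()
        a, b = X[in_mask], X[~in_mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, equal_var=False)
        t = np.nan_to_num(t, nan=0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        tab = pd.DataFrame({"gene": expr.columns, "t": t, "p": p})
        tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
        tab = tab.sort_values(
            by=["p_adj", "t", "gene"], ascending=[True, False, True]
        ).head(top_n)
        out[state] = Signature(state, pd.Series(tab["t"].to_numpy(), index=tab["gene"]))
    return out


def program_activity(
    profile: pd.Series,
    loadings: pd.Series,
    threshold: float = 0.1,
    min_n: int = MIN_N,
    name: str = "program",
) -> ActivityScore:
    """Program activity in a profile: ULM with loadings of magnitude
    strictly greater than ``threshold`` as weights."""
    kept = loadings[loadings.abs() > threshold]
    if int((kept != 0).sum()) < min_n:
        raise ValueError(
            f"only {int((kept != 0).sum())} loadings pass |loading| > {threshold}; "
            f"need {min_n}"
        )
    return ulm(profile, Signature(name, kept), min_n=min_n)


def read_gmt(path: str | Path) -> list[Signature]:
    """Read gene sets from GMT (name, description, genes...); weights 1."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name, genes = parts[0], [g for g in parts[2:] if g]
        sigs.append(Signature(name, pd.Series(1.0, index=pd.Index(genes))))
    return sigs


def read_regulon_tsv(path: str | Path) -> list[Signature]:
    """Read a (source, target, weight) TSV into signed regulon signatures."""
    df = pd.read_csv(path, sep="\t")
    need = {"source", "target", "weight"}
    if not need.issubset(df.columns):
        raise ValueError(f"regulon table must have columns {sorted(need)}")
    sigs = []
    for tf, sub in df.groupby("source"):
        sigs.append(
            Signature(str(tf), pd.Series(sub["weight"].to_numpy(), index=sub["target"]))
        )
    return sigs
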