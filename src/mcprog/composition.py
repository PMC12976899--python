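"""Compositional analysis of cell-type and cell-state abundances.

Relative abundances (cell types within a sample, or cell states within
one cell type) are zero-replaced multiplicatively, CLR-transformed, and
regressed on program scores with a random intercept per assay. The
reported quantity is the per-part slope t-score for each program score,
BH-adjusted across parts within each score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace as _multi_replace

from .association import bh_adjust

__all__ = [
    "clr",
    "composition_table",
    "state_composition_table",
    "abundance_vs_scores",
]

DEFAULT_DELTA = 0.001


def clr(props: np.ndarray, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """CLR transform with multiplicative replacement of zeros.

    Zeros become ``delta`` and non-zeros are rescaled by ``1 - z*delta``
    (z = number of zeros in the row) so each row still sums to one, then
    ``clr_i = log(p_i / geometric_mean(p))``.
    """
    arr = np.atleast_2d(np.asarray(props, dtype=float))
    if np.any(arr < 0):
        raise ValueError("proportions must be nonnegative")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each composition must sum to 1")
    z = (arr == 0).sum(axis=1)
    if np.any(z * delta >= 1.0):
        raise ValueError("delta too large for the number of zeros (z*delta >= 1)")
    if np.any(z > 0):
        arr = _multi_replace(arr, delta)
    out = np.atleast_2d(_skbio_clr(arr))
    return out[0] if np.ndim(props) == 1 else out


def composition_table(
    cells_per_type: pd.DataFrame, delta: float = DEFAULT_DELTA
) -> pd.DataFrame:
    """CLR-transformed relative abundances from a samples x parts count table."""
    counts = cells_per_type.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        bad = list(cells_per_type.index[(totals == 0).ravel()])
        raise ValueError(f"samples with no cells: {bad}")
    props = counts / totals
    return pd.DataFrame(
        clr(props, delta), index=cells_per_type.index, columns=cells_per_type.columns
    )


def state_composition_table(
    cells: pd.DataFrame,
    cell_type: str,
    used_samples: list[str] | None = None,
    delta: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """CLR state composition within one cell type.

    ``cells`` is a per-cell annotation frame with columns sample,
    cell_type, cell_state. ``used_samples`` restricts to the sample-cell
    type combinations retained by the factor analysis.
    """
    sub = cells[cells["cell_type"] == cell_type]
    if sub.empty:
        raise ValueError(
            f"unknown cell type {cell_type!r}; known: {sorted(cells['cell_type'].unique())}"
        )
    tab = (
        sub.groupby(["sample", "cell_state"], observed=True).size().unstack(fill_value=0)
    )
    if used_samples is not None:
        tab = tab.loc[[s for s in tab.index if s in set(used_samples)]]
    return composition_table(tab, delta)


def abundance_vs_scores(
    clr_table: pd.DataFrame,
    scores: pd.DataFrame,
    assay: pd.Series | None = None,
) -> pd.DataFrame:
    """Mixed-effect slopes of CLR abundance on program scores.

    One model per part: ``clr ~ score_1 + ... + score_m + (1 | assay)``
    fit by REML; slope t uses residual degrees of freedom. Falls back to
    OLS with a warning when the assay factor has a single level. BH
    adjustment runs across parts within each score column.
    """
    common = clr_table.index.intersection(scores.index)
    clr_t = clr_table.loc[common]
    sc = scores.loc[common]
    score_cols = list(sc.columns)
    rows = []
    for part in clr_t.columns:
        df = sc.copy()
        df["y"] = clr_t[part]
        df = df.dropna()
        n = len(df)
        if n < len(score_cols) + 3:
            continue
        p_fixed = len(score_cols) + 1
        use_ols = assay is None or assay.reindex(df.index).nunique() < 2
        formula = "y ~ " + " + ".join(f"Q('{c}')" for c in score_cols)
        if use_ols:
            if assay is not None:
                warnings.warn("single assay level; falling back to OLS")
            fit = smf.ols(formula, data=df).fit()
        else:
            df["assay"] = assay.reindex(df.index).to_numpy()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = smf.mixedlm(formula, data=df, groups=df["assay"]).fit(reml=True)
            except np.linalg.LinAlgError:
                warnings.warn(f"mixed model singular for part {part!r}; using OLS")
                fit = smf.ols(formula, data=df).fit()
        df_resid = n - p_fixed
        from scipy import stats as ss

        for c in score_cols:
            key = f"Q('{c}')"
            est = float(fit.params[key])
            se = float(fit.bse[key])
            t = est / se if se > 0 else np.inf
            p = 2.0 * ss.t.sf(abs(t), df_resid)
            rows.append({"part": part, "score": c, "estimate": est, "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for c in score_cols:
        sel = out["score"] == c
        out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out
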