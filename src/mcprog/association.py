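"""Associate per-sample factor scores with clinical metadata.

Categorical variables: one-way ANOVA after dropping levels with fewer
than 3 samples; continuous variables: simple OLS with a t-test on the
slope. P-values are Benjamini-Hochberg adjusted across all testable
variables for one factor, and significant categorical variables get a
Tukey HSD post-hoc table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AssociationResult", "associate", "bh_adjust", "anova_oneway", "tukey_hsd"]

MIN_LEVEL_N = 3


@dataclass
class AssociationResult:
    variable: str
    kind: str  # "categorical" | "continuous"
    statistic: float  # F or slope t
    p: float
    p_adj: float
    n: int
    testable: bool = True
    posthoc: pd.DataFrame | None = None
    note: str = ""


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_oneway(values: pd.Series, groups: pd.Series) -> tuple[float, float, int]:
    """One-way ANOVA F and p on levels with >= MIN_LEVEL_N samples.

    A zero within-group mean square with non-zero between-group spread is
    reported as (inf, 0.0) — the degenerate perfect-separation limit.
    """
    df = pd.DataFrame({"y": values, "g": groups}).dropna()
    counts = df["g"].value_counts()
    keep = counts[counts >= MIN_LEVEL_N].index
    df = df[df["g"].isin(keep)]
    levels = [df.loc[df["g"] == l, "y"].to_numpy() for l in keep]
    if len(levels) < 2 or len(df) < MIN_LEVEL_N:
        return np.nan, np.nan, len(df)
    grand = df["y"].mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in levels)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in levels)
    df_b = len(levels) - 1
    df_w = len(df) - len(levels)
    if ssw <= 0:
        return (np.inf, 0.0, len(df)) if ssb > 0 else (np.nan, np.nan, len(df))
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, len(df)


def tukey_hsd(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """All-pairs Tukey HSD (studentized range, pooled within variance)."""
    df = pd.DataFrame({"y": values, "g": groups}).dropna()
    counts = df["g"].value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding singleton level(s) from Tukey HSD: {singletons}")
        df = df[~df["g"].isin(singletons)]
    labels = sorted(df["g"].unique())
    if len(labels) < 2:
        raise ValueError("Tukey HSD needs >= 2 levels with >= 2 samples")
    arrays = [df.loc[df["g"] == l, "y"].to_numpy() for l in labels]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "level_a": labels[i],
                    "level_b": labels[j],
                    "diff": arrays[i].mean() - arrays[j].mean(),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def _is_categorical(col: pd.Series) -> bool:
    return (
        isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == object
        or col.dtype == bool
    )


def associate(
    scores: pd.Series,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> list[AssociationResult]:
    """Test one factor's scores against every metadata column.

    Missing metadata is dropped per variable; untestable variables (fewer
    than 2 usable levels, or fewer than 3 usable samples) are flagged and
    excluded from the BH family.
    """
    results: list[AssociationResult] = []
    for var in metadata.columns:
        col = metadata[var]
        joined = pd.DataFrame({"score": scores, "x": col}).dropna()
        if _is_categorical(col):
            F, p, n = anova_oneway(joined["score"], joined["x"])
            if not np.isfinite(F) and not (F == np.inf):
                results.append(
                    AssociationResult(var, "categorical", np.nan, np.nan, np.nan, n,
                                      testable=False, note="fewer than 2 usable levels")
                )
                continue
            results.append(AssociationResult(var, "categorical", F, p, np.nan, n))
        else:
            if len(joined) < 3 or joined["x"].nunique() < 2:
                results.append(
                    AssociationResult(var, "continuous", np.nan, np.nan, np.nan,
                                      len(joined), testable=False, note="too few samples")
                )
                continue
            lr = stats.linregress(joined["x"], joined["score"])
            t = lr.slope / lr.stderr if lr.stderr > 0 else np.inf
            results.append(
                AssociationResult(var, "continuous", float(t), float(lr.pvalue), np.nan,
                                  len(joined))
            )
    testable = [r for r in results if r.testable and np.isfinite(r.p)]
    if testable:
        adj = bh_adjust([r.p for r in testable])
        for r, a in zip(testable, adj):
            r.p_adj = float(a)
    # degenerate p=0 sentinels keep p_adj = 0
    for r in results:
        if r.testable and r.p == 0.0:
            r.p_adj = 0.0
    if posthoc:
        for r in results:
            if r.kind == "categorical" and r.testable and r.p_adj <= alpha:
                joined = pd.DataFrame({"score": scores, "x": metadata[r.variable]}).dropna()
                counts = joined["x"].value_counts()
                keep = counts[counts >= MIN_LEVEL_N].index
                sub = joined[joined["x"].isin(keep)]
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r.posthoc = tukey_hsd(sub["score"], sub["x"])
                except ValueError:
                    pass
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "type": r.kind,
                "stat": r.statistic,
                "p": r.p,
                "p_adj": r.p_adj,
                "n": r.n,
                "testable": r.testable,
            }
            for r in results
        ]
    )
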