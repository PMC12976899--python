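"""Per-cell-type pseudobulk views: aggregation, QC filters, normalization.

A *view* is a sample x gene matrix obtained by summing raw counts over all
cells of one cell type in each sample. Views share a single ordered sample
index; samples missing a view (too few cells/counts) are masked rather
than imputed. Filtering proceeds in the order: per-profile QC at build
time (min cells, min counts), then view-level representation (drop views
present in too few samples), then sample-level coverage (drop samples
covering too few of the remaining views). The gene space of each view is
filtered independently with an edgeR-style sufficient-counts rule, then
library-size normalized to a common depth and log1p transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PseudobulkViews",
    "build_views",
    "filter_views",
    "filter_genes",
    "normalize_log1p",
    "select_hvgs",
    "save_views",
    "load_views",
]


@dataclass
class PseudobulkViews:
    """Sample x gene count matrices per cell type over a shared sample index."""

    samples: list[str]
    views: dict[str, pd.DataFrame] = field(default_factory=dict)  # rows = present samples
    cell_counts: dict[str, pd.Series] = field(default_factory=dict)
    assay: pd.Series | None = None  # per sample

    def present(self, view: str) -> list[str]:
        return list(self.views[view].index)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean samples x views presence mask."""
        m = pd.DataFrame(False, index=self.samples, columns=list(self.views))
        for v, df in self.views.items():
            m.loc[df.index, v] = True
        return m

    def copy(self) -> "PseudobulkViews":
        return PseudobulkViews(
            samples=list(self.samples),
            views={k: v.copy() for k, v in self.views.items()},
            cell_counts={k: v.copy() for k, v in self.cell_counts.items()},
            assay=None if self.assay is None else self.assay.copy(),
        )


def build_views(
    cells: ad.AnnData, min_cells: int = 25, min_counts: int = 1000
) -> PseudobulkViews:
    """Sum raw counts per (sample, cell type); keep profiles with at least
    ``min_cells`` cells and ``min_counts`` total counts."""
    if cells.n_obs == 0:
        raise ValueError("empty cell table")
    for col in ("sample", "cell_type"):
        if col not in cells.obs:
            raise ValueError(f"cell table lacks obs column {col!r}")
    X = cells.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    samples = list(pd.unique(cells.obs["sample"].astype(str)))
    samples.sort()
    genes = list(cells.var_names)
    assay = None
    if "assay" in cells.obs:
        assay = (
            cells.obs.groupby(cells.obs["sample"].astype(str), observed=True)["assay"]
            .first()
            .reindex(samples)
        )
        assay.name = "assay"
    out = PseudobulkViews(samples=samples, assay=assay)
    ct_labels = cells.obs["cell_type"].astype(str)
    for ct in sorted(pd.unique(ct_labels)):
        sel = (ct_labels == ct).to_numpy()
        sub = X[sel]
        sub_samples = cells.obs["sample"].astype(str).to_numpy()[sel]
        # indicator matrix samples x cells for exact integer summation
        cats = pd.Categorical(sub_samples, categories=samples)
        codes = cats.codes
        ind = sparse.csr_matrix(
            (np.ones(len(codes)), (codes, np.arange(len(codes)))),
            shape=(len(samples), len(codes)),
        )
        agg = np.asarray((ind @ sub).todense())
        ncells = np.bincount(codes, minlength=len(samples))
        keep = (ncells >= min_cells) & (agg.sum(axis=1) >= min_counts)
        if not keep.any():
            continue
        idx = [s for s, k in zip(samples, keep) if k]
        out.views[ct] = pd.DataFrame(agg[keep], index=idx, columns=genes)
        out.cell_counts[ct] = pd.Series(ncells[keep], index=idx)
    if not out.views:
        raise ValueError("no pseudobulk profile passed QC")
    return out


def filter_views(
    views: PseudobulkViews, min_view_frac: float = 0.5, min_sample_frac: float = 0.5
) -> PseudobulkViews:
    """Drop under-represented views, then under-covered samples (that order)."""
    out = views.copy()
    n_samples = len(out.samples)
    keep_views = [
        v for v, df in out.views.items() if len(df) >= min_view_frac * n_samples
    ]
    if not keep_views:
        raise ValueError("all views removed by representation filter")
    out.views = {v: out.views[v] for v in keep_views}
    out.cell_counts = {v: out.cell_counts[v] for v in keep_views}
    n_views = len(keep_views)
    coverage = out.mask.sum(axis=1)
    keep_samples = coverage[coverage >= min_sample_frac * n_views].index
    if len(keep_samples) == 0:
        raise ValueError("all samples removed by coverage filter")
    out.samples = [s for s in out.samples if s in set(keep_samples)]
    for v in list(out.views):
        df = out.views[v]
        idx = [s for s in df.index if s in set(out.samples)]
        out.views[v] = df.loc[idx]
        out.cell_counts[v] = out.cell_counts[v].loc[idx]
    if out.assay is not None:
        out.assay = out.assay.reindex(out.samples)
    return out


def filter_genes(
    counts: pd.DataFrame,
    min_count: int = 10,
    min_total: int = 15,
    min_prop: float = 0.7,
    groups: pd.Series | None = None,
) -> pd.Series:
    """edgeR ``filterByExpr``-style gene mask for one view.

    Keep a gene iff its CPM exceeds the CPM equivalent of ``min_count``
    (at the median library size) in at least ``k = min_prop * smallest
    group size`` samples (all samples forming one group when ``groups`` is
    None), and its total count across samples is at least ``min_total``.
    """
    lib = counts.sum(axis=1).to_numpy().astype(float)
    if np.any(lib <= 0):
        bad = list(counts.index[lib <= 0])
        raise ValueError(f"zero-library sample(s): {bad}")
    if groups is None:
        smallest = len(counts)
    else:
        smallest = int(groups.reindex(counts.index).value_counts().min())
    k = min_prop * smallest
    cpm_cutoff = min_count / np.median(lib) * 1e6
    cpm = counts.to_numpy() / lib[:, None] * 1e6
    n_pass = (cpm >= cpm_cutoff).sum(axis=0)
    total = counts.sum(axis=0).to_numpy()
    mask = (n_pass >= k) & (total >= min_total)
    return pd.Series(mask, index=counts.columns)


def normalize_log1p(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Scale each profile to ``target_sum`` total counts, then log1p."""
    if counts.empty:
        return counts.astype(float)
    lib = counts.sum(axis=1).to_numpy().astype(float)
    scale = np.divide(target_sum, lib, out=np.zeros_like(lib), where=lib > 0)
    return pd.DataFrame(
        np.log1p(counts.to_numpy() * scale[:, None]),
        index=counts.index,
        columns=counts.columns,
    )


def select_hvgs(
    lognorm: pd.DataFrame, assay: pd.Series | None = None, n_top: int = 2000
) -> pd.Index:
    """Highly variable genes: top ``n_top`` by variance of the
    log-normalized values per assay, union over assays."""
    if assay is None:
        var = lognorm.var(axis=0)
        return var.sort_values(ascending=False).index[:n_top]
    chosen: set[str] = set()
    for a in pd.unique(assay.reindex(lognorm.index).dropna()):
        sub = lognorm.loc[assay.reindex(lognorm.index) == a]
        if len(sub) < 2:
            continue
        var = sub.var(axis=0)
        chosen |= set(var.sort_values(ascending=False).index[:n_top])
    if not chosen:
        var = lognorm.var(axis=0)
        chosen = set(var.sort_values(ascending=False).index[:n_top])
    return pd.Index([g for g in lognorm.columns if g in chosen])


def save_views(views: PseudobulkViews, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.array(views.samples, dtype="S"))
        if views.assay is not None:
            f.create_dataset(
                "assay", data=np.array(views.assay.astype(str).to_numpy(), dtype="S")
            )
        grp = f.create_group("views")
        for name in sorted(views.views):
            df = views.views[name]
            g = grp.create_group(name)
            g.create_dataset("matrix", data=df.to_numpy())
            g.create_dataset("samples", data=np.array(df.index, dtype="S"))
            g.create_dataset("genes", data=np.array(df.columns, dtype="S"))
            g.create_dataset(
                "cell_counts", data=views.cell_counts[name].to_numpy()
            )


def load_views(path: str | Path) -> PseudobulkViews:
    with h5py.File(path, "r") as f:
        samples = [s.decode() for s in f["samples"][...]]
        assay = None
        if "assay" in f:
            assay = pd.Series([s.decode() for s in f["assay"][...]], index=samples)
        out = PseudobulkViews(samples=samples, assay=assay)
        for name, g in f["views"].items():
            idx = [s.decode() for s in g["samples"][...]]
            cols = [s.decode() for s in g["genes"][...]]
            out.views[name] = pd.DataFrame(g["matrix"][...], index=idx, columns=cols)
            out.cell_counts[name] = pd.Series(g["cell_counts"][...], index=idx)
    return out
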