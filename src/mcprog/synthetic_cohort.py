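"""Synthetic patient cohort with known acute/chronic program scores.

Generates every input the downstream pipeline consumes — a cell x gene
count table with sample/assay/cell-type/cell-state labels, per-sample
clinical metadata, two biofluid protein panels on distinct platforms, and
a survival outcome table — from two latent per-sample scores ("acute" and
"chronic" program activity). The latent scores drive

* cell-state composition: within each cell type, state proportions are
  softmax(baseline logit + acute_slope * s_a + chronic_slope * s_c);
* molecular state: per-cell negative-binomial counts whose log-rate adds
  sparse per-cell-type gene loadings scaled by the scores;
* metadata: monotone functions of the scores plus noise (eGFR-like,
  fibrosis-like, ordinal stage/risk, enrollment-like category);
* protein panels: platform 1 is a linear read-out of the scores per
  protein; platform 2 is an affine per-protein distortion of a
  name-overlapping platform-1 subset plus independent noise;
* outcomes: exponential event times with log-hazard linear in the
  standardized scores, administratively censored.

The ground truth (scores, state proportions, loadings, protein weights,
hazard coefficients) is returned alongside so tests can score recovery;
pipeline stages never read it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "StateSpec",
    "CellTypeSpec",
    "GroupSpec",
    "ProteinSpec",
    "Panel2Spec",
    "CohortSpec",
    "CohortTruth",
    "ProteinTable",
    "generate_cohort",
    "simulate_outcomes",
    "default_spec",
    "write_cohort",
]

# fixed offsets for per-stage substreams of the cohort seed
_STREAMS = {
    "scores": 0,
    "cells": 1,
    "genes": 2,
    "metadata": 3,
    "proteins": 4,
    "outcomes": 5,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],)))


@dataclass(frozen=True)
class StateSpec:
    name: str
    baseline_logit: float
    acute_slope: float = 0.0
    chronic_slope: float = 0.0


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    baseline_fraction: float
    states: tuple[StateSpec, ...]
    # score -> cell-type-level abundance shift (softmax over type logits)
    acute_slope: float = 0.0
    chronic_slope: float = 0.0
    # scale of the sparse molecular loadings for this type
    acute_loading_scale: float = 0.5
    chronic_loading_scale: float = 0.5


@dataclass(frozen=True)
class GroupSpec:
    label: str
    fraction: float
    mean_acute: float
    mean_chronic: float


@dataclass(frozen=True)
class ProteinSpec:
    name: str
    acute_weight: float
    chronic_weight: float
    noise_sd: float


@dataclass(frozen=True)
class Panel2Spec:
    """Platform-2 protein: affine distortion of the same-named platform-1 protein."""

    name: str
    scale: float
    offset: float
    noise_sd: float


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int
    groups: tuple[GroupSpec, ...]
    cell_types: tuple[CellTypeSpec, ...]
    n_genes: int
    library_size: float
    nb_dispersion: float
    protein_panel: tuple[ProteinSpec, ...]
    panel2: tuple[Panel2Spec, ...]
    hazard_coefs: dict[str, tuple[float, float]]
    seed: int
    score_sd: float = 1.0
    score_corr: float = 0.4
    mean_cells_per_sample: float = 150.0
    loading_sparsity: float = 0.8
    n_state_markers: int = 25
    state_marker_effect: float = 1.5
    assay_fractions: tuple[float, float] = (0.6, 0.4)
    assay_shift_sd: float = 0.15
    censor_horizon: float = 5.0
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"AKI": 0.05, "CKD": 0.05}
    )

    def validate(self) -> None:
        for fname, value in (
            ("n_samples", self.n_samples),
            ("n_genes", self.n_genes),
            ("library_size", self.library_size),
            ("nb_dispersion", self.nb_dispersion),
            ("mean_cells_per_sample", self.mean_cells_per_sample),
        ):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"CohortSpec.{fname} must be finite and positive, got {value!r}")
        gf = np.array([g.fraction for g in self.groups], float)
        if not np.all(np.isfinite(gf)):
            raise ValueError("CohortSpec.groups: non-finite fraction")
        if abs(gf.sum() - 1.0) > 1e-9:
            raise ValueError(f"CohortSpec.groups fractions must sum to 1 (got {gf.sum()})")
        cf = np.array([c.baseline_fraction for c in self.cell_types], float)
        if not np.all(np.isfinite(cf)):
            raise ValueError("CohortSpec.cell_types: non-finite baseline_fraction")
        if abs(cf.sum() - 1.0) > 1e-9:
            raise ValueError(f"CohortSpec.cell_types fractions must sum to 1 (got {cf.sum()})")
        for ct in self.cell_types:
            for st in ct.states:
                for fname in ("baseline_logit", "acute_slope", "chronic_slope"):
                    if not np.isfinite(getattr(st, fname)):
                        raise ValueError(f"CohortSpec state {st.name}: non-finite {fname}")
        if not (-1.0 < self.score_corr < 1.0):
            raise ValueError("CohortSpec.score_corr must be in (-1, 1)")


@dataclass
class ProteinTable:
    """Sample x protein abundance matrix for one fluid/platform."""

    values: pd.DataFrame  # samples x proteins
    fluid: str  # "plasma" | "urine"
    platform: str = "platform1"
    creatinine: pd.Series | None = None  # per-sample, urine only

    @property
    def protein_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        df = self.values.copy()
        if self.creatinine is not None:
            df.insert(0, "creatinine", self.creatinine)
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, fluid: str, platform: str = "platform1") -> "ProteinTable":
        df = pd.read_csv(path, index_col=0)
        creat = None
        if "creatinine" in df.columns:
            creat = df.pop("creatinine")
        return cls(values=df, fluid=fluid, platform=platform, creatinine=creat)


@dataclass
class CohortTruth:
    """Generator ground truth; consumed by tests only, never by pipeline stages."""

    scores: pd.DataFrame  # samples x (acute, chronic)
    group: pd.Series
    assay: pd.Series
    type_proportions: pd.DataFrame  # samples x cell types (expected)
    state_proportions: dict[str, pd.DataFrame]  # cell type -> samples x states (expected)
    loadings: dict[str, pd.DataFrame]  # cell type -> genes x (acute, chronic)
    protein_weights: pd.DataFrame  # proteins x (acute, chronic)
    hazard_coefs: dict[str, tuple[float, float]]


def default_spec(
    seed: int = 0,
    n_samples: int = 100,
    n_genes: int = 1000,
    mean_cells_per_sample: float = 500.0,
) -> CohortSpec:
    """Default study conditions for the synthetic cohort.

    Eight cell-type views; injured-state logit slopes concentrated in the
    tubular epithelium (aPT/cycPT and the acute score, frPT and the chronic
    score, analogous shifts in TAL), a myofibroblast shift with the acute
    score, and monocyte expansion; DCT, CNT, EC and RC states carry no
    slope and serve as compositional nulls. Program scores are bivariate
    normal (sd 1, correlation 0.4) around enrollment-group means.
    """
    cell_types = (
        CellTypeSpec(
            "PT", 0.30,
            (
                StateSpec("PT-S1", 1.5),
                StateSpec("aPT", -0.5, acute_slope=1.5, chronic_slope=0.5),
                StateSpec("frPT", -1.0, chronic_slope=1.5),
                StateSpec("cycPT", -2.0, acute_slope=1.0),
            ),
            acute_loading_scale=1.0, chronic_loading_scale=1.0,
        ),
        CellTypeSpec(
            "TAL", 0.15,
            (
                StateSpec("TAL-1", 1.2),
                StateSpec("aTAL", -0.6, acute_slope=1.0),
                StateSpec("frTAL", -1.2, chronic_slope=1.0),
            ),
            acute_loading_scale=0.85, chronic_loading_scale=0.85,
        ),
        CellTypeSpec(
            "DCT", 0.08,
            (StateSpec("DCT-1", 0.8), StateSpec("DCT-2", -0.8)),
            acute_loading_scale=0.7, chronic_loading_scale=0.6,
        ),
        CellTypeSpec(
            "CNT", 0.07,
            (StateSpec("CNT-1", 0.8), StateSpec("CNT-2", -0.8)),
            acute_loading_scale=0.7, chronic_loading_scale=0.6,
        ),
        CellTypeSpec(
            "EC", 0.12,
            (StateSpec("EC-PTC", 0.8), StateSpec("EC-GC", -0.4), StateSpec("cycEC", -1.6)),
            acute_loading_scale=0.4, chronic_loading_scale=0.3,
        ),
        CellTypeSpec(
            "FIB", 0.08,
            (
                StateSpec("FIB", 1.0),
                StateSpec("MYOF", -0.8, acute_slope=0.8),
                StateSpec("dFIB", -1.4, chronic_slope=0.6),
            ),
            chronic_slope=0.4,
            acute_loading_scale=0.55, chronic_loading_scale=0.6,
        ),
        CellTypeSpec(
            "IMM", 0.12,
            (StateSpec("resMAC", 0.6), StateSpec("MON", -0.4, acute_slope=0.8), StateSpec("LYM", -0.6)),
            acute_slope=0.5,
            acute_loading_scale=0.4, chronic_loading_scale=0.3,
        ),
        CellTypeSpec(
            "RC", 0.08,
            (StateSpec("POD", 0.5), StateSpec("MC", -0.3), StateSpec("PEC", -1.0)),
            acute_loading_scale=0.3, chronic_loading_scale=0.6,
        ),
    )
    groups = (
        GroupSpec("DM-R", 0.2, -1.0, -0.8),
        GroupSpec("CKD", 0.4, 0.2, 0.8),
        GroupSpec("AKI", 0.4, 1.0, 0.1),
    )
    gene_names = [f"G{i:04d}" for i in range(n_genes)]
    rng = np.random.default_rng(np.random.SeedSequence(1234567, spawn_key=(99,)))
    # platform-1 panel: signal proteins named after genes (half acute, half
    # chronic read-outs), noise proteins named after genes, plus decoys
    # outside the gene space; sizes shrink with small gene spaces
    n_panel = min(180, n_genes)
    n_sig = min(20, max(1, n_panel // 9))
    sig_idx = rng.choice(n_genes, size=n_panel, replace=False)
    panel1 = []
    for j, gi in enumerate(sig_idx):
        if j < n_sig:
            w_a, w_c = float(rng.normal(0, 1.0)) + np.sign(rng.standard_normal()) * 0.8, 0.0
        elif j < 2 * n_sig:
            w_a, w_c = 0.0, float(rng.normal(0, 1.0)) + np.sign(rng.standard_normal()) * 0.8
        else:
            w_a = w_c = 0.0
        panel1.append(ProteinSpec(gene_names[gi], w_a, w_c, noise_sd=0.6))
    panel1 += [ProteinSpec(f"DECOY{i:03d}", 0.0, 0.0, 0.6) for i in range(20)]
    # platform 2: overlaps 2/3 of the platform-1 proteins (all signal ones)
    overlap = [p.name for p in panel1[: min(120, n_panel)]]
    panel2 = tuple(
        Panel2Spec(
            name,
            scale=float(rng.uniform(0.5, 2.0)),
            offset=float(rng.normal(0, 1.0)),
            noise_sd=0.4,
        )
        for name in overlap
    )
    return CohortSpec(
        n_samples=n_samples,
        groups=groups,
        cell_types=cell_types,
        n_genes=n_genes,
        library_size=2000.0,
        nb_dispersion=0.3,
        protein_panel=tuple(panel1),
        panel2=panel2,
        hazard_coefs={"AKI": (0.5, 0.15), "CKD": (0.15, 0.5)},
        seed=seed,
        mean_cells_per_sample=mean_cells_per_sample,
    )


def _softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _draw_scores(spec: CohortSpec, rng: np.random.Generator):
    n = spec.n_samples
    counts = np.floor(np.array([g.fraction for g in spec.groups]) * n).astype(int)
    counts[0] += n - counts.sum()
    labels = np.repeat([g.label for g in spec.groups], counts)
    rng.shuffle(labels)
    mean_a = {g.label: g.mean_acute for g in spec.groups}
    mean_c = {g.label: g.mean_chronic for g in spec.groups}
    cov = spec.score_sd**2 * np.array([[1.0, spec.score_corr], [spec.score_corr, 1.0]])
    eps = rng.multivariate_normal([0, 0], cov, size=n)
    s_a = np.array([mean_a[l] for l in labels]) + eps[:, 0]
    s_c = np.array([mean_c[l] for l in labels]) + eps[:, 1]
    return labels, s_a, s_c


def generate_cohort(spec: CohortSpec):
    """Generate the full synthetic cohort.

    Returns ``(cells, metadata, proteins, outcomes, truth)`` where ``cells``
    is an AnnData of raw counts with obs columns sample/assay/cell_type/
    cell_state, ``metadata`` a per-sample DataFrame, ``proteins`` a dict
    with keys ``plasma`` (platform 1), ``urine`` (platform 1) and
    ``platform2`` (plasma, second platform), ``outcomes`` a long-format
    survival table and ``truth`` the :class:`CohortTruth`.
    """
    spec.validate()
    sample_ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    gene_names = [f"G{i:04d}" for i in range(spec.n_genes)]

    labels, s_a, s_c = _draw_scores(spec, _rng(spec.seed, "scores"))
    scores = pd.DataFrame({"acute": s_a, "chronic": s_c}, index=sample_ids)

    rng_cells = _rng(spec.seed, "cells")
    # assay assignment (one chemistry per sample)
    n_sn = int(round(spec.assay_fractions[0] * spec.n_samples))
    assay = np.array(["sn"] * n_sn + ["sc"] * (spec.n_samples - n_sn))
    rng_cells.shuffle(assay)
    assay = pd.Series(assay, index=sample_ids, name="assay")

    rng_genes = _rng(spec.seed, "genes")
    baseline = rng_genes.normal(0.0, 1.0, size=spec.n_genes)
    # per-assay gene shift (chemistry effect removed by grouped centering)
    assay_shift = rng_genes.normal(0.0, spec.assay_shift_sd, size=spec.n_genes)

    loadings: dict[str, pd.DataFrame] = {}
    state_offsets: dict[tuple[str, str], np.ndarray] = {}
    for ct in spec.cell_types:
        L = np.zeros((spec.n_genes, 2))
        n_active = int(round((1.0 - spec.loading_sparsity) * spec.n_genes))
        for k, scale in enumerate((ct.acute_loading_scale, ct.chronic_loading_scale)):
            idx = rng_genes.choice(spec.n_genes, size=n_active, replace=False)
            L[idx, k] = rng_genes.normal(0.0, scale, size=n_active)
        loadings[ct.name] = pd.DataFrame(L, index=gene_names, columns=["acute", "chronic"])
        for st in ct.states:
            off = np.zeros(spec.n_genes)
            midx = rng_genes.choice(
                spec.n_genes, size=min(spec.n_state_markers, spec.n_genes), replace=False
            )
            off[midx] = spec.state_marker_effect
            state_offsets[(ct.name, st.name)] = off

    type_names = [ct.name for ct in spec.cell_types]
    base_type_logits = np.log(np.array([ct.baseline_fraction for ct in spec.cell_types]))
    type_a = np.array([ct.acute_slope for ct in spec.cell_types])
    type_c = np.array([ct.chronic_slope for ct in spec.cell_types])

    exp_type_props = _softmax(
        base_type_logits[None, :] + np.outer(s_a, type_a) + np.outer(s_c, type_c), axis=1
    )
    exp_state_props: dict[str, np.ndarray] = {}
    for t, ct in enumerate(spec.cell_types):
        logit = np.array([st.baseline_logit for st in ct.states])[None, :] + np.outer(
            s_a, [st.acute_slope for st in ct.states]
        ) + np.outer(s_c, [st.chronic_slope for st in ct.states])
        exp_state_props[ct.name] = _softmax(logit, axis=1)

    # ---- cells ----
    obs_rows = []
    count_blocks = []
    disp = spec.nb_dispersion
    for i, sid in enumerate(sample_ids):
        n_cells = rng_cells.poisson(spec.mean_cells_per_sample)
        if n_cells == 0:
            continue
        type_counts = rng_cells.multinomial(n_cells, exp_type_props[i])
        for t, ct in enumerate(spec.cell_types):
            if type_counts[t] == 0:
                continue
            state_counts = rng_cells.multinomial(type_counts[t], exp_state_props[ct.name][i])
            L = loadings[ct.name].to_numpy()
            for u, st in enumerate(ct.states):
                m = state_counts[u]
                if m == 0:
                    continue
                eta = (
                    baseline
                    + (assay_shift if assay[sid] == "sc" else 0.0)
                    + state_offsets[(ct.name, st.name)]
                    + s_a[i] * L[:, 0]
                    + s_c[i] * L[:, 1]
                )
                w = np.exp(eta - eta.max())
                mu = spec.library_size * w / w.sum()
                lam = rng_cells.gamma(1.0 / disp, disp * np.broadcast_to(mu, (m, spec.n_genes)))
                counts = rng_cells.poisson(lam)
                count_blocks.append(sparse.csr_matrix(counts))
                for _ in range(m):
                    obs_rows.append((sid, assay[sid], ct.name, st.name))
    X = sparse.vstack(count_blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["sample", "assay", "cell_type", "cell_state"])
    obs.index = [f"cell{j:06d}" for j in range(len(obs))]
    obs["sample"] = obs["sample"].astype("category")
    cells = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    )

    # ---- metadata ----
    rng_meta = _rng(spec.seed, "metadata")
    n = spec.n_samples
    egfr = 90.0 - 8.0 * s_a - 12.0 * s_c + rng_meta.normal(0, 8, n)
    acr_log = 1.0 + 0.5 * s_a + 0.3 * s_c + rng_meta.normal(0, 0.5, n)
    fibrosis = np.clip(15.0 + 10.0 * s_c + rng_meta.normal(0, 5, n), 0.0, 100.0)
    aki_latent = s_a + rng_meta.normal(0, 0.7, n)
    aki_stage = np.digitize(aki_latent, [0.0, 1.0, 2.0]).astype(int)
    ckd_latent = s_c + rng_meta.normal(0, 0.7, n)
    ckd_risk = np.array(["low", "moderate", "high", "very_high"])[
        np.digitize(ckd_latent, [0.0, 1.0, 2.0])
    ]
    metadata = pd.DataFrame(
        {
            "enrollment": labels,
            "assay": assay.values,
            "egfr": np.round(egfr, 3),
            "log_acr": np.round(acr_log, 4),
            "fibrosis_pct": np.round(fibrosis, 3),
            "aki_stage": pd.Categorical([f"stage{k}" for k in aki_stage]),
            "ckd_risk": pd.Categorical(ckd_risk),
            "unrelated_noise": np.round(rng_meta.normal(0, 1, n), 4),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # ---- proteins ----
    rng_prot = _rng(spec.seed, "proteins")
    w_a = np.array([p.acute_weight for p in spec.protein_panel])
    w_c = np.array([p.chronic_weight for p in spec.protein_panel])
    sds = np.array([p.noise_sd for p in spec.protein_panel])
    pnames = [p.name for p in spec.protein_panel]

    def platform1_log2(rng):
        return (
            np.outer(s_a, w_a)
            + np.outer(s_c, w_c)
            + rng.normal(0, 1, (n, len(pnames))) * sds[None, :]
        )

    plasma_log2 = platform1_log2(rng_prot)
    urine_log2 = platform1_log2(rng_prot)
    creat = pd.Series(
        np.exp(rng_prot.normal(0.0, 0.4, n)), index=sample_ids, name="creatinine"
    )
    plasma = ProteinTable(
        values=pd.DataFrame(2.0 ** plasma_log2, index=sample_ids, columns=pnames),
        fluid="plasma",
    )
    urine = ProteinTable(
        values=pd.DataFrame(
            2.0 ** urine_log2 * creat.to_numpy()[:, None], index=sample_ids, columns=pnames
        ),
        fluid="urine",
        creatinine=creat,
    )
    # platform 2: affine per-protein distortion of platform-1 plasma (log2 scale)
    p1 = pd.DataFrame(plasma_log2, index=sample_ids, columns=pnames)
    p2_cols = {}
    for ps in spec.panel2:
        x = p1[ps.name].to_numpy()
        p2_cols[ps.name] = ps.scale * x + ps.offset + rng_prot.normal(0, ps.noise_sd, n)
    platform2 = ProteinTable(
        values=pd.DataFrame(p2_cols, index=sample_ids), fluid="plasma", platform="platform2"
    )
    proteins = {"plasma": plasma, "urine": urine, "platform2": platform2}

    # ---- outcomes ----
    rng_out = _rng(spec.seed, "outcomes")
    covars = pd.DataFrame(
        {
            "age": np.round(rng_out.normal(57, 8, n), 1),
            "sex": rng_out.integers(0, 2, n),
            "bmi": np.round(rng_out.normal(27, 4, n), 2),
            "baseline_egfr": np.round(egfr, 3),
        },
        index=sample_ids,
    )
    outcomes = simulate_outcomes(
        scores,
        spec.hazard_coefs,
        baseline_hazard=spec.baseline_hazard,
        censor_horizon=spec.censor_horizon,
        rng=rng_out,
        covariates=covars,
    )

    truth = CohortTruth(
        scores=scores,
        group=pd.Series(labels, index=sample_ids, name="enrollment"),
        assay=assay,
        type_proportions=pd.DataFrame(exp_type_props, index=sample_ids, columns=type_names),
        state_proportions={
            ct.name: pd.DataFrame(
                exp_state_props[ct.name], index=sample_ids,
                columns=[st.name for st in ct.states],
            )
            for ct in spec.cell_types
        },
        loadings=loadings,
        protein_weights=pd.DataFrame({"acute": w_a, "chronic": w_c}, index=pnames),
        hazard_coefs=dict(spec.hazard_coefs),
    )
    return cells, metadata, proteins, outcomes, truth


def simulate_outcomes(
    scores: pd.DataFrame,
    hazard_coefs: dict[str, tuple[float, float]],
    baseline_hazard: dict[str, float],
    censor_horizon: float,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exponential event times with log-hazard linear in standardized scores.

    One row per subject per outcome type; columns tstart/tstop/event plus
    any covariates. Reused at large n for survival-recovery checks.
    """
    z = (scores - scores.mean()) / scores.std(ddof=0)
    rows = []
    for outcome, (b_a, b_c) in hazard_coefs.items():
        lam = baseline_hazard[outcome] * np.exp(
            b_a * z["acute"].to_numpy() + b_c * z["chronic"].to_numpy()
        )
        t = rng.exponential(1.0 / lam)
        event = (t <= censor_horizon).astype(int)
        tstop = np.minimum(t, censor_horizon)
        df = pd.DataFrame(
            {
                "subject_id": scores.index,
                "outcome": outcome,
                "tstart": 0.0,
                "tstop": tstop,
                "event": event,
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if covariates is not None:
        out = out.merge(covariates, left_on="subject_id", right_index=True, how="left")
    return out


def write_cohort(outdir: str | Path, cells, metadata, proteins, outcomes, truth) -> None:
    """Write the cohort as plain-text artifacts (MTX + TSV/CSV + JSON)."""
    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "counts.mtx"), sparse.csr_matrix(cells.X))
    cells.obs.rename_axis("barcode").to_csv(outdir / "cells.tsv", sep="\t")
    cells.var.rename_axis("gene").to_csv(outdir / "genes.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    for key, table in proteins.items():
        table.to_csv(outdir / f"proteins_{key}.csv")
    outcomes.to_csv(outdir / "outcomes.tsv", sep="\t", index=False)
    truth.scores.rename_axis("sample_id").to_csv(outdir / "truth_scores.tsv", sep="\t")
    truth.protein_weights.rename_axis("protein").to_csv(
        outdir / "truth_protein_weights.tsv", sep="\t"
    )
    meta = {
        "hazard_coefs": {k: list(v) for k, v in truth.hazard_coefs.items()},
        "cell_types": list(truth.type_proportions.columns),
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def spec_to_json(spec: CohortSpec) -> str:
    return json.dumps(dataclasses.asdict(spec), default=list, sort_keys=True)
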