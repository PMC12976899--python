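"""Config-driven orchestration of the analysis stages.

Stages run in dependency order (simulate → pseudobulk → mcfa →
associate / composition / decompose → signature → validate); each stage
writes its artifacts plus a manifest recording parameters and SHA-256
checksums of inputs and outputs, so a rerun with the same config and
seed is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biofluid, composition, decomposition, enrichment, factor_model
from . import pseudobulk as pb
from . import synthetic_cohort as sc
from . import validation
from .association import associate, results_table

__all__ = ["DEFAULT_CONFIG", "load_config", "run", "STAGES"]

STAGES = [
    "simulate",
    "pseudobulk",
    "mcfa",
    "associate",
    "composition",
    "enrich",
    "decompose",
    "signature",
    "validate",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "run",
    "simulate": {"n_samples": 100, "n_genes": 1000, "mean_cells_per_sample": 500.0},
    "pseudobulk": {
        "min_cells": 25,
        "min_counts": 1000,
        "min_view_frac": 0.5,
        "min_sample_frac": 0.5,
        "target_sum": 1e4,
        "n_hvg": 2000,
    },
    "mcfa": {"k": 7, "tol": 1e-4, "max_iter": 1000, "reference": "DM-R"},
    "associate": {"factors": ["Factor1", "Factor2"]},
    "composition": {"delta": 0.001, "cell_types": ["PT", "TAL"]},
    "enrich": {"threshold": 0.1, "cell_type": "PT"},
    "decompose": {"cell_type": "PT"},
    "signature": {"k_folds": 3, "n_bootstrap": 100},
    "validate": {"cutpoints": [1.0, 3.0], "outcome": "AKI"},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key: {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(base[key], val, path=f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[Path]):
    payload = {
        "stage": stage,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def verify_manifests(outdir: str | Path) -> bool:
    """Re-hash every artifact referenced by the manifests."""
    outdir = Path(outdir)
    for mf in sorted(outdir.glob("manifest_*.json")):
        payload = json.loads(mf.read_text())
        for section in ("inputs", "outputs"):
            for name, digest in payload[section].items():
                if _sha256(outdir / name) != digest:
                    return False
    return True


def run(config: dict, stages: list[str] | None = None, log=print) -> Path:
    """Execute the requested stages; returns the run directory."""
    stages = stages or STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    # outdir is location metadata, not part of the run's identity
    (outdir / "config.yaml").write_text(
        yaml.safe_dump({k: v for k, v in config.items() if k != "outdir"}, sort_keys=True)
    )
    seed = int(config["seed"])
    state: dict = {}

    def need(artifact: str, producer: str):
        if artifact in state:
            return state[artifact]
        raise RuntimeError(
            f"missing dependency artifact {artifact!r}: run stage {producer!r} first"
        )

    for stage in stages:
        params = config[stage] if stage in config else {}
        log(f"[mcprog] stage {stage}")
        if stage == "simulate":
            spec = sc.default_spec(seed=seed, **{
                k: params[k] for k in ("n_samples", "n_genes", "mean_cells_per_sample")
            })
            cells, metadata, proteins, outcomes, truth = sc.generate_cohort(spec)
            sc.write_cohort(outdir, cells, metadata, proteins, outcomes, truth)
            state.update(cells=cells, metadata=metadata, proteins=proteins,
                         outcomes=outcomes, truth=truth)
            outs = [outdir / n for n in (
                "counts.mtx", "cells.tsv", "genes.tsv", "metadata.tsv",
                "outcomes.tsv", "truth_scores.tsv")]
            _manifest(outdir, stage, params, [], outs)
        elif stage == "pseudobulk":
            cells = need("cells", "simulate")
            views = pb.build_views(cells, params["min_cells"], params["min_counts"])
            views = pb.filter_views(views, params["min_view_frac"], params["min_sample_frac"])
            norm = views.copy()
            for v in list(norm.views):
                mask = pb.filter_genes(norm.views[v])
                counts = norm.views[v].loc[:, mask]
                logn = pb.normalize_log1p(counts, params["target_sum"])
                hvgs = pb.select_hvgs(logn, norm.assay, n_top=params["n_hvg"])
                norm.views[v] = logn[hvgs]
            state["views_counts"] = views
            state["views"] = norm
            path = outdir / "pseudobulk.h5"
            pb.save_views(norm, path)
            _manifest(outdir, stage, params, [], [path])
        elif stage == "mcfa":
            views = need("views", "pseudobulk")
            model = factor_model.fit_mcfa(
                views, K=params["k"], max_iter=params["max_iter"],
                tol=params["tol"], seed=seed,
            )
            metadata = need("metadata", "simulate")
            model = factor_model.orient_factors(
                model, metadata["enrollment"], params["reference"]
            )
            state["model"] = model
            mpath = outdir / "factor_model.h5"
            factor_model.save_model(model, mpath)
            zpath = outdir / "factor_scores.tsv"
            model.Z.round(6).rename_axis("sample_id").to_csv(zpath, sep="\t")
            r2path = outdir / "variance_explained.tsv"
            model.R2.round(6).rename_axis("view").to_csv(r2path, sep="\t")
            _manifest(outdir, stage, params, [outdir / "pseudobulk.h5"],
                      [mpath, zpath, r2path])
        elif stage == "associate":
            model = need("model", "mcfa")
            metadata = need("metadata", "simulate").drop(columns=["assay"])
            outs = []
            for f in params["factors"]:
                res = associate(model.Z[f], metadata)
                path = outdir / f"associations_{f}.tsv"
                results_table(res).round(6).to_csv(path, sep="\t", index=False)
                outs.append(path)
            _manifest(outdir, stage, params, [outdir / "factor_scores.tsv"], outs)
        elif stage == "composition":
            model = need("model", "mcfa")
            cells = need("cells", "simulate")
            views = need("views", "pseudobulk")
            scores = model.Z[[c for c in ("Factor1", "Factor2") if c in model.Z]]
            outs = []
            available = [ct for ct in params["cell_types"] if ct in views.views]
            if not available:
                raise RuntimeError(
                    "none of the configured cell types survived view filtering; "
                    f"views present: {sorted(views.views)}"
                )
            for ct in available:
                clr_t = composition.state_composition_table(
                    cells.obs, ct, used_samples=views.present(ct),
                    delta=params["delta"],
                )
                tab = composition.abundance_vs_scores(clr_t, scores, views.assay)
                path = outdir / f"composition_{ct}.tsv"
                tab.round(6).to_csv(path, sep="\t", index=False)
                outs.append(path)
            _manifest(outdir, stage, params, [outdir / "factor_scores.tsv"], outs)
        elif stage == "enrich":
            model = need("model", "mcfa")
            cells = need("cells", "simulate")
            ct = params["cell_type"]
            if ct not in model.W:
                raise RuntimeError(f"cell type {ct!r} not in the factor model views")
            sub = cells[cells.obs["cell_type"] == ct]
            expr = pd.DataFrame(
                np.log1p(np.asarray(sub.X.todense(), dtype=float)),
                index=sub.obs_names, columns=sub.var_names,
            )
            markers = enrichment.state_markers(expr, sub.obs["cell_state"], top_n=100)
            loadings = model.W[ct]["Factor1"]
            rows = []
            for st, sig in markers.items():
                score = enrichment.ulm(loadings.rename("Factor1"), sig)
                rows.append({"state": st, "t": score.t, "p": score.p})
            path = outdir / f"marker_enrichment_{ct}.tsv"
            pd.DataFrame(rows).round(6).to_csv(path, sep="\t", index=False)
            state["markers"] = markers
            _manifest(outdir, stage, params, [], [path])
        elif stage == "decompose":
            model = need("model", "mcfa")
            cells = need("cells", "simulate")
            ct = params["cell_type"]
            rows = build_state_activity(cells, model, ct)
            res = decomposition.fit_state_disease(rows, response="activity")
            path = outdir / f"decomposition_{ct}.tsv"
            pd.DataFrame(
                [{
                    "cell_type": ct, "response": "program_activity",
                    "r2_state": res.r2_state, "r2_score": res.r2_score,
                    "slope": res.slope, "t": res.slope_t, "method": res.method,
                }]
            ).round(6).to_csv(path, sep="\t", index=False)
            _manifest(outdir, stage, params, [], [path])
        elif stage == "signature":
            model = need("model", "mcfa")
            proteins = need("proteins", "simulate")
            gene_space = set().union(*(set(w.index) for w in model.W.values()))
            outs = []
            for fluid in ("plasma", "urine"):
                table = proteins[fluid]
                Xp = biofluid.restrict_to_gene_space(
                    biofluid.preprocess(table), gene_space
                )
                sig = biofluid.fit_lasso_cv(
                    Xp, model.Z["Factor1"], k=params["k_folds"], seed=seed,
                    fluid=fluid, program="acute",
                )
                sig.stability = biofluid.bootstrap_stability(
                    Xp, model.Z["Factor1"], sig.lambda_,
                    B=params["n_bootstrap"], seed=seed,
                )
                path = outdir / f"signature_{fluid}_acute.json"
                biofluid.save_signature(sig, path)
                state[f"signature_{fluid}"] = sig
                outs.append(path)
            _manifest(outdir, stage, params, [], outs)
        elif stage == "validate":
            sig = need("signature_plasma", "signature")
            proteins = need("proteins", "simulate")
            outcomes = need("outcomes", "simulate")
            proj = validation.project_signature(sig, proteins["platform2"].values)
            ppath = outdir / "projected_scores.tsv"
            proj.round(6).rename_axis("sample_id").to_csv(ppath, sep="\t")
            sub = outcomes[outcomes["outcome"] == params["outcome"]].copy()
            sub = sub.set_index("subject_id")
            sub["score"] = proj["z"]
            hr_tab, _ = piecewise_safe(sub.reset_index(), params["cutpoints"])
            cpath = outdir / "piecewise_cox.tsv"
            hr_tab.round(6).to_csv(cpath, sep="\t", index=False)
            _manifest(outdir, stage, params, [], [ppath, cpath])
    return outdir


def build_state_activity(cells, model, cell_type: str) -> pd.DataFrame:
    """Per (sample, state) program activity of Factor1 in state pseudobulks."""
    sub = cells[cells.obs["cell_type"] == cell_type]
    loadings = model.W[cell_type]["Factor1"]
    rows = []
    grouped = sub.obs.groupby(["sample", "cell_state"], observed=True).indices
    X = sub.X.tocsr() if hasattr(sub.X, "tocsr") else sub.X
    assay = model.groups
    for (sample, st), idx in grouped.items():
        if len(idx) < 3 or sample not in model.Z.index:
            continue
        profile = np.asarray(X[idx].sum(axis=0)).ravel()
        total = profile.sum()
        if total == 0:
            continue
        logn = pd.Series(
            np.log1p(profile / total * 1e4), index=sub.var_names, name=str(sample)
        )
        try:
            act = enrichment.program_activity(logn, loadings)
        except ValueError:
            continue
        rows.append(
            {
                "sample": sample, "state": st, "activity": act.t, "y": act.t,
                "score": model.Z.loc[sample, "Factor1"], "patient": sample,
                "assay": None if assay is None else assay.get(sample),
            }
        )
    return pd.DataFrame(rows)


def piecewise_safe(sub: pd.DataFrame, cutpoints: list[float]):
    """Piecewise Cox on a score column with standard guard rails."""
    sub = sub.dropna(subset=["score"])
    return validation.piecewise_cox(sub, "score", cutpoints)
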