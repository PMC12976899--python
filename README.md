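# mcprog — multicellular injury programs from single-cell kidney cohorts

Acute kidney injury (AKI) and chronic kidney disease (CKD) are defined by
functional read-outs (creatinine, eGFR) that hide very different tissue
states. Single-nucleus transcriptomics of patient biopsies makes it
possible to describe each patient by *multicellular programs*: latent
factors whose per-sample score varies coordinately across cell-type
pseudobulk profiles, with per-view gene loadings. Two such programs — an
**acute** injury program and a **chronic** damage program — capture
compositional shifts toward adaptive and failed-repair tubular states
together with cell-state-agnostic molecular stress responses, and can be
read out non-invasively from plasma and urine proteins.

`mcprog` implements that entire analysis as a tested library plus an
analysis-project layout:

- **Pseudobulk views** (`mcprog.pseudobulk`): sum counts per (sample,
  cell type); profile QC (≥ 25 cells, ≥ 1000 counts), view/sample
  representation filters (50%/50%, in that order), per-view
  sufficient-counts gene filtering, depth normalization + log1p, HVGs.
- **Factor model** (`mcprog.factor_model`): multi-view Gaussian factor
  analysis `x_vsg = Σ_k z_sk w_vgk + ε` with shared scores, per-view
  loadings and per-gene noise, fit by EM over per-sample missing-view
  patterns (assay-grouped centering, K = 7 by default), identified by
  promax rotation of the stacked sparse loadings, sign-oriented so a
  reference group scores lowest; per-view variance explained.
- **Associations** (`mcprog.association`): ANOVA / OLS of scores
  against metadata, BH adjustment, Tukey HSD post-hocs.
- **Composition** (`mcprog.composition`): CLR with multiplicative zero
  replacement; mixed models `clr ~ scores + (1|assay)`, slope t-scores.
- **ULM enrichment** (`mcprog.enrichment`): one scoring engine for
  hallmark sets, TF regulons, cell-state markers (one-vs-rest t
  weights) and thresholded program loadings — the activity is the slope
  t of profile-on-weights regression.
- **Decomposition** (`mcprog.decomposition`): `y ~ state + score +
  (1|patient:assay)` with semi-partial R² per fixed effect — is a
  program compositional, molecular, or mixed?
- **Biofluid signatures** (`mcprog.biofluid`): LASSO surrogates of the
  program scores from creatinine-normalized, log2 protein panels;
  3-fold CV with fold-wise scaling and Spearman-selected λ; 500-draw
  bootstrap stability f·m/s.
- **External validation** (`mcprog.validation`): name-harmonized
  projection onto a second proteomic platform (column z-scaling, weight
  winsorization at q99, L2 normalization), CKD-EPI 2021 eGFR,
  restricted-cubic-spline nonlinearity tests, logistic PheWAS, an
  Efron-ties start–stop Cox solver with piecewise (interval-specific)
  hazard ratios, and median-split dual-hit risk groups.
- **Synthetic cohort** (`mcprog.synthetic_cohort`): a fully labelled
  generator (cells, metadata, two protein platforms, outcomes) driven by
  known latent acute/chronic scores, so every stage has ground truth.

Real cohort data (restricted-access atlases and biobanks) are out of
scope; the package demonstrates and validates the entire method chain on
the synthetic cohort.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (seed 1; 100 samples, 8 cell types, ~50k cells, 1000
genes) and write tables under `results/`. Running them in order prints,
among other things:

```
$ python analysis/03_fit_factor_model.py
acute program -> Factor1 (|r|=0.988); chronic program -> Factor2 (|r|=0.993)
```

i.e. after fitting K = 7 factors the two leading factors recover the
generator's true acute and chronic scores almost perfectly.

```
$ python analysis/05_composition_shifts.py
   PT/frPT Factor2    4.5226  26.7483 0.0000 0.0000
    PT/aPT Factor1    2.0697  25.2373 0.0000 0.0000
   IMM/MON Factor1    1.3492  21.6736 0.0000 0.0000
```

CLR state-composition slopes: the failed-repair PT state tracks the
chronic factor, adaptive PT and monocytes track the acute factor, and
reference states (PT-S1, TAL-1, resMAC) decline — the compensatory
decreases forced by compositional closure.

```
$ python analysis/08_biofluid_signatures.py
plasma: CV Spearman 0.9842, 43 proteins selected
urine:  CV Spearman 0.9834, 19 proteins selected
```

Sparse protein surrogates of the acute score, with bootstrap stability
tables ranking the most reliably selected proteins.

```
$ python analysis/09_external_validation.py
platform-2 projection vs true acute score: r = 0.992
dual-hit group sizes: {'Reference': 26, 'Double Hit': 26, 'High Acute Only': 24, 'High Chronic Only': 24}
```

The plasma signature, projected by protein name onto the
affine-distorted second platform, still orders subjects by their true
acute score; median-split dual-hit groups show the enrichment of
Reference/Double Hit expected for positively correlated scores.

The same stages are available as a config-driven CLI:

```bash
mcp run --config cfg.yaml --stages all --seed 7 --outdir run7
mcp verify run7         # re-checks every manifest checksum
```

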