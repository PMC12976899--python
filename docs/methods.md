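# Methods

This note documents the models implemented in `mcprog`, the choices made
where the design was genuinely open, what the synthetic cohort does and
does not emulate, and the numerical conventions used throughout.

## The multicellular program model

Pseudobulk expression of sample *s* in cell-type view *v* is modelled as
a multi-view Gaussian factor analysis with shared per-sample scores:

    x_vsg = Σ_k z_sk · w_vgk + ε_vsg,   z_s ~ N(0, I_K),  ε_vsg ~ N(0, 1/τ_vg)

Each view contributes its own gene loadings `W_v` and per-gene noise
precisions; samples may be missing from any view, and the per-sample
posterior over `z_s` uses exactly the views that sample has. Maximum
likelihood is obtained by expectation–maximization grouped over
missing-view patterns; the exact marginal log-likelihood (via the
Woodbury identity) is evaluated every iteration and asserted
non-decreasing. Convergence is declared when the relative change of the
log-likelihood drops below `tol` (default 1e-4, a deliberately moderate
setting — the downstream statistics use scores and loadings, not the
tail of the likelihood ascent; `max_iter` 1000).

**Grouping.** Assays (two 10x chemistries in the emulated design) are
handled by centering each view's features within each assay group before
fitting. This removes the chemistry offset that would otherwise dominate
the first factor. Full per-group noise models were considered and
rejected: the downstream association, composition and decomposition
analyses consume scores and loadings, neither of which changes
materially under per-group τ, and the simpler model keeps the likelihood
exactly computable per sample.

**Rotational identification.** Gaussian factor analysis is identified
only up to an invertible transform of the factor space, and the EM
solution tends to return whitened, mixed factors. Because multicellular
programs load sparsely on genes, the fitted loadings (stacked across
views) are rotated to the sparsest axis system: varimax followed by an
oblique promax step (power 4, default). The oblique family matters —
acute and chronic program scores are positively correlated across
patients, and no orthogonal rotation can recover correlated factors from
a whitened solution. Scores are counter-rotated so the reconstruction
`Z Wᵀ` is bitwise unchanged. Factors are then ordered by total variance
explained and sign-oriented so that a designated reference group (the
lowest-disease-burden enrollment group) has the lowest mean score on
every factor.

**Variance explained** per view and factor is the single-factor
definition `R²_vk = 1 − ‖X_v − z_k w_vkᵀ‖² / ‖X_v‖²` on group-centered
data, floored at 0; single-factor (rather than cumulative) R² keeps
factors comparable after oblique rotation.

## Pseudobulk construction

Counts are summed per (sample, cell type); profiles with fewer than 25
cells or 1000 counts are discarded. Views present in under half the
samples are dropped first, then samples covering under half of the
remaining views — the order matters and is fixed. Genes are filtered
per view by a sufficient-counts rule (keep a gene if its CPM exceeds the
CPM-equivalent of 10 counts at the median library size in at least
0.7 × smallest-group-size samples, and its total count is ≥ 15),
then profiles are scaled to 10,000 counts and log1p-transformed.
10k is the standard single-cell depth convention; the analysis is
insensitive to the target because profiles are compared after scaling.
Highly variable genes are the top 2000 by log-normalized variance per
assay, unioned across assays.

## Associations, composition, decomposition

*Metadata associations* use one-way ANOVA (categorical; levels with
fewer than 3 samples dropped, degenerate zero-within-variance separation
reported as p→0) or simple OLS (continuous), BH-adjusted across the
variables tested for one factor — the per-factor family matches how the
results are reported per program. Significant categorical variables get
Tukey HSD post-hocs (studentized range on pooled within-group variance,
Tukey–Kramer for unequal sizes).

*Composition* works on relative abundances of cell types per sample, or
states within one cell type, restricted to the sample–cell-type
combinations retained by the factor model. Zeros are multiplicatively
replaced (delta = 0.001 by default; the replacement library's default
delta depends on the matrix, so an explicit value is fixed here) and the
composition is CLR-transformed. Each part is regressed on the program
scores with a random intercept per assay (REML); the reported quantity
is the slope t with residual degrees of freedom n − p. Satterthwaite or
Kenward–Roger corrections are out of scope: the slope t-scores are used
for ranking and sign, not for boundary-precision inference. With a
single assay level the model degrades to OLS with a warning. Note one
structural caveat: compositional closure means a genuine shift in one
state induces a compensatory CLR slope of opposite sign (≈ −b/m for m
states) in its sibling states; "null" states in the validation
simulations are therefore states of cell types with no shifted state at
all.

*State-vs-disease decomposition* fits `y ~ state + score +
(1 | patient:assay)` by REML for a response measured per (sample, state)
— program activity, TF activity, or gene expression — and reports the
semi-partial R² of each fixed effect from its Wald F:
`R² = (ν₁/ν₂·F)/(1 + ν₁/ν₂·F)` with ν₂ = n − rank(fixed design). This is
the standardized-generalized-variance flavour of mixed-model partial R²;
alternatives (Kenward–Roger or NSJ denominators) change the absolute
values slightly but not the state-vs-score ranking the analysis relies
on. The random intercept is over the patient × assay interaction.

## ULM activity scoring

Activity of a weighted gene signature in a profile is the t-statistic of
the slope from regressing profile values on signature weights over *all*
profile genes, with absent genes carrying weight zero. The same engine
scores binary hallmark-style sets, signed TF regulons, cell-state marker
signatures (one-vs-rest Welch t per gene, BH-ranked, top 200, t as
weight; ties broken by t descending then gene id), and program loadings
(restricted to |loading| strictly greater than 0.1). At least 5 weighted
genes must overlap the profile. The ULM t is algebraically the Pearson
correlation transform `r·sqrt(df/(1−r²))`, which the tests verify.

## Biofluid signatures

Urine protein abundances are divided by urine creatinine; both fluids
are log2-transformed. Proteins are restricted to those whose gene is in
the factor-model gene space. LASSO — objective `(1/2n)‖y − b₀ − Xb‖² +
λ‖b‖₁`, solved by cyclic coordinate descent — is tuned on a 50-point
log-spaced λ grid from λ_max down to 10⁻³λ_max with 3-fold CV;
standardization inside each fold uses train-fold moments only, and λ
maximizes the mean held-out Spearman correlation (the rank metric is
robust to the monotone-but-nonlinear mapping between protein space and
scores). The final model refits on the fully standardized data.
Stability is measured over 500 bootstrap resamples at the chosen λ:
inclusion frequency f, and mean m / sd s of the coefficient *including
zeros* — counting zeros keeps f and m on the same sample space — with
the stability statistic f·m/s (signed infinity when s = 0 with f > 0,
ranked first by magnitude).

## Cross-platform projection and outcome models

A signature is projected onto a second platform by protein-name
intersection of its nonzero support with the panel; panel columns are
z-scaled (which exactly cancels any affine per-protein distortion),
weights are winsorized at the 99th percentile of absolute magnitude
(computed over the intersected support with the "higher" quantile
convention, so a weight that *is* the boundary is not clipped) and
L2-normalized, and the resulting raw scores are z-standardized across
subjects.

eGFR uses the CKD-EPI 2021 creatinine equation. Nonlinearity of the
score–eGFR relation is tested with natural cubic splines (default 4 df;
knots at evenly spaced quantiles between the 5th and 95th percentile,
which for 4 df lands at the 5/35/65/95 positions) versus the nested
linear model by likelihood-ratio chi-square; df = 1 degenerates exactly
to OLS. The PheWAS fits one logistic model per binary phenotype (IRLS),
excludes phenotypes with fewer than 20 prevalent cases, flags separated
or non-converged fits, and reports OR per SD of score ranked by |log OR|.

Survival uses an in-house Newton optimizer of the Efron-ties Cox partial
likelihood on counting-process (start, stop] episodes, vectorized over
event times with prefix-sum risk sets, converged to a relative
log-likelihood change of 1e-12 with step halving. The tight tolerance is
what makes episode-split fits reproduce unsplit fits to ~1e-8; an
established survival package is used as an independent oracle in the
tests. Piecewise models split follow-up at pre-specified cutpoints and
interact the exposure with the interval indicator (interval main effects
are deliberately absent — they are deterministic functions of time and
unidentified in a partial likelihood); intervals with zero events are
reported as missing and fewer than 5 events triggers a warning. Dual-hit
stratification median-splits the two projected scores into four groups,
with ties at the median assigned to "low".

## The synthetic cohort

The generator emulates the statistical structure the pipeline is built
for, not kidney biology: 100 samples in three enrollment-like groups
(20/40/40), latent acute and chronic scores bivariate normal (sd 1,
correlation 0.4, matching the positive score correlation reported in
population cohorts) around group means; eight cell types with
baseline fractions summing to 1 and within-type states whose logits
shift with the scores (injured proximal-tubule states track the acute
score, failed-repair states the chronic score; four cell types carry no
state slopes and act as compositional nulls); per-cell negative-binomial
counts (mean library 2000, dispersion 0.3 in the Var = μ + αμ²
parameterization) whose log-rates add sparse per-type program loadings
(20% of 1000 genes active per program and type, Gaussian effect sizes
with per-type scales chosen so that the two programs' molecular
footprint clearly exceeds the multinomial composition noise — tubular
views strongest, interstitial weakest); 500 cells per sample on average
so every cell type passes the 25-cell pseudobulk QC in most samples;
clinical metadata as monotone functions of the scores plus noise; a
platform-1 protein panel whose log2 values are linear score read-outs
(40 signal proteins named after genes, 140 gene-named noise proteins, 20
decoys outside the gene space so the gene-space filter is a real step);
a platform-2 panel that is an affine per-protein distortion of a
name-overlapping platform-1 subset plus noise; and exponential event
times with log-hazard linear in the standardized scores, censored at 5
years. One seeded generator is threaded through fixed-offset substreams
per stage, so any stage regenerates identically.

What it does **not** emulate — and therefore what passing tests do not
establish about real data: ambient RNA, doublets, batch chemistry beyond
a per-assay mean shift, gene–gene correlation beyond the factor
structure, nonlinear protein–score relations, aptamer cross-reactivity,
informative censoring, or competing risks. Gene names are synthetic
(G0000…), so protein–gene "harmonization" reduces to exact string
matching.

Problem sizes in the test-suite and acceptance checks (replicate counts,
5000-subject survival cohorts, reduced gene spaces for composition-only
replicates) are the package's chosen verification scales: large enough
that the Monte-Carlo acceptance bands are stable, small enough to run
routinely.

## Known limitations

- Factor alignment to ground truth relies on loading sparsity; a cohort
  whose programs load densely would be recovered only up to rotation
  (the subspace tests would still pass, per-factor matching would not).
- Mixed models use large-sample Wald t with residual df; small-sample
  p-values near the significance boundary should not be over-read.
- The LASSO λ is shared across folds (tuned globally); per-fold tuning
  would give slightly more honest CV performance estimates.
- The piecewise Cox model assumes proportional hazards within each
  interval and shares covariate effects across intervals.
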