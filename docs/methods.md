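# Methods

This note documents the statistical models implemented in `rtproteomics`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Data model and preprocessing

The central container (`AbundanceMatrix`) is a protein × sample grid of
log₂ intensities with per-sample metadata (patient, cohort, timepoint
t0…tT, optional binary toxicity label). Timepoints are treated as equally
spaced integer indices — the sampling design is weekly — so linear
interpolation in time operates on the index.

The model-based preprocessing chain is **interpolate → quantile normalise →
log₂/z-score**:

* *Interpolation* fills only interior gaps of each patient's time course;
  measured endpoints are never altered and missing endpoints are never
  invented. Proteins absent from every sample are dropped; a protein with
  fewer than two observations for a patient stays missing there and is
  counted in the report.
* *Quantile normalisation* maps every sample onto the mean of sorted
  columns. *TIC normalisation* (equal total intensity per sample) is a
  separate, linear-scale operation: where raw intensities are the input,
  TIC comes first and the log₂ transform after — the order is configurable
  because the upstream convention is ambiguous.
* *z-scoring* is per protein across all samples of a run. Zero-variance
  proteins are kept with all-zero rows (and a warning) so protein universes
  stay aligned across contrasts.

One caveat discovered during development: the composed chain has no exact
fixed point. Each step individually is a projection (running it twice
changes nothing), but per-protein z-scoring perturbs the common column
distribution that quantile normalisation enforces, so re-running the full
chain on its own output changes values by a small residual (median |Δ|
≈ 0.05 z-units at realistic scale, correlation > 0.99). The tests assert
per-step idempotence exactly and composed-chain stability at that level.

## Paired differential abundance

Contrasts are complete-case: a patient enters the t_a-vs-t_b contrast only
with both samples present, so every protein is tested on the same pairs.
The primary fold-change statistic is the mean paired log₂ difference; a
linear-scale ratio-of-means ("max fold change", the vendor-tool
convention) is carried alongside for comparison. Degenerate cases are
deterministic: all-zero differences give p = 1; a nonzero constant
difference (unbounded t) reports the smallest positive double as p.
BH adjustment is applied per contrast, not pooled. A one-way
repeated-measures ANOVA over a list of timepoints is provided as the
within-subject omnibus complement (F = t² at two timepoints).

## Power under multiplicity

Exact two-sided paired-t power: under effect δ and within-subject SD σ the
t statistic follows a noncentral t with df = n−1 and ncp = (δ/σ)√n, and
both rejection tails are counted. At δ = 0 the function returns α exactly.
For |ncp| large enough that scipy's noncentral-t tails underflow, the
Gaussian approximation t′ ~ N(ncp, 1 + ncp²/2df) substitutes (power is
within 10⁻⁶ of 1 in that regime). Multiplicity enters through the applied
α: Bonferroni α/m, or the BH step-up boundary at rank k, (k/m)·q, when
about k of m discoveries are expected at FDR q. With m = 600, k = 30,
q = 0.05 this gives α_eff = 0.0025; the formula is the standard one even
where other summaries of the same quantity circulate.

## Kinetic clustering

Longitudinally shared DAPs are summarised by per-timepoint means across
patients. Trajectories are z-scored by default (shape, not level, should
drive similarity; a flag disables this), their Pearson correlation matrix
computed, and each protein's row of correlations used as its feature
vector — "clustering the correlation values" with a Euclidean metric only
makes sense on such feature vectors. Complete-linkage agglomeration is cut
to three clusters; the silhouette is computed in the same feature space.
The alternative distance 1−r sits behind a flag. Constant trajectories
(undefined correlation) are excluded with a warning. The archetype
classifier calls a trajectory increasing when all successive differences
are ≥ −tol with positive net change (tol defaults to 5% of the range),
decreasing symmetrically, and non-monotone otherwise.

## Latent factor models

`fit_factor_model` is Gaussian probabilistic factor analysis — x = Wz + ε,
z ~ N(0, I_K), heteroscedastic diagonal noise — fitted by EM to a relative
log-likelihood tolerance of 10⁻⁶ (max 2000 sweeps; non-convergence returns
a flagged model). This is a re-implementation of the model *class* used by
MOFA-style tools, not a port of their variational schemes; acceptance is
parameter recovery, not numerical parity.

Three reporting conventions remove the usual indeterminacies:

1. **Varimax rotation.** The FA likelihood is invariant under orthogonal
   rotation of the latent space, so raw EM solutions mix sparse generating
   factors arbitrarily and differ between restarts. Varimax picks the
   maximally sparse-loading rotation, restoring the axis alignment that
   sparsity/ARD priors provide in MOFA, and makes refits reproducible
   (factor-wise |r| > 0.95 across seeds on separated planted factors).
2. **Ordering by incremental variance explained.** Factors are appended
   greedily by residual-SS reduction; each increment is
   100·(SS_drop)/SS_tot, floored at 0 (correlated posterior scores can
   produce tiny negative increments), and a final stable sort enforces the
   descending convention.
3. **Sign.** Each loading column is flipped so its largest-magnitude entry
   is positive.

Retention keeps factors with ≥ 2% variance explained (at least one always
survives). A note on scale: with ~130 samples the Marchenko–Pastur noise
share per spurious factor crosses 2% from above as the panel grows past
roughly 300–400 proteins, so the 2% rule prunes noise factors at the
~500-protein panel scale this pipeline targets but cannot at much smaller
panels. ARD-style pruning is deliberately omitted; the ≥2% rule and the
K = 15 cap are the only truncation mechanisms.

`fit_temporal_model` adds the longitudinal structure: alternating between
(i) posterior-mean score updates given loadings followed by per-patient
GP-regression smoothing of each factor over time, and (ii) ridge
least-squares loading updates. The squared-exponential kernel's
hyperparameters — lengthscale ℓ ∈ {0.5, 1, 2, 4, 8} weeks and the share of
score variance assigned to the smooth component r ∈ {0.05 … 0.99} — are
chosen per factor by maximising the summed GP marginal likelihood over
patients. The per-factor *smoothness* statistic is var(smoothed)/var(raw)
scores. ℓ < 10⁻⁶ is an explicit no-smoothing special case returning the EM
scores unchanged (the GP limit would otherwise shrink by r). A single
observed timepoint falls back to the non-temporal model with a warning.

## Toxicity stratification

Patients are clustered into two groups by Ward agglomeration on factor
scores. Because FA scores are unit-scale by construction (factor strength
lives in the loadings), Euclidean clustering of raw or standardised scores
weights every factor equally and lets noise factors swamp an outcome-linked
axis; the default therefore weights each factor's scores by √(variance
explained) — the analogue of PCA scores carrying their eigenvalues —
with per-factor standardisation and complete linkage available as options.
Cluster–outcome association uses the two-sided Fisher exact test;
per-factor cluster separation uses Welch t-tests with Bonferroni
correction over factors.

Biomarker selection takes the top 5% of proteins by absolute loading on
the lead factor (ties broken by identifier, flagged), then filters by a
permutation null: loadings are shuffled across protein labels B = 1000
times and a protein's empirical p is the add-one-smoothed proportion of
permutations whose assigned |loading| strictly exceeds its observed one —
the strict inequality puts the top-magnitude protein at the floor 1/(B+1).
Shuffling outcome labels instead is available as an option. Two-fold
validation flags strict |log₂ FC| > 1 between outcome groups.

Per-feature screening reports Cohen's d with pooled SD (|d| ≥ 0.8 large,
0.5–0.8 moderate), a two-sided Mann–Whitney test (exact for ≤ 10 untied
observations per group, tie-corrected normal approximation otherwise), the
AUC as U/(n₁n₀), a patient-level percentile bootstrap CI (B = 2000;
single-class resamples are redrawn), and a univariable logistic odds ratio
per log₂ unit with a 95% Wald CI. Perfect or quasi-separation is detected
and reported as a flagged non-estimable OR rather than a silently diverged
fit.

## Nested cross-validation

The outer loop is stratified k-fold (default 10; reduced with a warning
when the smaller class is smaller than k): held-out folds never touch
feature selection or model fitting. Within each outer-training partition,
candidate features are scored by univariable AUC over repeated stratified
CV (5-fold × 50). One selection event is recorded per *repeat* — features
ranked by their mean validation-fold AUC across that repeat's folds —
because a per-split pick on 2–5-patient validation folds is pure noise;
selection frequency is the fraction of repeats selecting the feature, with
stability bands ≥ 0.8 highly reproducible / ≥ 0.5 moderately stable /
otherwise unstable. The default selection rule is top-3 by mean inner AUC;
an AUC-threshold mode is available. The final per-fold model is L2-ridge
logistic regression (small fixed penalty keeps 2–3-patient folds
estimable). Both the mean of per-fold AUCs and the pooled out-of-fold AUC
are reported; the pooled estimate is much more stable at small n and is
the one used in calibration checks. The composite ranking is the mean of
min–max-normalised [AUC, −log₁₀ p, selection frequency] — a documented
default, configurable by pre-transforming inputs. `bootstrap_refit_auc`
reports the apparent AUC under patient-level resampling with refitting and
is flagged in-sample/optimism-prone in its output.

## Over-representation analysis

One-sided Fisher exact (hypergeometric upper tail) per gene set against a
user-supplied background, BH across the sets tested, results filtered at
q < 0.01 by default. The odds ratio is the cross-product ratio with a
Haldane 0.5 correction for zero cells. The background defaults to the
proteins quantified in the run, not the genome: nanoparticle-corona panels
are a biased universe and a genomic background would inflate enrichment.

## Synthetic cohort generator

The generator emulates the study design on the log₂ scale:

x[j,i,t] = μ_j + b_{ij} + g_j(t) + Σ_k W_{jk} Z_{itk} + ε, with

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 26 | prostate cohort size (bladder 23, head & neck 11) |
| `timepoints` | t0–t4 | weekly sampling (t0–t6 for head & neck) |
| `n_proteins` | 500 | panel size |
| `sigma_within` | 0.45 log₂ | within-subject noise SD ε |
| `intercept_sd` | 0.3 log₂ | patient random intercept b |
| `baseline_mean/sd` | 20 / 2 log₂ | log-normal linear dynamic range μ |
| `n_factors_true` | 3 | planted factors |
| `loading_density` | 0.05 | fraction of proteins loaded per factor |
| `loading_sd` | 0.8 | loading scale W |
| `toxicity_effect` | 2.0 | Cohen's-d shift on the toxicity factor |
| `frac_toxic` | 17/26 | toxic-patient fraction |
| `secondary_score_sd` | 0.6 | score SD of non-toxicity factors |
| `kinetic_fraction` | 0.3 | proteins with planted trajectories g |
| `kinetic_amplitude` | 1.0 log₂ | trajectory span |
| `missing_rate` | 0 | interior patient-timepoints dropped |

Choices where the upstream description is silent: the toxicity outcome is
a constant-in-time mean shift on one factor's scores (a time-growing ramp
is optional); the toxicity-linked factor is the dominant patient-level
axis (secondary factors at 0.6 score SD), mirroring a primary factor of
variation that separates outcome groups; loading SD 0.8 makes planted
biomarkers shift > 2-fold between outcome groups at d = 2, matching the
magnitude reported for validated biomarkers; loading density 5% makes the
planted-biomarker set commensurate with a top-5% selection on a ~500-
protein panel. All randomness flows from one seed through SeedSequence
spawning, so outputs are bit-identical given a configuration.

What the generator does *not* emulate: peptide-level quantification,
missingness that is abundance-dependent (MNAR), batch effects, heavy-tailed
or correlated noise, cohort-specific biology, or real pathway structure.
Passing recovery tests therefore demonstrates that the estimators recover
the stated generative structure at the stated sizes — not that real plasma
data satisfies that structure.

## Problem sizes in the test-suite

Statistical checks run at sizes chosen to make the checked property, not
its sampling noise, the binding constraint: type-I/FDR calibration at
2000/1000 null proteins; Monte-Carlo power verification at 50 000
replicates; biomarker-pipeline recovery at the full study geometry
(26 patients × 5 timepoints × 500 proteins, 20 seeds); nested-CV
calibration and recovery at 60–80 patients, where fold-level AUC noise no
longer dominates; GP-smoothness discrimination over 50 replicates of
15-patient, 40-protein panels.

## Known limitations

* The EM factor model has no sparsity prior; identifiability rests on
  varimax, which assumes the generating loadings are approximately sparse.
* The ≥2% retention rule is scale-dependent (see above); at panels ≪ 300
  proteins it cannot separate signal from Marchenko–Pastur noise factors.
* GP hyperparameters come from a small grid, not continuous optimisation;
  lengthscales outside 0.5–8 weeks are not considered.
* Nested-CV fold AUCs at n ≈ 26 with 10 outer folds rest on 2–3 held-out
  patients each and are individually uninformative; use the pooled AUC.
* The bootstrap refit AUC is an in-sample quantity and is reported only as
  an optimism-prone upper reference, never as a performance estimate.
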