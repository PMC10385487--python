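# Methods

This note documents the models hybridgp implements, the choices made where
the design was genuinely open, and what the synthetic data do and do not
establish about behavior on real trials.

## REML engine

All models are instances of `y = Xb + Σk Zk uk + e` with
`uk ~ N(0, Kk(θ))` and `e ~ N(0, R(θ))`.  Random-term covariances are
linear combinations of fixed basis matrices (`σ² K₀` for kernel terms;
`Σ ⊗ I` with an unstructured small `Σ` for the hybrid-by-location term),
which lets the solver precompute `Zk B Zkᵀ` once per fit.  Residual
structures: IID, AR1 along columns, AR1 columns + nugget, AR1 rows × AR1
columns + nugget (all built on the full field grid and marginalized to
observed plots by taking the corresponding submatrix), and a known
diagonal (never rescaled — used when each observation carries its own
known error variance).

* **Optimizer.** Average-information updates with step-halving; if a
  (ridged) AI step cannot increase the restricted likelihood, a scaled
  gradient-ascent step with line search is taken instead, so the
  log-likelihood is non-decreasing across iterations.  Convergence:
  relative log-likelihood change < 1e-8 or 100 iterations; a
  non-converged fit is returned flagged, never silently.
* **Parameterization.** Variances on the log scale, correlations through
  atanh, unstructured blocks through a log-Cholesky factor.  Every
  iterate is therefore feasible; boundary estimates appear as variances
  shrinking toward zero (clipped at exp(±25)).
* **Initialization.** Deterministic: the OLS-residual variance split
  equally across variance components, correlations at 0.  (Raw
  phenotypic variance would be a poor scale here because stage-1 models
  carry hundreds of fixed hybrid effects.)  Two fits of the same model
  and data are bit-identical.
* **AIC** = −2·logLik + 2·k with k the number of *estimated* variance
  parameters; components held fixed do not count.  AIC comparison
  refuses fits whose fixed-effect specifications differ, since REML
  likelihoods are only comparable under a common fixed part.
* **BLUPs.** Random terms may carry kernel levels with no data; their
  incidence columns are zero and `û = K Zᵀ P y` then yields the
  kernel-conditional expectation `K_new,obs K_obs,obs⁻¹ û_obs`
  automatically.  This is how untested hybrids and unevaluated parents
  are predicted.
* **Aliased fixed-effect columns** are dropped left-to-right with a
  warning (first occurrence wins).
* Known degenerate behavior: when a nugget absorbs all residual variance
  the AR1 correlation becomes unidentified (a likelihood ridge) and its
  estimate is arbitrary; consumers should read ρ̂ together with σ̂²ₑ.

## Stage 1 (single-trial spatial analysis)

The ladder crosses two mean structures (fixed hybrid + fixed block;
plus a random column effect) with the four residual structures — eight
models per trial/trait.  Hybrids are fixed effects; blocks use
sum-to-zero contrasts so each hybrid's one-hot coefficient is directly
its BLUE at the average block, with its standard error from the
fixed-effect covariance.  In a complete two-block RCBD with IID errors
this reproduces the raw hybrid mean exactly.  Entries that fail or do
not converge are excluded from AIC selection; selection requires at
least one converged entry.  An empirical semivariogram (pairs binned by
Euclidean plot distance rounded to integer lags) is provided for
residual diagnostics.

## Multi-trial model

Raw plot data from all trials enter one model with fixed trial
intercepts, fixed blocks nested in trials, a random hybrid-by-location
term with an unstructured 2×2 location covariance, and an IID residual.
Broad-sense heritability per location is `σ²a(loc)/(σ²a(loc)+σ²ε)`;
CVG uses each location's observed plot mean, CVε the grand mean.  The
AVG prediction target is defined as the mean fixed trial intercept plus
each hybrid's across-location mean BLUP — predictions for AVG likewise
add the stage-2 mean trial intercept, so correlation is unaffected and
RMSE is computed on a common scale.

## Stage 2 (combining ability)

The GCA incidence enters one parent-effect vector twice per hybrid, so
the implied hybrid additive covariance is
`σ²gca (G_ii + G_jj + 2G_ij)`; reporting follows the scalar `2σ²gca`
bookkeeping, which is what the published partition arithmetic uses (the
matrix and scalar conventions differ by the parent-relationship terms;
the scalar form is the one whose proportions reproduce the published
table).  δ is IID over hybrids in both models.  The hybrid-by-trial
kernel indexes all trials independently (`I_t ⊗ Gh`).  The GCA+SCA
model pins `σ²gca` and `σ²gxt` to the GCA fit's estimates as fixed
components of the covariance — verified exactly equal, not re-estimated.
Stage-1 SEs enter as a known diagonal residual with no rescaling.

## Marker QC and kinship

MAF (≥ 0.05) and missingness (≤ 0.10) bounds are inclusive; PIC is the
standard biallelic informativeness `1 − (p²+q²) − 2p²q²`.  LD between
sites uses the kinship-corrected rv²: both dosage vectors are whitened
by the inverse Cholesky factor of a kinship matrix and correlated after
projecting out the whitened intercept (equivalently a GLS regression);
with an identity kinship this is the plain squared Pearson r.  The
centered VanRaden GRM is singular by construction, so callers ridge it
(e.g. +1% of the mean diagonal) before whitening — the CLI does this.
Pruning scans SNPs in descending PIC order (ties by genome order) and
keeps a SNP only if its rv² with every kept SNP is below the threshold;
within any clique of mutually linked sites exactly the most informative
one survives, and the scan is deterministic.  Missing dosages are
mean-imputed per SNP before centering for PCA and GRMs.  Relationship
matrices are validated symmetric and PSD; eigenvalues in (−1e-8, 0) are
tolerated, anything lower is an error.

## Synthetic data generator

The generator emulates a diploid hybrid breeding study: founder
haplotypes with allele frequencies uniform on [0.1, 0.9] (monomorphic
draws rejected); fully homozygous inbred parents as founder mosaics
(first-order Markov switches along each chromosome, geometric segment
lengths) — full homozygosity makes F1 dosages the deterministic parent
mean; a sparse random mating design with year cohorts and a thin set of
hybrids planted in both years; and RCBD trials whose plot values sum a
trial mean, random block effects, parental GCAs (marker additive
effects), hybrid SCA (per-locus heterozygosity effects), per-trial
deviations drawn with the hybrids' own additive kernel, an IID genetic
residual, an AR1⊗AR1 field error and a nugget.  Genetic draws (GCA,
SCA, G×T, δ) are centered and rescaled so realized variances equal the
configured targets exactly, which makes recovery tests sharp.  Defaults
mirror the study conditions (16 founders, 456 parents × 704 SNPs, 769
hybrids, 2 locations × 2 years, 2 replicates); `SimConfig.desk_scale()`
is the quarter-scale variant (120 parents, 200 hybrids).

What the generator does **not** emulate: linkage maps in centimorgans or
realistic LD decay (LD exists only through the mosaic structure),
selection during inbreeding, genotyping error, trait-specific biology,
or non-separable spatial trends.  Passing tests therefore demonstrate
that the estimators recover the parameters of this generative family and
that the pipeline's decisions (model selection, weighting, constrained
two-step estimation, parent-disjoint evaluation) behave as designed —
not that real potato trials meet these assumptions.

A second generator (`simulate_stage2_response`) draws hybrid-by-trial
responses directly from the stage-2 model with all effects on the
kernel scale; it exists because plot-level truth is defined on the
realized-variance scale, whereas variance-component recovery must be
judged on the model's own scale.

## Cross-validation

Parents are assigned to the evaluated set by independent Bernoulli(0.5)
draws (the 0.5 is forced by the intended training:test expectations of
1 and 0.5 for 0EP and 1EP).  Within a repetition both genetic models are
fit on the identical training split (paired comparison); no test
hybrid's BLUE ever enters a training fit, which is asserted each
repetition.  Degenerate splits are resampled with a logged note; more
than 10% failures aborts.  Repetitions are summarized by medians.  The
scaled-RMSE denominator is the mean of the target's truth values over
all hybrids.

## Problem sizes in the shipped experiments

The acceptance-style tests run, by design, at sizes a single CPU
handles in minutes: cross-validation at quarter scale (120 parents, 200
hybrids, 4 trials, 30 repetitions, AVG target); variance-component
recovery with 400 hybrids × 2 trials × 20 replicates; spatial-selection
rates on 16×20-plot fields (160 hybrids × 2 replicates, 100 fields for
the autocorrelated case).  The spatial-selection experiment uses fields
where the spatial variance dominates (σ²ₑ=16, nugget 4, ρ=0.5): smaller
or weakly structured fields leave too few residual degrees of freedom —
after ~160 fixed hybrid effects — for AIC to resolve the full
row×column structure, which is itself a finding about the design sizes
this analysis needs.

## Known limitations

Dense linear algebra throughout: fits scale as O(n³) in plots per trial
and are comfortable to a few thousand observations, not beyond.
Single-trait models only.  Two locations are assumed by the shipped
multi-trial reports (the unstructured block generalizes, but is
untested beyond 2).  Standard errors of variance components are not
reported (no information-matrix inversion at the optimum is exposed).
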