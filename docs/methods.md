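# Methods

## Problem setting

Untargeted LC-MS metabolomics yields a samples-by-metabolites intensity
matrix `X ∈ R^{n×p}` with substantial missingness and strong inter-feature
correlation, together with a categorical phenotype `y` (here: three
diagnostic groups, coded 0/1/2).  The goal is to select the metabolites
genuinely associated with the phenotype while controlling the false
discovery rate (FDR), i.e. the expected fraction of selected metabolites
that are in fact null.  Univariate tests ignore the correlation structure;
most multivariate learners produce no valid p-values.  Model-X knockoffs
bridge the two: a synthetic copy `X̃` of the feature matrix, sampled without
looking at `y`, acts as a per-feature negative control inside any learner.

## Pipeline

For a missingness threshold `t ∈ [0, 100]` the workflow is:

1. **t% rule.**  Metabolite `j` is kept iff it has an observed, nonzero
   intensity in at least `ceil(t/100 · n)` samples.  `t = 0` disables the
   filter; `t = 100` keeps exactly the complete metabolites.  Zeros are
   treated as missing by default (the common export convention for
   undetected peaks); a flag treats them as measurements.
2. **KNN imputation** (skipped at `t = 100`, where survivors are complete).
   A missing entry `(i, j)` takes the mean of metabolite `j` over the `k`
   nearest samples that observed `j`, with inter-sample distances Euclidean
   over co-observed metabolites rescaled to the full feature count.
   Default `k = 10` (the range recommended in the original expression-data
   KNN-imputation work).  Imputation is over nearest *samples*, not nearest
   features: with `n ≈ 546 ≫ p` per chromatography mode, sample space is
   far better populated.  The feature-space reading of "KNN imputation"
   exists in the literature; the choice here is fixed, not configurable per
   call, and recorded in the preprocessing report.
3. **Standardization** to zero mean, unit variance per metabolite
   (denominator `n − 1`, consistent with the covariance estimate below).
   Constant columns are dropped with a warning.
4. **Gaussian knockoff model.**  `X ~ N(μ, Σ)` with `μ` the column means
   and `Σ` a Ledoit–Wolf shrinkage estimate (toward a scaled identity).
   Shrinkage guarantees the positive-definite `Σ` that the conditional
   formulas require even when `p` approaches `n`; the intensity is the
   Ledoit–Wolf automatic choice by default and configurable.  The
   decorrelation vector uses the equi-correlated rule on the correlation
   scale, `s_j = min(2 λ_min(corr(Σ)), 1) · Σ_jj` — deterministic and
   dependency-free, versus the SDP variant which buys a little power at the
   cost of a solver.  Knockoffs are drawn from
   `X̃ | X ~ N(X − (X − 1μᵀ) Σ⁻¹ diag(s), 2 diag(s) − diag(s) Σ⁻¹ diag(s))`,
   the conditional covariance eigenvalue-floored at zero (warning if the
   floored mass exceeds 1e-8 of the trace).  `B = 15` copies are drawn from
   per-copy RNG streams spawned from the master seed, so each copy is
   independently reproducible.
5. **Importance.**  Each `[X, X̃^(b)]` (2p columns; original/knockoff pair
   positions randomly swapped, recorded, and undone afterwards — a guard
   against column-order bias that a flag disables) is scored by a random
   forest classifier: 1000 trees by default, `mtry = round(sqrt(2p))`,
   per-tree out-of-bag (OOB) permutation importance in Breiman's original
   form.  A tree that never uses a feature contributes a zero decrease.
   `Z_j = |mean decrease|`; a flag switches to mean-of-absolute-decreases,
   the other reading of "absolute mean decrease".
6. **Selection.**  `W_j = |Z_orig_j| − |Z_knock_j|`; per draw
   `π_j = (1 + #{k : W_k ≤ −W_j})/p` if `W_j > 0` else 1 (`W_j = 0` counts
   as no evidence); aggregation `π̄_j = min(1, q_γ({π_j^(b)})/γ)` with
   `γ = 0.5` and the lower empirical quantile (order statistic at rank
   `ceil(γB)` — deterministic and conservative); Benjamini–Hochberg step-up
   at `α = 0.05` on the post-filter feature count `m`, ties at the
   threshold all selected.

The threshold sweep re-filters, re-imputes and re-standardizes per `t`
(the surviving feature set differs per `t`), and by default mixes `t` into
the random stream so per-threshold selections do not share knockoff noise;
a flag switches to fully shared randomness for sensitivity analysis.

## Synthetic data generator

The generator emulates the structure of a multi-mode IBD stool metabolomics
cohort: `n = 546` samples, 150 metabolites, three classes of equal size
(remainder to class 0), AR(1) latent correlation (`ρ = 0.5`; independent
and block-equicorrelated structures available), log-normal positive
intensities (`exp` of the latent Gaussian), 20% missingness, and a minority
(45/150) of truly class-associated metabolites whose latent means are
equally spaced across classes with step `effect_size` (in within-class SD
units).  Signal positions are a seeded shuffle so signal status is
independent of the correlation blocks.  Missingness is either MCAR or
intensity-dependent through a logistic link in the latent value (left
censoring, the dominant MS mechanism); the link's offset is calibrated by a
probit approximation, so the realised rate matches the target only
approximately in that mode.  Not simulated: retention-time drift, adducts,
isotopes, batch effects, heteroscedastic technical noise.  Passing tests on
this generator therefore demonstrate the statistical machinery under a
correlated-Gaussian-latent model, not robustness to instrument artifacts.

## Operating characteristics and an intrinsic granularity

Two structural facts shape what this estimator can and cannot do; both are
consequences of the operative definitions above, and both are verified
empirically by the test suite.

**Minimum discovery count.**  The intermediate p-values are empirical
ranks, so `π_j ≥ 1/p`, hence `π̄_j ≥ 1/(γp)` (= `2/p` at `γ = 0.5`).  BH
rejects the `k` smallest aggregated p-values only if `π̄_(k) ≤ kα/m`; with
`m = p` the floor forces `k ≥ 1/(γα)` — 40 features at the defaults.  The
selection is therefore all-or-nothing below that scale: either at least 40
metabolites are selected at once, or none.

**Importance dilution.**  Per-feature permutation importance measures the
*marginal* contribution of a feature to forest accuracy.  When 40+ features
all carry strong signal, the classification task saturates (OOB accuracy at
ceiling) and every individual feature becomes redundant: permuting one
barely moves accuracy, `W` collapses toward noise, and few features reach
the p-value floor.  Strengthening the per-feature effect makes this worse,
not better.  Empirically (n = 300, p = 100, 50 signals at 1.5 SD; the
signal-recovery test below) at most about half of the signals reach the
floor in any one draw, and the BH condition is never met: the selection is empty and
power is zero.  The combination "RF OOB permutation importance + empirical
knockoff p-values + BH at α = 0.05, γ = 0.5" thus has essentially no power
at desk scale, and the signal-recovery acceptance test documents this
honestly by failing.  Reference implementations of aggregated knockoffs
achieve their reported power with sparse regression coefficient statistics,
which give strongly separated `W` for every signal simultaneously; swapping
the importance engine is deliberately out of scope here.

FDR control, by contrast, holds trivially in this regime — an empty
selection has a false discovery proportion of zero — and the headline FDR
simulation (30 replicates, n = 200, p = 100, 10 signals at 1.0 SD, AR(1)
ρ = 0.5, B = 15, 200 trees) reports a computed mean FDP of 0 ≤ α.

## Problem sizes and numerical choices

Simulation-based checks use 200-tree forests (the package default stays at
1000; the evaluation harness passes 200), 30 replicates for FDR and 20 for
power — sizes chosen so the whole suite runs on a single CPU in minutes.
Determinism: every stochastic step (generator, knockoff draws, pair swaps,
bootstrap, tree construction, OOB permutations) derives from one master
seed through `numpy` `SeedSequence` spawning; the same seed reproduces
selections bit-for-bit on the same platform.  Degenerate inputs: constant
columns are dropped before scaling; all-missing columns are dropped with a
warning before imputation at `t = 0`; a singular covariance (even after
shrinkage) or a filter that removes every metabolite raise errors naming
the remedy.  Ties: BH selects all features tied at the threshold; the
intermediate p-value counts boundary ties `W_k = −W_j` by its closed
inequality; KNN donor ties follow the partial-sort order of the underlying
imputer (measure-zero for continuous data).

## Known limitations

- The Gaussian working model is an approximation; on log-normal intensities
  the knockoffs are only moment-matched after standardization.
- Empirical FDR control is demonstrated, not proven, for the RF importance
  statistic; the model-X guarantee assumes the knockoff distribution is
  exact.
- The minimum-discovery granularity above makes the procedure unsuitable
  when fewer than `1/(γα)` associated features are expected.
- No deep generative knockoffs; no alternative importance statistics.
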