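# Methods

## Generative model of the synthetic cohort

The pipeline's statistical assumptions are linear-Gaussian, so the
synthetic cohort is built from a linear latent-factor model for which CCA
is exactly consistent and population canonical correlations are available
in closed form — that is what makes oracle testing possible.

Per participant, latent factors z ~ N(0, diag(s²)) with strictly
decreasing strengths s₁ > … > s_k are mixed into the two views through
sparse unit-norm loading rows A (k×p, DN) and B (k×q, HC):

    DN = Z A + σ E₁ ,   HC = Z B + σ E₂ ,

with i.i.d. standard-normal noise E and noise scale σ (`noise_sd`).  The
population joint covariance is then Σxx = AᵀS²A + σ²I, Σyy = BᵀS²B + σ²I,
Σxy = AᵀS²B, and population canonical correlations are the square roots of
the eigenvalues of Σxx⁻¹ΣxyΣyy⁻¹Σyx (`population_joint_covariance` /
`population_canonical_correlations`).

Group structure: a balanced binary label (1 = low social support).  For
labelled participants the loading entries listed in `perturbed_entries`
are shifted by `delta` before mixing — the perturbation acts on the
co-variation *pattern*, not on mean volumes, because the group contrast
operates on canonical vectors.  Confounds (age ~ N(55, 7.5²) clipped to
[40, 70], sex ~ Bernoulli(½), three standard-normal scanner-like
nuisances, plus age², sex·age, sex·age² from uncentered age) are added
with known linear coefficients on standardized columns.  Genotypes are
binomial(2, maf) per SNP with maf ~ U(`maf_range`); when
`prs_mode_coupling = c ≠ 0` the designated mode's factor is rebuilt as
`c·standardize(Σ gᵢβᵢ) + √(1−c²)·fresh noise`, so the weighted genotype
score correlates with that mode's expression by ≈ c.

Defaults: `n_per_group=1000`, `p_dn=91`, `q_hc=38`, `k_true=5`,
`factor_strengths=(3.0, 2.5, 2.0, 1.5, 1.0)`, `loading_sparsity=0.3`,
`noise_sd=1.0`, `n_snps=500`, `maf_range=(0.05, 0.5)`.  Volumes are
unitless: the analysis consumes z-scored residuals, so only the ratio of
factor strengths to noise matters; the covariance scale of real subregion
volumes is not modelled.  One global seed drives named RNG sub-streams per
data block (loadings, factors, noise, confounds, genotypes, labels), so
e.g. changing `n_snps` leaves the volume tables untouched.

What the generator does **not** emulate: image-level artifacts, nonlinear
confound effects, LD structure among SNPs, ancestry stratification,
non-Gaussian volume distributions, and site/batch heteroscedasticity.
Passing tests therefore certify the statistical machinery under its own
assumptions, not robustness to the full messiness of real imaging-genetic
cohorts.

## Deconfounding

OLS residualization of every volume column on an intercept plus all
confound columns, followed by z-scoring with the *sample* (n−1) standard
deviation.  Interaction columns are derived from uncentered age when
absent.  Missing values are rejected rather than imputed (complete-case
design).  Deconfounding happens once on the full cohort, before any group
split.  Rank-deficient designs are rejected with the collinear columns
named (pivoted-QR detection).

## CCA engine

SVD of the Cholesky-whitened cross-covariance: with Σ̂xx = LxLxᵀ,
Σ̂yy = LyLyᵀ, the singular values of Lx⁻¹Σ̂xyLy⁻ᵀ are the canonical
correlations and back-substitution gives the weights.  This is more stable
than the generalized-eigenvalue formulation.  Conventions:

* weights are scaled so each variate has unit sample variance;
* deterministic sign: per mode, the HC-side weight of largest magnitude is
  made positive, so refits are byte-identical (ties in ρ keep SVD order);
* no regularization by default (the intended regime is n ≫ p+q); an
  optional ridge on the within-view covariances supports small-n synthetic
  runs, and a warning fires when n ≤ p+q;
* near-singular within-view covariance raises a numerical error that
  suggests the ridge.

The contrast stage operates on the weights (canonical vectors) as the
model defines them, not on structure loadings (variable-variate
correlations), which remain computable from the stored solution.

## Mode matching

Mode order and sign are not identifiable across refits.  Two solutions are
matched by building the k×k matrix of absolute Pearson correlations
between concatenated canonical vectors [vₗ; uₗ] — both views together, so
a mode is identified by its full anatomical signature — and solving the
assignment exactly with the Hungarian algorithm (greedy matching can
cascade errors when neighbouring ρ values are close).  The sign is −1
where the matched pair's signed correlation is negative.  Matches with
score < 0.5 are flagged; downstream stages count them (default: keep and
flag rather than drop replicates).

## Bootstrap group contrast

Resampling is stratified within group, preserving each group's size, so
every replicate yields a fittable per-group model; pooled resampling is
available behind a flag for sensitivity checks.  Both group solutions are
aligned to a single full-cohort reference, which fixes their mutual
alignment and a stable orientation across replicates simultaneously.
Differences are low-support minus adequate-support, so a positive entry
means a larger canonical weight in the isolated group.  Intervals are
plain percentile (default 10/90, an 80%-coverage two-sided interval, so
~20% of null entries are flagged by construction); no bias correction.  No
multiple-testing correction across the k×(p+q) tests — the result records
how many were performed.  `determine_hits` recomputes flags at other
percentile bounds from the stored draws without refitting.

## Genetic association

QC thresholds are strict inequalities (maf < 0.01 and info < 0.8 are
excluded; exact boundary values are retained).  Extreme-group selection
takes ⌊qn⌋ participants per tail after a stable sort on (score,
participant_id) — a deterministic tie rule; an all-tied score vector is
rejected as undefined.

The extreme-group outcome is modelled with Bayesian logistic regression
(the design intended for a binary outcome; a Gaussian-likelihood variant
on the continuous score is available via `family="linear"`).  Priors are
standard normal on all 25 mode slopes, the sex-specific intercepts and the
sex-specific slopes on z-scored age.  Predictors are z-scored by default
(configurable).  Sampling uses emcee's affine-invariant ensemble with
differential-evolution moves, 64 walkers, and ≥3 independent chains seeded
from a single spawning sequence.  Walkers are initialized from the Laplace
approximation at the MAP (Hessian-scaled noise): ball initialization at
the MAP leaves the ensemble under-dispersed for hundreds of steps and
biases posterior tail mass, which we verified against the analytic Laplace
solution; dispersed initialization removes the bias.  Of the ensemble
moves, the differential-evolution move reproduces a known Gaussian target
exactly, and is used alone.  Convergence requires split-R̂ ≤ 1.01 and
effective sample size ≥ 400 per coefficient; failures mark the summary
unreliable (with a warning) rather than silently returning.

Relevance rule: a coefficient is flagged when ≥95% of posterior mass lies
on one side of zero.  Note this is a one-sided 0.05 tail — under a null
coefficient it fires with probability ≈ 0.10 in the weak-prior regime, not
0.05; the calibration tests document this property.

## Reporting

Hits are tallied per mode × category (HC: CA1, CA2/3, CA4, DG, HATA, Para,
PrS, Sub, Fissure, Fimbria, ML, Tail; DN: temporal, prefrontal, parietal,
posterior cingulate), with margins cross-checked by construction.
Percentages are rounded to one decimal for display; raw fractions stay in
machine output, and empty tables report shares as undefined rather than
0/0.  The DN parcel-to-category mapping shipped with the default atlas is
a reconstruction (the source analysis did not publish one); the published
hit tables encoded in `reference_tables.py` are reproduced as printed,
including their internal inconsistencies with the accompanying text, which
are documented there rather than reconciled.

## Problem sizes in the test suite and acceptance script

Stochastic suites run at sizes chosen to make their Monte-Carlo bands
tight enough to be meaningful while keeping the suite practical on one
CPU: contrast null calibration at p=12/q=8, n=400/group, B=100 over 50
seeds (the calibration property is size-free); planted-perturbation
recovery at the full 91+38 atlas, n=2000/group, 20 seeds; Bayesian null
calibration at n=2000 over 20 seeds; the weak-prior MLE comparison at
n=50000; end-to-end PRS power at n=5000 with coupling 0.3 over 10 seeds.
The acceptance script uses the same designs with slightly fewer seeds.

## Known limitations

* The bootstrap contrast's false-alarm rate is set by the 10/90 interval;
  interpreting raw hit counts requires the ~20% per-entry baseline in
  mind.
* Percentile intervals ignore bootstrap bias; with B=100 the interval
  endpoints themselves carry Monte-Carlo noise.
* CCA weights are only identified up to the quality of mode separation;
  when neighbouring ρ values are close, matching degrades and flagged
  replicates rise.
* The Bayesian stage assumes independent N(0,1) priors as specified; no
  hierarchical shrinkage across modes.
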