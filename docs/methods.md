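# Methods

## The model

The unit of analysis is a patient with a binary lesion mask, an acute
NIHSS severity score (0–42), and clinical covariates. Lesion anatomy
enters the model through a two-step reduction:

**Lesion loads.** A mask is reduced to lesioned-voxel counts over 129
parcels — 109 gray-matter regions (47 cortical and 7 subcortical per
hemisphere plus the brainstem) from one label atlas and 20 white-matter
tracts from a second. The two atlases are treated as independent label
volumes: a voxel lying in both a gray-matter region and a tract counts
toward both (dual counting is deliberate; neither readout is privileged).
Masks must be strictly binary and share the atlas grid and affine; no
resampling or thresholding is performed.

**Lesion atoms.** The loads matrix is `log1p`-transformed and factorized
by NMF, `X ≈ H·W`, into `k = 10` atoms. `log1p` handles the many zero
loads while compressing the heavy-tailed counts; `k` is fixed
configuration, not selected by the package. The factorization minimizes
squared Frobenius error with multiplicative updates from a deterministic
NNDSVD initialization (structural zeros filled with the matrix mean so
updates can move them, except columns that are zero in the data, which
remain exactly zero). The per-iteration error trace is recorded and is
non-increasing by construction. Basis rows are L2-normalized with the
scale moved into the scores; this resolves NMF's scale indeterminacy so
that regression coefficients are comparable across runs and cohorts.
Multiplicative updates were implemented in-package because the contract
requires the recorded monotone error trace and normalized rows; tests
cross-check the attained reconstruction error against scikit-learn's NMF.
A fitted basis embeds a new cohort via per-patient non-negative least
squares on the `log1p` loads; atoms from two independent fits are aligned
by maximizing total Pearson correlation with an assignment solver.

**Regression design.** Atom scores and the NIHSS outcome are both
residualized by OLS on `[1, log1p(lesion volume in ml)]`, removing pure
lesion-size effects; residualization also centers the outcome, which the
intercept prior below presumes. Scores are then scaled to unit variance.
Covariates: z-scored age, its square (computed from the z-score so both
age terms share a scale), sex coded female = 1, four comorbidity
indicators (hypertension, diabetes, atrial fibrillation, coronary artery
disease) and `log1p` WMH volume. Rows with missing values raise an error
listing patient ids — complete-case analysis, nothing dropped silently.
Every fitted transform parameter (age mean/SD, volume-regression
coefficients, score scales) is captured in a serializable
`DesignTransform`, so a validation cohort can be processed with the
derivation cohort's transform verbatim rather than refit.

**Hierarchical likelihood.** Severity is Gaussian around a linear
predictor with sex-specific atom coefficients:

    hyper_σ_β ~ HalfCauchy(5)
    σ_β,g     ~ HalfCauchy(hyper_σ_β)
    hyper_μ_β ~ Normal(0, 10)
    μ_β,g     ~ Normal(hyper_μ_β, 10)
    α         ~ Normal(0, 1)
    β_k,g     ~ Normal(μ_β,g, σ_β,g)        k = 1..10 atoms
    β_age, β_age² ~ Normal(0, 10)
    β_sex, β_comorb, β_WMHv ~ Normal(0, 1)
    ε ~ HalfCauchy(20)
    y_i ~ Normal(α + Σ_k β_k,g(i)·s_ik + c_i·β_cov, ε)

Groups g are `{all}` (pooled model: the same hierarchy with one group),
`{male, female}`, or, in the two-level stratified variant, stratum × sex
cells with an intermediate stratum level (global hypers → stratum-level
μ/σ → sex-within-stratum μ/σ → per-cell coefficients); the covariate
block is shared across cells. The non-hierarchical sex covariate absorbs
lesion-independent severity differences between the sexes, so the
sex-specific atom coefficients capture interaction effects only. The
Gaussian likelihood is kept for the bounded integer NIHSS deliberately —
it is the model's stated form and the synthetic generator's form; a
clipped/rounded outcome is available behind a flag for realism checks.
The HalfCauchy(hyper_σ_β) level uses hyper_σ_β as the scale parameter.

## Sampling

Posteriors are drawn with emcee's affine-invariant ensemble sampler using
a 0.8/0.2 mixture of differential-evolution and snooker moves, which
mixes markedly better than stretch moves in this ~25–65-dimensional
posterior. The model is parameterized to be sampler-friendly:
coefficients as standardized offsets from their group means (non-centered
— removes the funnel between σ_β,g and β_k,g), all half-Cauchy scales on
the log scale with the Jacobian in the target, tail-stable log-density
evaluation throughout. Walkers (max(64, 2·dim+8)) start in a small ball
around the least-squares solution. Defaults: 1500 warmup ensemble steps,
thinning 8, two independent ensembles whose retained, flattened draws
together meet the requested draw count (default 5000). Convergence is
summarized by split-R̂ with one diagnostic chain per independent ensemble
(walkers within an ensemble are mutually dependent, so walker-as-chain
R̂ would be meaningless) plus the mean acceptance fraction; R̂ > 1.05 or
very low acceptance adds an explicit warning to the posterior metadata.
Divergence counts are reported as zero — the concept does not apply to
this sampler. Identical spec and seed reproduce draws bit-for-bit.

## Posterior summaries

The 90% HPDI is the shortest contiguous window over the sorted draws
containing ⌈0.9·N⌉ of them; a parameter is *relevant* when its HPDI
excludes zero. Sex contrasts are male-minus-female differences formed per
MCMC iteration (both parameter sets live in one posterior, so pairing is
exact); each contrast reports mean, HPDI, a relevance flag, and the
fraction of draws opposing the median's sign. Region-wise relevance
propagates the full coefficient draws through the basis
(`relevance_j = Σ_k β_k·W_kj` per draw), so regions get HPDIs, not just
point estimates; whether region relevances should instead come from
refit region-level models is an open interpretation — mean
back-projection is what is implemented. Relevance maps from two
embeddings are compared by Pearson correlation of parcel-wise posterior
means.

## The synthetic generator

`generate_cohort` emulates a hospital-based acute stroke cohort:
sex ~ Bernoulli(0.38 female); age truncated-normal per sex (women
67.7 ± 16.3, men 63.3 ± 13.5, truncated to 18–100 years); sex-specific
comorbidity prevalences (hypertension 29.3/27.4%, diabetes 17.8/20.5%,
atrial fibrillation 9.1/4.6%, coronary disease 6.7/8.1% for women/men);
WMH volume log-normal with mean 11.5 and SD 13.5 ml. Lesion anatomy comes
from a planted non-negative basis of 10 atoms with contiguous, mildly
overlapping parcel blocks (unit L2 rows) and sparse patient scores (1–2
dominant atoms, log-normal magnitudes, log-mean 2.3, log-SD 0.5); integer
loads are `round(expm1(S·W + N(0, 0.05)))`, capped at `expm1(11.5)`
(~10⁵ voxels) per parcel. These scales give median ~0.6 ml / mean ~18 ml
lesion volumes — the right order for an acute cohort — and keep the
`log1p` reconstruction error of the planted low-rank pattern below 0.15.
NIHSS is generated from the model's own likelihood: planted sex-specific
coefficients on the z-scored true scores, covariate effects, Gaussian
noise (default SD 2). The default planted coefficient vectors give a few
atoms relevant in both sexes and several female-only effects — the
pattern the pipeline exists to detect.

The generator emits an *oracle model input*: the exact z-scored true
scores and covariates used to build the outcome, with the outcome
mean-centered (mirroring what volume residualization does in the real
pipeline, and what the Normal(0,1) intercept prior presumes). Exact
coefficient recovery is asserted against this oracle input only;
end-to-end runs from raw loads are checked qualitatively (detection
flags), because NMF's rotation/scale indeterminacy breaks exact
coefficient equality even when the fitted atoms match the planted ones
closely.

What the generator does **not** emulate: real vascular-territory
geometry, registration error, segmentation noise, integer/bounded NIHSS
(by default), and any dependence of lesion topography on covariates.
Passing tests therefore demonstrate the statistical machinery —
identifiability, calibration, detection — under the model's own
generative assumptions, not robustness to the mismatches of real imaging
data.

Phantom atlases partition a small grid into contiguous labeled blocks by
recursive proportional bisection; the gray-matter and white-matter
phantoms occupy disjoint slabs so that fixture masks (which realize a
requested load matrix voxel-for-voxel) round-trip exactly through the
parcellation stage.

## Parameters that matter

| Parameter | Default | Units / meaning |
|---|---|---|
| `n_atoms` | 10 | embedding dimension, fixed configuration |
| `ModelSpec.draws` | 5000 | retained posterior draws (2000 in routine tests) |
| `ModelSpec.warmup` / `thin` / `chains` | 1500 / 8 / 2 | ensemble steps discarded / thinning / independent ensembles |
| prior scales | 5, 20, 10, 1 | HalfCauchy hyper-σ and ε, Normal μ-level SD, α and low-level β SD (NIHSS units) |
| `SimConfig.noise_sd` | 2.0 | outcome noise SD, NIHSS units |
| HPDI mass | 0.90 | relevance and difference flags |
| Bonferroni α | 0.05 / 129 | per-test threshold in region-wise group comparisons |

## Numerical and design choices

- Problem sizes in routine runs: cohorts of n = 555 (38% women), 2000
  retained draws; recovery/calibration checks use 20 replicate seeds,
  detection checks 10, null-rate checks 30 (null flags cluster within a
  replicate — a spurious group-mean shift flags many atoms at once — so
  the rate needs more replicates to stabilize).
- Welch's t test by default in cohort summaries (config-switchable to
  Student); two-sided Fisher exact tests for binary variables; Bonferroni
  correction divides α by the number of parcels per test family.
- "Affected" in frequency comparisons means load > 0 voxels.
- Ties and degenerate inputs: constant volume regressor → mean-centering
  with a logged warning; constant age → zero z-scores with a warning;
  zero basis rows are left unnormalized; HPDI of constant draws is the
  degenerate point interval; HPDI requires ≥ 20 samples.
- Reports are tidy CSV tables (plus JSON provenance with config hash and
  stage seeds); no plotting or 3-D rendering is produced.

## Known limitations

- The Gaussian likelihood ignores the bounded, discrete, zero-inflated
  character of observed NIHSS; posterior predictive draws can leave
  [0, 42].
- The ensemble sampler has no NUTS-style divergence diagnostics; heavy
  prior tails are handled by parameterization, and pathologies would
  surface as R̂/acceptance warnings instead.
- Atlases are consumed as deterministic maximum-probability label images;
  probabilistic-atlas thresholding, spatial normalization and lesion
  segmentation are out of scope.
- The two-level stratified hierarchy is a structural extrapolation of the
  printed single-level model (stratum level inserted between global
  hypers and sex-level parameters); alternative placements of the
  intermediate level are conceivable.
- With ~10% prevalence differences and n ≈ 555, single-cohort Fisher
  tests (e.g., atrial fibrillation by sex) sit near the significance
  boundary; small simulation seeds move them across it.
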