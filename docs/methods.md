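# Methods and design notes

This note records the models `hexdiv` implements, the choices made where the
design was genuinely open, and what the synthetic-data studies do and do not
demonstrate.

## Geodesic grid

The grid is the spherical Voronoi diagram of the vertices of a class-I
(frequency-f) subdivided icosahedron, computed with
`scipy.spatial.SphericalVoronoi`. A frequency-f subdivision has 10·f² + 2
vertices, hence that many cells; twelve of them (at the icosahedron
vertices) are pentagons and are kept as ordinary cells. A cell's *diameter*
is defined as the maximum vertex-to-vertex great-circle distance of its
Voronoi polygon, and grid resolution is specified as the target **median**
diameter over all cells. The subdivision frequency is chosen by a
regular-hexagon area heuristic and the realized median is required to fall
within 10% of the target; because frequencies are integers, some coarse
targets (for example 2000 km, which falls between f = 4 and f = 5) are
unattainable and are rejected with the closest attainable value. The
500 km resolution realizes a median diameter of 498.8 km (f = 18, 3,242
cells); 300 km realizes f = 30.

Grids cover the full sphere — there is no land mask. Cells enter any
analysis only if they receive data, which reproduces the practical effect of
a mask without importing one.

Point-to-cell assignment is nearest-generator on the sphere, which for a
Voronoi tessellation is exact containment. Jitter draws displacements
area-uniformly on the spherical cap of the given radius (distance CDF
proportional to cap area, bearing uniform); the radius is a hard bound.

Planar coordinates for all spatial smooths use the Equal Earth projection
with the 150°E central meridian (the Asia-Pacific variant, EPSG:8859),
implemented from the published polynomial series with a Newton inverse.
Round-trip accuracy is below 1e-6 degrees and the equal-area property holds
to well under 0.5%.

## Feature-state models and entropy

Each feature is fitted independently. Binary features use a Bernoulli
likelihood with logit link; features with J > 2 states use a categorical
likelihood with softmax link and the first observed state as the reference
category (J − 1 free linear predictors; a redundant J-predictor softmax is
not identifiable and the reference-coded model spans the same likelihood
set). The linear predictor contains a global intercept, random intercepts
for geohistorical area, grid cell and language family, and a tensor-product
smooth over projected cell-centroid coordinates. Priors are Normal(0, 2) on
the intercept and half-Normal(0, 2) on every random-effect SD and on the
spline SD.

The tensor smooth is a tensor product of two marginal cubic B-spline bases
(default 5 × 5 = 25 basis functions, open uniform knots over the data
range, inputs clamped to the fitted domain for prediction), with all
coefficients sharing one Normal(0, σ_spline) prior. No sum-to-zero
constraint is imposed; the overlap with the global intercept is resolved by
the priors, and only identified combinations (cell-level probabilities)
are reported.

Cell-level state probabilities are computed per posterior draw as the
**unweighted mean of the expected state-probability vectors of the coded
languages assigned to the cell** (`aggregation="language_mean"`, the
default). An alternative reading — evaluating probabilities directly from
the cell-level linear predictor with family effects at zero — is available
as `aggregation="cell_effect"`; both are exposed behind one switch because
the aggregation step is not uniquely determined by the modelling idiom, and
tests exercise both.

Normalized entropy is Hn = −Σ π_j log π_j / log J with 0·log 0 = 0. For the
logit summaries Hn is clamped to [1e-6, 1 − 1e-6] first, because cells with
a single coded language can produce numerically degenerate entropies. Rows
whose entropy SD collapses to zero still enter the regression, where the
total observation SD then reduces to the residual σ.

## Wright's F

Per individual, F = (H_O − H_E)/(N_NM − H_E). H_E sums 1 − 2·p_j·q_j·c_j
over the individual's non-missing SNPs. The correction factor defaults to
c_j = N_j/(N_j − 1) with N_j the non-missing individuals at SNP j (the
small-sample form used by standard SNP toolkits); `small_sample_correction=
False` selects the plain Hardy–Weinberg expectation c_j = 1, which is the
variant used in the recovery studies because the generator draws exact
Hardy–Weinberg genotypes. Allele frequencies are estimated from the pooled
sample by default. Monomorphic SNPs are excluded; individuals whose
denominator vanishes (no informative SNPs) are flagged with F = NaN rather
than dropped silently.

The cell-level model is Gaussian: F_i ~ N(α + α_AREA + α_CELL + α_POP +
t2(x, y), σ) with the same prior family as above. The reported cell
quantity is the posterior of α + α_AREA + α_CELL + t2 — the cell-level
expected F with population effects marginalised at zero. z-scoring happens
once, across all cells with data (not within areas: area structure is
already absorbed by the random effects), and the measurement SD is divided
by the same factor so predictor and uncertainty stay on one scale.

## Measurement-error regression (m1–m8)

One row per (feature, cell) where linguistic and genetic data are both
available. The response is the posterior mean logit entropy with its known
SD; the total observation SD is σ_i = sqrt(sd_i² + σ²) with σ estimated
(half-Normal(0, 2)). The ladder m1 = {R, T}, m2 = +P1,P2, m3 = +D,
m4 = +F, m5 = +P1,P2,D, m6 = +P1,P2,F, m7 = +D,F, m8 = all. Every included
fixed effect has varying slopes by feature and by area; intercepts
additionally vary by cell (intercept-only, no cell slopes); each group's
intercept-plus-slopes vector follows a multivariate normal whose SD vector
has half-Normal(0, 2) priors and whose correlation matrix has an LKJ(2)
prior. Predictors are centred and scaled over the **unique cells** entering
the analysis, not over rows, so feature coverage does not re-weight them.
When F is included it enters as a latent cell-level value with
F_true = F_obs + F_sd·z, z ~ N(0, 1) — the Normal measurement model around
the estimated value.

Model comparison uses PSIS-LOO (arviz) on the pointwise log likelihood;
the comparison table reports each model's elpd with SE, the pairwise
Δelpd ± SE against the best model, and the maximum Pareto k. Group-level
marginal slopes are β + group deviation, summarised with 50/89/95% HPDIs
and P(slope > 0); features are classified by whether the 89% interval
excludes zero (the package's interval convention throughout).

## Inference engines

No probabilistic-programming framework is used; the package carries its own
inference stack:

- `_ad.py` — a minimal reverse-mode autodiff over numpy arrays (tape in
  creation order, fused kernels for the common prior terms).
- `_nuts.py` — multinomial NUTS with dual-averaging step-size adaptation
  and windowed mass-matrix estimation (diagonal, dense, or block-diagonal),
  warm-startable from a previously adapted mass matrix.
- Scale parameters are sampled through the folded-normal parameterisation
  σ = |u|, u ~ N(0, 2) — exactly the half-normal prior law, but without the
  long left tail a log transform produces when the data barely constrain a
  scale. Correlation matrices are parameterised by canonical partial
  correlations (tanh-transformed), under which the LKJ(η) prior factorises
  into independent scaled Betas; the construction is validated against the
  analytic LKJ marginals in the tests.

Three interchangeable exact samplers target the regression posterior:

1. `fit_model` — NUTS on the full non-centred parameterisation (the
   reference implementation).
2. `fit_model_marginal` — NUTS on the collapsed posterior: all Gaussian
   coefficients are integrated out analytically (Woodbury identities,
   hand-derived gradients), and recovered afterwards by conjugate draws.
3. `fit_model_gibbs` — blocked Gibbs: joint conjugate updates for all
   coefficients, conjugate per-cell updates for latent F, adaptive
   Metropolis-within-Gibbs for scale and correlation parameters, slice
   updates for the remaining scalars.

All three produce the same posterior; the test suite verifies their
agreement on one dataset. They trade off differently with data size: the
full NUTS path is robust but needs hours at hundreds of cells × tens of
features in pure Python, the collapsed sampler excels for small data, and
the Gibbs sampler — whose sweeps cost one sparse gram and one Cholesky —
is used for the large recovery fits and the replicate sweeps. In strongly
data-dominated regimes its conditionals are tight and mixing is excellent
(effective sample sizes near the draw count in the recovery studies).
The F-cell model is likewise fitted by collapsing to its five scale
hyperparameters. The per-feature entropy models have non-Gaussian
likelihoods and always use NUTS.

MCMC runs are seeded and reproducible; convergence is checked with split-
R̂ ≤ 1.05 and bulk ESS via arviz on every reported quantity (fit functions
raise on failure rather than returning silently; calibration sweeps skip
per-replicate diagnostics for cost and rely on the sweep-level checks).

## Synthetic worlds

The generator emulates the structure the analysis assumes, at desk scale:
ten contiguous geohistorical areas (nearest-of-ten far-apart seed cells),
spatially clustered nested families (family → branch → language), languages
placed with a smooth log-intensity field so per-cell richness is uneven
(the real-world richness distribution is not pinned down, so the
concentration is a config knob), populations with a median of eight
genotyped individuals, and Beta-distributed allele frequencies with
genotypes drawn as autozygous-with-probability-f else Hardy–Weinberg.

The genetic–linguistic coupling is latent: one smooth isolation field over
cells raises population autozygosity (via its logit) *and* multiplies the
SD of cell-level feature intercepts (log-linearly), so isolated regions
have both lower genetic diversity and higher expected feature entropy.
Neither data type is computed from the other; they are conditionally
independent given the field, matching the causal reading that demographic
isolation drives both.

Feature-state spatial autocorrelation is generated by a Gaussian random
field over cell centroids with squared-exponential covariance (length scale
3,000 km, the generative counterpart of the tensor smooth). Environmental
PCs and log density are independent standardized GRFs.

What the generator does **not** emulate: linkage disequilibrium, SNP
ascertainment bias, coalescent population structure, real family-tree
topologies, or any association between covariates and feature states beyond
the configurable dispersion modulation. Passing recovery tests therefore
show that the pipeline's inference chain is self-consistent and calibrated
under its own assumptions — not that those assumptions hold for real data.

## Recovery and calibration studies

The acceptance studies in `tests/test_acceptance.py` use reduced problem
sizes chosen once:

- Sign recovery: one m8 fit (with spline) on 200 cells × 40 features ×
  10 areas, true scaled-F slope 0.11. The generating slope dispersions
  mirror the reported group-level spreads: by-feature SD 0.15 (consistent
  with roughly a fifth of features excluding zero upward and a tenth
  downward around a 0.11 slope), by-area SD 0.05 (area slopes clustering
  within ≈ 0.04–0.16), with larger intercept heterogeneity (0.3/0.2).
- Interval calibration: 50 replicates of 12 cells × 20 features × 5 areas
  (m8 without spline) at the same dispersions; the 89% HPDI for the F slope
  must cover 0.11 at the nominal rate within a 99% binomial band. Twenty
  features per replicate keep the slope posterior data-dominated, which is
  what makes near-nominal frequentist coverage the right expectation; with
  very few groups the posterior reverts to the prior and coverage is no
  longer diagnostic.
- Null calibration: the same design with the F slope at zero (m4),
  checking nominal coverage of zero and approximate uniformity of
  P(slope > 0) across replicates.
- Model selection: ten replicates with a strong F effect (0.8); the
  F-containing model must beat the null rung by > 2·SE of Δelpd in ≥ 90%.
- The PSIS-LOO oracle compares against exact leave-one-out refitting on a
  40-row null-structure dataset (41 Gibbs fits).

## Numerical details and degenerate inputs

- HPDI: shortest contiguous window over sorted draws; multimodal draw sets
  still yield a single interval but are flagged by a histogram-dip
  heuristic.
- Scale floors of 1e-8 keep collapsed-likelihood evaluations finite when a
  scale parameter touches zero.
- Exactly constant response data put the posterior mode on the boundary of
  every scale parameter (a density spike); this degenerate case is outside
  any sampler's comfort zone and is treated in tests with a small jitter.
- Rounding in the equivalent-feature-count conversion is to the nearest
  integer.
- The CPC tanh transform is shrunk by 1e-12 to keep log(1 − p²) finite for
  extreme proposals.

## Known limitations

- Feature models are fitted one at a time; nothing pools information across
  features at the entropy stage (by design, matching the modelling idiom),
  which makes the entropy stage the computational bottleneck for many
  features.
- The taxonomic diversity index is a documented surrogate (mean over
  taxonomy levels of the effective number of distinct nodes, i.e. exp of
  the Shannon entropy of node frequencies per level; the log enters as
  predictor T). It preserves the intended orderings — more families or more
  balanced branches score higher; a new family adds more than a sister
  dialect — but is not guaranteed to match any specific published index;
  it is isolated in one function so an alternative can be dropped in.
- Cell random intercepts and the tensor smooth are both included, as in the
  modelled structure; in sparse regimes they compete for the same variation
  and only their sum is well identified. Diagnostics are reported per
  quantity so this shows up as low ESS on the separate terms, not as silent
  bias in the cell-level predictions.
- The pure-Python NUTS path is 1–2 orders of magnitude slower than
  compiled samplers; the collapsed and Gibbs strategies are the intended
  route for anything beyond small fits.
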