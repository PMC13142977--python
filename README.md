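# hexdiv

Hierarchical Bayesian analysis of the relationship between **structural
linguistic diversity** and **genetic diversity** on a geodesic hexagonal
grid.

Languages differ in structural features (presence of tone, basic word order,
colexification patterns, ...). In some regions — diversity hotspots or
accumulation zones — neighbouring languages disagree wildly on these
features; in spread zones they are homogeneous. `hexdiv` implements a
pipeline that measures this local structural diversity as normalized Shannon
entropy, measures local genetic diversity through Wright's inbreeding
coefficient *F* estimated from SNP genotypes, and asks whether the two are
inversely related: do genetically isolated regions (high *F*, low diversity)
harbour structurally more diverse languages?

It is written for quantitative linguists and population geneticists who want
to run, extend or stress-test this inference chain on simulated worlds with
known ground truth.

## The model chain

1. **Grid.** The sphere is tessellated into near-uniform hexagons (a
   spherical Voronoi diagram of a subdivided icosahedron; 12 pentagons
   remain, as in any icosahedral tessellation), at a target median cell
   diameter such as 500 km. Point coordinates are optionally jittered within
   a great-circle radius for robustness analyses. Planar coordinates for
   spatial smooths use the Equal Earth projection (EPSG:8859).

2. **Feature entropy.** For each binary or J-state feature, language states
   are modelled as

   state_i ~ Bernoulli(logit⁻¹(η_i))  or  Categorical(softmax(η_i)),
   η_i = α + α_AREA(i) + α_CELL(i) + α_FAMILY(i) + t2(x_i, y_i),

   with N(0, 2) priors on the intercept and every random-effect SD and a
   tensor-product B-spline smooth t2. Posterior draws of the expected state
   probabilities are averaged per cell and converted to normalized entropy
   Hn = −Σ π_j log π_j / log J, summarised as per-cell posterior means and
   SDs of Hn and logit Hn.

3. **Wright's F.** Per individual, F = (H_O − H_E)/(N_NM − H_E) from
   observed vs Hardy–Weinberg-expected homozygous genotype counts over
   non-missing SNPs (optionally with the small-sample correction
   N/(N−1) on 2pq). Individual F is smoothed into cell-level posterior
   estimates by a hierarchical Gaussian model with area, cell and population
   intercepts plus a spatial smooth, then z-scored across cells.

4. **Measurement-error regression.** The main model regresses
   logit(Hn_i) ~ N(η_i, σ_i), σ_i² = sd(logit Hn_i)² + σ², on scaled F and
   covariates (log language richness R, log taxonomic diversity T,
   environmental PCs P1/P2, log population density D), with correlated
   varying intercepts+slopes by feature and by geohistorical area (LKJ(2)
   priors), cell intercepts, a spatial smooth, and a latent-value
   measurement model for F. Models m1–m8 add predictors cumulatively and
   are compared by PSIS-LOO.

All posteriors can be drawn by three interchangeable exact samplers (a NUTS
implementation over the package's own reverse-mode autodiff, a collapsed
NUTS on the marginal hyperparameter posterior, and a blocked Gibbs sampler);
they are cross-validated against each other in the test suite.

## Worked example

```python
import numpy as np
from hexdiv import (GridSpec, build_grid, WorldConfig, generate_world,
                    compute_individual_F, fit_F_model, scale_F,
                    entropy_summaries, build_dataset, ModelSpec,
                    effect_on_probability_scale,
                    entropy_change_to_feature_count)
from hexdiv import fit_model_gibbs

grid = build_grid(GridSpec(1800.0))          # coarse demo grid, 252 cells
world = generate_world(WorldConfig(n_languages=200, n_features_binary=4,
                                   categorical_state_counts=(3,),
                                   n_populations=30, n_snps=500, seed=3),
                       grid)

find = compute_individual_F(world.genotypes,
                            world.individuals["individual_id"].to_numpy(),
                            small_sample_correction=False)
tab = world.individuals.merge(find, on="individual_id")
est, post = fit_F_model(tab, grid, n_chains=2, n_warmup=250, n_draws=250,
                        seed=4)
est = scale_F(est)
print(est["scaled_f"].describe().round(2))
```

On the demo world above this prints a z-scored cell F distribution with
`mean 0.00, std 1.00` across 28 cells, and the posterior mean cell F
correlates at r = 0.93 with the generating per-population autozygosity —
the smoothing recovers the latent genetic-diversity surface.

The headline interpretive conversions:

```python
>>> effect_on_probability_scale(0.291, 0.11)   # logit shift at Hn = 29.1%
0.0230699...                                   # +2.3 points of entropy
>>> entropy_change_to_feature_count(0.023, 333, 0.05)
11                                             # ≈ 11 features made variable
```

A one-SD increase in the scaled-F predictor (logit effect 0.11) at the
median baseline entropy of 29.1% raises normalized entropy by 2.3 percentage
points — equivalent, across 333 binary features, to turning 11 features from
nearly fixed (rare state at 5%) to maximally variable.

The same pipeline is scriptable from the shell (`hexdiv simulate`,
`hexdiv entropy`, `hexdiv genetics`, `hexdiv regress`, `hexdiv report`,
`hexdiv grid build/assign/jitter`).

## Layout

```
src/hexdiv/
  geogrid.py     geodesic grids, Equal Earth projection, jitter
  synthetic.py   synthetic-world generator with recorded ground truth
  entropy.py     per-feature hierarchical models -> cell entropy summaries
  genetics.py    Wright's F and hierarchical cell smoothing
  regression.py  dataset assembly, m1-m8 ladder, PSIS-LOO, slopes
  reporting.py   HPDI, probability-scale conversions, slope summaries
  cli.py         command-line interface
  _ad.py, _nuts.py, _bayes.py, _marginal.py, _gibbs.py   inference engines
docs/methods.md  modelling and design notes
```
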