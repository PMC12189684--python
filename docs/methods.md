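# Methods

## Scope and design

The package reproduces the arithmetic and procedure of a
trawl-survey-driven ensemble habitat analysis: survey CPUE metrics, a
ten-algorithm presence/absence ensemble gated by held-out AUC,
delta-method bias correction of climate-model layers, and habitat
loss/gain accounting. Real survey catches and Bio-ORACLE/CMIP6 rasters
are not redistributable, so correctness is established two ways: exact
arithmetic checks against published-style summary tables, and parameter
recovery on a synthetic world with a known niche. A green test therefore
certifies the machinery, not any statement about real squid stocks.

## The synthetic world

- **Grid.** Cell-center registered, 26.5–35 °N × 120–127 °E at 0.5°
  (18 × 15 cells), matching a 30-minute survey grid; a synthetic coast
  occupies the western margin (meandering mask) so masked-cell handling
  is always exercised. Experiments needing ≥500 distinct station cells
  (the parameter-recovery world) use the same window at 0.25°.
- **Hydrography.** SST follows a seasonal north–south gradient anchored
  to realistic East China Sea values (e.g. autumn 24 °C south → 17 °C
  north); SBT = SST minus a cross-shelf offset (1.5–4 °C); salinities
  increase offshore from ~30 to ~34 ‰ with bottom salinity 0.8 ‰ above
  surface; depth rises 15→125 m across the shelf. Smooth seeded noise
  (Gaussian-filtered white noise) perturbs every layer; values are
  clipped to plausible ranges (temperatures 5–30 °C, salinities
  27–35.5 ‰). Not emulated: currents, fronts, monsoon forcing, seasonal
  autocorrelation — so green tests say nothing about oceanographic
  realism.
- **Niche and catches.** True suitability is a product of per-covariate
  responses (Gaussian or flat), bounded in [0,1]; the default species
  responds only to SBT (optimum 20 °C, breadth 2 °C). Counts per
  one-hour tow are negative binomial with mean
  `detection_scale × suitability` (detection scale 10 ind·h⁻¹ at
  perfect suitability, dispersion k = 2 — overdispersed, as trawl
  catches are; k → ∞ recovers Poisson). Catch weight = count × a
  lognormal per-individual weight with mean 40 g, in the range of
  loliginid average individual weights. Stations occupy distinct sea
  cells, drawn uniformly without replacement. The default 150 stations
  per season is a free choice (survey station counts are rarely
  published); it gives the ~600-station annual data set a seasonal
  survey of this window would produce.
- **Paired climate layers.** `truth_future = truth + shift`;
  the simulated climate model reports both epochs through one
  systematic bias (default +0.8 °C on temperatures, −0.3 ‰ on
  salinities) plus independent noise (σ = 0.1), so its
  future-minus-baseline anomaly equals the true shift up to noise —
  exactly the structure the delta method exploits. Default true shifts
  per scenario (temperature / salinity): SSP1-2.6 +0.6/−0.05 (2050s)
  and +1.0/−0.10 (2090s); SSP2-4.5 +0.9/−0.10 and +1.9/−0.20; SSP3-7.0
  +1.1/−0.15 and +2.9/−0.35; SSP5-8.5 +1.3/−0.20 and +3.8/−0.45 —
  magnitudes in line with CMIP6-era projections for northwest Pacific
  shelf seas, fixed once and not tuned.

## Algorithms

The ten learners are given canonical forms (the roster names algorithms,
not settings): GLM = logistic regression with linear + quadratic terms
per covariate; GAM = penalized cubic-spline additive logistic model
(spline basis + ridge-penalized logistic fit); GBM = gradient-boosted
trees, 500 trees of depth 3; XGBOOST = histogram-based gradient
boosting (the same algorithm family; the dedicated xgboost library is
not a dependency); RF = 500-tree random forest; CTA = one
cost-complexity-pruned classification tree, pruning strength chosen by
a small seeded cross-validation over the pruning path; ANN = one hidden
layer of 8 units; MARS = hinge-basis expansion selected by a
forward/backward pass (forward: greedy reflected-pair addition by
least-squares residual reduction, knots at presence-absence-pooled
quantiles; backward: GCV pruning with smoothing penalty 3), with a
logistic link refitted on the selected basis; FDA = linear discriminant
analysis on the same MARS basis; SRE = per-covariate quantile envelope
(default q = 0.025, the conventional 95 % envelope; quantiles by linear
interpolation between order statistics so tests can state the oracle
exactly). No class reweighting by default — the trawl absences are true
absences, not pseudo-absences — and no hyperparameter search.

## Evaluation and ensembling

The 20 % test split is stratified by class even though a plain random
split would be the most literal protocol: at survey sample sizes an
unstratified split can land a single-class test set, making AUC
undefined. This is a deliberate, documented deviation. TSS thresholds
scan all distinct scores plus midpoints; ties break to the smallest
maximizing threshold.

Ensemble weights are proportional to member AUC (the gate metric). The
weighted-average rule of ensemble platforms admits variants (TSS
weights, decay weighting); weight-by-AUC with proportional
normalization is adopted and isolated behind the `build_ensemble`
surface so alternatives can be swapped in. The gate is a strict
inequality (AUC > 0.8); an empty gate is an explicit error, never a
silent keep-all.

Permutation importance is 1 − Pearson r between original and
permuted-column predictions, averaged over 10 seeded permutations,
clipped to [0,1]; constant predictions define importance 0. With
correlated covariates (SST and SBT share the shelf gradient) importance
spreads across the correlated set — the synthetic validation therefore
contrasts the driving covariate against an independent decoy rather
than against its collinear partner. Response curves use the
evaluation-strip convention with non-focal covariates at their training
means (mean, not median — switchable).

## Projection and accounting

The delta correction is additive for salinity as well as temperature —
chosen for symmetry and because multiplicative corrections behave badly
near fresh values; the per-covariate rule is isolated in
`delta_correct`. Projections beyond the training covariate range are
allowed but flagged per cell in a novel-environment mask, since warming
scenarios exceed baselines by design.

Binarization uses one threshold — the ensemble's max-TSS threshold —
applied identically to current and future maps. Both loss% and gain%
are divided by the *current* suitable-cell count, the only convention
under which a range expansion can print gains above 100 %; net% is
defined as gain% + loss% with loss signed negative. Published tables of
this form occasionally print a total-loss row (loss −100, gain 0) with
a positive net entry; this package follows the stated definition and
reports net −100 in that situation. Area sums exact spherical cell
areas, R²·Δλ·(sin φ_top − sin φ_bottom) with R = 6371 km.

## Pipeline and reproducibility

`run_pipeline` chains the stages from a single `RunConfig`; the four
stage seeds (simulation, split, fit, permutation) are the only entropy
sources — no global random state is read anywhere — so identical
configs reproduce outputs byte for byte. Outputs are CSV tables, NetCDF
(CF-style cell-center coordinates, via xarray's scipy backend; GeoTIFF
support was dropped since no raster library is a dependency) and a JSON
metrics file, all stamped with a config hash.

## Known limitations

- The synthetic generator's spatial fields are smooth gradients plus
  blurred noise; no mesoscale structure, no inter-season coherence.
- AUC/TSS are computed on a single split by default; repeated-split
  uncertainty is left to the caller (loop over `split` seeds).
- MARS/FDA use a deliberately small hinge-candidate set (5 knots per
  covariate, ≤8 pairs) for speed; they are canonical in form, not tuned
  implementations of the original algorithms.
- The SRE envelope treats covariates independently (axis-aligned box);
  correlated niches are over-covered.
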