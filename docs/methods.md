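# Methods

This note documents the models and procedures implemented in `phycohealth`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Culture health scoring

Outdoor algal cultures are sampled twice daily for ash-free dry weight
(AFDW, g l⁻¹). The observed specific growth rate over the daytime interval
is

    mu_obs = ln(AFDW_e / AFDW_m) / (t_e − t_m)      [day⁻¹]

with morning/evening pairing by local clock time: the first sample before
solar noon is "morning", the last at or after it "evening" (cutoff
configurable; days lacking either sample are skipped and logged). The
Health Index compares `mu_obs` with the rate `mu_model` a healthy-growth
simulator predicts for the same interval:

    HI_raw = −(mu_obs − mu_model) / mu_obs

`HI_raw = 0` means observation matches the healthy model; the negated value
`hi_plot = −HI_raw` is the canonical score for plotting and correlation so
that larger is healthier. Because the formula divides by `mu_obs`, it is
undefined near zero and flips sign for negative observed rates. The package
therefore (a) flags records with `|mu_obs| ≤ tol` (default 1e−3 day⁻¹) as
invalid rather than fabricating a value, and (b) offers a bounded
alternative score `(mu_obs − mu_model)/max(|mu_obs|, |mu_model|)` behind the
`bounded=True` flag, which stays finite and monotone through declining-
culture days. How days with negative `mu_obs` enter downstream regressions
is a user policy; both inclusion and exclusion are supported.

Areal biomass productivity between consecutive measurements is
`Δconc × volume / (area × days)` in g m⁻² day⁻¹ and may be negative during
decline.

## Healthy-growth simulator

The simulator predicts daytime biomass growth of an uncontaminated culture
from surface irradiance and water temperature. The published description of
the reference model specifies its structure (maximum specific growth rate as
a function of light and temperature, with density-dependent self-shading)
but not its equations, so this package fixes a canonical form with every
piece pluggable:

- temperature response: cardinal temperature model with inflexion (CTMI),
  zero at/outside `t_min`/`t_max`, one at `t_opt`;
- light response: `tanh(I / i_sat)` on PAR irradiance (a configurable PAR
  fraction, default 0.45, is applied to total solar input);
- self-shading: Beer–Lambert decay `I(z) = I_0 exp(−(k_w + σ_a·X)·z)` with
  `X` in g m⁻³, averaged over `n_layers` equal depth layers;
- dynamics: `dX/dt = mu̅(X, t)·X` integrated from the morning to the evening
  sampling time.

Quantitative agreement with the original calibration is not claimed; the
pipeline needs *a* validated healthy-growth reference with the stated
structure, and all parameters are overridable from a YAML config.

Defaults: `mu_max = 5.9 day⁻¹` at `t_opt = 36 °C` (the lab-characterised
optimum of the targeted high-temperature *Chlorella sorokiniana* strain),
`t_min = 5`, `t_max = 45 °C`, `i_sat = 100 W m⁻²`, `k_w = 0.2 m⁻¹`,
`σ_a = 0.1 m² g⁻¹`, `depth = 0.25 m`, 50 layers, step `dt = 1e−3 day`. The
default integrator is classical RK4: forward Euler is first-order and at
`dt = 1e−3` leaves ~0.7 % endpoint error on a full-speed exponential day,
while RK4 is exact to ~1e−9 % there; Euler remains available
(`integrator="euler"`). No night respiration or loss term is applied by
default (the simulated interval is daytime only); a linear loss rate is
available behind `night_loss_rate`.

The environment series driving a simulation must cover the interval
without gaps larger than `max_env_gap` (default 0.05 day ≈ 1.2 h, chosen so
hourly weather-station records pass while truly sparse series are
rejected). When only sample-time readings are available (twice-daily
metadata), the health-series driver falls back to linear interpolation
between them and relaxes the guard; this coarse profile misrepresents
midday irradiance and is intended for smoke use — supply a dense profile
for quantitative work.

## Dirichlet-multinomial mixture community typing

Raw ASV counts per sample (never relative abundances) are modelled as draws
from a k-component Dirichlet-multinomial (DM) mixture; components act as
community state types. Fitting is EM:

- E-step: responsibilities ∝ weight_c × DM(x_i | α_c), computed with
  log-gamma identities including the multinomial coefficient;
- M-step: weights are responsibility means; each α_c is updated by L-BFGS
  ascent in log-α (positivity without constraints) under a weak
  Normal(0, 10²) prior on log α, warm-started from the incumbent so the
  penalized observed-data objective is monotone non-decreasing;
- initialization: k-means on CLR-transformed counts (pseudocount 0.5),
  plus seeded restarts (default 3); the best restart by final objective is
  returned. All randomness flows from the `seed` argument.

The number of components is selected by a Laplace approximation of the
negative log model evidence: the penalized log-likelihood at the optimum,
minus the Gaussian-integral correction `½·kD·ln 2π − ½·Σ_c ln det H_c`,
plus a `½(k−1)·ln N` term for the mixture weights, with prior normalising
constants included so evidences are comparable across k. `H_c` is the
negative Hessian in log-α of component c's responsibility-weighted
penalized likelihood; it has rank-1-plus-diagonal structure, so the
determinant is evaluated exactly via the matrix determinant lemma, with a
ridge fallback (logged) if positive definiteness fails away from an
interior optimum. This complete-data (EM-style) Hessian is a standard
approximation to the observed-data curvature. Lower values indicate better
expected out-of-sample fit; `select_k` returns the argmin over the
requested range.

Day-to-day transitions between assigned states are counted within each run
between consecutive *observed* days. With multiple samples per day, the
default pairs every sample on day t with every sample on the next observed
day (one count per pair); a modal-label pairing (one count per day pair) is
available — the original study does not state which rule it used.

## Multinomial-regression differentials

Counts are regressed on sample covariates via
`x_i ~ Multinomial(n_i, softmax(z_i B))`, with `B` in additive-log-ratio
parameterization (last ASV as fitting reference) and an independent
Normal(0, `prior_sd`=1) penalty on all non-intercept coefficients. The
intercept row is left unpenalized so the intercept-only fit reproduces the
closed-form CLR of the pooled composition exactly at the MLE. Optimization
is batch L-BFGS with analytic gradients — deterministic at desk scale,
initialized at zero plus a seeded 1e−6 jitter, reproducible bit-wise given
the seed.

Reported differentials are the CLR-centered transform of the full
coefficient matrix: per covariate they sum to zero across ASVs and are
reference-free, expressing relative log-fold association per standardized
covariate unit. Continuous covariates are z-scored before fitting (the
units span °C, W m⁻², g l⁻¹); binary covariates are coded 0/1 unscaled.
Samples with any missing covariate are dropped with a logged manifest.

ASVs are flagged as significantly associated when the per-covariate
z-score of their differential exceeds 3 (the study's rule), or under the
box-whisker alternative (outside median ± 1.5·IQR bounds). Flagged ASVs
are summarised per taxonomic order and direction. Note that under a true
null the z>3 rule still flags ~0.27 % of ASVs by chance; with D ASVs per
covariate, the expected number of chance flags is ~0.003·D.

## Community statistics

Faith's phylogenetic diversity, Jaccard, Bray–Curtis and (un)weighted
UniFrac distances, PCoA and PERMANOVA are delegated to scikit-bio behind
this package's interfaces. Presence for Jaccard/Faith PD means count > 0;
no rarefaction is applied by default (an optional seeded rarefy-to-depth
utility is provided). Weighted UniFrac is the unnormalized variant unless
`normalized=True`. PCoA uses exact symmetric eigendecomposition; axes with
negative eigenvalues (non-Euclidean metrics) are reported and dropped, and
coordinates are re-centered. PERMANOVA p-values use the (1+b)/(1+m)
permutation estimator with a seeded permutation stream; pseudo-F follows
the standard distance partition. Group dispersion is measured as Euclidean
distance to a reference group's centroid in the positive-axis PCoA
embedding.

ANCOM is authored here in its canonical two-group construction: for each
ASV i, `W_i` counts the pairwise log-ratio tests (Mann–Whitney U at
α = 0.05, no correction within pairs) that reject across all j ≠ i;
detection requires `W_i ≥ 0.7·(D−1)`. Pseudocounts default to 1 for ANCOM
and 0.5 for the log-ratio correlation utility (zeros are ubiquitous in ASV
tables; the handling is configurable and recorded in outputs). Log-ratio
correlations use summed counts over arbitrary disjoint numerator and
denominator taxon sets, Pearson's test and a least-squares line.

## Synthetic data generator

The generator emulates the targeted study design so every stage is
testable without the deposited sequencing data: 4 baseline batch runs
sampled twice daily for 14 days plus 8 survey runs sampled every other day,
150 taxa, sequencing depth lognormal around 20,000 — the same order of
magnitude as the original 575 samples × 914 ASVs without matching them.
Every generator is a pure function of (scenario, seed) via keyed RNG
substreams; the emitted truth manifest regenerates all fixtures
bit-identically.

Per run, a diurnal environment (half-sine irradiance 06:00–18:00 with
seeded daily peaks; sinusoidal water temperature around a seasonal mean) is
sampled at 0.02-day resolution and drives the growth simulator day by day;
evening AFDW gets multiplicative lognormal noise (sd 0.05). From a
scheduled crash day (delayed 3 days in the biocide-treated arm) the planted
pathogen suppresses realised growth in *rate* terms: the evening value
becomes `AFDW_m · (AFDW_e′/AFDW_m)^γ` with γ = 0.5, i.e. `mu_obs =
γ·mu_model`. Suppressing the rate rather than deflating the level keeps
`mu_obs` strictly positive while strictly below the model, so the Health
Index's sign behaviour is well defined on every crash day (a hard collapse
with negative `mu_obs` is available by choosing γ < 0, and is the regime
where the bounded HI variant is the appropriate score).

Counts are drawn from a DM mixture whose component schedule follows culture
age (monotone over each run); later components have progressively larger
taxon supports, which is what makes phylogenetic diversity rise with days
after inoculation. Component Dirichlet rows are tilted log-linearly by
standardized covariates with planted centered effect vectors, and the
pathogen taxon's parameter is boosted multiplicatively from each run's
crash day. A configured fraction of taxa (default 5 %) carries chloroplast
or mitochondria lineages at a constant small share, exercising the
organelle filter. A random sequential-join bifurcating tree with
exponential branch lengths covers all taxa.

The differential-recovery benchmark (`generate_differential_counts`) is a
separate, deliberately calibration-valid design: compositions are
`softmax(log base + z·B + ε)` with a moderately even lognormal base
(log-sd 0.5) and uniform logistic-normal overdispersion (sd 0.5) — the
regression model's own noise family, sized so the rarest taxon's
multinomial noise sits below the uniform dispersion floor. Under this
design every planted coefficient is identifiable with the same log-scale
noise, so the null covariate's z-scores are calibrated (no excess
kurtosis) and the planted effects (centered Normal, sd 0.8) are recovered
with rank correlation > 0.95. A shared-concentration Dirichlet over a very
uneven base would instead give rare taxa per-taxon concentrations ≪ 1,
making their planted coefficients unidentifiable in principle — a benchmark
defect, not an estimator property.

### What the generator does not emulate

Real phycosphere data have features the generator omits deliberately:
taxon-taxon interaction structure beyond mixture membership, seasonal
succession across runs, chimeras/contaminants, compositional zeros from
library-size artefacts, and the long-tailed abundance distribution of real
ASV tables. Passing recovery tests therefore demonstrates correctness of
the estimators under their assumed sampling models and the stated planted
structure — not performance guarantees on field data.

## Problem sizes and determinism

Test and acceptance workloads are sized for a single desktop CPU: mixture
recovery at N = 100 samples × 30 taxa × depth 5000, differential recovery
at N = 300 × 50 × 10000 over 20 replicate seeds, PERMANOVA calibration over
200 null simulations with 199 permutations, and the full synthetic study at
224 samples × 150 taxa. Every stochastic stage takes an explicit seed and
is reproducible bit-wise; p-values use the (1+b)/(1+m) estimator so zero
p-values cannot occur.

## Known limitations

- The growth model is a canonical stand-in with the published structure,
  not the original calibrated implementation; HI magnitudes on real data
  are therefore not comparable against the original study's.
- Eq.-style HI is undefined/explosive near `mu_obs = 0` and changes sign
  for declining cultures; interpret only with the validity flags, or use
  the bounded variant.
- The Laplace evidence uses the complete-data Hessian approximation;
  evidence differences between near-tied k values should not be
  over-interpreted.
- ANCOM's within-pair tests are uncorrected by construction; the W cutoff
  (0.7) is the conventional heuristic, not a calibrated error rate.
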