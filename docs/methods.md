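# Methods

This note documents the models, estimation procedures, numerical choices and
known limitations of the `trophic` package, module by module.

## Growth-curve fitting (`growthfit`)

Two sigmoidal models are fit to batch-culture cell concentrations by maximum
likelihood:

* lag model (Zwietering form applied to ln concentration):
  ln C(t) = ln K / (1 + exp[(4μ/ln K)(λ − t) + 2]), where μ (d⁻¹) is the
  exponential growth rate, K the carrying-capacity argument (K > 1 is
  required because ln K appears in a denominator; concentrations are treated
  as ≥ 1 cells ml⁻¹), and λ (d) the lag-end time at which the ln-scale slope
  reaches μ. The maximum ln-slope of the fitted curve equals μ and is
  attained at t = λ + ln K/(2μ) — a property the tests exploit as an oracle.
* logistic model: C(t) = K / (1 + exp[−μ(t − t_m)]) with inflection at t_m,
  where C = K/2.

**Error model.** Independent Gaussian noise on ln C with the error sd
profiled out analytically. This matches multiplicative count noise and makes
ML equivalent to least squares on the log scale. The synthetic generator uses
the same noise structure, so generator and fitter are exact duals.

**Optimization.** Nelder–Mead from 8 data-driven starts (μ₀ from the maximum
between-point log-slope, K₀ from the maximum concentration, inflection start
from the time of maximum slope, each jittered); the best likelihood wins and
ties go to the smaller μ. Both models have equal parameter counts, so the
`auto` mode's AIC comparison reduces to the higher maximized likelihood.
Series whose final log concentration does not exceed the first are reported
as μ = 0 with `converged=False`.

**Decline trimming.** The series is cut at its global maximum only when a
later point falls more than 10% below that maximum; flat plateaus within
tolerance are kept. The 10% tolerance is robust to terminal noise without
eating the stationary phase.

## Tradeoff estimation (`tradeoff`)

The phototrophy–phagotrophy tradeoff is the one-parameter curve
g = (1 − p)^φ linking the phototrophic capacity fraction p to the
phagotrophic capacity fraction g. φ = 1 is the linear zero-sum tradeoff;
φ > 1 penalizes generalists.

**Fraction construction.** p_i = growth_high_light_i / (max autotroph
growth); g_i = clearance_i / (max observed clearance). Autotrophs define the
pure-phototroph endpoint; the fastest observed grazer the phagotroph
endpoint.

**Curvature fit.** Least squares of g against A·(1 − p)^φ with the amplitude
A profiled analytically for each candidate φ (1-D bounded search over log φ).
Profiling A makes the curvature estimate invariant to the clearance units and
to whether any sampled strain actually sits at the pure-heterotroph endpoint;
with A pinned to 1 the estimate would be biased whenever the fastest sampled
grazer retains some phototrophic capacity. On noiseless on-curve data the fit
recovers φ exactly.

**Uncertainty.** Seeded nonparametric percentile bootstrap over strains
(default 1000 resamples). Resamples with fewer than two distinct mixotrophs
or no autotroph are skipped and counted. With ~11 strains the interval is
honest but wide, and simulation shows ≈ 90–95% coverage at nominal 95%.

**Correlations.** Spearman rank correlation with average ranks for ties
(autotrophs tie at clearance 0). The two-sided p-value uses the exact
permutation distribution for n ≤ 9 (vectorized over all n! permutations) and
the t approximation for larger n.

**Bundled panel.** `trophic.datasets.load_synthetic_isolate_traits` ships an
11-strain synthetic table (7 mixotrophs, 4 autotrophs). Its rank structure
was found by exhaustive search so that the mixotroph-only and all-strain
Spearman correlations between high-light growth and clearance match published
values (−0.85, −0.74) at two decimals, while respecting qualitative anatomy:
the fastest grazer (a chrysophyte-like strain) cannot grow phototrophically,
the slowest grazers (Florenciella-like) are the fastest-growing mixotrophs,
the two Chrysochromulina-like strains tie in growth, autotroph low-light
growth spans 0.25–0.42 d⁻¹ and only one mixotroph grows at low light. The
individual numbers are constructed, not measurements.

## Trait × environment GLMM (`nichemodel`)

Reads of OTU i in sample j out of the phytoplankton total N_j follow a
beta-binomial with logit-linear mean:

    logit(p_ij) = Int_i + Sample_j + (CRz_i · CReff + slope_i) · Env_j
    reads_ij ~ BetaBinom(N_j, α = p_ij V_i, β = (1 − p_ij) V_i)

The mean/precision parametrization keeps V_i interpretable (the large-V limit
is binomial). Clearance rates are z-scored; depth is coded DCM = 0,
surface = 1; Chl a is z-scored on its linear scale and restricted to surface
samples, excluding samples without Chl a and any sample above 5 µg l⁻¹
(anomalously eutrophic stations distort a linear response fitted to
oligotrophic range data).

**Estimation.** Default `map_laplace`: the joint posterior over
(CReff, intercept mean, three random-effect sds, per-OTU log V, and all
non-centered random effects) is maximized by L-BFGS with fully analytic
gradients (digamma identities for the beta-binomial, chain rule through the
logit link). Priors are weakly informative: Normal(0, 2.5²) on CReff and the
intercept mean, half-Normal(1) on random-effect sds, Gamma(2, scale 200) on
each V_i. The 95% interval for CReff is Wald, using the inverse of the full
Hessian obtained by central differences of the analytic gradient (2·dim
gradient calls). Simulation calibration (13 OTUs × 40 samples, 20 seeds per
effect size) shows mean bias below 0.06 logit units and interval coverage at
or above nominal. An `mcmc` mode runs emcee on the same posterior; with ~80
parameters the ensemble sampler needs long chains (defaults 8000 steps, 3000
burn-in) before its percentile intervals are trustworthy — the Laplace mode
is the workhorse, MCMC the cross-check.

**Taxon random effects.** Optional taxon-level random slopes use a fixed
taxon sd profiled over a grid {0, 0.05, 0.1, 0.2, 0.4, 0.8} by the
Laplace-approximate marginal likelihood (joint-mode log posterior minus half
the log determinant of the Hessian). A free joint-mode sd would not shrink to
zero under a null taxon structure; the marginal criterion does, and the
reported `taxon_variance` is the winning sd squared.

**Read universe.** Per-sample totals sum reads over a 21-taxogroup
phytoplankton whitelist. Dinoflagellates are never counted (phototrophic vs
heterotrophic status is ambiguous for many taxa) and known-heterotroph OTUs
can be excluded by id. Samples with zero whitelisted reads are dropped with a
logged warning; unknown taxogroup labels raise in strict mode.

**Niche summaries.** From a depth fit: the per-OTU surface:DCM ratio of
expected relative abundance with sample effects at zero (for small p this
approaches exp of the logit difference). From a Chl fit: the per-OTU
logit-scale slope CRz_i·CReff + slope_i per sd of Chl a. The trait–niche R²
is the squared Pearson correlation between clearance rate and the log ratio
(depth) or slope (Chl).

## Ordination (`ordination`)

Classical PCoA of per-sample relative-abundance profiles of the focal OTUs,
renormalized within the focal set by default (division by total phytoplankton
reads is available via `renormalize=False`; both modes exist because either
convention is defensible for a focal subset). Bray–Curtis is the default
metric, with Euclidean and Hellinger as switches. When the Gower-centered
matrix has eigenvalues below −1e−8 × (largest), the Cailliez constant is
added to off-diagonal distances — but not to exact zeros, so duplicate
samples keep identical coordinates; remaining tiny negatives are clamped.
Variance explained is computed over the corrected positive eigenvalues. OTUs
are projected as abundance-weighted averages of sample scores. Axis
orientation is normalized (largest-|score| OTU positive), and the
environment-correlation table re-orients axis 1 to correlate positively with
Chl a so that the axis reads as decreasing stratification.

## Competition model (`tradecomp`)

A chemostat in nitrogen currency (µmol N l⁻¹, fixed quotas): dissolved
nitrogen N, bacterial prey B, and plankton populations P_k on a strategy grid
x ∈ [0, 1] with s_photo = 1 − x scaling photosynthesis and N uptake and
s_graze = x^φ scaling maximum ingestion (the exponent placement on ingestion
is fixed by the anchor that 50% photosynthetic capacity keeps 29% ingestion
capacity at φ = 1.8).

Per strategy: ρ = s_photo·V_max·N/(N+K_N) (uptake),
ψ = s_photo·μ_I·I/(I+K_I) (photosynthesis),
g = s_graze·I_max·B/(B+K_B) (ingestion), and growth

    μ = min(ρ + e_N·g,  ψ + e_C·g)

— the Liebig minimum of a nitrogen channel and an energy channel, each
subsidized by prey with its own assimilation efficiency (defaults e_N = 0.7,
e_C = 0.3: respiration taxes the carbon of a meal more than its nitrogen).
The two-channel form is load-bearing: with a single shared efficiency the
growth rate is convex in x for φ > 1 and the two specialists competitively
exclude every interior strategy, which contradicts both observation and the
intended behaviour. Separate efficiencies let a mixotroph cover its energy
budget photosynthetically and use prey mainly for nitrogen, so it can
suppress bacteria below the density a pure heterotroph needs.

**Nitrogen bookkeeping.** Realized dissolved uptake is what growth actually
incorporates beyond prey N (clip(μ − e_N g, 0, ρ)); ingested N not built into
biomass is recycled to the dissolved pool with efficiency ω, as are all
mortality terms. In the closed configuration (a = 0, ω = 1) total nitrogen is
conserved to integrator precision, which the tests verify pointwise and along
trajectories.

**Mortality closures.** Two standard stabilizing closures are part of the
default structure: a quadratic bacterial mortality m2_B·B² (viral-lysis-type
self-limitation; without it Holling-II grazing drives paradox-of-enrichment
limit cycles in which bacteria numerically underflow), and a shared plankton
loss m + m2_P·ΣP representing implicit generalist higher predators. The
shared closure couples standing stock back into per-capita rates, so the
equilibrium N* rises with nutrient input; with purely linear mortality the
interior equilibrium environment is pinned by break-evens and community
composition would be independent of N_in, which is inconsistent with the
niche gradients the model is meant to explain. Because the loss is shared
(not per-strategy), competition among strategies remains winner-take-most and
the mixotroph proportion still declines with nutrient input.

**Defaults.** μ_I = 0.7 d⁻¹ and K_I = 10 µmol photons m⁻² s⁻¹ put the pure
autotroph's prey-free growth at 0.35 d⁻¹ under 10 µmol photons m⁻² s⁻¹
(inside the observed 0.25–0.42 d⁻¹ range for autotroph isolates) and
0.64 d⁻¹ at 100. Bacteria are better nitrogen competitors than phytoplankton
(K_NB = 0.05 vs K_N = 0.15 µM) as in oligotrophic systems. Mixing a = 0.1
d⁻¹, background mortality m = 0.05 d⁻¹, ω = 0.5 recycling. The full ODE
structure is this package's own construction, isolated behind
`model_derivatives` so alternatives can be swapped.

**Equilibration.** LSODA in 100-day windows (rtol 1e−8, atol 1e−16 so deep
transient troughs are tracked rather than truncated). Populations are never
zeroed mid-run; convergence requires (1) the set of components above the
extinction threshold (default 1e−9·N_in) to be stable between windows, (2)
every above-threshold component's relative change over a window to be below
1e−6, and (3) every below-threshold component that was present initially to
have non-positive per-capita growth at the resident state (uninvadability —
otherwise a transiently rare population would wrongly be declared extinct).
If t_max (20 000 d) is reached the attractor is treated as a limit cycle and
the returned state is a 1000-day time average flagged `converged=False`.

## Synthetic data (`synthio`)

The generators draw from exactly the structures the estimators assume, so
parameter-recovery tests are well-posed: lognormal noise on growth curves;
trait pairs on a known curve with Gaussian fraction noise clipped to [0, 1]
(the fastest grazer is generated as an obligate mixotroph with zero
phototrophic growth, anchoring the phagotrophic end); and read tables drawn
by Beta(pV, (1−p)V) → Binomial(N_j) from the GLMM's linear predictor.
Environmental covariates load on a single latent stratification factor
(+Chl a, +nitrate, +MLD; −SST, −PAR, configurable loadings) with independent
noise, then map to field-plausible ranges (Chl a ~0.02–0.6 µg l⁻¹ lognormal,
SST around 22 °C). Sub-streams for environment, random effects and read
sampling are spawned deterministically from one master seed, so identical
configurations are bit-reproducible.

What the generators do **not** emulate: sequence-level artifacts (chimeras,
OTU clustering error), compositional closure beyond the beta-binomial
(focal OTUs are a modest share, ~2% each, of the read universe), spatial or
temporal autocorrelation among stations, and phylogenetic correlation of
traits. Passing recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to survey-data
pathologies.

**Problem sizes.** The test suite and calibration checks use 13 OTUs × 40
samples with 20 seeds per condition for the GLMM, 50 seeded panels for
curvature recovery, 50 seeded series for growth-rate recovery, and a 5-point
nitrogen-input transect (21 strategies) plus a prey-enrichment pair for the
competition model; these sizes give stable Monte-Carlo verdicts while keeping
the default suite around a minute. The CLI exposes full 15×15 sweeps.

## Known limitations

* The GLMM interval is Wald at the joint mode; for very small OTU panels a
  profile or full-MCMC interval would be more accurate in the tails.
* `estimate_phi` fits the curvature alone; hooks for joint fitting with the
  light-response parameters exist in the design but joint estimation is not
  implemented.
* The competition ODE is a constructed model: its rate forms, closures and
  defaults are documented choices, not measurements, and conclusions should
  be read as qualitative. The irradiance dimension in particular is
  parameter-sensitive.
* Printed credible intervals and R² values from survey-data analyses are not
  unit-comparable to this implementation without the original data and
  scaling; they are treated as sign/shape references only.
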