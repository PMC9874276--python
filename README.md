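# trophic

Tools for linking the trophic strategies of small eukaryotic phytoplankton to
their ocean niches. Many open-ocean picoeukaryotes and nanoeukaryotes are
phagotrophic mixotrophs: they photosynthesize and also ingest bacterial prey.
This package implements the computational chain for asking (1) whether
phototrophic and phagotrophic performance trade off across strains, (2)
whether a strain's grazing ability predicts where its population lives in the
ocean, and (3) whether resource competition can explain those niche shifts.
It is aimed at plankton ecologists working with culture growth assays and
18S metabarcode survey tables.

## What it computes

**Growth-curve fitting** (`trophic.growthfit`). Batch-culture cell counts are
fit by maximum likelihood (Gaussian error on ln *C*) to two sigmoidal models:
a lag-phase model on the log scale,
ln *C*(t) = ln *K* / (1 + exp[(4μ/ln *K*)(λ − t) + 2]),
and the plain logistic *C*(t) = *K* / (1 + exp[−μ(t − t_m)]),
with automatic model selection, decline-phase trimming and per-strain ×
light-treatment summaries (mean ± SE over replicates).

**Phototrophy–phagotrophy tradeoff** (`trophic.tradeoff`). Traits are placed
on a capacity-fraction scale (autotrophs anchor the phototrophic endpoint,
the fastest grazer the phagotrophic endpoint) and the one-parameter tradeoff
curve

&nbsp;&nbsp;&nbsp;&nbsp;*g* = (1 − *p*)^φ

is fit by least squares with a seeded nonparametric bootstrap CI for the
curvature φ. φ > 1 penalizes generalists: at φ = 1.8, a strategy with 50% of
an autotroph's photosynthetic capacity keeps only 29% of a heterotroph's
ingestion capacity. Spearman trait correlations (average ranks, exact
permutation p for small n) are included.

**Trait × environment GLMM** (`trophic.nichemodel`). OTU read counts out of
per-sample phytoplankton totals are modelled as beta-binomial with a logit
link:

&nbsp;&nbsp;&nbsp;&nbsp;logit(p_ij) = Int_i + Sample_j + (CR_i·CReff + slope_i)·Env_j,
&nbsp;&nbsp;&nbsp;&nbsp;reads_ij ~ BetaBinom(p_ij, V_i, N_j)

where CReff measures how clearance rate tilts an OTU's response to depth
(surface vs DCM) or to a Chl *a* gradient. Fitting is penalized ML at the
joint posterior mode with a Laplace/Wald interval (default) or MCMC (emcee).
Per-OTU niche summaries (surface:DCM ratios, Chl-a slopes), read-universe
assembly over a phytoplankton taxogroup whitelist (dinoflagellates excluded),
and community-weighted mean grazing ability are derived from the same table.

**Ordination** (`trophic.ordination`). Classical PCoA (Bray–Curtis by
default, Cailliez correction when needed) of OTU composition across surface
samples, with axis–environment correlations and the correlation between
per-OTU axis positions and grazing ability.

**Competition model** (`trophic.tradecomp`). A chemostat ODE model in which a
spectrum of strategies x ∈ [0, 1] (autotroph → heterotroph) competes for
dissolved nitrogen and bacterial prey at fixed irradiance. Photosynthesis and
N uptake scale with 1 − x, maximum ingestion with x^φ; growth is the Liebig
minimum of a nitrogen channel and an energy channel, each subsidized by prey
with its own assimilation efficiency. Equilibria are found by windowed
integration with uninvadability checks, and grids over nitrogen input ×
irradiance summarize autotroph/mixotroph/heterotroph biomass, mixotroph
proportion, and the biomass-weighted mean strategy.

**Synthetic data** (`trophic.synthio`). Seeded generators for every input:
sigmoidal growth series with lognormal noise, trait pairs scattered around a
known tradeoff curve, and OTU×sample read tables drawn from the GLMM's exact
generative structure with a correlated "stratification" block of
environmental covariates (+Chl a, +nitrate, +MLD; −SST, −PAR).

## Worked example

```python
from trophic import nichemodel, synthio, tradeoff
from trophic.datasets import load_synthetic_isolate_traits

records = load_synthetic_isolate_traits()
rho_mix, p_mix = tradeoff.correlate_traits(records, "mixotrophs_only")
print(f"Spearman (mixotrophs): rho = {rho_mix:.2f}, p = {p_mix:.3f}")

fit = tradeoff.estimate_phi(records, n_boot=1000, seed=1)
print(f"tradeoff curvature phi = {fit.phi:.2f}  "
      f"95% CI [{fit.ci_low:.2f}, {fit.ci_high:.2f}]")

config = synthio.CommunitySimConfig(n_otus=13, n_samples=40,
                                    creff_true=0.5, seed=42)
table, meta, traits, truth = synthio.gen_community_dataset(config)
glmm = nichemodel.fit_trait_niche_glmm(table, meta, traits,
                                       env_kind="depth_binary")
print(f"depth GLMM CReff = {glmm.creff:.2f}  "
      f"95% CI [{glmm.creff_low:.2f}, {glmm.creff_high:.2f}]")
```

prints

```
Spearman (mixotrophs): rho = -0.85, p = 0.024
tradeoff curvature phi = 1.98  95% CI [0.82, 24.16]
depth GLMM CReff = 0.40  95% CI [-0.26, 1.05]
```

The negative Spearman correlation says faster grazers grow more slowly under
high light. The curvature estimate near 2 (wide CI with only 11 strains) says
the tradeoff is convex — mixed strategies pay a disproportionate price. The
GLMM recovers the generating interaction (0.5) within its interval: an OTU
one sd above the mean clearance rate gains about 0.4 logit units of relative
abundance more than average when moving from DCM to surface.

The bundled isolate table is synthetic: a constructed stand-in whose rank
structure matches published trait correlations (see
`trophic.datasets.load_synthetic_isolate_traits`).

## Command line

```bash
trophic simulate --out data/ --seed 1              # synthetic dataset
trophic growth-fit --input counts.csv --out fits.csv
trophic tradeoff --traits traits.csv --boot 1000 --seed 7
trophic niche glmm --env depth --reads data/reads.tsv --totals data/totals.tsv \
    --metadata data/metadata.tsv --traits data/traits.csv --out glmm.json
trophic niche pcoa --reads ... --out scores.csv
trophic compete --phi 1.8 --grid-size 15 --out grid.csv
trophic run-all --config pipeline.yaml
```

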