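"""Synthetic-data generators with the statistical structure the analyses assume.

Three generators cover the pipeline's inputs:

* :func:`gen_growth_series` — sigmoidal batch-culture cell counts with
  multiplicative (lognormal) noise, from either growth model in
  :mod:`trophic.growthfit`.
* :func:`gen_trait_pairs` — strain trait pairs scattered around a tradeoff
  curve with known curvature ``phi``.
* :func:`gen_community_dataset` — OTU x sample read tables drawn from the
  exact generative structure of the beta-binomial trait x environment GLMM in
  :mod:`trophic.nichemodel`, together with a sample-metadata table whose
  environmental covariates share a single latent "stratification" factor
  (positive loadings for Chl a, nitrate and mixed-layer depth; negative for
  temperature and PAR).

All generators take explicit integer seeds; identical configuration and seed
produce bit-identical output.  Sub-streams for the different tables of a
community dataset are derived deterministically from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from trophic.growthfit import CellCountSeries, lag_log_curve, logistic_curve
from trophic.tradeoff import TraitRecord, tradeoff_fraction, records_to_frame

__all__ = [
    "GrowthSimConfig",
    "CommunitySimConfig",
    "gen_growth_series",
    "gen_trait_pairs",
    "gen_community_dataset",
    "write_community_dataset",
]


@dataclass(frozen=True)
class GrowthSimConfig:
    """Configuration for one simulated growth curve.

    ``lambda_or_tm`` is the lag-end time (lag model) or the inflection time
    (logistic model), in days.  ``noise_sigma`` is the sd of additive Gaussian
    noise on ln concentration, i.e. lognormal multiplicative noise on counts.
    """

    model_kind: str  # "lag" | "logistic"
    mu: float
    K: float
    lambda_or_tm: float
    noise_sigma: float
    times: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.model_kind not in ("lag", "logistic"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.K <= 1:
            raise ValueError("K must exceed 1 (the lag model divides by ln K)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-empty and strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    @property
    def C0_implied(self) -> float:
        """Initial concentration implied by the model parameters at t = 0."""
        if self.model_kind == "lag":
            return float(np.exp(lag_log_curve(np.array([0.0]), self.mu, self.K, self.lambda_or_tm)[0]))
        return float(logistic_curve(np.array([0.0]), self.mu, self.K, self.lambda_or_tm)[0])


def gen_growth_series(
    config: GrowthSimConfig,
    strain_id: str = "sim",
    treatment: str = "high_light_100",
    replicate: str = "r1",
) -> CellCountSeries:
    """Simulate one cell-concentration time series from a growth model."""
    t = np.asarray(config.times, dtype=float)
    if config.model_kind == "lag":
        log_curve = lag_log_curve(t, config.mu, config.K, config.lambda_or_tm)
    else:
        log_curve = np.log(logistic_curve(t, config.mu, config.K, config.lambda_or_tm))
    if not np.all(np.isfinite(log_curve)):
        raise ValueError("growth model produced non-finite values for this configuration")
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sigma, size=len(t)) if config.noise_sigma > 0 else 0.0
    return CellCountSeries(
        strain_id=strain_id,
        treatment=treatment,
        replicate=replicate,
        times=t,
        concentrations=np.exp(log_curve + noise),
    )


def gen_trait_pairs(
    phi_true: float,
    n_mixotrophs: int = 7,
    n_autotrophs: int = 4,
    noise_sigma: float = 0.05,
    seed: int = 0,
    p_ref_growth: float = 0.55,
    g_ref_clearance: float = 8.0,
) -> list[TraitRecord]:
    """Trait pairs scattered around a tradeoff curve of known curvature.

    Mixotrophs receive phototrophic fractions spread over (0, 1) and
    phagotrophic fractions ``(1 - p)**phi_true`` plus Gaussian noise (sd
    ``noise_sigma``), clipped to [0, 1].  Autotrophs have clearance exactly 0
    and phototrophic fraction drawn near 1.  Fractions are mapped back to
    trait units via the reference growth rate and clearance.
    """
    if phi_true <= 0:
        raise ValueError("phi_true must be positive")
    if n_mixotrophs < 2:
        raise ValueError("need >= 2 mixotrophs (the tradeoff fit requires them)")
    rng = np.random.default_rng(seed)
    # the fastest grazer is an obligate mixotroph (no phototrophic growth),
    # mirroring chrysophyte-like strategies at the phagotrophic end
    p_mix = np.linspace(0.0, 0.9, n_mixotrophs)
    g_mix = tradeoff_fraction(p_mix, phi_true)
    if noise_sigma > 0:
        g_mix = np.clip(g_mix + rng.normal(0.0, noise_sigma, n_mixotrophs), 0.0, 1.0)
    p_auto = np.clip(1.0 - np.abs(rng.normal(0.0, 0.02, n_autotrophs)), 0.0, 1.0)
    # the endpoint anchor: the fastest autotroph defines fraction 1 exactly
    if n_autotrophs > 0:
        p_auto[0] = 1.0

    records = []
    for i, (p, g) in enumerate(zip(p_mix, g_mix)):
        records.append(
            TraitRecord(
                strain_id=f"mixo_{i:02d}",
                clearance_specific=float(g * g_ref_clearance),
                growth_high_light=float(p * p_ref_growth),
                growth_low_light=0.0,
                is_mixotroph=True,
            )
        )
    for i, p in enumerate(p_auto):
        records.append(
            TraitRecord(
                strain_id=f"auto_{i:02d}",
                clearance_specific=0.0,
                growth_high_light=float(p * p_ref_growth),
                growth_low_light=float(0.3 * p * p_ref_growth + 0.1),
                is_mixotroph=False,
            )
        )
    return records


# loadings of each metadata variable on the latent stratification factor;
# positive block (Chl a, nitrate, MLD) and negative block (SST, PAR)
DEFAULT_ENV_LOADINGS = {
    "chla": 0.9,
    "nitrate": 0.85,
    "mld": 0.8,
    "sst": -0.7,
    "par_surface": -0.6,
    "par_depth": -0.75,
    "abs_latitude": 0.5,
}


@dataclass(frozen=True)
class CommunitySimConfig:
    """Configuration for one synthetic OTU x sample community dataset.

    The generative model is the beta-binomial GLMM itself::

        logit(p_ij) = Int_i + Sample_j + (CRz_i * creff_true + slope_i) * Envz_j
        reads_ij ~ BetaBinom(N_j, alpha = p_ij * V_i, beta = (1 - p_ij) * V_i)

    where ``CRz`` and (for a continuous environment) ``Envz`` are z-scored.
    ``dispersion`` is the beta-binomial precision ``V`` (large V = binomial
    limit).  ``env_kind`` selects a binary depth layer (DCM = 0, surface = 1)
    or a continuous Chl a gradient tied to the latent stratification factor.
    """

    n_otus: int = 13
    n_samples: int = 40
    creff_true: float = 0.5
    intercept_sd: float = 0.8
    slope_sd: float = 0.3
    sample_sd: float = 0.3
    dispersion: float = 150.0
    total_reads: int | Sequence[int] = 10_000
    env_kind: str = "depth_binary"
    trait_values: tuple[float, ...] | None = None
    intercept_mean: float | None = None
    env_loadings: tuple[tuple[str, float], ...] = tuple(DEFAULT_ENV_LOADINGS.items())
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.intercept_sd, self.slope_sd, self.sample_sd) < 0:
            raise ValueError("random-effect sds must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.env_kind not in ("depth_binary", "chla_continuous"):
            raise ValueError(f"unknown env_kind {self.env_kind!r}")
        totals = np.atleast_1d(np.asarray(self.total_reads, dtype=int))
        if np.any(totals < 1):
            raise ValueError("total_reads must be >= 1")
        if self.trait_values is not None:
            tv = tuple(float(x) for x in self.trait_values)
            if len(tv) != self.n_otus:
                raise ValueError("trait_values length must equal n_otus")
            if any(x < 0 for x in tv):
                raise ValueError("trait_values must be >= 0")
            object.__setattr__(self, "trait_values", tv)

    def totals_array(self) -> np.ndarray:
        totals = np.atleast_1d(np.asarray(self.total_reads, dtype=int))
        if len(totals) == 1:
            totals = np.full(self.n_samples, totals[0])
        if len(totals) != self.n_samples:
            raise ValueError("total_reads must be scalar or length n_samples")
        return totals


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate environment: zero variance")
    return (x - x.mean()) / sd


def _sub_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-table sub-streams derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def gen_community_dataset(config: CommunitySimConfig):
    """Generate (ReadCountTable, SampleMetadata frame, traits, truth dict).

    Returns a 4-tuple ``(table, meta, traits, truth)`` where ``table`` is a
    :class:`trophic.nichemodel.ReadCountTable`, ``meta`` a sample-metadata
    DataFrame, ``traits`` a list of :class:`trophic.tradeoff.TraitRecord`
    matched to the OTUs, and ``truth`` the generating parameters (for
    recovery tests).
    """
    from trophic.nichemodel import ReadCountTable  # deferred: avoid import cycle

    rng_env, rng_re, rng_reads = _sub_rngs(config.seed, 3)
    n_i, n_j = config.n_otus, config.n_samples
    totals = config.totals_array()

    # --- environment: latent stratification factor + loaded covariates
    strat = rng_env.normal(0.0, 1.0, n_j)
    loadings = dict(config.env_loadings)
    noise_sd = 0.4
    cols = {}
    for name, load in loadings.items():
        cols[name] = load * strat + rng_env.normal(0.0, noise_sd, n_j)
    layer = np.tile(["surface", "DCM"], n_j)[:n_j]
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{j:03d}" for j in range(n_j)],
            "station": [f"st{j // 2:03d}" for j in range(n_j)],
            "layer": layer,
            # map latent scores to plausible field ranges
            "chla": np.exp(-1.9 + 0.9 * cols["chla"]),          # ~0.02-0.6 ug/l
            "par_surface": np.exp(3.4 + 0.3 * cols["par_surface"]),
            "par_depth": np.exp(2.5 + 0.5 * cols["par_depth"]),
            "nitrate": np.exp(-0.5 + 1.0 * cols["nitrate"]),
            "sst": 22.0 + 4.0 * cols["sst"],
            "mld": np.exp(3.3 + 0.5 * cols["mld"]),
            "abs_latitude": np.clip(25.0 + 12.0 * cols["abs_latitude"], 0.0, 70.0),
        }
    )

    if config.env_kind == "depth_binary":
        env = (layer == "surface").astype(float)  # DCM = 0, surface = 1
        env_model = env
    else:
        env = meta["chla"].to_numpy()
        env_model = _zscore(env)
    if np.ptp(env) == 0:
        raise ValueError("degenerate environment: zero variance")

    # --- traits: specific clearance rates (autotroph zeros + spread of grazers)
    if config.trait_values is not None:
        cr = np.asarray(config.trait_values, dtype=float)
    else:
        n_auto = max(1, n_i // 3)
        cr = np.concatenate([np.zeros(n_auto), np.linspace(0.3, 8.0, n_i - n_auto)])
    if np.ptp(cr) == 0:
        raise ValueError("trait values must vary across OTUs")
    cr_z = _zscore(cr)

    # --- random effects and linear predictor
    base = config.intercept_mean
    if base is None:
        # keep the focal OTUs a modest share of the read universe
        base = float(np.log(0.02 / 0.98))
    intercepts = base + rng_re.normal(0.0, config.intercept_sd, n_i)
    slopes = rng_re.normal(0.0, config.slope_sd, n_i)
    sample_eff = rng_re.normal(0.0, config.sample_sd, n_j)
    eta = (
        intercepts[:, None]
        + sample_eff[None, :]
        + (cr_z[:, None] * config.creff_true + slopes[:, None]) * env_model[None, :]
    )
    p = 1.0 / (1.0 + np.exp(-eta))

    # --- beta-binomial reads: Beta(pV, (1-p)V) mixed over Binomial(N_j)
    V = config.dispersion
    q = rng_reads.beta(p * V, (1.0 - p) * V)
    reads = rng_reads.binomial(totals[None, :], q)

    otu_ids = [f"OTU{i:03d}" for i in range(n_i)]
    table = ReadCountTable(
        otu_ids=otu_ids,
        sample_ids=list(meta["sample_id"]),
        reads=reads,
        totals=totals,
        taxon_of_otu={o: f"taxon{(k % 5)}" for k, o in enumerate(otu_ids)},
    )
    traits = [
        TraitRecord(
            strain_id=f"strain_{i:03d}",
            otu_id=otu_ids[i],
            clearance_specific=float(cr[i]),
            growth_high_light=float(max(0.05, 0.55 - 0.05 * cr[i])),
            growth_low_light=0.0 if cr[i] > 0 else 0.3,
            is_mixotroph=bool(cr[i] > 0),
        )
        for i in range(n_i)
    ]
    truth = {
        "creff_true": config.creff_true,
        "intercepts": intercepts.tolist(),
        "slopes": slopes.tolist(),
        "sample_effects": sample_eff.tolist(),
        "dispersion": V,
        "env_kind": config.env_kind,
        "env_model": env_model.tolist(),
        "cr_z": cr_z.tolist(),
        "seed": config.seed,
    }
    return table, meta, traits, truth


def write_community_dataset(outdir, table, meta, traits, truth) -> dict[str, Path]:
    """Write a community dataset as TSV/CSV plus a truth-sidecar JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.tsv",
        "totals": outdir / "totals.tsv",
        "metadata": outdir / "metadata.tsv",
        "traits": outdir / "traits.csv",
        "truth": outdir / "truth.json",
    }
    reads_frame = pd.DataFrame(table.reads, columns=table.sample_ids)
    reads_frame.insert(0, "otu_id", table.otu_ids)
    reads_frame.insert(1, "taxogroup", [table.taxon_of_otu[o] for o in table.otu_ids])
    reads_frame.to_csv(paths["reads"], sep="\t", index=False)
    pd.DataFrame({"sample_id": table.sample_ids, "total_reads": table.totals}).to_csv(
        paths["totals"], sep="\t", index=False
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    records_to_frame(traits).to_csv(paths["traits"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
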