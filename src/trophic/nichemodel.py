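"""Beta-binomial trait x environment GLMM and niche summaries.

The central model asks whether an OTU's grazing ability (body-volume-specific
clearance rate, ``CR``) predicts how its relative abundance responds to an
environmental gradient.  Read counts are modelled as beta-binomial draws out
of the per-sample phytoplankton read total with a logit link::

    logit(p_ij) = Int_i + Sample_j + (CRz_i * CReff + slope_i) * Env_j
    reads_ij ~ BetaBinom(p_ij, V_i, N_j)

``Int_i`` are OTU random intercepts, ``Sample_j`` sample random effects,
``slope_i`` OTU random slopes capturing environmental responses not explained
by the trait, ``V_i`` per-OTU beta-binomial precisions, and ``CReff`` the
fixed effect of interest: the amount by which one sd of clearance rate tilts
an OTU's logit-scale environmental response.

Two environments are supported: a binary depth contrast (DCM = 0, surface =
1) and a continuous (z-scored) Chl a gradient restricted to surface samples.

Estimation is penalized maximum likelihood at the joint posterior mode with
weakly-informative priors (``map_laplace``, the default: Wald interval from
the inverse Hessian, analytic gradients), or MCMC over the same posterior via
emcee (``mcmc``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from trophic.tradeoff import TraitRecord

__all__ = [
    "ReadCountTable",
    "GlmmFit",
    "PHYTOPLANKTON_TAXOGROUPS",
    "assemble_read_universe",
    "betabinom_logpmf",
    "fit_trait_niche_glmm",
    "derive_otu_niche_summaries",
    "community_weighted_trait",
]

logger = logging.getLogger(__name__)

#: Read-universe whitelist: taxogroups treated as phytoplankton when summing
#: per-sample totals.  Dinoflagellates are deliberately absent (phototrophic
#: vs heterotrophic status cannot be assigned for many taxa).
PHYTOPLANKTON_TAXOGROUPS = (
    "Bacillariophyta",
    "Bolidophyceae",
    "Chlorarachnea",
    "Chlorophyceae",
    "Chrysophyceae/Synurophyceae",
    "Cryptophyta",
    "Dictyochophyceae",
    "Euglenida",
    "Glaucocystophyta",
    "Haptophyta",
    "Mamiellophyceae",
    "Other Archaeplastida",
    "Other Chlorophyta",
    "Pelagophyceae",
    "Phaeophyceae",
    "Pinguiophyceae",
    "Prasino-Clade-7",
    "Pyramimonadales",
    "Raphidophyceae",
    "Rhodophyta",
    "Trebouxiophyceae",
)


@dataclass
class ReadCountTable:
    """OTU x sample integer read counts with per-sample phytoplankton totals."""

    otu_ids: list[str]
    sample_ids: list[str]
    reads: np.ndarray
    totals: np.ndarray
    taxon_of_otu: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if self.reads.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("reads must be (n_otus, n_samples)")
        if len(self.totals) != len(self.sample_ids):
            raise ValueError("totals must have one entry per sample")
        if np.any(self.reads < 0):
            raise ValueError("reads must be >= 0")
        if np.any(self.totals < 1):
            raise ValueError("totals must be >= 1")
        if np.any(self.reads > self.totals[None, :]):
            raise ValueError("reads_ij must not exceed the sample total N_j")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    def select_otus(self, otu_ids: Sequence[str]) -> "ReadCountTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return ReadCountTable(
            otu_ids=list(otu_ids),
            sample_ids=list(self.sample_ids),
            reads=self.reads[idx, :],
            totals=self.totals.copy(),
            taxon_of_otu={o: self.taxon_of_otu[o] for o in otu_ids if o in self.taxon_of_otu},
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ReadCountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ReadCountTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            reads=self.reads[:, idx],
            totals=self.totals[idx],
            taxon_of_otu=dict(self.taxon_of_otu),
        )


def assemble_read_universe(
    raw_table: pd.DataFrame,
    whitelist: Sequence[str] = PHYTOPLANKTON_TAXOGROUPS,
    heterotroph_otus: Sequence[str] = (),
    strict: bool = True,
) -> ReadCountTable:
    """Build the phytoplankton read universe from an annotated OTU table.

    ``raw_table`` must have columns ``otu_id`` and ``taxogroup`` followed by
    one integer column per sample.  Per-sample totals ``N_j`` sum reads over
    the whitelisted taxogroups only; dinoflagellates (not whitelisted) and the
    configured heterotroph OTUs contribute nothing and are dropped from the
    table.  Samples whose ``N_j`` is 0 are dropped with a logged warning.
    Unknown taxogroup labels raise in strict mode and are excluded otherwise.
    """
    if len(whitelist) == 0:
        raise ValueError("empty taxogroup whitelist")
    for col in ("otu_id", "taxogroup"):
        if col not in raw_table.columns:
            raise ValueError(f"annotated OTU table missing column {col!r}")
    sample_cols = [c for c in raw_table.columns if c not in ("otu_id", "taxogroup")]
    if not sample_cols:
        raise ValueError("annotated OTU table has no sample columns")
    wl = set(whitelist)
    known = wl | {"Dinophyceae", "Dinoflagellata"}
    unknown = set(raw_table["taxogroup"]) - known
    if unknown and strict:
        raise ValueError(f"unknown taxogroup labels: {sorted(unknown)}")
    keep = raw_table["taxogroup"].isin(wl) & ~raw_table["otu_id"].isin(set(heterotroph_otus))
    kept = raw_table.loc[keep]
    reads = kept[sample_cols].to_numpy(dtype=np.int64)
    totals = reads.sum(axis=0)
    nonzero = totals > 0
    if not np.all(nonzero):
        dropped = [s for s, ok in zip(sample_cols, nonzero) if not ok]
        logger.warning("dropping %d samples with zero phytoplankton reads: %s", len(dropped), dropped)
    sample_ids = [s for s, ok in zip(sample_cols, nonzero) if ok]
    return ReadCountTable(
        otu_ids=list(kept["otu_id"]),
        sample_ids=sample_ids,
        reads=reads[:, nonzero],
        totals=totals[nonzero],
        taxon_of_otu=dict(zip(kept["otu_id"], kept["taxogroup"])),
    )


# ---------------------------------------------------------------------------
# beta-binomial likelihood (mean/precision parametrization)

def betabinom_logpmf(k, n, p, V):
    """log pmf of BetaBinom(n, alpha=p*V, beta=(1-p)*V) at k."""
    return stats.betabinom.logpmf(k, n, p * V, (1.0 - p) * V)


def _bb_dldp_dldV(k, n, p, V):
    """Analytic d(logpmf)/dp and d(logpmf)/dV for the mean/precision form."""
    a = p * V
    b = (1.0 - p) * V
    common = special.digamma(a + b) - special.digamma(n + a + b)
    dla = special.digamma(k + a) - special.digamma(a) + common
    dlb = special.digamma(n - k + b) - special.digamma(b) + common
    return V * (dla - dlb), p * dla + (1.0 - p) * dlb


@dataclass
class GlmmFit:
    """Fitted beta-binomial trait x environment GLMM."""

    creff: float
    creff_low: float
    creff_high: float
    intercepts: np.ndarray
    sample_effects: np.ndarray
    slopes: np.ndarray
    dispersions: np.ndarray
    env_kind: str
    fit_method: str
    otu_ids: list[str]
    sample_ids: list[str]
    cr_values: np.ndarray
    cr_z: np.ndarray
    taxon_variance: float | None = None
    diagnostics: dict = field(default_factory=dict)
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.creff_low <= self.creff <= self.creff_high):
            raise ValueError("CReff interval must bracket the estimate")
        if np.any(self.dispersions <= 0):
            raise ValueError("dispersions must be positive")
        if self.taxon_variance is not None and self.taxon_variance < 0:
            raise ValueError("taxon_variance must be >= 0")


class _GlmmDesign:
    """Flattened parameter bookkeeping for the joint posterior.

    Optional taxon random slopes enter with a FIXED sd ``s_taxon`` (profiled
    outside via the Laplace-approximate marginal likelihood, where a null
    taxon structure correctly shrinks to zero; a free joint-mode sd would
    not).
    """

    def __init__(self, k, n, cr_z, env, taxon_idx=None, s_taxon=0.0,
                 pool_dispersion=False):
        self.k = k              # (n_i, n_j) reads
        self.n = n              # (n_j,) totals
        self.cr_z = cr_z        # (n_i,)
        self.env = env          # (n_j,)
        self.n_i, self.n_j = k.shape
        self.taxon_idx = taxon_idx  # (n_i,) int codes or None
        self.s_taxon = float(s_taxon)
        self.n_tax = 0 if taxon_idx is None else int(taxon_idx.max()) + 1
        self.pool_dispersion = pool_dispersion
        self.n_V = 1 if pool_dispersion else self.n_i
        self.has_taxon = taxon_idx is not None
        # layout: creff, mu_int, log_s_int, log_s_slope, log_s_sample,
        #         log_V (n_V), int_raw (n_i), slope_raw (n_i), samp_raw (n_j),
        #         [tax_raw (n_tax)]
        sizes = [1, 1, 1, 1, 1, self.n_V, self.n_i, self.n_i, self.n_j]
        if self.has_taxon:
            sizes.append(self.n_tax)
        self.offsets = np.cumsum([0] + sizes)
        self.dim = self.offsets[-1]

    def start(self) -> np.ndarray:
        theta0 = np.zeros(self.dim)
        p_bar = max(self.k.sum() / (self.n.sum() * self.n_i), 1e-6)
        theta0[1] = math.log(p_bar / (1.0 - p_bar))
        theta0[self.offsets[5]:self.offsets[6]] = math.log(50.0)
        return theta0

    def unpack(self, theta):
        o = self.offsets
        out = {
            "creff": theta[0],
            "mu_int": theta[1],
            "ls_int": theta[2],
            "ls_slope": theta[3],
            "ls_samp": theta[4],
            "log_V": theta[o[5]:o[6]],
            "int_raw": theta[o[6]:o[7]],
            "slope_raw": theta[o[7]:o[8]],
            "samp_raw": theta[o[8]:o[9]],
        }
        if self.has_taxon:
            out["tax_raw"] = theta[o[9]:o[10]]
        return out

    def eta_p(self, u):
        s_int, s_slope, s_samp = np.exp(u["ls_int"]), np.exp(u["ls_slope"]), np.exp(u["ls_samp"])
        slope_total = self.cr_z * u["creff"] + s_slope * u["slope_raw"]
        if self.has_taxon:
            slope_total = slope_total + self.s_taxon * u["tax_raw"][self.taxon_idx]
        eta = (
            (u["mu_int"] + s_int * u["int_raw"])[:, None]
            + (s_samp * u["samp_raw"])[None, :]
            + slope_total[:, None] * self.env[None, :]
        )
        p = special.expit(eta)
        return eta, np.clip(p, 1e-12, 1.0 - 1e-12)

    def V_matrix(self, u):
        V = np.exp(u["log_V"])
        if self.pool_dispersion:
            V = np.full(self.n_i, V[0])
        return V

    # priors: N(0, 2.5^2) on creff and mu_int; standard normal on raws;
    # half-normal(1) on random-effect sds; Gamma(2, scale=200) on V
    def log_posterior_and_grad(self, theta):
        u = self.unpack(theta)
        _, p = self.eta_p(u)
        V = self.V_matrix(u)
        Vm = V[:, None]
        ll = betabinom_logpmf(self.k, self.n[None, :], p, Vm)
        dldp, dldV = _bb_dldp_dldV(self.k, self.n[None, :], p, Vm)
        dlde = dldp * p * (1.0 - p)  # chain through logit link

        s_int, s_slope, s_samp = np.exp(u["ls_int"]), np.exp(u["ls_slope"]), np.exp(u["ls_samp"])
        per_otu = dlde.sum(axis=1)
        per_otu_env = (dlde * self.env[None, :]).sum(axis=1)
        per_sample = dlde.sum(axis=0)
        o = self.offsets
        g = np.zeros_like(theta)
        g[0] = np.sum(dlde * (self.cr_z[:, None] * self.env[None, :]))
        g[1] = np.sum(dlde)
        g[2] = s_int * float(per_otu @ u["int_raw"])
        g[3] = s_slope * float(per_otu_env @ u["slope_raw"])
        g[4] = s_samp * float(per_sample @ u["samp_raw"])
        dV_per_otu = dldV.sum(axis=1) * V  # d/d log V_i
        g[o[5]:o[6]] = dV_per_otu.sum() if self.pool_dispersion else dV_per_otu
        g[o[6]:o[7]] = s_int * per_otu
        g[o[7]:o[8]] = s_slope * per_otu_env
        g[o[8]:o[9]] = s_samp * per_sample
        if self.has_taxon:
            g[o[9]:o[10]] = self.s_taxon * np.bincount(
                self.taxon_idx, weights=per_otu_env, minlength=self.n_tax
            )

        lp = float(ll.sum())
        lp += -0.5 * (u["creff"] / 2.5) ** 2 - 0.5 * (u["mu_int"] / 2.5) ** 2
        g[0] += -u["creff"] / 2.5**2
        g[1] += -u["mu_int"] / 2.5**2
        for idx, s in ((2, s_int), (3, s_slope), (4, s_samp)):
            lp += -0.5 * s**2 + theta[idx]  # half-normal(1) + log-Jacobian
            g[idx] += -(s**2) + 1.0
        # Gamma(2, scale=200) on V, log-parametrized: (2-1) ln V - V/200 + ln V
        logV = u["log_V"]
        Vv = np.exp(logV)
        lp += float(np.sum(2.0 * logV - Vv / 200.0))
        g[o[5]:o[6]] += 2.0 - Vv / 200.0
        for name in ("int_raw", "slope_raw", "samp_raw", "tax_raw"):
            if name in u:
                lp += -0.5 * float(u[name] @ u[name])
        g[o[6]:o[7]] += -u["int_raw"]
        g[o[7]:o[8]] += -u["slope_raw"]
        g[o[8]:o[9]] += -u["samp_raw"]
        if self.has_taxon:
            g[o[9]:o[10]] += -u["tax_raw"]
        return lp, g


def _map_fit(design: _GlmmDesign, theta0: np.ndarray | None = None):
    def neg(theta):
        lp, g = design.log_posterior_and_grad(theta)
        return -lp, -g

    res = optimize.minimize(neg, theta0 if theta0 is not None else design.start(),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 3000, "ftol": 1e-12, "gtol": 1e-8})
    return res


def _neg_hessian(design: _GlmmDesign, theta_hat: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Hessian of the negative log posterior by central differences of the gradient."""
    d = design.dim
    H = np.empty((d, d))
    for a in range(d):
        tp = theta_hat.copy(); tp[a] += h
        tm = theta_hat.copy(); tm[a] -= h
        _, gp = design.log_posterior_and_grad(tp)
        _, gm = design.log_posterior_and_grad(tm)
        H[:, a] = -(gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _fit_taxon_sd(design: _GlmmDesign, taxon_idx: np.ndarray, pool_dispersion: bool):
    """Profile the taxon random-slope sd over a grid of candidates.

    Candidates are compared by the Laplace-approximate marginal likelihood
    ``lp(theta_hat) - 0.5 log|H|`` (parameter counts are equal across the
    grid because tax_raw is always present).  Returns the winning sd, its
    design and its MAP result.
    """
    best = None
    for s_tax in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8):
        d = _GlmmDesign(design.k, design.n, design.cr_z, design.env,
                        taxon_idx=taxon_idx, s_taxon=s_tax,
                        pool_dispersion=pool_dispersion)
        res = _map_fit(d)
        lp, _ = d.log_posterior_and_grad(res.x)
        H = _neg_hessian(d, res.x)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            w = np.clip(np.linalg.eigvalsh(H), 1e-8, None)
            logdet = float(np.sum(np.log(w)))
        marginal = lp - 0.5 * logdet
        if best is None or marginal > best[0]:
            best = (marginal, s_tax, d, res)
    return best[1], best[2], best[3]


def _prepare_inputs(
    table: ReadCountTable,
    meta: pd.DataFrame,
    traits: Sequence[TraitRecord],
    env_kind: str,
    subset: str,
    chla_max: float = 5.0,
):
    """Match OTUs to traits, select samples, build env and z-scored CR."""
    trait_by_otu = {t.otu_id: t for t in traits if t.otu_id is not None}
    otus = [o for o in table.otu_ids if o in trait_by_otu]
    if subset == "mixotrophs_only":
        otus = [o for o in otus if trait_by_otu[o].is_mixotroph]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(otus) < 3:
        raise ValueError("need >= 3 trait-matched OTUs")
    meta = meta.set_index("sample_id").loc[[s for s in table.sample_ids if s in set(meta["sample_id"])]]

    if env_kind == "depth_binary":
        samples = list(meta.index)
        env = (meta["layer"].to_numpy() == "surface").astype(float)
    elif env_kind == "chla_continuous":
        ok = (meta["layer"] == "surface") & meta["chla"].notna() & (meta["chla"] <= chla_max)
        samples = list(meta.index[ok])
        chla = meta.loc[samples, "chla"].to_numpy(dtype=float)
        if len(samples) < 3 or np.ptp(chla) == 0:
            raise ValueError("not enough Chl a variation among usable surface samples")
        env = (chla - chla.mean()) / chla.std()
    else:
        raise ValueError(f"unknown env_kind {env_kind!r}")
    if np.ptp(env) == 0:
        raise ValueError("degenerate environment: zero variance")

    sub = table.select_otus(otus).select_samples(samples)
    cr = np.array([trait_by_otu[o].clearance_specific for o in otus])
    if np.ptp(cr) == 0:
        raise ValueError("CReff unidentifiable: all clearance rates identical")
    cr_z = (cr - cr.mean()) / cr.std()
    return sub, env, cr, cr_z


def fit_trait_niche_glmm(
    table: ReadCountTable,
    meta: pd.DataFrame,
    traits: Sequence[TraitRecord],
    env_kind: str = "depth_binary",
    subset: str = "all",
    fit_method: str = "map_laplace",
    include_taxon_effects: bool = False,
    pool_dispersion: bool = False,
    chla_max: float = 5.0,
    seed: int = 0,
    mcmc_steps: int = 8000,
    mcmc_burn: int = 3000,
) -> GlmmFit:
    """Fit the beta-binomial trait x environment GLMM.

    ``env_kind`` is ``depth_binary`` (all samples, DCM = 0 / surface = 1) or
    ``chla_continuous`` (surface samples only, samples without Chl a or above
    ``chla_max`` excluded, Chl a z-scored).  ``fit_method`` is
    ``map_laplace`` (joint posterior mode, Wald interval from the inverse
    Hessian) or ``mcmc`` (emcee over the same posterior; percentile interval).
    """
    sub, env, cr, cr_z = _prepare_inputs(table, meta, traits, env_kind, subset, chla_max)
    design = _GlmmDesign(sub.reads, sub.totals, cr_z, env, pool_dispersion=pool_dispersion)

    res = _map_fit(design)
    theta_hat = res.x
    taxon_variance = None
    if include_taxon_effects:
        taxa = [sub.taxon_of_otu.get(o, "unknown") for o in sub.otu_ids]
        codes = {t: i for i, t in enumerate(dict.fromkeys(taxa))}
        taxon_idx = np.array([codes[t] for t in taxa])
        s_tax, design, res = _fit_taxon_sd(design, taxon_idx, pool_dispersion)
        theta_hat = res.x
        taxon_variance = float(s_tax**2)
    u = design.unpack(theta_hat)
    lp_hat, _ = design.log_posterior_and_grad(theta_hat)

    if fit_method == "map_laplace":
        cov00 = _wald_var(design, theta_hat)
        se = math.sqrt(max(cov00, 0.0))
        creff = float(u["creff"])
        lo, hi = creff - 1.96 * se, creff + 1.96 * se
        diagnostics = {"optimizer_converged": bool(res.success), "creff_se": se,
                       "log_posterior": lp_hat, "n_iter": int(res.nit)}
    elif fit_method == "mcmc":
        import emcee

        ndim = design.dim
        nwalkers = max(2 * ndim + 2, 64)
        rng = np.random.default_rng(seed)
        p0 = theta_hat[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))

        def logp(th):
            lp, _ = design.log_posterior_and_grad(th)
            return lp if np.isfinite(lp) else -np.inf

        sampler = emcee.EnsembleSampler(nwalkers, ndim, logp)
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(p0, mcmc_steps, progress=False)
        chain = sampler.get_chain(discard=mcmc_burn, flat=True)
        creff_draws = chain[:, 0]
        creff = float(np.median(creff_draws))
        lo, hi = (float(x) for x in np.percentile(creff_draws, [2.5, 97.5]))
        try:
            tau = float(np.mean(sampler.get_autocorr_time(tol=0)))
        except Exception:
            tau = float("nan")
        acc = float(np.mean(sampler.acceptance_fraction))
        diagnostics = {"acceptance_fraction": acc, "autocorr_time": tau,
                       "n_steps": mcmc_steps, "converged": acc > 0.1}
        # centre the point estimate on the posterior median draw
        u = design.unpack(np.median(chain, axis=0))
    else:
        raise ValueError(f"unknown fit_method {fit_method!r}")

    s_int, s_slope, s_samp = (math.exp(u["ls_int"]), math.exp(u["ls_slope"]),
                              math.exp(u["ls_samp"]))
    V = design.V_matrix(u)
    return GlmmFit(
        creff=creff,
        creff_low=float(min(lo, creff)),
        creff_high=float(max(hi, creff)),
        intercepts=u["mu_int"] + s_int * u["int_raw"],
        sample_effects=s_samp * u["samp_raw"],
        slopes=s_slope * u["slope_raw"],
        dispersions=V,
        env_kind=env_kind,
        fit_method=fit_method,
        otu_ids=list(sub.otu_ids),
        sample_ids=list(sub.sample_ids),
        cr_values=cr,
        cr_z=cr_z,
        taxon_variance=taxon_variance,
        diagnostics=diagnostics,
        loglik=float(lp_hat),
    )


def _wald_var(design: _GlmmDesign, theta_hat: np.ndarray, h: float = 1e-4) -> float:
    """Var(creff) from the inverse Hessian of the joint negative log posterior.

    The Hessian is built column-by-column by central differences of the
    analytic gradient, so the cost is 2 * dim gradient evaluations.
    """
    H = _neg_hessian(design, theta_hat, h)
    # guard against indefiniteness from flat directions
    w, U = np.linalg.eigh(H)
    w = np.clip(w, 1e-8, None)
    cov = U @ np.diag(1.0 / w) @ U.T
    return float(cov[0, 0])


def derive_otu_niche_summaries(fit: GlmmFit, traits: Sequence[TraitRecord]) -> pd.DataFrame:
    """Per-OTU niche summaries from a fitted GLMM.

    For a depth fit: the ratio of expected relative abundance in surface
    versus DCM samples with sample effects at 0.  For a Chl a fit: the
    logit-scale slope ``CRz_i * CReff + slope_i`` per sd of Chl a.  The
    returned frame also carries clearance rates, and the trait-niche
    regression R^2 is stored in ``frame.attrs["r_squared"]``.
    """
    effects = fit.cr_z * fit.creff + fit.slopes
    if fit.env_kind == "depth_binary":
        p_dcm = special.expit(fit.intercepts)
        p_surf = special.expit(fit.intercepts + effects)
        summary = p_surf / p_dcm
        col = "surface_dcm_ratio"
        niche_metric = np.log(summary)
    elif fit.env_kind == "chla_continuous":
        summary = effects
        col = "chla_slope"
        niche_metric = summary
    else:
        raise TypeError(f"cannot summarize env_kind {fit.env_kind!r}")
    frame = pd.DataFrame({
        "otu_id": fit.otu_ids,
        col: summary,
        "clearance_specific": fit.cr_values,
    })
    if np.ptp(fit.cr_values) > 0 and np.ptp(niche_metric) > 0:
        r = stats.pearsonr(fit.cr_values, niche_metric)[0]
    else:
        r = float("nan")
    frame.attrs["r_squared"] = float(r**2)
    return frame


def community_weighted_trait(
    table: ReadCountTable,
    traits: Sequence[TraitRecord],
) -> pd.Series:
    """Read-abundance-weighted mean clearance rate per sample.

    ``CWM_j = sum_i w_ij * CR_i`` with weights the relative reads among
    trait-matched OTUs.  Samples with zero matched reads get NaN.
    """
    trait_by_otu = {t.otu_id: t.clearance_specific for t in traits if t.otu_id is not None}
    otus = [o for o in table.otu_ids if o in trait_by_otu]
    if not otus:
        raise ValueError("no trait-matched OTUs in the table")
    sub = table.select_otus(otus)
    cr = np.array([trait_by_otu[o] for o in otus])
    matched = sub.reads.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = (cr[:, None] * sub.reads).sum(axis=0) / matched
    cwm = np.where(matched > 0, cwm, np.nan)
    return pd.Series(cwm, index=sub.sample_ids, name="cwm_clearance")
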