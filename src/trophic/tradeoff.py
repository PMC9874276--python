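"""Phototrophy-phagotrophy tradeoff: curve, trait correlations, curvature fit.

Mixotrophic phytoplankton trade phototrophic performance (growth on light and
dissolved nutrients) against phagotrophic performance (clearance rate on
bacterial prey).  The tradeoff is modelled as a one-parameter curve linking a
strain's phototrophic capacity fraction ``p`` (relative to a pure autotroph)
to its phagotrophic capacity fraction ``g`` (relative to the best grazer)::

    g = (1 - p) ** phi

``phi`` controls the curvature: ``phi > 1`` penalizes generalists (an
intermediate strategy keeps less than the zero-sum share of each function),
``phi < 1`` rewards them, ``phi = 1`` is the linear zero-sum tradeoff.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TraitRecord",
    "TradeoffFit",
    "tradeoff_fraction",
    "inverse_tradeoff_fraction",
    "correlate_traits",
    "estimate_phi",
    "records_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class TraitRecord:
    """Trophic traits of one strain (optionally matched to an OTU).

    ``clearance_specific`` is the body-volume-specific clearance rate when fed
    *Prochlorococcus* (water volume cleared per unit predator biovolume per
    day); strains that show no phagotrophic growth are autotrophs and carry a
    clearance of exactly 0.  Growth rates are phototrophic (no prey) rates at
    100 and 10 umol photons m-2 s-1.
    """

    strain_id: str
    clearance_specific: float
    growth_high_light: float
    growth_low_light: float
    is_mixotroph: bool
    otu_id: str | None = None

    def __post_init__(self) -> None:
        if self.clearance_specific < 0:
            raise ValueError(
                f"{self.strain_id}: clearance_specific must be >= 0, "
                f"got {self.clearance_specific}"
            )
        if not self.is_mixotroph and self.clearance_specific != 0:
            raise ValueError(
                f"{self.strain_id}: autotrophs must have clearance_specific = 0"
            )


@dataclass
class TradeoffFit:
    """Fitted tradeoff curvature with bootstrap uncertainty."""

    phi: float
    ci_low: float
    ci_high: float
    p_ref: float
    g_ref: float
    n_strains: int
    n_boot: int = 0
    n_boot_skipped: int = 0
    boot_samples: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not (self.ci_low <= self.phi <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


def tradeoff_fraction(p_frac: float, phi: float) -> float:
    """Phagotrophic capacity fraction of a strategy with phototrophic fraction ``p_frac``.

    Returns ``(1 - p_frac) ** phi``.  Strictly decreasing in ``p_frac``; for
    ``phi = 1.8`` a strategy with 50% of the photosynthetic capacity of an
    autotroph retains only ~29% of the ingestion capacity of a heterotroph.
    """
    p = np.asarray(p_frac, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_frac must lie in [0, 1]")
    if phi <= 0:
        raise ValueError("phi must be positive")
    out = (1.0 - p) ** phi
    return float(out) if np.isscalar(p_frac) else out


def inverse_tradeoff_fraction(g_frac: float, phi: float) -> float:
    """Phototrophic fraction implied by a phagotrophic fraction: ``1 - g**(1/phi)``."""
    g = np.asarray(g_frac, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("g_frac must lie in [0, 1]")
    if phi <= 0:
        raise ValueError("phi must be positive")
    out = 1.0 - g ** (1.0 / phi)
    return float(out) if np.isscalar(g_frac) else out


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho with tied ranks."""
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    py_c = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (py_c**2).sum(axis=1))
    rhos = (py_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_traits(
    records: Iterable[TraitRecord],
    subset: str = "all",
) -> tuple[float, float]:
    """Spearman correlation of high-light growth rate with specific clearance rate.

    ``subset`` is ``"mixotrophs_only"`` or ``"all"``.  Ties (autotrophs share a
    clearance of 0) receive average ranks.  The two-sided p-value uses the
    exact permutation distribution for n <= 9 and the t approximation above.
    """
    recs = [r for r in records]
    if subset == "mixotrophs_only":
        recs = [r for r in recs if r.is_mixotroph]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    recs = [r for r in recs if math.isfinite(r.growth_high_light)]
    if len(recs) < 4:
        raise ValueError("need >= 4 records with finite growth_high_light")
    x = np.array([r.growth_high_light for r in recs])
    y = np.array([r.clearance_specific for r in recs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a trait")
    rho, p_t = stats.spearmanr(x, y)
    if len(recs) <= 9:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(p_t)
    return float(rho), p


def _capacity_fractions(
    records: Sequence[TraitRecord],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalize traits to fraction scale.

    The pure-phototroph endpoint is the fastest autotroph under high light
    (p_frac = growth / max autotroph growth); the pure-phagotroph endpoint is
    the fastest observed grazer (g_frac = clearance / max clearance).
    """
    autos = [r for r in records if not r.is_mixotroph]
    if not autos:
        raise ValueError("need >= 1 autotroph record to anchor the phototrophic endpoint")
    p_ref = max(r.growth_high_light for r in autos)
    g_ref = max(r.clearance_specific for r in records)
    if p_ref <= 0 or g_ref <= 0:
        raise ValueError("reference rates must be positive")
    p_frac = np.array([min(max(r.growth_high_light / p_ref, 0.0), 1.0) for r in records])
    g_frac = np.array([min(r.clearance_specific / g_ref, 1.0) for r in records])
    return p_frac, g_frac, p_ref, g_ref


def _fit_phi_ols(p_frac: np.ndarray, g_frac: np.ndarray) -> float:
    """Least-squares curvature of ``g_frac ~ A * (1 - p_frac)**phi``.

    The amplitude ``A`` is profiled analytically for each candidate ``phi``;
    it absorbs the arbitrary scale of the clearance normalization (no strain
    need sit exactly at the pure-heterotroph endpoint), so the curvature
    estimate is invariant to the choice of reference units.
    """
    interior = (p_frac > 0) & (p_frac < 1)
    if not np.any((g_frac > 0) & (g_frac < 1)) and not np.any(interior):
        raise ValueError("tradeoff curvature unidentifiable: all points at endpoints")

    def sse(log_phi: float) -> float:
        phi = math.exp(log_phi)
        w = (1.0 - p_frac) ** phi
        denom = float(w @ w)
        amp = float(w @ g_frac) / denom if denom > 0 else 0.0
        amp = max(amp, 1e-12)
        resid = g_frac - amp * w
        return float(resid @ resid)

    res = optimize.minimize_scalar(sse, bounds=(math.log(1e-3), math.log(1e3)), method="bounded")
    return float(math.exp(res.x))


def estimate_phi(
    records: Sequence[TraitRecord],
    n_boot: int = 1000,
    seed: int = 0,
) -> TradeoffFit:
    """Estimate the tradeoff curvature ``phi`` with a bootstrap 95% interval.

    Growth and clearance are converted to capacity fractions (autotrophs anchor
    the phototrophic endpoint, the fastest grazer the phagotrophic endpoint)
    and ``phi`` minimizes the squared residuals of ``g_frac`` against
    ``(1 - p_frac) ** phi``.  The interval is a seeded nonparametric percentile
    bootstrap over strains; resamples with fewer than two distinct mixotrophs
    are skipped and counted.
    """
    records = list(records)
    mixos = [r for r in records if r.is_mixotroph]
    if len(mixos) < 2:
        raise ValueError("need >= 2 mixotroph records")
    p_frac, g_frac, p_ref, g_ref = _capacity_fractions(records)
    phi_hat = _fit_phi_ols(p_frac, g_frac)

    rng = np.random.default_rng(seed)
    boots = []
    skipped = 0
    n = len(records)
    idx_all = np.arange(n)
    is_mix = np.array([r.is_mixotroph for r in records])
    for _ in range(n_boot):
        idx = rng.choice(idx_all, size=n, replace=True)
        mix_idx = idx[is_mix[idx]]
        if len(np.unique(mix_idx)) < 2 or not np.any(~is_mix[idx]):
            skipped += 1
            continue
        sub = [records[i] for i in idx]
        try:
            pb, gb, _, _ = _capacity_fractions(sub)
            boots.append(_fit_phi_ols(pb, gb))
        except ValueError:
            skipped += 1
    boots_arr = np.array(boots)
    if len(boots_arr) >= 10:
        ci_low, ci_high = np.percentile(boots_arr, [2.5, 97.5])
        ci_low = min(ci_low, phi_hat)
        ci_high = max(ci_high, phi_hat)
    else:
        ci_low = ci_high = phi_hat
    return TradeoffFit(
        phi=phi_hat,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_ref=p_ref,
        g_ref=g_ref,
        n_strains=n,
        n_boot=n_boot,
        n_boot_skipped=skipped,
        boot_samples=boots_arr,
    )


_TRAIT_COLUMNS = [
    "strain_id",
    "clearance_specific",
    "growth_high_light",
    "growth_low_light",
    "is_mixotroph",
    "otu_id",
]


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    rows = [
        {
            "strain_id": r.strain_id,
            "clearance_specific": r.clearance_specific,
            "growth_high_light": r.growth_high_light,
            "growth_low_light": r.growth_low_light,
            "is_mixotroph": r.is_mixotroph,
            "otu_id": r.otu_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_TRAIT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TraitRecord]:
    missing = set(_TRAIT_COLUMNS[:5]) - set(frame.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        otu = row.get("otu_id")
        if otu is not None and (isinstance(otu, float) and math.isnan(otu)):
            otu = None
        records.append(
            TraitRecord(
                strain_id=str(row["strain_id"]),
                clearance_specific=float(row["clearance_specific"]),
                growth_high_light=float(row["growth_high_light"]),
                growth_low_light=float(row["growth_low_light"]),
                is_mixotroph=bool(row["is_mixotroph"]),
                otu_id=None if otu is None else str(otu),
            )
        )
    return records
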