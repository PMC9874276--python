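"""Principal coordinate analysis of OTU composition with trait/environment overlays.

Samples are ordinated by classical PCoA (double-centred squared-distance
eigendecomposition, via scikit-bio) of Bray-Curtis distances between
per-sample relative-abundance profiles of the focal OTUs.  OTUs are placed in
the sample ordination as abundance-weighted averages of sample scores.  The
first axis is then correlated with environmental covariates (the
"stratification" interpretation: positive with Chl a, nitrate and mixed-layer
depth, negative with temperature and PAR) and with per-OTU grazing ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from trophic.nichemodel import ReadCountTable
from trophic.tradeoff import TraitRecord

__all__ = [
    "OrdinationResult",
    "pcoa_composition",
    "correlate_axis_environment",
    "correlate_axis_trait",
    "ENV_VARIABLES",
]

ENV_VARIABLES = ("chla", "par_surface", "par_depth", "nitrate", "sst", "mld", "abs_latitude")


@dataclass
class OrdinationResult:
    """Sample scores, eigenvalues and OTU projections from a PCoA."""

    axis_scores: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    otu_scores: pd.DataFrame       # OTUs x axes (weighted-average projection)
    distance_metric: str
    cailliez_constant: float = 0.0
    negative_eigenvalue_fraction: float = 0.0

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained)
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise ValueError("variance_explained must lie in [0, 1]")
        if np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")


def _relative_abundance(table: ReadCountTable, renormalize: bool) -> np.ndarray:
    """Per-sample composition matrix (samples x OTUs)."""
    reads = table.reads.astype(float)
    if renormalize:
        colsum = reads.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError("sample with zero focal reads cannot be renormalized")
        rel = reads / colsum[None, :]
    else:
        rel = reads / table.totals[None, :].astype(float)
    return rel.T


def _distances(profiles: np.ndarray, metric: str) -> np.ndarray:
    if metric == "braycurtis":
        return squareform(pdist(profiles, metric="braycurtis"))
    if metric == "euclidean":
        return squareform(pdist(profiles, metric="euclidean"))
    if metric == "hellinger":
        root = np.sqrt(profiles / profiles.sum(axis=1, keepdims=True))
        return squareform(pdist(root, metric="euclidean"))
    raise ValueError(f"unknown metric {metric!r}")


def _gower_eigvals(d: np.ndarray) -> np.ndarray:
    n = len(d)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    return np.linalg.eigvalsh(B)


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making the distance matrix Euclidean."""
    n = len(d)
    J = np.eye(n) - np.ones((n, n)) / n
    B1 = -0.5 * J @ (d**2) @ J
    B2 = -0.5 * J @ d @ J
    upper = np.hstack([np.zeros((n, n)), 2.0 * B1])
    lower = np.hstack([-np.eye(n), -4.0 * B2])
    M = np.vstack([upper, lower])
    eig = np.linalg.eigvals(M)
    return float(np.max(eig.real))


def pcoa_composition(
    table: ReadCountTable,
    samples: Sequence[str] | None = None,
    metric: str = "braycurtis",
    renormalize: bool = True,
) -> OrdinationResult:
    """Classical PCoA of OTU composition across the selected samples.

    ``samples`` restricts the ordination (typically to surface samples);
    ``renormalize`` divides reads by the focal-set column sum (otherwise by
    the full phytoplankton total ``N_j``).  Strongly negative eigenvalues
    trigger a Cailliez correction of the distance matrix; tiny negatives are
    clamped to zero.  Axis orientation is normalized so the OTU with the
    largest |score| on each axis is positive.
    """
    sub = table.select_samples(list(samples)) if samples is not None else table
    if len(sub.sample_ids) < 3:
        raise ValueError("need >= 3 samples to ordinate")
    profiles = _relative_abundance(sub, renormalize)
    d = _distances(profiles, metric)
    if np.all(d[~np.eye(len(d), dtype=bool)] < 1e-12):
        raise ValueError("degenerate ordination: all pairwise distances are zero")

    eigs = _gower_eigvals(d)
    c = 0.0
    if eigs.min() < -1e-8 * eigs.max():
        c = _cailliez_constant(d)
        # add the constant off-diagonal but preserve exact zeros so duplicate
        # samples keep coinciding in the ordination
        d = d + c * ((d > 0) & ~np.eye(len(d), dtype=bool))
    neg_frac = float(np.abs(eigs[eigs < 0]).sum() / np.abs(eigs).sum()) if eigs.max() > 0 else 0.0

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix(d, ids=sub.sample_ids), method="eigh",
                          warn_neg_eigval=False)
    eigvals = np.clip(res.eigvals.to_numpy(), 0.0, None)
    keep = eigvals > 1e-12 * eigvals.max()
    eigvals = eigvals[keep]
    scores = res.samples.to_numpy()[:, keep]
    var_exp = eigvals / eigvals.sum()

    # OTU positions: abundance-weighted averages of sample scores
    w = profiles / profiles.sum(axis=0, keepdims=True)  # weights per OTU over samples
    otu_scores = w.T @ scores

    # orientation: largest-|loading| OTU positive on each axis
    for a in range(scores.shape[1]):
        i = int(np.argmax(np.abs(otu_scores[:, a])))
        if otu_scores[i, a] < 0:
            otu_scores[:, a] *= -1.0
            scores[:, a] *= -1.0

    axis_names = [f"PC{a+1}" for a in range(scores.shape[1])]
    return OrdinationResult(
        axis_scores=pd.DataFrame(scores, index=sub.sample_ids, columns=axis_names),
        eigenvalues=eigvals,
        variance_explained=var_exp,
        otu_scores=pd.DataFrame(otu_scores, index=sub.otu_ids, columns=axis_names),
        distance_metric=metric,
        cailliez_constant=c,
        negative_eigenvalue_fraction=neg_frac,
    )


def correlate_axis_environment(
    result: OrdinationResult,
    meta: pd.DataFrame,
    variables: Sequence[str] = ENV_VARIABLES,
) -> pd.DataFrame:
    """Pearson correlations of axis-1 scores with environmental variables.

    The sign convention orients axis 1 to correlate positively with Chl a (so
    stratification decreases along the axis); when the raw correlation with
    Chl a is negative the whole axis — and all reported correlations — are
    flipped.  Variables with fewer than 3 paired observations are skipped.
    """
    meta = meta.set_index("sample_id")
    shared = [s for s in result.axis_scores.index if s in meta.index]
    axis1 = result.axis_scores.loc[shared, "PC1"].to_numpy()

    flip = 1.0
    if "chla" in variables and "chla" in meta.columns:
        chla = meta.loc[shared, "chla"].to_numpy(dtype=float)
        ok = np.isfinite(chla)
        if ok.sum() >= 3 and np.ptp(axis1[ok]) > 0 and np.ptp(chla[ok]) > 0:
            if stats.pearsonr(axis1[ok], chla[ok])[0] < 0:
                flip = -1.0

    rows = []
    for var in variables:
        if var not in meta.columns:
            continue
        vals = meta.loc[shared, var].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 3 or np.ptp(vals[ok]) == 0:
            continue
        r, p = stats.pearsonr(flip * axis1[ok], vals[ok])
        rows.append({"variable": var, "r": float(r), "p_value": float(p), "n": int(ok.sum())})
    out = pd.DataFrame(rows, columns=["variable", "r", "p_value", "n"])
    out.attrs["axis_flipped"] = flip < 0
    return out


def correlate_axis_trait(
    result: OrdinationResult,
    traits: Sequence[TraitRecord],
    subset: str = "all",
) -> tuple[float, float]:
    """Pearson correlation of per-OTU axis-1 position with clearance rate."""
    trait_by_otu = {t.otu_id: t for t in traits if t.otu_id is not None}
    otus = [o for o in result.otu_scores.index if o in trait_by_otu]
    if subset == "mixotrophs_only":
        otus = [o for o in otus if trait_by_otu[o].is_mixotroph]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(otus) < 3:
        raise ValueError("need >= 3 trait-matched OTUs (n = 2 is trivially r = +/-1)")
    pos = result.otu_scores.loc[otus, "PC1"].to_numpy()
    cr = np.array([trait_by_otu[o].clearance_specific for o in otus])
    if np.ptp(cr) == 0:
        raise ValueError("correlation undefined: constant trait vector")
    r, p = stats.pearsonr(pos, cr)
    return float(r), float(p)
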