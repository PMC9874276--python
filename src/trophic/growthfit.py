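"""Maximum-likelihood fitting of batch-culture growth curves.

Two sigmoidal models are supported, both fit to cell-concentration time
series by maximum likelihood with independent Gaussian noise on the natural
log of concentration (the error sd is profiled out analytically):

* ``lag`` — Zwietering-type model with a lag phase, applied on the ln scale::

      ln C(t) = ln(K) / (1 + exp[(4 mu / ln K)(lambda - t) + 2])

  ``mu`` is the exponential growth rate (d-1), ``K`` the carrying capacity
  argument (the model requires ``K > 1`` so ``ln K > 0``), ``lambda`` the
  lag-end time where the ln-scale slope attains ``mu``.

* ``logistic`` — the plain logistic on the concentration scale::

      C(t) = K / (1 + exp[-mu (t - t_m)])

  ``t_m`` is the inflection time, where ``C = K / 2``.

Series that decline after the stationary peak are trimmed first so the
sigmoid fits the growth portion only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CellCountSeries",
    "GrowthFit",
    "trim_decline_phase",
    "fit_growth_model",
    "summarize_growth_rates",
    "lag_log_curve",
    "logistic_curve",
]

HIGH_LIGHT = "high_light_100"
LOW_LIGHT = "low_light_10"

#: fractional drop below the running maximum that counts as a decline phase
TRIM_TOLERANCE = 0.10


@dataclass(frozen=True)
class CellCountSeries:
    """Cell concentrations over time for one culture replicate."""

    strain_id: str
    treatment: str
    replicate: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GrowthFit:
    """Result of a maximum-likelihood growth-model fit."""

    strain_id: str
    treatment: str
    replicate: str
    model_kind: str  # "lag" | "logistic"
    mu: float
    K: float
    lag_lambda: float | None
    t_m: float | None
    loglik: float
    converged: bool
    n_points_used: int
    sigma: float = float("nan")

    def predict_log(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.model_kind == "lag":
            return lag_log_curve(times, self.mu, self.K, self.lag_lambda)
        return np.log(logistic_curve(times, self.mu, self.K, self.t_m))


def lag_log_curve(t: np.ndarray, mu: float, K: float, lam: float) -> np.ndarray:
    """ln C(t) for the lag model; requires K > 1."""
    if K <= 1:
        raise ValueError("lag model requires K > 1 (ln K appears in a denominator)")
    lnK = math.log(K)
    u = (4.0 * mu / lnK) * (lam - np.asarray(t, dtype=float)) + 2.0
    return lnK / (1.0 + np.exp(u))


def logistic_curve(t: np.ndarray, mu: float, K: float, t_m: float) -> np.ndarray:
    """C(t) for the logistic model."""
    return K / (1.0 + np.exp(-mu * (np.asarray(t, dtype=float) - t_m)))


def trim_decline_phase(series: CellCountSeries, tolerance: float = TRIM_TOLERANCE) -> CellCountSeries:
    """Drop the post-peak decline so only the sigmoidal portion is fit.

    The series is cut at the global maximum concentration, but only when some
    later point falls below the maximum by more than ``tolerance`` (fractional
    drop); a flat plateau within tolerance is retained unchanged.
    """
    c = series.concentrations
    i_max = int(np.argmax(c))
    after = c[i_max + 1 :]
    if len(after) == 0 or np.all(after >= c[i_max] * (1.0 - tolerance)):
        out = series
    else:
        out = replace(
            series,
            times=series.times[: i_max + 1],
            concentrations=c[: i_max + 1],
        )
    if len(out) < 4:
        raise ValueError(
            f"{series.strain_id}/{series.replicate}: fewer than 4 points remain after trimming"
        )
    return out


def _profile_loglik(log_c: np.ndarray, log_pred: np.ndarray) -> tuple[float, float]:
    """Gaussian log-likelihood on ln concentration with sigma profiled out."""
    resid = log_c - log_pred
    n = len(resid)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return ll, math.sqrt(sigma2)


def _starts(times: np.ndarray, log_c: np.ndarray) -> list[dict]:
    """Data-driven multi-start heuristics."""
    dlog = np.diff(log_c) / np.diff(times)
    mu0 = max(float(np.max(dlog)), 1e-3)
    K0 = float(np.exp(np.max(log_c)))
    i_slope = int(np.argmax(dlog))
    t_slope = float(0.5 * (times[i_slope] + times[i_slope + 1]))
    starts = []
    for mu_f in (1.0, 0.5, 2.0, 0.25):
        for t_f in (0.0, 0.3 * (times[-1] - times[0])):
            starts.append({"mu": mu0 * mu_f, "K": K0, "t0": t_slope + t_f})
    return starts


def _neg_loglik_factory(model_kind: str, times: np.ndarray, log_c: np.ndarray):
    def nll(theta: np.ndarray) -> float:
        try:
            mu = math.exp(theta[0])
            K = 1.0 + math.exp(theta[1]) if model_kind == "lag" else math.exp(theta[1])
            t0 = theta[2]
            if model_kind == "lag":
                pred = lag_log_curve(times, mu, K, t0)
            else:
                pred = np.log(logistic_curve(times, mu, K, t0))
        except (OverflowError, ValueError):
            return 1e12
        if not np.all(np.isfinite(pred)):
            return 1e12
        ll, _ = _profile_loglik(log_c, pred)
        return -ll

    return nll


def _fit_one_model(series: CellCountSeries, model_kind: str) -> GrowthFit:
    times = series.times
    log_c = np.log(series.concentrations)
    nll = _neg_loglik_factory(model_kind, times, log_c)
    best = None
    for s in _starts(times, log_c):
        K_start = max(s["K"], 1.0 + 1e-6)
        theta0 = np.array(
            [
                math.log(s["mu"]),
                math.log(K_start - 1.0) if model_kind == "lag" else math.log(K_start),
                s["t0"],
            ]
        )
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        mu_hat = math.exp(res.x[0])
        # best loglik wins; ties (within 1e-9) broken by smaller mu
        key = (round(-res.fun, 9), -mu_hat)
        if best is None or key > best[0]:
            best = (key, res)
    res = best[1]
    mu = math.exp(res.x[0])
    K = 1.0 + math.exp(res.x[1]) if model_kind == "lag" else math.exp(res.x[1])
    t0 = float(res.x[2])
    pred = (
        lag_log_curve(times, mu, K, t0)
        if model_kind == "lag"
        else np.log(logistic_curve(times, mu, K, t0))
    )
    ll, sigma = _profile_loglik(log_c, pred)
    converged = bool(res.success) and np.isfinite(ll)
    # series with no net increase: report mu = 0, flag unconverged
    if log_c[-1] <= log_c[0] + 1e-12:
        mu, converged = 0.0, False
    return GrowthFit(
        strain_id=series.strain_id,
        treatment=series.treatment,
        replicate=series.replicate,
        model_kind=model_kind,
        mu=mu,
        K=K,
        lag_lambda=t0 if model_kind == "lag" else None,
        t_m=t0 if model_kind == "logistic" else None,
        loglik=ll,
        converged=converged,
        n_points_used=len(series),
        sigma=sigma,
    )


def fit_growth_model(series: CellCountSeries, model_kind: str = "auto") -> GrowthFit:
    """Fit a growth model by maximum likelihood (Gaussian noise on ln C).

    ``model_kind`` is ``"lag"``, ``"logistic"`` or ``"auto"``; auto fits both
    and keeps the higher maximized likelihood (equivalently lower AIC — the
    models have equal parameter counts).
    """
    if len(series) < 4:
        raise ValueError("need >= 4 points to attempt a fit")
    if model_kind in ("lag", "logistic"):
        return _fit_one_model(series, model_kind)
    if model_kind != "auto":
        raise ValueError(f"unknown model_kind {model_kind!r}")
    fits = [_fit_one_model(series, k) for k in ("lag", "logistic")]
    return max(fits, key=lambda f: f.loglik)


def summarize_growth_rates(
    fits: Iterable[GrowthFit],
    no_growth_flags: Mapping[tuple[str, str], bool] | None = None,
) -> pd.DataFrame:
    """Per strain x treatment growth-rate summary.

    Mean over replicate fits with SE = sample sd / sqrt(n); single-replicate
    cells report no SE.  Cells flagged no-growth report rate 0 with SE absent;
    a no-growth flag conflicting with a converged positive fit is an error.
    """
    no_growth_flags = dict(no_growth_flags or {})
    by_cell: dict[tuple[str, str], list[GrowthFit]] = {}
    for f in fits:
        by_cell.setdefault((f.strain_id, f.treatment), []).append(f)

    rows = []
    cells = set(by_cell) | set(no_growth_flags)
    for strain, treatment in sorted(cells):
        key = (strain, treatment)
        if no_growth_flags.get(key, False):
            conflicting = [f for f in by_cell.get(key, []) if f.converged and f.mu > 0]
            if conflicting:
                raise ValueError(
                    f"{strain}/{treatment}: flagged no-growth but has a converged positive fit"
                )
            rows.append({"strain_id": strain, "treatment": treatment,
                         "mean_rate": 0.0, "se": float("nan"), "n": 0})
            continue
        cell_fits = by_cell[key]
        mus = np.array([f.mu for f in cell_fits])
        n = len(mus)
        se = float(np.std(mus, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"strain_id": strain, "treatment": treatment,
                     "mean_rate": float(np.mean(mus)), "se": se, "n": n})
    return pd.DataFrame(rows, columns=["strain_id", "treatment", "mean_rate", "se", "n"])


def read_counts_csv(path) -> list[CellCountSeries]:
    """Read a long-format counts CSV (strain, treatment, replicate, day, cells_per_ml)."""
    frame = pd.read_csv(path)
    required = {"strain", "treatment", "replicate", "day", "cells_per_ml"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    series = []
    for (strain, treatment, rep), grp in frame.groupby(["strain", "treatment", "replicate"]):
        grp = grp.sort_values("day")
        series.append(
            CellCountSeries(
                strain_id=str(strain),
                treatment=str(treatment),
                replicate=str(rep),
                times=grp["day"].to_numpy(dtype=float),
                concentrations=grp["cells_per_ml"].to_numpy(dtype=float),
            )
        )
    return series


def fits_to_frame(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_id": f.strain_id,
                "treatment": f.treatment,
                "replicate": f.replicate,
                "model_kind": f.model_kind,
                "mu": f.mu,
                "K": f.K,
                "lag_lambda": f.lag_lambda,
                "t_m": f.t_m,
                "loglik": f.loglik,
                "sigma": f.sigma,
                "converged": f.converged,
                "n_points_used": f.n_points_used,
            }
            for f in fits
        ]
    )
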