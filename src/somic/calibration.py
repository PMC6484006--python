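"""Parameter calibration against observed SOC time series, plus the
goodness-of-fit and bootstrap statistics used to summarize model skill.

The loss is the unweighted sum of squared errors between modeled total SOC
and the observations, pooled over sites (optionally weighted per site).
Each candidate parameter set is evaluated end-to-end: spin-up under the
site's first-year climate, proportional rescaling of all pools to the first
observation, then a forward run over the full driver record.  The optimizer
is a seeded bounded global search (differential evolution) followed by a
local polish, which suits the multimodal low-dimensional landscapes these
models present.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import ModelParams, run, step
from .errors import InvalidInputError
from .forcing_io import SiteRecord
from .synthetic import spin_up

__all__ = [
    "CalibrationSpec",
    "FitStats",
    "objective",
    "calibrate",
    "fit_stats",
    "bootstrap_rmse_sd",
    "split_sites",
    "predict_site",
]

logger = logging.getLogger("somic")

PENALTY = 1e12


@dataclass(frozen=True)
class CalibrationSpec:
    """Free parameters with bounds, the fixed base set, and optimizer settings.

    ``free`` maps parameter names (fields of ModelParams or its modifiers,
    e.g. ``k4``, ``cue_ref``, ``k_m``) to (lower, upper) bounds.  Site id
    lists declare the calibration/validation split; they must be disjoint.
    """

    free: dict[str, tuple[float, float]]
    fixed: ModelParams
    calibration_sites: tuple[str, ...] = ()
    validation_sites: tuple[str, ...] = ()
    seed: int = 0
    maxiter: int = 25
    popsize: int = 8
    tol: float = 0.005
    site_weights: dict[str, float] | None = None

    def __post_init__(self):
        overlap = set(self.calibration_sites) & set(self.validation_sites)
        if overlap:
            raise InvalidInputError(f"calibration/validation sites overlap: {sorted(overlap)}")
        for name, (lo, hi) in self.free.items():
            if not lo < hi:
                raise InvalidInputError(f"empty bounds for '{name}': ({lo}, {hi})")
            # raises if the name exists nowhere
            self.fixed.with_(**{name: 0.5 * (lo + hi)})


@dataclass(frozen=True)
class FitStats:
    """r², rmse (units of the observations), sample size and correlation p-value.

    ``degenerate`` flags a constant predicted or observed series, for which
    the correlation is undefined and r² is reported as 0.
    """

    r2: float
    rmse: float
    n: int
    p_value: float
    degenerate: bool = False


def split_sites(site_ids: Sequence[str], seed: int, n_cal: int | None = None
                ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Seeded uniform random split into calibration and validation sets
    (half/half by default, mirroring an 11/11 design for 22 sites)."""
    ids = list(site_ids)
    if n_cal is None:
        n_cal = len(ids) // 2
    if not 0 < n_cal < len(ids):
        raise InvalidInputError(f"n_cal={n_cal} must split {len(ids)} sites non-trivially")
    perm = np.random.default_rng(seed).permutation(len(ids))
    cal = tuple(ids[i] for i in sorted(perm[:n_cal]))
    val = tuple(ids[i] for i in sorted(perm[n_cal:]))
    return cal, val


def predict_site(site: SiteRecord, p: ModelParams) -> np.ndarray:
    """Modeled total SOC at the site's observation times.

    Initialization: spin-up under the first year of drivers scaled by the
    site's pre-experiment input regime, then all pools rescaled
    proportionally so the modeled stock at the first observation time
    matches that observation (pool fractionation at the start of these
    records is unknown).
    """
    state = spin_up(site.drivers, p, litter_factor=site.pre_litter_factor)
    obs = site.observations
    if site.rescale_to_first_obs and len(obs) and state.total() > 0:
        t_first = int(obs["time"].iloc[0])
        probe = state
        for f in site.drivers:
            probe, _ = step(probe, f, p)
            if f.time >= t_first:
                break
        if probe.total() > 0:
            state = state.scaled(float(obs["soc"].iloc[0]) / probe.total())
    traj = run(state, site.drivers, p)
    soc = traj.total_soc()
    idx = {t: j for j, t in enumerate(traj.times)}
    return np.array([soc[idx[int(t)]] for t in obs["time"]])


def objective(p: ModelParams, sites: Sequence[SiteRecord],
              weights: dict[str, float] | None = None) -> float:
    """Sum of squared errors between modeled and observed total SOC.

    Model failures (numerical blow-up, absurd parameters) return a large
    finite penalty with a warning rather than raising, so global search can
    continue past bad corners of parameter space.
    """
    if not any(len(s.observations) for s in sites):
        raise InvalidInputError("need at least one site with observations")
    sse = 0.0
    for site in sites:
        if not len(site.observations):
            continue
        w = 1.0 if weights is None else weights.get(site.site_id, 1.0)
        try:
            pred = predict_site(site, p)
        except Exception as e:  # noqa: BLE001 - penalized per contract
            warnings.warn(f"model failure at site {site.site_id}: {e}", stacklevel=2)
            return PENALTY
        resid = pred - site.observations["soc"].to_numpy()
        sse += w * float(resid @ resid)
    return sse if math.isfinite(sse) else PENALTY


def _theta_to_params(theta: np.ndarray, names: Sequence[str], base: ModelParams) -> ModelParams:
    return base.with_(**dict(zip(names, (float(v) for v in theta))))


def calibrate(spec: CalibrationSpec, sites: Sequence[SiteRecord]
              ) -> tuple[ModelParams, dict]:
    """Fit the free parameters to the calibration sites.

    Returns the fitted parameter set and a diagnostics dict (initial/final
    loss, evaluation count, optimizer message).  Deterministic given
    ``spec.seed``; with no free parameters the fixed set is returned
    unchanged.  If the search fails to improve on the fixed set, the best
    point found so far is returned with a warning.
    """
    cal_sites = [s for s in sites if not spec.calibration_sites
                 or s.site_id in spec.calibration_sites]
    if not cal_sites:
        raise InvalidInputError("no calibration sites selected")
    names = list(spec.free)
    loss0 = objective(spec.fixed, cal_sites, spec.site_weights)
    if not names:
        return spec.fixed, {"initial_loss": loss0, "final_loss": loss0, "nfev": 0,
                            "message": "no free parameters"}

    bounds = [spec.free[n] for n in names]

    def f(theta: np.ndarray) -> float:
        return objective(_theta_to_params(theta, names, spec.fixed), cal_sites,
                         spec.site_weights)

    result = optimize.differential_evolution(
        f, bounds, seed=spec.seed, maxiter=spec.maxiter, popsize=spec.popsize,
        tol=spec.tol, polish=True, init="sobol",
    )
    if result.fun <= loss0:
        fitted = _theta_to_params(result.x, names, spec.fixed)
        final = float(result.fun)
    else:
        warnings.warn("optimizer budget exhausted without improvement; "
                      "returning best point found", stacklevel=2)
        fitted, final = spec.fixed, loss0
    diagnostics = {
        "initial_loss": loss0,
        "final_loss": final,
        "nfev": int(result.nfev),
        "message": str(result.message),
        "free": dict(zip(names, [getattr(fitted, n) if hasattr(fitted, n)
                                 else getattr(fitted.modifiers, n) for n in names])),
    }
    return fitted, diagnostics


def fit_stats(observed: Sequence[float], predicted: Sequence[float]) -> FitStats:
    """Squared Pearson correlation, RMSE and correlation p-value."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidInputError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 3:
        raise InvalidInputError("need at least 3 points for fit statistics")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return FitStats(r2=0.0, rmse=rmse, n=obs.size, p_value=float("nan"), degenerate=True)
    r, p = stats.pearsonr(obs, pred)
    return FitStats(r2=float(r**2), rmse=rmse, n=obs.size, p_value=float(p))


def bootstrap_rmse_sd(
    observed: Sequence[float],
    predicted: Sequence[float],
    n_iter: int = 10_000,
    sample_size: int = 50,
    seed: int = 0,
) -> float:
    """Monte-Carlo bootstrap s.d. of the RMSE.

    Each iteration resamples ``sample_size`` (observed, predicted) pairs
    with replacement and computes their RMSE; returns the sample standard
    deviation over iterations.  Seed-reproducible.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise InvalidInputError("observed/predicted must be equal-length, non-empty")
    if n_iter < 2 or sample_size < 1:
        raise InvalidInputError(f"invalid n_iter={n_iter} or sample_size={sample_size}")
    sq = (obs - pred) ** 2
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sq.size, size=(n_iter, sample_size))
    rmses = np.sqrt(sq[idx].mean(axis=1))
    return float(np.std(rmses, ddof=1))
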