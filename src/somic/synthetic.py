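"""Synthetic forcing, sites, and atmospheric ¹⁴C curves.

Emulates the structure of century-scale agricultural experiment records —
monthly drivers with seasonal temperature and moisture cycles, litter
concentrated in autumn, episodic manure amendments, and sparse noisy
observations of total SOC — so the whole pipeline (I/O, simulation,
calibration, radiocarbon) is testable without any external data.  Every
generator is a pure function of its spec and seed.

What these series deliberately do NOT emulate: real weather autocorrelation
beyond the seasonal cycle, management changes mid-record, measurement-method
drift, or spatial covariance between sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ForcingRecord, ModelParams, PoolState, equilibrate, run
from .errors import ConvergenceError, InvalidInputError
from .forcing_io import SiteRecord
from .radiocarbon import AtmosphereCurve

__all__ = ["ClimateSpec", "make_forcing", "make_site", "make_atm_curve",
           "make_profile", "make_profile_forcing", "spin_up"]

MONTHS = 12


@dataclass(frozen=True)
class ClimateSpec:
    """Site climate and input regime for the driver generator.

    Defaults describe a cool temperate cropland running 150 years: mean
    annual temperature 9 °C with ±7 °C seasonal swing, moist winters,
    3 t C ha⁻¹ y⁻¹ litter concentrated in autumn, no manure unless asked.
    """

    mat: float = 9.0               # mean annual soil temperature, degC
    t_amp: float = 7.0             # seasonal half-amplitude, degC
    t_noise_sd: float = 1.0        # monthly temperature noise, degC
    w_mean: float = 0.75           # mean moisture scalar
    w_amp: float = 0.15            # seasonal half-amplitude of moisture
    w_noise_sd: float = 0.05
    litter: float = 3.0            # t C ha-1 y-1
    litter_cv: float = 0.1         # interannual litter variability (CV)
    manure: float = 0.0            # t C ha-1 y-1, applied each spring
    manure_fs: float = 0.3         # soluble fraction of manure
    clay: float = 0.25
    years: int = 150
    seed: int = 0
    # Ratio of pre-experiment to experimental C inputs.  Long-term
    # agricultural records typically begin at a land-use change (e.g. plow-out
    # of grassland), so SOC is in transition, not at equilibrium, over the
    # record; 2.0 yields the classic multi-decadal decline.
    pre_litter_factor: float = 2.0

    def __post_init__(self):
        if self.years < 1:
            raise InvalidInputError(f"years must be >= 1, got {self.years}")
        for name in ("litter", "manure", "t_noise_sd", "w_noise_sd", "litter_cv"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if not 0.0 <= self.clay <= 1.0:
            raise InvalidInputError(f"clay must lie in [0, 1], got {self.clay}")


# Fraction of the annual litter input arriving in each calendar month
# (Jan..Dec): concentrated in autumn leaf-fall/harvest-residue months.
_LITTER_WEIGHTS = np.array([2, 2, 3, 3, 4, 4, 5, 6, 15, 22, 22, 12], dtype=float)
_LITTER_WEIGHTS /= _LITTER_WEIGHTS.sum()


def make_forcing(spec: ClimateSpec) -> list[ForcingRecord]:
    """Monthly driver series: sinusoidal temperature (warmest in July),
    bounded moisture (wettest in winter), seasonal litter with interannual
    variability, and optional spring manure.  Reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.years * MONTHS
    m = np.arange(n)
    month_of_year = m % MONTHS
    temp = (spec.mat
            + spec.t_amp * np.cos(2.0 * np.pi * (month_of_year - 6) / MONTHS)
            + rng.normal(0.0, spec.t_noise_sd, n))
    moist = (spec.w_mean
             - spec.w_amp * np.cos(2.0 * np.pi * (month_of_year - 6) / MONTHS)
             + rng.normal(0.0, spec.w_noise_sd, n))
    moist = np.clip(moist, 0.0, 1.0)
    annual_factor = np.clip(rng.normal(1.0, spec.litter_cv, spec.years), 0.0, None)
    litter = spec.litter * _LITTER_WEIGHTS[month_of_year] * annual_factor[m // MONTHS]
    amendment = np.where(month_of_year == 3, spec.manure, 0.0)  # April application
    return [
        ForcingRecord(
            time=int(t), temp=float(temp[t]), moisture=float(moist[t]),
            litter=float(litter[t]), clay=spec.clay,
            amendment=float(amendment[t]),
            amendment_fs=spec.manure_fs if amendment[t] > 0 else None,
        )
        for t in m
    ]


def spin_up(drivers: Sequence[ForcingRecord], p: ModelParams,
            litter_factor: float = 1.0,
            tol: float = 1e-6, max_cycles: int = 400) -> PoolState:
    """Equilibrate under the first year of drivers (the pre-experiment climate).

    ``litter_factor`` scales the C inputs of the spin-up cycle relative to
    the experimental period, representing the input regime of the land use
    that preceded the record.  Non-convergence is tolerated: the last state
    is returned, since field-site initialization rescales pools to the first
    observation and synthetic truth runs only need a reproducible start.
    """
    from dataclasses import replace as _replace

    cycle = [
        _replace(f, litter=f.litter * litter_factor, amendment=f.amendment * litter_factor)
        for f in drivers[:MONTHS]
    ]
    try:
        return equilibrate(cycle, p, tol=tol, max_cycles=max_cycles)
    except ConvergenceError as e:
        return e.state


def make_site(
    true_params: ModelParams,
    spec: ClimateSpec,
    obs_noise_sd: float | None = None,
    obs_times: Sequence[int] | None = None,
    site_id: str = "synthetic",
) -> SiteRecord:
    """Drivers plus noisy SOC observations generated from a known-truth run.

    The truth run starts from spin-up under the pre-experiment input regime
    (``spec.pre_litter_factor`` times the experimental inputs), so the
    record captures the transient that follows the land-use change.
    ``obs_noise_sd`` defaults to 2% of the mean simulated stock;
    ``obs_times`` defaults to a baseline sample at month 0 plus one
    observation per year.  Observation noise is drawn from a seed derived
    from ``spec.seed`` so drivers and noise can be varied independently.
    """
    drivers = make_forcing(spec)
    span = (drivers[0].time, drivers[-1].time)
    if obs_times is None:
        obs_times = list(range(span[0], span[1] + 1, MONTHS))
    for t in obs_times:
        if t < span[0] or t > span[1]:
            raise InvalidInputError(f"observation time {t} outside driver span {span}")
    init = spin_up(drivers, true_params, litter_factor=spec.pre_litter_factor)
    traj = run(init, drivers, true_params)
    soc = traj.total_soc()
    idx = {t: j for j, t in enumerate(traj.times)}
    truth = np.array([soc[idx[t]] for t in obs_times])
    if obs_noise_sd is None:
        obs_noise_sd = 0.02 * float(np.mean(soc))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 714025]))
    noisy = truth + rng.normal(0.0, obs_noise_sd, len(truth)) if obs_noise_sd > 0 else truth
    import pandas as pd

    obs = pd.DataFrame({"time": list(obs_times), "soc": noisy})
    return SiteRecord(site_id=site_id, clay=spec.clay, depth_m=0.23,
                      drivers=drivers, observations=obs,
                      pre_litter_factor=spec.pre_litter_factor,
                      rescale_to_first_obs=False)


def make_atm_curve(years: int, bomb: bool = False, seed: int = 0,
                   start_month: int = 0) -> AtmosphereCurve:
    """Synthetic atmospheric ¹⁴C curve (fraction modern vs month).

    Pre-bomb: slightly depleted (Δ¹⁴C ≈ −20 ‰, the Suess-era baseline)
    with a slow linear decline.  With ``bomb=True`` the final 60 years add
    a thermonuclear-era transient: a rapid rise peaking near +700 ‰
    followed by exponential relaxation (e-folding ≈ 16 y) — a synthetic
    stand-in shaped like the Northern-Hemisphere record, not a transcription
    of any compilation.
    """
    if years < 1:
        raise InvalidInputError(f"years must be >= 1, got {years}")
    n = years * MONTHS
    t = np.arange(start_month, start_month + n)
    rel = np.arange(n) / MONTHS  # years since curve start
    delta = -15.0 - 10.0 * rel / max(years, 1)  # slow pre-bomb decline, permil
    if bomb and years > 5:
        peak_year = max(years - 57.0, 1.0)  # 1963-style spike near the end
        rise = 5.0
        d_bomb = np.where(
            rel < peak_year,
            700.0 * np.exp(-((rel - peak_year) ** 2) / (2 * rise**2)),
            700.0 * np.exp(-(rel - peak_year) / 16.0),
        )
        delta = delta + d_bomb
    f = 1.0 + delta / 1000.0
    return AtmosphereCurve(times=t.astype(float), f_modern=f)


def make_profile_forcing(spec: ClimateSpec) -> list[ForcingRecord]:
    """Surface forcing for profile runs: same generator, exposed for symmetry."""
    return make_forcing(spec)


def make_profile(
    p: ModelParams,
    n_layers: int = 4,
    thickness: float = 0.225,
    clay: float = 0.25,
    velocity: float = 0.001,
    temp: float = 10.0,
    moisture: float = 0.8,
    litter: float = 0.25,
):
    """Layered soil column initialized layer-by-layer at analytic steady state.

    The surface layer receives the litter input; each deeper layer's only C
    input is the DOC advected from the layer above (velocity in m month⁻¹),
    and its pools are started at the steady state that input implies, so
    profile runs begin near the column's attractor instead of from bare
    soil.  All layers start with a modern isotope signature (F = 1).
    """
    from dataclasses import replace as _replace

    from .core import _mean_forcing_steady
    from .radiocarbon import IsotopeState, SoilLayer, SoilProfile

    f0 = ForcingRecord(time=0, temp=temp, moisture=moisture, litter=litter, clay=clay)
    layers = []
    lit = litter
    for _ in range(n_layers):
        st = _mean_forcing_steady([_replace(f0, litter=lit)], p)
        layers.append(SoilLayer(thickness, clay, st, IsotopeState.uniform(1.0)))
        lit = (velocity / thickness) * st.doc
    return SoilProfile(layers, [velocity] * n_layers)
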