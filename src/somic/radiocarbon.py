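"""Per-pool radiocarbon (fraction modern) accounting and layered-profile transport.

Each pool carries a fraction-modern value F (¹⁴C/¹²C normalized to the
modern standard, so Δ¹⁴C = (F − 1)·1000 ‰).  Isotope bookkeeping mirrors the
carbon fluxes of a completed Euler (sub-)step: inflows carry the source
pool's F, litter carries the atmospheric signature, and all ¹⁴C mass then
decays with the true mean life 8267 y.  The Libby mean life 8033 y is used
only inside the conventional-age formula, per standard radiocarbon practice.

With the decay constant set to zero the same machinery is a conserved
two-source tracer: initialize F = 1 on pre-existing carbon and feed litter
with F = 0 to measure how much *old* carbon is mineralized — the tool used
for priming experiments.

A layered :class:`SoilProfile` adds downward advection of DOC (first-order
upwind, free outflow at the bottom), producing radiocarbon age-vs-depth
profiles from a model whose pools all cycle on annual-to-decadal timescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ForcingRecord,
    ModelParams,
    PoolState,
    StepFluxes,
    Trajectory,
    _env_coeffs,
    _euler_substep,
    _n_substeps,
    effective_rates,
)
from .errors import InvalidInputError, NumericalError

__all__ = [
    "TRUE_MEAN_LIFE_Y",
    "LIBBY_MEAN_LIFE_Y",
    "IsotopeState",
    "IsotopeFluxes",
    "SoilLayer",
    "SoilProfile",
    "AtmosphereCurve",
    "delta14c_to_fraction_modern",
    "fraction_modern_to_delta14c",
    "fraction_modern_to_age",
    "isotope_step",
    "run_with_isotopes",
    "advect_doc",
    "run_profile",
]

TRUE_MEAN_LIFE_Y = 8267.0
LIBBY_MEAN_LIFE_Y = 8033.0

#: Physical decay rate per month (used in simulation steps).
LAMBDA_PER_MONTH = 1.0 / (TRUE_MEAN_LIFE_Y * 12.0)

_POOLS = ("spm", "ipm", "doc", "mac", "mb")
_EMPTY = 1e-15  # below this carbon mass, F is undefined


def delta14c_to_fraction_modern(delta: float) -> float:
    """Δ¹⁴C (‰) → fraction modern, F = 1 + Δ/1000."""
    if not math.isfinite(delta) or delta < -1000.0:
        raise InvalidInputError(f"delta14C must be >= -1000 permil, got {delta}")
    return 1.0 + delta / 1000.0


def fraction_modern_to_delta14c(f: float) -> float:
    """Fraction modern → Δ¹⁴C (‰)."""
    return (f - 1.0) * 1000.0


def fraction_modern_to_age(f: float) -> float:
    """Conventional radiocarbon age (years), −8033·ln F."""
    if not (f > 0) or not math.isfinite(f):
        raise InvalidInputError(f"fraction modern must be > 0, got {f}")
    return -LIBBY_MEAN_LIFE_Y * math.log(f)


@dataclass(frozen=True)
class IsotopeState:
    """Fraction modern per pool; NaN marks the undefined F of an empty pool."""

    spm: float = 1.0
    ipm: float = 1.0
    doc: float = 1.0
    mac: float = 1.0
    mb: float = 1.0

    def __post_init__(self):
        for name in _POOLS:
            v = getattr(self, name)
            if not math.isnan(v) and (not math.isfinite(v) or v < 0):
                raise InvalidInputError(f"fraction modern of {name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.spm, self.ipm, self.doc, self.mac, self.mb])

    @classmethod
    def uniform(cls, f: float) -> "IsotopeState":
        return cls(f, f, f, f, f)

    def masses(self, state: PoolState) -> np.ndarray:
        """¹⁴C mass per pool (empty pools hold zero regardless of F)."""
        c = state.as_array()
        f = np.where(np.isnan(self.as_array()), 0.0, self.as_array())
        return f * c


@dataclass
class IsotopeFluxes:
    """¹⁴C leaving the system during a step: respired, decayed (and, in
    profile runs, exported through the bottom boundary)."""

    co2: float = 0.0
    decay: float = 0.0
    export: float = 0.0

    def add(self, other: "IsotopeFluxes") -> None:
        self.co2 += other.co2
        self.decay += other.decay
        self.export += other.export


def _safe_f(f: float) -> float:
    return 0.0 if math.isnan(f) else f


def isotope_step(
    state: PoolState,
    iso: IsotopeState,
    fluxes: StepFluxes,
    litter_f: float,
    dt: float,
    lam: float = LAMBDA_PER_MONTH,
) -> tuple[IsotopeState, IsotopeFluxes]:
    """Update per-pool fraction modern to mirror one completed Euler step.

    ``state`` is the state *before* the step and ``fluxes`` the carbon moved
    during it; ``litter_f`` is the fraction modern of litter/amendment
    inputs and ``dt`` the step length in months.  Outflows carry the source
    pool's F, then every ¹⁴C mass decays by ``exp(-lam*dt)``.
    """
    if dt < 0:
        raise InvalidInputError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return iso, IsotopeFluxes()
    f1, f2, f3, f4, f5 = (_safe_f(getattr(iso, n)) for n in _POOLS)
    m = iso.masses(state)
    rem3 = fluxes.doc_removal()
    m_new = np.array([
        m[0] + fluxes.litter_spm * litter_f - fluxes.doc_in_spm * f1,
        m[1] + fluxes.litter_ipm * litter_f - fluxes.doc_in_ipm * f2,
        m[2]
        + fluxes.doc_in_spm * f1 + fluxes.doc_in_ipm * f2
        + fluxes.doc_in_mac * f4 + fluxes.doc_in_mb * f5
        - rem3 * f3,
        m[3] + fluxes.sorption * f3 - fluxes.doc_in_mac * f4,
        m[4] + fluxes.uptake * f3 - fluxes.doc_in_mb * f5,
    ])
    if np.any(m_new < -1e-9 * max(1.0, m.sum())):
        worst = _POOLS[int(np.argmin(m_new))]
        raise NumericalError(f"negative 14C mass in pool {worst}")
    m_new = np.clip(m_new, 0.0, None)
    co2_14 = fluxes.co2 * f3
    factor = math.exp(-lam * dt)
    decay_loss = m_new.sum() * (1.0 - factor)
    m_new *= factor

    # carbon after the step, reconstructed from the flux bookkeeping
    c_new = np.array([
        state.spm + fluxes.litter_spm - fluxes.doc_in_spm,
        state.ipm + fluxes.litter_ipm - fluxes.doc_in_ipm,
        state.doc + fluxes.doc_in_spm + fluxes.doc_in_ipm
        + fluxes.doc_in_mac + fluxes.doc_in_mb - rem3,
        state.mac + fluxes.sorption - fluxes.doc_in_mac,
        state.mb + fluxes.uptake - fluxes.doc_in_mb,
    ])
    f_new = [m_new[i] / c_new[i] if c_new[i] > _EMPTY else math.nan for i in range(5)]
    return IsotopeState(*f_new), IsotopeFluxes(co2=co2_14, decay=decay_loss)


def run_with_isotopes(
    init: PoolState,
    iso0: IsotopeState,
    forcing: Sequence[ForcingRecord],
    p: ModelParams,
    litter_f,
    lam: float = LAMBDA_PER_MONTH,
) -> tuple[Trajectory, list[IsotopeState], np.ndarray]:
    """Run the carbon model with inline isotope accounting.

    ``litter_f`` is a scalar or a per-record sequence of input fractions
    modern.  Isotope mixing is applied at every integration sub-step so that
    the isotope mass balance holds exactly.  Returns the trajectory, the
    end-of-step isotope states, and the cumulative ¹⁴C respired as CO₂
    (the tracer readout of a priming experiment when ``lam = 0``).
    """
    if np.isscalar(litter_f):
        lf = [float(litter_f)] * len(forcing)
    else:
        lf = [float(x) for x in litter_f]
        if len(lf) != len(forcing):
            raise InvalidInputError("litter_f length must match forcing length")
    traj = Trajectory()
    isos: list[IsotopeState] = []
    cum_co2_14 = np.zeros(len(forcing))
    state, iso = init, iso0
    total_14co2 = 0.0
    for j, f in enumerate(forcing):
        k_eff = effective_rates(state, f, p)
        env, fsorb, cue, fs_a = _env_coeffs(f, p)
        n = _n_substeps(env, p, 1.0)
        sub = 1.0 / n
        month = StepFluxes()
        for _ in range(n):
            new_state, fl = _euler_substep(state, f, p, sub, env, fsorb, cue, fs_a)
            iso, ifl = isotope_step(state, iso, fl, lf[j], sub, lam)
            total_14co2 += ifl.co2
            state = new_state
            month.add(fl)
        traj.append(f.time, state, month, k_eff)
        isos.append(iso)
        cum_co2_14[j] = total_14co2
    return traj, isos, cum_co2_14


# ---------------------------------------------------------------------------
# Layered profile


@dataclass
class SoilLayer:
    thickness: float  # m
    clay: float
    state: PoolState
    iso: IsotopeState

    def __post_init__(self):
        if not self.thickness > 0:
            raise InvalidInputError(f"layer thickness must be > 0, got {self.thickness}")


@dataclass
class SoilProfile:
    """Ordered soil layers (top first) with a downward DOC advection velocity
    (m month⁻¹) at each layer's lower interface; the last velocity is the
    free-outflow export through the bottom boundary."""

    layers: list[SoilLayer]
    velocities: list[float]

    def __post_init__(self):
        if len(self.velocities) != len(self.layers):
            raise InvalidInputError("need one interface velocity per layer")
        for v in self.velocities:
            if not math.isfinite(v):
                raise InvalidInputError("advection velocities must be finite")
            if v < 0:
                raise InvalidInputError("upward (negative) DOC advection is not supported")

    def depths(self) -> np.ndarray:
        """Midpoint depth of each layer (m)."""
        tops = np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])[:-1]])
        return tops + 0.5 * np.array([l.thickness for l in self.layers])


@dataclass(frozen=True)
class AtmosphereCurve:
    """Atmospheric ¹⁴C signature: fraction modern vs time (months)."""

    times: np.ndarray
    f_modern: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f_modern, dtype=float)
        if t.ndim != 1 or t.shape != f.shape or len(t) < 1:
            raise InvalidInputError("atmosphere curve needs matching 1-d time/F arrays")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise InvalidInputError("atmosphere curve times must be strictly increasing")
        if np.any(~np.isfinite(f)) or np.any(f < 0):
            raise InvalidInputError("atmosphere F values must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "f_modern", f)

    def f_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.f_modern))

    def delta14c(self) -> np.ndarray:
        return (self.f_modern - 1.0) * 1000.0


def advect_doc(profile: SoilProfile, dt: float = 1.0) -> tuple[SoilProfile, float, float]:
    """Move DOC (and its ¹⁴C) downward between adjacent layers.

    First-order upwind: layer i exports ``(v_i / h_i) · DOC_i · dt`` to the
    layer below (or out of the column for the deepest layer).  Sub-steps
    internally to satisfy the CFL condition ``v·dt ≤ h``.  Returns the new
    profile and the carbon / ¹⁴C exported through the bottom boundary.
    """
    if dt <= 0:
        raise InvalidInputError(f"dt must be > 0, got {dt}")
    n = len(profile.layers)
    h = np.array([l.thickness for l in profile.layers])
    v = np.array(profile.velocities, dtype=float)
    courant = np.max(v * dt / h) if n else 0.0
    nsub = max(1, math.ceil(courant / 0.9))
    sub = dt / nsub

    c = np.array([l.state.doc for l in profile.layers])
    m = np.array([_safe_f(l.iso.doc) * l.state.doc for l in profile.layers])
    export_c = export_m = 0.0
    for _ in range(nsub):
        out_c = (v / h) * c * sub
        out_m = np.divide(out_c * m, c, out=np.zeros_like(c), where=c > _EMPTY)
        c = c - out_c
        m = m - out_m
        c[1:] += out_c[:-1]
        m[1:] += out_m[:-1]
        export_c += out_c[-1]
        export_m += out_m[-1]

    layers = []
    for i, l in enumerate(profile.layers):
        new_state = replace(l.state, doc=float(max(c[i], 0.0)))
        f_doc = m[i] / c[i] if c[i] > _EMPTY else math.nan
        layers.append(SoilLayer(l.thickness, l.clay, new_state, replace(l.iso, doc=f_doc)))
    return SoilProfile(layers, list(profile.velocities)), float(export_c), float(export_m)


def _bulk(layer: SoilLayer) -> tuple[float, float]:
    """Bulk (F, total C) of a layer; F is NaN for an empty layer."""
    c = layer.state.as_array()
    m = layer.iso.masses(layer.state)
    tot = c.sum()
    return (m.sum() / tot if tot > _EMPTY else math.nan), float(tot)


def run_profile(
    profile: SoilProfile,
    forcing: Sequence[ForcingRecord] | Sequence[Sequence[ForcingRecord]],
    atm: AtmosphereCurve,
    p: ModelParams,
    lam: float = LAMBDA_PER_MONTH,
) -> tuple[pd.DataFrame, SoilProfile]:
    """Depth-resolved run: per-layer biogeochemistry, isotope mixing, then
    downward DOC advection each month.

    ``forcing`` is either a surface forcing sequence (litter applied to the
    top layer only; temperature/moisture shared down the column, clay taken
    from each layer) or one sequence per layer.  Litter carries the
    atmospheric fraction modern at that month.  Returns a tidy frame with
    one row per (time, layer): pools total, bulk fraction modern, Δ¹⁴C and
    conventional age, plus the final profile.
    """
    if len(profile.layers) < 1:
        raise InvalidInputError("profile needs at least one layer")
    nlay = len(profile.layers)
    if len(forcing) and isinstance(forcing[0], ForcingRecord):
        per_layer = []
        for i, layer in enumerate(profile.layers):
            per_layer.append([
                replace(f, litter=f.litter if i == 0 else 0.0,
                        amendment=f.amendment if i == 0 else 0.0,
                        clay=layer.clay)
                for f in forcing
            ])
    else:
        per_layer = [list(seq) for seq in forcing]
        if len(per_layer) != nlay:
            raise InvalidInputError("need one forcing sequence per layer")
    nt = len(per_layer[0])

    depths = profile.depths()
    rows = []
    prof = profile
    for j in range(nt):
        layers = []
        for i, layer in enumerate(prof.layers):
            f = per_layer[i][j]
            lf = atm.f_at(f.time)
            env, fsorb, cue, fs_a = _env_coeffs(f, p)
            n = _n_substeps(env, p, 1.0)
            sub = 1.0 / n
            state, iso = layer.state, layer.iso
            for _ in range(n):
                new_state, fl = _euler_substep(state, f, p, sub, env, fsorb, cue, fs_a)
                iso, _ = isotope_step(state, iso, fl, lf, sub, lam)
                state = new_state
            layers.append(SoilLayer(layer.thickness, layer.clay, state, iso))
        prof = SoilProfile(layers, list(prof.velocities))
        prof, _, _ = advect_doc(prof, 1.0)
        t = per_layer[0][j].time
        for i, layer in enumerate(prof.layers):
            fbulk, ctot = _bulk(layer)
            rows.append({
                "time": t,
                "layer": i,
                "depth_m": depths[i],
                "total_soc": ctot,
                "f_modern": fbulk,
                "delta14c": fraction_modern_to_delta14c(fbulk) if not math.isnan(fbulk) else math.nan,
                "age_y": fraction_modern_to_age(fbulk) if fbulk and fbulk > 0 else math.nan,
            })
    return pd.DataFrame(rows), prof
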