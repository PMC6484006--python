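"""Dimensionless rate-modifying coefficients for the decomposition kinetics.

Every pool's base rate constant :math:`k_i` (month⁻¹) is scaled into an
effective rate factor :math:`k'_i` by a product of three coefficients:

* a temperature coefficient :math:`f_T(T)`, normalized to 1 at the reference
  temperature (15 °C by default);
* a moisture coefficient :math:`f_w(w) \\in [0, 1]`, equal to 1 at
  non-limiting moisture (``w = 1``, field capacity);
* a microbial coefficient :math:`f_{mb} = MB / (K_m + MB)` from reverse
  Michaelis–Menten kinetics — decomposition saturates in microbial biomass,
  not in substrate.  Microbial-biomass turnover itself is first order and
  does not carry :math:`f_{mb}`.

This module also provides the two partitioning coefficients applied to the
dissolved-organic-carbon (DOC) removal flux: the sorbed fraction
``f_sorb(clay)`` (mineral protection, linear in clay content) and the
microbial carbon-use efficiency ``CUE(T)`` (fraction of uptake allocated to
growth rather than respiration, linear in temperature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from .errors import InvalidInputError

__all__ = [
    "ModifierParams",
    "temperature_modifier",
    "moisture_modifier",
    "microbial_modifier",
    "sorbed_fraction",
    "carbon_use_efficiency",
    "mac_base_mrt",
]

logger = logging.getLogger("somic")

#: Temperature-modifier strategies available in :func:`temperature_modifier`.
TEMP_FORMS = ("q10", "rothc")

# RothC sigmoid coefficients (Coleman & Jenkinson); used un-normalized the
# function spans ~0-10, here it is rescaled to equal 1 at the reference T.
_ROTHC_A, _ROTHC_B, _ROTHC_C = 47.91, 106.06, 18.27


@dataclass(frozen=True)
class ModifierParams:
    """Coefficients of the rate-modifying functions.

    Attributes
    ----------
    temp_form:
        ``"q10"`` (exponential, default) or ``"rothc"`` (sigmoid); both are
        normalized to 1 at ``t_ref``.
    q10:
        Factor by which rates multiply per 10 °C warming (q10 form only).
    t_ref:
        Reference temperature (°C) where the temperature modifier equals 1
        and where ``cue_ref`` applies.
    w_min:
        Value of the moisture modifier at ``w = 0`` (dry soil floor).
    k_m:
        Reverse-MM half-saturation constant for microbial biomass
        (t C ha⁻¹, same units as the pools).
    s0, s1:
        Intercept and slope of the sorbed fraction vs. clay content.
    cue_ref, cue_slope:
        Carbon-use efficiency at ``t_ref`` and its linear temperature
        dependence (°C⁻¹).
    """

    temp_form: str = "q10"
    q10: float = 17.0 / 5.5
    t_ref: float = 15.0
    w_min: float = 0.2
    k_m: float = 0.45
    s0: float = 0.05
    s1: float = 1.5
    cue_ref: float = 0.28
    cue_slope: float = -0.0081

    def __post_init__(self) -> None:
        if self.temp_form not in TEMP_FORMS:
            raise InvalidInputError(
                f"temp_form must be one of {TEMP_FORMS}, got {self.temp_form!r}"
            )
        for name in ("q10", "t_ref", "w_min", "k_m", "s0", "s1", "cue_ref", "cue_slope"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v}")
        if self.k_m <= 0:
            raise InvalidInputError(f"k_m must be > 0, got {self.k_m}")
        if self.q10 <= 0:
            raise InvalidInputError(f"q10 must be > 0, got {self.q10}")
        if not 0.0 <= self.s0 <= 1.0:
            raise InvalidInputError(f"s0 must lie in [0, 1], got {self.s0}")
        if not 0.0 < self.cue_ref < 1.0:
            raise InvalidInputError(f"cue_ref must lie in (0, 1), got {self.cue_ref}")
        if not 0.0 <= self.w_min < 1.0:
            raise InvalidInputError(f"w_min must lie in [0, 1), got {self.w_min}")

    def with_(self, **kwargs) -> "ModifierParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _check_finite(name: str, x: float) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise InvalidInputError(f"{name} must be finite, got {x}")
    return x


def temperature_modifier(t: float, p: ModifierParams) -> float:
    """Dimensionless temperature coefficient, equal to 1 at ``p.t_ref``.

    ``q10`` form: ``q10 ** ((T - t_ref) / 10)``.
    ``rothc`` form: the RothC sigmoid ``a/(1 + exp(b/(T + c)))`` rescaled by
    its value at ``t_ref``; it tends to 0 for deeply frozen soil.
    Both are continuous and non-decreasing in T.
    """
    t = _check_finite("temperature", t)
    if p.temp_form == "q10":
        return p.q10 ** ((t - p.t_ref) / 10.0)
    return _rothc_raw(t) / _rothc_raw(p.t_ref)


def _rothc_raw(t: float) -> float:
    if t <= -_ROTHC_C:
        return 0.0
    return _ROTHC_A / (1.0 + math.exp(_ROTHC_B / (t + _ROTHC_C)))


def moisture_modifier(w: float, p: ModifierParams) -> float:
    """Dimensionless moisture coefficient in [w_min, 1].

    ``w`` is a moisture scalar in [0, 1] (fraction of the non-limiting
    water content); the modifier interpolates linearly between the dry floor
    ``w_min`` at ``w = 0`` and 1 at field capacity.
    """
    w = _check_finite("moisture scalar", w)
    if not 0.0 <= w <= 1.0:
        raise InvalidInputError(f"moisture scalar must lie in [0, 1], got {w}")
    return p.w_min + (1.0 - p.w_min) * w


def microbial_modifier(mb: float, k_m: float) -> float:
    """Reverse Michaelis–Menten coefficient ``mb / (k_m + mb)`` in [0, 1)."""
    mb = _check_finite("microbial biomass", mb)
    k_m = _check_finite("k_m", k_m)
    if mb < 0:
        raise InvalidInputError(f"microbial biomass must be >= 0, got {mb}")
    if k_m <= 0:
        raise InvalidInputError(f"k_m must be > 0, got {k_m}")
    return mb / (k_m + mb)


def sorbed_fraction(clay: float, p: ModifierParams) -> float:
    """Fraction of the DOC removal flux partitioned to mineral sorption.

    Linear in clay content, ``clamp(s0 + s1 * clay, 0, 1)``; the remainder
    ``1 - f_sorb`` is taken up by microbes.
    """
    clay = _check_finite("clay fraction", clay)
    if not 0.0 <= clay <= 1.0:
        raise InvalidInputError(f"clay fraction must lie in [0, 1], got {clay}")
    return min(1.0, max(0.0, p.s0 + p.s1 * clay))


def carbon_use_efficiency(t: float, p: ModifierParams) -> float:
    """Microbial carbon-use efficiency, linear in temperature, clamped to [0, 1]."""
    t = _check_finite("temperature", t)
    cue = p.cue_ref + p.cue_slope * (t - p.t_ref)
    if cue < 0.0 or cue > 1.0:
        logger.debug("CUE clamped at T=%.2f degC (raw value %.4f)", t, cue)
        return min(1.0, max(0.0, cue))
    return cue


def mac_base_mrt(t: float, p: ModifierParams, k4: float) -> float:
    """Base mean residence time (years) of mineral-associated C at temperature ``t``.

    "Base" means before microbial mediation: the reverse-MM factor is fixed
    at 1, moisture is non-limiting, so MRT = 1 / (k4 · f_T(t)) months,
    returned in years.
    """
    if not math.isfinite(k4) or k4 <= 0:
        raise InvalidInputError(f"k4 must be > 0, got {k4}")
    months = 1.0 / (k4 * temperature_modifier(t, p) * moisture_modifier(1.0, p))
    return months / 12.0
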