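"""Pedo-transfer functions for soil hydraulic properties.

Implements the Saxton & Rawls (2006) moisture-retention regressions that
predict volumetric water content at wilting point (-1500 kPa), field
capacity (-33 kPa) and saturation, plus saturated hydraulic conductivity,
from sand, clay and organic-matter content alone.

Unit conventions
----------------
The published regression coefficients take **sand and clay as decimal
fractions** (0-1) and **organic matter in mass %**.  This module follows
that convention strictly; a sanity assertion rejects sand or clay values
that look like percentages.  Water contents are volumetric fractions
(cm3 cm-3), conductivity is produced in mm h-1 with a cm h-1 convenience
conversion for crop-model output.

Validity domain
---------------
The regressions were fitted on agricultural soils; extreme corners of the
texture triangle can yield non-physical output (negative or inverted water
contents).  Outputs are therefore constrained to a documented validity
domain -- theta1500 >= 0.01, theta33 - theta1500 >= 0.01,
thetaS <= 0.60, thetaS > theta33 -- by clamping to the nearest bound.
Every clamp is recorded in the returned flag mask; nothing is silently
altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gridsol")

__all__ = [
    "TextureComposition",
    "OrganicContent",
    "HydraulicProperties",
    "InvalidSoilInputError",
    "FLAG_OK",
    "FLAG_WILTING_LOW",
    "FLAG_FC_BELOW_WP",
    "FLAG_SAT_HIGH",
    "FLAG_SAT_BELOW_FC",
    "organic_carbon_to_matter",
    "wilting_point",
    "field_capacity",
    "saturation",
    "saturated_conductivity",
    "derive_layer_hydraulics",
]

# texture closure tolerance, percentage points
TEXTURE_SUM_TOL = 0.5

# validity-domain bounds (volumetric fractions)
MIN_THETA1500 = 0.01
MIN_AWC_SPREAD = 0.01      # minimum theta33 - theta1500
MAX_THETAS = 0.60
MIN_SAT_SPREAD = 2e-3      # minimum thetaS - theta33 after clamping
                           # (>= 2x the 3-decimal print precision so clamped
                           # values stay ordered after rounding)

# out-of-domain flag bits
FLAG_OK = 0
FLAG_WILTING_LOW = 1       # theta1500 clamped up to MIN_THETA1500
FLAG_FC_BELOW_WP = 2       # theta33 clamped up to theta1500 + MIN_AWC_SPREAD
FLAG_SAT_HIGH = 4          # thetaS clamped down to MAX_THETAS
FLAG_SAT_BELOW_FC = 8      # thetaS clamped up to theta33 + MIN_SAT_SPREAD


class InvalidSoilInputError(ValueError):
    """Raised when soil inputs violate a precondition (negative OC,
    texture not summing to 100, missing layer values)."""


@dataclass(frozen=True)
class TextureComposition:
    """Sand / clay / silt mass percentages for one soil layer.

    sand: 0.05-2 mm particles; clay: < 0.002 mm; silt: 0.002-0.05 mm.
    Components must be in [0, 100] and sum to 100 within 0.5.
    """

    sand_pct: float
    clay_pct: float
    silt_pct: float

    def __post_init__(self) -> None:
        for name in ("sand_pct", "clay_pct", "silt_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise InvalidSoilInputError(f"{name}={v!r} outside [0, 100]")
        total = self.sand_pct + self.clay_pct + self.silt_pct
        if abs(total - 100.0) > TEXTURE_SUM_TOL:
            raise InvalidSoilInputError(
                f"texture components sum to {total:.3f}, not 100 +/- {TEXTURE_SUM_TOL}"
            )

    @property
    def sand_frac(self) -> float:
        return self.sand_pct / 100.0

    @property
    def clay_frac(self) -> float:
        return self.clay_pct / 100.0


@dataclass(frozen=True)
class OrganicContent:
    """Soil organic carbon and organic matter, both mass %."""

    organic_carbon_pct: float
    organic_matter_pct: float

    def __post_init__(self) -> None:
        if self.organic_carbon_pct < 0 or self.organic_matter_pct < 0:
            raise InvalidSoilInputError("organic content must be >= 0")


@dataclass
class HydraulicProperties:
    """Derived hydraulic properties for one layer (volumetric fractions).

    ``flags`` is a bitmask of validity-domain clamps applied; 0 means the
    raw regression output was physical as-is.
    """

    theta1500: float
    theta33: float
    thetaS: float
    thetaS33: float
    ks_mm_h: float
    flags: int = FLAG_OK
    lambda_slope: float = field(default=np.nan)
    B_coeff: float = field(default=np.nan)

    @property
    def ks_cm_h(self) -> float:
        """Saturated conductivity in cm h-1 (crop-model output unit)."""
        return self.ks_mm_h / 10.0


def organic_carbon_to_matter(oc_g_per_kg: float) -> OrganicContent:
    """Convert organic carbon in g kg-1 to OC % and OM %.

    OM = 2 x OC; the factor 2 is deliberate (more accurate for these soils
    than the conventional van-Bemmelen 1.724).
    """
    oc = float(oc_g_per_kg)
    if oc < 0 or np.isnan(oc):
        raise InvalidSoilInputError(
            f"organic carbon must be >= 0 and finite, got {oc_g_per_kg!r}"
        )
    oc_pct = oc / 10.0
    return OrganicContent(oc_pct, 2.0 * oc_pct)


def _as_frac_om(tex: TextureComposition | tuple, om: OrganicContent | float):
    """Normalise inputs to (S fraction, C fraction, OM %)."""
    if isinstance(tex, TextureComposition):
        s, c = tex.sand_frac, tex.clay_frac
    else:
        s, c = float(tex[0]), float(tex[1])
    if isinstance(om, OrganicContent):
        om_pct = om.organic_matter_pct
    else:
        om_pct = float(om)
    if s > 1.5 or c > 1.5:
        raise InvalidSoilInputError(
            "sand/clay must enter the regressions as decimal fractions; "
            f"got S={s}, C={c} (looks like percent)"
        )
    return s, c, om_pct


def _theta1500(s, c, om):
    t = (-0.024 * s + 0.487 * c + 0.006 * om
         + 0.005 * (s * om) - 0.013 * (c * om)
         + 0.068 * (s * c) + 0.031)
    return t + (0.14 * t - 0.02)


def _theta33(s, c, om):
    t = (-0.251 * s + 0.195 * c + 0.011 * om
         + 0.006 * (s * om) - 0.027 * (c * om)
         + 0.452 * (s * c) + 0.299)
    return t + (1.283 * t * t - 0.374 * t - 0.015)


def _thetaS33(s, c, om):
    t = (0.278 * s + 0.034 * c + 0.022 * om
         - 0.018 * (s * om) - 0.027 * (c * om)
         - 0.584 * (s * c) + 0.078)
    return t + (0.636 * t - 0.107)


def _thetaS(s, c, om):
    return _theta33(s, c, om) + _thetaS33(s, c, om) - 0.097 * s + 0.043


def wilting_point(tex, om) -> float:
    """Volumetric water content at -1500 kPa (wilting point, SLLL)."""
    s, c, om_pct = _as_frac_om(tex, om)
    return float(_theta1500(s, c, om_pct))


def field_capacity(tex, om) -> float:
    """Volumetric water content at -33 kPa (field capacity, SDUL)."""
    s, c, om_pct = _as_frac_om(tex, om)
    return float(_theta33(s, c, om_pct))


def saturation(tex, om) -> float:
    """Volumetric water content at saturation (SSAT)."""
    s, c, om_pct = _as_frac_om(tex, om)
    return float(_thetaS(s, c, om_pct))


def saturated_conductivity(theta1500: float, theta33: float, thetaS: float) -> float:
    """Saturated hydraulic conductivity in mm h-1.

    KS = 1930 (thetaS - theta33)^(3 - lambda) with
    lambda = 1/B, B = [ln 1500 - ln 33] / [ln theta33 - ln theta1500].
    The exponent applies to the moisture difference thetaS - theta33.
    """
    if not (thetaS >= theta33 > theta1500 > 0):
        raise InvalidSoilInputError(
            f"need thetaS >= theta33 > theta1500 > 0, got "
            f"{thetaS}, {theta33}, {theta1500}"
        )
    if theta33 == theta1500:
        raise InvalidSoilInputError("theta33 == theta1500: B coefficient undefined")
    b = (np.log(1500.0) - np.log(33.0)) / (np.log(theta33) - np.log(theta1500))
    lam = 1.0 / b
    return float(1930.0 * (thetaS - theta33) ** (3.0 - lam))


def _clamp_and_flag(th1500, th33, thS):
    """Apply the validity-domain clamps; return clamped triple + flag bits.

    Works elementwise on numpy arrays.
    """
    flags = np.zeros(np.shape(th1500), dtype=np.int32)
    low = th1500 < MIN_THETA1500
    th1500 = np.where(low, MIN_THETA1500, th1500)
    flags |= np.where(low, FLAG_WILTING_LOW, 0)

    inv = th33 < th1500 + MIN_AWC_SPREAD
    th33 = np.where(inv, th1500 + MIN_AWC_SPREAD, th33)
    flags |= np.where(inv, FLAG_FC_BELOW_WP, 0)

    # field capacity must leave room below the saturation cap
    fc_high = th33 > MAX_THETAS - MIN_SAT_SPREAD
    th33 = np.where(fc_high, MAX_THETAS - MIN_SAT_SPREAD, th33)
    flags |= np.where(fc_high, FLAG_SAT_HIGH, 0)

    high = thS > MAX_THETAS
    thS = np.where(high, MAX_THETAS, thS)
    flags |= np.where(high, FLAG_SAT_HIGH, 0)

    sinv = thS < th33 + MIN_SAT_SPREAD
    thS = np.where(sinv, th33 + MIN_SAT_SPREAD, thS)
    flags |= np.where(sinv, FLAG_SAT_BELOW_FC, 0)
    return th1500, th33, thS, flags


def derive_layer_hydraulics(tex, oc_g_per_kg: float) -> HydraulicProperties:
    """Full hydraulic-property bundle for one layer.

    Runs the four regressions, applies the validity-domain clamps, and
    computes KS from the (possibly clamped) water contents.  Pure function:
    identical inputs give bit-identical outputs.
    """
    oc = np.asarray(oc_g_per_kg, dtype=float)
    if np.ndim(oc) != 0 or np.isnan(oc):
        raise InvalidSoilInputError(f"incomplete layer inputs: OC={oc_g_per_kg!r}")
    om = organic_carbon_to_matter(float(oc))
    s, c, om_pct = _as_frac_om(tex, om)

    th1500 = _theta1500(s, c, om_pct)
    th33 = _theta33(s, c, om_pct)
    thS33 = _thetaS33(s, c, om_pct)
    thS = th33 + thS33 - 0.097 * s + 0.043
    th1500, th33, thS, flags = _clamp_and_flag(th1500, th33, thS)
    flags = int(flags)
    if flags:
        logger.debug(
            "out-of-domain PTF output clamped (flags=%d) for S=%.3f C=%.3f OM=%.2f",
            flags, s, c, om_pct,
        )

    b = (np.log(1500.0) - np.log(33.0)) / (np.log(th33) - np.log(th1500))
    lam = 1.0 / b
    ks = 1930.0 * (thS - th33) ** (3.0 - lam)
    return HydraulicProperties(
        theta1500=float(th1500),
        theta33=float(th33),
        thetaS=float(thS),
        thetaS33=float(thS - th33),
        ks_mm_h=float(ks),
        flags=flags,
        lambda_slope=float(lam),
        B_coeff=float(b),
    )


def derive_hydraulics_grid(sand_pct, clay_pct, oc_g_per_kg):
    """Vectorised hydraulics over property grids.

    Parameters are arrays of sand %, clay % and OC g kg-1 (NaN = nodata).
    Returns dict of arrays: theta1500, theta33, thetaS, ks_mm_h, flags.
    NaN inputs propagate to NaN outputs with flag 0.
    """
    s = np.asarray(sand_pct, dtype=float) / 100.0
    c = np.asarray(clay_pct, dtype=float) / 100.0
    om = np.asarray(oc_g_per_kg, dtype=float) / 10.0 * 2.0

    valid = np.isfinite(s) & np.isfinite(c) & np.isfinite(om)
    s_ = np.where(valid, s, 0.3)
    c_ = np.where(valid, c, 0.3)
    om_ = np.where(valid, om, 1.0)

    th1500 = _theta1500(s_, c_, om_)
    th33 = _theta33(s_, c_, om_)
    thS = th33 + _thetaS33(s_, c_, om_) - 0.097 * s_ + 0.043
    th1500, th33, thS, flags = _clamp_and_flag(th1500, th33, thS)

    b = (np.log(1500.0) - np.log(33.0)) / (np.log(th33) - np.log(th1500))
    ks = 1930.0 * (thS - th33) ** (3.0 - 1.0 / b)

    nan = np.float64(np.nan)
    return {
        "theta1500": np.where(valid, th1500, nan),
        "theta33": np.where(valid, th33, nan),
        "thetaS": np.where(valid, thS, nan),
        "ks_mm_h": np.where(valid, ks, nan),
        "flags": np.where(valid, flags, 0).astype(np.int32),
    }
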