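"""Synthetic input generators for testing the pipeline end to end.

Real inputs are continental rasters of sand/silt/clay %, organic carbon,
bulk density, pH and CEC at six depth intervals.  This module emulates
their statistical structure -- spatially correlated fields, exact
texture closure (sand + silt + clay = 100 per pixel), plausible property
ranges, a consistent nodata region shaped like a coastline -- from a
seed, so every test and the acceptance run are self-contained and
reproducible.

Correlated fields are built by Gaussian-kernel smoothing of white noise
(``scipy.ndimage.gaussian_filter``) and re-standardising; the
correlation length is the kernel sigma in pixels.  The generator makes
no attempt to emulate the true spatial statistics of any real soil
database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import hc27
from .pipeline import N_LAYERS, GridSpec, InputStack
from .sol import write_sol

__all__ = ["FixtureSpec", "generate_input_stack", "generate_template_set",
           "THREE_ZONE_TEXTURES"]

# depth trend multipliers for organic carbon (topsoil richest)
_OC_DEPTH = (1.0, 0.85, 0.65, 0.42, 0.25, 0.15)

# per-zone base composition (sand %, clay %) for the "three-zone" preset;
# zones are vertical bands left -> right, constructed to classify as
# CLAY / LOAM / SAND respectively under the default texture rule
THREE_ZONE_TEXTURES = {
    "clay": (20.0, 52.0),
    "loam": (40.0, 22.0),
    "sand": (80.0, 8.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic input stack."""

    shape: tuple[int, int] = (80, 80)
    block: int = 10
    seed: int = 0
    nodata_fraction: float = 0.1
    correlation_length_px: float = 8.0
    preset: str | None = None            # None or "three-zone"
    west: float = 30.0
    south: float = -5.0
    fine_cellsize_deg: float = 1.0 / 120.0
    # field means/spreads: (mean, sd) on the fine grid
    sand_stats: tuple[float, float] = (40.0, 22.0)
    clay_stats: tuple[float, float] = (24.0, 13.0)
    oc_topsoil_g_kg: tuple[float, float] = (13.0, 0.55)   # lognormal mu in g/kg, sigma of log
    bd_stats: tuple[float, float] = (1350.0, 140.0)
    ph_stats: tuple[float, float] = (6.4, 0.7)
    cec_g_kg: tuple[float, float] = (15.0, 0.45)          # lognormal
    n_countries: int = 2
    extra: dict = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Standardised smoothed white noise (zero mean, unit sd)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def _zone_of_column(col: int, ncols: int) -> str:
    third = ncols / 3.0
    if col < third:
        return "clay"
    if col < 2 * third:
        return "loam"
    return "sand"


def generate_input_stack(spec: FixtureSpec) -> InputStack:
    """Generate the full 7-property x 6-layer synthetic fine-grid stack
    plus a coarse country mask splitting the domain into two countries."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    sigma = spec.correlation_length_px

    z = {name: _smooth_field(rng, shape, sigma) for name in
         ("sand", "clay", "oc", "bd", "ph", "cec", "coast")}
    layer_jitter = {name: [_smooth_field(rng, shape, sigma) * 0.15
                           for _ in range(N_LAYERS)]
                    for name in ("sand", "clay", "oc", "bd", "ph", "cec")}

    # nodata geometry: a synthetic coastline covering nodata_fraction of pixels
    if spec.nodata_fraction > 0:
        thresh = np.quantile(z["coast"], spec.nodata_fraction)
        nodata = z["coast"] < thresh
    else:
        nodata = np.zeros(shape, dtype=bool)

    grids: dict[str, list[np.ndarray]] = {p: [] for p in
                                          ("sand", "silt", "clay", "oc", "bd", "ph", "cec")}
    cols = np.arange(shape[1])
    for li in range(N_LAYERS):
        if spec.preset == "three-zone":
            base_sand = np.empty(shape)
            base_clay = np.empty(shape)
            for c in cols:
                zs, zc = THREE_ZONE_TEXTURES[_zone_of_column(c, shape[1])]
                base_sand[:, c] = zs
                base_clay[:, c] = zc
            sand = base_sand + 2.0 * layer_jitter["sand"][li]
            clay = base_clay + 2.0 * layer_jitter["clay"][li]
        else:
            sand = (spec.sand_stats[0] + spec.sand_stats[1] * z["sand"]
                    + 6.0 * layer_jitter["sand"][li])
            clay = (spec.clay_stats[0] + spec.clay_stats[1] * z["clay"]
                    + 4.0 * layer_jitter["clay"][li])
        sand = np.clip(sand, 2.0, 90.0)
        clay = np.clip(clay, 2.0, 62.0)
        # keep silt non-negative, then close exactly
        over = sand + clay > 96.0
        scale = np.where(over, 96.0 / (sand + clay), 1.0)
        sand *= scale
        clay *= scale
        # quantise to a 2^-20 binary grid so sand + silt + clay sums to 100
        # exactly in floating point, in any summation order
        q = 2.0 ** 20
        sand = np.round(sand * q) / q
        clay = np.round(clay * q) / q
        silt = 100.0 - sand - clay

        oc = spec.oc_topsoil_g_kg[0] * _OC_DEPTH[li] * np.exp(
            spec.oc_topsoil_g_kg[1] * (z["oc"] + layer_jitter["oc"][li]))
        oc = np.clip(oc, 0.3, 80.0)
        bd = np.clip(spec.bd_stats[0] + 20.0 * li
                     + spec.bd_stats[1] * (z["bd"] + layer_jitter["bd"][li]),
                     900.0, 1800.0)
        ph = np.clip(spec.ph_stats[0] + 0.05 * li
                     + spec.ph_stats[1] * (z["ph"] + layer_jitter["ph"][li]),
                     4.0, 9.0)
        cec = np.clip(spec.cec_g_kg[0] * np.exp(
            spec.cec_g_kg[1] * (z["cec"] + layer_jitter["cec"][li])), 1.0, 60.0)

        for name, arr in (("sand", sand), ("silt", silt), ("clay", clay),
                          ("oc", oc), ("bd", bd), ("ph", ph), ("cec", cec)):
            out = arr.astype(float).copy()
            out[nodata] = np.nan
            grids[name].append(out)

    gspec = GridSpec(
        shape_fine=shape, west=spec.west, south=spec.south,
        fine_cellsize_deg=spec.fine_cellsize_deg, block=spec.block,
    )
    mask, codes = _country_mask(gspec, spec.n_countries)
    stack = InputStack(spec=gspec, grids=grids, country_mask=mask,
                       country_codes=codes)
    stack.validate()
    return stack


def _country_mask(gspec: GridSpec, n_countries: int):
    """Split the coarse grid into vertical-band 'countries' AA, AB, ..."""
    nrc, ncc = gspec.shape_coarse
    mask = np.zeros((nrc, ncc), dtype=int)
    codes = {}
    n = max(1, min(n_countries, ncc))
    for i in range(n):
        c0 = i * ncc // n
        c1 = (i + 1) * ncc // n
        mask[:, c0:c1] = i + 1
        codes[i + 1] = "A" + chr(ord("A") + i)
    return mask, codes


def generate_template_set(seed: int, out_dir: str | Path) -> list[Path]:
    """Write 27 synthetic generic-template *.SOL files (HC_GEN0001-27).

    The templates are the packaged defaults with a small seeded
    perturbation of the surface evaporation limit and drainage rate
    (kept inside their valid ranges); all template invariants hold by
    construction.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for pid, template in sorted(hc27.build_default_templates().items()):
        surf = template.surface
        surf.slu1 = round(float(np.clip(surf.slu1 + rng.normal(0, 0.3), 4.0, 12.0)), 1)
        surf.sldr = round(float(np.clip(surf.sldr + rng.normal(0, 0.02), 0.1, 0.85)), 2)
        template.validate()
        profile = hc27.template_to_profile(template)
        path = out / f"{pid}.SOL"
        write_sol([profile], path)
        paths.append(path)
    return paths
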