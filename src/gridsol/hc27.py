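"""Generic soil-profile classification (HC27 decision tree).

Every grid cell is mapped to one of 27 generic profiles keyed by a
three-way decision tree: texture (clay / loam / sand), fertility
(high / medium / low, proxied by topsoil organic carbon) and rooting
depth (deep / medium / shallow, proxied by the available water content
of the top metre of soil).  The 27 keys, ``HC_GEN0001`` ...
``HC_GEN0027``, follow the canonical ordering clay < loam < sand, then
high < medium < low fertility, then deep < medium < shallow depth.

Template profiles carry the parameters that cannot be derived from the
gridded inputs: the ten surface parameters, the per-layer root growth
factor (SRGF) and total nitrogen (SLNI).  Real HC27 *.SOL files can be
supplied and are parsed with :mod:`gridsol.sol`; when none are given, a
packaged synthetic default set is generated from a documented rule.
The defaults are stand-ins for the published HC27 profiles, not copies
of them -- supply the real files where fidelity to HC27 matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ptf import TextureComposition, derive_layer_hydraulics
from .sol import (
    MISSING,
    SoilLayerRecord,
    SoilProfile,
    SurfaceParameters,
    read_sol,
)

__all__ = [
    "TextureClass",
    "FertilityClass",
    "DepthClass",
    "GenericProfileKey",
    "GenericProfileTemplate",
    "ProfileAWC",
    "IncompleteProfileError",
    "TemplateConfigurationError",
    "ALL_PROFILE_IDS",
    "compute_awc_1m",
    "classify_texture",
    "classify_fertility",
    "classify_rooting_depth",
    "select_generic_profile",
    "profile_key_from_id",
    "build_default_templates",
    "load_templates",
    "template_to_profile",
]


class TextureClass(Enum):
    CLAY = "clay"
    LOAM = "loam"
    SAND = "sand"


class FertilityClass(Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


class DepthClass(Enum):
    DEEP = "deep"
    MEDIUM = "medium"
    SHALLOW = "shallow"


_TEXTURE_ORDER = (TextureClass.CLAY, TextureClass.LOAM, TextureClass.SAND)
_FERTILITY_ORDER = (FertilityClass.HIGH, FertilityClass.MEDIUM, FertilityClass.LOW)
_DEPTH_ORDER = (DepthClass.DEEP, DepthClass.MEDIUM, DepthClass.SHALLOW)

# generic-template depth structure: 7 horizons, bottoms in cm
HC27_LAYER_BOTTOMS = (10, 30, 60, 90, 120, 150, 180)
HC27_LAYER_TOPS = (0, 10, 30, 60, 90, 120, 150)

# rootable depth per depth class, cm (template truncation rule)
ROOTABLE_DEPTH_CM = {
    DepthClass.DEEP: 180,
    DepthClass.MEDIUM: 120,
    DepthClass.SHALLOW: 60,
}

# standard gridded depth intervals, cm
STANDARD_LAYER_BOUNDS = ((0, 5), (5, 15), (15, 30), (30, 60), (60, 100), (100, 200))

# default classification rules; every value is overridable via config
DEFAULT_TEXTURE_RULE = {
    "clay_min_clay_pct": 40.0,
    "sand_min_sand_pct": 65.0,
    "sand_max_clay_pct": 18.0,
}
DEFAULT_FERTILITY_THRESHOLDS_PCT = {"high": 1.2, "medium": 0.7}
# AWC breakpoints in mm per metre of soil: (deep_above, medium_above);
# intervals are lower-exclusive / upper-inclusive
DEFAULT_DEPTH_LOOKUP_MM = {
    "clay": (150.0, 100.0),
    "loam": (150.0, 75.0),
    "sand": (125.0, 75.0),
}


class IncompleteProfileError(ValueError):
    """A profile is missing layer values needed for classification."""


class TemplateConfigurationError(ValueError):
    """A user-supplied template set is missing, duplicated or invalid."""


@dataclass(frozen=True)
class GenericProfileKey:
    texture: TextureClass
    fertility: FertilityClass
    depth: DepthClass

    @property
    def profile_id(self) -> str:
        idx = (
            _TEXTURE_ORDER.index(self.texture) * 9
            + _FERTILITY_ORDER.index(self.fertility) * 3
            + _DEPTH_ORDER.index(self.depth)
            + 1
        )
        return f"HC_GEN{idx:04d}"


ALL_PROFILE_IDS = tuple(
    GenericProfileKey(t, f, d).profile_id
    for t in _TEXTURE_ORDER for f in _FERTILITY_ORDER for d in _DEPTH_ORDER
)


def profile_key_from_id(profile_id: str) -> GenericProfileKey:
    """Inverse of :attr:`GenericProfileKey.profile_id`."""
    try:
        idx = int(profile_id.removeprefix("HC_GEN")) - 1
        if not 0 <= idx < 27:
            raise ValueError
    except ValueError:
        raise TemplateConfigurationError(
            f"not a generic profile id: {profile_id!r}"
        ) from None
    return GenericProfileKey(
        _TEXTURE_ORDER[idx // 9], _FERTILITY_ORDER[(idx // 3) % 3], _DEPTH_ORDER[idx % 3]
    )


@dataclass(frozen=True)
class ProfileAWC:
    """Available water content of the top ``zr_m`` metres, in mm."""

    awc_mm_per_m: float
    zr_m: float = 1.0


def compute_awc_1m(
    sdul: Sequence[float],
    slll: Sequence[float],
    layer_bounds_cm: Sequence[tuple[int, int]] = STANDARD_LAYER_BOUNDS,
    zr_m: float = 1.0,
) -> ProfileAWC:
    """Available water content of the top metre:
    AWC = 1000 * sum over layers of (SDUL - SLLL) * overlap thickness (m).

    Layers are clipped to [0, zr] so the 100-200 cm layer contributes
    nothing at the default 1-m root zone.
    """
    if len(sdul) != len(slll) or len(sdul) != len(layer_bounds_cm):
        raise IncompleteProfileError(
            f"need matching layer arrays, got {len(sdul)}/{len(slll)} values "
            f"for {len(layer_bounds_cm)} layers"
        )
    zr_cm = zr_m * 100.0
    awc = 0.0
    for (top, bottom), fc, wp in zip(layer_bounds_cm, sdul, slll):
        if not (np.isfinite(fc) and np.isfinite(wp)):
            raise IncompleteProfileError(
                f"layer {top}-{bottom} cm has missing water contents"
            )
        overlap_m = max(0.0, min(bottom, zr_cm) - top) / 100.0
        awc += (fc - wp) * overlap_m
    return ProfileAWC(awc_mm_per_m=1000.0 * awc, zr_m=zr_m)


def classify_texture(
    tex: TextureComposition, rule: Mapping[str, float] | None = None
) -> TextureClass:
    """Three-way texture split (a coarse collapse of the texture triangle).

    CLAY if clay >= 40 %; SAND if sand >= 65 % and clay < 18 %; else LOAM.
    Thresholds are configurable.
    """
    r = dict(DEFAULT_TEXTURE_RULE, **(rule or {}))
    if tex.clay_pct >= r["clay_min_clay_pct"]:
        return TextureClass.CLAY
    if tex.sand_pct >= r["sand_min_sand_pct"] and tex.clay_pct < r["sand_max_clay_pct"]:
        return TextureClass.SAND
    return TextureClass.LOAM


def classify_fertility(
    oc_topsoil_pct: float, thresholds: Mapping[str, float] | None = None
) -> FertilityClass:
    """Fertility from topsoil (0-30 cm thickness-weighted) organic carbon %:
    HIGH >= 1.2, MEDIUM in [0.7, 1.2), LOW < 0.7 by default."""
    if oc_topsoil_pct < 0 or not np.isfinite(oc_topsoil_pct):
        raise IncompleteProfileError(f"bad topsoil OC: {oc_topsoil_pct!r}")
    t = dict(DEFAULT_FERTILITY_THRESHOLDS_PCT, **(thresholds or {}))
    if oc_topsoil_pct >= t["high"]:
        return FertilityClass.HIGH
    if oc_topsoil_pct >= t["medium"]:
        return FertilityClass.MEDIUM
    return FertilityClass.LOW


def classify_rooting_depth(
    awc: ProfileAWC | float,
    tex_class: TextureClass,
    lookup: Mapping[str, Sequence[float]] | None = None,
) -> DepthClass:
    """Rooting-depth class from top-1-m AWC (mm) and texture.

    Per-texture breakpoints (deep_above, medium_above), lower-exclusive /
    upper-inclusive: e.g. clay with AWC 140 mm falls in (100, 150] and is
    MEDIUM; above 150 is DEEP; at or below 100 is SHALLOW.
    """
    mm = awc.awc_mm_per_m if isinstance(awc, ProfileAWC) else float(awc)
    table = dict(DEFAULT_DEPTH_LOOKUP_MM)
    if lookup:
        table.update({k: tuple(v) for k, v in lookup.items()})
    deep_above, medium_above = table[tex_class.value]
    if mm > deep_above:
        return DepthClass.DEEP
    if mm > medium_above:
        return DepthClass.MEDIUM
    return DepthClass.SHALLOW


def select_generic_profile(
    texture: TextureClass, fertility: FertilityClass, depth: DepthClass
) -> GenericProfileKey:
    """Total function over the 27 class triples."""
    return GenericProfileKey(texture, fertility, depth)


# ---------------------------------------------------------------------------
# templates

@dataclass(frozen=True)
class GenericProfileTemplate:
    """Template-inherited parameters for one generic profile:
    surface parameters plus SRGF and SLNI on the 7 template horizons."""

    key: GenericProfileKey
    surface: SurfaceParameters
    srgf_by_hc27_layer: tuple[float, ...]
    slni_by_hc27_layer: tuple[float, ...]

    def validate(self) -> None:
        for name, values in (
            ("SRGF", self.srgf_by_hc27_layer),
            ("SLNI", self.slni_by_hc27_layer),
        ):
            if len(values) != 7:
                raise TemplateConfigurationError(
                    f"{self.key.profile_id}: {name} needs 7 layer values, "
                    f"got {len(values)}"
                )
        srgf = self.srgf_by_hc27_layer
        if any(not (0.0 <= v <= 1.0) for v in srgf):
            raise TemplateConfigurationError(
                f"{self.key.profile_id}: SRGF outside [0, 1]: {srgf}"
            )
        if any(b > a + 1e-9 for a, b in zip(srgf, srgf[1:])):
            raise TemplateConfigurationError(
                f"{self.key.profile_id}: SRGF must be non-increasing with depth: {srgf}"
            )
        rootable = ROOTABLE_DEPTH_CM[self.key.depth]
        for top, v in zip(HC27_LAYER_TOPS, srgf):
            if top >= rootable and v != 0.0:
                raise TemplateConfigurationError(
                    f"{self.key.profile_id}: SRGF must be 0 below the "
                    f"{rootable} cm rootable depth, got {v} at {top} cm"
                )
        self.surface.validate()


# per-texture surface-parameter defaults (crop-model conventional values)
_SURFACE_BY_TEXTURE = {
    TextureClass.CLAY: dict(salb=0.13, slu1=9.5, sldr=0.30, slro=85.0),
    TextureClass.LOAM: dict(salb=0.12, slu1=9.0, sldr=0.50, slro=75.0),
    TextureClass.SAND: dict(salb=0.15, slu1=6.0, sldr=0.75, slro=65.0),
}
# topsoil total-N % per fertility class for the synthetic default templates
_SLNI_BASE = {FertilityClass.HIGH: 0.15, FertilityClass.MEDIUM: 0.10,
              FertilityClass.LOW: 0.05}
# SRGF depth-decay rate below the 15-cm full-rooting zone, cm-1
_SRGF_DECAY = 0.02


def _default_srgf(depth_class: DepthClass) -> tuple[float, ...]:
    rootable = ROOTABLE_DEPTH_CM[depth_class]
    out = []
    for top, bottom in zip(HC27_LAYER_TOPS, HC27_LAYER_BOTTOMS):
        if top >= rootable:
            out.append(0.0)
            continue
        mid = 0.5 * (top + bottom)
        out.append(1.0 if mid <= 15.0 else math.exp(-_SRGF_DECAY * (mid - 15.0)))
    return tuple(out)


def _default_slni(key: GenericProfileKey) -> tuple[float, ...]:
    base = _SLNI_BASE[key.fertility]
    return tuple(
        round(base * math.exp(-0.01 * 0.5 * (t + b)), 4)
        for t, b in zip(HC27_LAYER_TOPS, HC27_LAYER_BOTTOMS)
    )


def build_default_templates() -> dict[str, GenericProfileTemplate]:
    """The packaged synthetic default template set (27 profiles).

    SRGF: 1.0 for horizons with midpoint <= 15 cm, exponential decay
    exp(-0.02 (mid - 15)) below, truncated to 0 below the class rootable
    depth (deep 180, medium 120, shallow 60 cm).  Surface parameters are
    texture-conventional defaults.  These are synthetic stand-ins for the
    published HC27 set.
    """
    out: dict[str, GenericProfileTemplate] = {}
    for t in _TEXTURE_ORDER:
        for f in _FERTILITY_ORDER:
            for d in _DEPTH_ORDER:
                key = GenericProfileKey(t, f, d)
                tmpl = GenericProfileTemplate(
                    key=key,
                    surface=SurfaceParameters(**_SURFACE_BY_TEXTURE[t]),
                    srgf_by_hc27_layer=_default_srgf(d),
                    slni_by_hc27_layer=_default_slni(key),
                )
                tmpl.validate()
                out[key.profile_id] = tmpl
    return out


# representative layer properties used only when rendering synthetic
# template *.SOL files (texture %, OC %, bulk density g cm-3, CEC)
_TEMPLATE_SOIL = {
    TextureClass.CLAY: dict(sand=22.0, clay=50.0, bdm=1.30, cec=28.0),
    TextureClass.LOAM: dict(sand=40.0, clay=20.0, bdm=1.40, cec=15.0),
    TextureClass.SAND: dict(sand=80.0, clay=8.0, bdm=1.55, cec=5.0),
}
_TEMPLATE_OC_TOP = {FertilityClass.HIGH: 1.5, FertilityClass.MEDIUM: 0.9,
                    FertilityClass.LOW: 0.4}
_OC_DEPTH_FACTOR = (1.0, 0.85, 0.65, 0.45, 0.30, 0.20, 0.15)


def template_to_profile(template: GenericProfileTemplate) -> SoilProfile:
    """Render a template as a full 7-horizon *.SOL profile (synthetic
    layer properties; used to materialise the default template files)."""
    key = template.key
    soil = _TEMPLATE_SOIL[key.texture]
    oc_top = _TEMPLATE_OC_TOP[key.fertility]
    layers = []
    for li, (top, bottom) in enumerate(zip(HC27_LAYER_TOPS, HC27_LAYER_BOTTOMS)):
        sand, clay = soil["sand"], soil["clay"]
        tex = TextureComposition(sand, clay, 100.0 - sand - clay)
        oc_pct = oc_top * _OC_DEPTH_FACTOR[li]
        hyd = derive_layer_hydraulics(tex, oc_pct * 10.0)
        layers.append(SoilLayerRecord(
            slb=bottom,
            slmh=("A", "A", "AB", "BA", "B", "BC", "C")[li],
            slll=round(hyd.theta1500, 3),
            sdul=round(hyd.theta33, 3),
            ssat=round(hyd.thetaS, 3),
            srgf=round(template.srgf_by_hc27_layer[li], 3),
            ssks=round(hyd.ks_cm_h, 2),
            sbdm=soil["bdm"],
            sloc=round(oc_pct, 2),
            slcl=clay,
            slsi=100.0 - sand - clay,
            slcf=MISSING,
            slni=template.slni_by_hc27_layer[li],
            slhw=6.5,
            slhb=MISSING,
            scec=soil["cec"],
        ))
    return SoilProfile(
        profile_id=key.profile_id,
        source="GRIDSOL",
        texture_label=key.texture.value[0].upper(),
        depth_cm=HC27_LAYER_BOTTOMS[-1],
        description=(
            f"Synthetic generic {key.texture.value} {key.fertility.value}-fertility "
            f"{key.depth.value} profile"
        ),
        site="Generic",
        country="ZZ",
        lat=0.0,
        lon=0.0,
        family="Generic",
        surface=template.surface,
        layers=layers,
    )


def _template_from_profile(profile: SoilProfile) -> GenericProfileTemplate:
    key = profile_key_from_id(profile.profile_id)
    slbs = tuple(l.slb for l in profile.layers)
    if slbs != HC27_LAYER_BOTTOMS:
        raise TemplateConfigurationError(
            f"{profile.profile_id}: template must have the 7 horizons "
            f"{HC27_LAYER_BOTTOMS}, got {slbs}"
        )
    tmpl = GenericProfileTemplate(
        key=key,
        surface=profile.surface,
        srgf_by_hc27_layer=tuple(l.srgf for l in profile.layers),
        slni_by_hc27_layer=tuple(
            0.0 if l.slni == MISSING else l.slni for l in profile.layers
        ),
    )
    tmpl.validate()
    return tmpl


def load_templates(
    source: str | Path | None = None, allow_partial: bool = False
) -> dict[str, GenericProfileTemplate]:
    """Load the 27 generic templates.

    With no ``source``, returns the packaged synthetic defaults.  With a
    directory of *.SOL files, parses them and validates the template
    invariants (hard error on violation).  The directory must cover all
    27 ids unless ``allow_partial=True``, in which case user templates
    override defaults id-by-id.
    """
    defaults = build_default_templates()
    if source is None:
        return defaults

    src = Path(source)
    found: dict[str, GenericProfileTemplate] = {}
    for path in sorted(src.glob("*.SOL")) + sorted(src.glob("*.sol")):
        for profile in read_sol(path):
            pid = profile.profile_id
            if pid in found:
                raise TemplateConfigurationError(f"duplicate template id {pid}")
            found[pid] = _template_from_profile(profile)
    missing = [pid for pid in ALL_PROFILE_IDS if pid not in found]
    extra = [pid for pid in found if pid not in ALL_PROFILE_IDS]
    if extra:
        raise TemplateConfigurationError(f"unexpected template ids: {extra}")
    if missing and not allow_partial:
        raise TemplateConfigurationError(
            f"template directory {src} is missing ids: {missing}"
        )
    merged = dict(defaults)
    merged.update(found)
    return merged
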