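"""Reader and writer for the DSSAT *.SOL soil input format.

The *.SOL dialect is a fixed-width ASCII format: each profile has a
``*`` header line, a site line, one line of surface parameters and one
line per soil horizon, each under its own ``@`` column-header line.
The sentinel ``-99`` marks values the crop model should replace with
defaults at run time.

"Bit-exact" output is defined by the single format descriptor table in
this module (:data:`SURFACE_FIELDS` / :data:`LAYER_FIELDS`): every
numeric field is right-aligned in a 6-character column at a fixed
decimal precision, lines are LF-terminated ASCII with no trailing
whitespace, so a rerun on identical inputs reproduces the file byte for
byte.

The reader has two modes: *tolerant* (whitespace-tokenised, accepts any
well-formed DSSAT-dialect file, including hand-edited template sets) and
*strict* (fixed-column slicing per the descriptor, used to verify our
own output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable

MISSING = -99.0

# standard output horizon bottoms, cm
STANDARD_SLB = (5, 15, 30, 60, 100, 200)
# fixed master-horizon sequence for the six standard layers
STANDARD_SLMH = ("A", "A", "AB", "BA", "B", "BC")

FIELD_WIDTH = 6

# (name, kind, decimals) -- kind: "str", "int", "float"
SURFACE_FIELDS = (
    ("SCOM", "str", None),
    ("SALB", "float", 2),
    ("SLU1", "float", 1),
    ("SLDR", "float", 2),
    ("SLRO", "float", 1),
    ("SLNF", "float", 2),
    ("SLPF", "float", 2),
    ("SMHB", "str", None),
    ("SMPX", "str", None),
    ("SMKE", "str", None),
)

LAYER_FIELDS = (
    ("SLB", "int", None),
    ("SLMH", "str", None),
    ("SLLL", "float", 3),
    ("SDUL", "float", 3),
    ("SSAT", "float", 3),
    ("SRGF", "float", 3),
    ("SSKS", "float", 2),
    ("SBDM", "float", 2),
    ("SLOC", "float", 2),
    ("SLCL", "float", 1),
    ("SLSI", "float", 1),
    ("SLCF", "float", 1),
    ("SLNI", "float", 3),
    ("SLHW", "float", 1),
    ("SLHB", "float", 1),
    ("SCEC", "float", 1),
)


class SolFormatError(ValueError):
    """Malformed *.SOL content or a value that cannot be formatted."""


class SolParseError(SolFormatError):
    """Parse failure; message carries the 1-based line number."""


@dataclass
class SurfaceParameters:
    """The ten surface/whole-profile parameters of a DSSAT soil.

    scom: Munsell-style color code; salb: albedo (0-1); slu1: stage-1
    evaporation limit, mm; sldr: drainage rate, fraction day-1; slro:
    SCS runoff curve number; slnf: mineralization factor (0-1); slpf:
    photosynthesis factor (0-1); smhb/smpx/smke: lab method codes.
    """

    scom: str = "BN"
    salb: float = 0.13
    slu1: float = 9.0
    sldr: float = 0.50
    slro: float = 75.0
    slnf: float = 1.0
    slpf: float = 1.0
    smhb: str = "IB001"
    smpx: str = "IB001"
    smke: str = "IB001"

    def validate(self) -> None:
        if not (0.0 < self.salb < 1.0):
            raise SolFormatError(f"SALB={self.salb} outside (0, 1)")
        if not (0.0 < self.sldr <= 1.0):
            raise SolFormatError(f"SLDR={self.sldr} outside (0, 1]")
        if not (0.0 < self.slnf <= 1.0):
            raise SolFormatError(f"SLNF={self.slnf} outside (0, 1]")
        if not (0.0 < self.slpf <= 1.0):
            raise SolFormatError(f"SLPF={self.slpf} outside (0, 1]")


@dataclass
class SoilLayerRecord:
    """One soil horizon.  Water contents in cm3 cm-3, SSKS in cm h-1,
    SBDM in g cm-3, SLOC/SLCL/SLSI/SLNI in %, SCEC in cmol(+) kg-1.
    -99 marks a missing value."""

    slb: int
    slmh: str = "A"
    slll: float = MISSING
    sdul: float = MISSING
    ssat: float = MISSING
    srgf: float = MISSING
    ssks: float = MISSING
    sbdm: float = MISSING
    sloc: float = MISSING
    slcl: float = MISSING
    slsi: float = MISSING
    slcf: float = MISSING
    slni: float = MISSING
    slhw: float = MISSING
    slhb: float = MISSING
    scec: float = MISSING
    extras: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        trio = (self.slll, self.sdul, self.ssat)
        if all(v != MISSING for v in trio):
            if not (self.slll < self.sdul < self.ssat):
                raise SolFormatError(
                    f"layer SLB={self.slb}: need SLLL < SDUL < SSAT, got {trio}"
                )


@dataclass
class SoilProfile:
    """One soil profile: metadata, surface parameters and horizons."""

    profile_id: str
    source: str = "gridsol"
    texture_label: str = "L"
    depth_cm: int = 200
    description: str = ""
    site: str = "Generic"
    country: str = "ZZ"
    lat: float = 0.0
    lon: float = 0.0
    family: str = "Generic"
    surface: SurfaceParameters = dc_field(default_factory=SurfaceParameters)
    layers: list[SoilLayerRecord] = dc_field(default_factory=list)

    def validate(self) -> None:
        if not self.profile_id or len(self.profile_id) > 10:
            raise SolFormatError(f"profile_id {self.profile_id!r} not 1-10 chars")
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise SolFormatError(
                f"{self.profile_id}: lat/lon ({self.lat}, {self.lon}) out of range"
            )
        if not self.layers:
            raise SolFormatError(f"{self.profile_id}: no layers")
        slbs = [l.slb for l in self.layers]
        if any(b <= a for a, b in zip(slbs, slbs[1:])):
            raise SolFormatError(
                f"{self.profile_id}: SLB must be strictly increasing, got {slbs}"
            )
        self.surface.validate()
        for layer in self.layers:
            layer.validate()

    def validate_standard_layers(self) -> None:
        """Enforce the gridded-output contract: exactly 6 horizons at
        bottoms 5/15/30/60/100/200 cm."""
        self.validate()
        slbs = tuple(l.slb for l in self.layers)
        if slbs != STANDARD_SLB:
            raise SolFormatError(
                f"{self.profile_id}: expected layer bottoms {STANDARD_SLB}, got {slbs}"
            )


# ---------------------------------------------------------------------------
# formatting

def _fmt(value, kind: str, decimals, name: str, profile_id: str) -> str:
    """Right-align one value in its fixed column."""
    if kind == "str":
        text = str(value)
    elif kind == "int":
        text = str(int(value))
    else:
        v = float(value)
        if v == MISSING:
            text = "-99"
        elif math.isnan(v):
            text = "-99"
        else:
            text = f"{v:.{decimals}f}"
    if len(text) > FIELD_WIDTH:
        raise SolFormatError(
            f"profile {profile_id}: field {name} value {text!r} overflows "
            f"its {FIELD_WIDTH}-character column"
        )
    return text.rjust(FIELD_WIDTH)


def _header_row(fields) -> str:
    return "@" + "".join(name.rjust(FIELD_WIDTH) for name, _, _ in fields)[1:]


def format_profile(profile: SoilProfile) -> str:
    """Render one profile as its *.SOL text block."""
    profile.validate()
    pid = profile.profile_id
    lines = [
        f"*{pid:<10}  {profile.source:<11} {profile.texture_label:<5}"
        f"{profile.depth_cm:>4}  {profile.description}".rstrip(),
        "@SITE        COUNTRY          LAT     LONG SCS FAMILY",
        f" {profile.site:<11} {profile.country:<13}{profile.lat:>8.3f}"
        f"{profile.lon:>9.3f} {profile.family}".rstrip(),
        _header_row(SURFACE_FIELDS),
        "".join(
            _fmt(getattr(profile.surface, name.lower()), kind, dec, name, pid)
            for name, kind, dec in SURFACE_FIELDS
        ),
        _header_row(LAYER_FIELDS),
    ]
    for layer in profile.layers:
        lines.append(
            "".join(
                _fmt(getattr(layer, name.lower()), kind, dec, name, pid)
                for name, kind, dec in LAYER_FIELDS
            )
        )
    return "\n".join(lines)


def write_sol(profiles: Iterable[SoilProfile], destination) -> Path:
    """Write profiles to one *.SOL file (ASCII, LF, no trailing spaces)."""
    profiles = list(profiles)
    blocks = ["*SOILS: gridsol soil profile file"]
    blocks.extend(format_profile(p) for p in profiles)
    text = "\n\n".join(blocks) + "\n"
    path = Path(destination)
    path.write_text(text, encoding="ascii", newline="\n")
    return path


# ---------------------------------------------------------------------------
# parsing

def _parse_token(tok: str, kind: str, name: str, lineno: int):
    if kind == "str":
        return tok
    try:
        if kind == "int":
            return int(float(tok))
        return float(tok)
    except ValueError:
        raise SolParseError(
            f"line {lineno}: non-numeric value {tok!r} in column {name}"
        ) from None


def _slice_fixed(line: str, nfields: int, lineno: int) -> list[str]:
    toks = [line[i * FIELD_WIDTH:(i + 1) * FIELD_WIDTH].strip()
            for i in range(nfields)]
    if any(not t for t in toks):
        raise SolParseError(f"line {lineno}: truncated record")
    return toks


_SURFACE_KIND = {name: (kind, dec) for name, kind, dec in SURFACE_FIELDS}
_LAYER_KIND = {name: (kind, dec) for name, kind, dec in LAYER_FIELDS}


def read_sol(source, strict: bool = False) -> list[SoilProfile]:
    """Parse a *.SOL file into :class:`SoilProfile` objects.

    ``strict=True`` slices fixed 6-character columns per the module's
    format descriptor (verifies our own writer); the default tolerant
    mode tokenises on whitespace and accepts files with extra trailing
    columns, which are preserved in each layer's ``extras`` dict.
    """
    path = Path(source)
    lines = path.read_text(encoding="ascii", errors="replace").splitlines()

    profiles: list[SoilProfile] = []
    i = 0
    n = len(lines)

    def err(lineno, msg):
        return SolParseError(f"{path.name}: line {lineno}: {msg}")

    while i < n:
        line = lines[i]
        if not line.startswith("*") or line.upper().startswith("*SOILS"):
            i += 1
            continue
        header_lineno = i + 1
        body = line[1:]
        parts = body.split(None, 3)
        if len(parts) < 3:
            raise err(header_lineno, f"malformed profile header {line!r}")
        pid = parts[0]
        source_name = parts[1] if len(parts) > 1 else ""
        texture_label = parts[2] if len(parts) > 2 else ""
        depth_cm, description = 0, ""
        if len(parts) > 3:
            rest = parts[3].split(None, 1)
            try:
                depth_cm = int(float(rest[0]))
            except (ValueError, IndexError):
                raise err(header_lineno, f"malformed profile header {line!r}")
            description = rest[1].strip() if len(rest) > 1 else ""
        prof = SoilProfile(
            profile_id=pid, source=source_name, texture_label=texture_label,
            depth_cm=depth_cm, description=description, layers=[],
        )
        i += 1

        # site block
        while i < n and not lines[i].upper().startswith("@SITE"):
            if lines[i].startswith("*"):
                raise err(i + 1, f"profile {pid}: missing @SITE block")
            i += 1
        if i >= n:
            raise err(n, f"profile {pid}: missing @SITE block")
        i += 1
        toks = lines[i].split() if i < n else []
        if len(toks) < 4:
            raise err(i + 1, f"profile {pid}: malformed site line")
        prof.site, prof.country = toks[0], toks[1]
        prof.lat = _parse_token(toks[2], "float", "LAT", i + 1)
        prof.lon = _parse_token(toks[3], "float", "LONG", i + 1)
        prof.family = " ".join(toks[5:]) if len(toks) > 5 else (toks[4] if len(toks) > 4 else "")
        i += 1

        # surface block
        while i < n and not (lines[i].startswith("@") and "SALB" in lines[i]):
            i += 1
        if i >= n - 1:
            raise err(n, f"profile {pid}: missing surface-parameter block")
        surf_names = lines[i].lstrip("@").split()
        i += 1
        lineno = i + 1
        toks = (_slice_fixed(lines[i], len(surf_names), lineno) if strict
                else lines[i].split())
        if len(toks) < len(surf_names):
            raise err(lineno, f"profile {pid}: truncated surface line")
        surf = SurfaceParameters()
        for name, tok in zip(surf_names, toks):
            if name in _SURFACE_KIND:
                kind, _ = _SURFACE_KIND[name]
                setattr(surf, name.lower(), _parse_token(tok, kind, name, lineno))
        prof.surface = surf
        i += 1

        # layer block
        while i < n and not (lines[i].startswith("@") and "SLB" in lines[i]):
            i += 1
        if i >= n:
            raise err(n, f"profile {pid}: missing layer block")
        layer_names = lines[i].lstrip("@").split()
        i += 1
        while i < n and lines[i].strip() and not lines[i].startswith(("*", "@")):
            lineno = i + 1
            known = [nm for nm in layer_names if nm in _LAYER_KIND]
            toks = (_slice_fixed(lines[i], len(layer_names), lineno) if strict
                    else lines[i].split())
            if len(toks) < len(known):
                raise err(lineno, f"profile {pid}: truncated layer line")
            rec = SoilLayerRecord(slb=0)
            for name, tok in zip(layer_names, toks):
                if name in _LAYER_KIND:
                    kind, _ = _LAYER_KIND[name]
                    setattr(rec, name.lower(), _parse_token(tok, kind, name, lineno))
                else:
                    rec.extras[name] = tok
            prof.layers.append(rec)
            i += 1
        if not prof.layers:
            raise err(i, f"profile {pid}: no layer records")
        profiles.append(prof)
    return profiles
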