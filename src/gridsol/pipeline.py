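"""End-to-end gridded build: rasters in, country *.SOL files out.

The pipeline ingests per-depth-layer property grids at fine resolution
(default 30 arc-seconds), aggregates them to coarse cells (default
5 arc-minutes, i.e. 10 x 10 fine-pixel blocks) by arithmetic averaging,
derives hydraulic properties through the pedo-transfer functions,
classifies each coarse cell into one of the 27 generic profiles,
assembles a six-layer soil profile per cell and writes one *.SOL file
per country (ISO 3166-1 alpha-2 filename), plus a machine-readable run
report.

Raster I/O uses the plain-text ESRI ASCII grid format (one single-band
``.asc`` file per property and depth layer); the in-memory API takes
plain numpy arrays, so any raster reader can feed it.

The pipeline itself is deterministic: cells are processed row-major,
countries are written in sorted order, and numeric formatting is fixed,
so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import hc27, layers as layermod, ptf, sol
from .config import load_config

logger = logging.getLogger("gridsol")

__all__ = [
    "GridSpec",
    "InputStack",
    "CellInputs",
    "PipelineError",
    "PROPERTIES",
    "read_ascii_grid",
    "write_ascii_grid",
    "aggregate_block",
    "aggregate_grid",
    "renormalize_texture",
    "build_cell_profile",
    "partition_by_country",
    "run_build",
    "validate_sol_file",
]

# grid property names, in file-naming order
PROPERTIES = ("sand", "silt", "clay", "oc", "bd", "ph", "cec")

N_LAYERS = 6
LAYER_BOUNDS = layermod.STANDARD_LAYER_BOUNDS
# 0-30 cm thickness weights of the first three layers (topsoil averages)
_TOPSOIL_W = np.array([5.0, 10.0, 15.0]) / 30.0

_BASE36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the fine input grid and the coarse output grid.

    The coarse cell edge must be an integer multiple (``block``) of the
    fine cell edge.  Grids are north-up, row-major, WGS84 degrees.
    """

    shape_fine: tuple[int, int]
    west: float = 0.0
    south: float = 0.0
    fine_cellsize_deg: float = 1.0 / 120.0   # 30 arc-sec
    block: int = 10                           # -> 5 arc-min coarse cells
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        nr, nc = self.shape_fine
        if nr % self.block or nc % self.block:
            raise PipelineError(
                f"fine shape {self.shape_fine} not divisible by block {self.block}"
            )

    @property
    def shape_coarse(self) -> tuple[int, int]:
        return self.shape_fine[0] // self.block, self.shape_fine[1] // self.block

    @property
    def coarse_cellsize_deg(self) -> float:
        return self.fine_cellsize_deg * self.block

    @property
    def north(self) -> float:
        return self.south + self.shape_fine[0] * self.fine_cellsize_deg

    def coarse_cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of a coarse cell center; row 0 is the north edge."""
        cs = self.coarse_cellsize_deg
        lat = self.north - (row + 0.5) * cs
        lon = self.west + (col + 0.5) * cs
        return lat, lon


@dataclass
class InputStack:
    """Fine-resolution input grids: per property, one 2-D array per
    depth layer (NaN = nodata), plus an optional coarse country mask."""

    spec: GridSpec
    grids: dict[str, list[np.ndarray]]
    country_mask: np.ndarray | None = None       # coarse shape, int codes
    country_codes: dict[int, str] = dc_field(default_factory=dict)

    def validate(self) -> None:
        for prop in PROPERTIES:
            if prop not in self.grids:
                raise PipelineError(f"missing property grids: {prop}")
            if len(self.grids[prop]) != N_LAYERS:
                raise PipelineError(
                    f"{prop}: need {N_LAYERS} layer grids, got {len(self.grids[prop])}"
                )
            for arr in self.grids[prop]:
                if arr.shape != self.spec.shape_fine:
                    raise PipelineError(
                        f"{prop}: grid shape {arr.shape} != {self.spec.shape_fine}"
                    )
        if self.country_mask is not None:
            if self.country_mask.shape != self.spec.shape_coarse:
                raise PipelineError(
                    f"country mask shape {self.country_mask.shape} != "
                    f"coarse shape {self.spec.shape_coarse}"
                )

    # ---------------- file round trip (ESRI ASCII grids) ----------------

    @classmethod
    def from_directory(cls, directory: str | Path) -> "InputStack":
        """Load ``{prop}_l{1..6}.asc`` grids (plus optional
        ``country_mask.asc`` / ``country_codes.json``) from a directory."""
        d = Path(directory)
        grids: dict[str, list[np.ndarray]] = {}
        spec = None
        for prop in PROPERTIES:
            grids[prop] = []
            for li in range(1, N_LAYERS + 1):
                path = d / f"{prop}_l{li}.asc"
                if not path.exists():
                    raise PipelineError(f"missing input grid {path}")
                arr, meta = read_ascii_grid(path)
                if spec is None:
                    spec = GridSpec(
                        shape_fine=arr.shape,
                        west=meta["xllcorner"],
                        south=meta["yllcorner"],
                        fine_cellsize_deg=meta["cellsize"],
                        nodata=meta["nodata_value"],
                    )
                grids[prop].append(arr)
        mask = None
        codes: dict[int, str] = {}
        mask_path = d / "country_mask.asc"
        if mask_path.exists():
            marr, _ = read_ascii_grid(mask_path)
            mask = np.where(np.isfinite(marr), marr, 0).astype(int)
            codes_path = d / "country_codes.json"
            if codes_path.exists():
                codes = {int(k): v for k, v in json.loads(codes_path.read_text()).items()}
        stack = cls(spec=spec, grids=grids, country_mask=mask, country_codes=codes)
        stack.validate()
        return stack

    def to_directory(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for prop in PROPERTIES:
            for li, arr in enumerate(self.grids[prop], start=1):
                write_ascii_grid(
                    d / f"{prop}_l{li}.asc", arr,
                    self.spec.west, self.spec.south,
                    self.spec.fine_cellsize_deg, self.spec.nodata,
                )
        if self.country_mask is not None:
            write_ascii_grid(
                d / "country_mask.asc", self.country_mask.astype(float),
                self.spec.west, self.spec.south,
                self.spec.coarse_cellsize_deg, self.spec.nodata,
            )
            (d / "country_codes.json").write_text(
                json.dumps({str(k): v for k, v in sorted(self.country_codes.items())},
                           indent=1) + "\n"
            )
        return d


# ---------------------------------------------------------------------------
# raster text I/O

def write_ascii_grid(path, array, xllcorner, yllcorner, cellsize, nodata=-9999.0):
    """Write one 2-D array as an ESRI ASCII grid (NaN -> nodata)."""
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xllcorner!r}\n"
        f"yllcorner {yllcorner!r}\n"
        f"cellsize {cellsize!r}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n", encoding="ascii")
    return Path(path)


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; nodata becomes NaN.  Returns (array, meta)."""
    lines = Path(path).read_text(encoding="ascii").splitlines()
    meta: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, value = lines[i].split(None, 1)
        meta[key.lower()] = float(value)
        i += 1
    arr = np.loadtxt(lines[i:], dtype=float)
    arr = np.atleast_2d(arr)
    nodata = meta.get("nodata_value", -9999.0)
    arr = np.where(arr == nodata, np.nan, arr)
    if "ncols" in meta and arr.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise PipelineError(
            f"{path}: grid is {arr.shape}, header says "
            f"({int(meta['nrows'])}, {int(meta['ncols'])})"
        )
    meta.setdefault("xllcorner", 0.0)
    meta.setdefault("yllcorner", 0.0)
    meta.setdefault("cellsize", 1.0)
    meta["nodata_value"] = nodata
    return arr, meta


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# aggregation

def aggregate_block(fine_values, nodata_mask=None, min_valid_fraction=0.5):
    """Arithmetic mean of one coarse cell's block of fine pixels.

    Pixels that are NaN (or masked) are excluded; if the valid fraction
    falls below ``min_valid_fraction`` the cell is nodata (NaN).
    """
    vals = np.asarray(fine_values, dtype=float)
    valid = np.isfinite(vals)
    if nodata_mask is not None:
        valid &= ~np.asarray(nodata_mask, dtype=bool)
    frac = valid.sum() / vals.size
    if frac < min_valid_fraction or not valid.any():
        return float("nan")
    return float(vals[valid].mean())


def aggregate_grid(fine, block, min_valid_fraction=0.5):
    """Block-mean a fine grid to the coarse grid (vectorised).

    Returns (coarse values, valid-pixel fraction per coarse cell); cells
    below the valid-fraction threshold are NaN.
    """
    arr = np.asarray(fine, dtype=float)
    nr, nc = arr.shape
    blocks = arr.reshape(nr // block, block, nc // block, block)
    valid = np.isfinite(blocks)
    count = valid.sum(axis=(1, 3))
    total = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    frac = count / (block * block)
    mean = np.where(frac >= min_valid_fraction, mean, np.nan)
    return mean, frac


def renormalize_texture(sand, silt, clay):
    """Rescale independently averaged texture components to close at 100 %.

    Returns (sand, silt, clay, deviation) where deviation is the
    pre-rescale |sum - 100|.  Zero or invalid sums yield NaN components.
    Silt is computed as the closure remainder so the sum is exactly 100.
    """
    s = np.asarray(sand, dtype=float)
    si = np.asarray(silt, dtype=float)
    c = np.asarray(clay, dtype=float)
    total = s + si + c
    ok = np.isfinite(total) & (total > 0)
    dev = np.where(ok, np.abs(total - 100.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(ok, 100.0 / total, np.nan)
    s2 = s * scale
    c2 = c * scale
    si2 = 100.0 - s2 - c2
    if np.ndim(sand) == 0:
        return float(s2), float(si2), float(c2), float(dev)
    return s2, si2, c2, dev


# ---------------------------------------------------------------------------
# per-cell profile assembly

@dataclass
class CellInputs:
    """Aggregated inputs for one coarse cell: per output layer, closed
    texture, OC (g kg-1), bulk density (kg m-3), pH and CEC; optionally
    pre-aggregated hydraulic properties (when PTFs ran at fine scale)."""

    row: int
    col: int
    lat: float
    lon: float
    sand: Sequence[float]
    silt: Sequence[float]
    clay: Sequence[float]
    oc_g_kg: Sequence[float]
    bd_kg_m3: Sequence[float]
    ph: Sequence[float]
    cec: Sequence[float]
    valid_fraction: float = 1.0
    hydraulics: Mapping[str, Sequence[float]] | None = None
    flags: int = 0

    def is_complete(self) -> bool:
        arrays = [self.sand, self.silt, self.clay, self.oc_g_kg,
                  self.bd_kg_m3, self.ph, self.cec]
        if self.hydraulics is not None:
            arrays += [self.hydraulics[k] for k in
                       ("theta1500", "theta33", "thetaS", "ks_mm_h")]
        return all(
            len(a) == N_LAYERS and np.all(np.isfinite(np.asarray(a, dtype=float)))
            for a in arrays
        )


def encode_cell_id(iso: str, row: int, col: int, ncols: int) -> str:
    """10-character profile id: ISO alpha-2 + 8-char base-36 cell index."""
    idx = row * ncols + col
    digits = []
    for _ in range(8):
        idx, r = divmod(idx, 36)
        digits.append(_BASE36[r])
    return iso[:2].upper() + "".join(reversed(digits))


def decode_cell_id(profile_id: str, ncols: int) -> tuple[int, int]:
    """Recover (row, col) from a profile id built by :func:`encode_cell_id`."""
    idx = int(profile_id[2:], 36)
    return idx // ncols, idx % ncols


def build_cell_profile(
    cell: CellInputs,
    templates: Mapping[str, hc27.GenericProfileTemplate],
    config: Mapping,
    iso: str = "ZZ",
    ncols: int = 1,
) -> sol.SoilProfile | None:
    """Assemble one coarse cell's six-layer soil profile.

    Returns None (and logs the reason) for incomplete cells.  Pure
    function of its inputs.
    """
    if not cell.is_complete():
        logger.debug("cell (%d, %d) skipped: incomplete inputs", cell.row, cell.col)
        return None

    # hydraulics per layer: pre-aggregated (fine-stage PTFs) or derived here
    flags = int(cell.flags)
    if cell.hydraulics is not None:
        th1500 = list(cell.hydraulics["theta1500"])
        th33 = list(cell.hydraulics["theta33"])
        thS = list(cell.hydraulics["thetaS"])
        ks_cm = [v / 10.0 for v in cell.hydraulics["ks_mm_h"]]
    else:
        th1500, th33, thS, ks_cm = [], [], [], []
        for li in range(N_LAYERS):
            tex = ptf.TextureComposition(cell.sand[li], cell.clay[li], cell.silt[li])
            hyd = ptf.derive_layer_hydraulics(tex, cell.oc_g_kg[li])
            th1500.append(hyd.theta1500)
            th33.append(hyd.theta33)
            thS.append(hyd.thetaS)
            ks_cm.append(hyd.ks_cm_h)
            flags |= hyd.flags

    awc = hc27.compute_awc_1m(th33, th1500)

    # classification inputs are thickness-weighted over the 0-30 cm topsoil
    top_sand = float(np.dot(_TOPSOIL_W, np.asarray(cell.sand[:3], dtype=float)))
    top_clay = float(np.dot(_TOPSOIL_W, np.asarray(cell.clay[:3], dtype=float)))
    s2, si2, c2, _ = renormalize_texture(top_sand, 100.0 - top_sand - top_clay, top_clay)
    top_tex = ptf.TextureComposition(s2, c2, si2)
    oc_top_pct = float(np.dot(_TOPSOIL_W, np.asarray(cell.oc_g_kg[:3], dtype=float))) / 10.0

    tex_class = hc27.classify_texture(top_tex, config.get("texture_rule"))
    fert_class = hc27.classify_fertility(oc_top_pct, config.get("fertility_thresholds_pct"))
    depth_class = hc27.classify_rooting_depth(awc, tex_class, config.get("depth_lookup_mm"))
    key = hc27.select_generic_profile(tex_class, fert_class, depth_class)
    template = templates[key.profile_id]

    scheme = layermod.DEFAULT_SCHEME
    if config.get("layer_weight_scheme"):
        scheme = layermod.LayerWeightScheme.from_config(config["layer_weight_scheme"])
    srgf6 = layermod.remap_template_values(
        template.srgf_by_hc27_layer, scheme, clamp_unit=True)
    slni6 = layermod.remap_template_values(template.slni_by_hc27_layer, scheme)

    records = []
    for li in range(N_LAYERS):
        records.append(sol.SoilLayerRecord(
            slb=sol.STANDARD_SLB[li],
            slmh=sol.STANDARD_SLMH[li],
            slll=th1500[li],
            sdul=th33[li],
            ssat=thS[li],
            srgf=srgf6[li],
            ssks=ks_cm[li],
            sbdm=cell.bd_kg_m3[li] / 1000.0,
            sloc=cell.oc_g_kg[li] / 10.0,
            slcl=cell.clay[li],
            slsi=cell.silt[li],
            slcf=sol.MISSING,
            slni=slni6[li],
            slhw=cell.ph[li],
            slhb=sol.MISSING,
            scec=cell.cec[li],
        ))
    profile = sol.SoilProfile(
        profile_id=encode_cell_id(iso, cell.row, cell.col, ncols),
        source="GRIDSOL",
        texture_label=tex_class.value[0].upper(),
        depth_cm=sol.STANDARD_SLB[-1],
        description=(
            f"{tex_class.value}/{fert_class.value}/{depth_class.value}"
            f" from {key.profile_id}"
        ),
        site="Grid",
        country=iso,
        lat=round(cell.lat, 3),
        lon=round(cell.lon, 3),
        family=key.profile_id,
        surface=template.surface,
        layers=records,
    )
    profile.validate_standard_layers()
    return profile


def partition_by_country(
    cells: Sequence[tuple[int, int]],
    country_mask: np.ndarray | None,
    country_codes: Mapping[int, str],
    catchall_iso: str = "ZZ",
) -> dict[tuple[int, int], str]:
    """Assign each (row, col) coarse cell to an ISO code by its cell
    center (the mask is on the coarse grid, so center == cell lookup).
    Cells outside the mask go to the catch-all code."""
    if country_mask is None:
        logger.warning("no country mask supplied; writing a single combined file")
        return {rc: catchall_iso for rc in cells}
    out = {}
    for row, col in cells:
        code = int(country_mask[row, col])
        out[(row, col)] = country_codes.get(code, catchall_iso)
    return out


# ---------------------------------------------------------------------------
# the build

def run_build(
    stack: InputStack,
    out_dir: str | Path,
    config: Mapping | str | Path | None = None,
    bbox: tuple[float, float, float, float] | None = None,
    countries: Sequence[str] | None = None,
) -> dict:
    """Run the full pipeline and write per-country *.SOL files.

    Returns the run report (also written to ``out_dir/run_report.json``).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    stack.validate()
    spec = stack.spec
    if bbox is not None:
        stack = _crop_to_bbox(stack, bbox)
        spec = stack.spec
    block = spec.block
    mvf = cfg["min_valid_fraction"]
    nrc, ncc = spec.shape_coarse

    # 1. aggregate every property x layer to the coarse grid
    coarse: dict[str, list[np.ndarray]] = {p: [] for p in PROPERTIES}
    for prop in PROPERTIES:
        for arr in stack.grids[prop]:
            mean, _ = aggregate_grid(arr, block, mvf)
            coarse[prop].append(mean)

    # 2. close the texture components per layer
    renorm_dev_max = 0.0
    for li in range(N_LAYERS):
        s, si, c, dev = renormalize_texture(
            coarse["sand"][li], coarse["silt"][li], coarse["clay"][li])
        coarse["sand"][li], coarse["silt"][li], coarse["clay"][li] = s, si, c
        if np.any(np.isfinite(dev)):
            renorm_dev_max = max(renorm_dev_max, float(np.nanmax(dev)))

    # 3. hydraulic properties
    fine_pixels_clamped = 0
    hyd_coarse: list[dict[str, np.ndarray]] = []
    if cfg["ptf_stage"] == "fine":
        for li in range(N_LAYERS):
            h = ptf.derive_hydraulics_grid(
                stack.grids["sand"][li], stack.grids["clay"][li],
                stack.grids["oc"][li])
            fine_pixels_clamped += int(np.count_nonzero(h["flags"]))
            agg = {}
            for kname in ("theta1500", "theta33", "thetaS", "ks_mm_h"):
                agg[kname], _ = aggregate_grid(h[kname], block, mvf)
            flag_any = (h["flags"] > 0).astype(float)
            fmean, _ = aggregate_grid(flag_any, block, mvf)
            agg["clamped_fraction"] = fmean
            hyd_coarse.append(agg)
    else:
        for li in range(N_LAYERS):
            h = ptf.derive_hydraulics_grid(
                coarse["sand"][li], coarse["clay"][li], coarse["oc"][li])
            h["clamped_fraction"] = (h["flags"] > 0).astype(float)
            hyd_coarse.append(h)

    # 4. per-cell profiles, row-major
    templates = hc27.load_templates(cfg.get("template_dir"))
    cell_iso = partition_by_country(
        [(r, c) for r in range(nrc) for c in range(ncc)],
        stack.country_mask, stack.country_codes, cfg["catchall_iso"])
    wanted = {c.upper() for c in countries} if countries else None

    by_iso: dict[str, list[sol.SoilProfile]] = {}
    n_complete = n_skipped = n_clamped = 0
    class_counts: dict[str, int] = {}
    for row in range(nrc):
        for col in range(ncc):
            lat, lon = spec.coarse_cell_center(row, col)
            hyd = {
                k: [hyd_coarse[li][k][row, col] for li in range(N_LAYERS)]
                for k in ("theta1500", "theta33", "thetaS", "ks_mm_h")
            }
            clamped = any(
                np.nan_to_num(hyd_coarse[li]["clamped_fraction"][row, col]) > 0
                for li in range(N_LAYERS)
            )
            cell = CellInputs(
                row=row, col=col, lat=lat, lon=lon,
                sand=[coarse["sand"][li][row, col] for li in range(N_LAYERS)],
                silt=[coarse["silt"][li][row, col] for li in range(N_LAYERS)],
                clay=[coarse["clay"][li][row, col] for li in range(N_LAYERS)],
                oc_g_kg=[coarse["oc"][li][row, col] for li in range(N_LAYERS)],
                bd_kg_m3=[coarse["bd"][li][row, col] for li in range(N_LAYERS)],
                ph=[coarse["ph"][li][row, col] for li in range(N_LAYERS)],
                cec=[coarse["cec"][li][row, col] for li in range(N_LAYERS)],
                hydraulics=hyd,
            )
            iso = cell_iso[(row, col)]
            if wanted is not None and iso not in wanted:
                continue
            profile = build_cell_profile(cell, templates, cfg, iso=iso, ncols=ncc)
            if profile is None:
                n_skipped += 1
                continue
            n_complete += 1
            n_clamped += int(clamped)
            class_counts[profile.family] = class_counts.get(profile.family, 0) + 1
            by_iso.setdefault(iso, []).append(profile)

    # 5. emit per-country files (sorted, no empty files)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for iso in sorted(by_iso):
        path = out / f"{iso}.SOL"
        sol.write_sol(by_iso[iso], path)
        files[iso] = len(by_iso[iso])

    report = {
        "cells_total": nrc * ncc,
        "cells_complete": n_complete,
        "cells_skipped": n_skipped,
        "cells_clamped": n_clamped,
        "fine_pixels_clamped": fine_pixels_clamped,
        "texture_renorm_max_deviation_pct": renorm_dev_max,
        "profiles_per_country": files,
        "generic_class_counts": dict(sorted(class_counts.items())),
        "ptf_stage": cfg["ptf_stage"],
        "min_valid_fraction": mvf,
        "coarse_shape": [nrc, ncc],
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    logger.info("build complete: %d profiles in %d countries, %d cells skipped",
                n_complete, len(files), n_skipped)
    return report


def _crop_to_bbox(stack: InputStack, bbox) -> InputStack:
    """Crop the stack to the coarse cells intersecting (W, S, E, N)."""
    w, s, e, n = bbox
    spec = stack.spec
    cs = spec.coarse_cellsize_deg
    c0 = max(0, int(np.floor((w - spec.west) / cs)))
    c1 = min(spec.shape_coarse[1], int(np.ceil((e - spec.west) / cs)))
    r0 = max(0, int(np.floor((spec.north - n) / cs)))
    r1 = min(spec.shape_coarse[0], int(np.ceil((spec.north - s) / cs)))
    if r0 >= r1 or c0 >= c1:
        raise PipelineError(f"bbox {bbox} does not intersect the grid")
    b = spec.block
    new_spec = GridSpec(
        shape_fine=((r1 - r0) * b, (c1 - c0) * b),
        west=spec.west + c0 * cs,
        south=spec.north - r1 * cs,
        fine_cellsize_deg=spec.fine_cellsize_deg,
        block=b,
        nodata=spec.nodata,
    )
    grids = {
        p: [a[r0 * b:r1 * b, c0 * b:c1 * b] for a in stack.grids[p]]
        for p in PROPERTIES
    }
    mask = None
    if stack.country_mask is not None:
        mask = stack.country_mask[r0:r1, c0:c1]
    return InputStack(spec=new_spec, grids=grids, country_mask=mask,
                      country_codes=stack.country_codes)


def validate_sol_file(path: str | Path, standard_layers: bool = False) -> list[sol.SoilProfile]:
    """Parse a *.SOL file and validate every profile; returns them."""
    profiles = sol.read_sol(path)
    for p in profiles:
        if standard_layers:
            p.validate_standard_layers()
        else:
            p.validate()
    return profiles
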