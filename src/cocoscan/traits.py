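"""Agronomic and digital trait extraction from labelled CT volumes.

Two registries are computed per sample: 21 agronomic traits (the
quantities a breeder measures by hand -- lengths, perimeters, shapes and
weights) and 47 digital traits (voxel/mesh descriptors: volumes, surface
areas, enclosing/inscribed sphere and bounding-box ratios, maximal
cross/longitudinal section families, CT integrals and thicknesses).

Conventions: the z axis is the rotation axis (fruit stood upright), so
"length" is the vertical extent and "width" the maximal transverse
extent; bounding boxes are axis-aligned in that frame; perimeters are
measured on sub-pixel boundary contours; CT integrals use the
air = 0 / water = 200 value convention.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import find_contours
from skimage.morphology import skeletonize

from . import mesh3d
from .models import liquid_weight
from .phantom import LABEL_IDS

__all__ = [
    "AGRONOMIC_KEYS",
    "DIGITAL_KEYS",
    "TraitEntry",
    "TraitTable",
    "WeightConfig",
    "min_enclosing_sphere",
    "max_inscribed_sphere",
    "bounding_box",
    "max_sections",
    "ct_integral",
    "average_thickness",
    "classify_shape",
    "agronomic_traits",
    "digital_traits",
]

logger = logging.getLogger(__name__)

AGRONOMIC_KEYS = (
    "FS", "FLS", "FL", "ET", "FLP", "FW", "FP",
    "SP", "SLS", "SL", "SLP", "SW", "SAT",
    "FTW", "STW", "MW", "CW", "LAW", "SAW", "FDB", "FDBR",
)

#: The duplicated CT-integral abbreviation (coat vs copra) is
#: disambiguated as CoatCTIV / CopraCTIV; originals kept in metadata.
DIGITAL_KEYS = (
    "Vol", "Sa", "VolSaR",
    "CSVol", "CSVolR", "ISVol", "ISVolR",
    "BBVol", "BBVolR", "BBL", "BBW", "BBH",
    "MLSA", "LSPAR", "LSBRH", "LSBRW", "LSAR",
    "MCSA", "CSPAR", "CSBRH", "CSBRW", "CSBRAR",
    "SCTIV", "MCITV",
    "SVol", "SSa", "SVSAR",
    "SCSVol", "SCSVolR", "SISVol", "SISVolR",
    "SBBV", "SBBVR", "SBBL", "SBBW", "SBBH",
    "SMLSA", "SLSPAR", "SLSBRH", "SLSBRW", "SLSAR",
    "SAT", "CAT", "CVol", "MVol",
    "CoatCTIV", "CopraCTIV",
)

DIGITAL_KEY_ALIASES = {"CoatCTIV": "CCTIV", "CopraCTIV": "CCTIV"}


@dataclass
class TraitEntry:
    value: object  # float or category string; None when not measurable
    unit: str
    provenance: str  # voxel | mesh | section | model


@dataclass
class TraitTable:
    """Named trait registry (value, unit, provenance)."""

    entries: dict[str, TraitEntry]
    kind: str = ""  # "agronomic" | "digital"
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> TraitEntry:
        return self.entries[key]

    def value(self, key: str):
        return self.entries[key].value

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": k,
                    "value": e.value,
                    "unit": e.unit,
                    "provenance": e.provenance,
                }
                for k, e in self.entries.items()
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        d = {
            k: {"value": e.value, "unit": e.unit, "provenance": e.provenance}
            for k, e in self.entries.items()
        }
        Path(path).write_text(json.dumps({"kind": self.kind, "traits": d}, indent=2))


@dataclass
class WeightConfig:
    """Densities (g/mL) for direct weights plus optional fitted models.

    ``regression_models`` maps a weight trait key (e.g. "CW") to a fitted
    :class:`~cocoscan.models.RegressionModel` applied to the named
    predictor trait; ``dry_matter_fraction`` enables the solid-albumen dry
    biomass traits when a drying model has been calibrated.
    """

    densities: dict[str, float] = field(
        default_factory=lambda: {
            "epicarp": 1.05,
            "mesocarp": 0.45,
            "shell": 1.30,
            "solid_albumen": 1.02,
            "liquid_albumen": 1.00,
        }
    )
    regression_models: dict[str, tuple[object, str]] = field(default_factory=dict)
    dry_matter_fraction: float | None = None


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _circumsphere(pts: np.ndarray):
    """Smallest sphere through all given points (<= 4); the centre is
    solved inside the points' affine hull (a minimum-norm solution off
    the hull would inflate the radius)."""
    p0 = pts[0]
    if len(pts) == 1:
        return p0.copy(), 0.0
    V = (pts[1:] - p0).T  # 3 x (k-1) affine-hull basis
    A = 2.0 * (pts[1:] - p0)
    b = np.einsum("ij,ij->i", pts[1:], pts[1:]) - p0 @ p0 - A @ p0
    M = A @ V
    try:
        t = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        t, *_ = np.linalg.lstsq(M, b, rcond=None)
    c = p0 + V @ t
    return c, float(np.linalg.norm(pts[0] - c))


def _min_ball_small(pts: np.ndarray, tol=1e-10):
    """Exact minimal enclosing ball of <= ~5 points by subset enumeration."""
    best = None
    n = len(pts)
    for k in range(1, min(n, 4) + 1):
        for subset in itertools.combinations(range(n), k):
            c, r = _circumsphere(pts[list(subset)])
            if np.all(np.linalg.norm(pts - c, axis=1) <= r * (1 + tol) + tol):
                if best is None or r < best[1]:
                    best = (c, r, subset)
    return best


def min_enclosing_sphere(points: np.ndarray, tol: float = 1e-9):
    """Exact minimal enclosing sphere (centre, radius).

    Pivoting variant of Welzl's algorithm: keep a support set of at most
    four points; while some point lies outside, recompute the exact small
    ball of support + that point.  The radius strictly grows, so the loop
    terminates with the global optimum.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 3), axis=0)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if len(pts) <= 5:
        c, r, _ = _min_ball_small(pts, tol)
        return c, r
    c, r, subset = _min_ball_small(pts[:2], tol)
    support = pts[:2][list(subset)]
    for _ in range(10 * len(pts)):
        d = np.linalg.norm(pts - c, axis=1)
        far = int(np.argmax(d))
        if d[far] <= r * (1 + tol) + tol:
            break
        cand = np.vstack([support, pts[far]])
        c, r, subset = _min_ball_small(cand, tol)
        support = cand[list(subset)]
    return c, r


def max_inscribed_sphere(mask: np.ndarray, voxel_size_mm: float = 1.0):
    """Largest sphere inside the mask via the Euclidean distance transform.

    Radius = (max EDT - 0.5) voxels (the half-voxel keeps the ball inside
    the voxel cubes; a single-voxel mask yields half a voxel).  The centre
    is the lowest-index arg-max.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    edt = ndi.distance_transform_edt(mask)
    idx = np.unravel_index(int(np.argmax(edt)), edt.shape)
    r = max(float(edt[idx]) - 0.5, 0.5 if mask.sum() else 0.0)
    center = mesh3d._world_from_indices(
        np.array([idx]), mask.shape, voxel_size_mm
    )[0]
    return center, r * voxel_size_mm


def _extent(mask_any: np.ndarray) -> int:
    nz = np.nonzero(mask_any)[0]
    return int(nz[-1] - nz[0] + 1) if len(nz) else 0


def bounding_box(mask: np.ndarray, voxel_size_mm: float = 1.0):
    """Axis-aligned bounding box in the rotation-axis frame.

    Returns dict with L (z extent, the vertical fruit axis), W (y), H (x),
    BBVol and BBVolR (= voxel volume / box volume).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    L = _extent(mask.any(axis=(1, 2))) * voxel_size_mm
    W = _extent(mask.any(axis=(0, 2))) * voxel_size_mm
    H = _extent(mask.any(axis=(0, 1))) * voxel_size_mm
    bbvol = L * W * H
    vol = float(mask.sum()) * voxel_size_mm**3
    return {"L": L, "W": W, "H": H, "BBVol": bbvol, "BBVolR": vol / bbvol}


def _contour_perimeter(mask2d: np.ndarray, spacing: float = 1.0) -> float:
    """Sub-pixel outer boundary length of the largest structure (mm)."""
    if not mask2d.any():
        return 0.0
    padded = np.pad(mask2d.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    longest = max(contours, key=len)
    seg = np.diff(longest, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1]))) * spacing


def max_sections(
    mask: np.ndarray, voxel_size_mm: float = 1.0, angle_step_deg: float = 1.0
) -> dict[str, float]:
    """Maximal cross (axial) and longitudinal (axis-containing) sections.

    Cross sections are the axial slices; longitudinal sections are planes
    containing the z axis sampled at ``angle_step_deg`` rotations (the
    maximal-area plane is reported).  Returns MCSA/MLSA areas, perimeter
    ratios (perimeter / area), tight bounding-rectangle extents and aspect
    ratios.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vox = voxel_size_mm
    nz, ny, nx = mask.shape

    # cross sections: axial slices
    areas = mask.reshape(nz, -1).sum(axis=1)
    kmax = int(np.argmax(areas))
    cs = mask[kmax]
    mcsa = float(areas[kmax]) * vox**2
    cs_perim = _contour_perimeter(cs, vox)
    csbrh = _extent(cs.any(axis=1)) * vox  # y extent
    csbrw = _extent(cs.any(axis=0)) * vox  # x extent

    # longitudinal sections: sample planes through the z axis
    step = vox / 2.0
    rmax = max(nx, ny) / 2.0 * vox
    s = np.arange(-rmax, rmax + step / 2.0, step)
    z = np.arange(0, nz) * vox  # slice positions
    thetas = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    best = (-1.0, None, None)
    f = mask.astype(np.float32)
    Z, S = np.meshgrid(np.arange(nz, dtype=float), s / vox, indexing="ij")
    for th in thetas:
        ix = S * np.cos(th) + (nx - 1) / 2.0
        iy = S * np.sin(th) + (ny - 1) / 2.0
        sec_f = ndi.map_coordinates(
            f, np.stack([Z, np.broadcast_to(iy, Z.shape), np.broadcast_to(ix, Z.shape)]),
            order=1, mode="constant", cval=0.0,
        )
        area = float(sec_f.sum()) * vox * step  # linear interp integrates partial cells
        sec = sec_f >= 0.5
        if area > best[0]:
            best = (area, sec, th)
    mlsa, sec, _ = best
    # the section grid is anisotropic (vox along z, step along s)
    sec_perim = _contour_perimeter_aniso(sec, vox, step)
    lsbrh = _extent(sec.any(axis=1)) * vox  # z extent
    lsbrw = _extent(sec.any(axis=0)) * step

    return {
        "MCSA": mcsa,
        "CSPAR": cs_perim / mcsa if mcsa > 0 else np.nan,
        "CSBRH": csbrh,
        "CSBRW": csbrw,
        "CSBRAR": csbrh / csbrw if csbrw > 0 else np.nan,
        "MLSA": mlsa,
        "LSPAR": sec_perim / mlsa if mlsa > 0 else np.nan,
        "LSBRH": lsbrh,
        "LSBRW": lsbrw,
        "LSAR": lsbrh / lsbrw if lsbrw > 0 else np.nan,
    }


def _contour_perimeter_aniso(mask2d, spacing_r, spacing_c) -> float:
    if not mask2d.any():
        return 0.0
    padded = np.pad(mask2d.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    longest = max(contours, key=len)
    seg = np.diff(longest, axis=0)
    return float(np.sum(np.hypot(seg[:, 0] * spacing_r, seg[:, 1] * spacing_c)))


def ct_integral(ct_values, mask: np.ndarray, voxel_size_mm: float = 1.0) -> float:
    """Sum of CT values over the mask times the voxel volume (ct * mm^3),
    a density-weighted mass proxy."""
    values = np.asarray(getattr(ct_values, "values", ct_values), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    return float(values[mask].sum()) * voxel_size_mm**3


def average_thickness(mask: np.ndarray, voxel_size_mm: float = 1.0) -> float:
    """Mean local thickness of a shell/layer-like mask (mm).

    Local thickness = 2 x EDT sampled on the morphological skeleton
    (medial surface); if the mask is too thin to skeletonize the mean is
    taken over all mask voxels instead (flagged in the log).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    edt = ndi.distance_transform_edt(mask)
    skel = skeletonize(mask)
    if not skel.any():
        logger.warning("skeleton empty; averaging 2*EDT over the full mask")
        return float(2.0 * edt[mask].mean()) * voxel_size_mm
    return float(2.0 * edt[skel].mean()) * voxel_size_mm


def classify_shape(
    length: float, width: float, rho_round: float = 1.05, rho_oblong: float = 1.25
) -> str:
    """Rule-based shape category from the length/width ratio.

    ratio >= rho_oblong -> "oblong"; >= rho_round -> "oval"; else "round".
    """
    if width <= 0:
        raise ValueError("width must be positive")
    ratio = length / width
    if ratio >= rho_oblong:
        return "oblong"
    if ratio >= rho_round:
        return "oval"
    return "round"


# ---------------------------------------------------------------------------
# registries
# ---------------------------------------------------------------------------

def _sphere_box_traits(mask, vox, prefix=""):
    """CSVol/ISVol/BB trait block for one mask."""
    vol = float(mask.sum()) * vox**3
    boundary = mesh3d.boundary_points(
        _labels_from_mask(mask), 1, voxel_size_mm=vox
    )
    # enclose the voxel cubes, not only their centres
    corners = (
        boundary[:, None, :]
        + np.array(list(itertools.product([-0.5, 0.5], repeat=3))) * vox
    ).reshape(-1, 3)
    _, r_cs = min_enclosing_sphere(corners)
    csvol = 4.0 / 3.0 * np.pi * r_cs**3
    _, r_is = max_inscribed_sphere(mask, vox)
    isvol = 4.0 / 3.0 * np.pi * r_is**3
    bb = bounding_box(mask, vox)
    return {
        f"{prefix}CSVol": csvol,
        f"{prefix}CSVolR": vol / csvol,
        f"{prefix}ISVol": isvol,
        f"{prefix}ISVolR": isvol / vol,
    }, bb, vol


def _labels_from_mask(mask):
    return mask.astype(np.uint8)  # label id 1


def _mask_of(labels, name):
    return np.asarray(labels) == LABEL_IDS[name]


def digital_traits(
    labels: np.ndarray,
    ct_volume,
    voxel_size_mm: float | None = None,
    meshes: dict[str, "mesh3d.SurfaceMesh"] | None = None,
    angle_step_deg: float = 1.0,
) -> TraitTable:
    """The 47-entry digital trait registry for one segmented sample.

    Whole-fruit descriptors, the shell ("S"-prefixed) block, thicknesses,
    copra/milk volumes and CT integrals.  Surface areas come from the
    compartment meshes (built on demand when not supplied).
    """
    labels = np.asarray(getattr(labels, "labels", labels))
    vox = voxel_size_mm or getattr(ct_volume, "voxel_size_mm", 1.0)
    ct = np.asarray(getattr(ct_volume, "values", ct_volume), dtype=float)
    meshes = meshes or {}
    E: dict[str, TraitEntry] = {}

    def put(key, value, unit, prov):
        E[key] = TraitEntry(value, unit, prov)

    fruit = labels != 0
    if not fruit.any():
        raise ValueError("no foreground voxels")

    def _area(mask, name):
        if name in meshes:
            return mesh3d.mesh_area(meshes[name])
        hull = ndi.binary_fill_holes(mask)
        # light smoothing removes the marching-cubes staircase (~8% area
        # inflation on a binary grid) without moving the surface
        return mesh3d.mesh_area(
            mesh3d.mesh_from_mask(hull, vox, name, smooth_sigma=1.0)
        )

    sph, bb, vol = _sphere_box_traits(fruit, vox)
    sa = _area(fruit, "fruit")
    put("Vol", vol, "mm^3", "voxel")
    put("Sa", sa, "mm^2", "mesh")
    put("VolSaR", vol / sa, "mm", "mesh")
    for k, v in sph.items():
        put(k, v, "mm^3" if "R" not in k else "", "voxel")
    put("BBVol", bb["BBVol"], "mm^3", "voxel")
    put("BBVolR", bb["BBVolR"], "", "voxel")
    put("BBL", bb["L"], "mm", "voxel")
    put("BBW", bb["W"], "mm", "voxel")
    put("BBH", bb["H"], "mm", "voxel")
    secs = max_sections(fruit, vox, angle_step_deg)
    for k in ("MLSA", "LSPAR", "LSBRH", "LSBRW", "LSAR", "MCSA", "CSPAR", "CSBRH", "CSBRW", "CSBRAR"):
        unit = "mm^2" if k.endswith("SA") else ("1/mm" if k.endswith("PAR") else ("" if k.endswith("AR") else "mm"))
        put(k, secs[k], unit, "section")

    shell = _mask_of(labels, "shell")
    liquid = _mask_of(labels, "liquid_albumen")
    solid = _mask_of(labels, "solid_albumen")
    epicarp = _mask_of(labels, "epicarp")

    put("SCTIV", ct_integral(ct, shell, vox) if shell.any() else None, "ct*mm^3", "voxel")
    put("MCITV", ct_integral(ct, liquid, vox) if liquid.any() else None, "ct*mm^3", "voxel")

    if shell.any():
        ssph, sbb, svol = _sphere_box_traits(shell, vox, prefix="S")
        hull_area = _area(shell, "shell")
        put("SVol", svol, "mm^3", "voxel")
        put("SSa", hull_area, "mm^2", "mesh")
        put("SVSAR", svol / hull_area, "mm", "mesh")
        for k, v in ssph.items():
            put(k, v, "mm^3" if "R" not in k else "", "voxel")
        put("SBBV", sbb["BBVol"], "mm^3", "voxel")
        put("SBBVR", sbb["BBVolR"], "", "voxel")
        put("SBBL", sbb["L"], "mm", "voxel")
        put("SBBW", sbb["W"], "mm", "voxel")
        put("SBBH", sbb["H"], "mm", "voxel")
        ssecs = max_sections(shell, vox, angle_step_deg)
        put("SMLSA", ssecs["MLSA"], "mm^2", "section")
        put("SLSPAR", ssecs["LSPAR"], "1/mm", "section")
        put("SLSBRH", ssecs["LSBRH"], "mm", "section")
        put("SLSBRW", ssecs["LSBRW"], "mm", "section")
        put("SLSAR", ssecs["LSAR"], "", "section")
        put("SAT", average_thickness(shell, vox), "mm", "voxel")
    else:
        for k in ("SVol", "SSa", "SVSAR", "SCSVol", "SCSVolR", "SISVol",
                  "SISVolR", "SBBV", "SBBVR", "SBBL", "SBBW", "SBBH",
                  "SMLSA", "SLSPAR", "SLSBRH", "SLSBRW", "SLSAR", "SAT"):
            put(k, None, "", "voxel")

    put("CAT", average_thickness(solid, vox) if solid.any() else None, "mm", "voxel")
    put("CVol", float(solid.sum()) * vox**3 if solid.any() else None, "mm^3", "voxel")
    put("MVol", float(liquid.sum()) * vox**3 if liquid.any() else None, "mm^3", "voxel")
    put("CoatCTIV", ct_integral(ct, epicarp, vox) if epicarp.any() else None, "ct*mm^3", "voxel")
    put("CopraCTIV", ct_integral(ct, solid, vox) if solid.any() else None, "ct*mm^3", "voxel")

    ordered = {k: E[k] for k in DIGITAL_KEYS}
    return TraitTable(ordered, kind="digital", metadata={"aliases": DIGITAL_KEY_ALIASES})


def agronomic_traits(
    labels: np.ndarray,
    ct_volume,
    voxel_size_mm: float | None = None,
    meshes: dict | None = None,
    weights: WeightConfig | None = None,
    angle_step_deg: float = 1.0,
) -> TraitTable:
    """The 21-entry agronomic trait registry.

    Geometric traits are measured on the labelled volume; weight traits
    come from compartment densities or configured regression models; the
    dry-biomass traits require a calibrated drying model and are reported
    missing otherwise.
    """
    labels = np.asarray(getattr(labels, "labels", labels))
    vox = voxel_size_mm or getattr(ct_volume, "voxel_size_mm", 1.0)
    ct = np.asarray(getattr(ct_volume, "values", ct_volume), dtype=float)
    w = weights or WeightConfig()
    E: dict[str, TraitEntry] = {}

    def put(key, value, unit, prov):
        E[key] = TraitEntry(value, unit, prov)

    fruit = labels != 0
    seed_mask = np.isin(labels, [LABEL_IDS["shell"], LABEL_IDS["solid_albumen"],
                                 LABEL_IDS["liquid_albumen"], LABEL_IDS["cavity"]])
    if not fruit.any():
        raise ValueError("no foreground voxels")

    def _lw(mask):
        bbox = bounding_box(mask, vox)
        return bbox["L"], max(bbox["W"], bbox["H"])

    fl, fw = _lw(fruit)
    fsecs = max_sections(fruit, vox, angle_step_deg)
    put("FL", fl, "mm", "voxel")
    put("FW", fw, "mm", "voxel")
    put("FP", _contour_perimeter_of_max_slice(fruit, vox), "mm", "section")
    put("FLP", _longitudinal_perimeter(fsecs), "mm", "section")
    put("FS", classify_shape(fl, fw), "", "section")
    put("FLS", classify_shape(fsecs["LSBRH"], fsecs["LSBRW"]), "", "section")

    shell = _mask_of(labels, "shell")
    solid = _mask_of(labels, "solid_albumen")
    liquid = _mask_of(labels, "liquid_albumen")
    meso = _mask_of(labels, "mesocarp")

    put("ET", average_thickness(shell, vox) if shell.any() else None, "mm", "voxel")
    put("SAT", average_thickness(solid, vox) if solid.any() else None, "mm", "voxel")

    if seed_mask.any():
        sl, sw = _lw(seed_mask)
        ssecs = max_sections(seed_mask, vox, angle_step_deg)
        put("SL", sl, "mm", "voxel")
        put("SW", sw, "mm", "voxel")
        put("SLP", _longitudinal_perimeter(ssecs), "mm", "section")
        put("SP", classify_shape(sl, sw), "", "section")
        put("SLS", classify_shape(ssecs["LSBRH"], ssecs["LSBRW"]), "", "section")
    else:
        for k in ("SL", "SW", "SLP", "SP", "SLS"):
            put(k, None, "", "voxel")

    # weight traits: densities or configured regression models
    def _weight(mask, name):
        if not mask.any():
            return None
        return liquid_weight(float(mask.sum()) * vox**3, w.densities[name])

    vols = {
        name: float(_mask_of(labels, name).sum()) * vox**3
        for name in ("epicarp", "mesocarp", "shell", "solid_albumen", "liquid_albumen")
    }
    ftw = sum(
        liquid_weight(v, w.densities[n]) for n, v in vols.items() if v > 0
    )
    stw = sum(
        liquid_weight(vols[n], w.densities[n])
        for n in ("shell", "solid_albumen", "liquid_albumen")
        if vols[n] > 0
    )
    put("FTW", ftw if fruit.any() else None, "g", "model")
    put("STW", stw if seed_mask.any() else None, "g", "model")
    put("MW", _weight(meso, "mesocarp"), "g", "model")
    put("LAW", _weight(liquid, "liquid_albumen"), "g", "model")
    put("SAW", _weight(solid, "solid_albumen"), "g", "model")

    cw = _weight(solid, "solid_albumen")
    if "CW" in w.regression_models and solid.any():
        model, predictor = w.regression_models["CW"]
        x = ct_integral(ct, solid, vox) if predictor == "CopraCTIV" else vols["solid_albumen"]
        cw = float(model.predict([x])[0])
    put("CW", cw, "g", "model")

    if w.dry_matter_fraction is not None and solid.any():
        fdb = (cw or 0.0) * w.dry_matter_fraction
        put("FDB", fdb, "g", "model")
        put("FDBR", w.dry_matter_fraction, "", "model")
    else:
        put("FDB", None, "g", "model")
        put("FDBR", None, "", "model")

    ordered = {k: E[k] for k in AGRONOMIC_KEYS}
    return TraitTable(ordered, kind="agronomic")


def _contour_perimeter_of_max_slice(mask, vox):
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    return _contour_perimeter(mask[int(np.argmax(areas))], vox)


def _longitudinal_perimeter(secs) -> float:
    return secs["LSPAR"] * secs["MLSA"]
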