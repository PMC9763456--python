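"""Parametric coconut fruit/seed voxel phantoms.

A coconut fruit is modelled as a nest of quasi-ellipsoidal compartments,
from outside in: epicarp (skin), mesocarp (fibrous husk), shell (endocarp),
solid albumen (copra) and the lumen holding liquid albumen (coconut water)
with an optional air cavity above the liquid level.  Each compartment
carries a monochromatic X-ray attenuation coefficient so the phantom can be
pushed through the full simulate -> reconstruct -> segment -> measure
pipeline, and every compartment has a closed-form ground-truth volume so
each downstream stage is checkable without real scans.

Conventions: volume arrays are indexed ``[z, y, x]``; the z axis is the
rotation (vertical) axis; world coordinates are in mm with the origin at
the grid centre and voxel centres at ``(i - (n-1)/2) * voxel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "PhantomSpec",
    "GroundTruth",
    "LABEL_IDS",
    "LABEL_NAMES",
    "MU_WATER",
    "make_fruit_phantom",
    "make_water_cylinder",
    "fruit_spec",
    "seed_spec",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "ellipsoid_cap_volume",
]

#: Default water attenuation in mm^-1 (order of magnitude of soft tissue
#: at the tube voltages used for fruit imaging).
MU_WATER = 0.02

LABEL_IDS = {
    "background": 0,
    "epicarp": 1,
    "mesocarp": 2,
    "shell": 3,
    "solid_albumen": 4,
    "liquid_albumen": 5,
    "cavity": 6,
}
LABEL_NAMES = {v: k for k, v in LABEL_IDS.items()}

_KNUD_THOMSEN_P = 1.6075


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of an ellipsoid with semi-axes a, b, c (mm^3)."""
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Knud-Thomsen approximation of the ellipsoid surface area (mm^2).

    Exact for spheres, relative error below ~1.1% in general.
    """
    p = _KNUD_THOMSEN_P
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * np.pi * s ** (1.0 / p)


def ellipsoid_cap_volume(a: float, b: float, c: float, z0: float) -> float:
    """Volume of the ellipsoid region above the plane z = z0.

    ``z0`` is relative to the ellipsoid centre; valid for -c <= z0 <= c.
    """
    if z0 <= -c:
        return ellipsoid_volume(a, b, c)
    if z0 >= c:
        return 0.0
    return np.pi * a * b * (2.0 * c / 3.0 - z0 + z0**3 / (3.0 * c**2))


@dataclass(frozen=True)
class Compartment:
    """One nested compartment: its *outer* ellipsoid and attenuation."""

    name: str
    semi_axes_mm: tuple[float, float, float]  # (ax, ay, az)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (cx, cy, cz)
    mu: float = 0.0  # attenuation, mm^-1

    def __post_init__(self) -> None:
        if self.name not in LABEL_IDS or self.name in ("background", "cavity"):
            raise ValueError(f"unknown compartment name: {self.name!r}")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError(f"{self.name}: semi-axes must be positive")
        if self.mu < 0:
            raise ValueError(f"{self.name}: attenuation must be >= 0")


@dataclass
class PhantomSpec:
    """Parametric nested-compartment phantom description.

    Parameters
    ----------
    grid_shape
        Voxels per axis, ``(nz, ny, nx)``.
    voxel_size_mm
        Isotropic voxel spacing.
    compartments
        Ordered outside-in.  Compartment ``i`` occupies its ellipsoid minus
        the ellipsoid of compartment ``i+1``; the innermost compartment
        (normally ``liquid_albumen``) fills its whole ellipsoid, the lumen.
    cavity_fraction
        Fraction of the lumen height (top-down) assigned to an air cavity
        above the liquid level, in [0, 1].
    seed, roughness_mm
        Seeded smooth radial perturbation of the outermost surface;
        ``roughness_mm = 0`` keeps the closed-form ground truth exact.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    compartments: list[Compartment]
    cavity_fraction: float = 0.0
    seed: int = 0
    roughness_mm: float = 0.0
    mu_water: float = MU_WATER
    supersample: bool = False

    def validate(self) -> None:
        nz, ny, nx = self.grid_shape
        if min(nz, ny, nx) < 1 or self.voxel_size_mm <= 0:
            raise ValueError("invalid grid")
        if not self.compartments:
            raise ValueError("at least one compartment required")
        if not 0.0 <= self.cavity_fraction <= 1.0:
            raise ValueError("cavity_fraction must be in [0, 1]")
        # outermost compartment fits with a >= 2-voxel margin
        outer = self.compartments[0]
        half = (
            np.array([nx, ny, nz]) * self.voxel_size_mm / 2.0
            - 2.0 * self.voxel_size_mm
        )
        ext = np.abs(np.array(outer.center_mm)) + np.array(outer.semi_axes_mm)
        if np.any(ext + self.roughness_mm > half):
            raise ValueError(
                f"compartment {outer.name!r} exceeds the grid "
                f"(needs {ext} mm, available {half} mm)"
            )
        # strict nesting, accounting for centre offsets
        for out, inn in zip(self.compartments, self.compartments[1:]):
            off = np.abs(np.array(inn.center_mm) - np.array(out.center_mm))
            if np.any(off + np.array(inn.semi_axes_mm) >= np.array(out.semi_axes_mm)):
                raise ValueError(
                    f"nesting violation: {inn.name!r} does not fit strictly "
                    f"inside {out.name!r}"
                )

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "cavity_fraction": self.cavity_fraction,
            "seed": self.seed,
            "roughness_mm": self.roughness_mm,
            "mu_water": self.mu_water,
            "compartments": [
                {
                    "name": c.name,
                    "semi_axes_mm": list(c.semi_axes_mm),
                    "center_mm": list(c.center_mm),
                    "mu": c.mu,
                }
                for c in self.compartments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            voxel_size_mm=float(d["voxel_size_mm"]),
            compartments=[
                Compartment(
                    name=c["name"],
                    semi_axes_mm=tuple(c["semi_axes_mm"]),
                    center_mm=tuple(c.get("center_mm", (0, 0, 0))),
                    mu=float(c.get("mu", 0.0)),
                )
                for c in d["compartments"]
            ],
            cavity_fraction=float(d.get("cavity_fraction", 0.0)),
            seed=int(d.get("seed", 0)),
            roughness_mm=float(d.get("roughness_mm", 0.0)),
            mu_water=float(d.get("mu_water", MU_WATER)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Closed-form per-compartment truth plus voxel-count ('digital') truth."""

    volume_mm3: dict[str, float]
    voxel_volume_mm3: dict[str, float]
    surface_area_mm2: dict[str, float]  # Knud-Thomsen, approximate
    axis_lengths_mm: dict[str, tuple[float, float, float]]
    ct_integral: dict[str, float]  # CT value x volume, air=0/water=200
    total_volume_mm3: float = 0.0
    voxel_size_mm: float = 0.0

    def to_json(self, path: str | Path) -> None:
        d = {
            k: getattr(self, k)
            for k in (
                "volume_mm3",
                "voxel_volume_mm3",
                "surface_area_mm2",
                "axis_lengths_mm",
                "ct_integral",
                "total_volume_mm3",
                "voxel_size_mm",
            )
        }
        Path(path).write_text(json.dumps(d, indent=2, default=list))


def _world_coords(grid_shape, voxel_size):
    nz, ny, nx = grid_shape
    z = (np.arange(nz) - (nz - 1) / 2.0) * voxel_size
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size
    return (
        z[:, None, None],
        y[None, :, None],
        x[None, None, :],
    )


def _roughness_field(grid_shape, seed, amplitude_mm):
    """Seeded smooth random field in mm, zero-mean, for surface perturbation."""
    from scipy.ndimage import zoom

    rng = np.random.RandomState(seed)
    coarse = rng.standard_normal((7, 7, 7))
    factors = [s / 7.0 for s in grid_shape]
    f = zoom(coarse, factors, order=3)[
        : grid_shape[0], : grid_shape[1], : grid_shape[2]
    ]
    f -= f.mean()
    m = np.abs(f).max()
    return f / m * amplitude_mm if m > 0 else f


def make_fruit_phantom(spec: PhantomSpec):
    """Rasterize a phantom spec into attenuation + label volumes with truth.

    Returns ``(mu_volume, label_volume, ground_truth)``.  Membership is
    decided at voxel centres so the voxel-count truth is exact and
    deterministic; pass ``spec.supersample=True`` for 2x antialiased
    attenuation (labels stay centre-sampled).
    """
    spec.validate()
    vox = spec.voxel_size_mm
    zz, yy, xx = _world_coords(spec.grid_shape, vox)

    rough = None
    if spec.roughness_mm > 0:
        rough = _roughness_field(spec.grid_shape, spec.seed, spec.roughness_mm)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    inner_mask = None
    for idx, comp in enumerate(spec.compartments):
        ax, ay, az = comp.semi_axes_mm
        cx, cy, cz = comp.center_mm
        r2 = (
            ((xx - cx) / ax) ** 2
            + ((yy - cy) / ay) ** 2
            + ((zz - cz) / az) ** 2
        )
        if idx == 0 and rough is not None:
            amax = max(comp.semi_axes_mm)
            inside = np.sqrt(r2) <= 1.0 + rough / amax
        else:
            inside = r2 <= 1.0
        labels[inside] = LABEL_IDS[comp.name]
        inner_mask = inside

    # liquid/cavity partition: lumen voxels above the level plane
    lumen = spec.compartments[-1]
    if spec.cavity_fraction > 0 and lumen.name == "liquid_albumen":
        cz = lumen.center_mm[2]
        c = lumen.semi_axes_mm[2]
        z0 = cz + c * (1.0 - 2.0 * spec.cavity_fraction)
        cavity = inner_mask & (zz + np.zeros_like(labels, dtype=float) > z0)
        labels[cavity] = LABEL_IDS["cavity"]

    mu_by_label = np.zeros(7)
    for comp in spec.compartments:
        mu_by_label[LABEL_IDS[comp.name]] = comp.mu
    mu = mu_by_label[labels]

    if spec.supersample:
        mu = _supersampled_mu(spec)

    gt = _ground_truth(spec, labels)
    return mu, labels, gt


def _supersampled_mu(spec: PhantomSpec):
    """2x supersampled attenuation volume (partial-volume averaged)."""
    fine = PhantomSpec(
        grid_shape=tuple(2 * s for s in spec.grid_shape),
        voxel_size_mm=spec.voxel_size_mm / 2.0,
        compartments=spec.compartments,
        cavity_fraction=spec.cavity_fraction,
        seed=spec.seed,
        roughness_mm=spec.roughness_mm,
        mu_water=spec.mu_water,
        supersample=False,
    )
    mu_fine, _, _ = make_fruit_phantom(fine)
    nz, ny, nx = spec.grid_shape
    return (
        mu_fine.reshape(nz, 2, ny, 2, nx, 2).mean(axis=(1, 3, 5))
    )


def _ground_truth(spec: PhantomSpec, labels) -> GroundTruth:
    vox3 = spec.voxel_size_mm**3
    vols: dict[str, float] = {}
    areas: dict[str, float] = {}
    axes: dict[str, tuple[float, float, float]] = {}
    cts: dict[str, float] = {}

    ell_vols = [ellipsoid_volume(*c.semi_axes_mm) for c in spec.compartments]
    for i, comp in enumerate(spec.compartments):
        v = ell_vols[i] - (ell_vols[i + 1] if i + 1 < len(ell_vols) else 0.0)
        vols[comp.name] = v
        areas[comp.name] = ellipsoid_surface_area(*comp.semi_axes_mm)
        axes[comp.name] = tuple(2.0 * s for s in comp.semi_axes_mm)

    lumen = spec.compartments[-1]
    if spec.cavity_fraction > 0 and lumen.name == "liquid_albumen":
        a, b, c = lumen.semi_axes_mm
        z0 = c * (1.0 - 2.0 * spec.cavity_fraction)
        vcav = ellipsoid_cap_volume(a, b, c, z0)
        vols["cavity"] = vcav
        vols["liquid_albumen"] = ell_vols[-1] - vcav
        axes["cavity"] = (2 * a, 2 * b, 2 * c * spec.cavity_fraction)

    for comp in spec.compartments:
        ct = 200.0 * comp.mu / spec.mu_water
        cts[comp.name] = ct * vols[comp.name]
    if "cavity" in vols:
        cts["cavity"] = 0.0

    voxel_vols = {
        name: float((labels == lid).sum()) * vox3
        for name, lid in LABEL_IDS.items()
        if name != "background" and (labels == lid).any()
    }
    return GroundTruth(
        volume_mm3=vols,
        voxel_volume_mm3=voxel_vols,
        surface_area_mm2=areas,
        axis_lengths_mm=axes,
        ct_integral=cts,
        total_volume_mm3=ell_vols[0],
        voxel_size_mm=spec.voxel_size_mm,
    )


def make_water_cylinder(
    radius_mm: float,
    height_mm: float,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    mu_water: float = MU_WATER,
):
    """Axis-aligned (z) water cylinder attenuation volume, the air=0/water=200
    calibration fixture."""
    if radius_mm < 0 or height_mm < 0:
        raise ValueError("radius and height must be >= 0")
    nz, ny, nx = grid_shape
    half = np.array([nx, ny, nz]) * voxel_size_mm / 2.0
    if radius_mm > half[0] or radius_mm > half[1] or height_mm / 2.0 > half[2]:
        raise ValueError("cylinder exceeds the grid")
    zz, yy, xx = _world_coords(grid_shape, voxel_size_mm)
    inside = (xx**2 + yy**2 <= radius_mm**2) & (np.abs(zz) <= height_mm / 2.0)
    return np.where(inside, mu_water, 0.0)


def fruit_spec(
    grid_shape=(128, 128, 128),
    voxel_size_mm=1.0,
    cavity_fraction=0.25,
    mature=True,
    mu_water=MU_WATER,
    seed=0,
) -> PhantomSpec:
    """Reference mature coconut fruit phantom.

    Semi-axes are scaled so the fruit fills the grid with margin; a mature
    fruit has a dry fibrous mesocarp (low attenuation) while a young one is
    water-laden (0.9 x water).
    """
    mw = mu_water
    mu_meso = 0.4 * mw if mature else 0.9 * mw
    scale = min(grid_shape[2] * voxel_size_mm / 128.0, 1.0e9)
    s = scale
    comps = [
        Compartment("epicarp", (45 * s, 45 * s, 55 * s), mu=1.8 * mw),
        Compartment("mesocarp", (42 * s, 42 * s, 52 * s), mu=mu_meso),
        Compartment("shell", (30 * s, 30 * s, 40 * s), mu=1.8 * mw),
        Compartment("solid_albumen", (25 * s, 25 * s, 35 * s), mu=1.05 * mw),
        Compartment("liquid_albumen", (19 * s, 19 * s, 29 * s), mu=mw),
    ]
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        compartments=comps,
        cavity_fraction=cavity_fraction,
        mu_water=mu_water,
        seed=seed,
    )


def seed_spec(
    grid_shape=(128, 128, 128),
    voxel_size_mm=0.6,
    cavity_fraction=0.35,
    mu_water=MU_WATER,
    seed=0,
) -> PhantomSpec:
    """Reference dehusked coconut seed phantom (no epicarp/mesocarp)."""
    mw = mu_water
    s = min(grid_shape[2] * voxel_size_mm / 76.8, 1.0e9)
    comps = [
        Compartment("shell", (30 * s, 30 * s, 34 * s), mu=1.8 * mw),
        Compartment("solid_albumen", (25 * s, 25 * s, 29 * s), mu=1.05 * mw),
        Compartment("liquid_albumen", (19 * s, 19 * s, 23 * s), mu=mw),
    ]
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        compartments=comps,
        cavity_fraction=cavity_fraction,
        mu_water=mu_water,
        seed=seed,
    )
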