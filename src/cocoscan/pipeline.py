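"""End-to-end pipeline orchestration.

``run_pipeline`` drives simulate -> calibrate -> reconstruct -> segment ->
mesh -> traits (-> optional model fitting) from one configuration, writes
every intermediate product and emits a manifest with per-stage checksums
so a fixed seed reproduces the run bit-for-bit (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io, mesh3d, traits as traits_mod
from .acquisition import ConeBeamGeometry, calibrate_projections, forward_project
from .phantom import LABEL_IDS, PhantomSpec, fruit_spec, make_fruit_phantom
from .recon import Volume, fdk_reconstruct, normalize_ct, to_grayscale8
from .segment import SeedSpec, SegParams, segment_volume

__all__ = ["PipelineConfig", "run_pipeline", "default_seeds_for"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reference run needs.

    ``phantom_spec`` may be a :class:`PhantomSpec`, a YAML path, or None
    for the built-in reference fruit; ``grid`` and ``voxel_size_mm``
    define the reconstruction grid; ``seeds`` may be None to derive
    albumen seeds automatically from the phantom labels (simulation runs
    only).
    """

    output_dir: str | Path
    phantom_spec: object = None
    geometry: str = "fruit"  # "fruit" | "seed" (desk-scaled for simulation)
    n_angles: int = 180
    detector_pixels: int = 192
    grid: tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: float = 1.0
    seeds: SeedSpec | None = None
    seg_params: SegParams = field(default_factory=SegParams)
    filter_window: str = "hann"
    seed: int = 0
    log_level: str = "INFO"


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def default_seeds_for(labels: np.ndarray, mid: int | None = None) -> SeedSpec:
    """Derive albumen seed points from a label slice (phantom runs stand in
    for the operator's manual clicks)."""
    mid = mid if mid is not None else labels.shape[0] // 2
    sl = labels[mid]
    seeds = SeedSpec()
    for lid, attr in ((LABEL_IDS["solid_albumen"], "solid_seeds"),
                      (LABEL_IDS["liquid_albumen"], "liquid_seeds")):
        pts = np.argwhere(sl == lid)
        if len(pts):
            from scipy import ndimage as ndi

            er = ndi.binary_erosion(sl == lid, iterations=2)
            pts = np.argwhere(er) if er.any() else pts
            getattr(seeds, attr).append(tuple(int(v) for v in pts[len(pts) // 2]))
    return seeds


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "geometry": config.geometry,
            "n_angles": config.n_angles,
            "grid": list(config.grid),
            "voxel_size_mm": config.voxel_size_mm,
            "seed": config.seed,
        },
        "stages": {},
        "warnings": [],
    }

    def stage_done(name, **info):
        manifest["stages"][name] = {"status": "ok", **info}
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    try:
        # 1. phantom
        spec = config.phantom_spec
        if spec is None:
            spec = fruit_spec(
                grid_shape=config.grid,
                voxel_size_mm=config.voxel_size_mm,
                seed=config.seed,
            )
        elif isinstance(spec, (str, Path)):
            spec = PhantomSpec.from_yaml(spec)
        mu, true_labels, gt = make_fruit_phantom(spec)
        gt.to_json(out / "ground_truth.json")
        stage_done("phantom", checksum=_checksum(mu))

        # 2. acquisition
        fov = max(config.grid[1], config.grid[2]) * config.voxel_size_mm
        geom = ConeBeamGeometry.desk(
            fov_mm=fov, n_pixels=config.detector_pixels, n_angles=config.n_angles
        )
        if config.geometry == "seed":
            geom = ConeBeamGeometry(
                dsd_mm=geom.dsd_mm,
                dsc_mm=600.0,
                detector_width_mm=fov * 1.1 * geom.dsd_mm / 600.0,
                detector_height_mm=fov * 1.1 * geom.dsd_mm / 600.0,
                detector_cols=geom.detector_cols,
                detector_rows=geom.detector_rows,
                n_angles=geom.n_angles,
                angle_step_deg=geom.angle_step_deg,
            )
        stack = forward_project(mu, geom, spec.voxel_size_mm)
        io.write_projections(stack, out / "projections")
        manifest["warnings"] += stack.meta.get("warnings", [])
        stage_done("acquisition", checksum=_checksum(stack.frames))

        # 3. reconstruction + CT normalization
        p = calibrate_projections(stack)
        vol = fdk_reconstruct(
            p, geom, config.grid, config.voxel_size_mm, window=config.filter_window
        )
        zz, yy, xx = vol.world_coords()
        r = np.broadcast_to(np.sqrt(xx**2 + yy**2), vol.values.shape)
        rmax = min(config.grid[1], config.grid[2]) * config.voxel_size_mm / 2.0
        air_mask = (r > 0.92 * rmax) & (r < 0.98 * rmax)
        air_mean = float(vol.values[air_mask].mean())
        # water anchor: mean reconstructed attenuation in the (eroded)
        # liquid-albumen region, the simulation's water-equivalent fixture
        from scipy import ndimage as ndi

        liquid_mask = true_labels == LABEL_IDS["liquid_albumen"]
        liquid_er = ndi.binary_erosion(liquid_mask, iterations=3)
        water_mean = float(
            vol.values[liquid_er if liquid_er.any() else liquid_mask].mean()
        )
        ct = normalize_ct(vol, air_mean, water_mean)
        io.write_volume(ct, out / "volume_ct.mhd")
        gray = to_grayscale8(ct)
        io.write_tiff_stack(gray, out / "slices")
        stage_done("reconstruction", checksum=_checksum(ct.values))

        # 4. segmentation (on CT values: the dense shell clamps in the
        # 8-bit export, which would bias its edges)
        seeds = config.seeds or default_seeds_for(true_labels)
        result = segment_volume(
            np.maximum(ct.values, 0.0), seeds, config.seg_params
        )
        labels = result.labels
        io.write_labels(labels, config.voxel_size_mm, out / "labels.mhd")
        if result.failed_slices:
            manifest["warnings"].append(
                f"{len(result.failed_slices)} slices interpolated during propagation"
            )
        stage_done(
            "segmentation",
            checksum=_checksum(labels),
            failed_slices=len(result.failed_slices),
        )

        # 5. meshes
        meshes = {}
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for name, lid in LABEL_IDS.items():
            if lid == 0 or not (labels == lid).any():
                continue
            try:
                m = mesh3d.mesh_from_mask(labels == lid, config.voxel_size_mm, name)
                meshes[name] = m
                io.write_mesh(m, mesh_dir / f"{name}.ply")
            except Exception as exc:  # sparse compartments may not mesh
                manifest["warnings"].append(f"mesh {name}: {exc}")
        cloud = mesh3d.fill_ct_pointcloud(labels, ct)
        stage_done("mesh", n_meshes=len(meshes), n_points=len(cloud.points))

        # 6. traits
        agro = traits_mod.agronomic_traits(labels, ct, config.voxel_size_mm)
        digi = traits_mod.digital_traits(labels, ct, config.voxel_size_mm)
        agro.to_csv(out / "traits_agronomic.csv")
        digi.to_csv(out / "traits_digital.csv")
        stage_done("traits", n_agronomic=len(agro), n_digital=len(digi))

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        io.write_json(manifest, out / "manifest.json")
        raise
    manifest["elapsed_s"] = round(time.time() - t0, 1)
    io.write_json(manifest, out / "manifest.json")
    return manifest
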