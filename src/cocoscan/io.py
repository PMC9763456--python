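"""Format readers/writers shared by the pipeline and the CLI.

Volumes and label volumes travel as MetaImage (.mhd/.raw) or NIfTI with
explicit spacing; projection stacks and slice exports as TIFF; meshes as
PLY/OBJ; traits, indices and manifests as CSV/JSON; configuration as
YAML.  Integer data round-trips bit-exactly and float volumes losslessly
(32/64-bit as stored).

Coordinate conventions at every boundary: arrays are indexed [z, y, x],
0-based, with the voxel-centre world mapping and z the rotation axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile
import trimesh
import yaml

from .mesh3d import SurfaceMesh
from .recon import Volume

__all__ = [
    "write_volume",
    "read_volume",
    "write_labels",
    "read_labels",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_projections",
    "read_projections",
    "write_mesh",
    "read_mesh",
    "write_json",
    "read_json",
    "write_yaml",
    "read_yaml",
]


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as MetaImage (.mhd/.raw) or NIfTI (.nii/.nii.gz)."""
    img = sitk.GetImageFromArray(np.asarray(vol.values))
    img.SetSpacing((vol.voxel_size_mm,) * 3)
    img.SetOrigin(tuple(float(o) for o in vol.origin_mm))
    sitk.WriteImage(img, str(path))
    meta = Path(str(path)).with_suffix(".units.json")
    meta.write_text(json.dumps({"units": vol.units}))


def read_volume(path: str | Path) -> Volume:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img)
    spacing = img.GetSpacing()
    units = "mu"
    meta = Path(str(path)).with_suffix(".units.json")
    if meta.exists():
        units = json.loads(meta.read_text()).get("units", "mu")
    return Volume(
        values=values,
        voxel_size_mm=float(spacing[0]),
        origin_mm=tuple(img.GetOrigin()),
        units=units,
    )


def write_labels(labels: np.ndarray, voxel_size_mm: float, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.asarray(labels, dtype=np.uint8))
    img.SetSpacing((voxel_size_mm,) * 3)
    sitk.WriteImage(img, str(path))


def read_labels(path: str | Path) -> tuple[np.ndarray, float]:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img).astype(np.uint8), float(img.GetSpacing()[0])


def write_tiff_stack(stack: np.ndarray, directory: str | Path, prefix="slice") -> None:
    """One TIFF per slice (z index in the filename)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, sl in enumerate(stack):
        tifffile.imwrite(directory / f"{prefix}_{k:05d}.tif", sl)


def read_tiff_stack(directory: str | Path, prefix="slice") -> np.ndarray:
    files = sorted(Path(directory).glob(f"{prefix}_*.tif"))
    if not files:
        raise FileNotFoundError(f"no {prefix}_*.tif in {directory}")
    return np.stack([tifffile.imread(f) for f in files])


def write_projections(stack, directory: str | Path) -> None:
    """Projection frames + dark/flat references as TIFF with a JSON sidecar
    (geometry and angles)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "frames.tif", stack.frames.astype(np.float32))
    tifffile.imwrite(directory / "black.tif", stack.black_current.astype(np.float32))
    tifffile.imwrite(directory / "white.tif", stack.white_current.astype(np.float32))
    sidecar = {
        "angles_deg": [float(a) for a in stack.angles_deg],
        "meta": stack.meta,
    }
    if stack.geom is not None:
        g = stack.geom
        sidecar["geometry"] = {
            "dsd_mm": g.dsd_mm,
            "dsc_mm": g.dsc_mm,
            "detector_width_mm": g.detector_width_mm,
            "detector_height_mm": g.detector_height_mm,
            "detector_cols": g.detector_cols,
            "detector_rows": g.detector_rows,
            "n_angles": g.n_angles,
            "angle_step_deg": g.angle_step_deg,
        }
    (directory / "projections.json").write_text(json.dumps(sidecar, indent=2))


def read_projections(directory: str | Path):
    from .acquisition import ConeBeamGeometry, ProjectionStack

    directory = Path(directory)
    sidecar = json.loads((directory / "projections.json").read_text())
    geom = (
        ConeBeamGeometry(**sidecar["geometry"]) if "geometry" in sidecar else None
    )
    return ProjectionStack(
        frames=tifffile.imread(directory / "frames.tif").astype(np.float64),
        black_current=tifffile.imread(directory / "black.tif").astype(np.float64),
        white_current=tifffile.imread(directory / "white.tif").astype(np.float64),
        angles_deg=np.asarray(sidecar["angles_deg"], dtype=float),
        geom=geom,
        meta=sidecar.get("meta", {}),
    )


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """PLY (binary) or OBJ, by extension."""
    mesh.to_trimesh().export(str(path))


def read_mesh(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices),
        faces=np.asarray(tm.faces),
        compartment=Path(str(path)).stem,
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
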