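"""Cone-beam acquisition: geometry arithmetic, frame handling, simulation
and projection calibration.

The scanner is a circular-trajectory cone-beam system: X-ray source and
flat-panel detector are fixed while the sample rotates on a platform
between them.  Magnification is DSD/DSC (source-detector over
source-rotation-centre distance), so the field of view at the rotation
axis is the detector active area scaled by DSC/DSD, and the projection
pixel pitch scales the same way.

Raw detector frames carry an additive dark-current offset (the "black
current" SB) and a gain captured by the open-beam "white current" frame
(SW).  A raw signal S0 is converted to a Beer-Lambert line integral as

    p = ln((SW - SB) / (S0 - SB))  >= 0  for attenuating objects,

the negative of the detector-calibration log-ratio G; ``forward_project``
emits exactly this signal model so calibration round-trips to machine
precision on noiseless data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import forward_project_kernel

__all__ = [
    "ConeBeamGeometry",
    "ProjectionStack",
    "fov_at_axis",
    "spatial_resolution_um",
    "forward_project",
    "project_line_integrals",
    "average_frames",
    "detect_rotation_keyframes",
    "calibrate_projections",
]

DEFAULT_BLACK = 100.0
DEFAULT_WHITE = 1100.0


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular cone-beam scanner description."""

    dsd_mm: float = 1200.0
    dsc_mm: float = 1050.0
    detector_width_mm: float = 248.0
    detector_height_mm: float = 298.0
    detector_cols: int = 2512
    detector_rows: int = 3008
    n_angles: int = 360
    angle_step_deg: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.dsc_mm <= self.dsd_mm:
            raise ValueError("require 0 < dsc <= dsd")
        if self.detector_cols < 1 or self.detector_rows < 1:
            raise ValueError("detector grid must be >= 1 per axis")
        if self.n_angles * self.angle_step_deg > 360.0 + 1e-9:
            raise ValueError("n_angles * angle_step_deg must be <= 360")

    # presets ---------------------------------------------------------------
    @classmethod
    def fruit(cls) -> "ConeBeamGeometry":
        """Coconut fruit preset (DSC 1050 mm)."""
        return cls()

    @classmethod
    def seed(cls) -> "ConeBeamGeometry":
        """Coconut seed preset (DSC 600 mm, higher magnification)."""
        return cls(dsc_mm=600.0)

    @classmethod
    def desk(
        cls,
        fov_mm: float,
        n_pixels: int = 192,
        n_angles: int = 180,
        margin: float = 1.1,
    ) -> "ConeBeamGeometry":
        """Desk-scale geometry: the fruit source/detector distances with the
        detector sized (with margin) to cover ``fov_mm`` at the axis."""
        det = fov_mm * margin * 1200.0 / 1050.0
        return cls(
            detector_width_mm=det,
            detector_height_mm=det,
            detector_cols=n_pixels,
            detector_rows=n_pixels,
            n_angles=n_angles,
            angle_step_deg=360.0 / n_angles,
        )

    @property
    def magnification(self) -> float:
        return self.dsd_mm / self.dsc_mm

    @property
    def pixel_pitch_mm(self) -> tuple[float, float]:
        return (
            self.detector_width_mm / self.detector_cols,
            self.detector_height_mm / self.detector_rows,
        )

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angle_step_deg


def fov_at_axis(geom: ConeBeamGeometry) -> tuple[int, int]:
    """Field of view (width, height) at the rotation axis, floored to whole
    mm as conventionally reported (e.g. 260.75 -> 260)."""
    s = geom.dsc_mm / geom.dsd_mm
    return (
        math.floor(geom.detector_width_mm * s),
        math.floor(geom.detector_height_mm * s),
    )


def spatial_resolution_um(geom: ConeBeamGeometry) -> int:
    """Projection pixel pitch at the rotation axis in µm, floored."""
    pitch = geom.detector_width_mm / geom.detector_cols
    return math.floor(pitch * geom.dsc_mm / geom.dsd_mm * 1000.0)


@dataclass
class ProjectionStack:
    """Per-angle raw detector frames with dark/flat reference frames."""

    frames: np.ndarray  # (n_angles, rows, cols) raw signal S0
    black_current: np.ndarray  # SB, (rows, cols)
    white_current: np.ndarray  # SW, (rows, cols)
    angles_deg: np.ndarray
    geom: ConeBeamGeometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_angles, rows, cols)")
        if self.black_current.shape != self.frames.shape[1:]:
            raise ValueError("black current shape mismatch")
        if self.white_current.shape != self.frames.shape[1:]:
            raise ValueError("white current shape mismatch")
        if np.any(self.white_current - self.black_current <= 0):
            raise ValueError("require SW - SB > 0 everywhere")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")


def project_line_integrals(
    vol_mu: np.ndarray, geom: ConeBeamGeometry, voxel_size_mm: float
) -> np.ndarray:
    """Exact (Siddon) line integrals of the attenuation volume for every
    angle and detector pixel; shape ``(n_angles, rows, cols)``."""
    pu, pv = geom.pixel_pitch_mm
    return forward_project_kernel(
        np.ascontiguousarray(vol_mu, dtype=np.float64),
        float(voxel_size_mm),
        np.deg2rad(geom.angles_deg),
        geom.dsc_mm,
        geom.dsd_mm,
        pu,
        pv,
        geom.detector_rows,
        geom.detector_cols,
    )


def _is_truncated(vol_mu, geom, voxel_size_mm) -> bool:
    """Object support wider than the FOV at the axis (worst-case radius)."""
    nz, ny, nx = vol_mu.shape
    support = np.nonzero(vol_mu)
    if len(support[0]) == 0:
        return False
    z, y, x = (
        (idx - (n - 1) / 2.0) * voxel_size_mm
        for idx, n in zip(support, (nz, ny, nx))
    )
    r = np.sqrt(x**2 + y**2).max()
    zmax = np.abs(z).max()
    fw, fh = (
        geom.detector_width_mm * geom.dsc_mm / geom.dsd_mm,
        geom.detector_height_mm * geom.dsc_mm / geom.dsd_mm,
    )
    return bool(2 * r > fw or 2 * zmax > fh)


def forward_project(
    vol_mu: np.ndarray,
    geom: ConeBeamGeometry,
    voxel_size_mm: float,
    black: float = DEFAULT_BLACK,
    white: float = DEFAULT_WHITE,
) -> ProjectionStack:
    """Simulate a scan: raw frames S0 = (SW-SB) * exp(-integral mu) + SB.

    A sample wider than the field of view does not fail -- the stack is
    flagged ``truncated`` in its metadata, mirroring real out-of-range
    samples that reconstruct with edge artifacts.
    """
    meta: dict = {"warnings": []}
    if _is_truncated(vol_mu, geom, voxel_size_mm):
        meta["truncated"] = True
        meta["warnings"].append("object exceeds the field of view; expect artifacts")
        warnings.warn("object exceeds the field of view", stacklevel=2)
    p = project_line_integrals(vol_mu, geom, voxel_size_mm)
    rows, cols = geom.detector_rows, geom.detector_cols
    sb = np.full((rows, cols), float(black))
    sw = np.full((rows, cols), float(white))
    frames = (white - black) * np.exp(-p) + black
    return ProjectionStack(
        frames=frames,
        black_current=sb,
        white_current=sw,
        angles_deg=geom.angles_deg.astype(float),
        geom=geom,
        meta=meta,
    )


def average_frames(frames_per_step) -> np.ndarray:
    """Pixel-wise arithmetic mean of the frames captured at one rotation
    step (noise reduction by sqrt(n))."""
    frames = [np.asarray(f, dtype=float) for f in frames_per_step]
    if not frames:
        raise ValueError("no frames to average")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("frames must share one shape")
    return np.mean(frames, axis=0)


def detect_rotation_keyframes(frame_stream, diff_threshold: float) -> list[int]:
    """Indices where the mean absolute inter-frame difference exceeds the
    threshold; consecutive boundaries delimit one averaging group.

    Returns boundary indices (the index of the first frame of each new
    group); a constant stream yields no boundary, i.e. one group.
    """
    prev = None
    boundaries: list[int] = []
    for i, frame in enumerate(frame_stream):
        f = np.asarray(frame, dtype=float)
        if prev is not None and np.mean(np.abs(f - prev)) > diff_threshold:
            boundaries.append(i)
        prev = f
    return boundaries


def calibrate_projections(
    stack: ProjectionStack, floor: float = 1e-12
) -> np.ndarray:
    """Dark/flat-corrected line-integral estimates p = ln((SW-SB)/(S0-SB)).

    Non-physical pixels (S0 <= SB) are clamped to a small positive floor
    and counted; a frame with more than 1% such pixels is rejected.
    """
    sb = stack.black_current
    sw = stack.white_current
    num = sw - sb
    sig = stack.frames - sb[None]
    bad = sig <= 0
    if bad.any():
        frac = bad.reshape(bad.shape[0], -1).mean(axis=1)
        worst = int(np.argmax(frac))
        if frac[worst] > 0.01:
            raise ValueError(
                f"frame {worst}: {frac[worst]:.1%} of pixels at or below the "
                "black current"
            )
        stack.meta.setdefault("warnings", []).append(
            f"{int(bad.sum())} pixels clamped to positive floor"
        )
        sig = np.where(bad, floor * num[None], sig)
    return np.log(num[None] / sig)
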