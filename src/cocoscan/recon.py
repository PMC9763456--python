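"""FDK cone-beam reconstruction and CT-value normalization.

The Feldkamp-Davis-Kress algorithm reconstructs a circular-trajectory
cone-beam scan by (1) cosine/distance pre-weighting each projection,
(2) ramp-filtering each detector row, and (3) distance-weighted
voxel-driven backprojection.  It is exact in the midplane and an
approximation off-plane (a circular orbit does not satisfy Tuy's
condition), which is ample for the fruit-scale cone angles used here.

Reconstructed attenuation volumes are mapped to the CT convention
"air = 0, water = 200" by a two-point affine normalization, then to 8-bit
grayscale slices (clamped below 255) for segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import fdk_backproject_kernel
from .acquisition import ConeBeamGeometry

__all__ = ["Volume", "fdk_reconstruct", "normalize_ct", "to_grayscale8", "ramp_kernel"]


@dataclass
class Volume:
    """Scalar voxel grid with spacing, centre-based origin and a units tag."""

    values: np.ndarray  # (nz, ny, nx)
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "mu"  # "mu" | "ct" | "gray8"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_coords(self):
        """Broadcastable (z, y, x) world coordinates of voxel centres."""
        nz, ny, nx = self.values.shape
        oz, oy, ox = self.origin_mm[2], self.origin_mm[1], self.origin_mm[0]
        v = self.voxel_size_mm
        z = (np.arange(nz) - (nz - 1) / 2.0) * v + oz
        y = (np.arange(ny) - (ny - 1) / 2.0) * v + oy
        x = (np.arange(nx) - (nx - 1) / 2.0) * v + ox
        return z[:, None, None], y[None, :, None], x[None, None, :]


def ramp_kernel(n: int, du: float, window: str = "ramlak") -> np.ndarray:
    """Frequency response (length n, for np.fft) of the discrete Ram-Lak
    ramp filter, optionally Hann-apodized.

    Built from the exact band-limited spatial kernel
    h[0] = 1/(4 du^2), h[n odd] = -1/(pi n du)^2, h[n even] = 0,
    which avoids the DC-offset bias of sampling |w| directly.
    """
    ns = np.concatenate((np.arange(0, n // 2 + 1), np.arange(n // 2 - n + 1, 0)))
    h = np.zeros(n)
    h[0] = 1.0 / (4.0 * du**2)
    odd = ns % 2 == 1
    h[odd] = -1.0 / (np.pi * ns[odd] * du) ** 2
    H = np.real(np.fft.fft(h))
    if window == "hann":
        f = np.fft.fftfreq(n)
        H *= 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
    elif window != "ramlak":
        raise ValueError(f"unknown filter window {window!r}")
    return H


def fdk_reconstruct(
    projections: np.ndarray,
    geom: ConeBeamGeometry,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    window: str = "ramlak",
) -> Volume:
    """Reconstruct calibrated line-integral projections to attenuation.

    Parameters
    ----------
    projections
        ``(n_angles, rows, cols)`` nonnegative line integrals (output of
        ``calibrate_projections``).
    geom
        Acquisition geometry; angles must cover the full circle (to within
        one step).
    grid_shape, voxel_size_mm
        Output grid; a grid wider than the FOV is reconstructed with a
        truncation warning rather than refused.
    """
    proj = np.ascontiguousarray(projections, dtype=np.float64)
    if proj.ndim != 3 or proj.shape[0] != geom.n_angles:
        raise ValueError("projection stack does not match geometry")
    coverage = geom.n_angles * geom.angle_step_deg
    if coverage < 360.0 - geom.angle_step_deg - 1e-9:
        raise ValueError(
            f"angular coverage {coverage:.1f} deg < full circle; FDK needs 360"
        )
    nz, ny, nx = grid_shape
    fov_w = geom.detector_width_mm * geom.dsc_mm / geom.dsd_mm
    if max(nx, ny) * voxel_size_mm > fov_w * (1 + 1e-9):
        warnings.warn(
            "reconstruction grid exceeds the field of view; truncation "
            "artifacts expected",
            stacklevel=2,
        )

    n_angles, rows, cols = proj.shape
    pu, pv = geom.pixel_pitch_mm
    scale = geom.dsc_mm / geom.dsd_mm
    du, dv = pu * scale, pv * scale  # sample spacing at the isocentre

    # cosine / distance pre-weighting at isocentre scale
    u = (np.arange(cols) - (cols - 1) / 2.0) * du
    v = ((rows - 1) / 2.0 - np.arange(rows)) * dv
    w = geom.dsc_mm / np.sqrt(geom.dsc_mm**2 + u[None, :] ** 2 + v[:, None] ** 2)
    weighted = proj * w[None]

    # row-wise ramp filtering, zero-padded to the next power of two >= 2N
    npad = 1 << int(np.ceil(np.log2(max(2 * cols, 64))))
    H = ramp_kernel(npad, du, window=window)
    spec = np.fft.fft(weighted, n=npad, axis=2)
    filtered = np.real(np.fft.ifft(spec * H[None, None, :], axis=2))[:, :, :cols]
    filtered *= du  # convolution -> integral

    dbeta = np.deg2rad(geom.angle_step_deg)
    vol = fdk_backproject_kernel(
        np.ascontiguousarray(filtered),
        np.deg2rad(geom.angles_deg),
        geom.dsc_mm,
        du,
        dv,
        float(voxel_size_mm),
        nz,
        ny,
        nx,
    )
    vol *= dbeta / 2.0  # full-scan: every ray measured twice over 2*pi
    return Volume(values=vol, voxel_size_mm=voxel_size_mm, units="mu")


def normalize_ct(
    vol: Volume,
    air_stat: float | np.ndarray,
    water_stat: float | np.ndarray,
    water_value: float = 200.0,
) -> Volume:
    """Affine map sending the measured air level to 0 and water to 200.

    ``air_stat`` / ``water_stat`` are either scalar region means or boolean
    masks over the volume (means are taken over the mask).
    """
    if vol.units != "mu":
        raise ValueError("normalize_ct expects an attenuation volume")
    air = (
        float(vol.values[air_stat].mean())
        if isinstance(air_stat, np.ndarray)
        else float(air_stat)
    )
    water = (
        float(vol.values[water_stat].mean())
        if isinstance(water_stat, np.ndarray)
        else float(water_stat)
    )
    if water <= air:
        raise ValueError("degenerate anchors: water mean must exceed air mean")
    ct = (vol.values - air) * (water_value / (water - air))
    return Volume(
        values=ct,
        voxel_size_mm=vol.voxel_size_mm,
        origin_mm=vol.origin_mm,
        units="ct",
        meta={**vol.meta, "ct_anchors": {"air": air, "water": water}},
    )


def to_grayscale8(vol: Volume) -> np.ndarray:
    """Clamp CT values to [0, 255] and round to 8-bit grayscale slices."""
    if vol.units != "ct":
        raise ValueError("to_grayscale8 expects a CT-normalized volume")
    return np.clip(np.rint(vol.values), 0, 255).astype(np.uint8)
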