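"""Classical semi-automatic coconut slice segmentation.

The workflow mirrors how a technician labels a CT stack by hand, but
automates everything except a handful of seed points:

1. a middle-height slice is segmented: Otsu thresholding pulls out the
   fruit, connected-component cleaning removes noise, a polar-coordinate
   edge-refinement (linear fits of boundary radius versus angle in sliding
   angular windows) locates the epicarp and shell rings, and seeded region
   growing separates solid from liquid albumen inside the shell;
2. that result is used as a template to segment the adjacent slices --
   eroded class masks become the seeds for region growing on the next
   slice, ring boundaries are re-refined, and classes that shrink away
   drop out naturally;
3. a-priori knowledge detects the cavity: near-air gray levels enclosed by
   the shell interior are relabelled as cavity.

The slice segmenter is an interface; the classical algorithm here is the
default implementation, and adapters for learned models can be registered
in :data:`SEGMENTERS`.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu

from .phantom import LABEL_IDS

__all__ = [
    "SegmentationError",
    "SeedSpec",
    "SegParams",
    "SegMetrics",
    "RingBoundary",
    "SegmentationResult",
    "otsu_threshold",
    "remove_small_components",
    "polar_edge_refine",
    "region_grow",
    "segment_middle_slice",
    "propagate_template",
    "detect_cavity",
    "segment_volume",
    "evaluate_segmentation",
    "SliceSegmenter",
    "ClassicalSliceSegmenter",
    "SEGMENTERS",
]

logger = logging.getLogger(__name__)

BACKGROUND = LABEL_IDS["background"]
EPICARP = LABEL_IDS["epicarp"]
MESOCARP = LABEL_IDS["mesocarp"]
SHELL = LABEL_IDS["shell"]
SOLID = LABEL_IDS["solid_albumen"]
LIQUID = LABEL_IDS["liquid_albumen"]
CAVITY = LABEL_IDS["cavity"]
_INTERIOR = 255  # transient placeholder for unresolved shell-interior pixels


class SegmentationError(RuntimeError):
    """A slice could not be segmented (e.g. no shell ring found)."""


@dataclass
class SeedSpec:
    """Manual seeds and gray-level tolerances for the albumen classes."""

    solid_seeds: list[tuple[int, int]] = field(default_factory=list)
    liquid_seeds: list[tuple[int, int]] = field(default_factory=list)
    solid_tolerance: float = 6.0
    liquid_tolerance: float = 6.0

    def validate(self, shape) -> None:
        for r, c in [*self.solid_seeds, *self.liquid_seeds]:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"seed ({r}, {c}) lies outside the image")
        if self.solid_tolerance < 0 or self.liquid_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class SegParams:
    """Tunables of the classical algorithm (gray units are 8-bit)."""

    n_rays: int = 720
    window_deg: float = 15.0
    k_mad: float = 3.0
    min_component_px: int = 25
    erosion_px: int = 3
    air_level: float = 0.0
    air_tolerance: float = 20.0
    max_missing_rays: float = 0.25
    radial_step_px: float = 0.5


@dataclass
class RingBoundary:
    """Smoothed closed boundaries of an annulus, radius per ray angle."""

    theta: np.ndarray  # radians, uniform over [0, 2pi)
    inner_r: np.ndarray
    outer_r: np.ndarray
    center: tuple[float, float]  # (row, col)

    def interp(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        period = 2.0 * np.pi
        t = np.mod(theta, period)
        inner = np.interp(t, self.theta, self.inner_r, period=period)
        outer = np.interp(t, self.theta, self.outer_r, period=period)
        return inner, outer


@dataclass
class SegMetrics:
    """Per-class and macro-averaged segmentation quality."""

    per_class: dict[int, dict[str, float]]
    precision: float
    recall: float
    f1: float
    iou: float


@dataclass
class SegmentationResult:
    """Stack segmentation output with per-slice propagation bookkeeping."""

    labels: np.ndarray
    middle_index: int
    failed_slices: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def otsu_threshold(image) -> int:
    """Otsu threshold over the 8-bit histogram (foreground = gray > t).

    Maximizes the between-class variance; ties break to the lowest
    threshold.  Constant images are rejected.
    """
    img = np.rint(np.asarray(image, dtype=float)).astype(np.int64)
    img = np.clip(img, 0, 255)
    if img.min() == img.max():
        raise ValueError("constant image has no Otsu threshold")
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    total, mt = w0[-1], m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    var = np.full(256, -1.0)
    var[valid] = (
        w0[valid]
        * w1[valid]
        * (m0[valid] / w0[valid] - (mt - m0[valid]) / w1[valid]) ** 2
    )
    return int(np.argmax(var))  # argmax returns the first (lowest) maximum


def remove_small_components(
    mask: np.ndarray, min_size_px: int, connectivity: int | None = None
) -> np.ndarray:
    """Delete connected components smaller than ``min_size_px`` pixels.

    Default connectivity is full (8-connected in 2-D, 26-connected in 3-D).
    """
    mask = np.asarray(mask, dtype=bool)
    if min_size_px <= 1 or not mask.any():
        return mask.copy()
    if connectivity is None:
        connectivity = mask.ndim
    structure = ndi.generate_binary_structure(mask.ndim, connectivity)
    lab, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size_px
    keep[0] = False
    return keep[lab]


def region_grow(
    image: np.ndarray,
    seeds,
    tolerance: float,
    allowed: np.ndarray | None = None,
    excluded: np.ndarray | None = None,
) -> np.ndarray:
    """Breadth-first flood over 4-connected pixels.

    A pixel joins the region while its gray level is within ``tolerance``
    of the running mean of the pixels accepted so far.  The queue is
    seeded in row-major order and neighbours are visited in a fixed order,
    so the result is deterministic.

    ``seeds`` is a sequence of (row, col) points or a boolean mask (all
    True pixels initialize the region).  ``allowed`` restricts growth;
    ``excluded`` marks already-labelled pixels a seed may not sit on.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    img = np.asarray(image, dtype=float)
    if isinstance(seeds, np.ndarray) and seeds.dtype == bool:
        seed_pts = [tuple(p) for p in np.argwhere(seeds)]
    else:
        seed_pts = [tuple(map(int, p)) for p in seeds]
    region = np.zeros(img.shape, dtype=bool)
    if not seed_pts:
        return region
    for p in seed_pts:
        if not (0 <= p[0] < img.shape[0] and 0 <= p[1] < img.shape[1]):
            raise ValueError(f"seed {p} lies outside the image")
        if excluded is not None and excluded[p]:
            raise ValueError(f"seed {p} sits on an excluded pixel")
        if allowed is not None and not allowed[p]:
            raise ValueError(f"seed {p} lies outside the allowed mask")

    queue: deque = deque()
    total = 0.0
    count = 0
    for p in sorted(seed_pts):
        if not region[p]:
            region[p] = True
            total += img[p]
            count += 1
            queue.append(p)
    nrows, ncols = img.shape
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (r + dr, c + dc)
            if not (0 <= q[0] < nrows and 0 <= q[1] < ncols):
                continue
            if region[q]:
                continue
            if allowed is not None and not allowed[q]:
                continue
            if excluded is not None and excluded[q]:
                continue
            if abs(img[q] - total / count) <= tolerance:
                region[q] = True
                total += img[q]
                count += 1
                queue.append(q)
    return region


# ---------------------------------------------------------------------------
# polar machinery
# ---------------------------------------------------------------------------

def _polar_samples(shape, center, n_rays, dr):
    """Nearest-pixel samples along equiangular rays from ``center``."""
    cr, cc = center
    nrows, ncols = shape
    corners = [(0, 0), (0, ncols - 1), (nrows - 1, 0), (nrows - 1, ncols - 1)]
    rmax = max(np.hypot(r - cr, c - cc) for r, c in corners) + 1.0
    radii = np.arange(dr, rmax, dr)
    theta = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    rr = cr + radii[None, :] * np.sin(theta)[:, None]
    cc_ = cc + radii[None, :] * np.cos(theta)[:, None]
    ir = np.rint(rr).astype(int)
    ic = np.rint(cc_).astype(int)
    inb = (ir >= 0) & (ir < nrows) & (ic >= 0) & (ic < ncols)
    return theta, radii, ir, ic, inb


def _sample_mask(mask, ir, ic, inb):
    out = np.zeros(ir.shape, dtype=bool)
    out[inb] = mask[ir[inb], ic[inb]]
    return out


def _runs_per_ray(sampled):
    """First (innermost) and last (outermost) True runs along each ray.

    Returns index arrays (first_start, first_end, last_start, last_end,
    run_count, any_hit); end indices are exclusive."""
    n_rays, n_r = sampled.shape
    any_ = sampled.any(axis=1)
    first = np.argmax(sampled, axis=1)
    ar = np.arange(n_r)
    after = (~sampled) & (ar[None, :] > first[:, None])
    first_end = np.where(after.any(axis=1), np.argmax(after, axis=1), n_r)
    rev = sampled[:, ::-1]
    last_rev = np.argmax(rev, axis=1)
    last_end = n_r - last_rev  # exclusive
    before = (~rev) & (ar[None, :] > last_rev[:, None])
    last_start = n_r - np.where(before.any(axis=1), np.argmax(before, axis=1), n_r)
    starts = sampled[:, 1:] & ~sampled[:, :-1]
    counts = starts.sum(axis=1) + sampled[:, 0]
    return first, first_end, last_start, last_end, counts, any_


def _circular_interp_nan(r):
    """Fill NaNs by periodic linear interpolation over the ray index."""
    out = np.asarray(r, dtype=float).copy()
    bad = np.isnan(out)
    if not bad.any():
        return out
    if bad.all():
        raise SegmentationError("no boundary radii found on any ray")
    n = len(out)
    idx = np.arange(n)
    out[bad] = np.interp(idx[bad], idx[~bad], out[~bad], period=n)
    return out


def _smooth_radii(r, n_window, k_mad, iterations: int = 2):
    """Sliding-window linear fit of radius vs. angle; radii deviating more
    than k*MAD from the local fit are replaced by the fitted value.

    Iterated so that a replacement value contaminated by a broad spike is
    itself corrected on the next pass.
    """
    n = len(r)
    w = max(3, n_window | 1)  # odd window
    half = w // 2
    offsets = np.arange(-half, half + 1)
    x = offsets.astype(float)  # symmetric, zero mean
    out = np.asarray(r, dtype=float).copy()
    for _ in range(iterations):
        win = out[(np.arange(n)[:, None] + offsets[None, :]) % n]  # (n, w)
        mean = win.mean(axis=1)
        slope = win @ x / (x @ x)
        pred = mean  # fitted value at the window centre
        resid = win - (mean[:, None] + slope[:, None] * x[None, :])
        med = np.median(resid, axis=1)
        mad = np.median(np.abs(resid - med[:, None]), axis=1)
        dev = np.abs(out - pred)
        out = np.where(dev > k_mad * np.maximum(mad, 1e-6), pred, out)
    return out


def polar_edge_refine(
    mask: np.ndarray,
    center: tuple[float, float],
    params: SegParams | None = None,
) -> RingBoundary:
    """Locate and smooth the inner/outer boundary of an annulus-like mask.

    Casts equiangular rays from ``center``, records first/last mask
    crossing radii per ray, interpolates rays with no crossing from their
    neighbours, and replaces outliers against sliding-window linear fits.
    Fails when more than ``params.max_missing_rays`` of the rays miss the
    mask entirely.
    """
    p = params or SegParams()
    theta, radii, ir, ic, inb = _polar_samples(
        mask.shape, center, p.n_rays, p.radial_step_px
    )
    sampled = _sample_mask(np.asarray(mask, dtype=bool), ir, ic, inb)
    first, first_end, last_start, last_end, counts, any_ = _runs_per_ray(sampled)
    if (~any_).mean() > p.max_missing_rays:
        raise SegmentationError(
            f"{(~any_).mean():.0%} of rays miss the mask; not annulus-like"
        )
    dr = p.radial_step_px
    nr = len(radii)
    inner = np.where(any_, radii[np.clip(first, 0, nr - 1)] - dr / 2.0, np.nan)
    outer = np.where(
        any_, radii[np.clip(last_end - 1, 0, nr - 1)] + dr / 2.0, np.nan
    )
    n_window = int(round(p.window_deg / 360.0 * p.n_rays))
    inner = _smooth_radii(_circular_interp_nan(inner), n_window, p.k_mad)
    outer = _smooth_radii(_circular_interp_nan(outer), n_window, p.k_mad)
    return RingBoundary(theta=theta, inner_r=inner, outer_r=outer, center=center)


def _refine_edges_gradient(gray_sampled, idx, rising, radii, halfwin=5):
    """Sub-pixel edge radii at the gray-gradient peak near each coarse index.

    A hard threshold crossing is biased when one plateau saturates (dense
    shell clamped at 255), so each boundary is pulled to the maximum of
    the signed radial gradient within ``halfwin`` samples, with parabolic
    sub-sample interpolation.  ``rising`` selects increasing (entering a
    bright run) vs decreasing gray.
    """
    n_rays, n_r = gray_sampled.shape
    grad = np.gradient(gray_sampled, axis=1)
    if not rising:
        grad = -grad
    out = np.full(n_rays, np.nan)
    for i in range(n_rays):
        j0 = idx[i]
        if j0 < 0 or j0 >= n_r:
            continue
        lo = max(j0 - halfwin, 1)
        hi = min(j0 + halfwin + 1, n_r - 1)
        if hi <= lo:
            continue
        j = lo + int(np.argmax(grad[i, lo:hi]))
        g0, g1, g2 = grad[i, j - 1], grad[i, j], grad[i, j + 1]
        denom = g0 - 2 * g1 + g2
        frac = 0.5 * (g0 - g2) / denom if abs(denom) > 1e-12 else 0.0
        frac = float(np.clip(frac, -1.0, 1.0))
        out[i] = radii[j] + frac * (radii[1] - radii[0])
    return out


def _extract_rings(
    bright, center, p: SegParams, expect=None, prev_rings=None, gray=None,
    surface_r: float | None = None,
):
    """Identify the shell (innermost) and epicarp (outermost) bright rings.

    ``expect`` optionally restricts which rings are present (template
    propagation); ``gray`` enables sub-pixel gradient refinement of the
    ring edges.  Returns (dict name -> RingBoundary, disk_flag); the disk
    flag marks a filled bright disk (e.g. the very tip of the fruit).
    """
    theta, radii, ir, ic, inb = _polar_samples(
        bright.shape, center, p.n_rays, p.radial_step_px
    )
    sampled = _sample_mask(np.asarray(bright, dtype=bool), ir, ic, inb)
    first, first_end, last_start, last_end, counts, any_ = _runs_per_ray(sampled)
    if (~any_).mean() > p.max_missing_rays:
        raise SegmentationError("shell not found: bright structure misses most rays")
    dr = p.radial_step_px
    nr = len(radii)

    def _r(idx, off):
        return radii[np.clip(idx, 0, nr - 1)] + off

    m = int(np.median(counts[any_]))
    inner_in = np.where(any_, _r(first, -dr / 2), np.nan)
    inner_out = np.where(any_, _r(first_end - 1, dr / 2), np.nan)
    outer_in = np.where(any_, _r(last_start, -dr / 2), np.nan)
    outer_out = np.where(any_, _r(last_end - 1, dr / 2), np.nan)

    if gray is not None:
        # bilinear gray samples along the rays for sub-pixel edges
        cr, cc0 = center
        rr_f = cr + radii[None, :] * np.sin(theta)[:, None]
        cc_f = cc0 + radii[None, :] * np.cos(theta)[:, None]
        gs = ndi.map_coordinates(
            np.asarray(gray, dtype=float),
            np.stack([rr_f, cc_f]),
            order=1,
            mode="nearest",
        )
        ref_ii = _refine_edges_gradient(gs, first, True, radii)
        ref_io = _refine_edges_gradient(gs, first_end - 1, False, radii)
        ref_oi = _refine_edges_gradient(gs, last_start, True, radii)
        ref_oo = _refine_edges_gradient(gs, last_end - 1, False, radii)
        inner_in = np.where(np.isfinite(ref_ii) & any_, ref_ii, inner_in)
        inner_out = np.where(np.isfinite(ref_io) & any_, ref_io, inner_out)
        outer_in = np.where(np.isfinite(ref_oi) & any_, ref_oi, outer_in)
        outer_out = np.where(np.isfinite(ref_oo) & any_, ref_oo, outer_out)

    disk = m == 1 and np.nanmedian(inner_in) < 2.0
    n_window = int(round(p.window_deg / 360.0 * p.n_rays))

    def _boundary(rin, rout):
        rin = _smooth_radii(_circular_interp_nan(rin), n_window, p.k_mad)
        rout = _smooth_radii(_circular_interp_nan(rout), n_window, p.k_mad)
        return RingBoundary(theta=theta, inner_r=rin, outer_r=rout, center=center)

    rings: dict[str, RingBoundary] = {}
    if disk:
        name = "epicarp" if expect is not None and "epicarp" in expect else "shell"
        rings[name] = _boundary(inner_in, inner_out)
        return rings, True
    if m >= 2:
        # rays seeing a single merged run are ambiguous; interpolate them
        two = counts >= 2
        rings["shell"] = _boundary(
            np.where(two, inner_in, np.nan), np.where(two, inner_out, np.nan)
        )
        rings["epicarp"] = _boundary(
            np.where(two, outer_in, np.nan), np.where(two, outer_out, np.nan)
        )
        return rings, False
    # One annular run.  Without a template (or for a dehusked seed, which
    # has no epicarp anywhere) it is the shell.  With a template that has
    # an epicarp, identify it geometrically: the epicarp hugs the fruit
    # surface, the shell sits well inside it.
    name = "shell"
    if expect is not None and "epicarp" in expect:
        at_surface = (
            surface_r is None
            or float(np.nanmedian(outer_out)) >= surface_r - 4.0
        )
        if at_surface:
            name = "epicarp"
    rings[name] = _boundary(inner_in, outer_out)
    return rings, False


# ---------------------------------------------------------------------------
# slice segmentation
# ---------------------------------------------------------------------------

def _bright_threshold(values: np.ndarray) -> float:
    """Upper multi-Otsu boundary separating the densest structures
    (epicarp/shell) from albumen and husk."""
    vals = values[np.isfinite(values)]
    if vals.size < 2 or np.ptp(vals) < 1:
        return float(vals.min()) if vals.size else 255.0
    try:
        t = threshold_multiotsu(vals, classes=3)
        # multiotsu reports bin centres; the half-level offset keeps a
        # discrete gray value sitting exactly on the threshold out of the
        # bright class
        return float(t[-1]) + 0.5
    except ValueError:  # fewer distinct gray levels than classes
        return float(otsu_threshold(np.clip(vals, 0, 255)))


def _assemble_slice(
    image,
    p: SegParams,
    solid_init=None,
    liquid_init=None,
    solid_tol=6.0,
    liquid_tol=6.0,
    expect=None,
    prev_rings=None,
):
    """Shared middle-slice / template-propagation engine.

    ``solid_init``/``liquid_init`` are seed point lists or boolean masks;
    ``expect`` names the classes known to be present (template mode).
    Returns (labels, rings)."""
    img = np.asarray(image, dtype=float)
    labels = np.zeros(img.shape, dtype=np.uint8)
    if img.max() <= 0 or np.ptp(img) < 1:
        return labels, {}
    # CT-unit slices may exceed 255 (dense shell); the foreground split
    # lies well below that, so the 8-bit Otsu runs on the clipped image
    thr = otsu_threshold(np.clip(img, 0, 255))
    fg = remove_small_components(img > thr, p.min_component_px)
    if not fg.any():
        return labels, {}
    fg_filled = ndi.binary_fill_holes(fg)
    center = tuple(np.mean(np.argwhere(fg_filled), axis=0))

    # tissue histogram excludes enclosed gas (cavity reads at the air level)
    tissue = fg_filled & (img > p.air_level + p.air_tolerance)
    bright = (img > _bright_threshold(img[tissue if tissue.any() else fg_filled])) & fg_filled
    bright = remove_small_components(bright, p.min_component_px)
    if not bright.any():
        raise SegmentationError("shell not found: no dense structure in slice")
    # fruit surface radius (median), for single-ring identification
    _, radii_fg, irf, icf, inbf = _polar_samples(
        img.shape, center, p.n_rays, p.radial_step_px
    )
    fg_sampled = _sample_mask(fg_filled, irf, icf, inbf)
    *_r_unused, fg_last, fg_counts, fg_any = _runs_per_ray(fg_sampled)
    surface_r = (
        float(np.nanmedian(np.where(fg_any, radii_fg[np.clip(fg_last - 1, 0, len(radii_fg) - 1)], np.nan)))
        if fg_any.any()
        else None
    )
    rings, disk = _extract_rings(
        bright, center, p, expect=expect, prev_rings=prev_rings, gray=img,
        surface_r=surface_r,
    )

    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    rad = np.hypot(rr - center[0], cc - center[1]).ravel()
    ang = np.arctan2(rr - center[0], cc - center[1]).ravel()
    flat_labels = labels.ravel()

    if disk:
        name = next(iter(rings))
        _, outer = rings[name].interp(ang)
        flat_labels[(rad <= outer) & fg_filled.ravel()] = LABEL_IDS[name]
        return labels, rings

    shell_rb = rings.get("shell")
    epi_rb = rings.get("epicarp")
    if epi_rb is not None:
        e_in, e_out = epi_rb.interp(ang)
        flat_labels[(rad > e_in) & (rad <= e_out)] = EPICARP
        meso_outer = e_in
    else:
        meso_outer = None
    if shell_rb is not None:
        s_in, s_out = shell_rb.interp(ang)
        flat_labels[(rad > s_in) & (rad <= s_out)] = SHELL
        if meso_outer is not None:
            flat_labels[(rad > s_out) & (rad <= meso_outer)] = MESOCARP
        interior = (rad <= s_in).reshape(img.shape)
    else:
        if meso_outer is not None:
            flat_labels[(rad <= meso_outer) & fg_filled.ravel()] = MESOCARP
        interior = np.zeros(img.shape, dtype=bool)

    if interior.any():
        labels[interior] = _INTERIOR
        # competitive growth: both albumen classes flood independently and
        # contested pixels go to the closer class mean (no order bias)
        grown: dict[int, np.ndarray] = {}
        for init, tol, lid in (
            (solid_init, solid_tol, SOLID),
            (liquid_init, liquid_tol, LIQUID),
        ):
            if init is None:
                continue
            if isinstance(init, np.ndarray) and init.dtype == bool:
                init = init & interior
                if not init.any():
                    continue
            grown[lid] = region_grow(img, init, tol, allowed=interior)
        if len(grown) == 2:
            overlap = grown[SOLID] & grown[LIQUID]
            if overlap.any():
                m_s = float(img[grown[SOLID] & ~overlap].mean()) if (grown[SOLID] & ~overlap).any() else float(img[grown[SOLID]].mean())
                m_l = float(img[grown[LIQUID] & ~overlap].mean()) if (grown[LIQUID] & ~overlap).any() else float(img[grown[LIQUID]].mean())
                to_solid = np.abs(img - m_s) <= np.abs(img - m_l)
                grown[SOLID] &= ~overlap | to_solid
                grown[LIQUID] &= ~overlap | ~to_solid
        for lid, g in grown.items():
            labels[g] = lid
        labels = _resplit_albumen(labels, img)
        labels = detect_cavity(labels, img, p)
        labels = _fill_residual(labels, img)
        labels = _majority_smooth_albumen(labels)
    return labels, rings


def _resplit_albumen(labels, img, window_px: int = 21):
    """Re-threshold the solid/liquid band at the *local* half-level.

    Running-mean region growing drifts where low-frequency reconstruction
    artifacts shade a plateau, and with only ~10 CT units between copra
    and coconut water the drift moves the interface.  Each class's level
    is estimated locally (windowed mean over its eroded core, away from
    blurred interfaces) and band pixels are reassigned against the local
    midpoint.
    """
    sol = labels == SOLID
    liq = labels == LIQUID
    if not (sol.any() and liq.any()):
        return labels

    def _local_level(mask):
        core = ndi.binary_erosion(mask, iterations=2)
        if not core.any():
            core = mask
        num = ndi.uniform_filter(np.where(core, img, 0.0), size=window_px)
        den = ndi.uniform_filter(core.astype(float), size=window_px)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = num / den
        level[den <= 0] = np.nan
        return level, float(np.median(img[core]))

    lvl_s, glob_s = _local_level(sol)
    lvl_l, glob_l = _local_level(liq)
    if glob_s <= glob_l + 1.0:
        return labels
    lvl_s = np.where(np.isfinite(lvl_s), lvl_s, glob_s)
    lvl_l = np.where(np.isfinite(lvl_l), lvl_l, glob_l)
    mid = (lvl_s + lvl_l) / 2.0
    band = sol | liq
    out = labels.copy()
    out[band & (img > mid)] = SOLID
    out[band & (img <= mid)] = LIQUID
    return out


def _majority_smooth_albumen(labels, iterations=2):
    """3x3 majority vote between solid and liquid albumen.

    Their gray levels differ by little more than the reconstruction noise,
    so per-pixel assignment leaves salt-and-pepper errors inside each
    region; a masked majority filter removes them while moving the
    interface by at most a pixel.
    """
    band = (labels == SOLID) | (labels == LIQUID)
    if not band.any():
        return labels
    out = labels.copy()
    kernel = np.ones((3, 3))
    for _ in range(iterations):
        solid = (out == SOLID).astype(float)
        inband = ((out == SOLID) | (out == LIQUID)).astype(float)
        n_solid = ndi.convolve(solid, kernel, mode="constant")
        n_band = ndi.convolve(inband, kernel, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_band > 0, n_solid / n_band, 0.5)
        sel = band & (out != CAVITY)
        out[sel & (frac > 0.5)] = SOLID
        out[sel & (frac < 0.5)] = LIQUID
    return out


def _fill_residual(labels, image=None):
    """Assign leftover interior pixels to the nearest class.

    With the gray image available, "nearest" is measured in gray value
    against the labelled class means -- for partial-volume pixels on a
    blurred interface this is the unbiased half-level split.  Without it,
    spatially nearest labelled pixels win.
    """
    residual = labels == _INTERIOR
    if not residual.any():
        return labels
    sources = (labels != BACKGROUND) & ~residual
    if not sources.any():
        labels[residual] = BACKGROUND
        return labels
    out = labels.copy()
    if image is not None:
        img = np.asarray(image, dtype=float)
        # residuals live inside the shell; only interior classes compete
        classes = [
            int(c)
            for c in np.unique(labels[sources])
            if c in (SOLID, LIQUID, CAVITY)
        ] or [int(c) for c in np.unique(labels[sources])]
        means = np.array([img[labels == c].mean() for c in classes])
        dist = np.abs(img[residual][:, None] - means[None, :])
        out[residual] = np.asarray(classes, dtype=labels.dtype)[
            np.argmin(dist, axis=1)
        ]
        return out
    _, (ir, ic) = ndi.distance_transform_edt(~sources, return_indices=True)
    out[residual] = labels[ir[residual], ic[residual]]
    return out


def detect_cavity(slice_labels: np.ndarray, image, params: SegParams | None = None):
    """A-priori cavity rule: connected near-air regions enclosed by the
    shell interior become cavity.

    The gas pocket above the coconut water reads at the air level; any
    sufficiently large shell-interior component with gray level at most
    ``air_level + air_tolerance`` is relabelled.  Finding no cavity is a
    valid outcome.
    """
    p = params or SegParams()
    img = np.asarray(image, dtype=float)
    labels = slice_labels.copy()
    interior = (
        (labels == SOLID)
        | (labels == LIQUID)
        | (labels == CAVITY)
        | (labels == _INTERIOR)
    )
    if not interior.any():
        return labels
    airlike = interior & (img <= p.air_level + p.air_tolerance)
    airlike = remove_small_components(airlike, p.min_component_px)
    labels[airlike] = CAVITY
    return labels


def segment_middle_slice(
    image, seeds: SeedSpec, params: SegParams | None = None
) -> np.ndarray:
    """Segment the middle-height slice from manual seeds and tolerances."""
    p = params or SegParams()
    img = np.asarray(image, dtype=float)
    seeds.validate(img.shape)
    labels, _ = _assemble_slice(
        img,
        p,
        solid_init=seeds.solid_seeds or None,
        liquid_init=seeds.liquid_seeds or None,
        solid_tol=seeds.solid_tolerance,
        liquid_tol=seeds.liquid_tolerance,
    )
    return labels


def propagate_template(
    prev: np.ndarray,
    next_image,
    seeds: SeedSpec | None = None,
    params: SegParams | None = None,
) -> np.ndarray:
    """Segment a neighbouring slice using ``prev`` as a template.

    Each albumen class of the template is eroded to provide region-growing
    seeds; ring boundaries are re-refined on the new image; classes whose
    template area vanished drop out (the cavity rule may still add
    cavity).
    """
    p = params or SegParams()
    s = seeds or SeedSpec()
    prev = np.asarray(prev)
    if not (prev != BACKGROUND).any():
        raise ValueError("empty template")
    if prev.shape != np.asarray(next_image).shape:
        raise ValueError("template and image shapes differ")
    selem = np.ones((2 * p.erosion_px + 1,) * 2, dtype=bool)
    img_next = np.asarray(next_image, dtype=float)

    def _seed_mask(lid, level=None, tol=None):
        m = prev == lid
        if m.sum() < p.min_component_px:
            return None
        er = ndi.binary_erosion(m, structure=selem)
        er = er if er.any() else m
        if level is not None:
            # a class can end between slices; seeds landing on tissue far
            # from the class's CT level would regrow a phantom region
            er = er & (np.abs(img_next - level) <= tol)
            if er.sum() < p.min_component_px:
                return None
        return er

    expect = {
        name
        for name, lid in LABEL_IDS.items()
        if lid != BACKGROUND and (prev == lid).sum() >= p.min_component_px
    }
    # liquid albumen is water, i.e. CT 200 by the normalization convention
    labels, _ = _assemble_slice(
        img_next,
        p,
        solid_init=_seed_mask(SOLID),
        liquid_init=_seed_mask(LIQUID, level=200.0, tol=2.0 * s.liquid_tolerance),
        solid_tol=s.solid_tolerance,
        liquid_tol=s.liquid_tolerance,
        expect=expect,
    )
    return labels


def segment_volume(
    volume,
    seeds: SeedSpec,
    params: SegParams | None = None,
    middle_index: int | None = None,
) -> SegmentationResult:
    """Segment a full gray8/CT stack.

    The middle slice is segmented from the manual seeds, then propagated
    up and down with the template algorithm; the cavity rule runs on every
    slice.  Slices where propagation fails are filled from their nearest
    successfully segmented neighbour and reported in ``failed_slices``.
    """
    p = params or SegParams()
    vol = np.asarray(getattr(volume, "values", volume), dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D stack")
    occupancy = (
        (vol > p.air_level + p.air_tolerance).reshape(vol.shape[0], -1).sum(axis=1)
    )
    nonempty = np.nonzero(occupancy > p.min_component_px)[0]
    if len(nonempty) == 0:
        return SegmentationResult(
            np.zeros(vol.shape, dtype=np.uint8), vol.shape[0] // 2
        )
    mid = middle_index if middle_index is not None else int(np.median(nonempty))
    labels = np.zeros(vol.shape, dtype=np.uint8)
    labels[mid] = segment_middle_slice(vol[mid], seeds, p)
    failed: list[int] = []
    for direction in (1, -1):
        prev = labels[mid]
        k = mid + direction
        while 0 <= k < vol.shape[0]:
            if occupancy[k] <= p.min_component_px or not (prev != BACKGROUND).any():
                prev = np.zeros_like(prev)
                labels[k] = prev
            else:
                try:
                    labels[k] = propagate_template(prev, vol[k], seeds, p)
                except (SegmentationError, ValueError):
                    failed.append(k)
                    labels[k] = prev  # interpolated from the nearest neighbour
                prev = labels[k]
            k += direction
    if failed:
        logger.warning(
            "propagation failed on %d slices: %s", len(failed), sorted(failed)[:10]
        )
    _refine_meniscus(labels, vol, p)
    return SegmentationResult(
        labels=labels, middle_index=mid, failed_slices=sorted(failed)
    )


def _refine_meniscus(labels, vol, p: SegParams) -> None:
    """3-D half-level refinement of the liquid/cavity interface.

    A slice cutting the gas-liquid meniscus averages air and liquid, so
    per-slice rules misplace the boundary by up to one slice.  Voxels are
    reassigned by propagating each phase into the other where the CT value
    falls on its side of the air/liquid midpoint.
    """
    liquid = labels == LIQUID
    cav = labels == CAVITY
    if not cav.any():
        return
    interior = liquid | (labels == SOLID)
    if not interior.any():
        return
    level = float(np.median(vol[liquid])) if liquid.any() else 200.0
    mid = (p.air_level + level) / 2.0
    s6 = ndi.generate_binary_structure(3, 1)
    to_cav = ndi.binary_propagation(
        cav, mask=cav | (interior & (vol < mid)), structure=s6
    )
    labels[to_cav & interior] = CAVITY
    if liquid.any():
        to_liq = ndi.binary_propagation(
            liquid, mask=liquid | (cav & (vol > mid)), structure=s6
        )
        labels[to_liq & cav] = LIQUID


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Per-class precision/recall/F1/IoU and their macro averages over the
    classes present in the ground truth (background excluded)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    classes = [int(c) for c in np.unique(truth) if c != BACKGROUND]
    per_class: dict[int, dict[str, float]] = {}
    for c in classes:
        tp = float(np.sum((pred == c) & (truth == c)))
        fp = float(np.sum((pred == c) & (truth != c)))
        fn = float(np.sum((pred != c) & (truth == c)))
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        iou = tp / (tp + fp + fn) if tp + fp + fn > 0 else 0.0
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "iou": iou,
        }
    if not per_class:
        raise ValueError("ground truth contains no foreground class")
    macro = {
        k: float(np.mean([m[k] for m in per_class.values()]))
        for k in ("precision", "recall", "f1", "iou")
    }
    return SegMetrics(per_class=per_class, **macro)


# ---------------------------------------------------------------------------
# pluggable slice-segmenter interface
# ---------------------------------------------------------------------------

class SliceSegmenter:
    """Interface for slice segmentation backends.

    The classical algorithm is the default; adapters for learned models
    (e.g. an encoder-decoder semantic segmentation network) can be
    registered in :data:`SEGMENTERS` and must implement ``segment``.
    """

    def segment(self, image, template=None) -> np.ndarray:
        raise NotImplementedError


class ClassicalSliceSegmenter(SliceSegmenter):
    """Default backend wrapping the classical semi-automatic algorithm."""

    def __init__(self, seeds: SeedSpec, params: SegParams | None = None):
        self.seeds = seeds
        self.params = params or SegParams()

    def segment(self, image, template=None) -> np.ndarray:
        if template is None:
            return segment_middle_slice(image, self.seeds, self.params)
        return propagate_template(template, image, self.seeds, self.params)


#: Registry of available slice segmenters; the deep-model slot ships empty.
SEGMENTERS: dict[str, type[SliceSegmenter]] = {"classical": ClassicalSliceSegmenter}
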