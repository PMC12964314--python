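"""Midsagittal-plane detection by Radon transform and symmetry.

The interhemispheric fissure appears as a dark, nearly straight line in
upper-brain axial slices.  The detector computes a Radon transform (line
averages indexed by normal direction ``theta`` and signed offset ``s``
from the slice's center of mass) and takes the minimum cell as the
fissure line, yielding the yaw angle and in-slice offset.  The roll angle
is found by rotating the central coronal slice of the yaw-aligned volume
over candidate angles and maximizing mirror symmetry about the midline
column.  Per-slice line estimates from several axial heights are combined
by the median for robustness, after correcting each offset for the roll
tilt at its slice height.  Finally the volume is resampled so the
detected plane becomes the central sagittal plane, the plane image is
standardized to 176x256 pixels, and a 128x128 ROI containing the
brainstem is cropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import PlaneParams, plane_coordinates, volume_center
from .phantom import MSP_SHAPE, ROI_SHAPE, DEFAULT_ROI_ORIGIN

__all__ = [
    "MspConfig", "Sinogram", "MspImage", "RoiImage",
    "select_axial_slice", "radon_transform", "find_msp_line",
    "estimate_roll", "extract_msp", "detect",
]


@dataclass(frozen=True)
class MspConfig:
    """Search grids and conventions of the detector.

    Angle grids span the accepted (-10, 10) degree range; the offset grid
    is centered on the slice's center of mass.  ``slice_fractions`` are
    heights within the foreground extent, measured from the superior end,
    at which axial slices are analyzed.
    """

    theta_step: float = 0.25  # degrees
    theta_max: float = 10.0
    s_step: float = 0.5  # voxels
    s_max: float = 20.0
    phi_step: float = 0.25
    phi_max: float = 9.75
    slice_fractions: tuple[float, ...] = (0.15, 0.20, 0.25, 0.30, 0.35)
    min_line_length: float = 16.0
    roi_origin: tuple[int, int] = DEFAULT_ROI_ORIGIN

    def theta_grid(self) -> np.ndarray:
        n = int(round(self.theta_max / self.theta_step))
        return np.arange(-n, n + 1) * self.theta_step

    def s_grid(self) -> np.ndarray:
        n = int(round(self.s_max / self.s_step))
        return np.arange(-n, n + 1) * self.s_step

    def phi_grid(self) -> np.ndarray:
        n = int(round(self.phi_max / self.phi_step))
        return np.arange(-n, n + 1) * self.phi_step


@dataclass
class Sinogram:
    """Line-average values over the (theta, s) search grid."""

    values: np.ndarray  # (n_theta, n_s)
    theta_grid: np.ndarray  # degrees
    s_grid: np.ndarray  # voxels
    origin: tuple[float, float]  # (row, col) Radon origin (center of mass)
    valid: np.ndarray  # bool, same shape as values


@dataclass
class MspImage:
    """Standardized 176x256 midsagittal-plane image."""

    intensities: np.ndarray
    pixel_spacing: tuple[float, float]
    provenance: PlaneParams


@dataclass
class RoiImage:
    """128x128 brainstem region of interest within the MSP image."""

    intensities: np.ndarray
    pixel_spacing: tuple[float, float]
    roi_origin: tuple[int, int]


class MspDetectionError(RuntimeError):
    """A detection stage failed; ``stage`` identifies which."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


def _foreground_extent(volume: np.ndarray) -> tuple[int, int]:
    fg = volume > 0.1 * float(volume.max())
    rows = np.flatnonzero(fg.any(axis=(1, 2)))
    if rows.size == 0:
        raise MspDetectionError("select_axial_slice", "volume is empty")
    return int(rows[0]), int(rows[-1])


def select_axial_slice(volume: np.ndarray, fraction: float = 0.25
                       ) -> tuple[np.ndarray, tuple[float, float], int]:
    """Pick an upper-brain axial slice and its binarized center of mass.

    ``fraction`` is the height within the foreground extent measured from
    the superior end (row 0); the default lands in the upper quarter of
    the head, above the brainstem.  The center of mass is computed on the
    Otsu-thresholded slice.  Returns (slice, (com_row, com_col), z index).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.shape[0] < 10:
        raise MspDetectionError("select_axial_slice",
                                "need a 3D volume with >= 10 axial slices")
    z0, z1 = _foreground_extent(volume)
    z = int(round(z0 + fraction * (z1 - z0)))
    sl = volume[z].astype(float)
    if not np.any(sl > 0):
        raise MspDetectionError(
            "select_axial_slice",
            f"axial slice at fraction {fraction} is empty; "
            "try a different slice fraction")
    binary = sl > threshold_otsu(sl)
    if not binary.any():
        raise MspDetectionError("select_axial_slice",
                                "thresholded slice is empty")
    com = ndimage.center_of_mass(binary)
    return sl, (float(com[0]), float(com[1])), z


def radon_transform(slice_2d: np.ndarray, origin: tuple[float, float],
                    theta_grid: np.ndarray, s_grid: np.ndarray,
                    min_line_length: float = 16.0) -> Sinogram:
    """Line-average Radon transform about an arbitrary origin.

    Cell (theta, s) holds the mean intensity along the line
    ``{p : (p - origin) . (sin t, cos t) = s}`` (components in (row, col)
    order, theta measured from the +col axis), sampled at unit steps with
    bilinear interpolation.  Cells whose line intersects the image support
    in fewer than ``min_line_length`` samples are flagged invalid.
    """
    img = np.asarray(slice_2d, dtype=float)
    h, w = img.shape
    oy, ox = origin
    if not (0 <= oy < h and 0 <= ox < w):
        raise ValueError("origin must lie inside the slice")
    theta_grid = np.asarray(theta_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)

    half = int(np.ceil(np.hypot(h, w) / 2)) + 1
    t_steps = np.arange(-half, half + 1, dtype=float)

    t = np.deg2rad(theta_grid)[:, None, None]
    s = s_grid[None, :, None]
    steps = t_steps[None, None, :]
    # normal (sin t, cos t), direction (cos t, -sin t) in (row, col)
    rows = oy + s * np.sin(t) + steps * np.cos(t)
    cols = ox + s * np.cos(t) - steps * np.sin(t)
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    vals = ndimage.map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="constant",
        cval=0.0).reshape(rows.shape)
    counts = inside.sum(axis=2)
    sums = np.where(inside, vals, 0.0).sum(axis=2)
    valid = counts >= min_line_length
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(valid, sums / np.maximum(counts, 1), np.nan)
    return Sinogram(values=values, theta_grid=theta_grid, s_grid=s_grid,
                    origin=(float(oy), float(ox)), valid=valid)


def find_msp_line(sino: Sinogram) -> tuple[float, float]:
    """Location (theta*, s*) of the minimal valid sinogram cell.

    Ties are broken by smallest ``|theta|``, then smallest ``|s|``, then
    the smaller signed value of each.
    """
    if not sino.valid.any():
        raise MspDetectionError("find_msp_line", "sinogram has no valid cell")
    vals = np.where(sino.valid, sino.values, np.inf)
    ti, si = np.nonzero(vals == vals.min())
    theta = sino.theta_grid[ti]
    s = sino.s_grid[si]
    order = np.lexsort((s, theta, np.abs(s), np.abs(theta)))
    k = order[0]
    return float(theta[k]), float(s[k])


def estimate_roll(coronal: np.ndarray, midline_column: float,
                  phi_grid: np.ndarray) -> float:
    """Roll angle maximizing vertical mirror symmetry of a coronal slice.

    For each candidate angle the slice is rotated about its center and
    scored by the negative mean absolute difference between the rotated
    image and its mirror about ``midline_column``, over foreground pixels.
    Ties go to the smallest ``|phi|``.
    """
    img = np.asarray(coronal, dtype=float)
    phi_grid = np.asarray(phi_grid, dtype=float)
    if np.any(np.abs(phi_grid) >= 10.0):
        raise ValueError("phi grid must lie within (-10, 10) degrees")
    fg_level = 0.1 * float(img.max())
    if not np.any(img > fg_level):
        raise MspDetectionError("estimate_roll", "coronal slice has no "
                                "foreground")
    h, w = img.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    mirror_cols = 2.0 * midline_column - cc
    scores = np.full(phi_grid.shape, -np.inf)
    for i, phi in enumerate(phi_grid):
        rot = ndimage.rotate(img, phi, reshape=False, order=1,
                             mode="constant", cval=0.0)
        mirrored = ndimage.map_coordinates(rot, [rr, mirror_cols], order=1,
                                           mode="constant", cval=np.nan)
        both = (rot > fg_level) & np.isfinite(mirrored)
        if not both.any():
            continue
        scores[i] = -np.mean(np.abs(rot[both] - mirrored[both]))
    if not np.isfinite(scores).any():
        raise MspDetectionError("estimate_roll",
                                "no candidate angle produced overlap")
    best = scores.max()
    cand = np.flatnonzero(scores == best)
    k = cand[np.lexsort((phi_grid[cand], np.abs(phi_grid[cand])))[0]]
    return float(phi_grid[k])


def extract_msp(volume: np.ndarray, params: PlaneParams,
                voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                ) -> MspImage:
    """Resample the detected plane into a standardized 176x256 image.

    The output pixel (i, j) samples the volume at the plane-aligned
    coordinates mapped through the pixel-center-preserving rescale from
    the native (nz, ny) sagittal geometry to 176x256.
    """
    if not (-10.0 <= params.yaw <= 10.0 and -10.0 <= params.roll <= 10.0):
        raise ValueError("plane parameters outside the accepted search range")
    nz, ny, nx = volume.shape
    c = volume_center(volume.shape)
    if abs(params.distance) >= nx / 2:
        raise MspDetectionError("extract_msp", "plane outside volume support")
    ii, jj = np.mgrid[0:MSP_SHAPE[0], 0:MSP_SHAPE[1]].astype(float)
    u = (ii + 0.5) * nz / MSP_SHAPE[0] - 0.5 - c[0]
    v = (jj + 0.5) * ny / MSP_SHAPE[1] - 0.5 - c[1]
    coords = plane_coordinates(volume.shape, params, u, v, np.zeros_like(u))
    vals = ndimage.map_coordinates(np.asarray(volume, dtype=float), coords,
                                   order=1, mode="constant", cval=0.0)
    sz, sy, _ = voxel_spacing
    spacing = (sz * nz / MSP_SHAPE[0], sy * ny / MSP_SHAPE[1])
    return MspImage(intensities=vals, pixel_spacing=spacing,
                    provenance=params)


def crop_roi(msp: MspImage, roi_origin: tuple[int, int] = DEFAULT_ROI_ORIGIN
             ) -> RoiImage:
    r0, c0 = roi_origin
    window = msp.intensities[r0:r0 + ROI_SHAPE[0], c0:c0 + ROI_SHAPE[1]]
    if window.shape != ROI_SHAPE:
        raise ValueError("ROI window exceeds the MSP image")
    return RoiImage(intensities=window, pixel_spacing=msp.pixel_spacing,
                    roi_origin=roi_origin)


def aggregate_distances(distances: np.ndarray) -> float:
    """Median aggregation of per-slice offsets (outlier-robust)."""
    return float(np.median(np.asarray(distances, dtype=float)))


def _coronal_slice_aligned(volume: np.ndarray, yaw: float) -> np.ndarray:
    """Central coronal slice after derotating the axial stack by -yaw."""
    nz, ny, nx = volume.shape
    c = volume_center(volume.shape)
    t = np.deg2rad(yaw)
    zz, xx = np.mgrid[0:nz, 0:nx].astype(float)
    dx = xx - c[2]
    # the aligned coronal plane y' = cy corresponds to rotating (y, x)
    # about (cy, cx) by +yaw
    rows = np.full_like(dx, 0.0)
    y_src = c[1] + rows * np.cos(t) + dx * np.sin(t)
    x_src = c[2] - rows * np.sin(t) + dx * np.cos(t)
    coords = [zz, y_src, x_src]
    return ndimage.map_coordinates(np.asarray(volume, dtype=float), coords,
                                   order=1, mode="constant", cval=0.0)


def detect(volume: np.ndarray, config: MspConfig | None = None,
           voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
           ) -> tuple[PlaneParams, MspImage, RoiImage]:
    """Full midsagittal-plane detection.

    Runs the Radon stage on several axial slices, estimates the roll on
    the central coronal slice of the yaw-aligned volume, corrects each
    per-slice offset for the roll tilt at its height, aggregates by the
    median, and returns the plane parameters together with the
    standardized MSP image and its brainstem ROI.
    """
    cfg = config or MspConfig()
    volume = np.asarray(volume)
    nz, ny, nx = volume.shape
    c = volume_center(volume.shape)

    theta_grid = cfg.theta_grid()
    s_grid = cfg.s_grid()
    per_slice = []  # (z, theta_ax, s about volume center axis)
    for frac in cfg.slice_fractions:
        try:
            sl, com, z = select_axial_slice(volume, fraction=frac)
        except MspDetectionError:
            continue
        sino = radon_transform(sl, com, theta_grid, s_grid,
                               min_line_length=cfg.min_line_length)
        if not sino.valid.any():
            continue
        theta_ax, s_com = find_msp_line(sino)
        t = np.deg2rad(theta_ax)
        # re-reference the offset from the slice COM to the volume center
        n_hat = np.array([np.sin(t), np.cos(t)])  # (row, col) = (y, x)
        s_center = s_com + float(
            n_hat @ (np.array(com) - np.array([c[1], c[2]])))
        per_slice.append((z, theta_ax, s_center))
    if not per_slice:
        raise MspDetectionError("radon", "no axial slice produced a valid "
                                "sinogram")

    theta_ax_med = float(np.median([t for _, t, _ in per_slice]))
    # the in-slice offsets vary linearly with slice height when the plane
    # is rolled; extrapolating to the central height gives an unbiased
    # midline column for the symmetry stage
    zs = np.array([z for z, _, _ in per_slice], dtype=float)
    ss = np.array([s for _, _, s in per_slice], dtype=float)
    if len(per_slice) >= 2 and np.ptp(zs) > 0:
        slope, intercept = np.polyfit(zs, ss, 1)
        s_mid = float(slope * c[0] + intercept)
    else:
        s_mid = float(np.median(ss))

    coronal = _coronal_slice_aligned(volume, theta_ax_med)
    phi_star = estimate_roll(coronal, c[2] + s_mid, cfg.phi_grid())

    # undo the axial-projection bias: the in-slice line angle theta_ax and
    # offset s_ax relate to the true plane (yaw, roll, distance) through
    #   tan(theta_ax) = tan(yaw) / cos(roll)
    #   s_ax * N = distance - sin(roll) cos(yaw) (z - cz),
    # with N = hypot(sin(yaw), cos(roll) cos(yaw))
    p = np.deg2rad(phi_star)
    yaw = float(np.rad2deg(np.arctan(np.tan(np.deg2rad(theta_ax_med))
                                     * np.cos(p))))
    ty = np.deg2rad(yaw)
    n_norm = float(np.hypot(np.sin(ty), np.cos(p) * np.cos(ty)))
    dists = [s * n_norm + np.sin(p) * np.cos(ty) * (z - c[0])
             for z, _, s in per_slice]
    distance = aggregate_distances(np.asarray(dists))

    params = PlaneParams(yaw=yaw, roll=phi_star, distance=distance)
    msp = extract_msp(volume, params, voxel_spacing)
    roi = crop_roi(msp, cfg.roi_origin)
    return params, msp, roi
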