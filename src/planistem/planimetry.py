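"""Planimetric measurement of binary segmentation masks.

Areas are obtained by counting foreground pixels and multiplying by the
pixel area.  Anteroposterior diameters are obtained by fitting an ellipse
to the boundary points of the mask in the (algebraic) least-squares sense
and taking the length of its minor axis, following the standard manual
planimetry protocol in which diameters are read off the minor axis of an
ellipse fitted to the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

__all__ = [
    "EllipseParams", "PlanimetricReport", "area_from_mask",
    "boundary_points", "fit_ellipse", "fit_mask_ellipse", "diameter",
    "measure", "rasterize_ellipse",
]

#: structuring element for the 4-neighborhood exterior test
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class EllipseParams:
    """Geometric parameters of an ellipse in pixel coordinates.

    ``center`` is (row, col); ``orientation`` is the angle of the major
    axis in degrees, counter-clockwise from the column (+x) axis.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})")


@dataclass
class PlanimetricReport:
    """Areas (mm^2) and diameters (mm) of midbrain and pons for one scan."""

    midbrain_area: float | None
    pons_area: float | None
    midbrain_diameter: float | None
    pons_diameter: float | None
    pixel_spacing: tuple[float, float]
    failures: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "midbrain_area_mm2": self.midbrain_area,
            "pons_area_mm2": self.pons_area,
            "midbrain_diameter_mm": self.midbrain_diameter,
            "pons_diameter_mm": self.pons_diameter,
            "pixel_spacing_mm": list(self.pixel_spacing),
            "failures": dict(self.failures),
            "provenance": dict(self.provenance),
        }


def area_from_mask(mask: np.ndarray, pixel_spacing: tuple[float, float]
                   ) -> float:
    """Foreground pixel count times the pixel area, in mm^2."""
    sy, sx = pixel_spacing
    if sy <= 0 or sx <= 0:
        raise ValueError("pixel spacing must be positive")
    return float(np.count_nonzero(mask) * sy * sx)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-neighbor outside the foreground.

    Pixels outside the image count as background, so structure pixels on
    the image border are boundary pixels.  Returns an (n, 2) array of
    (row, col) pixel-center coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior).astype(float)


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit to a set of (row, col) points.

    Minimizes the algebraic residual of the conic, constrained to
    ellipses (Halir-Flusser / Fitzgibbon direct fit).  Raises
    ``ValueError`` for fewer than 5 points or degenerate configurations
    (collinear points, non-elliptical solutions).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    # rank check catches collinear input before the conic solve
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("points are collinear; no ellipse fits them")
    # skimage works in (x, y) = (col, row)
    model = EllipseModel.from_estimate(pts[:, ::-1])
    if not model:
        raise ValueError("direct least-squares fit did not yield an ellipse")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = np.rad2deg(model.theta)
    if b > a:
        a, b = b, a
        theta += 90.0
    theta = (theta + 90.0) % 180.0 - 90.0
    if b <= 0 or not np.isfinite([xc, yc, a, b, theta]).all():
        raise ValueError("degenerate ellipse fit")
    return EllipseParams(center=(float(yc), float(xc)), semi_major=float(a),
                         semi_minor=float(b), orientation=float(theta))


def diameter(e: EllipseParams, pixel_spacing: tuple[float, float]) -> float:
    """Minor-axis length of the ellipse, converted to mm.

    Requires isotropic pixel spacing; with anisotropic pixels the mask
    must be resampled before fitting, otherwise the minor axis has no
    single mm scale.
    """
    sy, sx = pixel_spacing
    if not np.isclose(sy, sx):
        raise ValueError(
            "anisotropic pixel spacing: resample the mask before fitting")
    return float(2.0 * e.semi_minor * sx)


def rasterize_ellipse(shape: tuple[int, int], e: EllipseParams) -> np.ndarray:
    """Boolean mask of pixel centers inside the ellipse."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    t = np.deg2rad(e.orientation)
    x = cc - e.center[1]
    y = rr - e.center[0]
    xp = x * np.cos(t) + y * np.sin(t)
    yp = -x * np.sin(t) + y * np.cos(t)
    return (xp / e.semi_major) ** 2 + (yp / e.semi_minor) ** 2 <= 1.0


def fit_mask_ellipse(mask: np.ndarray,
                     boundary_offset: float = 0.5) -> EllipseParams:
    """Least-squares ellipse of a mask's boundary, rasterization-corrected.

    Boundary pixel centers lie on average half a pixel inside the
    continuous outline that produced the mask, so the fitted semi-axes
    are inflated by ``boundary_offset`` (pixels) to remove that bias.
    """
    e = fit_ellipse(boundary_points(mask))
    return replace(e, semi_major=e.semi_major + boundary_offset,
                   semi_minor=e.semi_minor + boundary_offset)


def _measure_diameter(mask: np.ndarray, spacing: tuple[float, float]):
    ellipse = fit_mask_ellipse(mask)
    return diameter(ellipse, spacing), ellipse


def measure(masks: dict[str, np.ndarray],
            pixel_spacing: tuple[float, float],
            provenance: dict | None = None) -> PlanimetricReport:
    """Planimetric report from the four task masks.

    ``masks`` must contain ``midbrain_area``, ``pons_area``,
    ``midbrain_ellipse`` and ``pons_ellipse``.  Empty masks are recorded
    as failures with null measurements rather than raised, mirroring the
    empty-output failure mode of a segmentation network under heavy
    noise.
    """
    required = {"midbrain_area", "pons_area", "midbrain_ellipse",
                "pons_ellipse"}
    missing = required - set(masks)
    if missing:
        raise ValueError(f"missing masks: {sorted(missing)}")

    failures: dict[str, str] = {}
    values: dict[str, float | None] = {}
    for name in ("midbrain_area", "pons_area"):
        if not np.any(masks[name]):
            failures[name] = "empty mask"
            values[name] = None
        else:
            values[name] = area_from_mask(masks[name], pixel_spacing)
    ellipses = {}
    for name in ("midbrain_ellipse", "pons_ellipse"):
        if not np.any(masks[name]):
            failures[name] = "empty mask"
            values[name] = None
            continue
        try:
            values[name], ellipses[name] = _measure_diameter(
                masks[name], pixel_spacing)
        except ValueError as exc:
            failures[name] = str(exc)
            values[name] = None

    prov = dict(provenance or {})
    prov["ellipses"] = {k: {"center": list(v.center),
                            "semi_major": v.semi_major,
                            "semi_minor": v.semi_minor,
                            "orientation": v.orientation}
                        for k, v in ellipses.items()}
    return PlanimetricReport(
        midbrain_area=values["midbrain_area"],
        pons_area=values["pons_area"],
        midbrain_diameter=values["midbrain_ellipse"],
        pons_diameter=values["pons_ellipse"],
        pixel_spacing=tuple(pixel_spacing),
        failures=failures,
        provenance=prov,
    )
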