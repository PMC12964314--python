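"""Synthetic head phantoms with known midsagittal geometry.

The phantom emulates the features of a T1-weighted head volume that the
planimetry pipeline actually relies on: a bright, approximately
ellipsoidal head on a dark background; a dark planar interhemispheric
fissure at a known yaw/roll/offset; and bright midline brainstem-like
structures (a bean-shaped "midbrain", an oval "pons") rendered on the
plane, with exact ground-truth masks and ellipses.  Before noise, the
volume is mirror-symmetric about the true plane by construction: every
intensity term depends on the plane-aligned coordinates only through the
absolute distance to the plane.

Two-dimensional ROI scenes (128x128) with the same structures serve as
training pairs for the segmentation networks.  Gaussian and Rician noise
can be added at a controlled signal-to-noise ratio.

Ellipse conventions follow :mod:`planistem.planimetry`: axes are given as
semi-lengths along the (x, y) = (col, row) template axes and orientations
are degrees counter-clockwise from +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import PlaneParams, rotation_matrix, volume_center
from .planimetry import EllipseParams, rasterize_ellipse

__all__ = [
    "StructureParams", "PhantomSpec", "RoiScene", "PhantomVolume",
    "make_roi_scene", "make_volume", "add_noise", "save_scene",
    "MSP_SHAPE", "ROI_SHAPE", "DEFAULT_ROI_ORIGIN",
]

#: fixed output geometry of the midsagittal-plane image and its ROI
MSP_SHAPE = (176, 256)
ROI_SHAPE = (128, 128)
#: (row, col) of the ROI window inside the MSP image: centered
#: horizontally, shifted toward the inferior half where the brainstem sits
DEFAULT_ROI_ORIGIN = (40, 64)

_MASK_NAMES = ("midbrain_area", "midbrain_ellipse", "pons_area",
               "pons_ellipse")


@dataclass(frozen=True)
class StructureParams:
    """Shape templates for the midline structures, in ROI pixel units.

    The midbrain template is the union of two overlapping ellipses
    ("lobes", one per cerebral peduncle) minus a notch at its superior
    edge; the pons is a single filled ellipse elongated along the
    superior-inferior axis.  Poses are jittered per scene within the
    stated bounds; a smooth low-order radial deformation adds outline
    variability.  Intensity levels are on the [0, 1] image scale: each
    structure body is brighter than the background and each ellipse core
    (the diameter-measurement region) is brighter still, so all four
    segmentation tasks are learnable from intensity alone.
    """

    midbrain_center: tuple[float, float] = (40.0, 60.0)  # (row, col)
    midbrain_lobe_axes: tuple[float, float] = (10.0, 15.0)  # (semi_x, semi_y)
    midbrain_lobe_offset: float = 5.0
    midbrain_notch_axes: tuple[float, float] = (6.0, 5.0)
    pons_center: tuple[float, float] = (84.0, 64.0)
    pons_ellipse_axes: tuple[float, float] = (15.0, 21.0)
    pons_area_factor: float = 1.22
    jitter_px: float = 5.0
    max_rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    deform_amp: float = 0.06
    background_level: float = 0.32
    texture_amp: float = 0.04
    #: Gaussian PSF (pixels) applied to scene images only: emulates the
    #: partial-volume softening of a resampled MRI slice; masks stay crisp
    psf_sigma: float = 0.7
    levels: dict = field(default_factory=lambda: {
        "midbrain_area": 0.62, "midbrain_ellipse": 0.78,
        "pons_area": 0.58, "pons_ellipse": 0.72})


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic head volume."""

    shape: tuple[int, int, int] = (176, 256, 256)
    head_semi_axes: tuple[float, float, float] | None = None
    fissure_yaw: float = 0.0
    fissure_roll: float = 0.0
    fissure_offset: float = 0.0
    fissure_width: float = 3.0
    fissure_contrast: float = 0.6
    structure_params: StructureParams = field(default_factory=StructureParams)
    noise_model: str = "none"
    snr: float | None = None
    seed: int = 0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_origin: tuple[int, int] = DEFAULT_ROI_ORIGIN

    def resolved_semi_axes(self) -> tuple[float, float, float]:
        """Head ellipsoid semi-axes along (in-plane z, in-plane y, normal)."""
        if self.head_semi_axes is not None:
            return self.head_semi_axes
        nz, ny, nx = self.shape
        return (0.46 * nz, 0.42 * ny, 0.40 * nx)

    def validate(self) -> None:
        if not (-10.0 < self.fissure_yaw < 10.0
                and -10.0 < self.fissure_roll < 10.0):
            raise ValueError("fissure yaw/roll must lie within (-10, 10) deg")
        if not (0.0 < self.fissure_contrast <= 1.0):
            raise ValueError("fissure_contrast must be in (0, 1]")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and (self.snr is None or self.snr <= 0):
            raise ValueError("snr must be positive when noise is requested")
        nz, ny, nx = self.shape
        au, av, _ = self.resolved_semi_axes()
        # the structure region (lower part of the ROI window) must lie
        # inside the head ellipsoid, otherwise the brainstem floats in air
        r0, c0 = self.roi_origin
        for msp_r, msp_c in ((r0 + 122, c0 + 92), (r0 + 122, c0 + 36)):
            u = (msp_r + 0.5) * nz / MSP_SHAPE[0] - 0.5 - (nz - 1) / 2.0
            v = (msp_c + 0.5) * ny / MSP_SHAPE[1] - 0.5 - (ny - 1) / 2.0
            if (u / au) ** 2 + (v / av) ** 2 > 0.95:
                raise ValueError(
                    "head semi-axes too small to contain the brainstem "
                    "structures inside the ROI window")


@dataclass
class RoiScene:
    """A 128x128 midplane scene with ground-truth masks and ellipses."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    truth_ellipses: dict[str, EllipseParams]
    seed: int


@dataclass
class PhantomVolume:
    """A rendered phantom with its complete ground truth."""

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]
    truth_plane: PlaneParams
    truth_masks: dict[str, np.ndarray]  # on the MSP pixel grid (176x256)
    truth_roi_origin: tuple[int, int]
    roi_truth: RoiScene  # same ground truth cropped to the ROI window
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# analytic scene model
# ---------------------------------------------------------------------------

def _ellipse_frame(rr, cc, center, angle_deg):
    """Rotated template frame (x along the template +x axis)."""
    t = np.deg2rad(angle_deg)
    x = np.asarray(cc, dtype=float) - center[1]
    y = np.asarray(rr, dtype=float) - center[0]
    xp = x * np.cos(t) + y * np.sin(t)
    yp = -x * np.sin(t) + y * np.cos(t)
    return xp, yp


def _deformed_q(rr, cc, center, axes, angle_deg, deform):
    """Normalized radius q and deformed outline radius rho(alpha).

    ``axes`` = (semi_x, semi_y) in the rotated template frame; ``deform``
    is a list of (mode, amplitude, phase) radial perturbations.
    """
    xp, yp = _ellipse_frame(rr, cc, center, angle_deg)
    ax, ay = axes
    q = np.sqrt((xp / ax) ** 2 + (yp / ay) ** 2)
    rho = np.ones_like(q)
    if deform:
        alpha = np.arctan2(yp, xp)
        for k, amp, phase in deform:
            rho = rho + amp * np.cos(k * alpha + phase)
    return q, rho


def _soft(q, rho, axes, edge=1.5):
    """Soft (partial-volume-like) coverage across the outline."""
    return np.clip(0.5 + (rho - q) * min(axes) / edge, 0.0, 1.0)


def _ellipse_params(center, semi_x, semi_y, angle_deg) -> EllipseParams:
    """Normalize a template ellipse to major/minor + orientation form."""
    if semi_x >= semi_y:
        a, b, t = semi_x, semi_y, angle_deg
    else:
        a, b, t = semi_y, semi_x, angle_deg + 90.0
    t = (t + 90.0) % 180.0 - 90.0
    return EllipseParams(center=tuple(center), semi_major=float(a),
                         semi_minor=float(b), orientation=float(t))


@dataclass
class _SceneModel:
    """Sampled analytic parameters of one scene, in ROI pixel coords."""

    params: StructureParams
    mb_center: tuple[float, float]
    mb_angle: float
    mb_lobe_axes: tuple[float, float]  # (semi_x, semi_y)
    mb_lobe_offset: float
    mb_notch_center: tuple[float, float]
    mb_notch_axes: tuple[float, float]
    mb_deform: list
    pons_center: tuple[float, float]
    pons_angle: float
    pons_axes: tuple[float, float]  # (semi_x, semi_y)
    pons_area_deform: list
    texture_phases: tuple[float, float]
    mb_ellipse: EllipseParams | None = None
    pons_ellipse: EllipseParams | None = None

    def _lobe_centers(self):
        t = np.deg2rad(self.mb_angle)
        dc = self.mb_lobe_offset * np.cos(t)
        dr = self.mb_lobe_offset * np.sin(t)
        cr, ccol = self.mb_center
        return ((cr - dr, ccol - dc), (cr + dr, ccol + dc))

    # --- hard (pixel-center) inside tests ---------------------------------
    def midbrain_area_inside(self, rr, cc):
        inside = np.zeros(np.shape(rr), dtype=bool)
        for c in self._lobe_centers():
            q, rho = _deformed_q(rr, cc, c, self.mb_lobe_axes, self.mb_angle,
                                 self.mb_deform)
            inside |= q <= rho
        qn, _ = _deformed_q(rr, cc, self.mb_notch_center, self.mb_notch_axes,
                            self.mb_angle, [])
        # the pons is rendered over the midbrain, so pixels inside both
        # templates look like pons and belong to the pons label only
        return inside & ~(qn <= 1.0) & ~self.pons_area_inside(rr, cc)

    def pons_area_inside(self, rr, cc):
        q, rho = _deformed_q(rr, cc, self.pons_center, self.pons_axes,
                             self.pons_angle, self.pons_area_deform)
        return q <= rho * self.params.pons_area_factor

    def masks_on_grid(self, rr, cc):
        def ell_inside(e):
            q, _ = _deformed_q(rr, cc, e.center,
                               (e.semi_major, e.semi_minor), e.orientation,
                               [])
            return q <= 1.0

        return {
            "midbrain_area": self.midbrain_area_inside(rr, cc),
            "midbrain_ellipse": ell_inside(self.mb_ellipse),
            "pons_area": self.pons_area_inside(rr, cc),
            "pons_ellipse": ell_inside(self.pons_ellipse),
        }

    # --- soft coverage for image rendering --------------------------------
    def coverage_layers(self, rr, cc):
        """Ordered (level, alpha) layers; later layers paint over earlier."""
        lv = self.params.levels
        layers = []
        mb = np.zeros(np.shape(rr), dtype=float)
        for c in self._lobe_centers():
            q, rho = _deformed_q(rr, cc, c, self.mb_lobe_axes, self.mb_angle,
                                 self.mb_deform)
            mb = np.maximum(mb, _soft(q, rho, self.mb_lobe_axes))
        qn, rn = _deformed_q(rr, cc, self.mb_notch_center, self.mb_notch_axes,
                             self.mb_angle, [])
        mb = mb * (1.0 - _soft(qn, rn, self.mb_notch_axes))
        layers.append((lv["midbrain_area"], mb))

        for name, e in (("midbrain_ellipse", self.mb_ellipse),
                        ("pons_area", None), ("pons_ellipse",
                                              self.pons_ellipse)):
            if name == "pons_area":
                q, rho = _deformed_q(rr, cc, self.pons_center, self.pons_axes,
                                     self.pons_angle, self.pons_area_deform)
                alpha = _soft(q, rho * self.params.pons_area_factor,
                              self.pons_axes)
            else:
                q, rho = _deformed_q(rr, cc, e.center,
                                     (e.semi_major, e.semi_minor),
                                     e.orientation, [])
                alpha = _soft(q, rho, (e.semi_major, e.semi_minor))
            layers.append((lv[name], alpha))
        return layers

    def structure_blend(self, rr, cc, background, profile=1.0):
        """Paint the structure layers over a background image."""
        out = np.asarray(background, dtype=float).copy()
        for level, alpha in self.coverage_layers(rr, cc):
            a = alpha * profile
            out = out * (1.0 - a) + level * a
        return out


def _sample_scene(rng: np.random.Generator,
                  params: StructureParams) -> _SceneModel:
    p = params
    j = p.jitter_px

    def jitter(center):
        return (center[0] + rng.uniform(-j, j),
                center[1] + rng.uniform(-j, j))

    def deform(n_modes=2):
        return [(int(k), rng.uniform(0.3, 1.0) * p.deform_amp,
                 rng.uniform(0, 2 * np.pi))
                for k in rng.choice([2, 3, 4], size=n_modes, replace=False)]

    # one scale and one vertical shift for the whole brainstem: the
    # midbrain sits directly superior to the pons, so their sizes and
    # positions move together and the templates stay disjoint
    scale = rng.uniform(*p.scale_range)
    row_shift = rng.uniform(-j, j)
    mb_center = (p.midbrain_center[0] + row_shift
                 + rng.uniform(-1.5, 1.5),
                 p.midbrain_center[1] + rng.uniform(-j, j))
    mb_angle = rng.uniform(-p.max_rotation_deg, p.max_rotation_deg)
    mb_axes = (p.midbrain_lobe_axes[0] * scale,
               p.midbrain_lobe_axes[1] * scale)
    # notch sits at the superior (small-row) edge of the bean
    notch_center = (mb_center[0] - 0.85 * mb_axes[1], mb_center[1])

    pons_center = (p.pons_center[0] + row_shift + rng.uniform(-1.5, 1.5),
                   p.pons_center[1] + rng.uniform(-j, j))
    pons_angle = rng.uniform(-p.max_rotation_deg, p.max_rotation_deg)
    pons_axes = (p.pons_ellipse_axes[0] * scale,
                 p.pons_ellipse_axes[1] * scale)

    scene = _SceneModel(
        params=p,
        mb_center=mb_center, mb_angle=mb_angle, mb_lobe_axes=mb_axes,
        mb_lobe_offset=p.midbrain_lobe_offset * scale,
        mb_notch_center=notch_center,
        mb_notch_axes=(p.midbrain_notch_axes[0] * scale,
                       p.midbrain_notch_axes[1] * scale),
        mb_deform=deform(),
        pons_center=pons_center, pons_angle=pons_angle, pons_axes=pons_axes,
        pons_area_deform=deform(),
        texture_phases=(rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
    )
    scene.pons_ellipse = _ellipse_params(pons_center, pons_axes[0],
                                         pons_axes[1], pons_angle)
    scene.mb_ellipse = _fit_midbrain_ellipse(scene)
    return scene


def _fit_midbrain_ellipse(scene: _SceneModel) -> EllipseParams:
    """Largest template ellipse inside the bean-shaped midbrain body.

    Starts from a fraction of the lobe template and shrinks until its
    rasterization is a subset of the rasterized body on the pixel grid.
    """
    rr, cc = np.mgrid[0:ROI_SHAPE[0], 0:ROI_SHAPE[1]]
    body = scene.midbrain_area_inside(rr, cc)
    semi_x0 = scene.mb_lobe_axes[0] + 0.8 * scene.mb_lobe_offset
    semi_y0 = 0.62 * scene.mb_lobe_axes[1]
    t = np.deg2rad(scene.mb_angle)
    drop = 0.30 * scene.mb_lobe_axes[1]  # inferior to dodge the notch
    center = (scene.mb_center[0] + drop * np.cos(t),
              scene.mb_center[1] - drop * np.sin(t))
    shrink = 1.0
    for _ in range(40):
        e = _ellipse_params(center, semi_x0 * shrink, semi_y0 * shrink,
                            scene.mb_angle)
        ell = rasterize_ellipse(ROI_SHAPE, e)
        if ell.any() and not np.any(ell & ~body):
            return e
        shrink *= 0.96
    raise RuntimeError("could not inscribe an ellipse in the midbrain body")


def _background(rr, cc, params: StructureParams, phases):
    tex = (1.0 + params.texture_amp
           * np.cos(np.asarray(rr) / 11.0 + phases[0])
           * np.cos(np.asarray(cc) / 13.0 + phases[1]))
    return params.background_level * tex


def make_roi_scene(seed: int,
                   shape_params: StructureParams | None = None) -> RoiScene:
    """Generate one 128x128 training scene with ground truth.

    Deterministic given ``seed``.  The pons area mask is strictly larger
    than the midbrain area mask (anatomical size ordering), and each
    ellipse-region mask is a subset of its area mask.
    """
    params = shape_params or StructureParams()
    rng = np.random.default_rng(seed)
    scene = _sample_scene(rng, params)
    rr, cc = np.mgrid[0:ROI_SHAPE[0], 0:ROI_SHAPE[1]]
    image = scene.structure_blend(
        rr, cc, _background(rr, cc, params, scene.texture_phases))
    if params.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter
        image = gaussian_filter(image, params.psf_sigma)
    masks = scene.masks_on_grid(rr, cc)
    # ellipse-region masks come from the shared rasterizer so the stored
    # truth ellipses rasterize back to them identically
    masks["midbrain_ellipse"] = rasterize_ellipse(ROI_SHAPE, scene.mb_ellipse)
    masks["pons_ellipse"] = rasterize_ellipse(ROI_SHAPE, scene.pons_ellipse)
    return RoiScene(
        image=image.astype(np.float32),
        masks={k: masks[k] for k in _MASK_NAMES},
        truth_ellipses={"midbrain_ellipse": scene.mb_ellipse,
                        "pons_ellipse": scene.pons_ellipse},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# 3D volume rendering
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


def make_volume(spec: PhantomSpec) -> PhantomVolume:
    """Render a phantom head volume with its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scene = _sample_scene(rng, spec.structure_params)

    nz, ny, nx = spec.shape
    cz, cy, cx = volume_center(spec.shape)
    r = rotation_matrix(spec.fissure_yaw, spec.fissure_roll)
    dz = (np.arange(nz, dtype=np.float32) - cz)[:, None, None]
    dy = (np.arange(ny, dtype=np.float32) - cy)[None, :, None]
    dx = (np.arange(nx, dtype=np.float32) - cx)[None, None, :]
    # plane-aligned coordinates: u in-plane z-like, v in-plane y-like,
    # d signed distance to the plane
    u = r[0, 0] * dz + r[1, 0] * dy + r[2, 0] * dx
    v = r[0, 1] * dz + r[1, 1] * dy + r[2, 1] * dx
    d = r[0, 2] * dz + r[1, 2] * dy + r[2, 2] * dx - spec.fissure_offset

    au, av, ad = spec.resolved_semi_axes()
    rad = np.sqrt((u / au) ** 2 + (v / av) ** 2 + (d / ad) ** 2)
    head_level = 0.8
    env = _sigmoid((1.0 - rad) / 0.02)
    ph1, ph2 = scene.texture_phases
    tex = (1.0 + spec.structure_params.texture_amp
           * np.cos(u / 11.0 + ph1) * np.cos(v / 13.0 + ph2)
           * np.cos(d / 9.0))
    sigma_f = spec.fissure_width / 2.0
    fissure = 1.0 - spec.fissure_contrast * np.exp(-0.5 * (d / sigma_f) ** 2)
    vol = (head_level * env * tex * fissure).astype(np.float32)

    # structures: render only near the plane, in MSP/ROI pixel units
    zz, yy, xx = np.nonzero(np.abs(d) < 6.0)
    u_n, v_n, d_n = u[zz, yy, xx], v[zz, yy, xx], d[zz, yy, xx]
    msp_r = (u_n + cz + 0.5) * MSP_SHAPE[0] / nz - 0.5
    msp_c = (v_n + cy + 0.5) * MSP_SHAPE[1] / ny - 0.5
    roi_r = msp_r - spec.roi_origin[0]
    roi_c = msp_c - spec.roi_origin[1]
    profile = np.exp(-0.5 * (d_n / 1.8) ** 2)
    blended = scene.structure_blend(roi_r, roi_c, vol[zz, yy, xx], profile)
    vol[zz, yy, xx] = blended.astype(np.float32)

    if spec.noise_model != "none":
        vol = add_noise(vol, spec.noise_model, spec.snr,
                        seed=int(rng.integers(2 ** 31)))

    # ground truth on the MSP pixel grid
    msp_rr, msp_cc = np.mgrid[0:MSP_SHAPE[0], 0:MSP_SHAPE[1]]
    r0, c0 = spec.roi_origin
    truth_masks = scene.masks_on_grid(msp_rr - r0, msp_cc - c0)
    for name, ell in (("midbrain_ellipse", scene.mb_ellipse),
                      ("pons_ellipse", scene.pons_ellipse)):
        shifted = replace(ell, center=(ell.center[0] + r0,
                                       ell.center[1] + c0))
        truth_masks[name] = rasterize_ellipse(MSP_SHAPE, shifted)

    roi_sl = (slice(r0, r0 + ROI_SHAPE[0]), slice(c0, c0 + ROI_SHAPE[1]))
    roi_truth = RoiScene(
        image=make_roi_scene(spec.seed, spec.structure_params).image,
        masks={k: truth_masks[k][roi_sl] for k in _MASK_NAMES},
        truth_ellipses={"midbrain_ellipse": scene.mb_ellipse,
                        "pons_ellipse": scene.pons_ellipse},
        seed=spec.seed,
    )
    return PhantomVolume(
        intensities=vol,
        voxel_spacing=spec.voxel_spacing,
        truth_plane=PlaneParams(yaw=spec.fissure_yaw, roll=spec.fissure_roll,
                                distance=spec.fissure_offset),
        truth_masks={k: truth_masks[k] for k in _MASK_NAMES},
        truth_roi_origin=spec.roi_origin,
        roi_truth=roi_truth,
        spec=spec,
    )


def save_scene(scene: RoiScene, stem) -> None:
    """Write a scene as PNGs (image + one mask per structure) + JSON.

    ``stem`` is a path prefix; files are ``<stem>.png``,
    ``<stem>_<mask>.png`` and ``<stem>.json``.
    """
    import json
    from pathlib import Path

    from PIL import Image

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img = np.clip(scene.image, 0.0, 1.0)
    Image.fromarray((img * 255).astype(np.uint8)).save(f"{stem}.png")
    for name, mask in scene.masks.items():
        Image.fromarray(mask.astype(np.uint8) * 255).save(
            f"{stem}_{name}.png")
    meta = {"seed": scene.seed,
            "truth_ellipses": {
                k: {"center": list(e.center), "semi_major": e.semi_major,
                    "semi_minor": e.semi_minor, "orientation": e.orientation}
                for k, e in scene.truth_ellipses.items()}}
    Path(f"{stem}.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(image: np.ndarray, model: str, snr: float,
              seed: int) -> np.ndarray:
    """Add Gaussian or Rician noise at a given signal-to-noise ratio.

    The noise level is ``sigma = mean(foreground) / snr`` where the
    foreground is the set of pixels above half the image maximum.  For
    Rician noise the output is ``sqrt((image + n1)^2 + n2^2)`` with
    ``n1, n2`` i.i.d. N(0, sigma^2), the magnitude-image noise model of
    MRI; on zero signal this reduces to a Rayleigh distribution.
    """
    if snr is None or snr <= 0:
        raise ValueError("snr must be positive")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    img = np.asarray(image, dtype=np.float32)
    fg = img > 0.5 * img.max()
    if not fg.any():
        raise ValueError("image has no foreground for SNR normalization")
    sigma = float(img[fg].mean()) / snr
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        return img + rng.normal(0.0, sigma, img.shape).astype(np.float32)
    n1 = rng.normal(0.0, sigma, img.shape).astype(np.float32)
    n2 = rng.normal(0.0, sigma, img.shape).astype(np.float32)
    return np.sqrt((img + n1) ** 2 + n2 ** 2)
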