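"""Midsagittal-plane geometry.

The midsagittal plane (MSP) of a head volume is parameterized by a yaw
angle (rotation of the plane normal within the axial (y, x)-plane), a roll
angle (rotation within the coronal (z, x)-plane) and a signed perpendicular
distance from the volume center, in voxels.

Volume axes are ordered ``(z, y, x)`` with ``z`` the axial (slice) axis,
row 0 superior.  Angles are in degrees, counter-clockwise positive.  The
plane is the set ``{p : n(yaw, roll) . (p - center) = distance}`` where
``n`` is the unit normal, which points along +x for yaw = roll = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class PlaneParams:
    """Yaw/roll/offset parameterization of a candidate midsagittal plane."""

    yaw: float  # degrees, rotation in the (y, x)-plane
    roll: float  # degrees, rotation in the (z, x)-plane
    distance: float  # voxels, signed perpendicular offset from volume center

    def as_dict(self) -> dict:
        return {"yaw": float(self.yaw), "roll": float(self.roll),
                "distance": float(self.distance)}


def rotation_matrix(yaw: float, roll: float) -> np.ndarray:
    """Rotation taking the aligned frame into the tilted-plane frame.

    Columns are the images of the unit vectors (e_z, e_y, e_x); in
    particular ``R @ e_x`` is the plane normal.  Axis order is (z, y, x).
    """
    t = np.deg2rad(yaw)
    p = np.deg2rad(roll)
    # yaw about the z-axis: e_x -> (0, sin t, cos t)
    r_yaw = np.array([[1.0, 0.0, 0.0],
                      [0.0, np.cos(t), np.sin(t)],
                      [0.0, -np.sin(t), np.cos(t)]])
    # roll about the y-axis: e_x -> (sin p, 0, cos p)
    r_roll = np.array([[np.cos(p), 0.0, np.sin(p)],
                       [0.0, 1.0, 0.0],
                       [-np.sin(p), 0.0, np.cos(p)]])
    return r_roll @ r_yaw


def plane_normal(yaw: float, roll: float) -> np.ndarray:
    """Unit normal of the plane, components in (z, y, x) order."""
    return rotation_matrix(yaw, roll)[:, 2]


def volume_center(shape: tuple[int, int, int]) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0


def plane_coordinates(shape: tuple[int, int, int], params: PlaneParams,
                      u: np.ndarray, v: np.ndarray, w: np.ndarray
                      ) -> np.ndarray:
    """Map plane-aligned coordinates to voxel coordinates.

    ``u`` runs along the in-plane z-like axis, ``v`` along the in-plane
    y-like axis, and ``w`` is the signed distance from the plane; all are
    measured in voxels from the volume center.  Returns an array of shape
    ``(3,) + u.shape`` of (z, y, x) voxel coordinates.
    """
    r = rotation_matrix(params.yaw, params.roll)
    c = volume_center(shape)
    q = np.stack([np.asarray(u, dtype=float),
                  np.asarray(v, dtype=float),
                  np.asarray(w, dtype=float) + params.distance])
    return np.tensordot(r, q, axes=(1, 0)) + c.reshape((3,) + (1,) * u.ndim)


def mirror_residual(volume: np.ndarray, params: PlaneParams,
                    half_width: int = 12, step: int = 2) -> float:
    """Mean absolute asymmetry of a volume about a candidate plane.

    Samples pairs of points mirrored across the plane at offsets
    ``1..half_width`` voxels and returns the mean absolute intensity
    difference.  Zero (up to interpolation error) for a volume that is
    perfectly mirror-symmetric about the plane.
    """
    nz, ny, nx = volume.shape
    uu = np.arange(-nz // 3, nz // 3, step, dtype=float)
    vv = np.arange(-ny // 3, ny // 3, step, dtype=float)
    u, v = np.meshgrid(uu, vv, indexing="ij")
    diffs = []
    for k in range(1, half_width + 1):
        cp = plane_coordinates(volume.shape, params, u, v, np.full_like(u, k))
        cm = plane_coordinates(volume.shape, params, u, v, np.full_like(u, -k))
        a = ndimage.map_coordinates(volume, cp, order=1, mode="constant",
                                    cval=np.nan)
        b = ndimage.map_coordinates(volume, cm, order=1, mode="constant",
                                    cval=np.nan)
        d = np.abs(a - b)
        d = d[np.isfinite(d)]
        if d.size:
            diffs.append(d)
    if not diffs:
        raise ValueError("plane does not intersect the volume support")
    return float(np.mean(np.concatenate(diffs)))
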