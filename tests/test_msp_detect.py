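"""Midsagittal-plane detection: Radon transform, symmetry, recovery."""

import numpy as np
import pytest

from planistem.geometry import PlaneParams, mirror_residual
from planistem.msp_detect import (MspConfig, MspDetectionError,
                                  aggregate_distances, crop_roi, detect,
                                  estimate_roll, extract_msp, find_msp_line,
                                  radon_transform, select_axial_slice,
                                  Sinogram)


def brute_force_radon(img, origin, theta_deg, s, min_len=16):
    """Independent per-line pixel walk with bilinear interpolation."""
    h, w = img.shape
    oy, ox = origin
    t = np.deg2rad(theta_deg)
    half = int(np.ceil(np.hypot(h, w) / 2)) + 1
    total, count = 0.0, 0
    for step in range(-half, half + 1):
        r = oy + s * np.sin(t) + step * np.cos(t)
        c = ox + s * np.cos(t) - step * np.sin(t)
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            continue
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
        fr, fc = r - r0, c - c0
        val = (img[r0, c0] * (1 - fr) * (1 - fc)
               + img[r1, c0] * fr * (1 - fc)
               + img[r0, c1] * (1 - fr) * fc
               + img[r1, c1] * fr * fc)
        total += val
        count += 1
    if count < min_len:
        return None
    return total / count


class TestSelectAxialSlice:
    def test_center_of_mass_of_centered_square(self):
        vol = np.zeros((20, 41, 41))
        vol[:, 10:31, 10:31] = 1.0
        _, com, _ = select_axial_slice(vol)
        assert com == pytest.approx((20.0, 20.0))

    def test_slice_in_upper_half_of_foreground(self, aligned_phantom):
        vol = aligned_phantom.intensities
        _, _, z = select_axial_slice(vol)
        fg = vol > 0.1 * vol.max()
        rows = np.flatnonzero(fg.any(axis=(1, 2)))
        assert rows[0] <= z < rows[0] + 0.5 * (rows[-1] - rows[0])

    def test_otsu_separates_bimodal_slice(self):
        # brute-force threshold search maximizing between-class variance
        rng = np.random.default_rng(0)
        vol = np.zeros((12, 32, 32))
        levels = np.where(rng.random((32, 32)) < 0.4, 0.2, 0.9)
        vol[:] = levels
        sl, com, _ = select_axial_slice(vol)
        from skimage.filters import threshold_otsu
        thr = threshold_otsu(sl)
        best_t, best_v = None, -1.0
        flat = sl.ravel()
        for t in np.unique(flat)[:-1]:
            lo, hi = flat[flat <= t], flat[flat > t]
            v = (len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
                 / len(flat) ** 2)
            if v > best_v:
                best_t, best_v = t, v
        assert np.array_equal(sl > thr, sl > best_t)

    def test_empty_slice_errors(self):
        vol = np.zeros((15, 10, 10))
        with pytest.raises(MspDetectionError):
            select_axial_slice(vol)


class TestRadon:
    def test_constant_image(self):
        img = np.full((41, 41), 3.7)
        sino = radon_transform(img, (20, 20), np.arange(-6, 7, 2.0),
                               np.arange(-5, 6, 1.0))
        assert np.allclose(sino.values[sino.valid], 3.7)

    def test_dark_line_is_minimum(self):
        # 1 everywhere except a thin dark line through the origin with
        # normal direction 4 degrees
        h = w = 101
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        t = np.deg2rad(4.0)
        dist = (rr - 50) * np.sin(t) + (cc - 50) * np.cos(t)
        img = np.where(np.abs(dist) < 0.5, 0.0, 1.0)
        thetas = np.arange(-10, 10.25, 0.5)
        ss = np.arange(-10, 10.5, 0.5)
        sino = radon_transform(img, (50, 50), thetas, ss)
        theta, s = find_msp_line(sino)
        assert abs(theta - 4.0) <= 0.5
        assert abs(s) <= 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        thetas = np.arange(-8, 9, 4.0)
        ss = np.arange(-6, 7, 3.0)
        for _ in range(10):
            img = rng.random((32, 32))
            origin = (rng.uniform(10, 22), rng.uniform(10, 22))
            sino = radon_transform(img, origin, thetas, ss)
            for i, th in enumerate(thetas):
                for j, s in enumerate(ss):
                    ref = brute_force_radon(img, origin, th, s)
                    if ref is None:
                        assert not sino.valid[i, j]
                    else:
                        assert sino.values[i, j] == pytest.approx(
                            ref, abs=1e-6)

    def test_origin_outside_rejected(self):
        with pytest.raises(ValueError):
            radon_transform(np.ones((10, 10)), (20, 0), np.array([0.0]),
                            np.array([0.0]))


class TestFindLine:
    def _sino(self, values, thetas, ss):
        values = np.asarray(values, dtype=float)
        return Sinogram(values=values, theta_grid=np.asarray(thetas, float),
                        s_grid=np.asarray(ss, float), origin=(0, 0),
                        valid=np.isfinite(values))

    def test_unique_minimum(self):
        sino = self._sino([[1, 2], [0.5, 3]], [-3, 3], [0, 1])
        assert find_msp_line(sino) == (3.0, 0.0)

    def test_tie_break_prefers_small_magnitude_then_signed(self):
        vals = np.ones((3, 3))
        vals[0, 1] = vals[2, 1] = 0.0  # theta = -3 and +3, same |theta|
        sino = self._sino(vals, [-3, 0, 3], [-1, 0, 1])
        assert find_msp_line(sino) == (-3.0, 0.0)
        vals = np.ones((3, 3))
        vals[1, 0] = vals[2, 2] = 0.0  # theta 0 beats theta 3
        sino = self._sino(vals, [-3, 0, 3], [-1, 0, 1])
        assert find_msp_line(sino) == (0.0, -1.0)

    def test_no_valid_cells(self):
        sino = self._sino([[np.nan]], [0], [0])
        with pytest.raises(MspDetectionError):
            find_msp_line(sino)


class TestEstimateRoll:
    def _head(self):
        rr, cc = np.mgrid[0:80, 0:80].astype(float)
        img = ((rr - 40) ** 2 / 900 + (cc - 40) ** 2 / 400 < 1).astype(float)
        img *= 1.0 + 0.2 * np.cos(rr / 5.0)
        return img

    def test_symmetric_image_gives_zero(self):
        phis = np.arange(-8, 8.5, 0.5)
        assert estimate_roll(self._head(), 40.0, phis) == 0.0

    def test_recovers_applied_rotation(self):
        from scipy import ndimage
        img = ndimage.rotate(self._head(), -4.0, reshape=False, order=1)
        phis = np.arange(-8, 8.25, 0.25)
        assert estimate_roll(img, 40.0, phis) == pytest.approx(4.0, abs=0.5)

    def test_rejects_out_of_range_grid_and_empty(self):
        with pytest.raises(ValueError):
            estimate_roll(self._head(), 40.0, np.array([-11.0, 0.0]))
        with pytest.raises(MspDetectionError):
            estimate_roll(np.zeros((20, 20)), 10.0, np.arange(-5, 6.0))


class TestExtract:
    def test_identity_params_equal_native_slice(self):
        rng = np.random.default_rng(3)
        vol = rng.random((176, 256, 21))
        msp = extract_msp(vol, PlaneParams(0, 0, 0))
        assert np.allclose(msp.intensities, vol[:, :, 10], atol=1e-12)

    def test_shape_contract(self, aligned_phantom):
        msp = extract_msp(aligned_phantom.intensities, PlaneParams(2, -1, 3))
        assert msp.intensities.shape == (176, 256)

    def test_round_trip_residual(self, tilted_phantom):
        res = mirror_residual(tilted_phantom.intensities,
                              tilted_phantom.truth_plane)
        assert res < 0.01

    def test_plane_outside_support(self, aligned_phantom):
        with pytest.raises(MspDetectionError):
            extract_msp(aligned_phantom.intensities,
                        PlaneParams(0, 0, 1000.0))


class TestDetect:
    def test_idempotent_on_aligned_volume(self, aligned_phantom):
        p, _, _ = detect(aligned_phantom.intensities)
        cfg = MspConfig()
        assert abs(p.yaw) <= cfg.theta_step
        assert abs(p.roll) <= cfg.phi_step
        assert abs(p.distance) <= cfg.s_step

    def test_recovers_tilted_plane(self, tilted_phantom):
        t = tilted_phantom.truth_plane
        p, msp, roi = detect(tilted_phantom.intensities)
        assert p.yaw == pytest.approx(t.yaw, abs=1.0)
        assert p.roll == pytest.approx(t.roll, abs=1.0)
        assert p.distance == pytest.approx(t.distance, abs=1.0)
        assert roi.intensities.shape == (128, 128)

    def test_roi_is_window_of_msp(self, aligned_phantom):
        _, msp, roi = detect(aligned_phantom.intensities)
        r0, c0 = roi.roi_origin
        assert np.array_equal(roi.intensities,
                              msp.intensities[r0:r0 + 128, c0:c0 + 128])
        window = crop_roi(msp, (r0, c0))
        assert np.array_equal(window.intensities, roi.intensities)

    def test_all_zero_volume_fails_with_stage_identity(self):
        with pytest.raises(MspDetectionError):
            detect(np.zeros((32, 32, 32)))


def test_median_aggregation_robust_to_outliers():
    """Corrupting <= 40% of per-slice offsets moves the result <= 1 px."""
    base = np.array([2.0, 2.1, 1.9, 2.05, 2.0])
    clean = aggregate_distances(base)
    corrupted = base.copy()
    corrupted[:2] += 50.0  # 40% outliers
    assert abs(aggregate_distances(corrupted) - clean) <= 1.0
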