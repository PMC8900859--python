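import numpy as np
import pytest
from scipy.ndimage import map_coordinates

import scatmap as sm
from scatmap.exceptions import NonLinearAttributeError
from scatmap.tomo import (absorption_attribute, build_sinogram,
                          estimate_center, forward_project,
                          make_band_attribute, make_peak_attribute,
                          make_ratio_attribute, ratio_tomogram,
                          reconstruct_fbp)

ANGLES = np.arange(-90.0, 90.0 + 1e-9, 1.5)     # 121 projections, 1.5 deg


def disk(n=64, radius_frac=0.35, density=2.5):
    yy, xx = np.indices((n, n)) - (n - 1) / 2.0
    return (np.hypot(xx, yy) <= radius_frac * n).astype(float) * density


def rotate_like_projector(image, angle_deg):
    """Rotate a map with the same sampling convention as project_map."""
    n = image.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.indices((n, n)) - c
    th = np.radians(angle_deg)
    x = xx * np.cos(th) + yy * np.sin(th)
    y = -xx * np.sin(th) + yy * np.cos(th)
    return map_coordinates(image, [y.ravel() + c, x.ravel() + c],
                           order=1, mode="constant").reshape(n, n)


class TestForwardProject:
    def test_hot_voxel_traces_a_sinusoid(self):
        n = 64
        ph = np.zeros((n, n))
        ph[40, 50] = 1.0
        sino = forward_project(ph, ANGLES, 1.0)
        c = (n - 1) / 2.0
        r = np.hypot(50 - c, 40 - c)
        phi0 = np.arctan2(40 - c, 50 - c)
        predicted = c + r * np.cos(np.radians(ANGLES) - phi0)
        peaks = sino.values.argmax(axis=1)
        assert np.max(np.abs(peaks - predicted)) < 1.0
        # amplitude/phase: the center-of-mass trace is the same sinusoid
        idx = np.arange(n)
        com = (sino.values * idx).sum(axis=1) / sino.values.sum(axis=1)
        th = np.radians(ANGLES)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.cos(th), np.sin(th), np.ones_like(th)]),
            com, rcond=None)
        assert np.hypot(coef[0], coef[1]) == pytest.approx(r, abs=0.1)
        assert np.arctan2(coef[1], coef[0]) == pytest.approx(phi0, abs=0.02)

    def test_rotationally_symmetric_phantom_rows_equal(self):
        # anti-aliased disk: row differences are interpolation-limited
        n = 48
        yy, xx = np.indices((n, n)) - (n - 1) / 2.0
        smooth = np.clip(0.35 * n + 0.5 - np.hypot(xx, yy), 0, 1) * 2.5
        sino = forward_project(smooth, np.arange(0, 180, 15), 1.0)
        assert np.allclose(sino.values, sino.values[0],
                           atol=0.03 * sino.values.max())

    def test_zero_phantom(self):
        sino = forward_project(np.zeros((32, 32)), ANGLES, 1.0)
        assert not sino.values.any()

    def test_disk_matches_analytic_chord_length(self):
        n, rf, dens = 96, 0.3, 1.7
        step = 0.01
        sino = forward_project(disk(n, rf, dens), [0.0, 37.0], step)
        radius = rf * n
        x = np.arange(n) - (n - 1) / 2.0
        chord = 2.0 * np.sqrt(np.clip(radius ** 2 - x ** 2, 0, None)) \
            * dens * step
        inner = np.abs(x) < 0.8 * radius
        for row in sino.values:
            assert np.allclose(row[inner], chord[inner], rtol=0.02)


class TestBuildSinogram:
    def test_nonlinear_ratio_attribute_rejected(self, mini_waxs_geom):
        ratio = make_ratio_attribute(make_peak_attribute(1.58, 0.1),
                                     make_band_attribute(2.1, 2.4))
        with pytest.raises(NonLinearAttributeError):
            build_sinogram(iter([]), ratio)

    def test_undeclared_attribute_rejected(self):
        with pytest.raises(NonLinearAttributeError):
            build_sinogram(iter([]), lambda p: 1.0)

    def test_disk_phantom_chord_profile(self, mini_waxs_geom,
                                        cellwall_materials):
        crystalline, amorphous, _ = cellwall_materials
        phantom = sm.disk_phantom(32, (crystalline, amorphous), (0.6, 0.4),
                                  radius_frac=0.35, pixel_size=0.005)
        angles = np.array([0.0, 45.0, 90.0])
        series = sm.simulate_tomo(phantom, {"waxs": mini_waxs_geom},
                                  angles=angles, seed=3, exposure=4000.0)
        sino = build_sinogram(series, make_band_attribute(0.5, 3.0))
        x = np.arange(32) - 15.5
        radius = 0.35 * 32
        chord_shape = 2.0 * np.sqrt(np.clip(radius ** 2 - x ** 2, 0, None))
        inner = np.abs(x) < 0.7 * radius
        for row in sino.values:
            # measured attribute is proportional to the beam-path length
            scale = (row[inner] * chord_shape[inner]).sum() \
                / (chord_shape[inner] ** 2).sum()
            assert np.allclose(row[inner], scale * chord_shape[inner],
                               rtol=0.06)
        # points with empty beam path carry ~zero attribute
        assert abs(sino.values[0, 0]) < 0.02 * sino.values[0].max()

    def test_monitor_attribute_matches_mu_line_integral(
            self, mini_waxs_geom, cellwall_materials):
        crystalline, amorphous, _ = cellwall_materials
        phantom = sm.disk_phantom(24, (crystalline, amorphous), (0.5, 0.5),
                                  pixel_size=0.005)
        angles = np.array([0.0, 30.0])
        series = sm.simulate_tomo(phantom, {"waxs": mini_waxs_geom},
                                  angles=angles, seed=1)
        sino = build_sinogram(series, absorption_attribute)
        mu = np.array([m.mu_mm for m in phantom.materials])
        expected = forward_project(phantom.weights @ mu, angles,
                                   phantom.pixel_size).values
        assert np.allclose(sino.values, expected, rtol=1e-9, atol=1e-12)


class TestEstimateCenter:
    def test_constructed_three_pixel_offset(self):
        sino = forward_project(disk(64), ANGLES, 1.0)
        shifted = np.zeros_like(sino.values)
        shifted[:, 3:] = sino.values[:, :-3]
        off = estimate_center(sm.Sinogram(shifted, ANGLES, sino.x_positions))
        assert off == pytest.approx(3.0, abs=0.2)

    def test_centered_sinogram(self):
        sino = forward_project(disk(64), ANGLES, 1.0)
        assert estimate_center(sino) == pytest.approx(0.0, abs=0.2)

    def test_flat_sinogram_warns_and_returns_zero(self):
        sino = sm.Sinogram(np.zeros((5, 32)), np.linspace(0, 120, 5),
                           np.arange(32.0))
        with pytest.warns(UserWarning, match="flat sinogram"):
            assert estimate_center(sino) == 0.0

    def test_com_fallback_without_conjugate_pair(self):
        # angles span < 180 deg: no conjugate pair exists, so the
        # center-of-mass sinusoid fit takes over; shifting the whole
        # sinogram in t moves the apparent rotation axis by that amount
        angles = np.arange(0.0, 160.0, 10.0)
        base = forward_project(disk(64), angles, 1.0)
        shifted = np.zeros_like(base.values)
        shifted[:, 4:] = base.values[:, :-4]
        off = estimate_center(sm.Sinogram(shifted, angles, base.x_positions))
        assert off == pytest.approx(4.0, abs=0.3)


class TestReconstructFBP:
    def test_disk_round_trip(self):
        n = 64
        ph = disk(n)
        sino = forward_project(ph, ANGLES, 0.005)
        rec = reconstruct_fbp(sino, center_offset=0.0)
        yy, xx = np.indices((n, n)) - (n - 1) / 2.0
        interior = np.hypot(xx, yy) <= 0.25 * n
        assert rec.slice[interior].mean() == pytest.approx(2.5, rel=0.02)
        rms = np.sqrt(np.mean((rec.slice - ph) ** 2)) / 2.5
        assert rms < 0.05

    def test_zero_sinogram_gives_zero_tomogram(self):
        sino = sm.Sinogram(np.zeros((12, 32)), np.linspace(0, 165, 12),
                           np.arange(32.0))
        rec = reconstruct_fbp(sino, center_offset=0.0)
        assert not rec.slice.any()

    def test_two_blob_centroids_within_one_voxel(self):
        n = 64
        yy, xx = np.indices((n, n)) - (n - 1) / 2.0
        ph = np.zeros((n, n))
        ph[np.hypot(xx - 10, yy + 5) <= 4] = 1.0
        ph[np.hypot(xx + 12, yy - 8) <= 3] = 2.0
        rec = reconstruct_fbp(forward_project(ph, ANGLES, 1.0),
                              center_offset=0.0).slice
        for cx, cy, rad in [(10, -5, 4), (-12, 8, 3)]:
            window = np.hypot(xx - cx, yy - cy) <= rad + 3
            w = np.where(window, np.clip(rec, 0, None), 0.0)
            gx = (w * xx).sum() / w.sum()
            gy = (w * yy).sum() / w.sum()
            assert np.hypot(gx - cx, gy - cy) < 1.0

    def test_fewer_than_two_angles_rejected(self):
        sino = sm.Sinogram(np.ones((1, 16)), np.array([0.0]),
                           np.arange(16.0))
        with pytest.raises(ValueError):
            reconstruct_fbp(sino, center_offset=0.0)

    def test_linearity(self):
        s1 = forward_project(disk(48), ANGLES, 1.0)
        s2 = forward_project(np.roll(disk(48, 0.2, 0.7), 5, axis=0),
                             ANGLES, 1.0)
        both = sm.Sinogram(s1.values + s2.values, ANGLES, s1.x_positions)
        r12 = reconstruct_fbp(both, 0.0).slice
        r1 = reconstruct_fbp(s1, 0.0).slice
        r2 = reconstruct_fbp(s2, 0.0).slice
        scale = np.max(np.abs(r12))
        assert np.max(np.abs(r12 - (r1 + r2))) < 1e-10 * scale

    def test_mass_conservation(self):
        step = 0.005
        sino = forward_project(disk(64), ANGLES, step)
        rec = reconstruct_fbp(sino, 0.0)
        mass = rec.slice.sum() * step ** 2
        ref = sino.values.sum(axis=1).mean() * step
        assert mass == pytest.approx(ref, rel=0.03)

    def test_error_decreases_with_angle_count(self):
        ph = disk(64)
        errs = []
        for n_ang in (11, 61, 121):
            ang = np.linspace(-90, 90, n_ang)
            rec = reconstruct_fbp(forward_project(ph, ang, 1.0), 0.0).slice
            errs.append(np.sqrt(np.mean((rec - ph) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_rotated_phantom_matches_rotated_reconstruction(self):
        ph = np.roll(disk(64, 0.2, 1.0), 8, axis=1) \
            + np.roll(disk(64, 0.1, 2.0), -10, axis=0)
        angles = np.arange(-90.0, 90.0, 1.5)
        step_deg = 1.5
        rec1 = reconstruct_fbp(forward_project(ph, angles, 1.0), 0.0).slice
        ph_rot = rotate_like_projector(ph, step_deg)
        rec2 = reconstruct_fbp(forward_project(ph_rot, angles, 1.0),
                               0.0).slice
        rms = np.sqrt(np.mean((rec2 - rotate_like_projector(rec1,
                                                            step_deg)) ** 2))
        assert rms < 0.02 * np.max(np.abs(rec1))

    def test_off_center_sinogram_reconstructed_with_estimated_axis(self):
        sino = forward_project(disk(64), ANGLES, 1.0)
        shifted = np.zeros_like(sino.values)
        shifted[:, 4:] = sino.values[:, :-4]
        rec = reconstruct_fbp(sm.Sinogram(shifted, ANGLES, sino.x_positions))
        assert rec.center_offset == pytest.approx(4.0, abs=0.2)
        # the disk is recovered around the estimated axis
        n = 64
        yy, xx = np.indices((n, n)) - (n - 1) / 2.0
        interior = np.hypot(xx, yy) <= 0.25 * n
        assert rec.slice[interior].mean() == pytest.approx(2.5, rel=0.03)

    def test_cross_check_against_independent_iradon(self):
        from skimage.transform import iradon
        ph = disk(64)
        sino = forward_project(ph, ANGLES, 1.0)
        ours = reconstruct_fbp(sino, 0.0).slice
        theirs = iradon(sino.values[:-1].T, theta=ANGLES[:-1] + 90.0,
                        filter_name="ramp", circle=True, output_size=64)
        n = 64
        yy, xx = np.indices((n, n)) - (n - 1) / 2.0
        inner = np.hypot(xx, yy) <= 0.3 * n
        # same reconstruction up to small differences in filter
        # discretization and padding
        assert ours[inner].mean() == pytest.approx(theirs[inner].mean(),
                                                   rel=0.01)
        assert np.allclose(ours[inner], theirs[inner],
                           atol=0.05 * np.abs(theirs[inner]).max())


class TestRatioAndAbsorption:
    def test_identical_tomograms_give_unity_on_support(self):
        t = sm.Tomogram(disk(32, 0.3, 4.0), 0.005)
        r = ratio_tomogram(t, t, 0.05)
        support = t.slice > 0.05 * t.slice.max()
        assert np.allclose(r.slice[support], 1.0)
        assert np.isnan(r.slice[~support]).all()

    def test_doubled_numerator(self):
        b = sm.Tomogram(disk(32, 0.3, 4.0), 0.005)
        a = sm.Tomogram(2.0 * b.slice, 0.005)
        r = ratio_tomogram(a, b, 0.05)
        assert np.nanmax(np.abs(r.slice - 2.0)) < 1e-12

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ratio_tomogram(sm.Tomogram(np.ones((8, 8)), 1.0),
                           sm.Tomogram(np.ones((9, 9)), 1.0))

    @pytest.mark.parametrize("pair, expected", [
        ((1e6, 1e6), 0.0), ((1e6, 1e6 / np.e), 1.0)])
    def test_absorption_identities(self, pair, expected):
        assert absorption_attribute(
            sm.TransmissionPair(*pair)) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_monitor_rejected(self):
        with pytest.raises(ValueError):
            absorption_attribute(sm.TransmissionPair(1e6, 0.0))

    def test_uniform_disk_mu_recovered_by_fbp(self):
        mu = 0.3
        ph = disk(64, 0.35, mu)
        sino = forward_project(ph, ANGLES, 0.005)
        rec = reconstruct_fbp(sino, 0.0)
        n = 64
        yy, xx = np.indices((n, n)) - (n - 1) / 2.0
        interior = np.hypot(xx, yy) <= 0.25 * n
        assert rec.slice[interior].mean() == pytest.approx(mu, rel=0.05)
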