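"""Traction force microscopy: Green's tensor, FTTC round trips, PIV."""

import numpy as np
import pytest

from gelmech.tfm import (BeadImagePair, DisplacementField, ElasticHalfSpace,
                         FTTCParams, TractionField, estimate_displacement,
                         forward_displacement, greens_tensor_fourier,
                         lambda_grid_search, read_vector_field,
                         reconstruct_traction, traction_summaries,
                         write_vector_field)
from gelmech.synthetic import gen_traction_scene, render_beads

SUBSTRATE = ElasticHalfSpace(E=12e3, poisson=0.5)


def dipole_patches(n, spacing, sd_steps=3.0, peak=300.0):
    """Equal-and-opposite Gaussian patches: zero net force by construction."""
    return [
        {"center": (0.3 * n * spacing, 0.5 * n * spacing), "sd": sd_steps * spacing,
         "peak_pa": peak, "direction": (1.0, 0.0)},
        {"center": (0.7 * n * spacing, 0.5 * n * spacing), "sd": sd_steps * spacing,
         "peak_pa": peak, "direction": (-1.0, 0.0)},
    ]


class TestGreensTensor:
    def test_incompressible_axis_values(self):
        # nu = 0.5, ky = 0: diag(1.5/(E k), 3/(E k)), zero off-diagonal
        k = 2e5
        G = greens_tensor_fourier(k, 0.0, SUBSTRATE)
        assert G[0, 0] == pytest.approx(1.5 / (12e3 * k), rel=1e-14)
        assert G[1, 1] == pytest.approx(3.0 / (12e3 * k), rel=1e-14)
        assert G[0, 1] == 0.0 and G[1, 0] == 0.0

    def test_axis_swap_symmetry(self):
        G1 = greens_tensor_fourier(1.2e5, 0.7e5, SUBSTRATE)
        G2 = greens_tensor_fourier(0.7e5, 1.2e5, SUBSTRATE)
        assert G1[0, 0] == pytest.approx(G2[1, 1], rel=1e-14)
        assert G1[1, 1] == pytest.approx(G2[0, 0], rel=1e-14)
        assert G1[0, 1] == pytest.approx(G2[0, 1], rel=1e-14)

    def test_inverse_modulus_scaling(self):
        G1 = greens_tensor_fourier(1e5, 3e4, ElasticHalfSpace(6e3))
        G2 = greens_tensor_fourier(1e5, 3e4, ElasticHalfSpace(12e3))
        np.testing.assert_allclose(G2, G1 / 2.0, rtol=1e-14)

    def test_symmetric_for_generic_k(self):
        G = greens_tensor_fourier(0.9e5, -1.4e5, ElasticHalfSpace(8e3, 0.45))
        assert G[0, 1] == G[1, 0]

    def test_offdiagonal_vanishes_only_on_axes(self):
        assert greens_tensor_fourier(1e5, 0.0, SUBSTRATE)[0, 1] == 0.0
        assert greens_tensor_fourier(0.0, 1e5, SUBSTRATE)[0, 1] == 0.0
        assert greens_tensor_fourier(1e5, 1e5, SUBSTRATE)[0, 1] != 0.0

    def test_dc_raises(self):
        with pytest.raises(ValueError):
            greens_tensor_fourier(0.0, 0.0, SUBSTRATE)


class TestForwardModel:
    def test_zero_traction_zero_displacement(self):
        t = TractionField(1e-6, np.zeros((16, 16)), np.zeros((16, 16)))
        u = forward_displacement(t, SUBSTRATE)
        assert np.all(u.ux == 0.0) and np.all(u.uy == 0.0)

    def test_linearity(self):
        scene = gen_traction_scene(dipole_patches(32, 1e-6), grid=(32, 32),
                                   spacing=1e-6, substrate=SUBSTRATE,
                                   pad_factor=1)
        t = scene.payload["traction"]
        u1 = forward_displacement(t, SUBSTRATE)
        t2 = TractionField(t.spacing, 2.0 * t.fx, 2.0 * t.fy)
        u2 = forward_displacement(t2, SUBSTRATE)
        np.testing.assert_allclose(u2.ux, 2.0 * u1.ux, rtol=1e-12)
        np.testing.assert_allclose(u2.uy, 2.0 * u1.uy, rtol=1e-12)

    def test_single_mode_matches_analytic_tensor(self):
        n, sp = 32, 1e-6
        x = np.arange(n) * sp
        k = 2.0 * np.pi * 3 / (n * sp)      # 3 cycles across the grid, ky = 0
        A = 50.0
        fx = A * np.cos(k * x)[None, :].repeat(n, axis=0)
        t = TractionField(sp, fx, np.zeros_like(fx))
        u = forward_displacement(t, SUBSTRATE)
        G = greens_tensor_fourier(k, 0.0, SUBSTRATE)
        expected = G[0, 0] * fx
        np.testing.assert_allclose(u.ux, expected, rtol=1e-10,
                                   atol=1e-12 * np.abs(expected).max())
        np.testing.assert_allclose(u.uy, 0.0, atol=1e-20)


class TestReconstruction:
    def test_zero_displacement_zero_traction(self):
        u = DisplacementField(1e-6, np.zeros((16, 16)), np.zeros((16, 16)))
        for lam in (0.0, 1e-9):
            f = reconstruct_traction(u, SUBSTRATE, FTTCParams(lam, 1))
            assert np.all(f.fx == 0.0) and np.all(f.fy == 0.0)

    def test_round_trip_identity_no_padding(self):
        """lambda = 0, no padding: exact inverse on zero-mean fields."""
        scene = gen_traction_scene(dipole_patches(64, 1e-6), grid=(64, 64),
                                   spacing=1e-6, substrate=SUBSTRATE,
                                   pad_factor=1)
        t = scene.payload["traction"]
        rec = reconstruct_traction(scene.payload["displacement"], SUBSTRATE,
                                   FTTCParams(0.0, 1))
        num = np.sum((rec.fx - t.fx) ** 2 + (rec.fy - t.fy) ** 2)
        den = np.sum(t.fx**2 + t.fy**2)
        assert np.sqrt(num / den) < 1e-8

    def test_round_trip_gaussian_patch_padded(self):
        """64x64 Gaussian patch, pad 2: support-restricted L2 error < 2%."""
        n, sp = 64, 1e-6
        patch = [{"center": (0.5 * n * sp, 0.5 * n * sp), "sd": 3 * sp,
                  "peak_pa": 300.0, "direction": (0.6, 0.8)}]
        scene = gen_traction_scene(patch, grid=(n, n), spacing=sp,
                                   substrate=SUBSTRATE, pad_factor=2)
        t = scene.payload["traction"]
        rec = reconstruct_traction(scene.payload["displacement"], SUBSTRATE,
                                   FTTCParams(0.0, 2))
        mag = t.magnitude
        supp = mag >= 0.05 * mag.max()
        num = np.sum((rec.fx[supp] - t.fx[supp]) ** 2
                     + (rec.fy[supp] - t.fy[supp]) ** 2)
        den = np.sum(t.fx[supp] ** 2 + t.fy[supp] ** 2)
        assert np.sqrt(num / den) < 0.02

    def test_single_mode_matches_analytic_solve(self):
        n, sp = 32, 1e-6
        x = np.arange(n) * sp
        y = np.arange(n) * sp
        kx = 2.0 * np.pi * 2 / (n * sp)
        ky = 2.0 * np.pi * 5 / (n * sp)
        phase = kx * x[None, :] + ky * y[:, None]
        G = greens_tensor_fourier(kx, ky, SUBSTRATE)
        f_true = np.array([120.0, -40.0])
        u_amp = G @ f_true
        u = DisplacementField(sp, u_amp[0] * np.cos(phase),
                              u_amp[1] * np.cos(phase))
        rec = reconstruct_traction(u, SUBSTRATE, FTTCParams(0.0, 1))
        np.testing.assert_allclose(rec.fx, f_true[0] * np.cos(phase),
                                   rtol=1e-10, atol=1e-10 * abs(f_true[0]))
        np.testing.assert_allclose(rec.fy, f_true[1] * np.cos(phase),
                                   rtol=1e-10, atol=1e-10 * abs(f_true[0]))

    def test_tikhonov_shrinkage_monotone(self):
        scene = gen_traction_scene(dipole_patches(32, 1e-6), grid=(32, 32),
                                   spacing=1e-6, substrate=SUBSTRATE,
                                   noise_sd_frac=0.05, seed=7)
        u = scene.payload["displacement"]
        lams = [0.0, 1e-10, 1e-9, 1e-8, 1e-7]
        norms = []
        for lam in lams:
            f = reconstruct_traction(u, SUBSTRATE, FTTCParams(lam, 1))
            norms.append(np.sqrt(np.sum(f.fx**2 + f.fy**2)))
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_noise_benefit_of_regularization(self):
        """Some lambda > 0 beats lambda = 0 under 5% displacement noise."""
        scene = gen_traction_scene(dipole_patches(64, 1e-6), grid=(64, 64),
                                   spacing=1e-6, substrate=SUBSTRATE,
                                   noise_sd_frac=0.05, seed=11, pad_factor=2)
        lams = [0.0] + list(np.geomspace(1e-11, 1e-7, 9))
        best, errors = lambda_grid_search(scene.payload["displacement"],
                                          SUBSTRATE, scene.payload["traction"],
                                          lams, pad_factor=2)
        assert best > 0.0
        assert errors.min() < errors[0]

    def test_rotation_equivariance(self):
        """Rotating the displacement rotates the reconstructed traction."""
        scene = gen_traction_scene(dipole_patches(32, 1e-6), grid=(32, 32),
                                   spacing=1e-6, substrate=SUBSTRATE,
                                   pad_factor=1)
        u = scene.payload["displacement"]
        f = reconstruct_traction(u, SUBSTRATE, FTTCParams(0.0, 1))
        u_rot = DisplacementField(u.spacing, np.rot90(u.uy), -np.rot90(u.ux))
        f_rot = reconstruct_traction(u_rot, SUBSTRATE, FTTCParams(0.0, 1))
        scale = np.abs(f.fx).max()
        np.testing.assert_allclose(f_rot.fx, np.rot90(f.fy),
                                   atol=1e-9 * scale)
        np.testing.assert_allclose(f_rot.fy, -np.rot90(f.fx),
                                   atol=1e-9 * scale)


class TestPIV:
    def test_identical_images_zero_vectors(self):
        rng = np.random.default_rng(5)
        img = render_beads((128, 128), rng.uniform([0, 0], [127, 127], (300, 2)))
        u = estimate_displacement(BeadImagePair(img, img, 1e-7), 16, 0.5)
        assert np.all(u.ux == 0.0) and np.all(u.uy == 0.0)

    def test_integer_shift_recovered_exactly(self):
        rng = np.random.default_rng(6)
        relaxed = render_beads((256, 256),
                               rng.uniform([0, 0], [255, 255], (1300, 2)))
        stressed = np.roll(relaxed, (3, 0), axis=(0, 1))
        ps = 1e-7
        u = estimate_displacement(BeadImagePair(stressed, relaxed, ps), 16, 0.5)
        assert np.median(u.uy) / ps == pytest.approx(3.0, abs=0)
        assert np.median(u.ux) / ps == pytest.approx(0.0, abs=0)

    def test_smooth_field_rms_below_fifth_of_pixel(self):
        scene = gen_traction_scene(
            [{"center": (30e-6, 30e-6), "sd": 5e-6, "peak_pa": 400.0,
              "direction": (1.0, 1.0)},
             {"center": (34e-6, 34e-6), "sd": 5e-6, "peak_pa": 400.0,
              "direction": (-1.0, -1.0)}],
            grid=(64, 64), spacing=1e-6, substrate=ElasticHalfSpace(3e3),
            render_bead_images=True, seed=1)
        pair = scene.payload["beads"]
        disp = scene.payload["displacement_clean"]
        u = estimate_displacement(pair, window_px=16, overlap=0.5)
        from scipy import ndimage
        ps = pair.pixel_size
        w, m, step = 16, 8, 8
        H, W = pair.image_relaxed.shape
        rows = np.array(range(m, H - w - m + 1, step)) + w / 2 - 0.5
        cols = np.array(range(m, W - w - m + 1, step)) + w / 2 - 0.5
        RR, CC = np.meshgrid(rows, cols, indexing="ij")
        coords = np.stack([RR.ravel() * ps / 1e-6, CC.ravel() * ps / 1e-6])
        tuy = ndimage.map_coordinates(disp.uy, coords, order=1).reshape(RR.shape)
        tux = ndimage.map_coordinates(disp.ux, coords, order=1).reshape(RR.shape)
        rms_px = np.sqrt(np.mean((u.ux - tux) ** 2 + (u.uy - tuy) ** 2)) / ps
        assert rms_px < 0.2

    def test_window_larger_than_image_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            estimate_displacement(BeadImagePair(img, img, 1e-7), 64, 0.5)


class TestSummaries:
    def test_uniform_field(self):
        n = 8
        f = TractionField(2e-6, np.full((n, n), 60.0), np.full((n, n), 80.0))
        mask = np.ones((n, n), dtype=bool)
        s = traction_summaries(f, mask)
        assert s.mean_stress == pytest.approx(100.0, rel=1e-14)
        assert s.max_stress == pytest.approx(100.0, rel=1e-14)
        assert s.total_force == pytest.approx(100.0 * n * n * (2e-6) ** 2,
                                              rel=1e-12)
        assert s.mask_area == pytest.approx(n * n * (2e-6) ** 2, rel=1e-12)

    def test_zero_field(self):
        f = TractionField(1e-6, np.zeros((4, 4)), np.zeros((4, 4)))
        s = traction_summaries(f, np.ones((4, 4), dtype=bool))
        assert s.total_force == 0.0 and s.max_stress == 0.0

    def test_single_hot_cell(self):
        fx = np.zeros((2, 2))
        fx[0, 0] = 200.0
        s = traction_summaries(TractionField(1e-6, fx, np.zeros((2, 2))),
                               np.ones((2, 2), dtype=bool))
        assert s.mean_stress == pytest.approx(50.0)
        assert s.max_stress == pytest.approx(200.0)

    def test_empty_mask_rejected(self):
        f = TractionField(1e-6, np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            traction_summaries(f, np.zeros((4, 4), dtype=bool))


class TestVectorFieldIO:
    def test_round_trip_both_kinds(self, tmp_path):
        scene = gen_traction_scene(dipole_patches(16, 2e-6), grid=(16, 16),
                                   spacing=2e-6, substrate=SUBSTRATE)
        for key, name in (("traction", "f.csv"), ("displacement", "u.csv")):
            path = tmp_path / name
            write_vector_field(path, scene.payload[key])
            back = read_vector_field(path)
            assert back.spacing == pytest.approx(2e-6, rel=1e-9)
            if key == "traction":
                np.testing.assert_allclose(back.fx, scene.payload[key].fx,
                                           rtol=1e-12)
            else:
                np.testing.assert_allclose(back.uy, scene.payload[key].uy,
                                           rtol=1e-12)
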