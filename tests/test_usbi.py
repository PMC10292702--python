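"""NCC/tracking, thickness, and GLCM texture — including an independent
pair-enumeration oracle for the GLCM path."""

import numpy as np
import pytest

from myofatigue.synthetic import PhantomSpec, generate_phantom_sequence
from myofatigue.usbi import (ROI, GLCMMatrix, compute_glcm, gray_quantize,
                             mean_response_amplitude,
                             normalized_cross_correlation, roi_texture,
                             texture_features, thickness_from_boundaries,
                             track_roi)


# ---------------------------------------------------------------------------
# oracle: brute-force pair enumeration, independent of the implementation
# ---------------------------------------------------------------------------


def glcm_oracle(img, offsets, levels, symmetric):
    counts = np.zeros((levels, levels))
    H, W = img.shape
    for dr, dc in offsets:
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W:
                    counts[img[r, c], img[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def texture_oracle(U):
    asm = contrast = hom = 0.0
    L = U.shape[0]
    for i in range(L):
        for j in range(L):
            asm += U[i, j] ** 2
            contrast += (i - j) ** 2 * U[i, j]
            hom += U[i, j] / (1 + (i - j) ** 2)
    return asm, contrast, hom


class TestNcc:
    def test_identical_patches(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert normalized_cross_correlation(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 5))
        assert normalized_cross_correlation(x, 3 * x + 2) == pytest.approx(1.0)
        assert normalized_cross_correlation(x, -2 * x + 1) == pytest.approx(-1.0)

    def test_hand_computed_anticorrelation(self):
        x = np.array([[1, 2], [3, 4]], dtype=float)
        y = np.array([[4, 3], [2, 1]], dtype=float)
        assert normalized_cross_correlation(x, y) == pytest.approx(-1.0)

    def test_constant_patch_rejected(self):
        with pytest.raises(ValueError):
            normalized_cross_correlation(np.ones((3, 3)), np.eye(3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalized_cross_correlation(np.ones((2, 3)), np.ones((3, 2)))

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 7))
        y = rng.standard_normal((6, 7))
        expected = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        assert normalized_cross_correlation(x, y) == pytest.approx(expected)


class TestTracking:
    def test_static_textured_phantom_constant_trajectory(self):
        spec = PhantomSpec(speckle_scale=0.3, n_frames=5, seed=0)
        seq = generate_phantom_sequence(spec)
        roi = ROI(70, 50, 20, 20)
        traj = track_roi(seq, roi, search_margin=3)
        assert all(r == roi for r in traj.rois)
        np.testing.assert_allclose(traj.rd, 1.0)
        assert not traj.truncated

    def test_noiseless_boundary_roi_perfect_rd(self):
        spec = PhantomSpec(speckle_scale=0.0, n_frames=4)
        seq = generate_phantom_sequence(spec)
        roi = ROI(70, 30, 20, 20)  # straddles the surface/deep interface
        traj = track_roi(seq, roi, search_margin=2)
        np.testing.assert_allclose(traj.rd, 1.0)

    def test_recovers_known_axial_shift(self):
        spec = PhantomSpec(speckle_scale=0.2, frame_displacement_mm=0.2,
                           n_frames=8, seed=5)
        seq = generate_phantom_sequence(spec)
        traj = track_roi(seq, ROI(70, 50, 20, 20), search_margin=4)
        rows = traj.displacements()[:, 0]
        np.testing.assert_allclose(rows, 2 * np.arange(8), atol=1.0)

    def test_margin_saturates_below_true_shift(self):
        spec = PhantomSpec(speckle_scale=0.2, frame_displacement_mm=0.4,
                           n_frames=3, seed=6)
        seq = generate_phantom_sequence(spec)
        traj = track_roi(seq, ROI(70, 50, 20, 20), search_margin=2)
        # true shift is 4 px/frame; each step is capped at the 2 px margin
        assert traj.displacements()[1, 0] <= 2

    def test_truncates_at_frame_border(self):
        spec = PhantomSpec(height_px=100, width_px=60,
                           surface_boundary_mm=2.0, deep_boundary_mm=5.0,
                           bottom_boundary_mm=7.5, speckle_scale=0.2,
                           frame_displacement_mm=0.2, n_frames=10, seed=7)
        seq = generate_phantom_sequence(spec)
        # ROI starts near the bottom edge; downward motion pushes it out
        traj = track_roi(seq, ROI(78, 20, 20, 20), search_margin=3)
        assert traj.truncated
        assert len(traj.rois) < 10

    def test_constant_template_rejected(self):
        spec = PhantomSpec(speckle_scale=0.0, n_frames=2)
        seq = generate_phantom_sequence(spec)
        with pytest.raises(ValueError):
            track_roi(seq, ROI(30, 30, 10, 10), search_margin=2)  # inside a layer


class TestThickness:
    def test_hand_arithmetic(self):
        t = thickness_from_boundaries(10, 60, 160, 0.1)
        assert t.surface_mm == pytest.approx(5.0)
        assert t.deep_mm == pytest.approx(10.0)
        assert t.total_mm == pytest.approx(15.0)

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            thickness_from_boundaries(10, 60, 160, 0.0)

    def test_non_monotone_rows_rejected(self):
        with pytest.raises(ValueError):
            thickness_from_boundaries(60, 10, 160, 0.1)

    def test_recovers_phantom_spec_thickness(self):
        spec = PhantomSpec(speckle_scale=0.0)
        seq = generate_phantom_sequence(spec)
        sp = spec.pixel_spacing_mm
        s, d, b = seq.boundaries_mm[0]
        t = thickness_from_boundaries(s / sp, d / sp, b / sp, sp)
        assert t.surface_mm == pytest.approx(
            spec.deep_boundary_mm - spec.surface_boundary_mm)
        assert t.deep_mm == pytest.approx(
            spec.bottom_boundary_mm - spec.deep_boundary_mm)


class TestAmplitude:
    def test_all_zero(self):
        frame = np.zeros((10, 10), dtype=np.uint8)
        assert mean_response_amplitude(frame, ROI(0, 0, 5, 5)) == 0.0

    def test_all_max(self):
        frame = np.full((10, 10), 255, dtype=np.uint8)
        assert mean_response_amplitude(frame, ROI(0, 0, 5, 5)) == 1.0

    def test_half_and_half(self):
        frame = np.zeros((10, 10), dtype=np.uint8)
        frame[:5] = 255
        assert mean_response_amplitude(frame, ROI(0, 0, 10, 10)) == pytest.approx(0.5)


class TestQuantize:
    def test_two_level_bin_edges(self):
        img = np.array([0, 127, 128, 255], dtype=np.uint8)
        np.testing.assert_array_equal(gray_quantize(img, 2), [0, 0, 1, 1])

    def test_constant_image_stays_constant(self):
        img = np.full((4, 4), 200, dtype=np.uint8)
        q = gray_quantize(img, 16)
        assert np.all(q == q.flat[0])

    def test_identity_at_256_levels(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        np.testing.assert_array_equal(gray_quantize(img, 256), img)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            gray_quantize(np.zeros((2, 2), dtype=np.uint8), 300)


class TestGlcm:
    def test_checkerboard_unsymmetrized(self):
        q = np.array([[0, 1], [1, 0]])
        g = compute_glcm(q, offsets=[(0, 1)], levels=2, symmetric=False)
        np.testing.assert_allclose(g.U, [[0, 0.5], [0.5, 0]])

    def test_constant_image_single_diagonal_entry(self):
        q = np.zeros((4, 4), dtype=int)
        g = compute_glcm(q, offsets=[(0, 1)], levels=2)
        assert g.U[0, 0] == 1.0

    def test_symmetrized_equals_transpose(self):
        rng = np.random.default_rng(3)
        q = rng.integers(0, 4, size=(8, 8))
        g = compute_glcm(q, levels=4, symmetric=True)
        np.testing.assert_allclose(g.U, g.U.T)

    def test_normalization(self):
        rng = np.random.default_rng(4)
        q = rng.integers(0, 3, size=(6, 6))
        g = compute_glcm(q, levels=3)
        assert g.U.sum() == pytest.approx(1.0)

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((3, 3), dtype=int), offsets=[(0, 5)], levels=2)

    def test_matches_brute_force_oracle_on_random_images(self):
        rng = np.random.default_rng(99)
        offsets_pool = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (1, 2)]
        for _ in range(100):
            H = int(rng.integers(2, 9))
            W = int(rng.integers(2, 9))
            L = int(rng.integers(2, 5))
            img = rng.integers(0, L, size=(H, W))
            n_off = int(rng.integers(1, 4))
            offsets = [offsets_pool[i]
                       for i in rng.choice(len(offsets_pool), n_off, replace=False)
                       if abs(offsets_pool[i][0]) < H and abs(offsets_pool[i][1]) < W]
            if not offsets:
                continue
            symmetric = bool(rng.integers(2))
            got = compute_glcm(img, offsets, levels=L, symmetric=symmetric)
            want = glcm_oracle(img, offsets, L, symmetric)
            np.testing.assert_allclose(got.U, want, atol=1e-12)
            asm_o, con_o, hom_o = texture_oracle(want)
            tf = texture_features(got)
            assert tf.asm == pytest.approx(asm_o, abs=1e-12)
            assert tf.contrast == pytest.approx(con_o, abs=1e-12)
            assert tf.hom == pytest.approx(hom_o, abs=1e-12)

    def test_matches_skimage_for_standard_directions(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(5)
        img = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        ours = compute_glcm(img, offsets=[(0, 1)], levels=8, symmetric=True)
        ref = graycomatrix(img, distances=[1], angles=[0], levels=8,
                           symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours.U, ref, atol=1e-12)


class TestTextureFeatures:
    def test_degenerate_constant_texture(self):
        U = np.zeros((4, 4))
        U[2, 2] = 1.0
        tf = texture_features(GLCMMatrix(U, 4, ((0, 1),), True))
        assert tf.asm == 1.0
        assert tf.contrast == 0.0
        assert tf.hom == 1.0

    def test_checkerboard_worked_example(self):
        q = np.array([[0, 1], [1, 0]])
        tf = texture_features(compute_glcm(q, offsets=[(0, 1)], levels=2))
        assert tf.asm == pytest.approx(0.5)
        assert tf.contrast == pytest.approx(1.0)
        assert tf.hom == pytest.approx(0.5)

    def test_uniform_matrix_closed_form(self):
        L = 4
        U = np.full((L, L), 1 / L**2)
        tf = texture_features(GLCMMatrix(U, L, ((0, 1),), True))
        assert tf.asm == pytest.approx(1 / L**2)

    def test_feature_ranges_on_random_images(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            tf = texture_features(compute_glcm(gray_quantize(img, 8), levels=8))
            assert 0 < tf.asm <= 1
            assert tf.contrast >= 0
            assert 0 < tf.hom <= 1

    def test_contrast_zero_iff_diagonal(self):
        U = np.diag([0.25, 0.25, 0.5])
        tf = texture_features(GLCMMatrix(U, 3, ((0, 1),), True))
        assert tf.contrast == 0.0

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            texture_features(GLCMMatrix(np.ones((3, 3)), 3, ((0, 1),), True))


def test_coarse_speckle_lowers_contrast_and_raises_homogeneity():
    """Coarser speckle grain → smoother texture: lower contrast, higher HOM
    (median over seeds)."""
    fine, coarse = [], []
    for seed in range(10):
        for grain, acc in ((1, fine), (4, coarse)):
            spec = PhantomSpec(speckle_scale=0.4, speckle_grain_px=grain,
                               seed=seed)
            seq = generate_phantom_sequence(spec)
            tf = roi_texture(seq.frames[0], ROI(25, 25, 50, 50), levels=16)
            acc.append((tf.contrast, tf.hom))
    fine_c, fine_h = np.median([c for c, _ in fine]), np.median([h for _, h in fine])
    coarse_c, coarse_h = np.median([c for c, _ in coarse]), np.median([h for _, h in coarse])
    assert coarse_c < fine_c
    assert coarse_h > fine_h
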