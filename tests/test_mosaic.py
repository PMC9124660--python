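"""Transform chaining, canvas computation, warping and blending."""

import numpy as np
import pytest

from fetomosaic.correspondence import CircularMask
from fetomosaic.geometry import AffineTransform
from fetomosaic.mosaic import (
    CanvasBounds,
    ChainBreakError,
    blend,
    build_mosaic,
    chain_to_reference,
    compute_canvas,
    incremental_preview,
    warp_frame,
)
from conftest import random_affine


class TestChaining:
    def test_identity_chain(self):
        traj = chain_to_reference([AffineTransform.identity()] * 4, reference_index=2)
        for A in traj.absolute:
            assert A.almost_equal(AffineTransform.identity())

    def test_translation_accumulates(self):
        t = AffineTransform.translation(3, -1)
        traj = chain_to_reference([t, t], reference_index=0)
        assert traj.absolute[2].almost_equal(AffineTransform.translation(6, -2))

    def test_matches_cumulative_matrix_product(self, rng):
        pairwise = [random_affine(rng) for _ in range(20)]
        ref = 0
        traj = chain_to_reference(pairwise, reference_index=ref)
        # oracle: cumulative homogeneous product
        M = np.eye(3)
        for f in range(1, 21):
            M = M @ pairwise[f - 1].as_matrix3()
            assert np.allclose(traj.absolute[f].as_matrix3(), M, atol=1e-9)

    def test_gauge_equivalence_across_references(self, rng):
        pairwise = [random_affine(rng) for _ in range(10)]
        t0 = chain_to_reference(pairwise, reference_index=0)
        t7 = chain_to_reference(pairwise, reference_index=7)
        gauge = t0.absolute[7].invert()
        for f in range(11):
            expected = gauge @ t0.absolute[f]
            assert np.allclose(t7.absolute[f].matrix, expected.matrix, atol=1e-6)

    def test_broken_chain_reports_index(self):
        pairwise = [AffineTransform.identity(), None, AffineTransform.identity()]
        with pytest.raises(ChainBreakError) as err:
            chain_to_reference(pairwise, reference_index=0)
        assert err.value.break_index == 1


class TestCanvas:
    def test_single_identity_frame(self):
        traj = chain_to_reference([], reference_index=0)
        b = compute_canvas(traj, (100, 120), margin=2)
        # pixel centers 0..w-1 plus a 2 px margin on both sides
        assert b.width == (120 - 1) + 4 + 1 and b.height == (100 - 1) + 4 + 1

    def test_translation_grows_canvas(self):
        traj = chain_to_reference([AffineTransform.translation(100, 0)], reference_index=0)
        b0 = compute_canvas(chain_to_reference([], 0), (100, 100))
        b = compute_canvas(traj, (100, 100))
        assert b.width == b0.width + 100

    def test_bounds_contain_all_transformed_corners(self, rng):
        pairwise = [random_affine(rng, max_translation=30) for _ in range(8)]
        traj = chain_to_reference(pairwise, reference_index=4)
        h, w = 80, 90
        b = compute_canvas(traj, (h, w))
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        for A in traj.absolute:
            pts = A.apply(corners)
            assert (pts[:, 0] >= b.x_min).all() and (pts[:, 0] <= b.x_min + b.width).all()
            assert (pts[:, 1] >= b.y_min).all() and (pts[:, 1] <= b.y_min + b.height).all()


class TestWarp:
    def test_identity_warp_preserves_frame(self, rng):
        img = rng.uniform(size=(40, 50))
        bounds = CanvasBounds(0.0, 0.0, 50, 40)
        warped, valid = warp_frame(img, AffineTransform.identity(), None, bounds)
        assert np.allclose(warped[valid], img[valid])
        assert valid.all()

    def test_integer_translation_is_exact_shift(self, rng):
        img = rng.uniform(size=(30, 30))
        A = AffineTransform.translation(5, 3)
        bounds = CanvasBounds(0.0, 0.0, 40, 40)
        warped, valid = warp_frame(img, A, None, bounds)
        assert np.allclose(warped[3:33, 5:35][valid[3:33, 5:35]], img[valid[3:33, 5:35]])

    def test_warp_inverse_warp_roundtrip(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        img = gaussian_filter(rng.uniform(size=(80, 80)), 2.0)  # smooth image
        A = AffineTransform.similarity(rotation_deg=7, scale=1.05, tx=4, ty=-3, center=(40, 40))
        bounds = CanvasBounds(-20.0, -20.0, 120, 120)
        fwd, v1 = warp_frame(img, A, None, bounds)
        # warp back into the original frame
        back_bounds = CanvasBounds(0.0, 0.0, 80, 80)
        shift = AffineTransform.translation(bounds.x_min, bounds.y_min)
        back, v2 = warp_frame(fwd, A.invert() @ shift, None, back_bounds)
        interior = np.zeros_like(v2)
        interior[10:-10, 10:-10] = True
        sel = v2 & interior
        assert np.abs(back - img)[sel].max() <= 0.02


class TestBlend:
    def test_single_frame_passthrough(self, rng):
        img = rng.uniform(size=(30, 30))
        valid = np.zeros((30, 30), bool)
        valid[5:25, 5:25] = True
        img = img * valid
        for mode in ("feather", "multiband"):
            out = blend([img], [valid], mode=mode)
            assert np.allclose(out[valid], img[valid], atol=1e-6)
            assert np.allclose(out[~valid], 0.0)

    @pytest.mark.parametrize("mode", ["feather", "multiband"])
    def test_constant_overlap_conserved(self, mode):
        c = 0.37
        v1 = np.zeros((40, 60), bool)
        v2 = np.zeros((40, 60), bool)
        v1[:, :40] = True
        v2[:, 20:] = True
        out = blend([np.full((40, 60), c) * v1, np.full((40, 60), c) * v2], [v1, v2], mode=mode)
        assert np.allclose(out[v1 & v2], c, atol=1e-10)

    def test_feather_overlap_convex(self):
        v1 = np.zeros((30, 50), bool)
        v2 = np.zeros((30, 50), bool)
        v1[:, :35] = True
        v2[:, 15:] = True
        out = blend([np.full((30, 50), 0.2) * v1, np.full((30, 50), 0.8) * v2], [v1, v2])
        overlap = v1 & v2
        assert (out[overlap] >= 0.2 - 1e-12).all() and (out[overlap] <= 0.8 + 1e-12).all()


class TestMosaicIntegration:
    def test_gt_mosaic_reproduces_texture(self, short_sequence, texture):
        """With ground-truth transforms the mosaic matches the underlying
        texture crop (SSIM >= 0.95 over the covered region)."""
        from skimage.metrics import structural_similarity

        from fetomosaic.flow import to_gray
        from fetomosaic.simulator import cumulative_placements

        seq = short_sequence
        traj = chain_to_reference(seq.gt_pairwise, reference_index=0)
        canvas = build_mosaic(seq.frames, traj, mask=seq.mask)
        placements = cumulative_placements(seq.gt_pairwise, (320, 320), 1024)
        # texture crop in frame-0 coordinates over the canvas
        bounds = CanvasBounds(canvas.origin_offset[0], canvas.origin_offset[1],
                              canvas.image.shape[1], canvas.image.shape[0])
        crop, _ = warp_frame(texture, placements[0].invert(), None, bounds)
        covered = canvas.weight > 0
        # vignetting dims the rendered frames toward the rim; compare where lit
        g1 = to_gray(canvas.image)
        g2 = to_gray(crop)
        score, smap = structural_similarity(g1, g2, data_range=1.0, full=True)
        assert np.median(smap[covered]) >= 0.95

    def test_incremental_preview_counts(self, short_sequence):
        seq = short_sequence
        traj = chain_to_reference(seq.gt_pairwise, reference_index=0)
        frames = seq.frames[:6]
        traj6 = chain_to_reference(seq.gt_pairwise[:5], reference_index=0)
        previews = incremental_preview(frames, traj6, mask=seq.mask, every_k=100)
        assert len(previews) == 1  # k larger than the sequence: final only
        previews = incremental_preview(frames, traj6, mask=seq.mask, every_k=1)
        assert len(previews) == 6
        final = build_mosaic(frames, traj6, mask=seq.mask)
        assert np.allclose(previews[-1][1].image, final.image)
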