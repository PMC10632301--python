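"""Homography estimation, composition, warping and exposure blending."""
from __future__ import annotations

import numpy as np
import pytest

from fetomosaic import (
    Frame,
    Homography,
    MosaicCanvas,
    compose_global,
    estimate_homography,
    exposure_weights,
    warp_frame,
)
from fetomosaic.features import MatchSet
from fetomosaic.frames import circular_fov_mask
from fetomosaic.mosaic import apply_h, mean_corner_error, normalize_h


def matchset(src: np.ndarray, dst: np.ndarray) -> MatchSet:
    n = len(src)
    return MatchSet(
        kpts_a=np.asarray(src, dtype=float),
        kpts_b=np.asarray(dst, dtype=float),
        confidences=np.ones(n),
        descr_a=np.zeros((n, 2)),
        descr_b=np.zeros((n, 2)),
    )


def random_homography(rng) -> np.ndarray:
    angle = rng.uniform(-0.2, 0.2)
    scale = rng.uniform(0.9, 1.1)
    h = np.array(
        [
            [scale * np.cos(angle), -scale * np.sin(angle), rng.uniform(-20, 20)],
            [scale * np.sin(angle), scale * np.cos(angle), rng.uniform(-20, 20)],
            [rng.uniform(-1e-5, 1e-5), rng.uniform(-1e-5, 1e-5), 1.0],
        ]
    )
    return h


class TestEstimateHomography:
    def test_exact_minimal_solve(self, rng, config):
        h_true = random_homography(rng)
        src = np.array([[10.0, 10.0], [90.0, 15.0], [85.0, 80.0], [12.0, 88.0]])
        dst = apply_h(h_true, src)
        got = estimate_homography(matchset(src, dst), config)
        assert got is not None
        assert np.allclose(got.matrix, h_true / h_true[2, 2], rtol=1e-6, atol=1e-6)

    def test_identity_correspondences(self, rng, config):
        pts = rng.uniform(0, 100, (40, 2))
        got = estimate_homography(matchset(pts, pts), config)
        assert got is not None
        assert np.allclose(got.matrix, np.eye(3), atol=1e-9)
        assert got.inlier_fraction == pytest.approx(1.0)

    def test_robust_to_thirty_percent_outliers(self, rng, config):
        h_true = random_homography(rng)
        src = rng.uniform(10, 240, (100, 2))
        dst = apply_h(h_true, src)
        n_out = 30
        dst[:n_out] = rng.uniform(0, 250, (n_out, 2))
        got = estimate_homography(matchset(src, dst), config)
        assert got is not None
        assert mean_corner_error(got.matrix, h_true, (256, 256)) < 0.5

    def test_too_few_matches_signal_failure(self, config):
        assert estimate_homography(matchset(np.zeros((3, 2)), np.zeros((3, 2))), config) is None

    def test_collinear_points_signal_failure(self, config):
        src = np.array([[i, 2.0 * i] for i in range(10)], dtype=float)
        assert estimate_homography(matchset(src, src + 1.0), config) is None

    def test_deterministic_given_seed(self, rng, config):
        h_true = random_homography(rng)
        src = rng.uniform(10, 240, (60, 2))
        dst = apply_h(h_true, src) + rng.normal(0, 1.0, (60, 2))
        a = estimate_homography(matchset(src, dst), config)
        b = estimate_homography(matchset(src, dst), config)
        assert np.array_equal(a.matrix, b.matrix)

    def test_bottom_right_entry_is_one(self, rng, config):
        h_true = random_homography(rng)
        src = rng.uniform(10, 240, (50, 2))
        got = estimate_homography(matchset(src, apply_h(h_true, src)), config)
        assert got.matrix[2, 2] == 1.0


class TestComposeGlobal:
    def test_identity_chain(self):
        rel = [Homography.identity() for _ in range(5)]
        out = compose_global(rel)
        for g in out:
            assert np.allclose(g.matrix, np.eye(3))

    def test_translations_accumulate(self):
        t = np.eye(3)
        t[0, 2] = 2.0
        rel = [Homography(matrix=t.copy()) for _ in range(4)]
        out = compose_global(rel)
        assert out[4].matrix[0, 2] == pytest.approx(8.0)
        assert out[4].matrix[1, 2] == pytest.approx(0.0)

    def test_consistency_with_relatives(self, rng):
        rel = [Homography(matrix=random_homography(rng)) for _ in range(6)]
        out = compose_global(rel)
        for i in range(1, 7):
            recomposed = np.linalg.solve(out[i - 1].matrix, out[i].matrix)
            assert np.allclose(
                normalize_h(recomposed), rel[i - 1].matrix, atol=1e-9
            )

    def test_failed_relative_breaks_the_chain(self, rng):
        rel = [Homography(matrix=random_homography(rng)) for _ in range(5)]
        rel[2] = None
        out = compose_global(rel)
        assert out[0] is not None and out[2] is not None
        assert out[3] is None and out[5] is None

    def test_central_anchor(self, rng):
        rel = [Homography(matrix=random_homography(rng)) for _ in range(4)]
        out = compose_global(rel, anchor=2)
        assert np.allclose(out[2].matrix, np.eye(3))
        assert all(g is not None for g in out)
        # frame 1 -> anchor composed with relative 1 maps frame 2 -> anchor
        assert np.allclose((out[1] @ rel[1]).matrix, np.eye(3), atol=1e-9)


def textured_frame(rng, size: int = 96) -> Frame:
    pixels = np.repeat(rng.random((size, size))[..., None], 3, axis=2)
    return Frame(pixels=pixels, mask=circular_fov_mask(size, size))


class TestWarpFrame:
    def test_identity_warp_reproduces_frame(self, rng):
        frame = textured_frame(rng)
        canvas = warp_frame(frame, Homography.identity(), MosaicCanvas())
        pano = canvas.render()
        ox, oy = canvas.origin_offset.astype(int)
        inner = frame.mask & (exposure_weights(frame) > 0)
        ys, xs = np.nonzero(inner)
        got = pano[ys - oy, xs - ox]
        assert np.abs(got - frame.pixels[inner]).max() < 1e-6

    def test_disjoint_footprints_do_not_mix(self, rng):
        a, b = textured_frame(rng), textured_frame(rng)
        shift = np.eye(3)
        shift[0, 2] = 300.0
        canvas = MosaicCanvas()
        warp_frame(a, Homography.identity(), canvas)
        warp_frame(b, Homography(matrix=shift), canvas)
        pano = canvas.render()
        ox, oy = canvas.origin_offset.astype(int)
        inner = a.mask & (exposure_weights(a) > 0)
        ys, xs = np.nonzero(inner)
        assert np.abs(pano[ys - oy, xs - ox] - a.pixels[inner]).max() < 1e-6
        inner_b = b.mask & (exposure_weights(b) > 0)
        ys, xs = np.nonzero(inner_b)
        assert np.abs(pano[ys - oy, xs - ox + 300] - b.pixels[inner_b]).max() < 1e-6

    def test_repeated_identity_warp_is_idempotent_after_render(self, rng):
        frame = textured_frame(rng)
        once = warp_frame(frame, Homography.identity(), MosaicCanvas()).render()
        twice_canvas = MosaicCanvas()
        warp_frame(frame, Homography.identity(), twice_canvas)
        twice = warp_frame(frame, Homography.identity(), twice_canvas).render()
        assert np.abs(once - twice).max() < 1e-9

    def test_blending_conservation(self, rng):
        canvas = MosaicCanvas()
        for dx in (0.0, 17.0):
            shift = np.eye(3)
            shift[0, 2] = dx
            warp_frame(textured_frame(rng), Homography(matrix=shift), canvas)
        pano = canvas.render()
        covered = canvas.weight > 0
        manual = np.zeros_like(canvas.accum)
        np.divide(canvas.accum, canvas.weight[..., None], out=manual,
                  where=canvas.weight[..., None] > 0)
        assert np.abs(pano[covered] - np.clip(manual, 0, 1)[covered]).max() < 1e-9
        assert pano.min() >= -1e-9 and pano.max() <= 1 + 1e-9


class TestExposureWeights:
    def test_flat_midgray_varies_only_by_taper(self):
        size = 96
        frame = Frame(pixels=np.full((size, size, 3), 0.5),
                      mask=circular_fov_mask(size, size))
        w = exposure_weights(frame)
        # well-exposedness is maximal (1) and contrast constant, so weights
        # must be a function of the distance to the FoV border alone
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(frame.mask)
        inside = frame.mask & (w > 0)
        order = np.argsort(dist[inside])
        sorted_w = w[inside][order]
        assert (np.diff(sorted_w) >= -1e-12).all()

    def test_near_black_frame_weighs_less_than_midgray(self):
        size = 96
        mask = circular_fov_mask(size, size)
        w_gray = exposure_weights(Frame(pixels=np.full((size, size, 3), 0.5), mask=mask))
        w_dark = exposure_weights(Frame(pixels=np.full((size, size, 3), 0.02), mask=mask))
        interior = w_gray > 0
        assert (w_dark[interior] < w_gray[interior]).all()

    def test_zero_at_border_positive_inside(self, rng):
        frame = textured_frame(rng)
        w = exposure_weights(frame)
        assert (w[~frame.mask] == 0).all()
        from scipy.ndimage import binary_erosion

        deep = binary_erosion(frame.mask, iterations=10)
        assert (w[deep] > 0).all()


def test_exposure_blending_reduces_vignette_seams(rng):
    """Blending two offset vignetted copies: exposure-fusion weights must
    leave a smaller maximum intensity step across the seam than uniform
    averaging of the same two frames."""
    size = 128
    base = np.repeat(rng.random((size, size))[..., None], 3, axis=2)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - (size - 1) / 2, yy - (size - 1) / 2) / (size / 2 - 1)
    vignette = 1.0 - 0.7 * np.clip(r, 0, 1) ** 2
    mask = circular_fov_mask(size, size)
    frame = Frame(pixels=np.clip(base * vignette[..., None], 0, 1), mask=mask)
    shift = np.eye(3)
    shift[0, 2] = 40.0

    def blended(weights_fn):
        canvas = MosaicCanvas()
        warp_frame(frame, Homography.identity(), canvas, weights_fn(frame))
        warp_frame(frame, Homography(matrix=shift), canvas, weights_fn(frame))
        return canvas

    def max_seam_step(canvas):
        pano = canvas.render().mean(axis=2)
        covered = canvas.weight > 0
        steps = np.abs(np.diff(pano, axis=1))
        both = covered[:, 1:] & covered[:, :-1]
        return steps[both].max()

    fused = max_seam_step(blended(exposure_weights))
    uniform = max_seam_step(blended(lambda f: np.where(f.mask, 1.0, 0.0)))
    assert fused < uniform


def test_build_mosaic_on_identical_frames_keeps_one_footprint(rng):
    """Two identical frames registered as identity cover a single footprint."""
    from fetomosaic import build_mosaic

    frame = textured_frame(rng)
    canvas = build_mosaic([frame, Frame(pixels=frame.pixels.copy(), index=1,
                                        mask=frame.mask.copy())])
    single = warp_frame(frame, Homography.identity(), MosaicCanvas())
    # estimated registration is identity to sub-pixel, so coverage matches
    # the single-frame footprint up to bilinear spill at the rim
    assert abs(int(canvas.coverage.sum()) - int(single.coverage.sum())) < 0.05 * single.coverage.sum()
    assert [r.status for r in canvas.frame_status] == ["tracked", "tracked"]
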