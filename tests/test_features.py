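"""Matching math against brute-force oracles, plus backend contracts."""
from __future__ import annotations

import numpy as np
import pytest

from fetomosaic import (
    ConfidenceMatrix,
    Frame,
    PipelineConfig,
    confidence_matrix,
    extract_features,
    match_pair,
    mutual_nearest_matches,
    refine_matches,
    score_matrix,
)
from fetomosaic.config import ConfigError
from fetomosaic.features import FeaturePyramid, ScoreMatrix


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def dual_softmax_oracle(s: np.ndarray) -> np.ndarray:
    """Entrywise two-loop dual softmax, no vectorized shortcuts."""
    n, m = s.shape
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            row = np.exp(s[i, :] - s[i, :].max())
            col = np.exp(s[:, j] - s[:, j].max())
            out[i, j] = (row[j] / row.sum()) * (col[i] / col.sum())
    return out


def mnn_oracle(p: np.ndarray, theta: float) -> set[tuple[int, int]]:
    """Exhaustive mutual-nearest-neighbour scan with lowest-index ties."""
    out = set()
    for i in range(p.shape[0]):
        j = int(np.argmax(p[i, :]))
        if int(np.argmax(p[:, j])) == i and p[i, j] >= theta:
            out.add((i, j))
    return out


def make_pyramid(desc: np.ndarray, fine: np.ndarray | None = None) -> FeaturePyramid:
    """Minimal pyramid wrapping a (Hc, Wc, D) descriptor grid."""
    hc, wc, d = desc.shape
    if fine is None:
        fine = np.zeros((hc * 4, wc * 4, 9))
    return FeaturePyramid(
        coarse=desc,
        fine=fine,
        coarse_stride=8,
        fine_stride=2,
        global_feature=desc.mean(axis=(0, 1)),
        valid_cells=np.ones((hc, wc), dtype=bool),
        frame_shape=(hc * 8, wc * 8),
    )


def unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# score matrix
# --------------------------------------------------------------------------

class TestScoreMatrix:
    def test_identical_unit_vectors_give_unit_diagonal(self, rng):
        desc = unit(rng.standard_normal((3, 3, 16)))
        p = make_pyramid(desc)
        s = score_matrix(p, p, tau=1.0)
        assert np.allclose(np.diag(s.values), 1.0)

    def test_linear_in_inverse_temperature(self, rng):
        a = make_pyramid(unit(rng.standard_normal((2, 3, 8))))
        b = make_pyramid(unit(rng.standard_normal((3, 2, 8))))
        assert np.allclose(
            score_matrix(a, b, tau=0.5).values, 2.0 * score_matrix(a, b, tau=1.0).values
        )

    def test_matches_brute_force_inner_products(self, rng):
        da = unit(rng.standard_normal((1, 3, 12)))
        db = unit(rng.standard_normal((3, 1, 12)))
        s = score_matrix(make_pyramid(da), make_pyramid(db), tau=0.1)
        expected = np.array(
            [[np.dot(x, y) * 10.0 for y in db.reshape(-1, 12)] for x in da.reshape(-1, 12)]
        )
        assert np.allclose(s.values, expected, atol=1e-12)

    def test_nonpositive_temperature_rejected(self, rng):
        p = make_pyramid(unit(rng.standard_normal((2, 2, 4))))
        with pytest.raises(ValueError, match="tau"):
            score_matrix(p, p, tau=0.0)


# --------------------------------------------------------------------------
# confidence matrix (dual softmax)
# --------------------------------------------------------------------------

class TestConfidenceMatrix:
    def test_singleton_is_one(self):
        c = confidence_matrix(ScoreMatrix(np.array([[3.7]]), 1.0, None, None))
        assert c.values[0, 0] == pytest.approx(1.0)

    def test_uniform_two_by_two_gives_quarter(self):
        c = confidence_matrix(ScoreMatrix(np.full((2, 2), 1.3), 1.0, None, None))
        assert np.allclose(c.values, 0.25)

    def test_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = rng.integers(1, 31, size=2)
            s = rng.normal(0, 3, size=shape)
            c = confidence_matrix(ScoreMatrix(s, 1.0, None, None))
            assert np.allclose(c.values, dual_softmax_oracle(s), atol=1e-12)

    def test_bounded_by_row_and_column_softmax_factors(self, rng):
        from scipy.special import softmax

        s = rng.normal(0, 2, (12, 9))
        c = confidence_matrix(ScoreMatrix(s, 1.0, None, None)).values
        assert ((c >= 0) & (c <= 1)).all()
        assert (c <= softmax(s, axis=1) + 1e-15).all()
        assert (c <= softmax(s, axis=0) + 1e-15).all()


# --------------------------------------------------------------------------
# mutual nearest neighbours
# --------------------------------------------------------------------------

class TestMutualNearestMatches:
    def test_dominant_diagonal(self):
        p = np.full((3, 3), 0.01)
        np.fill_diagonal(p, 0.9)
        got = mutual_nearest_matches(ConfidenceMatrix(values=p), theta_c=0.5)
        assert {(i, j) for i, j, _ in got} == {(0, 0), (1, 1), (2, 2)}

    def test_threshold_above_all_entries_empties_the_set(self):
        p = np.full((3, 3), 0.01)
        np.fill_diagonal(p, 0.9)
        assert mutual_nearest_matches(ConfidenceMatrix(values=p), theta_c=0.95) == []

    def test_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.random((20, 20))
            theta = rng.random() * 0.2
            got = mutual_nearest_matches(ConfidenceMatrix(values=p), theta_c=theta)
            assert {(i, j) for i, j, _ in got} == mnn_oracle(p, theta)

    def test_one_to_one_on_both_sides(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.random((15, 12))
            got = mutual_nearest_matches(ConfidenceMatrix(values=p), theta_c=0.0)
            rows = [i for i, _, _ in got]
            cols = [j for _, j, _ in got]
            assert len(rows) == len(set(rows)) and len(cols) == len(set(cols))

    def test_match_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(17)
        p = ConfidenceMatrix(values=rng.random((25, 25)))
        sets = [
            {(i, j) for i, j, _ in mutual_nearest_matches(p, theta_c=t)}
            for t in (0.1, 0.4, 0.8)
        ]
        assert sets[2] <= sets[1] <= sets[0]


def test_temperature_sharpening_reduces_row_entropy(rng):
    """For fixed scores, dividing by a smaller tau concentrates each row."""
    from scipy.special import softmax
    from scipy.stats import entropy

    s = rng.normal(0, 1, (10, 14))
    taus = [1.0, 0.5, 0.1, 0.05]
    entropies = [entropy(softmax(s / t, axis=1), axis=1).mean() for t in taus]
    assert all(a >= b - 1e-12 for a, b in zip(entropies, entropies[1:]))


# --------------------------------------------------------------------------
# backend contracts
# --------------------------------------------------------------------------

class TestDenseGridBackend:
    def test_constant_frame_gives_identical_valid_descriptors(self, config):
        frame = Frame(pixels=np.full((64, 64, 3), 0.4))
        pyr = extract_features(frame, config=config)
        desc = pyr.valid_descriptors
        assert len(desc) > 0
        assert np.allclose(desc, desc[0])

    def test_deterministic(self, small_seq, config):
        a = extract_features(small_seq.frames[0], config=config)
        b = extract_features(small_seq.frames[0], config=config)
        assert np.array_equal(a.coarse, b.coarse)
        assert np.array_equal(a.fine, b.fine)
        assert np.array_equal(a.global_feature, b.global_feature)

    def test_translation_equivariance_under_one_cell_roll(self, config, rng):
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.random((96, 96)), 1.5, mode="wrap")
        base = (base - base.min()) / (base.max() - base.min())
        pixels = np.repeat(base[..., None], 3, axis=2)
        full = np.ones((96, 96), dtype=bool)
        a = extract_features(Frame(pixels=pixels, mask=full), config=config)
        b = extract_features(
            Frame(pixels=np.roll(pixels, 8, axis=1), mask=full), config=config
        )
        # interior cells, away from the roll seam and filter borders
        assert np.allclose(a.coarse[3:-3, 3:-4], b.coarse[3:-3, 4:-3], atol=1e-6)

    def test_unknown_backend_is_a_configuration_error(self, small_seq, config):
        with pytest.raises(ConfigError, match="unknown feature backend"):
            extract_features(small_seq.frames[0], backend="resnet-fpn", config=config)

    def test_coarse_descriptors_unit_norm(self, small_seq, config):
        pyr = extract_features(small_seq.frames[0], config=config)
        norms = np.linalg.norm(pyr.valid_descriptors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_global_feature_finite(self, small_seq, config):
        pyr = extract_features(small_seq.frames[0], config=config)
        assert np.all(np.isfinite(pyr.global_feature))


# --------------------------------------------------------------------------
# coarse-to-fine refinement
# --------------------------------------------------------------------------

class TestRefineMatches:
    def test_identity_pair_keeps_keypoints_in_place(self, config, rng):
        # the softmax expectation has a small floor set by fine-descriptor
        # correlation between neighbouring cells; on an identity pair the
        # bulk of keypoints must stay put at well below a fine stride
        pixels = np.repeat(rng.random((64, 64))[..., None], 3, axis=2)
        frame = Frame(pixels=pixels, mask=np.ones((64, 64), dtype=bool))
        pyr = extract_features(frame, config=config)
        n = pyr.valid_cells.shape[0] * pyr.valid_cells.shape[1]
        matches = [(i, i, 1.0) for i in range(n)]
        ms = refine_matches(
            matches, pyr, pyr, window=config.refine_window, fine_tau=config.fine_tau
        )
        assert len(ms) == n
        dev = np.abs(ms.kpts_a - ms.kpts_b).max(axis=1)
        assert np.median(dev) < 0.2
        assert np.percentile(dev, 90) < 1.0

    def test_uniform_descriptors_give_window_centre(self):
        hc = wc = 3
        coarse = np.zeros((hc, wc, 4))
        fine = np.ones((hc * 4, wc * 4, 9))
        pyr = FeaturePyramid(
            coarse=coarse,
            fine=fine / np.linalg.norm(fine, axis=-1, keepdims=True),
            coarse_stride=8,
            fine_stride=2,
            global_feature=np.zeros(4),
            valid_cells=np.ones((hc, wc), dtype=bool),
            frame_shape=(hc * 8, wc * 8),
        )
        ms = refine_matches([(4, 4, 1.0)], pyr, pyr, window=5, fine_tau=0.02)
        # uniform similarities -> uniform weights -> centre of the window,
        # which for the central cell is the keypoint itself
        assert np.allclose(ms.kpts_a, ms.kpts_b, atol=1e-9)

    def test_recovers_sub_cell_shift(self, config, rng):
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.random((64, 64)), 1.2)
        base = (base - base.min()) / (base.max() - base.min())
        shifted = np.roll(base, 1, axis=1)  # 0.5 fine strides = 1 px
        full = np.ones((64, 64), dtype=bool)
        pa = extract_features(Frame(pixels=np.repeat(base[..., None], 3, 2), mask=full), config=config)
        pb = extract_features(Frame(pixels=np.repeat(shifted[..., None], 3, 2), mask=full), config=config)
        cells = [(i, i, 1.0) for i in range(9, 55)]  # interior coarse cells
        ms = refine_matches(cells, pa, pb, window=5, fine_tau=config.fine_tau)
        dx = np.median(ms.kpts_b[:, 0] - ms.kpts_a[:, 0])
        assert abs(dx - 1.0) < 0.5  # within 0.25 fine strides of the true shift

    def test_even_window_rejected(self, config, rng):
        p = make_pyramid(unit(rng.standard_normal((2, 2, 4))))
        with pytest.raises(ValueError, match="window"):
            refine_matches([], p, p, window=4)


# --------------------------------------------------------------------------
# full pair matching
# --------------------------------------------------------------------------

class TestMatchPair:
    def test_identity_pair_keypoints_coincide(self, config, rng):
        pixels = np.repeat(rng.random((96, 96))[..., None], 3, axis=2)
        frame = Frame(pixels=pixels, mask=np.ones((96, 96), dtype=bool))
        ms = match_pair(frame, frame, config)
        assert len(ms) >= 50
        dev = np.abs(ms.kpts_a - ms.kpts_b).max(axis=1)
        assert np.median(dev) < 0.2

    def test_pure_translation_recovered(self, config, rng):
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.random((128, 128)), 1.0)
        base = (base - base.min()) / (base.max() - base.min())
        full = np.ones((128, 128), dtype=bool)
        a = Frame(pixels=np.repeat(base[..., None], 3, 2), mask=full)
        b = Frame(pixels=np.repeat(np.roll(base, 10, axis=1)[..., None], 3, 2), mask=full)
        ms = match_pair(a, b, config)
        disp = np.median(ms.kpts_b - ms.kpts_a, axis=0)
        assert abs(disp[0] - 10.0) < 0.5 and abs(disp[1]) < 0.5

    def test_uncorrelated_noise_matches_fewer_than_translate(self, config, rng):
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.random((96, 96)), 1.0)
        base = (base - base.min()) / (base.max() - base.min())
        full = np.ones((96, 96), dtype=bool)
        a = Frame(pixels=np.repeat(base[..., None], 3, 2), mask=full)
        translate = Frame(
            pixels=np.repeat(np.roll(base, 8, axis=1)[..., None], 3, 2), mask=full
        )
        noise = Frame(pixels=rng.random((96, 96, 3)), mask=full)
        assert len(match_pair(a, noise, config)) < len(match_pair(a, translate, config))

    def test_mismatched_sizes_rejected(self, config):
        a = Frame(pixels=np.zeros((64, 64, 3)))
        b = Frame(pixels=np.zeros((48, 48, 3)))
        with pytest.raises(ValueError, match="size"):
            match_pair(a, b, config)
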