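"""Dense feature extraction and confidence-matrix matching.

A frame pair (A, B) is matched in four stages:

1. A pluggable backend extracts dense multi-scale features per frame: a
   coarse descriptor grid (one cell per ``coarse_stride`` pixels, used for
   candidate matching), a fine grid (``fine_stride``) for sub-pixel
   refinement, and a pooled global descriptor used by keyframe logic.
2. The temperature-scaled score matrix ``S(i, j) = <d_i^A, d_j^B> / tau``
   is turned into a dual-softmax confidence matrix
   ``P(i, j) = softmax_row(S)_ij * softmax_col(S)_ij``.
3. Mutual nearest neighbours of ``P`` above the confidence threshold
   ``theta_c`` become coarse matches (one-to-one by construction).
4. Each coarse match is refined: the B-side keypoint becomes the
   softmax-expectation of fine-cell centres in a local window, weighted by
   fine-descriptor similarity against the A-side centre cell.

The built-in ``dense-grid`` backend is a deterministic, training-free
stand-in for a learned pyramid encoder. It normalizes local contrast
(removing vignetting and haze shading), then builds soft-binned
gradient-orientation channels; coarse descriptors pool a 4x4 block of fine
cells from strongly smoothed channels, are centred and ZCA-whitened across
the frame's valid cells (which decorrelates the otherwise highly collinear
histograms) and L2-normalized. Fine descriptors are normalized 5x5-px
luminance patches, so their similarity behaves like local normalized
cross-correlation. Any callable meeting the :class:`FeaturePyramid`
contract can be registered as an alternative backend.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.special import softmax

from .config import ConfigError, PipelineConfig
from .frames import Frame

__all__ = [
    "FeaturePyramid",
    "ScoreMatrix",
    "ConfidenceMatrix",
    "MatchSet",
    "register_backend",
    "get_backend",
    "extract_features",
    "score_matrix",
    "confidence_matrix",
    "mutual_nearest_matches",
    "match_descriptor_sets",
    "refine_matches",
    "match_pyramids",
    "match_pair",
]


@dataclass
class FeaturePyramid:
    """Dense per-frame features at two resolutions plus a pooled global vector.

    ``coarse`` holds unit-norm descriptors on an (Hc, Wc) cell grid,
    ``fine`` unit-norm descriptors on an (Hf, Wf) grid; ``valid_cells``
    flags coarse cells sufficiently inside the circular FoV.
    ``global_feature`` is the mean of the *raw* (pre-normalization) coarse
    descriptors over valid cells, scaled by the backend's calibration factor.
    """

    coarse: np.ndarray
    fine: np.ndarray
    coarse_stride: int
    fine_stride: int
    global_feature: np.ndarray
    valid_cells: np.ndarray
    frame_shape: tuple[int, int]
    #: smoothed FoV-filled luminance kept for pixel-level patch correlation
    lum: np.ndarray | None = None
    #: per-pixel distance to the FoV border (px); patches must stay clear of
    #: the filled border region, whose radial smear is stationary in frame
    #: coordinates
    fov_distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.global_feature)):
            raise ValueError("global_feature must be finite")
        if self.valid_cells.shape != self.coarse.shape[:2]:
            raise ValueError("valid_cells must match the coarse grid")

    @property
    def valid_index(self) -> np.ndarray:
        """(N, 2) array of (row, col) coarse-cell indices inside the FoV."""
        return np.argwhere(self.valid_cells)

    @property
    def valid_descriptors(self) -> np.ndarray:
        return self.coarse[self.valid_cells]

    def cell_centers_px(self, cells: np.ndarray) -> np.ndarray:
        """Pixel xy coordinates of coarse-cell keypoints.

        The keypoint of a coarse cell is the centre of its central fine cell,
        which keeps coarse keypoints and the fine grid used for refinement on
        the same lattice on both sides of a pair.
        """
        block = self.coarse_stride // self.fine_stride
        fine_rc = cells * block + block // 2
        xy = (fine_rc[:, ::-1] + 0.5) * self.fine_stride - 0.5
        return xy.astype(np.float64)


@dataclass
class ScoreMatrix:
    """Temperature-scaled descriptor similarities between two valid-cell sets."""

    values: np.ndarray
    tau: float
    cells_a: np.ndarray
    cells_b: np.ndarray


@dataclass
class ConfidenceMatrix:
    """Dual-softmax mutual match probabilities in [0, 1]."""

    values: np.ndarray
    cells_a: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    cells_b: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))


@dataclass
class MatchSet:
    """Paired sub-pixel keypoints with confidences and coarse descriptors."""

    kpts_a: np.ndarray
    kpts_b: np.ndarray
    confidences: np.ndarray
    descr_a: np.ndarray
    descr_b: np.ndarray

    def __len__(self) -> int:
        return len(self.confidences)

    def swap(self) -> "MatchSet":
        """The same matches with the A and B sides exchanged."""
        return MatchSet(
            kpts_a=self.kpts_b,
            kpts_b=self.kpts_a,
            confidences=self.confidences,
            descr_a=self.descr_b,
            descr_b=self.descr_a,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kpts_a": self.kpts_a.tolist(),
                    "kpts_b": self.kpts_b.tolist(),
                    "confidences": self.confidences.tolist(),
                },
                indent=1,
            )
        )


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[[Frame, PipelineConfig], FeaturePyramid]] = {}


def register_backend(name: str):
    """Register a feature backend: ``callable(frame, config) -> FeaturePyramid``."""

    def deco(fn):
        _BACKENDS[name] = fn
        return fn

    return deco


def get_backend(name: str) -> Callable[[Frame, PipelineConfig], FeaturePyramid]:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ConfigError(
            f"unknown feature backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def _l2_normalize(arr: np.ndarray, axis: int = -1) -> np.ndarray:
    norm = np.linalg.norm(arr, axis=axis, keepdims=True)
    out = np.zeros_like(arr)
    np.divide(arr, norm, out=out, where=norm > 1e-12)
    return out


@register_backend("dense-grid")
def dense_grid_backend(frame: Frame, config: PipelineConfig) -> FeaturePyramid:
    cs, fs = config.coarse_stride, config.fine_stride
    block = cs // fs
    lum = frame.luminance
    mask0 = frame.mask
    if not mask0.all():
        # replace outside-FoV pixels by their nearest interior value: the
        # black border is stationary in frame coordinates and its strong
        # artificial edge would otherwise dominate border-cell descriptors
        # and lock matches to the frame instead of the scene
        idx = distance_transform_edt(~mask0, return_distances=False, return_indices=True)
        lum = lum[idx[0], idx[1]]
    # local contrast normalization: endoscopic vignetting (multiplicative)
    # and the turbidity veil (additive) are smooth patterns stationary in
    # frame coordinates; left in place they contaminate descriptors and
    # bias patch correlation toward zero radial displacement, which
    # integrates into a systematic scale drift. Subtracting the local mean
    # and dividing by the local contrast removes any smooth shading (wrap
    # mode keeps both estimates exactly translation-equivariant).
    mu = gaussian_filter(lum, 12.0, mode="wrap")
    dev = lum - mu
    sd = np.sqrt(np.maximum(gaussian_filter(dev**2, 12.0, mode="wrap"), 0.0))
    lum = 0.5 + 0.2 * np.clip(dev / (sd + 0.02), -3.0, 3.0)
    lum = gaussian_filter(lum, 1.0, mode="wrap")
    h, w = lum.shape
    # cell validity is judged on an eroded FoV so cells whose content is
    # mostly border smear never enter matching
    if not mask0.all():
        fov_dist = distance_transform_edt(mask0)
    else:
        fov_dist = np.full(mask0.shape, float(max(mask0.shape)))
    inner = fov_dist > 2.0 * fs
    ph, pw = (-h) % cs, (-w) % cs
    if ph or pw:
        lum = np.pad(lum, ((0, ph), (0, pw)), mode="edge")
        mask = np.pad(inner, ((0, ph), (0, pw)), mode="constant")
        fov_dist = np.pad(fov_dist, ((0, ph), (0, pw)), mode="constant")
    else:
        mask = inner
    hp, wp = lum.shape
    hf, wf = hp // fs, wp // fs
    hc, wc = hp // cs, wp // cs

    # circular central differences: together with wrap-mode filters the
    # whole backend commutes exactly with cyclic translation
    gx = 0.5 * (np.roll(lum, -1, axis=1) - np.roll(lum, 1, axis=1))
    gy = 0.5 * (np.roll(lum, -1, axis=0) - np.roll(lum, 1, axis=0))
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    # soft orientation binning (linear interp between adjacent bins) and
    # spatial smoothing of each orientation channel keep descriptors smooth
    # under sub-cell shifts and small rotations
    pos = ori / (2 * np.pi) * 8
    i0 = np.floor(pos).astype(np.int64) % 8
    frac = pos - np.floor(pos)
    channels = np.zeros((8, hp, wp))
    for b in range(8):
        channels[b] += np.where(i0 == b, mag * (1 - frac), 0.0)
        channels[b] += np.where((i0 + 1) % 8 == b, mag * frac, 0.0)
    # two smoothing scales: ~fine_stride for the fine (sub-pixel) level,
    # ~coarse_stride/2 for the coarse level so coarse descriptors stay
    # stable under displacements anywhere inside a coarse cell
    coarse_ch = np.stack(
        [gaussian_filter(c, cs / 2.0, mode="wrap") for c in channels]
    )
    # fine descriptors are normalized luminance patches (one 5x5-px patch
    # per fine cell): their similarity behaves like local normalized
    # cross-correlation, whose peak localizes displacement far better than
    # pooled gradient histograms do at this scale
    from numpy.lib.stride_tricks import sliding_window_view

    pad = np.pad(lum, 2, mode="wrap")
    patches = sliding_window_view(pad, (5, 5))[::fs, ::fs]
    fine_raw = patches.reshape(hf, wf, 25).astype(np.float64)

    hist_c = coarse_ch.reshape(8, hf, fs, wf, fs).mean(axis=(2, 4)).transpose(1, 2, 0)
    lum_c = gaussian_filter(lum, cs / 2.0, mode="wrap")
    int_c = lum_c.reshape(hf, fs, wf, fs).mean(axis=(1, 3))
    coarse_fine = np.concatenate([hist_c, int_c[..., None]], axis=2)
    coarse_raw = (
        coarse_fine.reshape(hc, block, wc, block, 9)
        .transpose(0, 2, 1, 3, 4)
        .reshape(hc, wc, block * block * 9)
    )
    cover = mask.reshape(hc, cs, wc, cs).mean(axis=(1, 3))
    valid = cover >= config.min_cell_cover
    d = coarse_raw.shape[2]
    if valid.any():
        mean_desc = coarse_raw[valid].mean(axis=0)
        global_feature = mean_desc * config.global_scale
        centered = coarse_raw - mean_desc
        # ZCA-whiten across the frame's valid cells: raw gradient histograms
        # are strongly correlated between cells, which would flood the dual
        # softmax with near-duplicate descriptors; whitening spreads cells
        # out so cosine similarity is selective, as learned features are.
        flat = centered[valid]
        cov = flat.T @ flat / max(len(flat) - 1, 1)
        eps = 1e-3 * np.trace(cov) / d + 1e-12
        evals, evecs = np.linalg.eigh(cov + eps * np.eye(d))
        whiten = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
        coarse = _l2_normalize(centered @ whiten)
    else:
        global_feature = np.zeros(d)
        coarse = np.zeros_like(coarse_raw)
    # centre fine descriptors as well: the raw mean-intensity component is
    # shared by every cell and would flatten the refinement softmax
    fine = _l2_normalize(fine_raw - fine_raw.mean(axis=2, keepdims=True))
    return FeaturePyramid(
        coarse=coarse,
        fine=fine,
        coarse_stride=cs,
        fine_stride=fs,
        global_feature=global_feature,
        valid_cells=valid,
        frame_shape=(h, w),
        lum=lum,
        fov_distance=fov_dist,
    )


def extract_features(
    frame: Frame, backend: str | None = None, config: PipelineConfig | None = None
) -> FeaturePyramid:
    """Run the configured backend on one frame."""
    config = config or PipelineConfig()
    return get_backend(backend or config.backend)(frame, config)


# ---------------------------------------------------------------------------
# matching math
# ---------------------------------------------------------------------------

def score_matrix(fa: FeaturePyramid, fb: FeaturePyramid, tau: float = 0.1) -> ScoreMatrix:
    """``S(i, j) = <d_i^A, d_j^B> / tau`` over valid coarse cells."""
    if tau <= 0:
        raise ValueError(f"temperature tau must be positive, got {tau}")
    da, db = fa.valid_descriptors, fb.valid_descriptors
    if da.shape[-1] != db.shape[-1]:
        raise ValueError("descriptor dimensions do not agree")
    return ScoreMatrix(
        values=(da @ db.T) / tau,
        tau=tau,
        cells_a=fa.valid_index,
        cells_b=fb.valid_index,
    )


def confidence_matrix(s: ScoreMatrix) -> ConfidenceMatrix:
    """Dual softmax: row softmax times column softmax, entrywise."""
    v = s.values
    if v.size == 0:
        return ConfidenceMatrix(values=np.zeros_like(v), cells_a=s.cells_a, cells_b=s.cells_b)
    if not np.all(np.isfinite(v)):
        raise ValueError("score matrix must be finite")
    p = softmax(v, axis=1) * softmax(v, axis=0)
    return ConfidenceMatrix(values=p, cells_a=s.cells_a, cells_b=s.cells_b)


def mutual_nearest_matches(
    p: ConfidenceMatrix | np.ndarray, theta_c: float = 0.5
) -> list[tuple[int, int, float]]:
    """Mutual-nearest-neighbour cells of the confidence matrix above ``theta_c``.

    ``(i, j)`` is kept iff j is the argmax of row i, i is the argmax of
    column j, and ``P(i, j) >= theta_c``. Argmax ties break to the lowest
    index, making the result deterministic and one-to-one on both sides.
    """
    if not 0.0 <= theta_c <= 1.0:
        raise ValueError("theta_c must lie in [0, 1]")
    values = p.values if isinstance(p, ConfidenceMatrix) else np.asarray(p)
    if values.size == 0:
        return []
    row_best = values.argmax(axis=1)
    col_best = values.argmax(axis=0)
    rows = np.arange(values.shape[0])
    mutual = col_best[row_best] == rows
    keep = mutual & (values[rows, row_best] >= theta_c)
    return [
        (int(i), int(row_best[i]), float(values[i, row_best[i]]))
        for i in rows[keep]
    ]


def match_descriptor_sets(
    da: np.ndarray, db: np.ndarray, tau: float, theta_c: float
) -> list[tuple[int, int, float]]:
    """MNN matching of two raw descriptor sets (keyframe bookkeeping path)."""
    if len(da) == 0 or len(db) == 0:
        return []
    s = da @ db.T / tau
    p = softmax(s, axis=1) * softmax(s, axis=0)
    return mutual_nearest_matches(ConfidenceMatrix(values=p), theta_c)


# ---------------------------------------------------------------------------
# coarse-to-fine refinement
# ---------------------------------------------------------------------------

def _expect_at(
    fb: FeaturePyramid,
    f_center: np.ndarray,
    frb: int,
    fcb: int,
    half: int,
    fine_tau: float,
) -> tuple[float, float, float]:
    """Softmax-expectation sub-pixel position around fine cell (frb, fcb) of B.

    The expectation window is first recentred on the local similarity peak:
    an expectation over a window centred elsewhere is biased toward that
    centre whenever the true displacement is off-centre. Returns
    ``(x, y, peak weight)`` in pixels.
    """
    hfb, wfb = fb.fine.shape[:2]
    fs = fb.fine_stride
    r0, r1 = max(frb - half, 0), min(frb + half + 1, hfb)
    c0, c1 = max(fcb - half, 0), min(fcb + half + 1, wfb)
    search = fb.fine[r0:r1, c0:c1] @ f_center
    pk = np.unravel_index(int(search.argmax()), search.shape)
    # recentre only on a strict peak: under ties (uniform descriptors) the
    # window must stay where it is so the expectation lands on its centre
    if search[pk] > search[min(frb, hfb - 1) - r0, min(fcb, wfb - 1) - c0] + 1e-12:
        frb, fcb = r0 + pk[0], c0 + pk[1]
    r0, r1 = max(frb - half, 0), min(frb + half + 1, hfb)
    c0, c1 = max(fcb - half, 0), min(fcb + half + 1, wfb)
    scores = fb.fine[r0:r1, c0:c1] @ f_center / fine_tau
    weights = softmax(scores.ravel()).reshape(scores.shape)
    rr = (np.arange(r0, r1) + 0.5) * fs - 0.5
    cc = (np.arange(c0, c1) + 0.5) * fs - 0.5
    yb = float((weights.sum(axis=1) * rr).sum())
    xb = float((weights.sum(axis=0) * cc).sum())
    return xb, yb, float(weights.max())


def guided_matches(
    fa: FeaturePyramid,
    fb: FeaturePyramid,
    h_ab: np.ndarray,
    config: PipelineConfig | None = None,
) -> MatchSet:
    """Geometry-guided dense re-matching given an initial homography A -> B.

    Every valid coarse cell of A is projected into B by ``h_ab`` and refined
    locally with the fine-level expectation; no confidence-matrix pass is
    needed because the geometry already disambiguates the candidates. Used
    as a second pass after an initial RANSAC estimate to beat down the
    noise of purely descriptor-driven matches.
    """
    config = config or PipelineConfig()
    cells = fa.valid_index
    block = fa.coarse_stride // fa.fine_stride
    half = config.refine_window // 2
    fs = fb.fine_stride
    hfb, wfb = fb.fine.shape[:2]
    centers = fa.cell_centers_px(cells)
    hom = np.c_[centers, np.ones(len(centers))] @ h_ab.T
    pred = hom[:, :2] / hom[:, 2:3]
    kpts_a, kpts_b, confs, descr_a, descr_b = [], [], [], [], []
    for (rc, center, p) in zip(cells, centers, pred):
        fcb = int(round((p[0] + 0.5) / fs - 0.5))
        frb = int(round((p[1] + 0.5) / fs - 0.5))
        if not (0 <= frb < hfb and 0 <= fcb < wfb):
            continue
        rb, cb = min(frb // block, fb.valid_cells.shape[0] - 1), min(
            fcb // block, fb.valid_cells.shape[1] - 1
        )
        if not fb.valid_cells[rb, cb]:
            continue
        ra, ca = rc
        f_center = fa.fine[ra * block + block // 2, ca * block + block // 2]
        xb, yb, peak = _expect_at(fb, f_center, frb, fcb, half, config.fine_tau)
        if peak < config.refine_min_peak:
            continue
        kpts_a.append(center)
        kpts_b.append([xb, yb])
        confs.append(peak)
        descr_a.append(fa.coarse[ra, ca])
        descr_b.append(fb.coarse[rb, cb])
    d = fa.coarse.shape[-1]
    return MatchSet(
        kpts_a=np.array(kpts_a, dtype=np.float64).reshape(-1, 2),
        kpts_b=np.array(kpts_b, dtype=np.float64).reshape(-1, 2),
        confidences=np.array(confs, dtype=np.float64),
        descr_a=np.array(descr_a, dtype=np.float64).reshape(-1, d),
        descr_b=np.array(descr_b, dtype=np.float64).reshape(-1, d),
    )


def patch_correspondences(
    fa: FeaturePyramid,
    fb: FeaturePyramid,
    h_ab: np.ndarray,
    config: PipelineConfig | None = None,
) -> MatchSet:
    """Pixel-level correlation correspondences guided by a homography A -> B.

    The fine descriptor grid localizes to about half a fine stride; this last
    hop correlates raw (smoothed, FoV-filled) luminance patches at 1 px steps
    around each cell's predicted position and interpolates the correlation
    peak to sub-pixel, which is what bounds the per-pair registration noise
    and hence the drift of a long composed chain. Requires pyramids built by
    a backend that stores ``lum``.
    """
    config = config or PipelineConfig()
    if fa.lum is None or fb.lum is None:
        return _empty_matchset(fa.coarse.shape[-1])
    rad, srch = config.patch_radius, config.patch_search
    lum_a, lum_b = fa.lum, fb.lum
    ha, wa = lum_a.shape
    hb, wb = lum_b.shape
    cells = fa.valid_index
    centers = fa.cell_centers_px(cells)
    hom = np.c_[centers, np.ones(len(centers))] @ h_ab.T
    pred = hom[:, :2] / hom[:, 2:3]

    ax, ay = np.round(centers[:, 0]).astype(int), np.round(centers[:, 1]).astype(int)
    bx, by = np.round(pred[:, 0]).astype(int), np.round(pred[:, 1]).astype(int)
    m = rad + srch + 1
    keep = (
        (ax >= rad) & (ax < wa - rad) & (ay >= rad) & (ay < ha - rad)
        & (bx >= m) & (bx < wb - m) & (by >= m) & (by < hb - m)
    )
    # keep patches clear of the FoV border: the nearest-value fill beyond it
    # is high-contrast after normalization and stationary in frame
    # coordinates, which would lock the radial displacement component
    if fa.fov_distance is not None:
        keep &= fa.fov_distance[np.clip(ay, 0, ha - 1), np.clip(ax, 0, wa - 1)] > rad + 1
    if fb.fov_distance is not None:
        keep &= fb.fov_distance[np.clip(by, 0, hb - 1), np.clip(bx, 0, wb - 1)] > m
    if not keep.any():
        return _empty_matchset(fa.coarse.shape[-1])
    cells, ax, ay, bx, by = cells[keep], ax[keep], ay[keep], bx[keep], by[keep]
    n = len(ax)
    dr = np.arange(-rad, rad + 1)
    py_, px_ = np.meshgrid(dr, dr, indexing="ij")
    # orthonormal [constant, x, y] basis: projecting it out of every patch
    # removes the local mean and linear shading. Smooth shading (residual
    # vignette, turbidity veil) is stationary in frame coordinates and
    # would otherwise bias each correlation peak toward zero displacement
    # along its gradient — which integrates into a systematic scale drift.
    basis = np.stack(
        [np.ones(py_.size), px_.ravel(), py_.ravel()], axis=1
    )
    q, _ = np.linalg.qr(basis)

    def _flatten(patches: np.ndarray) -> np.ndarray:
        return patches - (patches @ q) @ q.T

    pa = lum_a[ay[:, None, None] + py_, ax[:, None, None] + px_].reshape(n, -1)
    pa = _flatten(pa)
    na = np.linalg.norm(pa, axis=1)

    side = 2 * srch + 1
    scores = np.empty((n, side, side))
    for i, dy in enumerate(range(-srch, srch + 1)):
        for j, dx in enumerate(range(-srch, srch + 1)):
            pb = lum_b[
                (by + dy)[:, None, None] + py_, (bx + dx)[:, None, None] + px_
            ].reshape(n, -1)
            pb = _flatten(pb)
            nb = np.linalg.norm(pb, axis=1)
            scores[:, i, j] = (pa * pb).sum(axis=1) / (na * nb + 1e-12)

    flat = scores.reshape(n, -1)
    pk = flat.argmax(axis=1)
    pr, pc = np.divmod(pk, side)
    good = (
        (flat[np.arange(n), pk] >= config.patch_min_corr)
        & (na > 1e-6)
        & (pr > 0) & (pr < side - 1) & (pc > 0) & (pc < side - 1)
    )

    def _parab(v0, v1, v2):
        den = v0 - 2 * v1 + v2
        out = np.zeros_like(v1)
        np.divide(0.5 * (v0 - v2), den, out=out, where=np.abs(den) > 1e-12)
        return np.clip(out, -0.5, 0.5)

    idx = np.arange(n)
    center = scores[idx, pr, pc]
    dy_sub = _parab(
        scores[idx, np.maximum(pr - 1, 0), pc], center,
        scores[idx, np.minimum(pr + 1, side - 1), pc],
    )
    dx_sub = _parab(
        scores[idx, pr, np.maximum(pc - 1, 0)], center,
        scores[idx, pr, np.minimum(pc + 1, side - 1)],
    )
    kx = bx + (pc - srch) + dx_sub
    ky = by + (pr - srch) + dy_sub
    d = fa.coarse.shape[-1]
    descr_a = fa.coarse[cells[good, 0], cells[good, 1]]
    return MatchSet(
        kpts_a=np.c_[ax, ay][good].astype(np.float64),
        kpts_b=np.c_[kx, ky][good],
        confidences=flat[np.arange(n), pk][good],
        descr_a=descr_a,
        descr_b=descr_a.copy(),
    )


def _empty_matchset(d: int) -> MatchSet:
    return MatchSet(
        kpts_a=np.empty((0, 2)),
        kpts_b=np.empty((0, 2)),
        confidences=np.empty(0),
        descr_a=np.empty((0, d)),
        descr_b=np.empty((0, d)),
    )


def refine_matches(
    coarse_matches: list[tuple[int, int, float]],
    fa: FeaturePyramid,
    fb: FeaturePyramid,
    window: int = 5,
    fine_tau: float = 0.02,
    cells_a: np.ndarray | None = None,
    cells_b: np.ndarray | None = None,
    min_peak: float = 0.0,
) -> MatchSet:
    """Sub-pixel refinement: expectation over a local fine-cell similarity softmax.

    The A-side keypoint is pinned to the coarse cell centre; the B-side
    keypoint is the probability-weighted centroid of fine-cell centres in a
    ``window``x``window`` neighbourhood, with weights
    ``softmax(<f_A, f_B_k> / fine_tau)``. Windows are clipped at the fine-grid
    border and the weights renormalized.

    Matches whose weight distribution is nearly flat carry no sub-cell
    information (locally textureless cells); their expectation collapses to
    the window centre regardless of the true displacement, which would bias
    the downstream homography toward zero motion. ``min_peak`` drops matches
    whose maximum refinement weight falls below it.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("refinement window must be odd and >= 3")
    cells_a = fa.valid_index if cells_a is None else cells_a
    cells_b = fb.valid_index if cells_b is None else cells_b
    block = fa.coarse_stride // fa.fine_stride
    half = window // 2

    kpts_a, kpts_b, confs, descr_a, descr_b = [], [], [], [], []
    for ia, ib, conf in coarse_matches:
        ra, ca = cells_a[ia]
        rb, cb = cells_b[ib]
        fra, fca = ra * block + block // 2, ca * block + block // 2
        frb, fcb = rb * block + block // 2, cb * block + block // 2
        f_center = fa.fine[fra, fca]
        xb, yb, peak = _expect_at(fb, f_center, frb, fcb, half, fine_tau)
        if peak < min_peak:
            continue
        kpts_a.append([(fca + 0.5) * fa.fine_stride - 0.5, (fra + 0.5) * fa.fine_stride - 0.5])
        kpts_b.append([xb, yb])
        confs.append(conf)
        descr_a.append(fa.coarse[ra, ca])
        descr_b.append(fb.coarse[rb, cb])
    d = fa.coarse.shape[-1]
    return MatchSet(
        kpts_a=np.array(kpts_a, dtype=np.float64).reshape(-1, 2),
        kpts_b=np.array(kpts_b, dtype=np.float64).reshape(-1, 2),
        confidences=np.array(confs, dtype=np.float64),
        descr_a=np.array(descr_a, dtype=np.float64).reshape(-1, d),
        descr_b=np.array(descr_b, dtype=np.float64).reshape(-1, d),
    )


def match_pyramids(
    fa: FeaturePyramid, fb: FeaturePyramid, config: PipelineConfig | None = None
) -> MatchSet:
    """score -> dual softmax -> MNN(theta_c) -> coarse-to-fine refinement."""
    config = config or PipelineConfig()
    s = score_matrix(fa, fb, tau=config.tau)
    p = confidence_matrix(s)
    coarse = mutual_nearest_matches(p, theta_c=config.theta_c)
    return refine_matches(
        coarse,
        fa,
        fb,
        window=config.refine_window,
        fine_tau=config.fine_tau,
        cells_a=s.cells_a,
        cells_b=s.cells_b,
        min_peak=config.refine_min_peak,
    )


def match_pair(
    frame_a: Frame, frame_b: Frame, config: PipelineConfig | None = None
) -> MatchSet:
    """Full matching pipeline for a frame pair (may return few or no matches;
    the caller decides what counts as tracking loss)."""
    config = config or PipelineConfig()
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have identical size")
    fa = extract_features(frame_a, config=config)
    fb = extract_features(frame_b, config=config)
    return match_pyramids(fa, fb, config)
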