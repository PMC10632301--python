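"""Homography estimation, global composition and exposure-blended panoramas.

Matched keypoints from consecutive frames give a relative projective
homography (robust RANSAC, least-squares refit on the inliers). Relatives
are chained into global homographies mapping every frame into the anchor
frame's coordinates, and each frame is warped onto an auto-growing canvas
with per-pixel blend weights. Endoscopic vignetting (bright centre, dark
border) would otherwise leave dark circular seams at frame borders, so
blending uses exposure-fusion style weights: local contrast x
well-exposedness x a radial taper that falls to zero at the FoV border.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, laplace
from skimage.measure import ransac as _sk_ransac
from skimage.transform import AffineTransform, ProjectiveTransform, warp

from .config import PipelineConfig
from .features import FeaturePyramid, MatchSet, guided_matches, patch_correspondences
from .frames import Frame

__all__ = [
    "Homography",
    "MosaicCanvas",
    "FrameRecord",
    "estimate_homography",
    "compose_global",
    "corner_displacement",
    "mean_corner_error",
    "exposure_weights",
    "warp_frame",
    "build_mosaic",
]


def normalize_h(matrix: np.ndarray) -> np.ndarray:
    """Scale a 3x3 homography so its bottom-right entry is exactly 1."""
    m = np.asarray(matrix, dtype=np.float64)
    if abs(m[2, 2]) < 1e-12:
        raise ValueError("cannot normalize homography with zero bottom-right entry")
    return m / m[2, 2]


def apply_h(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a homography to (N, 2) xy points."""
    pts = np.atleast_2d(points)
    hom = np.c_[pts, np.ones(len(pts))] @ matrix.T
    return hom[:, :2] / hom[:, 2:3]


@dataclass
class Homography:
    """An estimated 3x3 projective transform with its RANSAC support."""

    matrix: np.ndarray
    inlier_count: int = 0
    inlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = normalize_h(self.matrix)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(matrix=np.eye(3), inlier_count=0, inlier_fraction=1.0)

    def inverse(self) -> "Homography":
        return Homography(
            matrix=np.linalg.inv(self.matrix),
            inlier_count=self.inlier_count,
            inlier_fraction=self.inlier_fraction,
        )

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(matrix=self.matrix @ other.matrix)


def _valid_matrix(m: np.ndarray) -> bool:
    return (
        np.all(np.isfinite(m))
        and abs(m[2, 2]) > 1e-12
        and abs(np.linalg.det(m)) > 1e-10
        and abs(np.linalg.det(m[:2, :2])) > 1e-10
    )


def _fit_transform(model_cls, src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    """Least-squares transform fit; ``None`` on degenerate input."""
    if hasattr(model_cls, "from_estimate"):
        tform = model_cls.from_estimate(src, dst)
        return tform.params if tform else None
    tform = model_cls()
    return tform.params if tform.estimate(src, dst) else None


def estimate_homography(
    matches: MatchSet, config: PipelineConfig | None = None
) -> Homography | None:
    """Robust projective fit of ``kpts_a -> kpts_b``; ``None`` signals failure.

    Failure (too few matches, RANSAC failure, or a degenerate/singular
    estimate) is a return value rather than an exception because it drives
    the tracking-loss logic downstream.
    """
    config = config or PipelineConfig()
    src, dst = matches.kpts_a, matches.kpts_b
    n = len(src)
    if n < 4:
        return None
    model_cls = AffineTransform if config.affine_fallback else ProjectiveTransform
    if n == 4:
        m = _fit_transform(ProjectiveTransform, src, dst)
        if m is None or not _valid_matrix(m):
            return None
        return Homography(matrix=m, inlier_count=4, inlier_fraction=1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # "no inliers" is a result, not a warning
            model, inliers = _sk_ransac(
                (src, dst),
                model_cls,
                min_samples=4,
                residual_threshold=config.ransac_threshold,
                max_trials=config.ransac_max_iters,
                stop_probability=config.ransac_confidence,
                rng=config.ransac_seed,
            )
    except Exception:  # degenerate sample sets raise inside skimage
        return None
    if model is None or inliers is None or inliers.sum() < 4:
        return None
    m = _fit_transform(model_cls, src[inliers], dst[inliers])
    if m is None or not _valid_matrix(m):
        return None
    return Homography(
        matrix=m,
        inlier_count=int(inliers.sum()),
        inlier_fraction=float(inliers.mean()),
    )


def _refine_from(
    seed: Homography, fa: FeaturePyramid, fb: FeaturePyramid, config: PipelineConfig
) -> tuple[Homography, bool]:
    """Guided re-matching + pixel-level patch correlation around a seed estimate.

    Returns ``(estimate, confirmed)``. Only the patch-correlation stage is
    discriminative: guided matches are constructed around the seed's own
    prediction, so even pure noise yields a spurious consensus there. An
    estimate that the patch stage never confirmed must not be trusted.
    """
    best = seed
    for _ in range(config.guided_iters):
        guided = guided_matches(fa, fb, best.matrix, config)
        h1 = estimate_homography(guided, config)
        if h1 is None or h1.inlier_count < best.inlier_count:
            break
        best = h1
    confirmed = False
    for _ in range(config.patch_iters):
        pc = patch_correspondences(fa, fb, best.matrix, config)
        if len(pc) < config.min_inliers:
            break
        h2 = estimate_homography(pc, config)
        if h2 is None or h2.inlier_count < config.min_inliers:
            break
        best, confirmed = h2, True
    return best, confirmed


def estimate_homography_refined(
    fa: FeaturePyramid,
    fb: FeaturePyramid,
    matches: MatchSet,
    config: PipelineConfig | None = None,
    h_init: np.ndarray | None = None,
) -> Homography | None:
    """Multi-stage estimate of the A -> B homography.

    A RANSAC fit on the descriptor-driven matches initializes the geometry;
    guided re-matching (every valid cell of A locally refined at its
    predicted position in B) then supplies a larger, far less noisy
    correspondence set, and a final pixel-level patch-correlation pass
    bounds the per-pair noise well below the fine-grid stride.

    ``h_init`` (typically the previous accepted relative homography — a
    constant-motion prior) seeds the same refinement chain whenever the
    descriptor-driven fit fails or is implausible; grid descriptors lose
    discriminability when the displacement sits near half a coarse cell,
    and the prior carries tracking through those phases. The final estimate
    must still earn its inliers from actual correlation peaks, so occluded
    or unrelated frames fail regardless of the prior.
    """
    config = config or PipelineConfig()
    h0 = estimate_homography(matches, config)
    bound = config.max_corner_disp_frac * fa.frame_shape[1]
    candidates: list[Homography] = []
    if h0 is not None:
        candidates.append(h0)
    h0_weak = (
        h0 is None
        or h0.inlier_count < config.min_inliers
        or corner_displacement(h0.matrix, fa.frame_shape) > bound
    )
    if h_init is not None and h0_weak:
        candidates.append(Homography(matrix=h_init))
    best: Homography | None = None
    require_patch = fa.lum is not None and fb.lum is not None
    for seed in candidates:
        refined, confirmed = _refine_from(seed, fa, fb, config)
        if require_patch and not confirmed:
            continue
        if best is None or refined.inlier_count > best.inlier_count:
            best = refined
    return best


def compose_global(
    relative: list[Homography | None], anchor: int = 0
) -> list[Homography | None]:
    """Chain relative homographies into per-frame global (frame -> anchor) maps.

    ``relative[i]`` maps frame ``i+1`` coordinates into frame ``i``
    coordinates; there are ``n_frames - 1`` of them. A failed (``None``)
    relative breaks the chain: every frame beyond it is unregistered
    (``None``) until a recovery step re-registers it.
    """
    n = len(relative) + 1
    if not 0 <= anchor < n:
        raise ValueError(f"anchor {anchor} outside frame range")
    out: list[Homography | None] = [None] * n
    out[anchor] = Homography.identity()
    for i in range(anchor + 1, n):
        prev, rel = out[i - 1], relative[i - 1]
        out[i] = None if (prev is None or rel is None) else prev @ rel
    for i in range(anchor - 1, -1, -1):
        nxt, rel = out[i + 1], relative[i]
        out[i] = None if (nxt is None or rel is None) else nxt @ rel.inverse()
    return out


def corner_displacement(matrix: np.ndarray, frame_shape: tuple[int, int]) -> float:
    """Maximum displacement of the four frame corners under a transform (px)."""
    h, w = frame_shape
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    return float(np.linalg.norm(apply_h(matrix, corners) - corners, axis=1).max())


def mean_corner_error(
    g_est: np.ndarray, g_true: np.ndarray, frame_shape: tuple[int, int]
) -> float:
    """Mean distance between frame corners mapped by two homographies (px)."""
    h, w = frame_shape
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    return float(
        np.linalg.norm(apply_h(g_est, corners) - apply_h(g_true, corners), axis=1).mean()
    )


# ---------------------------------------------------------------------------
# canvas and blending
# ---------------------------------------------------------------------------

@dataclass
class FrameRecord:
    """Per-frame tracking outcome recorded on the canvas."""

    index: int
    status: str  # tracked | lost | recovered
    global_h: Homography | None
    n_matches: int = 0
    n_inliers: int = 0
    reloc_keyframe: int | None = None


@dataclass
class MosaicCanvas:
    """Growing panorama: weighted RGB accumulation plus per-frame statuses.

    Canvas pixel (x, y) corresponds to anchor-frame coordinates
    ``(x + origin_offset[0], y + origin_offset[1])``; the rendered panorama
    is ``accum / weight`` wherever ``weight > 0``.
    """

    accum: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 3)))
    weight: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    origin_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    frame_status: list[FrameRecord] = field(default_factory=list)

    def ensure_bounds(self, x0: float, y0: float, x1: float, y1: float) -> None:
        """Grow the canvas so anchor-coordinate box [x0,x1]x[y0,y1] fits."""
        pad = 2
        x0, y0 = np.floor([x0 - pad, y0 - pad]).astype(int)
        x1, y1 = np.ceil([x1 + pad, y1 + pad]).astype(int)
        if self.weight.size == 0:
            self.origin_offset = np.array([x0, y0], dtype=float)
            h, w = y1 - y0 + 1, x1 - x0 + 1
            self.accum = np.zeros((h, w, 3))
            self.weight = np.zeros((h, w))
            return
        ox, oy = self.origin_offset
        h, w = self.weight.shape
        nx0, ny0 = min(x0, int(ox)), min(y0, int(oy))
        nx1, ny1 = max(x1, int(ox) + w - 1), max(y1, int(oy) + h - 1)
        if (nx0, ny0) == (int(ox), int(oy)) and (nx1 - nx0 + 1, ny1 - ny0 + 1) == (w, h):
            return
        na = np.zeros((ny1 - ny0 + 1, nx1 - nx0 + 1, 3))
        nw = np.zeros(na.shape[:2])
        dy, dx = int(oy) - ny0, int(ox) - nx0
        na[dy : dy + h, dx : dx + w] = self.accum
        nw[dy : dy + h, dx : dx + w] = self.weight
        self.accum, self.weight = na, nw
        self.origin_offset = np.array([nx0, ny0], dtype=float)

    def render(self) -> np.ndarray:
        """Panorama as RGB in [0, 1]; zero where nothing was accumulated."""
        out = np.zeros_like(self.accum)
        np.divide(self.accum, self.weight[..., None], out=out, where=self.weight[..., None] > 0)
        return np.clip(out, 0.0, 1.0)

    @property
    def coverage(self) -> np.ndarray:
        return self.weight > 0


def exposure_weights(frame: Frame, config: PipelineConfig | None = None) -> np.ndarray:
    """Per-pixel blend weights: contrast x well-exposedness x radial taper.

    Well-exposedness is a Gaussian of intensity around 0.5 (sigma 0.2), so
    the over-lit centre and under-lit border of an endoscopic frame both
    count less than the well-exposed mid annulus; the taper zeroes weights
    exactly at the FoV border so frame edges never leave seams.
    """
    lum = frame.luminance
    contrast = gaussian_filter(np.abs(laplace(lum)), 2.0, mode="nearest")
    cmax = contrast.max()
    contrast = contrast / cmax if cmax > 0 else contrast
    well_exposed = np.exp(-((lum - 0.5) ** 2) / (2 * 0.2**2))
    dist = distance_transform_edt(frame.mask)
    taper_width = 0.25 * (min(frame.shape) / 2.0)
    taper = np.clip(dist / taper_width, 0.0, 1.0)
    weights = (0.05 + 0.95 * contrast) * well_exposed * taper
    return np.where(frame.mask, weights, 0.0)


def warp_frame(
    frame: Frame,
    g: Homography,
    canvas: MosaicCanvas,
    blend_weights: np.ndarray | None = None,
) -> MosaicCanvas:
    """Warp one frame into the canvas and accumulate it with its blend weights."""
    w = exposure_weights(frame) if blend_weights is None else blend_weights
    w = np.where(frame.mask, w, 0.0)
    corners = apply_h(g.matrix, frame.corners())
    canvas.ensure_bounds(
        corners[:, 0].min(), corners[:, 1].min(), corners[:, 0].max(), corners[:, 1].max()
    )
    shift = np.eye(3)
    shift[:2, 2] = canvas.origin_offset
    inv_map = np.linalg.inv(g.matrix) @ shift  # canvas xy -> frame xy
    src = np.concatenate([frame.pixels * w[..., None], w[..., None]], axis=2)
    warped = warp(
        src,
        ProjectiveTransform(matrix=inv_map),
        output_shape=canvas.weight.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    canvas.accum += warped[..., :3]
    canvas.weight += np.maximum(warped[..., 3], 0.0)
    return canvas


def build_mosaic(
    frames: list[Frame],
    config: PipelineConfig | None = None,
    recovery: bool = False,
    render: bool = True,
) -> MosaicCanvas:
    """Sequential mosaicking over a frame list; see :mod:`fetomosaic.pipeline`."""
    from .pipeline import run_sequence

    return run_sequence(frames, config=config, recovery=recovery, render=render).canvas
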