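"""Registration quality metrics: SSIM, k-frame SSIM, recovery success rate.

Consecutive fetoscopic frames barely move, so plain pairwise SSIM saturates;
warping frame i onto frame i+k (default k=5) through the estimated global
homographies makes the measure sensitive to registration drift
(``SSIM_5``). Recovery robustness is summarized by the success rate,
``100 x #correct / #total`` over relocalization trials; on synthetic
sequences a relocalization counts as correct when the mean corner
reprojection error of the recovered global homography against the
simulator's ground truth is below 5 px.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.ndimage import binary_erosion
from skimage.metrics import structural_similarity
from skimage.transform import ProjectiveTransform, warp

from .config import PipelineConfig
from .frames import Frame
from .mosaic import Homography, mean_corner_error, normalize_h
from .pipeline import run_sequence
from .recovery import relocalize
from .synthetic import SyntheticSequence

__all__ = [
    "EvalReport",
    "EmptyOverlapError",
    "DistortionParams",
    "ssim",
    "ssim_k",
    "success_rate",
    "gt_globals",
    "drift_px",
    "recovery_trial_harness",
    "wilcoxon_ssim",
]

_SSIM_PAD = 5  # border radius of the 11x11 Gaussian SSIM window


class EmptyOverlapError(ValueError):
    """SSIM is undefined: the masked overlap region is empty."""


def ssim(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Masked structural similarity on the luminance channel.

    Canonical parameters: 11x11 Gaussian window (sigma 1.5), C1=(0.01 L)^2,
    C2=(0.03 L)^2 with L=1. The local SSIM map is averaged over the mask
    eroded by the window radius, so border effects never leak in.
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if a.ndim == 3:
        a = a @ np.array([0.299, 0.587, 0.114])
        b = b @ np.array([0.299, 0.587, 0.114])
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = binary_erosion(mask, iterations=_SSIM_PAD) if mask.any() else mask
    if not mask.any():
        raise EmptyOverlapError("empty mask after border erosion")
    _, smap = structural_similarity(
        a,
        b,
        data_range=1.0,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        full=True,
    )
    return float(smap[mask].mean())


def ssim_k(
    frames: list[Frame],
    globals_: list[Homography | np.ndarray | None],
    k: int = 5,
    config: PipelineConfig | None = None,
) -> tuple[list[float], list[tuple[int, str]]]:
    """k-frame SSIM under the estimated registration.

    For every i, frame i is warped into frame i+k's coordinates via
    ``inv(G_{i+k}) @ G_i`` and compared on the intersection of the two FoV
    masks. Pairs spanning an unregistered (lost) frame, or whose overlap is
    below ``min_overlap_px``, are skipped and reported alongside the values.
    """
    config = config or PipelineConfig()
    mats = [g.matrix if isinstance(g, Homography) else g for g in globals_]
    values: list[float] = []
    skipped: list[tuple[int, str]] = []
    for i in range(len(frames) - k):
        gi, gk = mats[i], mats[i + k]
        if gi is None or gk is None:
            skipped.append((i, "lost frame"))
            continue
        if k == 0:
            values.append(ssim(frames[i].pixels, frames[i].pixels, frames[i].mask))
            continue
        t = normalize_h(np.linalg.solve(gk, gi))  # frame i -> frame i+k
        tform = ProjectiveTransform(matrix=np.linalg.inv(t))
        tgt = frames[i + k]
        warped = warp(frames[i].pixels, tform, output_shape=tgt.pixels.shape[:2],
                      order=1, mode="constant", cval=0.0)
        wmask = warp(frames[i].mask.astype(float), tform,
                     output_shape=tgt.pixels.shape[:2], order=0, cval=0.0) > 0.5
        overlap = wmask & tgt.mask
        if overlap.sum() < config.min_overlap_px:
            skipped.append((i, f"overlap {int(overlap.sum())} px below minimum"))
            continue
        try:
            values.append(ssim(warped, tgt.pixels, overlap))
        except EmptyOverlapError:
            skipped.append((i, "empty overlap after erosion"))
    return values, skipped


def success_rate(trials: list[bool]) -> float:
    """``100 x #correct / #total`` over recovery trials."""
    if len(trials) == 0:
        raise ValueError("success_rate needs at least one trial")
    return 100.0 * sum(bool(t) for t in trials) / len(trials)


def gt_globals(seq: SyntheticSequence, anchor: int = 0) -> list[np.ndarray]:
    """Ground-truth global homographies (frame -> anchor frame) from the simulator."""
    h_anchor = seq.trajectory.homographies_gt[anchor]
    return [
        normalize_h(np.linalg.solve(h_anchor, h)) for h in seq.trajectory.homographies_gt
    ]


def drift_px(
    globals_est: list[Homography | None],
    seq: SyntheticSequence,
    anchor: int = 0,
) -> list[float]:
    """Per-frame mean corner reprojection error vs ground truth (registered frames)."""
    gts = gt_globals(seq, anchor)
    shape = seq.trajectory.frame_shape
    return [
        mean_corner_error(g.matrix, gt, shape)
        for g, gt in zip(globals_est, gts)
        if g is not None
    ]


@dataclass
class EvalReport:
    """Aggregate metrics of one mosaicking / recovery evaluation run."""

    ssim5_values: list[float] = field(default_factory=list)
    ssim5_mean: float = float("nan")
    ssim5_sd: float = float("nan")
    success_rate: float = float("nan")
    drift_px: list[float] = field(default_factory=list)
    n_lost: int = 0
    n_recovered: int = 0
    skipped_pairs: list[tuple[int, str]] = field(default_factory=list)

    @classmethod
    def from_values(cls, ssim5_values: list[float], **kw) -> "EvalReport":
        vals = list(ssim5_values)
        return cls(
            ssim5_values=vals,
            ssim5_mean=float(np.mean(vals)) if vals else float("nan"),
            ssim5_sd=float(np.std(vals)) if vals else float("nan"),
            **kw,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))

    def summary(self) -> str:
        lines = [
            f"SSIM_5: mean {self.ssim5_mean:.4f} sd {self.ssim5_sd:.4f} "
            f"over {len(self.ssim5_values)} pairs ({len(self.skipped_pairs)} skipped)",
            f"frames lost {self.n_lost}, recovered {self.n_recovered}",
        ]
        if np.isfinite(self.success_rate):
            lines.append(f"recovery success rate: {self.success_rate:.2f}%")
        if self.drift_px:
            lines.append(f"mean drift vs ground truth: {np.mean(self.drift_px):.3f} px")
        return "\n".join(lines)


@dataclass
class DistortionParams:
    """Affine distortion + corruption applied to relocalization trial frames."""

    max_rotation_deg: float = 10.0
    scale_low: float = 0.9
    scale_high: float = 1.1
    noise_sigma: float = 0.02

    @classmethod
    def none(cls) -> "DistortionParams":
        return cls(max_rotation_deg=0.0, scale_low=1.0, scale_high=1.0, noise_sigma=0.0)


def _distort_frame(
    frame: Frame, params: DistortionParams, rng: np.random.Generator
) -> tuple[Frame, np.ndarray]:
    """Affinely distorted + corrupted copy; returns (copy, A) with
    ``copy(x) = frame(A x)`` so the copy's true frame->texture map is
    ``H_gt @ A``."""
    h, w = frame.shape
    angle = np.deg2rad(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg))
    scale = rng.uniform(params.scale_low, params.scale_high)
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    ca, sa = np.cos(angle), np.sin(angle)
    lin = scale * np.array([[ca, -sa], [sa, ca]])
    a = np.eye(3)
    a[:2, :2] = lin
    a[:2, 2] = c - lin @ c
    pixels = warp(frame.pixels, ProjectiveTransform(matrix=a), order=1, cval=0.0)
    if params.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, params.noise_sigma, pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    mask = warp(frame.mask.astype(float), ProjectiveTransform(matrix=a),
                order=0, cval=0.0) > 0.5
    return Frame(pixels=pixels, index=frame.index, mask=mask), a


def recovery_trial_harness(
    sequence: SyntheticSequence,
    n_trials: int = 20,
    distortion_params: DistortionParams | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> EvalReport:
    """Seeded relocalization benchmark on a synthetic sequence.

    The pipeline first runs in recovery mode to build the keyframe store.
    Each trial draws a random registered, non-keyframe, non-occluded frame
    and relocalizes (a) the frame itself and (b) an affinely distorted +
    noise-corrupted copy; a recovery is correct when the recovered global
    homography lands within 5 px mean corner error of the simulator's ground
    truth. ``n_trials`` counts individual recoveries.
    """
    from .features import extract_features

    config = config or PipelineConfig()
    params = distortion_params or DistortionParams()
    rng = np.random.default_rng(seed)
    result = run_sequence(sequence.frames, config=config, recovery=True)
    store = result.store
    gts = gt_globals(sequence)
    shape = sequence.trajectory.frame_shape

    kf_set = set(store.indices())
    occluded = sequence.occluded_indices()
    eligible = [
        i
        for i, s in enumerate(result.statuses)
        if s != "lost" and i not in kf_set and i not in occluded
    ]
    if not eligible:
        raise ValueError("sequence has no eligible non-keyframe frames")

    outcomes: list[bool] = []
    while len(outcomes) < n_trials:
        i = int(rng.choice(eligible))
        variants: list[tuple[Frame, np.ndarray]] = [(sequence.frames[i], np.eye(3))]
        if len(outcomes) + 1 < n_trials:
            variants.append(_distort_frame(sequence.frames[i], params, rng))
        for trial_frame, a in variants:
            pyramid = extract_features(trial_frame, config=config)
            g_rec, _ = relocalize(pyramid, trial_frame, store, config)
            g_true = gts[i] @ a
            ok = (
                g_rec is not None
                and mean_corner_error(g_rec.matrix, g_true, shape) < 5.0
            )
            outcomes.append(bool(ok))
            if len(outcomes) >= n_trials:
                break

    ssim5, skipped = ssim_k(sequence.frames, result.globals_, k=config.ssim_k, config=config)
    return EvalReport.from_values(
        ssim5,
        success_rate=success_rate(outcomes),
        drift_px=drift_px(result.globals_, sequence),
        n_lost=result.n_lost,
        n_recovered=result.n_recovered,
        skipped_pairs=skipped,
    )


def wilcoxon_ssim(values_a: list[float], values_b: list[float]):
    """Convenience paired Wilcoxon signed-rank test between two SSIM_5 lists."""
    return stats.wilcoxon(values_a, values_b)
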