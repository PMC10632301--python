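"""Keyframe extraction and relocalization after tracking loss.

While tracking runs, a sparse store of keyframes summarizes the visited
placenta: the first frame is always a keyframe, and a new one is added
whenever the fraction of the last keyframe's descriptors still matched in
the current frame falls below ``t_discard`` (default 10%, i.e. the views
have almost stopped overlapping). Consecutive keyframes whose pooled global
features are closer than ``t_kf`` are redundant and deduplicated, keeping
the earlier one.

After a loss (occlusion, fast motion), each incoming frame is ranked against
the store by global-feature Euclidean distance; the top candidates are
re-matched in full, and the candidate whose registration gathers the most
confirmed inliers re-registers the frame on the panorama:
``G_lost = G_keyframe @ H_(lost -> keyframe)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import PipelineConfig
from .features import FeaturePyramid, match_descriptor_sets, match_pyramids
from .frames import Frame
from .mosaic import Homography, MosaicCanvas, estimate_homography_refined

__all__ = [
    "Keyframe",
    "KeyframeStore",
    "update_keyframes",
    "dedupe_keyframes",
    "relocalize",
    "track_with_recovery",
]


@dataclass
class Keyframe:
    """A stored reference view: features, keypoints and its global registration."""

    frame_index: int
    pyramid: FeaturePyramid
    global_homography: Homography

    @property
    def descriptors(self) -> np.ndarray:
        return self.pyramid.valid_descriptors

    @property
    def keypoints(self) -> np.ndarray:
        return self.pyramid.cell_centers_px(self.pyramid.valid_index)

    @property
    def global_feature(self) -> np.ndarray:
        return self.pyramid.global_feature


@dataclass
class KeyframeStore:
    keyframes: list[Keyframe] = field(default_factory=list)
    t_discard: float = 0.10
    t_kf: float = 1300.0

    def __len__(self) -> int:
        return len(self.keyframes)

    def indices(self) -> list[int]:
        return [kf.frame_index for kf in self.keyframes]

    def feature_distances(self, feature: np.ndarray) -> np.ndarray:
        if not self.keyframes:
            return np.empty(0)
        feats = np.stack([kf.global_feature for kf in self.keyframes])
        return np.linalg.norm(feats - feature, axis=1)


def match_fraction(
    keyframe: Keyframe, pyramid: FeaturePyramid, config: PipelineConfig
) -> float:
    """Fraction of the keyframe's descriptors MNN-matched in the new frame."""
    n_ref = len(keyframe.descriptors)
    if n_ref == 0:
        return 0.0
    matches = match_descriptor_sets(
        keyframe.descriptors, pyramid.valid_descriptors, config.tau, config.theta_c
    )
    return len(matches) / n_ref


def update_keyframes(
    store: KeyframeStore,
    current_pyramid: FeaturePyramid,
    current_index: int,
    current_global: Homography,
    config: PipelineConfig | None = None,
) -> KeyframeStore:
    """Apply the keyframe rule to a tracked frame; returns the (mutated) store.

    An empty store adopts the frame as the first keyframe. Otherwise the
    frame becomes a keyframe only if fewer than ``t_discard`` of the last
    keyframe's descriptors still match it, after which near-duplicate
    consecutive keyframes are pruned.
    """
    config = config or PipelineConfig()
    candidate = Keyframe(
        frame_index=current_index,
        pyramid=current_pyramid,
        global_homography=current_global,
    )
    if not store.keyframes:
        store.keyframes.append(candidate)
        return store
    fraction = match_fraction(store.keyframes[-1], current_pyramid, config)
    if fraction < store.t_discard:
        store.keyframes.append(candidate)
        dedupe_keyframes(store)
    return store


def dedupe_keyframes(store: KeyframeStore) -> KeyframeStore:
    """Drop the later of any consecutive keyframe pair closer than ``t_kf``.

    The scan repeats until stable, so a run of mutually close keyframes
    collapses onto its earliest member.
    """
    changed = True
    while changed:
        changed = False
        for i in range(len(store.keyframes) - 1):
            a, b = store.keyframes[i], store.keyframes[i + 1]
            if np.linalg.norm(a.global_feature - b.global_feature) < store.t_kf:
                del store.keyframes[i + 1]
                changed = True
                break
    return store


def relocalize(
    lost_frame_pyramid: FeaturePyramid,
    lost_frame: Frame,
    store: KeyframeStore,
    config: PipelineConfig | None = None,
) -> tuple[Homography | None, int]:
    """Re-register a lost frame against the nearest keyframes.

    Keyframes are ranked by ascending global-feature distance; each of the
    top ``reloc_k`` candidates is fully re-matched and the candidate whose
    registration gathers the most inliers (at least ``reloc_min_inliers``)
    wins. The pooled global feature ranks views only coarsely, so the
    geometric verification — not the ranking — makes the final choice; a
    marginally-supported registration to a nearer-ranked keyframe must not
    outrank an overwhelmingly supported one. Returns ``(global homography,
    keyframe index)`` or ``(None, -1)`` on failure — the caller simply
    tries again with the next frame.
    """
    config = config or PipelineConfig()
    if not store.keyframes:
        return None, -1
    # a lost frame may come back rotated/scaled or otherwise distorted;
    # a lower confidence gate feeds the robust fit more candidates and the
    # geometric verification supplies the selectivity
    config = replace(config, theta_c=config.reloc_theta_c)
    dists = store.feature_distances(lost_frame_pyramid.global_feature)
    order = np.argsort(dists, kind="stable")[: config.reloc_k]
    best: Homography | None = None
    best_kf = -1
    for idx in order:
        kf = store.keyframes[int(idx)]
        matches = match_pyramids(lost_frame_pyramid, kf.pyramid, config)
        # maps lost frame -> keyframe
        h = estimate_homography_refined(lost_frame_pyramid, kf.pyramid, matches, config)
        if h is None or h.inlier_count < config.reloc_min_inliers:
            continue
        if best is None or h.inlier_count > best.inlier_count:
            best = kf.global_homography @ h
            best.inlier_count = h.inlier_count
            best_kf = kf.frame_index
    return (best, best_kf) if best is not None else (None, -1)


def track_with_recovery(
    frames: list[Frame],
    config: PipelineConfig | None = None,
    render: bool = True,
) -> MosaicCanvas:
    """Mosaicking with keyframe maintenance and post-loss relocalization."""
    from .pipeline import run_sequence

    return run_sequence(frames, config=config, recovery=True, render=render).canvas
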