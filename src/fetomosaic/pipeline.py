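"""The sequential tracking loop shared by plain mosaicking and recovery mode.

Frame i is matched against the last successfully registered frame; the
relative homography passes a tracking-loss gate (estimation success, a
minimum inlier count, and a plausibility bound on corner displacement)
before being chained into the global registration and warped onto the
canvas. In recovery mode a keyframe store is maintained while tracked, and
every frame arriving after a loss goes through relocalization until one
re-registers, from which normal sequential tracking resumes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .features import FeaturePyramid, extract_features, match_pyramids
from .frames import Frame
from .mosaic import (
    FrameRecord,
    Homography,
    MosaicCanvas,
    corner_displacement,
    estimate_homography_refined,
    exposure_weights,
    warp_frame,
)
from .recovery import KeyframeStore, relocalize, update_keyframes

__all__ = ["PipelineResult", "run_sequence"]

log = logging.getLogger("fetomosaic")

TRACKED, LOST, RECOVERED = "tracked", "lost", "recovered"


@dataclass
class PipelineResult:
    canvas: MosaicCanvas
    globals_: list[Homography | None]
    statuses: list[str]
    store: KeyframeStore | None = None
    records: list[FrameRecord] = field(default_factory=list)

    @property
    def n_lost(self) -> int:
        return sum(s == LOST for s in self.statuses)

    @property
    def n_recovered(self) -> int:
        return sum(s == RECOVERED for s in self.statuses)

    def write_manifest(self, path: str | Path) -> None:
        """Per-frame statuses and global homographies, mirroring the simulator schema."""
        data = {
            "schema": "fetomosaic-mosaic/1",
            "n_frames": len(self.statuses),
            "statuses": self.statuses,
            "globals": [
                None if g is None else g.matrix.flatten().tolist() for g in self.globals_
            ],
            "records": [
                {
                    "index": r.index,
                    "status": r.status,
                    "n_matches": r.n_matches,
                    "n_inliers": r.n_inliers,
                    "reloc_keyframe": r.reloc_keyframe,
                }
                for r in self.records
            ],
            "keyframes": self.store.indices() if self.store is not None else None,
        }
        Path(path).write_text(json.dumps(data, indent=1))


def _loss_reason(
    h: Homography | None, frame_shape: tuple[int, int], config: PipelineConfig
) -> str | None:
    if h is None:
        return "estimation failure"
    if h.inlier_count < config.min_inliers:
        return f"inliers {h.inlier_count} < {config.min_inliers}"
    disp = corner_displacement(h.matrix, frame_shape)
    if disp > config.max_corner_disp_frac * frame_shape[1]:
        return f"implausible jump ({disp:.1f} px)"
    return None


def run_sequence(
    frames: list[Frame],
    config: PipelineConfig | None = None,
    recovery: bool = False,
    render: bool = True,
) -> PipelineResult:
    """Track, register and (optionally) blend an ordered frame sequence."""
    config = config or PipelineConfig()
    if len(frames) < 2:
        raise ValueError("mosaicking needs at least 2 frames")

    canvas = MosaicCanvas()
    store = KeyframeStore(t_discard=config.t_discard, t_kf=config.t_kf) if recovery else None
    globals_: list[Homography | None] = []
    statuses: list[str] = []
    records: list[FrameRecord] = []

    def register(frame: Frame, g: Homography) -> None:
        if render:
            warp_frame(frame, g, canvas, exposure_weights(frame, config))

    p_ref: FeaturePyramid | None = None  # pyramid of the last registered frame
    g_ref: Homography | None = None
    rel_prior: np.ndarray | None = None  # constant-motion prior
    lost = False

    for i, frame in enumerate(frames):
        pyramid = extract_features(frame, config=config)
        if i == 0:
            g = Homography.identity()
            status, rec = TRACKED, FrameRecord(i, TRACKED, g)
        elif not lost:
            matches = match_pyramids(p_ref, pyramid, config)
            # fit in the current -> reference direction so composition
            # G_cur = G_ref @ rel chains directly
            rel = estimate_homography_refined(
                pyramid, p_ref, matches.swap(), config, h_init=rel_prior
            )
            reason = _loss_reason(rel, frame.shape, config)
            if reason is None:
                g = g_ref @ rel
                status = TRACKED
                rel_prior = rel.matrix
                rec = FrameRecord(i, TRACKED, g, len(matches), rel.inlier_count)
            else:
                log.info("frame %d: tracking lost (%s)", i, reason)
                g, status = None, LOST
                rec = FrameRecord(i, LOST, None, len(matches),
                                  0 if rel is None else rel.inlier_count)
        else:  # currently lost
            g, status, rec = None, LOST, FrameRecord(i, LOST, None)
            if recovery and store is not None and len(store):
                g_rec, kf_idx = relocalize(pyramid, frame, store, config)
                if g_rec is not None:
                    g, status = g_rec, RECOVERED
                    rel_prior = None  # motion across the gap is unknown
                    rec = FrameRecord(i, RECOVERED, g, reloc_keyframe=kf_idx)
                    log.info("frame %d: relocalized against keyframe %d", i, kf_idx)

        if g is not None:
            register(frame, g)
            p_ref, g_ref, lost = pyramid, g, False
            if recovery and store is not None:
                update_keyframes(store, pyramid, i, g, config)
        else:
            lost = True
            rel_prior = None

        globals_.append(g)
        statuses.append(status)
        records.append(rec)
        log.debug(
            "frame %d: status=%s matches=%d inliers=%d",
            i, status, rec.n_matches, rec.n_inliers,
        )

    canvas.frame_status = records
    return PipelineResult(
        canvas=canvas, globals_=globals_, statuses=statuses, store=store, records=records
    )
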