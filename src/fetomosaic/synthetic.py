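"""Synthetic fetoscopy sequences with exact ground-truth homographies.

Real intra-operative fetoscopic video is not publicly deposited, so this
module emulates its named challenges on a synthetic placental scene: a small
circular field of view, centre-bright vignetting from the endoscopic light,
amniotic-fluid turbidity (veiling haze + noise), sparse vessel-like texture
over a texture-poor reddish background, a saturated laser-pointer dot, full
or partial transient occlusions, and smooth camera motion with occasional
fast jumps. Every frame's true frame-to-texture homography is recorded, so
downstream registration can be scored against exact ground truth.

Homography convention (used package-wide): 3x3 matrices act on homogeneous
pixel coordinates, 0-based, origin at the top-left pixel centre, x rightward
and y downward; ``H`` maps *frame* coordinates into *texture* (world)
coordinates. The true relative map from frame i+1 into frame i is therefore
``inv(H_i) @ H_{i+1}``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform, warp

from .frames import Frame, circular_fov_mask, read_frames, write_frames

__all__ = [
    "TextureImage",
    "MotionParams",
    "CameraTrajectory",
    "SyntheticSequence",
    "generate_placenta_texture",
    "simulate_trajectory",
    "render_sequence",
    "make_reference_sequence",
    "save_sequence",
    "load_sequence",
    "load_manifest",
]

OCCLUSION_TYPES = ("full", "partial")


@dataclass
class TextureImage:
    """Placental surface stand-in: RGB raster in [0,1] plus a vessel mask."""

    pixels: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.vessel_mask.shape != self.pixels.shape[:2]:
            raise ValueError("vessel_mask must match pixel raster shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class MotionParams:
    """Random-walk camera motion statistics (pixel units per frame).

    ``step_sigma`` drives translation, ``momentum`` smooths it into the slow
    sweeping motion of a careful placenta exploration; ``jump_prob`` injects
    the occasional fast movement (fetal kick, tool adjustment) with a
    displacement ``jump_scale`` times larger than a normal step.
    """

    step_sigma: float = 2.0
    momentum: float = 0.85
    rot_sigma_deg: float = 0.2
    zoom_sigma: float = 0.002
    persp_sigma: float = 1e-6
    jump_prob: float = 0.0
    jump_scale: float = 8.0
    margin: float = 4.0


@dataclass
class CameraTrajectory:
    homographies_gt: list[np.ndarray]
    motion_params: MotionParams
    frame_shape: tuple[int, int]
    texture_shape: tuple[int, int]

    def __post_init__(self) -> None:
        for h in self.homographies_gt:
            if abs(np.linalg.det(h)) < 1e-9:
                raise ValueError("ground-truth homography is singular")
            if abs(h[2, 2] - 1.0) > 1e-12:
                raise ValueError("homographies must be normalized (H[2,2] == 1)")

    def __len__(self) -> int:
        return len(self.homographies_gt)

    def relative(self, i: int) -> np.ndarray:
        """True map from frame ``i+1`` coordinates into frame ``i`` coordinates."""
        rel = np.linalg.solve(self.homographies_gt[i], self.homographies_gt[i + 1])
        return rel / rel[2, 2]


@dataclass
class SyntheticSequence:
    frames: list[Frame]
    trajectory: CameraTrajectory
    occlusions: list[tuple[int, int, str]]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.trajectory):
            raise ValueError("frames and ground-truth homographies differ in length")
        _check_occlusions(self.occlusions, len(self.frames))

    def occluded_indices(self) -> set[int]:
        out: set[int] = set()
        for s, e, _ in self.occlusions:
            out.update(range(s, e + 1))
        return out


def _check_occlusions(spec, n_frames: int) -> None:
    prev_end = -1
    for s, e, kind in sorted(spec):
        if kind not in OCCLUSION_TYPES:
            raise ValueError(f"unknown occlusion type {kind!r}")
        if not (0 <= s <= e < n_frames):
            raise ValueError(f"occlusion interval ({s}, {e}) outside frame range")
        if s <= prev_end:
            raise ValueError("occlusion intervals must not overlap")
        prev_end = e


# ---------------------------------------------------------------------------
# placental texture
# ---------------------------------------------------------------------------

def _stamp_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    h, w = mask.shape
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _grow_vessel_tree(mask: np.ndarray, rng: np.random.Generator, max_pixels: int) -> None:
    """One branching random walk of decreasing width stamped into ``mask``."""
    h, w = mask.shape
    start = rng.uniform([0, 0], [h - 1, w - 1])
    heading = rng.uniform(0, 2 * np.pi)
    stack = [(start[0], start[1], heading, rng.uniform(3.0, 6.0))]
    before = int(mask.sum())
    steps_budget = int(0.35 * max(h, w))
    while stack:
        y, x, ang, width = stack.pop()
        for _ in range(steps_budget):
            _stamp_disk(mask, y, x, width)
            if int(mask.sum()) - before > max_pixels:
                return
            ang += rng.normal(0.0, 0.15)
            y += 2.0 * np.sin(ang)
            x += 2.0 * np.cos(ang)
            if not (0 <= y < h and 0 <= x < w):
                break
            width *= 0.995
            if width < 0.8:
                break
            if rng.random() < 0.02 and len(stack) < 6:
                stack.append((y, x, ang + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9), width * 0.7))


def generate_placenta_texture(
    width: int, height: int, vessel_density: float, seed: int
) -> TextureImage:
    """Reddish low-frequency background threaded by darker branching vessels.

    Vessel trees are added until the vessel mask covers ``vessel_density`` of
    the raster (each tree is capped at ~0.8% of the raster, bounding the
    overshoot), giving coverage within about two percentage points of the
    request. Deterministic for a fixed seed.
    """
    if width < 256 or height < 256:
        raise ValueError("texture dimensions must be at least 256 px")
    if not 0.0 <= vessel_density <= 1.0:
        raise ValueError("vessel_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def field_layer(sigma: float, amp: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((height, width)), sigma, mode="wrap")
        peak = np.abs(f).max()
        return amp * f / peak if peak > 0 else f

    base = np.empty((height, width, 3))
    slow = field_layer(width / 16.0, 0.08)
    fast = field_layer(4.0, 0.05)
    speckle = field_layer(1.5, 0.045)  # villous surface granularity
    detail = fast + speckle
    base[..., 0] = 0.58 + slow + detail
    base[..., 1] = 0.26 + 0.6 * slow + 0.6 * detail
    base[..., 2] = 0.24 + 0.5 * slow + 0.5 * detail

    vessel_mask = np.zeros((height, width), dtype=bool)
    target = vessel_density * height * width
    cap = int(0.008 * height * width)
    guard = 0
    while vessel_mask.sum() < target and guard < 10_000:
        _grow_vessel_tree(vessel_mask, rng, cap)
        guard += 1

    vessel_color = np.array([0.33, 0.07, 0.08])
    depth = gaussian_filter(vessel_mask.astype(float), 1.0)
    depth = np.clip(depth, 0.0, 1.0)
    pixels = base * (1 - 0.85 * depth[..., None]) + vessel_color * 0.85 * depth[..., None]
    return TextureImage(pixels=np.clip(pixels, 0.0, 1.0), vessel_mask=vessel_mask)


# ---------------------------------------------------------------------------
# camera trajectory
# ---------------------------------------------------------------------------

def _pose_matrix(
    pos: np.ndarray, angle: float, scale: float, persp: np.ndarray,
    frame_shape: tuple[int, int],
) -> np.ndarray:
    h, w = frame_shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    ca, sa = np.cos(angle), np.sin(angle)
    rot = scale * np.array([[ca, -sa], [sa, ca]])
    m = np.eye(3)
    m[:2, :2] = rot
    m[:2, 2] = -rot @ c
    m[2, :2] = persp
    t = np.eye(3)
    t[:2, 2] = pos
    out = t @ m
    return out / out[2, 2]


def _projected_extent(m: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    """Projected frame-corner extents of a pose matrix with zero translation."""
    h, w = frame_shape
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    hom = np.c_[corners, np.ones(4)] @ m.T
    return hom[:, :2] / hom[:, 2:3]


def simulate_trajectory(
    n_frames: int,
    frame_size: int | tuple[int, int],
    texture_size: int | tuple[int, int],
    motion_params: MotionParams | None = None,
    seed: int = 0,
) -> CameraTrajectory:
    """Smooth random-walk camera path whose footprint never leaves the texture.

    Translation follows a momentum-smoothed Gaussian walk with occasional
    large jumps; rotation, zoom and a tiny perspective term drift slowly.
    When a step would push the frame footprint outside the texture, the
    position is clamped back inside and the velocity reflected.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    mp = motion_params or MotionParams()
    fh, fw = (frame_size, frame_size) if np.isscalar(frame_size) else frame_size
    th, tw = (texture_size, texture_size) if np.isscalar(texture_size) else texture_size
    rng = np.random.default_rng(seed)

    pos = np.array([(tw - 1) / 2.0, (th - 1) / 2.0])
    vel = np.zeros(2)
    angle, log_zoom = 0.0, 0.0
    persp = np.zeros(2)
    mats: list[np.ndarray] = []
    for k in range(n_frames):
        if k > 0:
            vel = mp.momentum * vel + np.sqrt(max(1 - mp.momentum**2, 0.0)) * rng.normal(
                0.0, mp.step_sigma, 2
            )
            pos = pos + vel
            if mp.jump_prob > 0 and rng.random() < mp.jump_prob:
                # transient fast movement: a one-frame position offset, not
                # a velocity change, so the walk resumes smoothly afterwards
                direction = rng.uniform(0, 2 * np.pi)
                pos = pos + mp.jump_scale * mp.step_sigma * np.array(
                    [np.cos(direction), np.sin(direction)]
                )
            angle += rng.normal(0.0, np.deg2rad(mp.rot_sigma_deg))
            log_zoom = np.clip(log_zoom + rng.normal(0.0, mp.zoom_sigma), -0.18, 0.18)
            persp = np.clip(persp + rng.normal(0.0, mp.persp_sigma, 2), -3e-5, 3e-5)
        m0 = _pose_matrix(np.zeros(2), angle, np.exp(log_zoom), persp, (fh, fw))
        ext = _projected_extent(m0, (fh, fw))
        lo = mp.margin - ext.min(axis=0)
        hi = np.array([tw - 1, th - 1]) - mp.margin - ext.max(axis=0)
        if np.any(lo > hi):
            raise ValueError("frame footprint cannot fit inside the texture")
        clamped = np.clip(pos, lo, hi)
        vel = np.where(clamped != pos, -vel, vel)  # reflect at the walls
        pos = clamped
        mats.append(_pose_matrix(pos, angle, np.exp(log_zoom), persp, (fh, fw)))
    return CameraTrajectory(
        homographies_gt=mats,
        motion_params=mp,
        frame_shape=(fh, fw),
        texture_shape=(th, tw),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _vignette(frame_shape: tuple[int, int], strength: float) -> np.ndarray:
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0 - 1.0
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) / radius
    return 1.0 - strength * np.clip(r, 0.0, 1.0) ** 2


def render_sequence(
    texture: TextureImage,
    trajectory: CameraTrajectory,
    vignette_strength: float = 0.6,
    turbidity: float = 0.3,
    laser_dot: bool = True,
    occlusion_spec: list[tuple[int, int, str]] | None = None,
    seed: int = 0,
) -> SyntheticSequence:
    """Render frames by sampling the texture under each ground-truth homography.

    Artifacts, in order: bilinear texture sampling, multiplicative radial
    vignette (centre bright), turbidity veil + Gaussian noise, optional
    saturated laser dot drifting near the centre, circular FoV mask, and
    occlusion intervals replaced by near-uniform occluder frames.
    """
    occlusions = [tuple(o) for o in (occlusion_spec or [])]
    n = len(trajectory)
    _check_occlusions(occlusions, n)
    rng = np.random.default_rng(seed)
    fh, fw = trajectory.frame_shape
    vig = _vignette((fh, fw), vignette_strength)[..., None]
    fov = circular_fov_mask(fh, fw)
    occluded = {
        i: kind for s, e, kind in occlusions for i in range(s, e + 1)
    }
    laser_pos = np.array([(fw - 1) / 2.0 + fw * 0.1, (fh - 1) / 2.0])
    laser_radius = 0.02 * fw
    frames: list[Frame] = []
    for i, hmat in enumerate(trajectory.homographies_gt):
        img = warp(
            texture.pixels,
            ProjectiveTransform(matrix=hmat),
            output_shape=(fh, fw),
            order=1,
            mode="constant",
            cval=0.0,
        )
        img = img * vig
        if turbidity > 0:
            veil = 0.5 * turbidity
            img = (1 - veil) * img + veil * np.array([0.75, 0.78, 0.80])
            img = img + rng.normal(0.0, 0.05 * turbidity, img.shape)
        if laser_dot:
            laser_pos = laser_pos + rng.normal(0.0, 1.0, 2)
            center = np.array([(fw - 1) / 2.0, (fh - 1) / 2.0])
            laser_pos = center + np.clip(laser_pos - center, -0.3 * fw, 0.3 * fw)
            yy, xx = np.mgrid[0:fh, 0:fw]
            dot = (xx - laser_pos[0]) ** 2 + (yy - laser_pos[1]) ** 2 <= laser_radius**2
            img[dot] = 1.0
        kind = occluded.get(i)
        if kind == "full":
            img = 0.45 + rng.normal(0.0, 0.02, img.shape)
        elif kind == "partial":
            # dark occluder disk covering >= 60% of the FoV
            yy, xx = np.mgrid[0:fh, 0:fw]
            occ_c = np.array([(fw - 1) / 2.0, (fh - 1) / 2.0]) + rng.normal(0, 0.05 * fw, 2)
            occ_r = np.sqrt(0.65) * (min(fh, fw) / 2.0)
            blob = (xx - occ_c[0]) ** 2 + (yy - occ_c[1]) ** 2 <= occ_r**2
            img[blob] = 0.25 + rng.normal(0.0, 0.02, img.shape)[blob]
        img = np.clip(img, 0.0, 1.0)
        img[~fov] = 0.0
        frames.append(Frame(pixels=img, index=i, mask=fov.copy()))
    return SyntheticSequence(
        frames=frames,
        trajectory=trajectory,
        occlusions=occlusions,
        seed=seed,
        params={
            "vignette_strength": vignette_strength,
            "turbidity": turbidity,
            "laser_dot": laser_dot,
        },
    )


def make_reference_sequence(
    n_frames: int = 100,
    frame_size: int = 256,
    texture_size: int = 1024,
    vessel_density: float = 0.05,
    vignette_strength: float = 0.6,
    turbidity: float = 0.3,
    laser_dot: bool = True,
    occlusion_spec: list[tuple[int, int, str]] | None = None,
    motion_params: MotionParams | None = None,
    seed: int = 0,
) -> SyntheticSequence:
    """Texture + trajectory + rendering in one call (the reference fixture).

    Child seeds for the three stages are drawn from a single generator seeded
    with ``seed``, so the whole sequence is reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    s_tex, s_traj, s_render = (int(s) for s in rng.integers(0, 2**31 - 1, 3))
    texture = generate_placenta_texture(texture_size, texture_size, vessel_density, s_tex)
    trajectory = simulate_trajectory(
        n_frames, frame_size, texture_size, motion_params, seed=s_traj
    )
    seq = render_sequence(
        texture,
        trajectory,
        vignette_strength=vignette_strength,
        turbidity=turbidity,
        laser_dot=laser_dot,
        occlusion_spec=occlusion_spec,
        seed=s_render,
    )
    seq.seed = seed
    return seq


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------

def save_sequence(seq: SyntheticSequence, out_dir: str | Path) -> Path:
    """Write PNG frames plus a JSON manifest (ground truth, occlusions, seed)."""
    out = Path(out_dir)
    write_frames(seq.frames, out)
    manifest = {
        "schema": "fetomosaic-sequence/1",
        "n_frames": len(seq.frames),
        "frame_shape": list(seq.trajectory.frame_shape),
        "texture_shape": list(seq.trajectory.texture_shape),
        "homographies_gt": [h.flatten().tolist() for h in seq.trajectory.homographies_gt],
        "occlusions": [[s, e, kind] for s, e, kind in seq.occlusions],
        "seed": seq.seed,
        "params": seq.params,
        "motion_params": asdict(seq.trajectory.motion_params),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_manifest(seq_dir: str | Path) -> dict:
    manifest = json.loads((Path(seq_dir) / "manifest.json").read_text())
    manifest["homographies_gt"] = [
        np.array(h).reshape(3, 3) for h in manifest["homographies_gt"]
    ]
    return manifest


def load_sequence(seq_dir: str | Path) -> SyntheticSequence:
    """Read back a directory written by :func:`save_sequence`."""
    manifest = load_manifest(seq_dir)
    frames = read_frames(seq_dir)
    trajectory = CameraTrajectory(
        homographies_gt=manifest["homographies_gt"],
        motion_params=MotionParams(**manifest["motion_params"]),
        frame_shape=tuple(manifest["frame_shape"]),
        texture_shape=tuple(manifest["texture_shape"]),
    )
    return SyntheticSequence(
        frames=frames,
        trajectory=trajectory,
        occlusions=[tuple(o) for o in manifest["occlusions"]],
        seed=manifest["seed"],
        params=manifest["params"],
    )
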