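"""Video frames and frame I/O.

A fetoscope delivers a small circular field of view (FoV) inside a dark
rectangular frame. Every :class:`Frame` therefore carries a boolean validity
mask marking the pixels inside the FoV; all matching, blending and evaluation
stages honour it.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Frame",
    "FrameReadError",
    "circular_fov_mask",
    "detect_fov_mask",
    "read_frames",
    "write_frames",
]


class FrameReadError(RuntimeError):
    """Raised when a frame file cannot be decoded; names the offending file."""


def circular_fov_mask(height: int, width: int, radius: float | None = None) -> np.ndarray:
    """Boolean mask of the inscribed circular field of view.

    The circle is centred on the pixel grid (0-based pixel-centre
    coordinates); ``radius`` defaults to half the short side minus one pixel,
    mimicking the black corners of an endoscopic frame.
    """
    if radius is None:
        radius = min(height, width) / 2.0 - 1.0
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


@dataclass
class Frame:
    """One video frame: RGB raster in [0, 1], sequence index, FoV mask."""

    pixels: np.ndarray
    index: int = 0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels, dtype=np.float64)
        if pix.ndim == 2:
            pix = np.repeat(pix[..., None], 3, axis=2)
        if pix.ndim != 3 or pix.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {pix.shape}")
        if pix.min() < -1e-9 or pix.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]")
        self.pixels = np.clip(pix, 0.0, 1.0)
        if self.mask is None:
            self.mask = circular_fov_mask(*self.shape)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask shape must match pixel raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def luminance(self) -> np.ndarray:
        """Rec. 601 luminance channel."""
        r, g, b = self.pixels[..., 0], self.pixels[..., 1], self.pixels[..., 2]
        return 0.299 * r + 0.587 * g + 0.114 * b

    def corners(self) -> np.ndarray:
        """Frame corners as (4, 2) xy pixel coordinates (0-based centres)."""
        h, w = self.shape
        return np.array(
            [[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
        )


def detect_fov_mask(pixels: np.ndarray, threshold: float = 2.0 / 255.0) -> np.ndarray:
    """Estimate the circular FoV as the largest inscribed circle of non-black pixels.

    The circle centre is the centroid of above-threshold pixels; the radius is
    grown until fewer than 99.5% of the circle's pixels are non-black.
    """
    lum = pixels.mean(axis=2) if pixels.ndim == 3 else pixels
    nb = lum > threshold
    h, w = nb.shape
    if not nb.any():
        return np.zeros_like(nb)
    ys, xs = np.nonzero(nb)
    cy, cx = ys.mean(), xs.mean()
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    r_max = min(cy, cx, h - 1 - cy, w - 1 - cx)
    lo, hi = 1.0, max(r_max, 1.0)
    for _ in range(30):  # bisect on coverage fraction
        mid = 0.5 * (lo + hi)
        disk = d2 <= mid**2
        if nb[disk].mean() >= 0.995:
            lo = mid
        else:
            hi = mid
    return d2 <= lo**2


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path) -> tuple:
    parts = _NUM_RE.findall(path.stem)
    return (int(parts[-1]) if parts else 0, path.name)


def read_frames(path: str | Path, mask: np.ndarray | None = None) -> list[Frame]:
    """Load an ordered frame sequence from a directory of numbered rasters.

    Frames are ordered by the trailing number in their file names. A
    ``mask.png`` file in the directory, or an explicit ``mask`` array,
    overrides FoV auto-detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in exts and p.stem != "mask"),
        key=_numeric_key,
    )
    if not files:
        raise FileNotFoundError(f"no frame images found in {path}")
    mask_file = path / "mask.png"
    if mask is None and mask_file.exists():
        mask = np.asarray(iio.imread(mask_file)) > 0
        if mask.ndim == 3:
            mask = mask[..., 0]
    frames: list[Frame] = []
    shape: tuple[int, int] | None = None
    for i, f in enumerate(files):
        try:
            arr = np.asarray(iio.imread(f))
        except Exception as exc:  # noqa: BLE001 - report the file, whatever failed
            raise FrameReadError(f"cannot read frame file {f}: {exc}") from exc
        if arr.dtype != np.float64:
            arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[..., :3]
        if shape is None:
            shape = arr.shape[:2]
        elif arr.shape[:2] != shape:
            raise FrameReadError(
                f"inconsistent frame size in {f}: {arr.shape[:2]} vs {shape}"
            )
        fov = mask if mask is not None else detect_fov_mask(arr)
        frames.append(Frame(pixels=arr, index=i, mask=fov))
    return frames


def write_frames(frames: list[Frame], out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded numbered 8-bit PNGs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames) - 1)))
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, (np.clip(frame.pixels, 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    return paths
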