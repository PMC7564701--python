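"""Frame I/O and body extraction by RGB color thresholding.

The recording setup films a single fly on a light, warm-toned background.
Every background pixel falls strictly inside a per-channel RGB window
(default ``(90, 50, 30)`` to ``(255, 255, 255)``) while the dark fly body
fails at least one channel.  Thresholding therefore yields a clean binary
background mask; inverting it gives the body silhouette image ``S`` used
as the spatial channel of the feature images.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image

__all__ = [
    "ColorThreshold",
    "read_frames",
    "background_mask",
    "body_image",
    "to_gray_square",
    "pad_to_square",
    "source_fps",
]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass(frozen=True)
class ColorThreshold:
    """Per-channel RGB window delimiting *background* pixels.

    A pixel is background iff every channel lies inside ``[low, high]``
    (inclusive).  Channel order is RGB.
    """

    low: tuple[int, int, int] = (90, 50, 30)
    high: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.low), np.asarray(self.high)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("thresholds must be 3-vectors (RGB)")
        if np.any(lo > hi):
            raise ValueError(f"low {self.low} exceeds high {self.high}")
        if np.any(lo < 0) or np.any(hi > 255):
            raise ValueError("threshold values must lie in [0, 255]")


def _numeric_key(path: Path) -> tuple:
    """Sort key ordering ``frame_2`` before ``frame_10``."""
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_frames(
    source: str | Path,
    frame_range: tuple[int, int] | None = None,
) -> Iterator[np.ndarray]:
    """Yield RGB uint8 frames from a directory of images or a video file.

    Directory sources are read in numeric filename order.  ``frame_range``
    is a half-open ``(start, stop)`` pair of frame indices.

    Raises
    ------
    FileNotFoundError
        If *source* does not exist.
    ValueError
        If the source contains no frames or cannot be decoded.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"no such video source: {source}")
    if source.is_dir():
        files = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no image files found in {source}")
        if frame_range is not None:
            files = files[frame_range[0] : frame_range[1]]
        for f in files:
            with Image.open(f) as im:
                yield np.asarray(im.convert("RGB"))
        return

    # Video container: delegate to imageio if a suitable plugin exists.
    import imageio.v2 as iio

    try:
        reader = iio.get_reader(str(source))
    except Exception as exc:  # pragma: no cover - depends on plugins
        raise ValueError(f"cannot decode video source {source}: {exc}") from exc
    start, stop = frame_range if frame_range is not None else (0, None)
    n = 0
    for i, frame in enumerate(reader):
        if i < start:
            continue
        if stop is not None and i >= stop:
            break
        arr = np.asarray(frame)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        yield arr[..., :3].astype(np.uint8)
        n += 1
    reader.close()
    if n == 0 and frame_range is None:
        raise ValueError(f"empty video source: {source}")


def source_fps(source: str | Path, default: float = 25.0) -> float:
    """Frame rate of *source*; directories fall back to *default*."""
    source = Path(source)
    if source.is_dir():
        return default
    import imageio.v2 as iio

    try:
        meta = iio.get_reader(str(source)).get_meta_data()
        return float(meta.get("fps", default))
    except Exception:
        return default


def background_mask(frame: np.ndarray, thr: ColorThreshold | None = None) -> np.ndarray:
    """Binary background mask: 255 where every channel lies inside the
    threshold window, 0 elsewhere.

    Bounds are inclusive (the `inRange` convention), so a pure-white
    pixel under the default ``high=(255,255,255)`` is background and the
    mask is idempotent under re-application to its own 3-channel
    broadcast.
    """
    if thr is None:
        thr = ColorThreshold()
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB frame, got shape {frame.shape}")
    lo = np.asarray(thr.low)
    hi = np.asarray(thr.high)
    inside = np.all((frame >= lo) & (frame <= hi), axis=2)
    return np.where(inside, 255, 0).astype(np.uint8)


def body_image(
    frame: np.ndarray,
    thr: ColorThreshold | None = None,
    out_size: int | None = 500,
    gray: np.ndarray | None = None,
    texture: bool = False,
) -> np.ndarray:
    """Body silhouette image S = 255 - background mask.

    Computed at native resolution, then zero-padded to square and resized
    to ``out_size`` so it shares the geometry of :func:`to_gray_square`
    outputs.  With ``texture=True`` the silhouette is modulated by the
    gray frame instead of being flat 255 (an optional variant; the flat
    binary silhouette is the default).

    Pass ``out_size=None`` to keep native resolution (no pad/resize).
    """
    mask = background_mask(frame, thr)
    s = (255 - mask.astype(np.int16)).astype(np.uint8)
    if texture:
        g = gray if gray is not None else _luminance(frame)
        s = ((s.astype(np.float64) / 255.0) * g).round().astype(np.uint8)
    if out_size is None:
        return s
    return _resize(pad_to_square(s), out_size)


def _luminance(frame: np.ndarray) -> np.ndarray:
    return (np.asarray(frame, dtype=np.float64) @ _LUMA).round().clip(0, 255).astype(np.uint8)


def pad_to_square(img: np.ndarray) -> np.ndarray:
    """Zero-pad the shorter dimension to square, split evenly with the odd
    row/column going to the bottom/right."""
    h, w = img.shape[:2]
    if h == w:
        return img
    n = max(h, w)
    ph, pw = n - h, n - w
    pad = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
    if img.ndim == 3:
        pad = pad + ((0, 0),)
    return np.pad(img, pad, mode="constant")


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] == size and img.shape[1] == size:
        return img
    return np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))


def to_gray_square(frame: np.ndarray, out_size: int = 500) -> np.ndarray:
    """BT.601 luminance, zero-pad to square, bilinear resize to
    ``out_size`` x ``out_size`` uint8."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        g = _luminance(frame)
    else:
        g = frame.astype(np.uint8)
    return _resize(pad_to_square(g), out_size)
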