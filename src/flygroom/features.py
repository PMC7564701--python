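"""Spatio-temporal feature images from sliding windows of video frames.

Each stride-1 window of ``w`` grayscale frames (default 7 at 25 fps,
i.e. 0.28 s) is turned into one 100x100x3 *feature image*:

* **red** — per-pixel spectral center of mass of the temporal magnitude
  spectrum (bright where intensity oscillates, dark where static),
  clipped to [0, 1] and scaled to 255;
* **green** — the body silhouette crop (S-ROI) divided by 1.8, so it
  never exceeds round(255/1.8) = 142;
* **blue** — the window's second gray frame (time index 1).

The crop box is a 100x100 region centred on the motion-energy argmax —
the accumulated absolute frame-to-frame gray difference ``D`` locates
the moving appendage, and both the temporal stack (T-ROI) and the
silhouette (S-ROI) are cut with the identical box.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .imaging import ColorThreshold, body_image, to_gray_square

__all__ = [
    "FeatureConfig",
    "ComMap",
    "FeatureImage",
    "motion_energy",
    "locate_roi",
    "crop_rois",
    "temporal_com",
    "fuse_channels",
    "extract_stream",
]

#: Green-channel divisor applied to the S-ROI silhouette.
SROI_DIVISOR = 1.8


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature-extraction stage.

    window
        Temporal window length ``w`` in frames.
    roi
        Side length of the square crop around the motion maximum.
    size
        Side length of the preprocessed square frames.
    threshold
        RGB background window used for body extraction.
    com_index_base
        First frequency index used as a center-of-mass weight.  0 (the
        default) weights DC as zero so static pixels map to black; 1
        preserves the literal one-based reading, under which every
        nonzero static pixel saturates after clipping.
    body_texture
        If true, modulate the silhouette by the gray frame instead of a
        flat binary silhouette.
    """

    window: int = 7
    roi: int = 100
    size: int = 500
    threshold: ColorThreshold = field(default_factory=ColorThreshold)
    com_index_base: int = 0
    body_texture: bool = False

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 frames")
        if not (0 < self.roi <= self.size):
            raise ValueError("roi must satisfy 0 < roi <= size")
        if self.com_index_base not in (0, 1):
            raise ValueError("com_index_base must be 0 or 1")


@dataclass(frozen=True)
class ComMap:
    """Per-pixel spectral center-of-mass map over one window."""

    raw: np.ndarray        #: unclipped center-of-mass values, >= 0
    normalized: np.ndarray  #: raw clipped to [0, 1]


@dataclass(frozen=True)
class FeatureImage:
    """Fused 3-channel feature image assigned to one absolute frame."""

    pixels: np.ndarray  #: R x R x 3 uint8
    window_index: int   #: absolute index of the frame this image represents


def motion_energy(stack: np.ndarray) -> np.ndarray:
    """Accumulated absolute frame-to-frame differences ``D``.

    ``stack`` is a ``w x S x S`` array of gray intensities (any scale);
    the result is ``sum_{i=1}^{w-1} |F_i - F_{i-1}|`` elementwise.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"need a w x S x S stack with w >= 2, got shape {stack.shape}")
    return np.abs(np.diff(stack, axis=0)).sum(axis=0)


def locate_roi(D: np.ndarray) -> tuple[int, int]:
    """(row, col) of the global maximum of the motion-energy map.

    Ties break to the first occurrence in row-major order, so an
    all-zero map yields (0, 0).
    """
    D = np.asarray(D)
    r, c = np.unravel_index(int(np.argmax(D)), D.shape)
    return int(r), int(c)


def _clamped_box(center: tuple[int, int], R: int, S: int) -> tuple[int, int]:
    """Top-left corner of an R-sized box nominally centred at *center*,
    shifted to lie fully inside an S-sized frame."""
    half = R // 2
    top = min(max(center[0] - half, 0), S - R)
    left = min(max(center[1] - half, 0), S - R)
    return top, left


def crop_rois(
    stack: np.ndarray,
    body: np.ndarray,
    center: tuple[int, int],
    R: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the T-ROI (temporal stack) and S-ROI (silhouette) with one box.

    Both crops use the identical ``R x R`` box centred at *center*,
    clamped to lie inside the frame, so the temporal and spatial
    channels stay pixel-aligned.
    """
    stack = np.asarray(stack)
    body = np.asarray(body)
    S = stack.shape[1]
    if R > S:
        raise ValueError(f"roi size {R} exceeds frame size {S}")
    if body.shape != stack.shape[1:]:
        raise ValueError(f"body shape {body.shape} != frame shape {stack.shape[1:]}")
    top, left = _clamped_box(center, R, S)
    troi = stack[:, top : top + R, left : left + R]
    sroi = body[top : top + R, left : left + R]
    return troi, sroi


def temporal_com(troi: np.ndarray, index_base: int = 0) -> ComMap:
    """Per-pixel center of mass of the temporal magnitude spectrum.

    For each pixel the ``w``-point DFT magnitude spectrum ``f`` is taken
    along time and the frequency-index-weighted mean
    ``m = sum_i (i + index_base) * f_i / sum_i f_i`` computed, with
    ``m = 0`` where the spectrum sums to zero.  The normalized map is
    ``clip(m, 0, 1)``.
    """
    troi = np.asarray(troi, dtype=np.float64)
    w = troi.shape[0]
    spectrum = np.abs(np.fft.fft(troi, axis=0))
    weights = np.arange(index_base, w + index_base, dtype=np.float64)
    num = np.tensordot(weights, spectrum, axes=(0, 0))
    den = spectrum.sum(axis=0)
    raw = np.divide(num, den, out=np.zeros_like(den), where=den > 0)
    return ComMap(raw=raw, normalized=np.clip(raw, 0.0, 1.0))


def fuse_channels(com: ComMap, sroi: np.ndarray, troi: np.ndarray) -> np.ndarray:
    """Fuse the three sources into an R x R x 3 uint8 feature image.

    red = 255 * clipped center of mass; green = S-ROI / 1.8;
    blue = 255 * second frame (time index 1) of the T-ROI.
    """
    red_f = com.normalized
    sroi = np.asarray(sroi, dtype=np.float64)
    troi = np.asarray(troi, dtype=np.float64)
    if not (red_f.shape == sroi.shape == troi.shape[1:]):
        raise ValueError(
            f"misaligned channels: com {red_f.shape}, sroi {sroi.shape}, troi {troi.shape}"
        )
    red = np.rint(255.0 * red_f)
    green = np.rint(sroi / SROI_DIVISOR)
    blue = np.rint(255.0 * troi[1])
    return np.stack([red, green, blue], axis=-1).clip(0, 255).astype(np.uint8)


def extract_stream(
    frames: Iterable[np.ndarray],
    cfg: FeatureConfig | None = None,
) -> Iterator[FeatureImage]:
    """One feature image per stride-1 window over a frame stream.

    A window starting at frame ``k`` is assigned ``window_index = k + 1``
    — the absolute index of the frame shown in the blue channel — so the
    per-frame classifier output lines up with the video timeline.  Frames
    are preprocessed once each; the stream is processed with O(w) memory.

    Yields nothing (after a warning) if the stream is shorter than one
    window.
    """
    if cfg is None:
        cfg = FeatureConfig()
    w, R = cfg.window, cfg.roi
    grays: deque[np.ndarray] = deque(maxlen=w)   # normalized gray frames
    bodies: deque[np.ndarray] = deque(maxlen=w)  # silhouette images
    diffs: deque[np.ndarray] = deque(maxlen=w - 1)
    k = 0
    n = 0
    prev: np.ndarray | None = None
    for frame in frames:
        gray = to_gray_square(frame, cfg.size).astype(np.float64) / 255.0
        body = body_image(frame, cfg.threshold, cfg.size, texture=cfg.body_texture)
        if prev is not None:
            diffs.append(np.abs(gray - prev))
        prev = gray
        grays.append(gray)
        bodies.append(body)
        n += 1
        if len(grays) == w:
            D = np.sum(diffs, axis=0)
            center = locate_roi(D)
            stack = np.stack(grays)
            troi, sroi = crop_rois(stack, bodies[1], center, R)
            com = temporal_com(troi, cfg.com_index_base)
            yield FeatureImage(pixels=fuse_channels(com, sroi, troi), window_index=k + 1)
            k += 1
    if n < w:
        warnings.warn(
            f"stream of {n} frames is shorter than one window (w={w}); no output",
            stacklevel=2,
        )
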