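"""Frame-level preprocessing: grayscale conversion and binary mask streams.

An overhead recording of a supine infant on a unicolor sheet is reduced to two
binary image streams that drive the whole analysis:

* the *background difference* mask — ``1`` where the frame differs from a
  reference background image by at least a brightness threshold ``T``; this
  marks the infant's body silhouette;
* the *interframe difference* mask — ``1`` where two time-adjacent frames
  differ by at least ``T``; this marks pixels where movement occurred.

Both comparisons use the absolute brightness difference and an inclusive
threshold (``|d| >= T``), so binarizing an already-binary image with any
``T <= 1`` is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from skimage.morphology import binary_opening

__all__ = [
    "FrameSequence",
    "MaskPair",
    "to_grayscale",
    "background_subtraction",
    "interframe_difference",
    "compute_masks",
    "temporal_median_background",
]

#: ITU-R BT.601 luma weights used for colour -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered grayscale frames with their frame rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Brightness values in ``[0, 255]``.
    frame_rate : float
        Sampling rate ``f_s`` in Hz.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, H, W) array, got shape {self.frames.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)


@dataclass
class MaskPair:
    """Binary masks of one frame: body silhouette and detected movement."""

    bg_mask: np.ndarray
    diff_mask: np.ndarray
    frame_index: int


def to_grayscale(frames: Sequence[np.ndarray] | np.ndarray, frame_rate: float) -> FrameSequence:
    """Convert colour or grayscale frames to a grayscale :class:`FrameSequence`.

    Already-grayscale input passes through unchanged.  Colour frames
    (trailing RGB axis) are reduced with BT.601 luma weights.

    Raises
    ------
    ValueError
        If the frames do not all share the same height/width; the message
        lists the offending frame indices.
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("empty frame sequence")
    shapes = [f.shape[:2] for f in frames]
    ref = shapes[0]
    bad = [i for i, s in enumerate(shapes) if s != ref]
    if bad:
        raise ValueError(f"frames with mismatched shapes at indices {bad} (expected {ref})")

    out = np.empty((len(frames), *ref), dtype=np.float64)
    for i, f in enumerate(frames):
        if f.ndim == 2:
            out[i] = f
        elif f.ndim == 3 and f.shape[2] in (3, 4):
            out[i] = f[..., :3].astype(np.float64) @ LUMA_WEIGHTS
        else:
            raise ValueError(f"frame {i} has unsupported shape {f.shape}")
    return FrameSequence(out, frame_rate)


def _binary_abs_diff(a: np.ndarray, b: np.ndarray, threshold: float) -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a.astype(np.float64) - b.astype(np.float64))
    return (diff >= threshold).astype(np.uint8)


def background_subtraction(frame: np.ndarray, background: np.ndarray, threshold: float) -> np.ndarray:
    """Binary body-silhouette mask: ``1`` where ``|frame - background| >= T``."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return _binary_abs_diff(frame, background, threshold)


def interframe_difference(
    frame: np.ndarray, previous: np.ndarray | None, threshold: float
) -> np.ndarray:
    """Binary movement mask between time-adjacent frames.

    The first frame has no predecessor; by contract its mask is all-zero
    (pass ``previous=None``).
    """
    if previous is None:
        return np.zeros(np.asarray(frame).shape[:2], dtype=np.uint8)
    return _binary_abs_diff(frame, previous, threshold)


def temporal_median_background(seq: FrameSequence) -> np.ndarray:
    """Per-pixel temporal median — automatic background fallback when no
    empty-crib reference frame is available."""
    return np.median(seq.frames, axis=0)


def compute_masks(
    seq: FrameSequence,
    background: np.ndarray,
    threshold: float,
    *,
    morphological_opening: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute both mask streams for a whole sequence.

    Returns ``(bg_masks, diff_masks)``, each ``(n, H, W)`` uint8 in {0, 1}.
    ``diff_masks[0]`` is all-zero by contract.  Optional morphological opening
    (3x3 structuring element) removes speckle from the silhouette masks;
    default off.
    """
    background = np.asarray(background, dtype=np.float32)
    frames = seq.frames.astype(np.float32, copy=False)
    bg = np.empty(frames.shape, dtype=np.uint8)
    diff = np.zeros_like(bg)
    for i in range(seq.n_frames):  # chunked to bound temporary memory
        np.greater_equal(np.abs(frames[i] - background), threshold, out=bg[i])
        if i:
            np.greater_equal(np.abs(frames[i] - frames[i - 1]), threshold, out=diff[i])
    if morphological_opening:
        for i in range(bg.shape[0]):
            bg[i] = binary_opening(bg[i].astype(bool)).astype(np.uint8)
    return bg, diff


def iter_mask_pairs(bg_masks: np.ndarray, diff_masks: np.ndarray) -> Iterator[MaskPair]:
    for i in range(bg_masks.shape[0]):
        yield MaskPair(bg_masks[i], diff_masks[i], i)
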