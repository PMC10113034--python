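"""Phase-1 image processing: background model, Otsu thresholding, blob extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .core import DARK_ON_LIGHT, FrameSequence, ROI


@dataclass
class BackgroundModel:
    mean_image: np.ndarray  # float, same shape as the frames
    n_frames_used: int


@dataclass
class Blob:
    """One 8-connected foreground component."""

    frame_index: int
    pixels: np.ndarray  # (N, 2) array of (row, col)
    outer_contour: np.ndarray  # (M, 2) closed polygon, (x, y) px, subpixel
    centroid: tuple[float, float]  # (x, y) px
    area_px: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) excl.

    _pixel_key: np.ndarray | None = None

    def pixel_key(self, width: int) -> np.ndarray:
        """Sorted linear pixel indices, for overlap tests."""
        if self._pixel_key is None:
            self._pixel_key = np.sort(self.pixels[:, 0] * width + self.pixels[:, 1])
        return self._pixel_key


def build_background(frames: FrameSequence) -> BackgroundModel:
    """Pixel-wise mean of up to 100 equidistant frames from the central third."""
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame sequence")
    lo, hi = n // 3, 2 * n // 3
    if hi <= lo:  # very short clip: central third empty, use everything
        lo, hi = 0, n
    span = hi - lo
    k = min(100, span)
    idx = np.unique(np.round(np.linspace(lo, hi - 1, k)).astype(int))
    acc = np.zeros(frames.shape, dtype=np.float64)
    for i in idx:
        acc += frames[i]
    return BackgroundModel(acc / len(idx), len(idx))


def segment_frame(
    frame: np.ndarray,
    bg: BackgroundModel,
    polarity: str = DARK_ON_LIGHT,
    roi: ROI | None = None,
) -> tuple[np.ndarray, bool]:
    """Threshold the signed background difference with Otsu's criterion.

    Returns ``(mask, degenerate)``; ``degenerate`` flags a constant
    difference image (no foreground), for which the mask is empty.
    """
    if frame.shape != bg.mean_image.shape:
        raise ValueError("frame and background shapes differ")
    diff = bg.mean_image - frame if polarity == DARK_ON_LIGHT else frame - bg.mean_image
    diff = np.clip(diff, 0, None)
    roi_mask = roi.mask(frame.shape) if roi is not None else None
    sample = diff[roi_mask] if roi_mask is not None else diff
    if sample.max() - sample.min() < 1e-9:
        return np.zeros(frame.shape, dtype=bool), True
    thr = threshold_otsu(sample.astype(np.float64), nbins=256)
    mask = diff > thr
    if roi_mask is not None:
        mask &= roi_mask
    return mask, False


def extract_blobs(
    mask: np.ndarray, min_area_px: int = 1, frame_index: int = 0
) -> list[Blob]:
    """8-connected components of the mask, with sub-pixel outer contours."""
    labels = measure.label(mask, connectivity=2)
    blobs: list[Blob] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        # trace the outer contour on a padded crop so find_contours closes it
        r0, c0, r1, c1 = region.bbox
        crop = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=float)
        crop[rr - r0 + 1, cc - c0 + 1] = 1.0
        contours = measure.find_contours(crop, 0.5)
        outer = max(contours, key=len)  # (row, col) in crop coords
        contour_xy = np.stack(
            [outer[:, 1] + c0 - 1, outer[:, 0] + r0 - 1], axis=1
        )
        cy, cx = region.centroid
        blobs.append(
            Blob(
                frame_index=frame_index,
                pixels=region.coords.copy(),
                outer_contour=contour_xy,
                centroid=(cx, cy),
                area_px=int(region.area),
                bbox=region.bbox,
            )
        )
    return blobs


def blob_mask(blob: Blob, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[blob.pixels[:, 0], blob.pixels[:, 1]] = True
    return m
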