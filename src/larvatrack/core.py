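"""Shared primitives: regions of interest, frame sequences, calibration."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

DARK_ON_LIGHT = "dark_on_light"
LIGHT_ON_DARK = "light_on_dark"


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest, in pixels."""

    x0: int
    y0: int
    x1: int  # exclusive
    y1: int  # exclusive

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.y0 : self.y1, self.x0 : self.x1] = True
        return m

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest (dish), centre and radius in pixels."""

    cx: float
    cy: float
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius**2


ROI = RectROI | CircleROI


class FrameSequence(Sequence[np.ndarray]):
    """Indexable stack of greyscale frames.

    Frames may be held in memory (``from_array``) or produced lazily by a
    renderer so long scenes never materialize at once.
    """

    def __init__(
        self,
        n_frames: int,
        shape: tuple[int, int],
        fps: float,
        getter: Callable[[int], np.ndarray],
    ):
        if n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        self._n = int(n_frames)
        self.shape = (int(shape[0]), int(shape[1]))
        self.fps = float(fps)
        self._getter = getter

    @classmethod
    def from_array(cls, stack: np.ndarray, fps: float) -> "FrameSequence":
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise ValueError("expected (T, H, W) array")
        return cls(stack.shape[0], stack.shape[1:], fps, lambda i: stack[i])

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> np.ndarray:
        if not 0 <= i < self._n:
            raise IndexError(i)
        return self._getter(i)

    def __iter__(self) -> Iterator[np.ndarray]:
        for i in range(self._n):
            yield self._getter(i)

    def materialize(self) -> np.ndarray:
        return np.stack([self[i] for i in range(self._n)])


def px_to_mm(points_px: np.ndarray, mm_per_px: float, img_height: int) -> np.ndarray:
    """Map pixel (x, y) to a y-up mm frame (row 0 is the top of the image)."""
    pts = np.asarray(points_px, dtype=float).copy()
    pts[..., 1] = (img_height - 1) - pts[..., 1]
    return pts * mm_per_px


def mm_to_px(points_mm: np.ndarray, mm_per_px: float, img_height: int) -> np.ndarray:
    pts = np.asarray(points_mm, dtype=float) / mm_per_px
    pts[..., 1] = (img_height - 1) - pts[..., 1]
    return pts
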