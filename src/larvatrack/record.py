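"""Per-identity track records: the pose time series consumed by the behavioural layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TrackRecord:
    """Time series of poses for one preserved identity.

    Spines are stored tail-first (index 0 = tail tip, index 11 = head tip)
    in a y-up millimetre frame. ``frames`` may contain gaps where the animal
    was inside an unresolved collision.
    """

    track_id: int
    frames: np.ndarray  # (T,) int frame indices, strictly increasing
    spine_mm: np.ndarray  # (T, 12, 2)
    fps: float
    contour24_mm: np.ndarray | None = None  # (T, 24, 2)
    body_length_mm: np.ndarray | None = None  # (T,)
    width_mm: np.ndarray | None = None
    area_mm2: np.ndarray | None = None
    perimeter_mm: np.ndarray | None = None
    valid: np.ndarray | None = None  # (T,) bool
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.spine_mm = np.asarray(self.spine_mm, dtype=float)
        if self.spine_mm.shape[1:] != (12, 2):
            raise ValueError("spine_mm must have shape (T, 12, 2)")
        if self.body_length_mm is None:
            seg = np.linalg.norm(np.diff(self.spine_mm, axis=1), axis=2)
            self.body_length_mm = seg.sum(axis=1)
        if self.valid is None:
            self.valid = np.ones(len(self.frames), dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_frames(self) -> int:
        """Number of frames with a valid pose (gaps excluded)."""
        return int(np.count_nonzero(self.valid))

    @property
    def head_mm(self) -> np.ndarray:
        return self.spine_mm[:, 11]

    @property
    def tail_mm(self) -> np.ndarray:
        return self.spine_mm[:, 0]

    @property
    def midpoint_mm(self) -> np.ndarray:
        """Sixth spine point (1-based), the defined body midpoint."""
        return self.spine_mm[:, 5]

    def head_vector(self) -> np.ndarray:
        """Vector spine point 9 -> 11 (1-based)."""
        return self.spine_mm[:, 10] - self.spine_mm[:, 8]

    def tail_vector(self) -> np.ndarray:
        """Vector spine point 2 -> 6 (1-based)."""
        return self.spine_mm[:, 5] - self.spine_mm[:, 1]

    def mean_body_length(self) -> float:
        return float(np.nanmean(np.asarray(self.body_length_mm)[self.valid]))

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "frame": self.frames,
            "larva_id": np.full(self.n_frames, self.track_id),
            "time_s": self.frames / self.fps,
        }
        for i in range(12):
            cols[f"spine{i + 1}_x"] = self.spine_mm[:, i, 0]
            cols[f"spine{i + 1}_y"] = self.spine_mm[:, i, 1]
        if self.contour24_mm is not None:
            for i in range(24):
                cols[f"contour{i + 1}_x"] = self.contour24_mm[:, i, 0]
                cols[f"contour{i + 1}_y"] = self.contour24_mm[:, i, 1]
        cols["body_length_mm"] = self.body_length_mm
        for name in ("width_mm", "area_mm2", "perimeter_mm"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        cols["valid"] = self.valid
        return pd.DataFrame(cols)
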