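"""Per-blob shape reconstruction: smoothing-spline contour, endpoints, spine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .core import px_to_mm
from .segmentation import Blob

N_CONTOUR = 200
N_SPINE = 12
N_CONTOUR_OUT = 24
MIN_ENDPOINT_SEPARATION = 30  # contour indices along the 200-point cycle


class ContourError(ValueError):
    pass


@dataclass
class ReconstructedContour:
    points: np.ndarray  # (200, 2) (x, y) px, closed, arc-length spaced
    curvature: np.ndarray  # (200,) signed, convex positive


@dataclass
class LarvaPose:
    """Single-frame pose; spine index 0 is one tip, index 11 the other.

    Which tip is the head is decided later by the track-level vote; until
    then the orientation is arbitrary but frame-consistent.
    """

    valid: bool
    spine_mm: np.ndarray | None = None  # (12, 2)
    contour24_mm: np.ndarray | None = None  # (24, 2)
    body_length_mm: float = np.nan
    width_mm: float = np.nan
    area_mm2: float = np.nan
    perimeter_mm: float = np.nan
    spine_px: np.ndarray | None = None  # (12, 2), raster coords
    tip_px: np.ndarray | None = None  # (2, 2): endpoint A and B positions
    meta: dict = field(default_factory=dict)

    @property
    def head_vector(self) -> np.ndarray:
        return self.spine_mm[10] - self.spine_mm[8]

    @property
    def tail_vector(self) -> np.ndarray:
        return self.spine_mm[5] - self.spine_mm[1]


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(np.vstack([points, points[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    tt = np.linspace(0, total, n, endpoint=False)
    closed = np.vstack([points, points[:1]])
    return np.stack([np.interp(tt, cum, closed[:, d]) for d in (0, 1)], axis=1)


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to n points equidistant in arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return np.repeat(points[:1], n, axis=0)
    tt = np.linspace(0, cum[-1], n)
    return np.stack([np.interp(tt, cum, points[:, d]) for d in (0, 1)], axis=1)


def reconstruct_contour(blob: Blob, smooth_px: float = 0.3) -> ReconstructedContour:
    """Fit a periodic cubic smoothing spline to the raw blob contour.

    The spline is resampled to 200 points equidistant in arc length;
    curvature comes analytically from the spline derivatives.
    """
    raw = np.asarray(blob.outer_contour, dtype=float)
    if len(raw) and np.allclose(raw[0], raw[-1]):
        raw = raw[:-1]
    if len(raw) < 8:
        raise ContourError("contour has fewer than 8 vertices")
    # thin out duplicate/near-duplicate vertices that break splprep
    keep = np.ones(len(raw), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(raw, axis=0), axis=1) > 1e-9
    raw = raw[keep]
    if len(raw) < 8 or np.ptp(raw[:, 0]) < 1e-6 or np.ptp(raw[:, 1]) < 1e-6:
        raise ContourError("degenerate contour")
    s = len(raw) * smooth_px**2
    try:
        tck, _ = interpolate.splprep([raw[:, 0], raw[:, 1]], per=1, s=s)
    except Exception as exc:  # pragma: no cover - scipy failure paths vary
        raise ContourError(str(exc)) from exc

    # dense evaluation -> arc-length parameterization
    ud = np.linspace(0, 1, max(1000, 4 * len(raw)), endpoint=False)
    xd, yd = interpolate.splev(ud, tck)
    dense = np.stack([xd, yd], axis=1)
    seg = np.linalg.norm(np.diff(np.vstack([dense, dense[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, cum[-1], N_CONTOUR, endpoint=False)
    u_eq = np.interp(targets, cum, np.append(ud, 1.0))

    x, y = interpolate.splev(u_eq, tck)
    dx, dy = interpolate.splev(u_eq, tck, der=1)
    ddx, ddy = interpolate.splev(u_eq, tck, der=2)
    denom = (dx**2 + dy**2) ** 1.5
    denom[denom < 1e-12] = 1e-12
    curvature = (dx * ddy - dy * ddx) / denom
    points = np.stack([x, y], axis=1)
    # normalize sign so convex regions are positive regardless of winding:
    # on a simple closed curve the curvature sign agrees with the winding,
    # and convex arcs dominate, so flip if the median sign is negative
    if np.median(np.sign(curvature[np.abs(curvature) > 1e-9])) < 0:
        curvature = -curvature
    return ReconstructedContour(points, curvature)


def _circular_moving_average(x: np.ndarray, width: int = 5, passes: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    out = x.copy()
    for _ in range(passes):
        padded = np.concatenate([out[-(width // 2):], out, out[: width // 2]])
        out = np.convolve(padded, kernel, mode="valid")
    return out


def find_endpoints(
    contour: ReconstructedContour, min_separation: int = MIN_ENDPOINT_SEPARATION
) -> tuple[int, int] | None:
    """Indices of the two largest smoothed-curvature maxima, or None.

    Returns None (endpoint failure) for near-circular blobs without two
    separated curvature peaks.
    """
    k = _circular_moving_average(contour.curvature)
    k_max = k.max()
    if k_max <= 0 or k_max < 2.0 * max(np.median(k), 1e-12):
        return None  # curvature peaks indistinct from the bulk: circle-like
    prev = np.roll(k, 1)
    nxt = np.roll(k, -1)
    maxima = np.where((k > prev) & (k >= nxt))[0]
    if len(maxima) < 2:
        return None
    order = maxima[np.argsort(k[maxima])[::-1]]
    a = int(order[0])
    n = len(k)
    # rasterized tips can fork into two adjacent curvature peaks; prefer the
    # candidate whose separation from the first endpoint approaches the
    # antipode, weighting curvature by sin(pi * separation / n)
    best_b, best_score = None, -np.inf
    for b in order[1:]:
        d = abs(int(b) - a)
        d = min(d, n - d)
        if d < min_separation:
            continue
        score = k[b] * np.sin(np.pi * d / n)
        if score > best_score:
            best_b, best_score = int(b), score
    if best_b is None:
        return None
    return (a, best_b) if a < best_b else (best_b, a)


def compute_pose(
    contour: ReconstructedContour,
    endpoints: tuple[int, int] | None,
    mm_per_px: float,
    img_height: int | None = None,
    n_arc_samples: int = 200,
) -> LarvaPose:
    """Spine as the midline of arc-paired contour points, plus shape metrics."""
    if endpoints is None:
        return LarvaPose(valid=False)
    ia, ib = endpoints
    pts = contour.points
    n = len(pts)
    arc1 = pts[np.arange(ia, ib + 1) % n]
    arc2 = pts[np.concatenate([np.arange(ib, n), np.arange(0, ia + 1)]) % n][::-1]
    # both arcs now run from endpoint A to endpoint B
    s1 = resample_polyline(arc1, n_arc_samples)
    s2 = resample_polyline(arc2, n_arc_samples)
    midline = (s1 + s2) / 2.0
    pair_dist = np.linalg.norm(s1 - s2, axis=1)
    width_px = float(pair_dist.max())

    spine_px = resample_polyline(midline, N_SPINE)
    body_length_px = float(
        np.linalg.norm(np.diff(spine_px, axis=0), axis=1).sum()
    )
    if body_length_px <= 0:
        return LarvaPose(valid=False)

    contour24_px = _resample_closed(np.roll(pts, -ia, axis=0), N_CONTOUR_OUT)
    closed = np.vstack([pts, pts[:1]])
    perimeter_px = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    x, y = pts[:, 0], pts[:, 1]
    area_px = float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2)

    def to_mm(p):
        if img_height is None:
            return p * mm_per_px
        return px_to_mm(p, mm_per_px, img_height)

    return LarvaPose(
        valid=True,
        spine_mm=to_mm(spine_px),
        contour24_mm=to_mm(contour24_px),
        body_length_mm=body_length_px * mm_per_px,
        width_mm=width_px * mm_per_px,
        area_mm2=area_px * mm_per_px**2,
        perimeter_mm=perimeter_px * mm_per_px,
        spine_px=spine_px,
        tip_px=np.stack([pts[ia], pts[ib]]),
    )


def pose_from_blob(
    blob: Blob, mm_per_px: float, img_height: int | None = None
) -> LarvaPose:
    """Convenience pipeline: contour -> endpoints -> pose; invalid on failure."""
    try:
        rc = reconstruct_contour(blob)
    except ContourError:
        return LarvaPose(valid=False)
    ep = find_endpoints(rc)
    pose = compute_pose(rc, ep, mm_per_px, img_height)
    pose.meta["contour"] = rc
    return pose
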