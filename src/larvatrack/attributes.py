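"""Per-larva behavioural attributes, delta/peak values and binned series."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import TrackEvents
from .record import TrackRecord

#: the 30 attributes fed to the random-forest layer
RF_ATTRIBUTES = [
    "bending_angle",
    "abs_bending_angle",
    "cv_abs_bending_angle",
    "hv_angular_speed",
    "abs_hv_angular_speed",
    "cv_abs_hv_angular_speed",
    "hv_angular_acceleration",
    "tv_angular_speed",
    "abs_tv_angular_speed",
    "cv_abs_tv_angular_speed",
    "tv_angular_acceleration",
    "is_angle",
    "abs_is_angle",
    "cv_abs_is_angle",
    "hc_rate",
    "hc_angle",
    "abs_hc_angle",
    "cv_abs_hc_angle",
    "head_forward_velocity",
    "cv_head_forward_velocity",
    "tail_forward_velocity",
    "cv_tail_forward_velocity",
    "is_distance_bl",
    "cv_is_distance",
    "is_interval",
    "cv_is_interval",
    "is_speed_bl",
    "cv_is_speed",
    "distance_travelled_bl",
    "distance_from_start_bl",
]


@dataclass(frozen=True)
class StimulusContext:
    odour_mm: tuple[float, float]
    near_far_cutoff_mm: float = 60.0
    orientation_cutoff_deg: float = 90.0
    # Table 4 words the HC reorientation as after-minus-before but glosses
    # positive as "towards the odour"; before-minus-after matches the gloss
    reorientation_before_minus_after: bool = True

    def __post_init__(self):
        if self.near_far_cutoff_mm <= 0 or self.orientation_cutoff_deg <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class AttributeRecord:
    track_id: int
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def get(self, key: str, default=np.nan) -> float:
        return self.values.get(key, default)


def coefficient_of_variation(samples) -> float:
    """100 x sample SD / mean. NaN (undefined) for n < 2 or zero mean."""
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    m = x.mean()
    if abs(m) < 1e-12:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


def _signed_angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle from u to v, positive when v lies clockwise (to the right) of u."""
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return -np.degrees(np.arctan2(cross, dot))


def compute_attributes(
    track: TrackRecord,
    events: TrackEvents,
    stimulus: StimulusContext | None = None,
) -> AttributeRecord:
    """Means over the observation period of the full attribute catalogue.

    Distances and speeds are reported in body lengths using the larva's mean
    body length; mm variants are kept where defined. Odour-relative fields
    are present only when a stimulus is given.
    """
    rec = AttributeRecord(track.track_id)
    out = rec.values
    s = events.series
    if s.empty:
        rec.flags["series"] = "too short"
        return rec
    ok = s.valid
    bl = s.mean_body_length_mm
    fps = s.fps
    duration_s = track.n_frames / fps

    def mean(x):
        return float(np.nanmean(x[ok])) if np.any(ok) else float("nan")

    out["body_length_mm"] = bl
    out["bending_angle"] = mean(s.bending_angle_deg)
    out["abs_bending_angle"] = mean(np.abs(s.bending_angle_deg))
    out["cv_abs_bending_angle"] = coefficient_of_variation(
        np.abs(s.bending_angle_deg[ok])
    )
    out["hv_angular_speed"] = mean(s.hv_angular_speed_deg_s)
    out["abs_hv_angular_speed"] = mean(np.abs(s.hv_angular_speed_deg_s))
    out["cv_abs_hv_angular_speed"] = coefficient_of_variation(
        np.abs(s.hv_angular_speed_deg_s[ok])
    )
    out["hv_angular_acceleration"] = mean(s.hv_angular_accel_deg_s2)
    out["tv_angular_speed"] = mean(s.tv_angular_speed_deg_s)
    out["abs_tv_angular_speed"] = mean(np.abs(s.tv_angular_speed_deg_s))
    out["cv_abs_tv_angular_speed"] = coefficient_of_variation(
        np.abs(s.tv_angular_speed_deg_s[ok])
    )
    out["tv_angular_acceleration"] = mean(s.tv_angular_accel_deg_s2)

    out["midpoint_speed_mm"] = mean(s.midpoint_speed_mm_s)
    out["midpoint_speed_bl"] = mean(s.midpoint_speed_bl_s)
    out["cv_midpoint_speed"] = coefficient_of_variation(s.midpoint_speed_mm_s[ok])
    out["head_forward_velocity"] = mean(s.head_forward_velocity_bl_s)
    out["cv_head_forward_velocity"] = coefficient_of_variation(
        s.head_forward_velocity_bl_s[ok]
    )
    out["tail_forward_velocity"] = mean(s.tail_forward_velocity_bl_s)
    out["cv_tail_forward_velocity"] = coefficient_of_variation(
        s.tail_forward_velocity_bl_s[ok]
    )

    # inter-step attributes
    if events.cycles:
        dist_mm = np.array([c.distance_mm for c in events.cycles])
        interval = np.array([c.interval_s for c in events.cycles])
        speed_mm = np.array([c.speed_mm_s for c in events.cycles])
        out["is_distance_mm"] = float(dist_mm.mean())
        out["is_distance_bl"] = float((dist_mm / bl).mean())
        out["cv_is_distance"] = coefficient_of_variation(dist_mm)
        out["is_interval"] = float(interval.mean())
        out["cv_is_interval"] = coefficient_of_variation(interval)
        out["is_speed_mm"] = float(speed_mm.mean())
        out["is_speed_bl"] = float((speed_mm / bl).mean())
        out["cv_is_speed"] = coefficient_of_variation(speed_mm)
    else:
        rec.flags["is"] = "no steps"
    if len(events.steps) >= 2:
        hv = s.hv_angle_deg
        is_angles = []
        for a, b in zip(events.steps, events.steps[1:]):
            # hv_angle is CCW-positive; left orientation change is positive
            is_angles.append(hv[b.frame] - hv[a.frame])
        is_angles = np.asarray(is_angles)
        out["is_angle"] = float(is_angles.mean())
        out["abs_is_angle"] = float(np.abs(is_angles).mean())
        out["cv_abs_is_angle"] = coefficient_of_variation(np.abs(is_angles))

    # head-cast attributes
    out["hc_rate"] = len(events.hcs) / duration_s
    if events.hcs:
        hc_angles = np.array([h.hc_angle_deg for h in events.hcs])
        out["hc_angle"] = float(hc_angles.mean())
        out["abs_hc_angle"] = float(np.abs(hc_angles).mean())
        out["cv_abs_hc_angle"] = coefficient_of_variation(np.abs(hc_angles))
    else:
        rec.flags["hc"] = "no head casts"

    # path attributes
    mid = s.midpoint_mm[ok]
    if len(mid) >= 2:
        path = float(np.linalg.norm(np.diff(mid, axis=0), axis=1).sum())
        out["distance_travelled_bl"] = path / bl
        out["distance_from_start_bl"] = float(
            np.linalg.norm(mid - mid[0], axis=1).max() / bl
        )

    if stimulus is not None:
        _odour_attributes(rec, track, events, stimulus)
    return rec


def _odour_attributes(
    rec: AttributeRecord,
    track: TrackRecord,
    events: TrackEvents,
    stim: StimulusContext,
) -> None:
    out = rec.values
    s = events.series
    ok = s.valid
    odour = np.asarray(stim.odour_mm, dtype=float)
    spine = s.spine_smooth_mm

    tv = spine[:, 5] - spine[:, 1]
    hv = spine[:, 10] - spine[:, 8]
    bearing = _signed_angle_between(tv, odour - spine[:, 0])
    heading = _signed_angle_between(hv, odour - spine[:, 8])

    out["bearing_angle"] = float(np.nanmean(bearing[ok]))
    out["abs_bearing_angle"] = float(np.nanmean(np.abs(bearing[ok])))
    out["heading_angle"] = float(np.nanmean(heading[ok]))
    out["abs_heading_angle"] = float(np.nanmean(np.abs(heading[ok])))
    out["distance_from_odour_mm"] = float(
        np.nanmean(np.linalg.norm(s.midpoint_mm[ok] - odour, axis=1))
    )

    toward = np.abs(bearing) < stim.orientation_cutoff_deg
    fps = s.fps
    t_toward = np.count_nonzero(toward & ok) / fps
    t_away = np.count_nonzero(~toward & ok) / fps
    n_hc_toward = sum(1 for h in events.hcs if toward[h.start_frame])
    n_hc_away = sum(1 for h in events.hcs if not toward[h.start_frame])
    rate_toward = n_hc_toward / t_toward if t_toward > 0 else np.nan
    rate_away = n_hc_away / t_away if t_away > 0 else np.nan
    denom = rate_toward + rate_away
    out["hc_rate_modulation"] = (
        float((rate_away - rate_toward) / denom)
        if np.isfinite(denom) and denom > 0
        else float("nan")
    )

    speeds_toward = [
        c.speed_mm_s for c in events.cycles if toward[c.start_frame]
    ]
    speeds_away = [
        c.speed_mm_s for c in events.cycles if not toward[c.start_frame]
    ]
    if speeds_toward and speeds_away:
        st, sa = float(np.mean(speeds_toward)), float(np.mean(speeds_away))
        out["is_speed_modulation"] = (st - sa) / (st + sa) if st + sa > 0 else np.nan
    else:
        rec.flags["is_speed_modulation"] = "one side has no cycles"

    if events.hcs:
        reorient = []
        for h in events.hcs:
            before = abs(heading[h.start_frame])
            after = abs(heading[h.end_frame])
            if stim.reorientation_before_minus_after:
                reorient.append(before - after)
            else:
                reorient.append(after - before)
        out["hc_reorientation"] = float(np.mean(reorient))


# --------------------------------------------------------------------------- #
# frame-level attribute series, delta values, peaks, binning
# --------------------------------------------------------------------------- #

_FRAME_SERIES = {
    "midpoint_speed_mm": "midpoint_speed_mm_s",
    "midpoint_speed_bl": "midpoint_speed_bl_s",
    "tail_forward_velocity": "tail_forward_velocity_bl_s",
    "head_forward_velocity": "head_forward_velocity_bl_s",
    "bending_angle": "bending_angle_deg",
    "hv_angular_speed": "hv_angular_speed_deg_s",
    "tv_angular_speed": "tv_angular_speed_deg_s",
}


def attribute_series(events: TrackEvents, attribute: str) -> np.ndarray:
    """Per-frame series of a named attribute (NaN on invalid frames)."""
    s = events.series
    if attribute in _FRAME_SERIES:
        x = np.asarray(getattr(s, _FRAME_SERIES[attribute]), dtype=float).copy()
    elif attribute == "abs_bending_angle":
        x = np.abs(s.bending_angle_deg).astype(float)
    elif attribute == "abs_hv_angular_speed":
        x = np.abs(s.hv_angular_speed_deg_s).astype(float)
    elif attribute == "abs_tv_angular_speed":
        x = np.abs(s.tv_angular_speed_deg_s).astype(float)
    elif attribute == "hc_frame":
        x = np.zeros(len(s.time_s))
        for h in events.hcs:
            x[h.start_frame : h.end_frame + 1] = 1.0
    else:
        raise KeyError(f"no per-frame series for attribute {attribute!r}")
    x[~s.valid] = np.nan
    return x


def _window_mean(x: np.ndarray, t: np.ndarray, lo: float, hi: float) -> float:
    sel = (t >= lo) & (t < hi)
    vals = x[sel]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def delta_values(
    events: TrackEvents,
    interval_during: tuple[float, float],
    interval_before: tuple[float, float],
    attribute: str,
) -> float:
    """Mean of the attribute during one interval minus during another."""
    x = attribute_series(events, attribute)
    t = events.series.time_s
    return _window_mean(x, t, *interval_during) - _window_mean(x, t, *interval_before)


def peak_values(
    events: TrackEvents, switch_time_s: float, attribute: str, half_s: float = 5.0
) -> float:
    """Mean over +-half_s around the switch minus the mean of the two flanks."""
    x = attribute_series(events, attribute)
    t = events.series.time_s
    centre = _window_mean(x, t, switch_time_s - half_s, switch_time_s + half_s)
    sel = ((t >= switch_time_s - 2 * half_s) & (t < switch_time_s - half_s)) | (
        (t >= switch_time_s + half_s) & (t < switch_time_s + 2 * half_s)
    )
    vals = x[sel]
    vals = vals[np.isfinite(vals)]
    flank = float(vals.mean()) if len(vals) else float("nan")
    return centre - flank


@dataclass
class BinnedSeries:
    bin_centres_s: np.ndarray
    mean: np.ndarray
    ci95_half: np.ndarray
    n: np.ndarray


def bin_series(
    tracks_events: list[TrackEvents],
    attribute: str,
    bin_s: float = 2.0,
    align: str = "clock",
    switch_direction: str = "to_backward",
) -> BinnedSeries:
    """Mean and 95% CI of the attribute per time bin, across animals.

    ``align='to_switch'`` shifts each animal's time origin to its first
    switch of the requested direction and drops animals without one. For
    ``attribute='hc_frame'`` the bin value is the fraction of HC frames.
    """
    if not tracks_events:
        raise ValueError("need at least one track")
    per_track: list[tuple[np.ndarray, np.ndarray]] = []
    for ev in tracks_events:
        t = ev.series.time_s.astype(float)
        if align == "to_switch":
            sw = [s for s in ev.switches if s.direction == switch_direction]
            if not sw:
                continue
            t = t - sw[0].time_s
        elif align != "clock":
            raise ValueError("align must be 'clock' or 'to_switch'")
        per_track.append((t, attribute_series(ev, attribute)))
    if not per_track:
        raise ValueError("no animal performed the requested switch")

    lo = min(t.min() for t, _ in per_track)
    hi = max(t.max() for t, _ in per_track)
    edges = np.arange(math.floor(lo / bin_s) * bin_s, hi + bin_s, bin_s)
    centres = edges[:-1] + bin_s / 2
    means = np.full(len(centres), np.nan)
    ci = np.full(len(centres), np.nan)
    counts = np.zeros(len(centres), dtype=int)
    for b in range(len(centres)):
        vals = []
        for t, x in per_track:
            sel = (t >= edges[b]) & (t < edges[b + 1])
            v = x[sel]
            v = v[np.isfinite(v)]
            if len(v):
                vals.append(v.mean())
        if vals:
            vals = np.asarray(vals)
            counts[b] = len(vals)
            means[b] = vals.mean()
            sem = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
            ci[b] = 1.96 * sem
    return BinnedSeries(centres, means, ci, counts)


def orientation_change_histogram(
    tracks_events: list[TrackEvents],
    window_s: float = 10.0,
    bracket_deg: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of absolute body-orientation change across switches.

    Per switch with full flanking windows, the mean tail-vector direction
    over the window before is compared with the window after; returns
    (bracket_edges_deg, percentage_per_bracket).
    """
    changes = []
    for ev in tracks_events:
        s = ev.series
        t = s.time_s
        ang = np.radians(s.tv_angle_deg)
        for sw in ev.switches:
            before = (t >= sw.time_s - window_s) & (t < sw.time_s)
            after = (t > sw.time_s) & (t <= sw.time_s + window_s)
            if t.min() > sw.time_s - window_s or t.max() < sw.time_s + window_s:
                continue  # truncated window: skip the switch
            if not (before.any() and after.any()):
                continue

            def mean_dir(sel):
                return math.atan2(
                    float(np.mean(np.sin(ang[sel]))), float(np.mean(np.cos(ang[sel])))
                )

            d = abs(math.degrees(mean_dir(after) - mean_dir(before)))
            d = d % 360.0
            changes.append(360.0 - d if d > 180.0 else d)
    edges = np.arange(0.0, 180.0 + bracket_deg, bracket_deg)
    if not changes:
        return edges, np.zeros(len(edges) - 1)
    hist, _ = np.histogram(changes, bins=edges)
    return edges, 100.0 * hist / len(changes)
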