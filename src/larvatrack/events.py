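"""Event layer: smoothing, velocities, head casts, runs, steps, switches.

Sign conventions (y-up mm frame): the bending angle is positive when the
larva bends to the left of its tail vector; angular speeds of the head and
tail vectors are positive for movement to the right (clockwise), so a right
head cast is an interval of angular speed above +threshold and a left head
cast one below -threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .record import TrackRecord


@dataclass(frozen=True)
class EventConfig:
    hc_threshold_deg_s: float = 35.0
    tv_discard_deg_s: float = 45.0
    step_min_speed_mm_s: float = 0.6
    run_exclusion_s: float = 1.5
    smooth_window_s: float = 0.3
    switch_persistence_s: float = 1.0
    switch_speed_floor_bl_s: float = 0.1

    def __post_init__(self):
        for name in (
            "hc_threshold_deg_s",
            "tv_discard_deg_s",
            "step_min_speed_mm_s",
            "run_exclusion_s",
            "smooth_window_s",
            "switch_persistence_s",
            "switch_speed_floor_bl_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MotionSeries:
    """Per-frame kinematic series for one oriented track."""

    fps: float
    time_s: np.ndarray
    valid: np.ndarray  # (T,) bool
    empty: bool = False
    mean_body_length_mm: float = np.nan
    midpoint_mm: np.ndarray | None = None  # smoothed (T, 2)
    midpoint_speed_mm_s: np.ndarray | None = None
    midpoint_speed_bl_s: np.ndarray | None = None
    head_forward_velocity_bl_s: np.ndarray | None = None
    tail_forward_velocity_mm_s: np.ndarray | None = None
    tail_forward_velocity_bl_s: np.ndarray | None = None
    hv_angle_deg: np.ndarray | None = None  # unwrapped CCW-positive angle
    tv_angle_deg: np.ndarray | None = None
    hv_angular_speed_deg_s: np.ndarray | None = None  # right positive
    tv_angular_speed_deg_s: np.ndarray | None = None
    hv_angular_accel_deg_s2: np.ndarray | None = None
    tv_angular_accel_deg_s2: np.ndarray | None = None
    bending_angle_deg: np.ndarray | None = None  # left positive
    spine_smooth_mm: np.ndarray | None = None


@dataclass
class HCInterval:
    start_frame: int
    end_frame: int  # inclusive
    side: str  # 'left' | 'right'
    hc_angle_deg: float  # bending angle at end minus at start


@dataclass
class StepEvent:
    frame: int
    time_s: float
    tail_velocity_mm_s: float


@dataclass
class ISCycle:
    start_frame: int
    end_frame: int
    interval_s: float
    distance_mm: float  # midpoint path length between the two steps
    speed_mm_s: float  # mean midpoint speed over the cycle
    cycle_class: str = "normal"  # 'normal' | 'stumble'
    n_minima: int = 1


@dataclass
class SwitchEvent:
    frame: int
    time_s: float
    direction: str  # 'to_backward' | 'to_forward'


def _signed_angle_deg(v: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(v[:, 1], v[:, 0]))


def _unwrap_deg(a: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(a)))


def smooth_and_differentiate(
    track: TrackRecord, cfg: EventConfig | None = None, fps: float | None = None
) -> MotionSeries:
    """Boxcar-smooth the spine and derive velocity/angle series.

    Velocities are per-frame displacements projected on the unit head/tail
    vectors times fps; angular speeds are central differences of unwrapped
    vector angles, sign-flipped so clockwise (rightward) is positive.
    """
    cfg = cfg or EventConfig()
    fps = fps or track.fps
    n = track.n_frames
    t = track.frames / fps
    win = max(1, int(round(cfg.smooth_window_s * fps)))
    if n < max(win, 5):
        return MotionSeries(fps=fps, time_s=t, valid=np.zeros(n, bool), empty=True)

    spine = uniform_filter1d(track.spine_mm, size=win, axis=0, mode="nearest")
    bl = np.linalg.norm(np.diff(spine, axis=1), axis=2).sum(axis=1)
    mean_bl = float(np.mean(bl[track.valid])) if track.valid.any() else float(np.mean(bl))

    head = spine[:, 10] - spine[:, 8]  # spine point 9 -> 11
    tail = spine[:, 5] - spine[:, 1]  # spine point 2 -> 6
    head_u = head / np.maximum(np.linalg.norm(head, axis=1, keepdims=True), 1e-12)
    tail_u = tail / np.maximum(np.linalg.norm(tail, axis=1, keepdims=True), 1e-12)

    def forward_velocity(point: np.ndarray, unit: np.ndarray) -> np.ndarray:
        disp = np.gradient(point, axis=0)
        return np.einsum("ij,ij->i", disp, unit) * fps

    tail_v_mm = forward_velocity(spine[:, 0], tail_u)
    head_v_mm = forward_velocity(spine[:, 11], head_u)

    mid = spine[:, 5]
    mid_speed = np.linalg.norm(np.gradient(mid, axis=0), axis=1) * fps

    hv_angle = _unwrap_deg(_signed_angle_deg(head))
    tv_angle = _unwrap_deg(_signed_angle_deg(tail))
    # CCW (left) increases the math angle; rightward-positive means negated
    hv_speed = -np.gradient(hv_angle) * fps
    tv_speed = -np.gradient(tv_angle) * fps
    hv_accel = np.gradient(hv_speed) * fps
    tv_accel = np.gradient(tv_speed) * fps

    # bending angle: tail vector vs midpoint->head vector, left positive
    mh = spine[:, 10] - spine[:, 5]
    cross = tail_u[:, 0] * mh[:, 1] - tail_u[:, 1] * mh[:, 0]
    dot = np.einsum("ij,ij->i", tail_u, mh)
    bending = np.degrees(np.arctan2(cross, dot))

    return MotionSeries(
        fps=fps,
        time_s=t,
        valid=track.valid.copy(),
        mean_body_length_mm=mean_bl,
        midpoint_mm=mid,
        midpoint_speed_mm_s=mid_speed,
        midpoint_speed_bl_s=mid_speed / mean_bl,
        head_forward_velocity_bl_s=head_v_mm / mean_bl,
        tail_forward_velocity_mm_s=tail_v_mm,
        tail_forward_velocity_bl_s=tail_v_mm / mean_bl,
        hv_angle_deg=hv_angle,
        tv_angle_deg=tv_angle,
        hv_angular_speed_deg_s=hv_speed,
        tv_angular_speed_deg_s=tv_speed,
        hv_angular_accel_deg_s2=hv_accel,
        tv_angular_accel_deg_s2=tv_accel,
        bending_angle_deg=bending,
        spine_smooth_mm=spine,
    )


def detect_head_casts(
    series: MotionSeries, steps: list[StepEvent], cfg: EventConfig | None = None
) -> list[HCInterval]:
    """Intervals of HV angular speed beyond the signed threshold.

    A candidate is discarded if the TV angular speed exceeds the TV limit at
    any frame inside it, or if two or more steps fall inside it.
    """
    cfg = cfg or EventConfig()
    if series.empty:
        return []
    w = series.hv_angular_speed_deg_s
    step_frames = np.array([s.frame for s in steps], dtype=int)
    out: list[HCInterval] = []
    for sign, side in ((1.0, "right"), (-1.0, "left")):
        above = sign * w > cfg.hc_threshold_deg_s
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = list(edges[above[edges + 1]] + 1)
        ends = list(edges[~above[edges + 1]])
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(w) - 1)
        for a, b in zip(starts, ends):
            if np.any(
                np.abs(series.tv_angular_speed_deg_s[a : b + 1]) > cfg.tv_discard_deg_s
            ):
                continue
            if np.count_nonzero((step_frames >= a) & (step_frames <= b)) >= 2:
                continue
            angle = series.bending_angle_deg[b] - series.bending_angle_deg[a]
            out.append(HCInterval(a, b, side, float(angle)))
    out.sort(key=lambda h: h.start_frame)
    return out


def classify_runs(
    hcs: list[HCInterval], n_frames: int, fps: float, cfg: EventConfig | None = None
) -> np.ndarray:
    """Boolean run mask: False inside HCs and within the exclusion margin."""
    cfg = cfg or EventConfig()
    mask = np.ones(n_frames, dtype=bool)
    margin = int(round(cfg.run_exclusion_s * fps))
    for hc in hcs:
        a = max(0, hc.start_frame - margin)
        b = min(n_frames - 1, hc.end_frame + margin)
        mask[a : b + 1] = False
    return mask


def detect_steps(
    series: MotionSeries,
    run_mask: np.ndarray | None = None,
    cfg: EventConfig | None = None,
) -> tuple[list[StepEvent], list[ISCycle]]:
    """Local maxima of tail forward velocity during runs, with the mm/s floor.

    Plateau maxima count once, at the first plateau frame. Consecutive steps
    with no run interruption between them define inter-step cycles.
    """
    cfg = cfg or EventConfig()
    if series.empty:
        return [], []
    v = series.tail_forward_velocity_mm_s
    n = len(v)
    if run_mask is None:
        run_mask = np.ones(n, dtype=bool)
    steps: list[StepEvent] = []
    for i in range(1, n - 1):
        if not run_mask[i] or v[i] < cfg.step_min_speed_mm_s:
            continue
        if v[i] <= v[i - 1]:
            continue
        # scan forward across any plateau of equal values
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and v[j + 1] < v[i]:
            steps.append(StepEvent(i, series.time_s[i], float(v[i])))

    cycles: list[ISCycle] = []
    for s0, s1 in zip(steps, steps[1:]):
        if not run_mask[s0.frame : s1.frame + 1].all():
            continue  # run interrupted between the two steps: not one cycle
        if np.any(v[s0.frame : s1.frame + 1] < 0):
            continue  # backward excursion inside: not one peristaltic cycle
        seg = series.midpoint_mm[s0.frame : s1.frame + 1]
        dist = float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())
        interval = (s1.frame - s0.frame) / series.fps
        speed = float(
            np.mean(series.midpoint_speed_mm_s[s0.frame : s1.frame + 1])
        )
        cycles.append(ISCycle(s0.frame, s1.frame, interval, dist, speed))
    return steps, cycles


def classify_stepping(
    cycles: list[ISCycle], series: MotionSeries
) -> list[ISCycle]:
    """Label each inter-step cycle normal (one velocity trough) or stumble (two+)."""
    v = series.tail_forward_velocity_mm_s
    for cyc in cycles:
        a, b = cyc.start_frame, cyc.end_frame
        inner = np.arange(a + 1, b)
        n_min = 0
        for i in inner:
            if v[i] < v[i - 1] and v[i] < v[i + 1]:
                n_min += 1
        cyc.n_minima = n_min
        cyc.cycle_class = "stumble" if n_min >= 2 else "normal"
    return cycles


def detect_switches(
    series: MotionSeries, cfg: EventConfig | None = None
) -> list[SwitchEvent]:
    """Forward/backward switches from the sustained sign of tail velocity.

    The velocity is averaged over the persistence window (so peristaltic
    troughs do not reset the criterion); a switch fires when the windowed
    mean crosses the signed floor, and directions alternate.
    """
    cfg = cfg or EventConfig()
    if series.empty:
        return []
    v = series.tail_forward_velocity_bl_s
    floor = cfg.switch_speed_floor_bl_s
    need = max(1, int(round(cfg.switch_persistence_s * series.fps)))
    vbar = uniform_filter1d(v, size=need, mode="nearest")
    state = "forward"
    events: list[SwitchEvent] = []
    for i in range(len(v)):
        if state == "forward" and vbar[i] < -floor:
            events.append(SwitchEvent(i, float(series.time_s[i]), "to_backward"))
            state = "backward"
        elif state == "backward" and vbar[i] > floor:
            events.append(SwitchEvent(i, float(series.time_s[i]), "to_forward"))
            state = "forward"
    return events


@dataclass
class TrackEvents:
    """Bundle of everything the attribute layer needs for one track."""

    series: MotionSeries
    steps: list[StepEvent]
    cycles: list[ISCycle]
    hcs: list[HCInterval]
    run_mask: np.ndarray
    switches: list[SwitchEvent]
    config: EventConfig = field(default_factory=EventConfig)


def analyse_track(track: TrackRecord, cfg: EventConfig | None = None) -> TrackEvents:
    """Full event pipeline.

    Steps are detected twice: a provisional pass (no run mask) feeds the HC
    multi-step discard rule; the final pass is restricted to run frames.
    """
    cfg = cfg or EventConfig()
    series = smooth_and_differentiate(track, cfg)
    if series.empty:
        return TrackEvents(
            series, [], [], [], np.zeros(track.n_frames, bool), [], cfg
        )
    provisional, _ = detect_steps(series, None, cfg)
    hcs = detect_head_casts(series, provisional, cfg)
    run_mask = classify_runs(hcs, track.n_frames, series.fps, cfg)
    steps, cycles = detect_steps(series, run_mask, cfg)
    cycles = classify_stepping(cycles, series)
    switches = detect_switches(series, cfg)
    return TrackEvents(series, steps, cycles, hcs, run_mask, switches, cfg)
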