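"""Synthetic larva scenes with frame-level ground truth.

Kinematically simulated larvae are rendered as tapered capsules onto a
uniform arena, so segmentation, pose extraction, tracking, collision
resolution and the event detectors can all be exercised without real video.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import DARK_ON_LIGHT, LIGHT_ON_DARK, CircleROI, FrameSequence, ROI, mm_to_px
from .record import TrackRecord


class OutOfBoundsError(ValueError):
    """A true spine left the arena."""


# --------------------------------------------------------------------------- #
# parameters and ground truth containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class LarvaKinematicParams:
    body_length_mm: float = 4.0
    peristaltic_period_s: float = 1.0
    stride_bl: float = 0.18  # distance per peristaltic cycle, in body lengths
    hc_rate_hz: float = 0.0
    hc_amplitude_deg: float = 40.0
    backward_episodes: tuple[tuple[float, float], ...] = ()
    rng_seed: int = 0
    # plumbing
    start_mm: tuple[float, float] = (0.0, 0.0)
    heading_deg: float = 0.0
    speed_osc_amp: float = 0.8  # fractional modulation of the axial speed
    length_osc_amp: float = 0.05  # peristaltic stretch/contraction of the body
    width_mm: float | None = None  # max body width; default body_length / 6
    hc_swing_s: float = 0.8
    hc_realign_s: float = 1.5
    confine: tuple[float, float, float] | None = None  # (cx, cy, radius) mm
    waypoints: tuple[tuple[float, float], ...] = ()  # (time_s, new_heading_deg)
    waypoint_turn_rate_deg_s: float = 60.0  # bounded turn rate toward waypoints

    def __post_init__(self):
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be positive")
        if self.peristaltic_period_s <= 0:
            raise ValueError("peristaltic_period_s must be positive")
        eps = sorted(self.backward_episodes)
        for a, b in eps:
            if b <= a:
                raise ValueError(f"bad backward episode ({a}, {b})")
        for (_, b), (a2, _) in zip(eps, eps[1:]):
            if a2 < b:
                raise ValueError("backward episodes overlap")

    @property
    def max_width_mm(self) -> float:
        return self.width_mm if self.width_mm is not None else self.body_length_mm / 6.0


@dataclass
class HCTruth:
    start_s: float
    end_s: float
    side: str  # 'left' | 'right'
    amplitude_deg: float
    detectable: bool  # peak HV angular speed exceeds the 35 deg/s threshold


@dataclass
class CollisionTruth:
    participants: tuple[int, ...]
    start_frame: int
    end_frame: int  # inclusive

    def duration_s(self, fps: float) -> float:
        return (self.end_frame - self.start_frame + 1) / fps


@dataclass
class LarvaTruth:
    identity: int
    fps: float
    duration_s: float
    body_length_mm: float
    max_width_mm: float
    spine_mm: np.ndarray  # (T, 12, 2), tail index 0, head index 11
    axial_velocity_mm_s: np.ndarray  # (T,) signed along the body axis
    step_times_s: np.ndarray
    hc_intervals: list[HCTruth]
    switch_times: list[tuple[float, str]]  # (time_s, 'to_backward' | 'to_forward')
    head_index: int = 11

    @property
    def n_frames(self) -> int:
        return self.spine_mm.shape[0]


@dataclass
class GroundTruth:
    """Per-identity truth plus scene-level collision events."""

    larvae: dict[int, LarvaTruth]
    fps: float
    duration_s: float
    collision_events: list[CollisionTruth] = field(default_factory=list)

    @property
    def single(self) -> LarvaTruth:
        if len(self.larvae) != 1:
            raise ValueError("ground truth holds more than one identity")
        return next(iter(self.larvae.values()))


@dataclass
class SyntheticScene:
    frames: FrameSequence
    fps: float
    mm_per_px: float
    polarity: str
    arena: ROI
    ground_truth: GroundTruth
    img_shape: tuple[int, int]


# --------------------------------------------------------------------------- #
# kinematic simulation
# --------------------------------------------------------------------------- #


def _schedule_hcs(
    rng: np.random.Generator, p: LarvaKinematicParams, duration_s: float
) -> list[tuple[float, str]]:
    """Draw a Poisson number of head casts and place them without overlap."""
    n = rng.poisson(p.hc_rate_hz * duration_s)
    total = p.hc_swing_s + p.hc_realign_s
    placed: list[tuple[float, str]] = []
    lo, hi = 1.5, duration_s - total - 1.5
    if hi <= lo:
        return []
    forbidden = [(a - total - 1.0, b + 1.0) for a, b in p.backward_episodes]
    for _ in range(n):
        for _attempt in range(200):
            t0 = rng.uniform(lo, hi)
            if any(abs(t0 - q) < total + 0.5 for q, _ in placed):
                continue
            if any(a <= t0 <= b for a, b in forbidden):
                continue
            side = "left" if rng.random() < 0.5 else "right"
            placed.append((t0, side))
            break
    placed.sort()
    return placed


def simulate_track(
    params: LarvaKinematicParams, duration_s: float, fps: float, identity: int = 0
) -> GroundTruth:
    """Simulate one larva and return single-identity ground truth."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if fps < 8:
        raise ValueError("fps must be at least 8")
    p = params
    for a, b in p.backward_episodes:
        if a < 0 or b > duration_s:
            raise ValueError("backward episode outside scene duration")

    rng = np.random.default_rng(p.rng_seed)
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    L = p.body_length_mm
    period = p.peristaltic_period_s

    # signed axial speed with peristaltic oscillation; peaks at period/2 + k*period
    v_mean = p.stride_bl * L / period
    osc = 1.0 + p.speed_osc_amp * np.cos(2 * np.pi * (t - period / 2) / period)
    direction = np.ones(n_frames)
    for a, b in p.backward_episodes:
        direction[(t >= a) & (t < b)] = -1.0
    v = direction * v_mean * osc

    # head casts: articulation angle phi (deg, CCW/left positive) and the
    # heading increment that realigns the body under the displaced head
    hcs = _schedule_hcs(rng, p, duration_s)
    phi = np.zeros(n_frames)
    dtheta_hc = np.zeros(n_frames)
    hc_truth: list[HCTruth] = []
    A = p.hc_amplitude_deg
    peak_speed = A * np.pi / (2 * p.hc_swing_s)
    for t0, side in hcs:
        sgn = 1.0 if side == "left" else -1.0
        swing = (t >= t0) & (t < t0 + p.hc_swing_s)
        u = (t[swing] - t0) / p.hc_swing_s
        phi[swing] += sgn * A * (1 - np.cos(np.pi * u)) / 2
        realign = (t >= t0 + p.hc_swing_s) & (t < t0 + p.hc_swing_s + p.hc_realign_s)
        ur = (t[realign] - t0 - p.hc_swing_s) / p.hc_realign_s
        phi[realign] += sgn * A * (1 - ur)
        if np.any(realign):
            per_frame = sgn * A / np.count_nonzero(realign)
            dtheta_hc[realign] += per_frame
        detectable = peak_speed > 35.0
        if detectable:
            # |phi'| = A*pi/(2*swing) * sin(pi*u) crosses 35 deg/s at:
            u1 = math.asin(min(1.0, 35.0 / peak_speed)) / math.pi
            hc_truth.append(
                HCTruth(t0 + u1 * p.hc_swing_s, t0 + (1 - u1) * p.hc_swing_s, side, A, True)
            )
        else:
            hc_truth.append(HCTruth(t0, t0 + p.hc_swing_s, side, A, False))

    # integrate tail position and heading
    theta = np.empty(n_frames)
    pos = np.empty((n_frames, 2))
    th = math.radians(p.heading_deg)
    xy = np.array(p.start_mm, dtype=float)
    waypoints = {int(round(w_t * fps)): math.radians(h) for w_t, h in p.waypoints}
    steer_rate = math.radians(25.0) / fps
    wp_rate = math.radians(p.waypoint_turn_rate_deg_s) / fps
    wp_target: float | None = None
    for k in range(n_frames):
        if k in waypoints:
            wp_target = waypoints[k]
        if wp_target is not None:
            diff = (wp_target - th + np.pi) % (2 * np.pi) - np.pi
            if abs(diff) <= wp_rate:
                th = wp_target
                wp_target = None
            else:
                th += math.copysign(wp_rate, diff)
        th += math.radians(dtheta_hc[k])
        if p.confine is not None:
            cx, cy, rad = p.confine
            lead = xy + (L if direction[k] > 0 else 0.0) * np.array(
                [math.cos(th), math.sin(th)]
            )
            dvec = lead - (cx, cy)
            dist = np.hypot(*dvec)
            if dist > rad - (L + 2.0):
                target = math.atan2(cy - xy[1], cx - xy[0])
                diff = (target - th + np.pi) % (2 * np.pi) - np.pi
                th += np.clip(diff, -steer_rate, steer_rate)
        theta[k] = th
        xy = xy + (v[k] / fps) * np.array([math.cos(th), math.sin(th)])
        pos[k] = xy

    # build the 12-point spine: straight body along theta, anterior 3 points
    # rotated about spine point 9 (index 8) by the articulation angle; the
    # body stretches and contracts with the peristaltic cycle (anchored at
    # the tail, so tail kinematics are unaffected)
    stretch = 1.0 + p.length_osc_amp * np.sin(2 * np.pi * t / period)
    seg = L / 11.0
    offsets = np.arange(12) * seg
    u_vec = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (T, 2)
    spine = (
        pos[:, None, :]
        + (offsets[None, :] * stretch[:, None])[:, :, None] * u_vec[:, None, :]
    )
    phi_r = np.radians(phi)
    c, s = np.cos(phi_r), np.sin(phi_r)
    pivot = spine[:, 8]
    for idx in (9, 10, 11):
        rel = spine[:, idx] - pivot
        spine[:, idx, 0] = pivot[:, 0] + c * rel[:, 0] - s * rel[:, 1]
        spine[:, idx, 1] = pivot[:, 1] + s * rel[:, 0] + c * rel[:, 1]

    # ground-truth steps: crests of the forward axial velocity, outside
    # backward episodes and outside detectable-HC exclusion zones
    steps = []
    k = 0
    while True:
        ts = period / 2 + k * period
        k += 1
        if ts >= duration_s:
            break
        if any(a <= ts < b for a, b in p.backward_episodes):
            continue
        if v_mean * (1 + p.speed_osc_amp) < 0.6:
            continue
        if any(
            h.detectable and (h.start_s - 1.5) <= ts <= (h.end_s + 1.5) for h in hc_truth
        ):
            continue
        steps.append(ts)

    switches: list[tuple[float, str]] = []
    for a, b in sorted(p.backward_episodes):
        switches.append((a, "to_backward"))
        if b < duration_s:
            switches.append((b, "to_forward"))

    truth = LarvaTruth(
        identity=identity,
        fps=fps,
        duration_s=duration_s,
        body_length_mm=L,
        max_width_mm=p.max_width_mm,
        spine_mm=spine,
        axial_velocity_mm_s=v,
        step_times_s=np.asarray(steps),
        hc_intervals=hc_truth,
        switch_times=switches,
    )
    return GroundTruth({identity: truth}, fps, duration_s)


def merge_truths(truths: list[GroundTruth]) -> GroundTruth:
    fps = truths[0].fps
    dur = truths[0].duration_s
    larvae: dict[int, LarvaTruth] = {}
    for gt in truths:
        if gt.fps != fps or gt.duration_s != dur:
            raise ValueError("all tracks must share fps and duration")
        for k, vv in gt.larvae.items():
            if k in larvae:
                raise ValueError(f"duplicate identity {k}")
            larvae[k] = vv
    return GroundTruth(larvae, fps, dur)


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #


def _capsule_samples(spine_mm: np.ndarray, width_mm: float, n: int = 64):
    """Dense centre/radius samples along a spine polyline (in mm)."""
    seg = np.linalg.norm(np.diff(spine_mm, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        centres = np.repeat(spine_mm[:1], n, axis=0)
        uu = np.linspace(0, 1, n)
    else:
        uu = np.linspace(0, 1, n)
        centres = np.stack(
            [np.interp(uu * total, cum, spine_mm[:, d]) for d in (0, 1)], axis=1
        )
    radii = 0.5 * width_mm * np.sqrt(np.sin(np.pi * uu).clip(0.02))
    return centres, radii, uu


def _truth_overlap(a: LarvaTruth, b: LarvaTruth, frame: int) -> bool:
    ca, ra, _ = _capsule_samples(a.spine_mm[frame], a.max_width_mm, n=24)
    cb, rb, _ = _capsule_samples(b.spine_mm[frame], b.max_width_mm, n=24)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    return bool(np.any(d < ra[:, None] + rb[None, :]))


def detect_collision_truth(gt: GroundTruth) -> list[CollisionTruth]:
    """Geometric contact events between rendered bodies, grouped over time."""
    ids = sorted(gt.larvae)
    n_frames = gt.larvae[ids[0]].n_frames
    # pairwise contact per frame
    frame_groups: list[list[frozenset]] = []
    for f in range(n_frames):
        parent = {i: i for i in ids}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1 :]:
                la, lb = gt.larvae[a], gt.larvae[b]
                # cheap bbox reject before the capsule test
                da = np.linalg.norm(la.spine_mm[f].mean(0) - lb.spine_mm[f].mean(0))
                if da > (la.body_length_mm + lb.body_length_mm):
                    continue
                if _truth_overlap(la, lb, f):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[ra] = rb
        groups: dict[int, set] = {}
        for i in ids:
            groups.setdefault(find(i), set()).add(i)
        frame_groups.append([frozenset(g) for g in groups.values() if len(g) > 1])

    # link groups across consecutive frames when they share a participant
    events: list[dict] = []
    active: list[dict] = []
    for f, groups in enumerate(frame_groups):
        new_active = []
        for g in groups:
            merged = None
            for ev in active:
                if ev["members"] & g:
                    if merged is None:
                        merged = ev
                        ev["members"] |= g
                        ev["end"] = f
                    else:
                        merged["members"] |= ev["members"]
                        merged["start"] = min(merged["start"], ev["start"])
                        ev["dead"] = True
            if merged is None:
                merged = {"members": set(g), "start": f, "end": f}
            if merged not in new_active:
                new_active.append(merged)
        for ev in active:
            if ev.get("dead"):
                continue
            if ev["end"] < f and ev not in new_active:
                events.append(ev)
        active = new_active
    events.extend(ev for ev in active if not ev.get("dead"))
    return sorted(
        (
            CollisionTruth(tuple(sorted(ev["members"])), ev["start"], ev["end"])
            for ev in events
        ),
        key=lambda e: e.start_frame,
    )


def render_scene(
    tracks: list[GroundTruth],
    arena: ROI,
    noise_sd: float = 2.0,
    polarity: str = DARK_ON_LIGHT,
    mm_per_px: float = 0.1,
    img_shape: tuple[int, int] | None = None,
    head_shade: float = 0.25,
    seed: int = 0,
) -> SyntheticScene:
    """Render ground-truth tracks to a lazy frame sequence.

    Each larva is a tapered capsule along its true spine; the anterior part
    is shaded darker by ``head_shade`` (set 0 to disable) so the head/tail
    brightness vote has signal, as for real larvae.
    """
    gt = merge_truths(tracks) if len(tracks) > 1 else replace_events(tracks[0])
    if img_shape is None:
        if isinstance(arena, CircleROI):
            side = int(math.ceil(2 * arena.radius + 20))
            img_shape = (side, side)
        else:
            img_shape = (arena.y1 + 10, arena.x1 + 10)
    h, w = img_shape
    arena_mask = arena.mask(img_shape)

    if polarity == DARK_ON_LIGHT:
        bg_val, body_val = 200.0, 70.0
    elif polarity == LIGHT_ON_DARK:
        bg_val, body_val = 40.0, 180.0
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    head_val = body_val * (1 - head_shade) if polarity == DARK_ON_LIGHT else (
        body_val - head_shade * (body_val - bg_val) * 0.8
    )

    larvae = list(gt.larvae.values())
    # precompute pixel-space spines; validate bounds once
    spines_px = {}
    for lv in larvae:
        sp = mm_to_px(lv.spine_mm, mm_per_px, h)
        spines_px[lv.identity] = sp
        ys = np.round(sp[..., 1]).astype(int).clip(0, h - 1)
        xs = np.round(sp[..., 0]).astype(int).clip(0, w - 1)
        inside = arena_mask[ys, xs]
        if not inside.all():
            f_bad = int(np.argmin(inside.all(axis=1)))
            raise OutOfBoundsError(
                f"larva {lv.identity} spine leaves the arena at frame {f_bad}"
            )

    n_frames = larvae[0].n_frames

    def render_frame(f: int) -> np.ndarray:
        img = np.full((h, w), bg_val, dtype=np.float32)
        for lv in larvae:
            centres, radii, uu = _capsule_samples(
                spines_px[lv.identity][f], lv.max_width_mm / mm_per_px
            )
            rmax = radii.max()
            x0 = max(0, int(centres[:, 0].min() - rmax - 2))
            x1 = min(w, int(centres[:, 0].max() + rmax + 3))
            y0 = max(0, int(centres[:, 1].min() - rmax - 2))
            y1 = min(h, int(centres[:, 1].max() + rmax + 3))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d = np.sqrt(
                (xx[..., None] - centres[:, 0]) ** 2
                + (yy[..., None] - centres[:, 1]) ** 2
            ) - radii  # (py, px, n_samples)
            best = np.argmin(d, axis=2)
            inside = np.take_along_axis(d, best[..., None], axis=2)[..., 0] <= 0
            u_best = uu[best]
            shade = np.clip((u_best - 0.7) / 0.3, 0, 1)
            vals = body_val + (head_val - body_val) * shade
            patch = img[y0:y1, x0:x1]
            patch[inside] = vals[inside]
        if noise_sd > 0:
            rng = np.random.default_rng([seed, f])
            img = img + rng.normal(0, noise_sd, img.shape)
        return np.clip(img, 0, 255).astype(np.uint8)

    frames = FrameSequence(n_frames, img_shape, gt.fps, render_frame)
    gt.collision_events = detect_collision_truth(gt)
    return SyntheticScene(frames, gt.fps, mm_per_px, polarity, arena, gt, img_shape)


def replace_events(gt: GroundTruth) -> GroundTruth:
    return GroundTruth(dict(gt.larvae), gt.fps, gt.duration_s, [])


# --------------------------------------------------------------------------- #
# canned scenarios
# --------------------------------------------------------------------------- #

COLLISION_KINDS = (
    "ephemeral_2",
    "long_2_distinct_sizes",
    "long_2_identical",
    "triple",
    "quadruple",
)

_ARENA_MM = 50.0  # square-ish arena, circle radius 24 mm at centre


def _default_arena(mm_per_px: float) -> tuple[CircleROI, tuple[int, int]]:
    side = int(round(_ARENA_MM / mm_per_px))
    c = (side - 1) / 2
    return CircleROI(c, c, 24.0 / mm_per_px), (side, side)


def _crossing_pair(
    kind: str, fps: float, duration_s: float
) -> list[GroundTruth]:
    """Two larvae whose paths cross at the arena centre at t_cross."""
    t_cross = duration_s * 0.45
    centre = np.array([_ARENA_MM / 2, _ARENA_MM / 2])
    speed = 0.72  # mm/s target mean speed

    def launch(ident, L, heading_deg, t_at_centre):
        period = 1.0
        stride = speed * period / L
        h = math.radians(heading_deg)
        # tail reaches the centre slightly after the midbody does; aim midbody
        start = centre - (speed * t_at_centre + L / 2) * np.array(
            [math.cos(h), math.sin(h)]
        )
        p = LarvaKinematicParams(
            body_length_mm=L,
            stride_bl=stride,
            hc_rate_hz=0.0,
            start_mm=tuple(start),
            heading_deg=heading_deg,
            rng_seed=ident,
            confine=(_ARENA_MM / 2, _ARENA_MM / 2, 22.0),
        )
        return simulate_track(p, duration_s, fps, identity=ident)

    if kind == "ephemeral_2":
        return [launch(0, 4.0, 0.0, t_cross), launch(1, 4.0, 90.0, t_cross)]
    if kind == "long_2_distinct_sizes":
        return [launch(0, 4.0, 0.0, t_cross), launch(1, 5.2, 8.0, t_cross)]
    if kind == "long_2_identical":
        return [launch(0, 4.0, 0.0, t_cross), launch(1, 4.0, 8.0, t_cross)]
    if kind == "triple":
        return [
            launch(0, 4.0, 0.0, t_cross),
            launch(1, 4.4, 120.0, t_cross),
            launch(2, 4.8, 240.0, t_cross),
        ]
    if kind == "quadruple":
        return [
            launch(0, 4.0, 0.0, t_cross),
            launch(1, 4.4, 90.0, t_cross),
            launch(2, 4.8, 180.0, t_cross),
            launch(3, 5.2, 270.0, t_cross),
        ]
    raise ValueError(f"unknown scenario kind {kind!r}")


def make_collision_scenario(
    kind: str,
    seed: int = 0,
    fps: float = 16.0,
    mm_per_px: float = 0.1,
    duration_s: float = 45.0,
    noise_sd: float = 2.0,
    polarity: str = DARK_ON_LIGHT,
) -> SyntheticScene:
    """Build a scene containing exactly one collision of the requested class."""
    if kind not in COLLISION_KINDS:
        raise ValueError(f"kind must be one of {COLLISION_KINDS}")
    arena, shape = _default_arena(mm_per_px)
    tracks = _crossing_pair(kind, fps, duration_s)
    return render_scene(
        tracks,
        arena,
        noise_sd=noise_sd,
        polarity=polarity,
        mm_per_px=mm_per_px,
        img_shape=shape,
        seed=seed,
    )


def make_benchmark_scene(
    seed: int = 0,
    fps: float = 16.0,
    mm_per_px: float = 0.1,
    duration_s: float = 190.0,
    noise_sd: float = 2.0,
) -> SyntheticScene:
    """Six larvae, four programmed pairwise collisions (2 ephemeral, 2 long
    with >= 25% body-length differences), scripted to stay inside the arena.
    """
    arena, shape = _default_arena(mm_per_px)
    speed = 0.4

    def scripted(ident, L, start, heading, waypoints):
        period = 1.0
        p = LarvaKinematicParams(
            body_length_mm=L,
            stride_bl=speed * period / L,
            hc_rate_hz=0.0,
            start_mm=start,
            heading_deg=heading,
            waypoints=tuple(waypoints),
            rng_seed=seed * 101 + ident,
        )
        return simulate_track(p, duration_s, fps, identity=ident)

    # scripted waypoint choreography (dead-reckoned at 0.4 mm/s):
    #   collision A: larvae 0/1, shallow 8 deg crossing near (16, 25) ~t=45,
    #                long (> 8 s), body lengths 4.0 vs 5.2 (30% apart)
    #   collision B: larvae 2/3, shallow crossing near (34, 25) ~t=110,
    #                long, body lengths 3.6 vs 4.8 (33% apart)
    #   collisions C/D: larvae 4/5 (5.0 vs 3.8, 32% apart) cross at ~t=60
    #                and re-cross at ~t=90; both exceed 8 s at this speed, so
    #                they exercise the statistical resolver as well
    #   brief (< 8 s) brushes also occur: (0,1) ~t=19, (0,5) ~t=80,
    #                (1,2) ~t=166, (2,5) ~t=179 -- shape-model territory
    tracks = [
        scripted(0, 4.0, (6.0, 35.0), 270.0,
                 [(25.0, 0.0), (72.0, 310.0), (107.0, 215.0), (142.0, 135.0)]),
        scripted(1, 5.2, (10.5, 14.8), 120.0,
                 [(25.0, 8.0), (75.0, 45.0), (108.0, 170.0), (150.0, 250.0)]),
        scripted(2, 3.6, (24.9, 11.2), 90.0,
                 [(50.0, 340.0), (95.0, 180.0), (160.0, 90.0)]),
        scripted(3, 4.8, (17.8, 41.9), 290.0,
                 [(50.0, 10.0), (95.0, 188.0), (140.0, 270.0), (175.0, 0.0)]),
        scripted(4, 5.0, (38.9, 8.86), 180.0,
                 [(40.0, 45.0), (80.0, 135.0), (130.0, 225.0), (170.0, 315.0)]),
        scripted(5, 3.8, (22.2, 3.3), 20.0,
                 [(40.0, 135.0), (84.0, 45.0), (133.0, 180.0)]),
    ]
    return render_scene(
        tracks,
        arena,
        noise_sd=noise_sd,
        mm_per_px=mm_per_px,
        img_shape=shape,
        seed=seed,
    )


# --------------------------------------------------------------------------- #
# bridges and export
# --------------------------------------------------------------------------- #


def truth_to_track(lv: LarvaTruth, fps: float | None = None) -> TrackRecord:
    """Build a TrackRecord directly from ground truth (bypassing the tracker)."""
    fps = fps or lv.fps
    n = lv.n_frames
    return TrackRecord(
        track_id=lv.identity,
        frames=np.arange(n),
        spine_mm=lv.spine_mm.copy(),
        fps=fps,
        width_mm=np.full(n, lv.max_width_mm),
        area_mm2=np.full(n, lv.body_length_mm * lv.max_width_mm * 0.8),
        perimeter_mm=np.full(n, 2 * lv.body_length_mm + np.pi * lv.max_width_mm / 2),
    )


def save_scene(scene: SyntheticScene, outdir) -> None:
    """Write PNG frames plus a JSON ground-truth file."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(outdir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(scene.frames):
        iio.imwrite(out / "frames" / f"frame_{i:06d}.png", frame)
    gt = scene.ground_truth
    payload = {
        "fps": scene.fps,
        "mm_per_px": scene.mm_per_px,
        "polarity": scene.polarity,
        "duration_s": gt.duration_s,
        "collision_events": [
            {
                "participants": list(ev.participants),
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
            }
            for ev in gt.collision_events
        ],
        "larvae": {
            str(k): {
                "body_length_mm": lv.body_length_mm,
                "spine_mm": lv.spine_mm.tolist(),
                "head_index": lv.head_index,
                "step_times_s": lv.step_times_s.tolist(),
                "hc_intervals": [
                    [h.start_s, h.end_s, h.side, h.amplitude_deg, h.detectable]
                    for h in lv.hc_intervals
                ],
                "switch_times": lv.switch_times,
            }
            for k, lv in gt.larvae.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
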