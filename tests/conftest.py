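import numpy as np
import pytest

from larvatrack.record import TrackRecord
from larvatrack.synth import (
    LarvaKinematicParams,
    make_benchmark_scene,
    make_collision_scenario,
    simulate_track,
    truth_to_track,
)
from larvatrack.trackgraph import TrackerConfig, track_video


def straight_track(
    n_frames: int = 200,
    fps: float = 10.0,
    speed_mm_s: float = 2.0,
    body_length_mm: float = 4.0,
    heading_deg: float = 0.0,
) -> TrackRecord:
    """Rigid larva translating along its own axis at constant speed."""
    th = np.radians(heading_deg)
    u = np.array([np.cos(th), np.sin(th)])
    t = np.arange(n_frames) / fps
    tail = t[:, None] * speed_mm_s * u
    offsets = np.linspace(0, body_length_mm, 12)
    spine = tail[:, None, :] + offsets[None, :, None] * u
    return TrackRecord(0, np.arange(n_frames), spine, fps)


def scripted_velocity_track(
    v_mm_s: np.ndarray, fps: float = 10.0, body_length_mm: float = 4.0
) -> TrackRecord:
    """Larva moving along +x with a prescribed axial velocity profile."""
    v = np.asarray(v_mm_s, dtype=float)
    x = np.concatenate([[0.0], np.cumsum(v[1:] + v[:-1]) / (2 * fps)])
    tail = np.stack([x, np.zeros_like(x)], axis=1)
    offsets = np.linspace(0, body_length_mm, 12)
    spine = tail[:, None, :] + np.stack(
        [offsets, np.zeros_like(offsets)], axis=1
    )[None, :, :]
    return TrackRecord(0, np.arange(len(v)), spine, fps)


@pytest.fixture(scope="session")
def hc_backward_truth():
    p = LarvaKinematicParams(
        hc_rate_hz=0.1, rng_seed=3, backward_episodes=((40.0, 50.0),)
    )
    return simulate_track(p, 60, 16).single


@pytest.fixture(scope="session")
def ephemeral_scene():
    return make_collision_scenario("ephemeral_2", duration_s=45.0)


@pytest.fixture(scope="session")
def ephemeral_tracked(ephemeral_scene):
    sc = ephemeral_scene
    cfg = TrackerConfig(
        mm_per_px=sc.mm_per_px, fps=sc.fps, polarity=sc.polarity, roi=sc.arena
    )
    return track_video(sc.frames, cfg)


@pytest.fixture(scope="session")
def benchmark_scene():
    return make_benchmark_scene()


@pytest.fixture(scope="session")
def benchmark_tracked(benchmark_scene):
    sc = benchmark_scene
    cfg = TrackerConfig(
        mm_per_px=sc.mm_per_px, fps=sc.fps, polarity=sc.polarity, roi=sc.arena
    )
    return track_video(sc.frames, cfg)


@pytest.fixture(scope="session")
def benchmark_tracked_unresolved(benchmark_scene):
    sc = benchmark_scene
    cfg = TrackerConfig(
        mm_per_px=sc.mm_per_px,
        fps=sc.fps,
        polarity=sc.polarity,
        roi=sc.arena,
        resolve_collisions=False,
    )
    return track_video(sc.frames, cfg)


def match_track_to_truth(track: TrackRecord, ground_truth) -> tuple[int, float]:
    """(best-matching identity, purity of the per-frame nearest identity)."""
    ids = sorted(ground_truth.larvae)
    per = np.stack(
        [
            np.linalg.norm(
                ground_truth.larvae[i].spine_mm[track.frames, 5] - track.midpoint_mm,
                axis=1,
            )
            for i in ids
        ]
    )
    nearest = per.argmin(axis=0)
    modal = np.bincount(nearest).argmax()
    return ids[modal], float((nearest == modal).mean())
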