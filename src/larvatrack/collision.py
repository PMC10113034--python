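"""Identity restoration across collisions.

Two routes: a five-segment articulated shape model fitted frame-by-frame for
ephemeral two-larva collisions (or brief touches), and statistical
re-identification from size-related shape attributes for longer events.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

MAX_SHAPE_MODEL_DURATION_S = 8.0
STAT_MAX_FRAMES = 45
STAT_FACTOR = 1000.0


class OversizedCollisionError(ValueError):
    """Resolution refused: four or more animals involved."""


@dataclass
class CollisionEvent:
    participants_in: list  # identifiers of entering subtracks/nodes
    participants_out: list
    start_frame: int
    end_frame: int  # inclusive
    n_larvae: int
    kind: str = ""  # symmetric_2 | symmetric_3 | asymmetric | oversized

    def __post_init__(self):
        if not self.kind:
            if self.n_larvae >= 4:
                self.kind = "oversized"
            elif len(self.participants_in) == len(self.participants_out) == self.n_larvae:
                self.kind = f"symmetric_{self.n_larvae}"
            else:
                self.kind = "asymmetric"

    def duration_s(self, fps: float) -> float:
        return (self.end_frame - self.start_frame + 1) / fps


@dataclass
class ShapeModelState:
    """Articulated larva: anchor (tail end), orientation and 4 joint angles.

    Five equal segments; joint angles are deviations of each subsequent
    segment from the previous one, bounded to +-90 degrees. Segment lengths
    and width are frozen at collision entry.
    """

    anchor_px: np.ndarray  # (2,)
    orientation_deg: float
    joint_angles_deg: np.ndarray  # (4,)
    segment_len_px: float
    width_px: float

    def backbone(self) -> np.ndarray:
        pts = [np.asarray(self.anchor_px, dtype=float)]
        ang = math.radians(self.orientation_deg)
        for k in range(5):
            if k > 0:
                ang += math.radians(float(self.joint_angles_deg[k - 1]))
            pts.append(
                pts[-1] + self.segment_len_px * np.array([math.cos(ang), math.sin(ang)])
            )
        return np.stack(pts)

    @classmethod
    def from_spine(cls, spine_px: np.ndarray, width_px: float) -> "ShapeModelState":
        """Initialize from a 12-point spine (tail first)."""
        length = float(np.linalg.norm(np.diff(spine_px, axis=0), axis=1).sum())
        # 6 backbone knots at equal arc positions along the spine
        idx = np.linspace(0, 11, 6).round().astype(int)
        knots = spine_px[idx]
        segs = np.diff(knots, axis=0)
        angles = np.degrees(np.arctan2(segs[:, 1], segs[:, 0]))
        joints = np.clip(np.diff(angles), -90, 90)
        return cls(
            anchor_px=spine_px[0].astype(float).copy(),
            orientation_deg=float(angles[0]),
            joint_angles_deg=joints.astype(float),
            segment_len_px=length / 5.0,
            width_px=float(width_px),
        )


@dataclass
class AssignmentResult:
    resolved: bool
    mapping: dict | None = None  # participant_in -> participant_out
    method: str = ""  # 'shape_model' | 'statistical'
    evidence: dict = field(default_factory=dict)
    reason: str = ""


# --------------------------------------------------------------------------- #
# shape-model route
# --------------------------------------------------------------------------- #


class _Window:
    """Local boolean raster holding one frame's merged-blob neighbourhood."""

    def __init__(self, pix_lin: np.ndarray, img_shape: tuple[int, int], pad: int = 25):
        h, w = img_shape
        rr, cc = pix_lin // w, pix_lin % w
        self.r0 = max(0, int(rr.min()) - pad)
        self.c0 = max(0, int(cc.min()) - pad)
        self.mask = np.zeros(
            (int(rr.max()) - self.r0 + pad + 1, int(cc.max()) - self.c0 + pad + 1),
            dtype=bool,
        )
        self.mask[rr - self.r0, cc - self.c0] = True

    def without(self, other: np.ndarray) -> np.ndarray:
        residual = self.mask & ~other
        return residual if residual.any() else self.mask


def _silhouette_mask(state: ShapeModelState, window: _Window) -> np.ndarray:
    """Boolean silhouette of the model on the window's raster."""
    bb = state.backbone()
    seg = np.linalg.norm(np.diff(bb, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = 32
    uu = np.linspace(0, 1, n)
    cx = np.interp(uu * cum[-1], cum, bb[:, 0]) - window.c0
    cy = np.interp(uu * cum[-1], cum, bb[:, 1]) - window.r0
    radii = 0.5 * state.width_px * np.sqrt(np.sin(np.pi * uu).clip(0.02))
    h, w = window.mask.shape
    out = np.zeros((h, w), dtype=bool)
    rmax = radii.max()
    x0 = max(0, int(cx.min() - rmax - 1))
    x1 = min(w, int(cx.max() + rmax + 2))
    y0 = max(0, int(cy.min() - rmax - 1))
    y1 = min(h, int(cy.max() + rmax + 2))
    if x1 <= x0 or y1 <= y0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (
        (xx[..., None] - cx) ** 2 + (yy[..., None] - cy) ** 2 <= radii**2
    ).any(axis=2)
    out[y0:y1, x0:x1] = inside
    return out


def _fit_score(model: np.ndarray, target: np.ndarray) -> float:
    inter = int(np.count_nonzero(model & target))
    union = int(np.count_nonzero(model)) + int(np.count_nonzero(target)) - inter
    return inter / union if union else 0.0


def _refine_state(
    state: ShapeModelState,
    target: np.ndarray,
    window: "_Window",
    orient_range: float = 15.0,
    orient_step: float = 3.0,
    joint_range: float = 20.0,
    joint_step: float = 5.0,
    translate_px: int = 2,
    passes: int = 1,
) -> tuple[ShapeModelState, float]:
    """Grid search around the previous state, one parameter at a time.

    A full Cartesian grid over orientation x 4 joints is prohibitively
    large; coordinate descent over the same per-parameter grids reaches the
    same neighbourhood optimum for these small inter-frame moves.
    """

    def clone(st, **kw):
        return ShapeModelState(
            kw.get("anchor_px", st.anchor_px.copy()),
            kw.get("orientation_deg", st.orientation_deg),
            kw.get("joint_angles_deg", st.joint_angles_deg.copy()),
            st.segment_len_px,
            st.width_px,
        )

    best = clone(state)
    best_score = _fit_score(_silhouette_mask(best, window), target)
    for _ in range(passes):
        for dx in range(-translate_px, translate_px + 1):
            for dy in range(-translate_px, translate_px + 1):
                if dx == 0 and dy == 0:
                    continue
                cand = clone(best, anchor_px=best.anchor_px + (dx, dy))
                sc = _fit_score(_silhouette_mask(cand, window), target)
                if sc > best_score:
                    best, best_score = cand, sc
        for d in np.arange(-orient_range, orient_range + 1e-9, orient_step):
            if d == 0:
                continue
            cand = clone(best, orientation_deg=best.orientation_deg + d)
            sc = _fit_score(_silhouette_mask(cand, window), target)
            if sc > best_score:
                best, best_score = cand, sc
        for j in range(4):
            for d in np.arange(-joint_range, joint_range + 1e-9, joint_step):
                if d == 0:
                    continue
                ja = best.joint_angles_deg.copy()
                ja[j] = np.clip(ja[j] + d, -90, 90)
                cand = clone(best, joint_angles_deg=ja)
                sc = _fit_score(_silhouette_mask(cand, window), target)
                if sc > best_score:
                    best, best_score = cand, sc
    return best, best_score


def resolve_shape_model(
    event: CollisionEvent,
    entry_spines_px: dict,
    entry_widths_px: dict,
    collision_pixels: list[np.ndarray],
    img_shape: tuple[int, int],
    exit_centroids_px: dict,
    fps: float,
    fit_floor: float = 0.2,
) -> AssignmentResult:
    """Track the articulated models through the merged blob and match exits.

    ``collision_pixels`` holds, per collision frame, the linear pixel indices
    of the merged blob. Each frame, every participant's model is fitted to
    the residual obtained by removing the counterparts' previous-frame
    silhouettes; on exit the model centroids are matched to the outgoing
    blobs' centroids by nearest distance.
    """
    if event.duration_s(fps) >= MAX_SHAPE_MODEL_DURATION_S:
        return AssignmentResult(False, reason="too long for shape model")
    pids = list(entry_spines_px)
    states = {
        p: ShapeModelState.from_spine(
            np.asarray(entry_spines_px[p], float), entry_widths_px[p]
        )
        for p in pids
    }
    scores_log = {p: [] for p in pids}
    for pix in collision_pixels:
        window = _Window(pix, img_shape)
        sil = {p: _silhouette_mask(states[p], window) for p in pids}
        new_states = {}
        for p in pids:
            if len(pids) > 1:
                others = np.logical_or.reduce([sil[q] for q in pids if q != p])
                residual = window.without(others)
            else:
                residual = window.mask
            st, sc = _refine_state(states[p], residual, window)
            new_states[p] = st
            scores_log[p].append(sc)
        states = new_states

    low = {
        p: np.mean(np.asarray(scores_log[p]) < fit_floor) if scores_log[p] else 1.0
        for p in pids
    }
    if any(v > 0.25 for v in low.values()):
        return AssignmentResult(
            False, method="shape_model", evidence={"low_fit_fraction": low},
            reason="fit below floor",
        )

    out_ids = list(exit_centroids_px)
    model_cent = {p: states[p].backbone().mean(axis=0) for p in pids}
    best_map, best_cost = None, np.inf
    for perm in itertools.permutations(out_ids, len(pids)):
        cost = sum(
            np.linalg.norm(model_cent[p] - np.asarray(exit_centroids_px[o]))
            for p, o in zip(pids, perm)
        )
        if cost < best_cost:
            best_cost, best_map = cost, dict(zip(pids, perm))
    return AssignmentResult(
        True,
        mapping=best_map,
        method="shape_model",
        evidence={"mean_fit": {p: float(np.mean(scores_log[p])) for p in pids},
                  "exit_cost_px": float(best_cost)},
    )


# --------------------------------------------------------------------------- #
# statistical route
# --------------------------------------------------------------------------- #


def _first_pc_projection(groups: dict) -> tuple[dict, float]:
    """Joint z-scoring of the 4 shape features, projected on the first PC."""
    all_rows = np.vstack(list(groups.values()))
    mu = all_rows.mean(axis=0)
    sd = all_rows.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    z = (all_rows - mu) / sd
    _, svals, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    pc1 = vt[0]
    var_ratio = float(svals[0] ** 2 / np.sum(svals**2))
    out = {k: (np.asarray(v) - mu) / sd @ pc1 for k, v in groups.items()}
    return out, var_ratio


def _truncate(groups: dict, take_tail: bool, n: int) -> dict:
    return {k: (v[-n:] if take_tail else v[:n]) for k, v in groups.items()}


def resolve_statistical(
    event: CollisionEvent,
    features_in: dict,
    features_out: dict,
    max_frames: int = STAT_MAX_FRAMES,
    min_frames: int = 10,
    factor: float = STAT_FACTOR,
) -> AssignmentResult:
    """Mann-Whitney re-identification on the first PC of shape features.

    Every in->out bijection competes; the event is resolved iff every
    p-value of one bijection exceeds every p-value of each competing
    bijection by at least ``factor``.
    """
    if event.n_larvae >= 4:
        raise OversizedCollisionError(
            "refused: collisions of four or more animals are not resolved"
        )
    features_in = {k: np.asarray(v, dtype=float) for k, v in features_in.items()}
    features_out = {k: np.asarray(v, dtype=float) for k, v in features_out.items()}
    if len(features_in) != len(features_out):
        return AssignmentResult(False, reason="participant counts differ")
    n_min = min(len(v) for v in list(features_in.values()) + list(features_out.values()))
    if n_min < min_frames:
        return AssignmentResult(False, reason="insufficient frame history")
    n_use = min(n_min, max_frames)
    # frames adjacent to the collision: last n before entry, first n after exit
    fin = _truncate(features_in, True, n_use)
    fout = _truncate(features_out, False, n_use)
    proj, var_ratio = _first_pc_projection({**{("in", k): v for k, v in fin.items()},
                                            **{("out", k): v for k, v in fout.items()}})

    in_ids = list(fin)
    out_ids = list(fout)
    bijections = []
    for perm in itertools.permutations(out_ids):
        ps = {}
        for i, o in zip(in_ids, perm):
            _, p = mannwhitneyu(
                proj[("in", i)], proj[("out", o)], alternative="two-sided"
            )
            ps[(i, o)] = float(p)
        bijections.append((dict(zip(in_ids, perm)), ps))

    evidence = {
        "pc1_variance_ratio": var_ratio,
        "n_frames": n_use,
        "bijections": [
            {"mapping": {str(k): str(v) for k, v in m.items()},
             "p_values": {f"{a}->{b}": p for (a, b), p in ps.items()}}
            for m, ps in bijections
        ],
    }
    # a competing bijection may share correctly-matched pairs with the
    # winner; those shared pairs carry the same p-value on both sides, so
    # the factor comparison is made on the differing pairs only (for two
    # larvae, where bijections share nothing, this is exactly the
    # both-p-values-vs-both rule)
    for mapping, ps in bijections:
        ok = True
        for other_m, other_ps in bijections:
            if other_m is mapping:
                continue
            own = [p for pair, p in ps.items() if pair not in other_ps]
            rival = [p for pair, p in other_ps.items() if pair not in ps]
            if not own or not rival:
                continue
            if min(own) < factor * max(rival):
                ok = False
                break
        if ok:
            return AssignmentResult(
                True, mapping=mapping, method="statistical", evidence=evidence
            )
    return AssignmentResult(
        False, method="statistical", evidence=evidence, reason="margin below factor"
    )


def resolve_asymmetric(
    lost_pool: dict,
    reappeared,
    max_frames: int = STAT_MAX_FRAMES,
    min_frames: int = 10,
    factor: float = STAT_FACTOR,
) -> AssignmentResult:
    """Match a reappearing larva against the pool of previously lost ones.

    U-tests are run between the reappeared larva and every pool member, and
    pairwise among pool members; the best match must beat every other
    computed p-value by ``factor``.
    """
    if not lost_pool:
        return AssignmentResult(False, reason="no candidates")
    lost_pool = {k: np.asarray(v, dtype=float) for k, v in lost_pool.items()}
    reappeared = np.asarray(reappeared, dtype=float)
    n_min = min([len(reappeared)] + [len(v) for v in lost_pool.values()])
    if n_min < min_frames:
        return AssignmentResult(False, reason="insufficient frame history")
    n_use = min(n_min, max_frames)
    groups = {("pool", k): v[-n_use:] for k, v in lost_pool.items()}
    groups[("new", "_")] = reappeared[:n_use]
    proj, var_ratio = _first_pc_projection(groups)

    match_p = {}
    for k in lost_pool:
        _, p = mannwhitneyu(proj[("new", "_")], proj[("pool", k)], alternative="two-sided")
        match_p[k] = float(p)
    cross_p = []
    keys = list(lost_pool)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            _, p = mannwhitneyu(
                proj[("pool", keys[i])], proj[("pool", keys[j])], alternative="two-sided"
            )
            cross_p.append(float(p))

    best = max(match_p, key=match_p.get)
    rivals = [p for k, p in match_p.items() if k != best] + cross_p
    evidence = {
        "pc1_variance_ratio": var_ratio,
        "match_p": match_p,
        "pool_pairwise_p": cross_p,
    }
    if all(match_p[best] >= factor * p for p in rivals):
        return AssignmentResult(
            True, mapping={"reappeared": best}, method="statistical", evidence=evidence
        )
    return AssignmentResult(
        False, method="statistical", evidence=evidence, reason="margin below factor"
    )
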