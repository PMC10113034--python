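"""Blob matching, collision graph, larva-count LP, subtracks, orchestration."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import linprog

from . import collision as col
from .core import DARK_ON_LIGHT, FrameSequence, ROI
from .geometry import LarvaPose, pose_from_blob
from .record import TrackRecord
from .segmentation import Blob, build_background, extract_blobs, segment_frame

CATEGORIES = ("one_one", "one_one_partial", "one_N", "N_one", "N_M")


@dataclass(frozen=True)
class TrackerConfig:
    mm_per_px: float
    fps: float
    polarity: str = DARK_ON_LIGHT
    roi: ROI | None = None
    min_area_px: int = 40
    brightness_radius_px: int = 10
    endpoint_jump_bl: float = 0.5
    partial_overlap_frac: float = 0.5
    resolve_collisions: bool = True
    shape_fit_floor: float = 0.2
    stat_min_history: int = 10
    stat_max_frames: int = 45
    stat_factor: float = 1000.0


@dataclass
class OverlapMatch:
    old_index: int
    new_index: int
    overlap_px: int
    category: str = ""


def match_blobs(
    prev: list[Blob],
    curr: list[Blob],
    img_width: int,
    partial_frac: float = 0.5,
    min_edge_frac: float = 0.25,
) -> list[OverlapMatch]:
    """Pixel-overlap bipartite matching between consecutive frames.

    Each connected component of the overlap graph is classified as
    one_one / one_one_partial / one_N / N_one / N_M; a lone pair is partial
    when the overlap is below ``partial_frac`` of the smaller blob's area.

    Weak edges (overlap below ``min_edge_frac`` of the smaller blob) are
    pruned when both endpoints keep another edge: grazing contacts otherwise
    wire genuinely separate animals into one merge/split component.
    """
    pairs: list[OverlapMatch] = []
    keys_prev = [b.pixel_key(img_width) for b in prev]
    keys_curr = [b.pixel_key(img_width) for b in curr]
    adj_old: dict[int, set[int]] = {i: set() for i in range(len(prev))}
    adj_new: dict[int, set[int]] = {j: set() for j in range(len(curr))}
    for i, j in itertools.product(range(len(prev)), range(len(curr))):
        bo, bn = prev[i], curr[j]
        if (
            bo.bbox[2] < bn.bbox[0]
            or bn.bbox[2] < bo.bbox[0]
            or bo.bbox[3] < bn.bbox[1]
            or bn.bbox[3] < bo.bbox[1]
        ):
            continue
        ov = np.intersect1d(keys_prev[i], keys_curr[j], assume_unique=True).size
        if ov > 0:
            pairs.append(OverlapMatch(i, j, int(ov)))
            adj_old[i].add(j)
            adj_new[j].add(i)

    # prune weak edges, weakest first, without orphaning any blob
    for m in sorted(pairs, key=lambda m: m.overlap_px):
        smaller = min(prev[m.old_index].area_px, curr[m.new_index].area_px)
        if (
            m.overlap_px < min_edge_frac * smaller
            and len(adj_old[m.old_index]) > 1
            and len(adj_new[m.new_index]) > 1
        ):
            pairs.remove(m)
            adj_old[m.old_index].discard(m.new_index)
            adj_new[m.new_index].discard(m.old_index)

    # classify per connected component of the bipartite overlap graph
    for m in pairs:
        olds, news = _component(m.old_index, adj_old, adj_new)
        if len(olds) == 1 and len(news) == 1:
            smaller = min(prev[m.old_index].area_px, curr[m.new_index].area_px)
            m.category = (
                "one_one" if m.overlap_px >= partial_frac * smaller else "one_one_partial"
            )
        elif len(olds) == 1:
            m.category = "one_N"
        elif len(news) == 1:
            m.category = "N_one"
        else:
            m.category = "N_M"
    return pairs


def _component(seed_old: int, adj_old, adj_new) -> tuple[set[int], set[int]]:
    olds, news = {seed_old}, set()
    frontier_old = [seed_old]
    while frontier_old:
        nxt = []
        for i in frontier_old:
            for j in adj_old[i]:
                if j not in news:
                    news.add(j)
                    for i2 in adj_new[j]:
                        if i2 not in olds:
                            olds.add(i2)
                            nxt.append(i2)
        frontier_old = nxt
    return olds, news


@dataclass
class GraphNode:
    node_id: int
    start_frame: int
    end_frame: int
    parents: list[int] = field(default_factory=list)
    children: list[int] = field(default_factory=list)
    frames: list[int] = field(default_factory=list)
    poses: list[LarvaPose] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    pixel_sets: list[np.ndarray] = field(default_factory=list)  # linear indices
    count: int = 0  # larva count from the LP


@dataclass
class CollisionGraph:
    nodes: dict[int, GraphNode] = field(default_factory=dict)

    def add_edge(self, parent: int, child: int) -> None:
        self.nodes[parent].children.append(child)
        self.nodes[child].parents.append(parent)


class GraphBuilder:
    """Streaming collision-graph construction from per-frame matches."""

    def __init__(self):
        self.graph = CollisionGraph()
        self._next_id = 0
        self.active: dict[int, int] = {}  # blob index in current frame -> node id

    def _new_node(self, frame: int) -> GraphNode:
        node = GraphNode(self._next_id, frame, frame)
        self.graph.nodes[self._next_id] = node
        self._next_id += 1
        return node

    def step(self, frame: int, matches: list[OverlapMatch], n_curr: int) -> dict[int, int]:
        """Advance one frame; returns blob-index -> node-id for the new frame."""
        new_active: dict[int, int] = {}
        for m in matches:
            if m.category in ("one_one", "one_one_partial"):
                nid = self.active[m.old_index]
                self.graph.nodes[nid].end_frame = frame
                new_active[m.new_index] = nid
        # merge/split components: every child blob starts a fresh node with
        # edges from all old nodes in its overlap component
        seen_pairs = [m for m in matches if m.category in ("one_N", "N_one", "N_M")]
        if seen_pairs:
            adj_old: dict[int, set[int]] = {}
            adj_new: dict[int, set[int]] = {}
            for m in seen_pairs:
                adj_old.setdefault(m.old_index, set()).add(m.new_index)
                adj_new.setdefault(m.new_index, set()).add(m.old_index)
            done: set[int] = set()
            for m in seen_pairs:
                if m.old_index in done:
                    continue
                olds, news = _component(m.old_index, adj_old, adj_new)
                done |= olds
                parent_ids = sorted({self.active[i] for i in olds})
                for j in news:
                    child = self._new_node(frame)
                    for pid in parent_ids:
                        self.graph.add_edge(pid, child.node_id)
                    new_active[j] = child.node_id

        for j in range(n_curr):
            if j not in new_active:
                node = self._new_node(frame)
                new_active[j] = node.node_id
        self.active = new_active
        return new_active


def graph_edges(graph: CollisionGraph) -> list[tuple[int, int]]:
    return sorted(
        {(p, nid) for nid, node in graph.nodes.items() for p in node.parents}
    )


def solve_larva_counts(graph: CollisionGraph) -> dict[int, int]:
    """Minimum total larva count under parent/child conservation.

    Each edge carries an unknown flow of at least one larva; every node's
    count equals its total inflow (when it has parents) and its total
    outflow (when it has children), and is at least one. Minimizing the
    summed counts as a linear program over this network matrix yields an
    integral vertex solution (asserted, then rounded within 1e-6).

    This implies the per-node balance between total parent and child larvae
    and the floors |P_i|, |C_i|, 1 on every count.
    """
    ids = sorted(graph.nodes)
    pos = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    if n == 0:
        return {}
    edges = graph_edges(graph)
    m = len(edges)
    epos = {e: n + k for k, e in enumerate(edges)}
    cvec = np.concatenate([np.ones(n), np.zeros(m)])
    bounds = [(1, None)] * n + [(1, None)] * m
    a_eq, b_eq = [], []
    for nid in ids:
        node = graph.nodes[nid]
        if node.parents:
            row = np.zeros(n + m)
            row[pos[nid]] = 1.0
            for p in node.parents:
                row[epos[(p, nid)]] = -1.0
            a_eq.append(row)
            b_eq.append(0.0)
        if node.children:
            row = np.zeros(n + m)
            row[pos[nid]] = 1.0
            for c in node.children:
                row[epos[(nid, c)]] = -1.0
            a_eq.append(row)
            b_eq.append(0.0)
    res = linprog(
        c=cvec,
        A_eq=np.asarray(a_eq) if a_eq else None,
        b_eq=np.asarray(b_eq) if b_eq else None,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"larva-count LP infeasible: {res.message}")
    x = res.x[:n]
    if np.max(np.abs(x - np.round(x))) > 1e-6:
        raise RuntimeError("LP solution unexpectedly non-integral")
    counts = {nid: int(round(x[pos[nid]])) for nid in ids}
    for nid, c in counts.items():
        graph.nodes[nid].count = c
    return counts


# --------------------------------------------------------------------------- #
# subtracks and head/tail voting
# --------------------------------------------------------------------------- #


@dataclass
class Subtrack:
    node_id: int
    frames: np.ndarray
    spine_px: np.ndarray  # (T, 12, 2), consistently oriented within subtrack
    poses: list[LarvaPose]
    tip_brightness: np.ndarray  # (T, 2) mean brightness near spine[0]/spine[11]
    centroids: np.ndarray  # (T, 2) blob centroids, px
    head_end: str = "ambiguous"  # 'A' (= spine index 11), 'B', or 'ambiguous'

    def oriented_spines(self) -> np.ndarray:
        """Spines with index 11 = head (index 0 = tail) when votes decided B."""
        if self.head_end == "B":
            return self.spine_px[:, ::-1, :]
        return self.spine_px


def split_and_orient_subtracks(
    node: GraphNode, cfg: TrackerConfig
) -> list[Subtrack]:
    """Split a single-larva node where endpoint continuity breaks, then vote.

    Three votes per subtrack: darker mean tip brightness, larger total tip
    travel, and net motion away from the previous frame's centroid; the
    majority assigns the head (spine index 11). Ties stay ambiguous.
    """
    runs: list[list[int]] = []
    current: list[int] = []
    flipped: list[bool] = []
    cur_flip: list[bool] = []
    prev_pose = None
    prev_flip = False
    for k, pose in enumerate(node.poses):
        if pose is None or not pose.valid:
            if current:
                runs.append(current)
                flipped.append(cur_flip)
            current, cur_flip = [], []
            prev_pose = None
            continue
        if prev_pose is None:
            current, cur_flip = [k], [False]
            prev_flip = False
        else:
            limit = cfg.endpoint_jump_bl * pose.body_length_mm / cfg.mm_per_px
            p_tips = prev_pose.spine_px[[0, 11]]
            if prev_flip:
                p_tips = p_tips[::-1]
            tips = pose.spine_px[[0, 11]]
            same = max(np.linalg.norm(tips - p_tips, axis=1))
            swap = max(np.linalg.norm(tips[::-1] - p_tips, axis=1))
            if min(same, swap) > limit:
                runs.append(current)
                flipped.append(cur_flip)
                current, cur_flip = [k], [False]
                prev_flip = False
            else:
                # p_tips already carries the previous flip, so the new flip
                # is absolute: flip iff the swapped pairing is closer
                prev_flip = swap < same
                current.append(k)
                cur_flip.append(prev_flip)
        prev_pose = pose
    if current:
        runs.append(current)
        flipped.append(cur_flip)

    subtracks: list[Subtrack] = []
    for run, flips in zip(runs, flipped):
        spines = []
        brightness = []
        cents = []
        poses = []
        for k, fl in zip(run, flips):
            pose = node.poses[k]
            sp = pose.spine_px[::-1] if fl else pose.spine_px
            spines.append(sp)
            tb = pose.meta.get("tip_brightness", (np.nan, np.nan))
            brightness.append(tb[::-1] if fl else tb)
            cents.append(node.centroids[k])
            poses.append(pose)
        st = Subtrack(
            node_id=node.node_id,
            frames=np.asarray([node.frames[k] for k in run]),
            spine_px=np.asarray(spines),
            poses=poses,
            tip_brightness=np.asarray(brightness, dtype=float),
            centroids=np.asarray(cents, dtype=float),
        )
        st.head_end = _vote_head(st)
        subtracks.append(st)
    return subtracks


def _vote_head(st: Subtrack) -> str:
    """A = spine index 11 end, B = spine index 0 end.

    Tip trajectories are boxcar-smoothed before the motion votes so that
    frame-to-frame tip-localization jitter does not masquerade as travel.
    """
    votes_a = votes_b = 0
    win = min(7, len(st.frames))
    tip_a = uniform_filter1d(st.spine_px[:, 11], size=win, axis=0, mode="nearest")
    tip_b = uniform_filter1d(st.spine_px[:, 0], size=win, axis=0, mode="nearest")
    # each criterion abstains when its signal is within jitter of a tie,
    # instead of casting a coin-flip vote
    # vote 1: darker surroundings
    ba = np.nanmean(st.tip_brightness[:, 1])
    bb = np.nanmean(st.tip_brightness[:, 0])
    if np.isfinite(ba) and np.isfinite(bb) and abs(ba - bb) > 2.0:
        if ba < bb:
            votes_a += 1
        else:
            votes_b += 1
    # vote 2: larger total distance covered
    da = float(np.linalg.norm(np.diff(tip_a, axis=0), axis=1).sum())
    db = float(np.linalg.norm(np.diff(tip_b, axis=0), axis=1).sum())
    if abs(da - db) > 0.05 * max(da, db, 1e-9):
        if da > db:
            votes_a += 1
        else:
            votes_b += 1
    # vote 3: net motion away from the previous frame's centroid
    if len(st.frames) >= 2:
        prev_c = st.centroids[:-1]
        na = float(
            np.sum(
                np.linalg.norm(tip_a[1:] - prev_c, axis=1)
                - np.linalg.norm(tip_a[:-1] - prev_c, axis=1)
            )
        )
        nb = float(
            np.sum(
                np.linalg.norm(tip_b[1:] - prev_c, axis=1)
                - np.linalg.norm(tip_b[:-1] - prev_c, axis=1)
            )
        )
        if abs(na - nb) > 0.05 * (abs(na) + abs(nb) + 1e-9):
            if na > nb:
                votes_a += 1
            else:
                votes_b += 1
    if votes_a > votes_b:
        return "A"
    if votes_b > votes_a:
        return "B"
    return "ambiguous"


# --------------------------------------------------------------------------- #
# full pipeline
# --------------------------------------------------------------------------- #


@dataclass
class TrackingResult:
    tracks: list[TrackRecord]
    graph: CollisionGraph
    events: list[col.CollisionEvent]
    resolutions: list[col.AssignmentResult]
    report: dict


def _tip_brightness(frame: np.ndarray, pose: LarvaPose, radius: int) -> tuple[float, float]:
    h, w = frame.shape
    out = []
    for tip in (pose.spine_px[0], pose.spine_px[11]):
        x, y = tip
        x0, x1 = max(0, int(x - radius)), min(w, int(x + radius + 1))
        y0, y1 = max(0, int(y - radius)), min(h, int(y + radius + 1))
        if x1 <= x0 or y1 <= y0:
            out.append(np.nan)
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
        out.append(float(frame[y0:y1, x0:x1][disc].mean()))
    return out[1], out[0]  # (brightness at spine[11] side unused order: see meta)


def track_video(frames: FrameSequence, cfg: TrackerConfig) -> TrackingResult:
    """Segmentation -> geometry -> graph -> counts -> subtracks -> resolution."""
    n_frames = len(frames)
    h, w = frames.shape
    bg = build_background(frames)
    builder = GraphBuilder()
    prev_blobs: list[Blob] = []
    stats = {"n_frames": n_frames, "blobs": 0, "pose_failures": 0}

    for f in range(n_frames):
        img = frames[f]
        mask, degenerate = segment_frame(img, bg, cfg.polarity, cfg.roi)
        blobs = extract_blobs(mask, cfg.min_area_px, frame_index=f) if not degenerate else []
        stats["blobs"] += len(blobs)
        matches = match_blobs(prev_blobs, blobs, w, cfg.partial_overlap_frac) if f else []
        active = builder.step(f, matches, len(blobs))
        for j, blob in enumerate(blobs):
            node = builder.graph.nodes[active[j]]
            pose = pose_from_blob(blob, cfg.mm_per_px, h)
            if pose.valid:
                b11, b0 = _tip_brightness(img, pose, cfg.brightness_radius_px)
                pose.meta["tip_brightness"] = (b0, b11)
                pose.meta.pop("contour", None)
            else:
                stats["pose_failures"] += 1
            node.frames.append(f)
            node.poses.append(pose)
            node.centroids.append(blob.centroid)
            node.areas.append(blob.area_px)
            node.pixel_sets.append(blob.pixel_key(w))
            node.end_frame = f
        prev_blobs = blobs

    graph = builder.graph
    counts = solve_larva_counts(graph)

    single_nodes = [nid for nid, c in counts.items() if c == 1]
    multi_nodes = [nid for nid, c in counts.items() if c >= 2]
    subtracks: dict[int, list[Subtrack]] = {
        nid: split_and_orient_subtracks(graph.nodes[nid], cfg) for nid in single_nodes
    }

    events = _collect_events(graph, counts)
    resolutions: list[col.AssignmentResult] = []
    links: dict[int, int] = {}  # in-node -> out-node identity links
    rev_links: dict[int, int] = {}
    if cfg.resolve_collisions:
        for ev, cluster in sorted(events, key=lambda e: e[0].start_frame):
            res = _resolve_event(ev, cluster, graph, cfg, (h, w), rev_links)
            resolutions.append(res)
            if res.resolved and res.mapping:
                for a, b in res.mapping.items():
                    if isinstance(a, int):
                        links[a] = b
                        rev_links[b] = a

    tracks = _build_tracks(graph, single_nodes, subtracks, links, cfg, h)
    long_frames = sum(
        t.duration_frames for t in tracks if t.duration_frames >= n_frames / 2
    )
    all_frames = sum(t.duration_frames for t in tracks)
    report = {
        **stats,
        "n_nodes": len(graph.nodes),
        "n_single_nodes": len(single_nodes),
        "n_multi_nodes": len(multi_nodes),
        "n_events": len(events),
        "n_resolved": sum(r.resolved for r in resolutions),
        "events": [
            {
                "kind": ev.kind,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
                "n_larvae": ev.n_larvae,
            }
            for ev, _ in events
        ],
        "resolutions": [
            {"resolved": r.resolved, "method": r.method, "reason": r.reason}
            for r in resolutions
        ],
        "fraction_frames_in_long_tracks": (long_frames / all_frames) if all_frames else 0.0,
    }
    return TrackingResult(tracks, graph, [ev for ev, _ in events], resolutions, report)


def _collect_events(graph: CollisionGraph, counts: dict[int, int]):
    """Group connected multi-larva nodes into collision events."""
    multi = {nid for nid, c in counts.items() if c >= 2}
    seen: set[int] = set()
    events = []
    for nid in sorted(multi):
        if nid in seen:
            continue
        cluster = {nid}
        frontier = [nid]
        while frontier:
            cur = frontier.pop()
            for nb in graph.nodes[cur].parents + graph.nodes[cur].children:
                if nb in multi and nb not in cluster:
                    cluster.add(nb)
                    frontier.append(nb)
        seen |= cluster
        parents_in = sorted(
            {
                p
                for c in cluster
                for p in graph.nodes[c].parents
                if p not in cluster and counts[p] == 1
            }
        )
        children_out = sorted(
            {
                c2
                for c in cluster
                for c2 in graph.nodes[c].children
                if c2 not in cluster and counts[c2] == 1
            }
        )
        start = min(graph.nodes[c].start_frame for c in cluster)
        end = max(graph.nodes[c].end_frame for c in cluster)
        n_larvae = max(counts[c] for c in cluster)
        ev = col.CollisionEvent(parents_in, children_out, start, end, n_larvae)
        events.append((ev, sorted(cluster)))
    return events


def _node_features(
    graph: CollisionGraph,
    nid: int,
    from_end: bool,
    max_n: int,
    rev_links: dict[int, int] | None = None,
) -> np.ndarray:
    """Shape features adjacent to a collision, following resolved links back.

    When an entering node is short (e.g. it was born at the exit of an
    already-resolved collision), its identity chain supplies earlier frames.
    """
    chunks = []
    cur: int | None = nid
    total = 0
    while cur is not None and total < max_n:
        node = graph.nodes[cur]
        feats = np.asarray(
            [
                (p.body_length_mm, p.width_mm, p.area_mm2, p.perimeter_mm)
                for p in node.poses
                if p is not None and p.valid
            ],
            dtype=float,
        ).reshape(-1, 4)
        chunks.append(feats)
        total += len(feats)
        cur = rev_links.get(cur) if (from_end and rev_links) else None
    if from_end:
        arr = np.vstack(chunks[::-1]) if chunks else np.empty((0, 4))
        return arr[-max_n:]
    arr = chunks[0] if chunks else np.empty((0, 4))
    return arr[:max_n]


def _resolve_event(
    ev: col.CollisionEvent,
    cluster: list[int],
    graph: CollisionGraph,
    cfg: TrackerConfig,
    img_shape: tuple[int, int],
    rev_links: dict[int, int] | None = None,
) -> col.AssignmentResult:
    fps = cfg.fps
    sym2 = len(ev.participants_in) == len(ev.participants_out) == 2 and ev.n_larvae == 2
    if sym2 and ev.duration_s(fps) < col.MAX_SHAPE_MODEL_DURATION_S:
        res = _try_shape_model(ev, cluster, graph, cfg, img_shape)
        if res.resolved:
            return res
        fallback = _try_statistical(ev, graph, cfg, rev_links)
        return fallback if fallback.resolved else res
    if ev.n_larvae >= 4:
        return col.AssignmentResult(False, method="statistical", reason="oversized: refused")
    if len(ev.participants_in) == len(ev.participants_out) and ev.n_larvae in (2, 3):
        return _try_statistical(ev, graph, cfg, rev_links)
    return col.AssignmentResult(False, reason=f"unhandled kind {ev.kind}")


def _try_shape_model(ev, cluster, graph, cfg, img_shape) -> col.AssignmentResult:
    entry_spines, entry_widths = {}, {}
    for nid in ev.participants_in:
        node = graph.nodes[nid]
        pose = next(
            (p for p in reversed(node.poses) if p is not None and p.valid), None
        )
        if pose is None:
            return col.AssignmentResult(False, reason="no entry pose")
        entry_spines[nid] = pose.spine_px
        entry_widths[nid] = pose.width_mm / cfg.mm_per_px
    # merged-blob pixels per collision frame, in time order
    frame_pix: dict[int, list[np.ndarray]] = {}
    for nid in cluster:
        node = graph.nodes[nid]
        for fr, pix in zip(node.frames, node.pixel_sets):
            frame_pix.setdefault(fr, []).append(pix)
    pixels = [np.concatenate(frame_pix[f]) for f in sorted(frame_pix)]
    exit_centroids = {}
    for nid in ev.participants_out:
        node = graph.nodes[nid]
        exit_centroids[nid] = np.array(node.centroids[0], dtype=float)
    return col.resolve_shape_model(
        ev,
        entry_spines,
        entry_widths,
        pixels,
        img_shape,
        exit_centroids,
        cfg.fps,
        fit_floor=cfg.shape_fit_floor,
    )


def _try_statistical(ev, graph, cfg, rev_links=None) -> col.AssignmentResult:
    fin = {
        nid: _node_features(graph, nid, True, cfg.stat_max_frames, rev_links)
        for nid in ev.participants_in
    }
    fout = {
        nid: _node_features(graph, nid, False, cfg.stat_max_frames)
        for nid in ev.participants_out
    }
    try:
        return col.resolve_statistical(
            ev,
            fin,
            fout,
            max_frames=cfg.stat_max_frames,
            min_frames=cfg.stat_min_history,
            factor=cfg.stat_factor,
        )
    except col.OversizedCollisionError as exc:
        return col.AssignmentResult(False, method="statistical", reason=str(exc))


def _build_tracks(
    graph: CollisionGraph,
    single_nodes: list[int],
    subtracks: dict[int, list[Subtrack]],
    links: dict[int, int],
    cfg: TrackerConfig,
    img_height: int,
) -> list[TrackRecord]:
    """Chain identity-linked nodes and emit one TrackRecord per chain."""
    chain_of: dict[int, int] = {}
    chains: dict[int, list[int]] = {}
    next_chain = 0
    for nid in sorted(single_nodes, key=lambda n: graph.nodes[n].start_frame):
        if nid in chain_of:
            continue
        cid = next_chain
        next_chain += 1
        chains[cid] = []
        cur = nid
        while cur is not None and cur not in chain_of:
            chain_of[cur] = cid
            chains[cid].append(cur)
            cur = links.get(cur)

    tracks = []
    for cid, nids in chains.items():
        rows_frames, rows_spine, rows = [], [], []
        prev_tail = None
        for nid in nids:
            for st in subtracks.get(nid, []):
                sp = st.oriented_spines().astype(float)
                if st.head_end == "ambiguous" and prev_tail is not None:
                    # inherit orientation by tail-position continuity
                    d_same = np.linalg.norm(sp[0, 0] - prev_tail)
                    d_flip = np.linalg.norm(sp[0, 11] - prev_tail)
                    if d_flip < d_same:
                        sp = sp[:, ::-1, :]
                rows_frames.append(st.frames)
                rows_spine.append(sp)
                rows.append(st)
                prev_tail = sp[-1, 0]
        if not rows_frames:
            continue
        frames_cat = np.concatenate(rows_frames)
        spine_px = np.concatenate(rows_spine, axis=0)
        order = np.argsort(frames_cat)
        frames_cat = frames_cat[order]
        spine_px = spine_px[order]
        spine_mm = spine_px.copy()
        spine_mm[..., 1] = (img_height - 1) - spine_mm[..., 1]
        spine_mm *= cfg.mm_per_px

        poses = [p for st in rows for p in st.poses]
        poses = [poses[i] for i in order]
        track = TrackRecord(
            track_id=cid,
            frames=frames_cat,
            spine_mm=spine_mm,
            fps=cfg.fps,
            width_mm=np.array([p.width_mm for p in poses]),
            area_mm2=np.array([p.area_mm2 for p in poses]),
            perimeter_mm=np.array([p.perimeter_mm for p in poses]),
            valid=np.array([p.valid for p in poses]),
            provenance=[("node", nid) for nid in nids],
        )
        tracks.append(track)
    return tracks
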