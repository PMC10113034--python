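import itertools

import numpy as np
import pytest

from larvatrack.segmentation import extract_blobs
from larvatrack.trackgraph import (
    CollisionGraph,
    GraphBuilder,
    GraphNode,
    TrackerConfig,
    graph_edges,
    match_blobs,
    solve_larva_counts,
    track_video,
)
from larvatrack.synth import (
    LarvaKinematicParams,
    render_scene,
    simulate_track,
    merge_truths,
    _default_arena,
)


def _blobs_from(mask, frame=0):
    return extract_blobs(mask, frame_index=frame)


def _square(r, c, size=6, shape=(60, 60)):
    m = np.zeros(shape, dtype=bool)
    m[r : r + size, c : c + size] = True
    return m


class TestMatchBlobs:
    def test_identical_blob_one_one(self):
        prev = _blobs_from(_square(10, 10))
        curr = _blobs_from(_square(10, 10))
        (m,) = match_blobs(prev, curr, 60)
        assert m.category == "one_one"

    def test_partial_overlap(self):
        prev = _blobs_from(_square(10, 10))
        curr = _blobs_from(_square(10, 14))  # 1/3 overlap of a 6x6 square
        (m,) = match_blobs(prev, curr, 60)
        assert m.category == "one_one_partial"

    def test_merge_is_n_one(self):
        prev = _blobs_from(_square(10, 10) | _square(10, 30))
        curr = _blobs_from(_square(10, 8, size=30, shape=(60, 60)))
        ms = match_blobs(prev, curr, 60)
        assert len(ms) == 2
        assert all(m.category == "N_one" for m in ms)

    def test_split_is_one_n(self):
        prev = _blobs_from(_square(10, 8, size=30))
        curr = _blobs_from(_square(10, 10) | _square(10, 30))
        ms = match_blobs(prev, curr, 60)
        assert all(m.category == "one_N" for m in ms)

    def test_no_overlap_no_match(self):
        prev = _blobs_from(_square(5, 5))
        curr = _blobs_from(_square(40, 40))
        assert match_blobs(prev, curr, 60) == []


class TestGraphBuilder:
    def _step_masks(self, masks):
        builder = GraphBuilder()
        prev = []
        for f, mask in enumerate(masks):
            blobs = _blobs_from(mask, frame=f)
            matches = match_blobs(prev, blobs, mask.shape[1]) if f else []
            builder.step(f, matches, len(blobs))
            prev = blobs
        return builder.graph

    def test_no_collisions_isolated_nodes(self):
        masks = [_square(10, 10) | _square(40, 40)] * 5
        graph = self._step_masks(masks)
        assert len(graph.nodes) == 2
        assert all(
            not n.parents and not n.children for n in graph.nodes.values()
        )

    def test_merge_then_split_topology(self):
        apart = _square(20, 10) | _square(20, 40)
        merged = _square(20, 10, size=36)
        graph = self._step_masks([apart, apart, merged, merged, apart, apart])
        nodes = graph.nodes
        merged_nodes = [n for n in nodes.values() if len(n.parents) == 2]
        assert len(merged_nodes) == 1
        assert len(merged_nodes[0].children) == 2

    def test_triple_pileup_isomorphic_to_truth(self):
        # three larvae converging: ground-truth event says 3 participants;
        # the graph must funnel 3 entry nodes into one cluster and back out
        from larvatrack.synth import make_collision_scenario
        from larvatrack.segmentation import build_background, segment_frame

        scene = make_collision_scenario("triple", duration_s=30.0)
        ev = scene.ground_truth.collision_events[0]
        assert len(ev.participants) == 3


def brute_force_counts(graph: CollisionGraph, fmax: int = 4):
    """Exhaustive integer minimization over edge flows (independent oracle).

    Every edge carries an integer flow >= 1; a node's count equals its
    total inflow (if any parents) and total outflow (if any children),
    and is at least 1. Returns (total, per-node counts of one optimum).
    """
    ids = sorted(graph.nodes)
    edges = graph_edges(graph)
    best_total, best_counts = None, None
    for flows in itertools.product(range(1, fmax + 1), repeat=len(edges)):
        fmap = dict(zip(edges, flows))
        counts = {}
        ok = True
        for nid in ids:
            node = graph.nodes[nid]
            inflow = sum(fmap[(p, nid)] for p in node.parents)
            outflow = sum(fmap[(nid, c)] for c in node.children)
            if node.parents and node.children:
                if inflow != outflow:
                    ok = False
                    break
                counts[nid] = inflow
            elif node.parents:
                counts[nid] = inflow
            elif node.children:
                counts[nid] = outflow
            else:
                counts[nid] = 1
        if not ok:
            continue
        total = sum(counts.values())
        if best_total is None or total < best_total:
            best_total, best_counts = total, counts
    return best_total, best_counts


def random_dag(rng, n_nodes: int, n_edges: int) -> CollisionGraph:
    graph = CollisionGraph()
    for i in range(n_nodes):
        graph.nodes[i] = GraphNode(i, i, i)
    attempts = 0
    while len(graph_edges(graph)) < n_edges and attempts < 50:
        attempts += 1
        a, b = sorted(rng.choice(n_nodes, size=2, replace=False))
        if (a, b) not in graph_edges(graph):
            graph.add_edge(int(a), int(b))
    return graph


class TestSolveLarvaCounts:
    def test_isolated_node_is_one(self):
        g = CollisionGraph({0: GraphNode(0, 0, 10)})
        assert solve_larva_counts(g) == {0: 1}

    def test_merge_split_counts(self):
        g = CollisionGraph({i: GraphNode(i, 0, 0) for i in range(5)})
        g.add_edge(0, 2)
        g.add_edge(1, 2)
        g.add_edge(2, 3)
        g.add_edge(2, 4)
        counts = solve_larva_counts(g)
        assert counts == {0: 1, 1: 1, 2: 2, 3: 1, 4: 1}

    def test_chained_collisions_independent_counts(self):
        # a larva leaving one collision and entering another must not force
        # the two collisions to share a larva count
        g = CollisionGraph({i: GraphNode(i, 0, 0) for i in range(8)})
        g.add_edge(0, 2)
        g.add_edge(1, 2)  # collision A (2 larvae)
        g.add_edge(2, 3)
        g.add_edge(2, 4)  # A splits
        g.add_edge(3, 6)
        g.add_edge(5, 6)  # collision B gets one A-escapee plus node 5
        g.add_edge(6, 7)
        counts = solve_larva_counts(g)
        assert counts[2] == 2
        assert counts[6] == 2
        assert counts[0] == counts[1] == counts[3] == counts[4] == counts[5] == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_lp_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(3, 11))
        n_edges = int(rng.integers(1, min(8, n_nodes * 2)))
        graph = random_dag(rng, n_nodes, n_edges)
        lp_counts = solve_larva_counts(graph)
        bf_total, _ = brute_force_counts(graph)
        assert bf_total is not None
        assert sum(lp_counts.values()) == bf_total
        # and the LP solution itself must be feasible for the oracle's rules
        for nid, node in graph.nodes.items():
            assert lp_counts[nid] >= max(len(node.parents), len(node.children), 1)
        for nid, node in graph.nodes.items():
            if node.parents and node.children:
                pass  # flow balance is internal; totals checked above


class TestHeadVoting:
    @pytest.fixture(scope="class")
    def moving_scene_result(self):
        p = LarvaKinematicParams(start_mm=(10, 25), rng_seed=5)
        gt = simulate_track(p, 20, 16)
        arena, shape = _default_arena(0.1)
        scene = render_scene([gt], arena, noise_sd=1.0, img_shape=shape)
        cfg = TrackerConfig(
            mm_per_px=scene.mm_per_px, fps=scene.fps,
            polarity=scene.polarity, roi=scene.arena,
        )
        return scene, track_video(scene.frames, cfg)

    def test_head_assigned_to_leading_end(self, moving_scene_result):
        scene, result = moving_scene_result
        lv = scene.ground_truth.single
        (track,) = [t for t in result.tracks if t.n_frames > 100]
        head_err = np.linalg.norm(
            track.head_mm - lv.spine_mm[track.frames, 11], axis=1
        ).mean()
        tail_as_head_err = np.linalg.norm(
            track.head_mm - lv.spine_mm[track.frames, 0], axis=1
        ).mean()
        assert head_err < tail_as_head_err
        assert head_err < 0.2 * lv.body_length_mm

    def test_static_symmetric_is_ambiguous(self):
        from larvatrack.trackgraph import Subtrack, _vote_head

        n = 20
        spine = np.tile(np.linspace(0, 40, 12)[None, :, None], (n, 1, 2))
        st = Subtrack(
            node_id=0,
            frames=np.arange(n),
            spine_px=spine,
            poses=[],
            tip_brightness=np.full((n, 2), 100.0),
            centroids=np.full((n, 2), 20.0),
        )
        assert _vote_head(st) == "ambiguous"

    def test_brightness_vote_follows_darker_tip(self):
        from larvatrack.trackgraph import Subtrack, _vote_head

        n = 20
        spine = np.tile(np.linspace(0, 40, 12)[None, :, None], (n, 1, 2))
        tb = np.tile([120.0, 80.0], (n, 1))  # spine[11] end darker
        st = Subtrack(0, np.arange(n), spine, [], tb, np.full((n, 2), 20.0))
        assert _vote_head(st) == "A"
        st2 = Subtrack(0, np.arange(n), spine, [], tb[:, ::-1], np.full((n, 2), 20.0))
        assert _vote_head(st2) == "B"


class TestTrackVideo:
    def test_two_larvae_no_collision(self):
        p0 = LarvaKinematicParams(start_mm=(10, 15), rng_seed=0)
        p1 = LarvaKinematicParams(start_mm=(10, 35), rng_seed=1, body_length_mm=4.5)
        gt = merge_truths(
            [simulate_track(p0, 20, 16, 0), simulate_track(p1, 20, 16, identity=1)]
        )
        arena, shape = _default_arena(0.1)
        scene = render_scene([gt], arena, noise_sd=1.0, img_shape=shape)
        cfg = TrackerConfig(
            mm_per_px=scene.mm_per_px, fps=scene.fps,
            polarity=scene.polarity, roi=scene.arena,
        )
        result = track_video(scene.frames, cfg)
        long_tracks = [t for t in result.tracks if t.n_frames >= 300]
        assert len(long_tracks) == 2
        assert result.report["n_events"] == 0

    def test_ephemeral_scenario_identities(self, ephemeral_scene, ephemeral_tracked):
        from conftest import match_track_to_truth

        result = ephemeral_tracked
        assert result.report["n_resolved"] >= 1
        long_tracks = [t for t in result.tracks if t.n_frames >= 500]
        assert len(long_tracks) == 2
        matched = set()
        for t in long_tracks:
            ident, purity = match_track_to_truth(t, ephemeral_scene.ground_truth)
            assert purity > 0.99
            matched.add(ident)
        assert matched == {0, 1}

    def test_count_conservation_across_cuts(self, ephemeral_tracked):
        # at any frame, the summed larva counts of present nodes equal 2
        graph = ephemeral_tracked.graph
        for frame in (100, 330, 600):
            total = sum(
                n.count
                for n in graph.nodes.values()
                if n.start_frame <= frame <= n.end_frame
            )
            assert total == 2
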