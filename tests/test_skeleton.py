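import numpy as np
import pytest

from vasquant.preprocess import BinaryMask
from vasquant.skeleton import (
    build_skeleton_graph,
    count_branch_points,
    edge_table,
    node_table,
    segment_length_stats,
    skeletonize,
)


def graph_of(px, pixel_size_um=1.0):
    return build_skeleton_graph(BinaryMask(np.asarray(px, dtype=bool), pixel_size_um))


class TestSkeletonize:
    def test_bar_thins_to_single_spanning_path(self):
        px = np.zeros((9, 54), dtype=bool)
        px[2:7, 2:52] = True
        g = build_skeleton_graph(skeletonize(BinaryMask(px, 1.0)))
        assert len(g.edges) == 1
        assert count_branch_points(g) == 0
        # the path spans most of the bar's long axis
        assert g.total_length_um >= 40

    def test_empty_mask_empty_skeleton(self):
        sk = skeletonize(BinaryMask(np.zeros((10, 10), bool), 1.0))
        assert not sk.pixels.any()
        g = build_skeleton_graph(sk)
        assert g.nodes == () and g.edges == ()

    def test_annulus_preserves_one_component_one_hole(self):
        """Homotopic thinning of a solid annulus yields a single closed
        loop: one component and one hole, confirmed by an Euler-number
        labeling oracle."""
        from scipy import ndimage as ndi

        yy, xx = np.mgrid[:40, :40]
        rr = np.hypot(yy - 20, xx - 20)
        ann = (rr > 8) & (rr < 14)
        sk = skeletonize(BinaryMask(ann, 1.0))
        _, n_fg = ndi.label(sk.pixels, structure=np.ones((3, 3), bool))
        bg4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
        _, n_bg = ndi.label(~sk.pixels, structure=bg4)
        assert n_fg == 1 and n_bg == 2  # outside + enclosed hole
        g = build_skeleton_graph(sk)
        assert len(g.edges) == 1
        e = g.edges[0]
        assert e.node_a == e.node_b
        assert g.nodes[e.node_a].kind == "cycle"

    def test_skeleton_subset_of_input(self, small_network):
        sk = skeletonize(small_network.clean_mask)
        assert not (sk.pixels & ~small_network.clean_mask.pixels).any()


class TestBuildSkeletonGraph:
    def test_straight_line_11px(self):
        px = np.zeros((5, 13), bool)
        px[2, 1:12] = True
        g = graph_of(px)
        kinds = sorted(n.kind for n in g.nodes)
        assert kinds == ["endpoint", "endpoint"]
        assert segment_length_stats(g) == {
            "total_um": 10.0,
            "mean_um": 10.0,
            "max_um": 10.0,
            "n_segments": 1,
        }

    def test_diagonal_run_6px(self):
        px = np.zeros((8, 8), bool)
        for i in range(6):
            px[i + 1, i + 1] = True
        g = graph_of(px)
        assert len(g.edges) == 1
        np.testing.assert_allclose(g.total_length_um, 5 * np.sqrt(2))

    def test_plus_sign_hand_traced(self, plus_sign_mask):
        """Two crossing 9-px lines: one merged junction, four endpoints,
        four arms of 4 um each (hand-enumerated)."""
        g = build_skeleton_graph(plus_sign_mask)
        assert count_branch_points(g) == 1
        assert sum(1 for n in g.nodes if n.kind == "endpoint") == 4
        stats = segment_length_stats(g)
        assert stats["n_segments"] == 4
        np.testing.assert_allclose(stats["mean_um"], 4.0)
        np.testing.assert_allclose(stats["total_um"], 16.0)

    def test_isolated_pixel(self):
        px = np.zeros((5, 5), bool)
        px[2, 2] = True
        g = graph_of(px)
        assert [n.kind for n in g.nodes] == ["isolated"]
        assert g.edges == ()

    def test_two_pixel_component_direct_edge(self):
        px = np.zeros((4, 4), bool)
        px[1, 1] = px[2, 2] = True
        g = graph_of(px)
        assert len(g.edges) == 1
        np.testing.assert_allclose(g.edges[0].length_um, np.sqrt(2))

    def test_rejects_thick_input(self):
        px = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            graph_of(px)

    def test_every_pixel_in_exactly_one_node_or_edge(self, small_network):
        sk = skeletonize(small_network.clean_mask)
        g = build_skeleton_graph(sk)
        seen = {}
        for n in g.nodes:
            for p in n.pixels:
                assert p not in seen
                seen[p] = ("node", n.id)
        for e in g.edges:
            for p in e.path:
                assert p not in seen
                seen[p] = ("edge", e.id)
        assert len(seen) == int(sk.pixels.sum())

    def test_node_degree_contract(self, small_network):
        """Endpoints touch exactly one edge end; junctions at least three."""
        g = build_skeleton_graph(skeletonize(small_network.clean_mask))
        degree = {n.id: 0 for n in g.nodes}
        for e in g.edges:
            degree[e.node_a] += 1
            degree[e.node_b] += 1
        for n in g.nodes:
            if n.kind == "endpoint":
                assert degree[n.id] == 1
            elif n.kind == "junction":
                assert degree[n.id] >= 3
            elif n.kind == "isolated":
                assert degree[n.id] == 0

    def test_total_length_is_sum_of_edges(self, small_network):
        g = build_skeleton_graph(skeletonize(small_network.clean_mask))
        np.testing.assert_allclose(
            g.total_length_um, sum(e.length_um for e in g.edges), rtol=1e-9
        )

    def test_step_sum_conservation_without_junctions(self):
        """On a junction-free skeleton the graph length equals the
        brute-force step-sum over all 8-adjacencies counted once."""
        px = np.zeros((20, 20), bool)
        path = [(2, 2), (3, 3), (4, 4), (4, 5), (4, 6), (5, 7), (6, 7), (7, 7)]
        for p in path:
            px[p] = True
        brute = 0.0
        pts = sorted(zip(*np.nonzero(px)))
        for i, a in enumerate(pts):
            for b in pts[i + 1 :]:
                if max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1:
                    brute += np.sqrt(2) if (a[0] != b[0] and a[1] != b[1]) else 1.0
        g = graph_of(px)
        np.testing.assert_allclose(g.total_length_um, brute)


class TestSymmetryAndCalibration:
    @pytest.mark.parametrize("op", [np.rot90, np.flipud, np.fliplr])
    def test_graph_metrics_invariant_under_symmetry(self, small_network, op):
        sk = skeletonize(small_network.clean_mask)
        g0 = build_skeleton_graph(sk)
        g1 = build_skeleton_graph(BinaryMask(op(sk.pixels).copy(), 1.0))
        np.testing.assert_allclose(g1.total_length_um, g0.total_length_um, rtol=1e-12)
        assert count_branch_points(g1) == count_branch_points(g0)
        assert len(g1.edges) == len(g0.edges)

    def test_doubling_pixel_size_doubles_lengths(self, plus_sign_mask):
        g1 = build_skeleton_graph(plus_sign_mask)
        g2 = build_skeleton_graph(BinaryMask(plus_sign_mask.pixels, 2.0))
        np.testing.assert_allclose(g2.total_length_um, 2 * g1.total_length_um, rtol=1e-15)
        for e1, e2 in zip(g1.edges, g2.edges):
            np.testing.assert_allclose(e2.length_um, 2 * e1.length_um, rtol=1e-15)


def test_stats_of_empty_graph():
    g = graph_of(np.zeros((5, 5), bool))
    assert segment_length_stats(g) == {
        "total_um": 0.0,
        "mean_um": 0.0,
        "max_um": 0.0,
        "n_segments": 0,
    }


def test_tables_roundtrip(plus_sign_mask):
    g = build_skeleton_graph(plus_sign_mask)
    et, nt = edge_table(g), node_table(g)
    assert len(et) == 4 and len(nt) == 5
    np.testing.assert_allclose(et["length_um"].sum(), g.total_length_um)
    assert set(nt["kind"]) == {"junction", "endpoint"}
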