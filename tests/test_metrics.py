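import numpy as np
import pytest

from vasquant.metrics import (
    area_fraction,
    branch_density,
    compute_metrics,
    length_density,
    nearest_neighbor_distances,
)
from vasquant.preprocess import BinaryMask
from vasquant.skeleton import build_skeleton_graph, skeletonize

from conftest import random_point_mask


def brute_force_nnd(points, pixel_size_um=1.0):
    """All-pairs nearest-neighbor distances, independent of any KD-tree."""
    out = []
    for i, a in enumerate(points):
        best = min(
            np.hypot(a[0] - b[0], a[1] - b[1])
            for j, b in enumerate(points)
            if j != i
        )
        out.append(best * pixel_size_um)
    return out


class TestAreaFraction:
    def test_empty_mask(self):
        assert area_fraction(BinaryMask(np.zeros((100, 100), bool), 1.0)) == 0.0

    def test_counted_pixels(self):
        px = np.zeros((100, 100), bool)
        px.ravel()[:250] = True
        assert area_fraction(BinaryMask(px, 1.0)) == 0.025

    def test_matches_generator_stamp_exactly(self, small_network):
        gt = small_network.ground_truth
        af = area_fraction(small_network.clean_mask)
        assert af == gt.stamped_foreground_px / small_network.clean_mask.pixels.size

    def test_strictly_increases_when_pixels_added(self):
        rng = np.random.default_rng(2)
        px = rng.random((50, 50)) > 0.8
        af0 = area_fraction(BinaryMask(px, 1.0))
        px2 = px.copy()
        px2[np.unravel_index(np.flatnonzero(~px)[0], px.shape)] = True
        assert area_fraction(BinaryMask(px2, 1.0)) > af0


class TestDensities:
    def test_length_density_unit_conversion(self):
        """A 10 000 um skeleton in a 1 mm^2 field is 10 mm/mm^2."""
        px = np.zeros((1000, 1000), bool)
        px[500, :] = True  # 999 um
        g = build_skeleton_graph(BinaryMask(px, 1.0))
        ld = length_density(g, (1000, 1000))
        np.testing.assert_allclose(ld, 0.999)

    def test_empty_graph_zero_density(self):
        g = build_skeleton_graph(BinaryMask(np.zeros((100, 100), bool), 1.0))
        assert length_density(g, (100, 100)) == 0.0
        assert branch_density(g, (100, 100)) == 0.0

    def test_plus_sign_branch_density(self, plus_sign_mask):
        g = build_skeleton_graph(plus_sign_mask)
        # 9x9 px at 1 um/px = 81e-6 mm^2
        np.testing.assert_allclose(branch_density(g, (9, 9)), 1 / 81e-6)

    def test_calibration_scaling(self, plus_sign_mask):
        """Doubling the pixel size halves mm/mm^2 and quarters 1/mm^2."""
        g1 = build_skeleton_graph(plus_sign_mask)
        g2 = build_skeleton_graph(BinaryMask(plus_sign_mask.pixels, 2.0))
        np.testing.assert_allclose(
            length_density(g2, (9, 9)), length_density(g1, (9, 9)) / 2, rtol=1e-12
        )
        np.testing.assert_allclose(
            branch_density(g2, (9, 9)), branch_density(g1, (9, 9)) / 4, rtol=1e-12
        )


class TestNearestNeighborDistances:
    def test_three_four_five_triangle(self):
        px = np.zeros((10, 10), bool)
        px[0, 0] = px[3, 4] = True
        d = nearest_neighbor_distances(BinaryMask(px, 1.0), "centroid")
        np.testing.assert_allclose(d, [5.0, 5.0])

    def test_collinear_triplet_matches_hand_computation(self):
        px = np.zeros((3, 30), bool)
        px[1, 0] = px[1, 10] = px[1, 25] = True
        d = nearest_neighbor_distances(BinaryMask(px, 1.0), "centroid")
        np.testing.assert_allclose(sorted(d), [10.0, 10.0, 15.0])
        np.testing.assert_allclose(np.mean(d), 35 / 3)

    def test_single_object_empty_list(self):
        px = np.zeros((10, 10), bool)
        px[3:6, 3:6] = True
        assert nearest_neighbor_distances(BinaryMask(px, 1.0), "centroid") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_centroid_mode_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        mask, pts = random_point_mask(rng, n_objects=n)
        got = nearest_neighbor_distances(mask, "centroid")
        expected = brute_force_nnd(pts)
        np.testing.assert_allclose(sorted(got), sorted(expected), rtol=1e-12)

    def test_translation_invariance(self):
        px = np.zeros((40, 40), bool)
        px[5, 5] = px[10, 20] = px[30, 8] = True
        d0 = nearest_neighbor_distances(BinaryMask(px, 1.0))
        d1 = nearest_neighbor_distances(BinaryMask(np.roll(px, (4, 4), (0, 1)), 1.0))
        np.testing.assert_allclose(sorted(d0), sorted(d1))

    def test_skeleton_mode_edge_to_edge(self):
        """Two parallel 3-px-thick bars 10 px apart: skeleton mode sees the
        centerline gap, centroid mode the same (symmetric bars)."""
        px = np.zeros((30, 30), bool)
        px[5:8, 5:25] = True
        px[15:18, 5:25] = True
        d_sk = nearest_neighbor_distances(BinaryMask(px, 1.0), "skeleton")
        assert len(d_sk) == 2
        np.testing.assert_allclose(d_sk, [10.0, 10.0])

    def test_all_distances_positive_and_one_per_object(self, small_network):
        d = nearest_neighbor_distances(small_network.clean_mask)
        assert len(d) == small_network.ground_truth.component_count
        assert all(x > 0 for x in d)


class TestComputeMetrics:
    def test_empty_mask_record(self):
        m = compute_metrics(BinaryMask(np.zeros((50, 50), bool), 1.0))
        assert m.area_fraction == 0.0
        assert m.length_density_mm_per_mm2 == 0.0
        assert m.branch_density_per_mm2 == 0.0
        assert m.mean_nnd_um is None and m.nnd_sd_um is None
        assert m.n_objects == 0

    def test_deterministic(self, small_network):
        a = compute_metrics(small_network.clean_mask)
        b = compute_metrics(small_network.clean_mask)
        assert a == b

    def test_against_generator_ground_truth(self, small_network):
        gt = small_network.ground_truth
        m = compute_metrics(small_network.clean_mask)
        assert m.n_branch_points == gt.n_bifurcations
        assert abs(m.total_length_um - gt.centerline_length_um) <= 0.05 * gt.centerline_length_um
        assert m.n_objects == gt.component_count

    def test_rarefaction_increases_spacing(self):
        """Randomly deleting vessel objects raises mean NND and lowers the
        density measures — the signature of vascular rarefaction."""
        from scipy import ndimage as ndi

        from vasquant.synthetic import generate_network

        up = 0
        trials = 8
        for seed in range(trials):
            net = generate_network(seed, field_px=(256, 256), n_seeds=10, branch_prob=0.0)
            mask = net.clean_mask
            lab, n = ndi.label(mask.pixels, structure=np.ones((3, 3), bool))
            rng = np.random.default_rng(100 + seed)
            drop = rng.choice(np.arange(1, n + 1), size=max(1, int(0.4 * n)), replace=False)
            thinned = BinaryMask(mask.pixels & ~np.isin(lab, drop), 1.0)
            m0, m1 = compute_metrics(mask), compute_metrics(thinned)
            assert m1.area_fraction < m0.area_fraction
            up += m1.mean_nnd_um > m0.mean_nnd_um
        assert up >= trials - 1
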