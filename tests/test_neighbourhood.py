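import numpy as np
import pytest

from conftest import make_mask
from oracles import brute_force_edge_distance, has_empty_circumsphere, random_blob_mask
from nucpipe import (
    HardCore,
    RunConfig,
    SceneSpec,
    build_graph,
    delaunay_adjacency,
    edge_distance,
    extract_nuclei,
    make_scene,
    summarise_distances,
)
from nucpipe.neighbourhood import jittered_points


class TestDelaunayAdjacency:
    def test_triangle_all_pairs_adjacent(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.0]])
        assert delaunay_adjacency(pts) == {(0, 1), (0, 2), (1, 2)}

    def test_unit_square_has_exactly_one_diagonal(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        pairs = delaunay_adjacency(pts)
        perimeter = {(0, 1), (0, 2), (1, 3), (2, 3)}
        diagonals = pairs - perimeter
        assert perimeter <= pairs
        assert len(diagonals) == 1 and diagonals <= {(0, 3), (1, 2)}
        # the reported adjacency passes the empty-circumcircle test on the
        # jittered points that were actually triangulated
        jit = jittered_points(pts)
        for i, j in pairs:
            assert has_empty_circumsphere(jit, i, j)

    def test_fewer_than_two_points_empty(self):
        assert delaunay_adjacency(np.empty((0, 3))) == set()
        assert delaunay_adjacency(np.array([[1.0, 2.0, 3.0]])) == set()

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            delaunay_adjacency(np.ones((4, 3)))

    def test_two_points_adjacent(self):
        assert delaunay_adjacency(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])) == {(0, 1)}

    def test_simplex_or_fewer_points_fully_connected_3d(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        assert delaunay_adjacency(pts) == {
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
        }

    def test_collinear_points_form_a_chain(self):
        pts = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 1.0], [0.0, 0.0, 3.0]])
        assert delaunay_adjacency(pts) == {(1, 2), (0, 2)}

    def test_single_slice_data_triangulated_in_2d(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [np.full(12, 5.0), rng.uniform(0, 50, 12), rng.uniform(0, 50, 12)]
        )
        pairs = delaunay_adjacency(pts)
        jit = jittered_points(pts[:, 1:])
        for i, j in pairs:
            assert has_empty_circumsphere(jit, i, j)

    @pytest.mark.parametrize("dim,n,seed", [(2, 18, 0), (2, 25, 1), (3, 12, 2), (3, 14, 3)])
    def test_empty_circumsphere_property_random_sets(self, dim, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(n, dim))
        pairs = delaunay_adjacency(pts)
        jit = jittered_points(pts)
        assert pairs
        for i, j in pairs:
            assert has_empty_circumsphere(jit, i, j)

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 60, size=(40, 3))
        assert delaunay_adjacency(pts) == delaunay_adjacency(pts)


class TestEdgeDistance:
    def test_two_single_voxels_three_apart(self):
        vox = np.zeros((1, 1, 5), dtype=np.int32)
        vox[0, 0, 0], vox[0, 0, 3] = 1, 2
        assert edge_distance(make_mask(vox), 1, 2) == 3.0

    def test_anisotropic_z_scaling(self):
        vox = np.zeros((3, 2, 2), dtype=np.int32)
        vox[0, 0, 0], vox[1, 0, 0] = 1, 2
        assert edge_distance(make_mask(vox, (2.0, 1.0, 1.0)), 1, 2) == 2.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(5)
        vox = random_blob_mask((6, 9, 9), [1, 2], rng)
        mask = make_mask(vox, (1.5, 0.8, 1.1))
        assert edge_distance(mask, 1, 2) == edge_distance(mask, 2, 1)

    def test_identical_labels_rejected(self):
        vox = np.ones((1, 2, 2), dtype=np.int32)
        with pytest.raises(ValueError, match="distinct"):
            edge_distance(make_mask(vox), 1, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_scan(self, seed):
        rng = np.random.default_rng(seed)
        vox = random_blob_mask((7, 10, 10), [1, 2], rng)
        voxel_size = (2.0, 1.0, 0.5)
        mask = make_mask(vox, voxel_size)
        assert edge_distance(mask, 1, 2) == brute_force_edge_distance(
            vox, 1, 2, voxel_size
        )

    def test_translation_invariance_whole_voxel_shift(self):
        rng = np.random.default_rng(12)
        vox = np.zeros((8, 14, 14), dtype=np.int32)
        vox[2:4, 3:5, 3:6] = 1
        vox[4:6, 8:10, 8:11] = 2
        mask = make_mask(vox, (2.0, 1.0, 1.0))
        shifted = make_mask(np.roll(vox, (1, 2, 3), axis=(0, 1, 2)), (2.0, 1.0, 1.0))
        assert edge_distance(mask, 1, 2) == edge_distance(shifted, 1, 2)


def two_sphere_scene():
    spec = SceneSpec(
        domain_size_um=(30.0, 40.0, 40.0),
        voxel_size_um=(1.0, 1.0, 1.0),
        n_nuclei=2,
        placement=HardCore(0.0),
        nucleus_radii_um=(5.0, 5.0, 5.0),
        radius_jitter=0.0,
        channels=[],
        seed=0,
    )
    from nucpipe import render_scene

    centres = np.array([[15.0, 10.0, 20.0], [15.0, 30.0, 20.0]])
    mask, _ = render_scene(centres, spec)
    return mask


class TestBuildGraph:
    def test_two_sphere_geometry(self):
        mask = two_sphere_scene()
        records = extract_nuclei(mask)
        graph = build_graph(records, mask, RunConfig(radius_um=40.0))
        assert graph.n_edges == 1
        edge = graph.edges.iloc[0]
        assert edge["centroid_distance_um"] == pytest.approx(20.0, abs=0.2)
        assert abs(edge["edge_distance_um"] - 10.0) <= 1.0  # one voxel pitch
        assert edge["edge_distance_um"] <= edge["centroid_distance_um"]

    def test_radius_rule_drops_distant_pairs(self):
        mask = two_sphere_scene()
        records = extract_nuclei(mask)
        graph = build_graph(records, mask, RunConfig(radius_um=15.0))
        assert graph.n_edges == 0

    def test_edges_subset_of_delaunay_and_dominance(self, small_scene):
        _, mask, _, _ = small_scene
        records = extract_nuclei(mask)
        graph = build_graph(records, mask, RunConfig(radius_um=40.0))
        centroids = np.array([r.centroid_um for r in records])
        labels = [r.label for r in records]
        adj = {
            tuple(sorted((labels[i], labels[j])))
            for i, j in delaunay_adjacency(centroids)
        }
        for _, e in graph.edges.iterrows():
            assert (int(e["label_a"]), int(e["label_b"])) in adj
            assert e["edge_distance_um"] <= e["centroid_distance_um"]
            assert e["centroid_distance_um"] <= 40.0

    def test_single_nucleus_graph_has_no_edges(self):
        vox = np.zeros((3, 5, 5), dtype=np.int32)
        vox[1, 2, 2] = 1
        mask = make_mask(vox)
        graph = build_graph(extract_nuclei(mask), mask)
        assert graph.n_edges == 0 and graph.n_nuclei == 1

    def test_border_policy_exclude_drops_clipped_nuclei(self):
        vox = np.zeros((3, 6, 6), dtype=np.int32)
        vox[0, 0, 0] = 1  # touches border
        vox[1, 3, 3] = 2
        vox[1, 3, 4] = 3
        mask = make_mask(vox)
        records = extract_nuclei(mask)
        graph = build_graph(records, mask, RunConfig(border_policy="exclude"))
        assert set(graph.nodes["label"]) == {2, 3}


class TestSummariseDistances:
    def test_mean_of_two_edges(self, small_scene):
        import pandas as pd

        from nucpipe.neighbourhood import NeighbourGraph

        edges = pd.DataFrame(
            {
                "label_a": [1, 2],
                "label_b": [2, 3],
                "centroid_distance_um": [5.0, 6.0],
                "edge_distance_um": [2.0, 4.0],
            }
        )
        nodes = pd.DataFrame({"label": [1, 2, 3]})
        g = NeighbourGraph(nodes, edges, 40.0, "img")
        s = summarise_distances(g)
        assert s.mean_edge_distance_um == 3.0 and s.n_edges == 2

    def test_subsample_reproducible_and_exact_size(self, small_scene):
        _, mask, _, _ = small_scene
        graph = build_graph(extract_nuclei(mask), mask, RunConfig(radius_um=40.0))
        cfg = RunConfig(subsample_n=50, seed=123)
        s1 = summarise_distances(graph, cfg)
        s2 = summarise_distances(graph, cfg)
        assert len(s1.distances_um) == 50
        assert np.array_equal(s1.distances_um, s2.distances_um)
        # subsample never exceeds the available edges
        cfg_big = RunConfig(subsample_n=10**6, seed=123)
        s3 = summarise_distances(graph, cfg_big)
        assert len(s3.distances_um) == graph.n_edges

    def test_zero_edges_flagged_not_silent_zero(self):
        vox = np.zeros((3, 5, 5), dtype=np.int32)
        vox[1, 2, 2] = 1
        mask = make_mask(vox)
        s = summarise_distances(build_graph(extract_nuclei(mask), mask))
        assert not s.mean_defined and np.isnan(s.mean_edge_distance_um)

    def test_density_integrates_to_one_and_kde_mean_consistent(self, small_scene):
        _, mask, _, _ = small_scene
        graph = build_graph(extract_nuclei(mask), mask, RunConfig(radius_um=40.0))
        s = summarise_distances(graph)
        area = np.trapezoid(s.density, s.density_grid_um)
        assert area == pytest.approx(1.0, abs=1e-6)
        # self-consistency on simulated draws: KDE mean tracks sample mean
        rng = np.random.default_rng(0)
        draws = np.clip(rng.normal(10.0, 2.0, 5000), 0.0, None)
        from nucpipe import density as dens

        grid = dens.shared_grid([draws])
        f = dens.kde_on_grid(draws, grid)
        kde_mean = np.trapezoid(grid * f, grid)
        assert abs(kde_mean - draws.mean()) / draws.mean() < 0.02


def test_monotone_cohesion_across_hard_core_separations():
    """Tighter packing yields shorter mean inter-nuclear edge distances."""
    means = {}
    for sep in (6.0, 14.0):
        spec = SceneSpec(
            domain_size_um=(30.0, 200.0, 200.0),
            voxel_size_um=(2.0, 1.0, 1.0),
            n_nuclei=130,
            placement=HardCore(sep),
            nucleus_radii_um=(2.5, 2.5, 2.5),
            radius_jitter=0.15,
            channels=[],
            seed=21,
        )
        mask, _, _ = make_scene(spec)
        g = build_graph(extract_nuclei(mask), mask, RunConfig(radius_um=40.0))
        means[sep] = summarise_distances(g).mean_edge_distance_um
    assert means[6.0] < means[14.0]
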