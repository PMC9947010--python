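import numpy as np
import pytest

from nanoloc.errors import NanolocError
from nanoloc.locproc import AffineTransform, make_table
from nanoloc.synthetic_data import (
    SimClusterConfig,
    make_two_channel,
    simulate_clustered_points,
)
from nanoloc.tessellation_coloc import (
    cluster_diameters,
    coloc_report,
    control_negative,
    control_positive,
    manders_coloc,
    segment_clusters,
    spearman_coloc,
    voronoi_densities,
)


def _grid_table(n=21, spacing=100.0):
    g = np.arange(n) * spacing
    xx, yy = np.meshgrid(g, g)
    return make_table(np.zeros(xx.size, int), xx.ravel(), yy.ravel())


@pytest.fixture(scope="module")
def disk_fixture():
    config = SimClusterConfig(
        n_clusters=2, cluster_radius=200.0, locs_per_cluster=1000,
        background_density=5.0, loc_precision=5.0,
        field_size=(3000.0, 3000.0), seed=3,
    )
    return simulate_clustered_points(config)


class TestVoronoiDensities:
    def test_square_grid_interior_density(self):
        spacing = 100.0
        dm = voronoi_densities(_grid_table(spacing=spacing))
        interior = (
            (dm.points[:, 0] == 1000.0) & (dm.points[:, 1] == 1000.0)
        )
        i = np.flatnonzero(interior)[0]
        assert dm.density[i] == pytest.approx(1.0 / spacing**2, rel=1e-9)

    def test_density_scales_inverse_square(self):
        table = _grid_table()
        scaled = table.copy()
        scaled[["x", "y"]] *= 3.0
        dm = voronoi_densities(table)
        dm_scaled = voronoi_densities(scaled)
        ok = ~dm.flagged & ~dm_scaled.flagged
        assert np.allclose(dm_scaled.density[ok], dm.density[ok] / 9.0, rtol=1e-9)

    def test_csr_mean_density_close_to_truth(self):
        gen = np.random.default_rng(50)
        pts = gen.uniform(0, 10000, (10000, 2))
        table = make_table(np.zeros(len(pts), int), pts[:, 0], pts[:, 1])
        dm = voronoi_densities(table)
        # 10000 points in 100 um^2 -> 100 per um^2 = 1e-4 per nm^2
        assert dm.mean_density == pytest.approx(1e-4, rel=0.10)

    def test_too_few_points_rejected(self):
        table = make_table([0, 0, 0], [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        with pytest.raises(NanolocError):
            voronoi_densities(table)

    def test_collinear_points_rejected(self):
        table = make_table(np.zeros(6, int), np.arange(6.0), np.arange(6.0) * 2.0)
        with pytest.raises(NanolocError):
            voronoi_densities(table)

    def test_partition_accounting(self, disk_fixture):
        table, _ = disk_fixture
        clusters = segment_clusters(table)
        dm = voronoi_densities(table)
        assert clusters.n_dense + clusters.n_non_dense + clusters.n_flagged == dm.n


class TestSegmentClusters:
    def test_two_disks_recovered(self, disk_fixture):
        table, truth = disk_fixture
        clusters = segment_clusters(table)
        assert len(clusters) == 2

    def test_disk_diameters_near_truth(self, disk_fixture):
        table, _ = disk_fixture
        diameters = cluster_diameters(segment_clusters(table))
        assert np.all(np.abs(diameters - 400.0) <= 60.0)

    def test_csr_null_behaviour(self):
        # at the default 1x threshold roughly half of a CSR pattern is
        # "dense" (percolation regime): only small chance runs may appear,
        # and a 2x threshold yields a clean null
        config = SimClusterConfig(
            n_clusters=0, cluster_radius=100.0, locs_per_cluster=0,
            background_density=10.0, field_size=(10000.0, 10000.0), seed=1,
        )
        csr, _ = simulate_clustered_points(config)
        chance = segment_clusters(csr)
        assert all(c.n_locs < 0.25 * len(csr) for c in chance)
        assert len(segment_clusters(csr, density_factor=2.0)) == 0

    def test_empty_table_rejected(self):
        table = make_table(np.empty(0, int), np.empty(0), np.empty(0))
        with pytest.raises(NanolocError):
            segment_clusters(table)

    def test_diameters_scale_with_coordinates(self, disk_fixture):
        table, _ = disk_fixture
        doubled = table.copy()
        doubled[["x", "y"]] *= 2.0
        d1 = np.sort(cluster_diameters(segment_clusters(table)))
        d2 = np.sort(cluster_diameters(segment_clusters(doubled)))
        assert np.allclose(d2, 2.0 * d1, rtol=1e-9)

    def test_cluster_members_disjoint(self, disk_fixture):
        table, _ = disk_fixture
        clusters = segment_clusters(table)
        all_members = np.concatenate([c.member_ids for c in clusters])
        assert len(all_members) == len(np.unique(all_members))


class TestSpearmanColoc:
    def test_exact_copy_gives_rho_one(self, clustered_pair):
        a, _ = clustered_pair
        result = spearman_coloc(a, a.copy())
        assert result.rho == pytest.approx(1.0)
        assert result.rho_a == pytest.approx(1.0)

    def test_noisy_copy_strongly_correlated(self, clustered_pair):
        a, b = clustered_pair
        assert spearman_coloc(a, b).rho >= 0.7

    def test_flipped_channel_uncorrelated(self, clustered_pair):
        a, _ = clustered_pair
        assert spearman_coloc(a, control_negative(a)).rho <= 0.1

    def test_roi_restriction_runs(self, clustered_pair):
        a, b = clustered_pair
        # 2.6 um^2 region around the first cluster (~1.6 x 1.6 um)
        roi = (1200.0, 1200.0, 2812.0, 2812.0)
        result = spearman_coloc(a, b, roi=roi)
        assert -1.0 <= result.rho <= 1.0
        assert result.n >= 100

    def test_degenerate_densities_rejected(self):
        grid = _grid_table(8)
        with pytest.raises(NanolocError):
            spearman_coloc(grid, grid.copy())


class TestMandersColoc:
    def test_identical_channels_symmetric(self, clustered_pair):
        a, _ = clustered_pair
        m_a, m_b = manders_coloc(a, a.copy())
        assert m_a == m_b

    def test_nested_clusters_high_m_a(self):
        gen = np.random.default_rng(60)
        centers = np.array([[3000.0, 3000.0], [7000.0, 7000.0]])
        b_pts, a_pts = [], []
        for c in centers:
            theta = gen.uniform(0, 2 * np.pi, 800)
            rad = 250.0 * np.sqrt(gen.uniform(0, 1, 800))
            b_pts.append(c + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]))
            theta = gen.uniform(0, 2 * np.pi, 300)
            rad = 100.0 * np.sqrt(gen.uniform(0, 1, 300))
            a_pts.append(c + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]))
        b_pts.append(gen.uniform(0, 10000, (300, 2)))  # sparse B background
        a_pts.append(gen.uniform(0, 10000, (10, 2)))  # negligible A background
        b_all = np.concatenate(b_pts)
        a_all = np.concatenate(a_pts)
        table_b = make_table(np.zeros(len(b_all), int), b_all[:, 0], b_all[:, 1])
        table_a = make_table(np.zeros(len(a_all), int), a_all[:, 0], a_all[:, 1])
        m_a, _ = manders_coloc(table_a, table_b)
        assert m_a >= 0.95

    def test_disjoint_dense_regions_zero(self):
        gen = np.random.default_rng(61)
        # B: one tight cluster left + diffuse right half
        b_cluster = gen.normal([2000.0, 5000.0], 100.0, (500, 2))
        b_bg = np.column_stack([
            gen.uniform(6000, 10000, 40), gen.uniform(0, 10000, 40)
        ])
        b_all = np.concatenate([b_cluster, b_bg])
        table_b = make_table(np.zeros(len(b_all), int), b_all[:, 0], b_all[:, 1])
        # A: entirely inside B's diffuse (non-dense) region
        a_pts = np.column_stack([
            gen.uniform(7000, 9000, 200), gen.uniform(4000, 6000, 200)
        ])
        table_a = make_table(np.zeros(len(a_pts), int), a_pts[:, 0], a_pts[:, 1])
        m_a, _ = manders_coloc(table_a, table_b)
        assert m_a == 0.0

    def test_values_in_unit_interval(self, clustered_pair):
        a, b = clustered_pair
        m_a, m_b = manders_coloc(a, b)
        assert 0.0 <= m_a <= 1.0 and 0.0 <= m_b <= 1.0

    def test_empty_channel_rejected(self, clustered_pair):
        a, _ = clustered_pair
        with pytest.raises(NanolocError):
            manders_coloc(a, a.iloc[:0])


class TestControls:
    def test_positive_control_conserves_counts(self, clustered_pair):
        a, _ = clustered_pair
        even, odd = control_positive(a)
        assert len(even) + len(odd) == len(a)
        assert (even["frame"] % 2 == 0).all()
        assert (odd["frame"] % 2 == 1).all()

    def test_even_frames_only_empty_half(self):
        table = make_table([0, 2, 2, 4], [0.0, 1.0, 2.0, 3.0], [0.0] * 4)
        even, odd = control_positive(table)
        assert len(odd) == 0
        with pytest.raises(NanolocError):
            spearman_coloc(even, odd)

    def test_single_frame_rejected(self):
        table = make_table([5, 5], [0.0, 1.0], [0.0, 0.0])
        with pytest.raises(NanolocError):
            control_positive(table)

    def test_negative_control_is_involution(self, clustered_pair):
        a, _ = clustered_pair
        twice = control_negative(control_negative(a))
        assert np.allclose(twice[["x", "y"]], a[["x", "y"]], atol=1e-9)

    def test_centroid_reflects_about_box_center(self, clustered_pair):
        a, _ = clustered_pair
        flipped = control_negative(a)
        center = (a["y"].min() + a["y"].max()) / 2
        assert flipped["y"].mean() == pytest.approx(2 * center - a["y"].mean())

    def test_point_outside_box_rejected(self, clustered_pair):
        a, _ = clustered_pair
        with pytest.raises(NanolocError):
            control_negative(a, bounding_box=(0.0, 0.0, 1.0, 1.0))


class TestTwoChannelOrdering:
    def test_rho_ordering_with_gaps(self):
        config = SimClusterConfig(
            n_clusters=20, cluster_radius=200.0, locs_per_cluster=250,
            background_density=10.0, field_size=(10000.0, 10000.0), seed=5,
        )
        a, _ = simulate_clustered_points(config)
        identity = AffineTransform.identity()
        rhos = {}
        for mode in ("coclustered", "independent", "mirrored"):
            _, b = make_two_channel(a, identity, mode, seed=6)
            rhos[mode] = spearman_coloc(a, b).rho
        assert rhos["coclustered"] - rhos["independent"] >= 0.3
        assert rhos["independent"] - rhos["mirrored"] >= 0.3

    def test_independent_on_csr_near_zero(self):
        config = SimClusterConfig(
            n_clusters=0, cluster_radius=100.0, locs_per_cluster=0,
            background_density=30.0, field_size=(10000.0, 10000.0), seed=7,
        )
        csr, _ = simulate_clustered_points(config)
        _, b = make_two_channel(csr, AffineTransform.identity(), "independent", seed=8)
        assert abs(spearman_coloc(csr, b).rho) <= 0.1

    def test_coloc_report_combines_statistics(self, clustered_pair):
        a, b = clustered_pair
        result = coloc_report(a, b)
        assert result.rho >= 0.7
        assert result.m_a > 0.5 and result.m_b > 0.5
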