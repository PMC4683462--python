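import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avigamut.gamut import (LocusMap, hull_overlap, hull_volume,
                            locus_summary, project_2d, rasterize_loci,
                            shared_unique_loci)
from avigamut.visual import TETRA_VOLUME, tetra_vertices


def brute_force_bins(points, cell_size, origin=(0.0, 0.0, 0.0)):
    """Independent per-point, per-axis binning oracle."""
    cells = {}
    for row, (x, y, z) in enumerate(points):
        key = (int(np.floor((x - origin[0]) / cell_size)),
               int(np.floor((y - origin[1]) / cell_size)),
               int(np.floor((z - origin[2]) / cell_size)))
        cells.setdefault(key, []).append(row)
    return cells


class TestHullVolume:
    def test_reference_tetrahedron_volume_closed_form(self):
        # regular tetrahedron of edge a: volume a^3 / (6 sqrt 2)
        res = hull_volume(tetra_vertices())
        assert res.volume == pytest.approx(np.sqrt(1.5) ** 3 / (6 * np.sqrt(2)),
                                           abs=1e-9)
        assert not res.degenerate

    def test_three_points_are_degenerate(self):
        res = hull_volume(np.eye(3))
        assert res.volume == 0.0 and res.degenerate

    def test_coplanar_points_are_degenerate(self):
        pts = np.column_stack([np.random.default_rng(0).uniform(0, 1, (10, 2)),
                               np.zeros(10)])
        assert hull_volume(pts).degenerate

    def test_scaled_cube_volume(self):
        corners = 0.1 * np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                                  for k in (0, 1)], float)
        assert hull_volume(corners).volume == pytest.approx(0.001)

    def test_adding_points_never_shrinks_volume(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.2, 0.2, (30, 3))
        v1 = hull_volume(pts[:10]).volume
        v2 = hull_volume(pts).volume
        assert v2 >= v1


class TestHullOverlap:
    def test_identical_sets_overlap_fully(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (20, 3))
        res = hull_overlap(pts, pts)
        assert res.frac_of_a == pytest.approx(1.0, abs=1e-9)
        assert res.frac_of_b == pytest.approx(1.0, abs=1e-9)

    def test_halved_copy_has_eighth_volume_overlap(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (40, 3))
        centroid = a.mean(axis=0)
        b = centroid + 0.5 * (a - centroid)
        res = hull_overlap(a, b)
        assert res.frac_of_b == pytest.approx(1.0, rel=1e-6)
        assert res.frac_of_a == pytest.approx(
            hull_volume(b).volume / hull_volume(a).volume, rel=1e-6)

    def test_disjoint_hulls_do_not_overlap(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (15, 3))
        b = a + 10.0
        assert hull_overlap(a, b).intersection_volume == 0.0

    def test_degenerate_input_gives_zero_overlap(self):
        assert hull_overlap(np.eye(3), np.eye(3)).intersection_volume == 0.0

    def test_monte_carlo_agrees_with_exact(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(50, 3))
        b = rng.normal(loc=0.5, size=(50, 3))
        exact = hull_overlap(a, b, "exact")
        mc = hull_overlap(a, b, "monte_carlo", n_samples=200_000, rng=5)
        assert mc.intersection_volume == pytest.approx(
            exact.intersection_volume, abs=3 * mc.mc_se)


class TestRasterizeLoci:
    def test_single_point_single_locus(self):
        lmap = rasterize_loci(np.array([[0.01, 0.01, 0.01]]))
        assert lmap.n_occupied == 1 and lmap.n_points == 1

    def test_copies_share_a_locus(self):
        lmap = rasterize_loci(np.tile([0.01, 0.01, 0.01], (10, 1)))
        assert lmap.n_occupied == 1 and lmap.n_points == 10

    def test_points_straddling_a_cell_edge_split(self):
        pts = np.array([[0.001, 0.01, 0.01], [0.031, 0.01, 0.01]])
        lmap = rasterize_loci(pts)
        assert lmap.n_occupied == 2
        assert {k[0] for k in lmap.cells} == {0, 1}

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_binning(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-0.75, 0.75, (200, 3))
        lmap = rasterize_loci(pts)
        assert lmap.counts() == {k: len(v) for k, v in
                                 brute_force_bins(pts, 0.022).items()}

    def test_equivalent_to_intersecting_two_2d_grids(self):
        # binning on the yz and yx planes then combining the 2D cell ids
        # identifies exactly the 3D loci (shared y axis, equal cell edge)
        rng = np.random.default_rng(9)
        pts = rng.uniform(-0.75, 0.75, (500, 3))
        cell = 0.022
        idx = np.floor(pts / cell).astype(int)
        combined = {(iy, iz, ix) for ix, iy, iz in idx}  # yz cell + yx cell
        lmap = rasterize_loci(pts, cell)
        assert {(iy, iz, ix) for ix, iy, iz in lmap.cells} == combined

    def test_adding_points_never_reduces_locus_count(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-0.5, 0.5, (100, 3))
        assert (rasterize_loci(pts).n_occupied
                >= rasterize_loci(pts[:40]).n_occupied)

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(ValueError):
            rasterize_loci(np.zeros((1, 3)), cell_size=0.0)


class TestLocusSummary:
    def test_single_crowded_cell(self):
        lmap = rasterize_loci(np.tile([0.01] * 3, (100, 1)))
        s = locus_summary(lmap)
        assert s.n_occupied == 1 and s.mass_fraction == 1.0

    def test_uneven_cells_concentrate_mass(self):
        pts = np.vstack([np.tile([0.01] * 3, (99, 1)),
                         [[0.5, 0.5, 0.5]]])
        s = locus_summary(rasterize_loci(pts))
        assert s.n_occupied == 2
        assert s.mass_fraction == pytest.approx(0.5)

    def test_loci_never_exceed_distinct_points(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-0.7, 0.7, (300, 3))
        assert rasterize_loci(pts).n_occupied <= 300

    def test_empty_map_summary_is_zero(self):
        s = locus_summary(LocusMap())
        assert s.n_occupied == 0 and s.n_points == 0


class TestSharedUniqueLoci:
    def test_identical_maps_fully_shared(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-0.5, 0.5, (50, 3))
        a = rasterize_loci(pts)
        part = shared_unique_loci(a, a)
        assert part.frac_shared == 1.0 and part.n_only_a == 0

    def test_disjoint_maps_share_nothing(self):
        a = rasterize_loci(np.array([[0.01, 0.01, 0.01]]))
        b = rasterize_loci(np.array([[0.5, 0.5, 0.5]]))
        part = shared_unique_loci(a, b)
        assert part.n_shared == 0 and part.n_only_a == 1 and part.n_only_b == 1

    def test_subset_map_has_no_unique_loci(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-0.5, 0.5, (50, 3))
        a = rasterize_loci(pts[:20])
        b = rasterize_loci(pts)
        assert shared_unique_loci(a, b).n_only_a == 0

    def test_grid_mismatch_rejected(self):
        a = rasterize_loci(np.zeros((1, 3)), cell_size=0.022)
        b = rasterize_loci(np.zeros((1, 3)), cell_size=0.05)
        with pytest.raises(ValueError):
            shared_unique_loci(a, b)


class TestProject2D:
    def test_single_point_occupies_one_cell_per_plane(self):
        pts = np.array([[0.1, 0.2, 0.3]])
        assert len(project_2d(pts, "yz")) == 1
        assert len(project_2d(pts, "yx")) == 1

    def test_marginalises_the_3d_locus_map(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(-0.6, 0.6, (200, 3))
        lmap = rasterize_loci(pts)
        grid = project_2d(pts, "yz")
        marginal = {}
        for (ix, iy, iz), members in lmap.cells.items():
            marginal[(iy, iz)] = marginal.get((iy, iz), 0) + len(members)
        assert grid == marginal

    def test_empty_input_empty_grid(self):
        assert project_2d(np.empty((0, 3)), "yx") == {}


def test_sample_hull_never_exceeds_tetra_volume(default_points):
    assert hull_volume(default_points).volume <= TETRA_VOLUME
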