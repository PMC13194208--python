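"""Unit and property tests for the per-landscape fragmentation measures."""

import numpy as np
import pytest

from forestfrag import (
    BinaryLandscape,
    binarize_forest,
    compute_metrics,
    delineate_landscape,
    edge_density,
    label_patches,
    mean_patch_size,
    proportion_habitat,
    remove_small_patches,
)
from forestfrag.landscape import OUTSIDE

from conftest import flood_fill_label, random_landscape


class TestBinarize:
    @pytest.mark.parametrize(
        "heights, mask, expected",
        [
            ([[6, 4], [5, 0]], None, [[1, 0], [1, 0]]),
            ([[4.9, 0], [2, 3]], None, [[0, 0], [0, 0]]),
            ([[6, 6]], [[False, True]], [[1, 0]]),  # masked water/cropland
        ],
    )
    def test_height_thresholding(self, heights, mask, expected):
        ls = binarize_forest(np.array(heights, dtype=float),
                             np.array(mask) if mask is not None else None)
        assert ls.cells.tolist() == expected

    def test_threshold_is_inclusive(self):
        ls = binarize_forest(np.array([[5.0, 4.999]]))
        assert ls.cells.tolist() == [[1, 0]]

    def test_rejects_nonpositive_threshold_and_shape_mismatch(self):
        with pytest.raises(ValueError, match="threshold"):
            binarize_forest(np.ones((2, 2)), threshold=0)
        with pytest.raises(ValueError, match="shape"):
            binarize_forest(np.ones((2, 2)), nonforest_mask=np.ones((3, 3), bool))


class TestRemoveSmallPatches:
    def test_isolated_pixel_removed(self):
        cells = np.zeros((5, 5), dtype=np.int8)
        cells[2, 2] = 1
        out = remove_small_patches(BinaryLandscape(cells, 30.0), max_cells=1)
        assert out.n_habitat == 0

    def test_zero_is_identity_and_two_cell_patch_survives(self):
        cells = np.zeros((5, 5), dtype=np.int8)
        cells[1, 1] = cells[1, 2] = 1
        ls = BinaryLandscape(cells, 30.0)
        assert np.array_equal(remove_small_patches(ls, 0).cells, cells)
        assert remove_small_patches(ls, 1).n_habitat == 2

    def test_never_increases_habitat_or_patch_count(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            ls = random_landscape(rng, n=15, p=rng.uniform(0.2, 0.8))
            out = remove_small_patches(ls, max_cells=int(rng.integers(0, 4)))
            assert out.n_habitat <= ls.n_habitat
            assert label_patches(out).n_patches <= label_patches(ls).n_patches


class TestDelineate:
    def _grid(self, n=21, cell=30.0):
        rng = np.random.default_rng(0)
        return random_landscape(rng, n=n, cell_size=cell)

    def test_covering_radius_leaves_no_outside(self):
        grid = self._grid(n=3)
        # 3x3 grid, 90 m wide; a 44-m circle from the center reaches every
        # cell center (farthest is at 30*sqrt(2) ~ 42.4 m) while staying
        # inside the grid extent
        out = delineate_landscape(grid, (45.0, 45.0), 44.0)
        assert (out.cells != OUTSIDE).all()

    def test_tiny_radius_keeps_one_cell(self):
        grid = self._grid(n=9)
        center = (4.5 * 30, 270 - 4.5 * 30)  # a cell center
        out = delineate_landscape(grid, center, 10.0)
        assert out.n_inside == 1

    def test_inside_count_matches_brute_force_at_250m(self):
        grid = self._grid(n=21, cell=30.0)
        center = (315.0, 315.0)
        out = delineate_landscape(grid, center, 250.0)
        xx, yy = grid.cell_centers()
        expected = int((np.hypot(xx - 315.0, yy - 315.0) <= 250.0).sum())
        assert out.n_inside == expected

    def test_out_of_extent_circle_is_refused(self):
        grid = self._grid(n=9)
        with pytest.raises(ValueError, match="extent"):
            delineate_landscape(grid, (30.0, 30.0), 200.0)

    def test_inside_count_monotone_in_radius(self):
        grid = self._grid(n=21)
        center = (315.0, 315.0)
        counts = [
            delineate_landscape(grid, center, r).n_inside
            for r in (50, 100, 150, 200, 250, 300)
        ]
        assert counts == sorted(counts)


class TestLabelPatches:
    def test_diagonal_pair_queen_vs_rook(self):
        ls = BinaryLandscape(np.array([[1, 0], [0, 1]], dtype=np.int8), 30.0)
        assert label_patches(ls, connectivity=8).n_patches == 1
        assert label_patches(ls, connectivity=4).n_patches == 2

    def test_full_grid_is_one_patch(self):
        ls = BinaryLandscape(np.ones((3, 3), dtype=np.int8), 30.0)
        lab = label_patches(ls)
        assert lab.n_patches == 1
        assert lab.patch_sizes.tolist() == [9]

    def test_invalid_connectivity(self):
        ls = BinaryLandscape(np.ones((2, 2), dtype=np.int8), 30.0)
        with pytest.raises(ValueError, match="connectivity"):
            label_patches(ls, connectivity=6)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ls = random_landscape(rng, n=20, p=rng.uniform(0.1, 0.9))
            lab = label_patches(ls, connectivity)
            oracle_labels, oracle_n = flood_fill_label(ls.habitat_mask(), connectivity)
            assert lab.n_patches == oracle_n
            # same partition up to relabeling: label pairs must biject
            ours = lab.labels[ls.habitat_mask()]
            theirs = oracle_labels[ls.habitat_mask()]
            assert len(set(zip(ours, theirs))) == oracle_n


class TestMetrics:
    def test_center_cell_hand_values(self, center_cell_landscape):
        m = compute_metrics(center_cell_landscape)
        assert m.p_habitat == pytest.approx(1 / 9)
        assert m.n_patches == 1
        # 4 rook edge segments of 30 m over 0.81 ha
        assert m.edge_density == pytest.approx(4 * 30 / 0.81)
        assert m.mean_patch_size == pytest.approx(0.09)
        assert m.landscape_area_ha == pytest.approx(0.81)

    def test_full_and_empty_fixtures(self, full_landscape, empty_landscape):
        full = compute_metrics(full_landscape)
        assert (full.p_habitat, full.n_patches, full.edge_density) == (1.0, 1, 0.0)
        assert full.mean_patch_size == pytest.approx(0.81)
        empty = compute_metrics(empty_landscape)
        assert (empty.p_habitat, empty.n_patches) == (0.0, 0)
        assert (empty.edge_density, empty.mean_patch_size) == (0.0, 0.0)
        assert empty.landscape_area_ha == pytest.approx(0.81)

    def test_proportion_excludes_outside_cells(self):
        cells = np.array([[-1, -1, 0], [-1, 1, 0], [-1, 1, 0]], dtype=np.int8)
        ls = BinaryLandscape(cells, 30.0)
        assert proportion_habitat(ls) == pytest.approx(0.4)

    def test_outside_boundary_contributes_no_edge(self):
        # habitat ring around an outside core: only habitat/non-habitat
        # pairs count, habitat/outside pairs do not
        cells = np.array([[1, 1, 1], [1, -1, 1], [1, 1, 1]], dtype=np.int8)
        ls = BinaryLandscape(cells, 30.0)
        assert edge_density(ls) == 0.0
        assert edge_density(ls, count_boundary=True) > 0.0

    def test_mean_patch_size_two_patches(self):
        cells = np.zeros((5, 5), dtype=np.int8)
        cells[0, 0] = 1  # patch of 1
        cells[3, 0:3] = 1  # patch of 3
        lab = label_patches(BinaryLandscape(cells, 30.0))
        assert lab.n_patches == 2
        assert mean_patch_size(lab, 30.0) == pytest.approx(0.18)

    def test_conservation_and_edge_bound_on_random_landscapes(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ls = random_landscape(rng, n=int(rng.integers(8, 30)),
                                  p=rng.uniform(0.05, 0.95))
            m = compute_metrics(ls)
            assert m.n_patches * m.mean_patch_size == pytest.approx(
                m.p_habitat * m.landscape_area_ha, rel=1e-9
            )
            assert m.edge_density <= 4e4 / ls.cell_size + 1e-9


class TestBinaryLandscapeInvariants:
    def test_rejects_bad_cells_and_cell_size(self):
        with pytest.raises(ValueError):
            BinaryLandscape(np.array([[2, 0]]), 30.0)
        with pytest.raises(ValueError):
            BinaryLandscape(np.array([[1, 0]]), 0.0)
        with pytest.raises(ValueError):
            BinaryLandscape(np.full((2, 2), OUTSIDE, dtype=np.int8), 30.0)

    def test_delineated_cells_lie_within_radius(self):
        grid = random_landscape(np.random.default_rng(5), n=21)
        out = delineate_landscape(grid, (315.0, 315.0), 200.0)
        xx, yy = out.cell_centers()
        inside = out.cells != OUTSIDE
        assert (np.hypot(xx - 315, yy - 315)[inside] <= 200.0).all()
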