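"""Per-landscape fragmentation measurements on binary habitat rasters.

A landscape is a grid of cells in one of three states: habitat,
non-habitat, or outside the analysis window.  Circular landscapes are cut
out of a larger raster as buffers around a sample point; cells whose
centers fall beyond the buffer radius are marked *outside* and excluded
from every measurement (area, edge, patches).

The four class-level measures computed here are the FRAGSTATS staples:
proportion of the landscape in habitat, number of patches, edge density
(meters of habitat/non-habitat edge per hectare), and mean patch size
(hectares).  All lengths are meters; the raster must be in a projected,
meter-unit coordinate system.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

# Cell states.  int8 grids keep landscapes cheap at 10-km radii.
OUTSIDE: int = -1
NONHABITAT: int = 0
HABITAT: int = 1

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclasses.dataclass
class BinaryLandscape:
    """A grid of {habitat, non-habitat, outside} cells.

    Parameters
    ----------
    cells
        2-D int array with values ``HABITAT`` (1), ``NONHABITAT`` (0) or
        ``OUTSIDE`` (-1).
    cell_size
        Side length of a cell in meters (> 0).
    origin
        Optional ``(x_min, y_max)`` of the grid's top-left corner in a
        projected meter-unit reference.  When absent, the grid is placed
        with its top-left corner at ``(0, nrows * cell_size)``.
    center, radius_m
        Set after delineation: the buffer center and radius in meters.
    """

    cells: np.ndarray
    cell_size: float
    origin: tuple[float, float] | None = None
    center: tuple[float, float] | None = None
    radius_m: float | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D grid")
        if not np.isin(self.cells, (OUTSIDE, NONHABITAT, HABITAT)).all():
            raise ValueError("cells must contain only -1 (outside), 0, 1")
        self.cells = self.cells.astype(np.int8)
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if not (self.cells != OUTSIDE).any():
            raise ValueError("landscape has no cells inside the analysis window")
        if self.radius_m is not None:
            self._check_radius()

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def n_inside(self) -> int:
        """Number of cells inside the analysis window."""
        return int((self.cells != OUTSIDE).sum())

    @property
    def n_habitat(self) -> int:
        return int((self.cells == HABITAT).sum())

    @property
    def area_ha(self) -> float:
        """Landscape area in hectares (inside cells only)."""
        return self.n_inside * self.cell_size**2 / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every cell center."""
        nrows, ncols = self.cells.shape
        if self.origin is None:
            x0, y0 = 0.0, nrows * self.cell_size
        else:
            x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def habitat_mask(self) -> np.ndarray:
        return self.cells == HABITAT

    def _check_radius(self) -> None:
        if self.center is None:
            raise ValueError("radius_m set without a center")
        xx, yy = self.cell_centers()
        d = np.hypot(xx - self.center[0], yy - self.center[1])
        inside = self.cells != OUTSIDE
        # allow a hair of float slack on the circle boundary
        if (d[inside] > self.radius_m * (1 + 1e-9) + 1e-9).any():
            raise ValueError("a non-outside cell center lies beyond radius_m")


@dataclasses.dataclass(frozen=True)
class PatchLabeling:
    """Connected-component labeling of the habitat cells.

    ``labels`` is 0 for non-habitat/outside cells and 1..n_patches for
    habitat cells; ``patch_sizes[k-1]`` is the cell count of patch k.
    """

    labels: np.ndarray
    n_patches: int
    patch_sizes: np.ndarray

    def __post_init__(self) -> None:
        if self.n_patches != len(self.patch_sizes):
            raise ValueError("n_patches must match len(patch_sizes)")


@dataclasses.dataclass(frozen=True)
class FragMetrics:
    """The four per-landscape measures for one time point."""

    p_habitat: float
    n_patches: int
    edge_density: float
    mean_patch_size: float
    landscape_area_ha: float


def _check_connectivity(connectivity: int) -> None:
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def binarize_forest(
    height_grid: np.ndarray,
    nonforest_mask: np.ndarray | None = None,
    threshold: float = 5.0,
    cell_size: float = 30.0,
    origin: tuple[float, float] | None = None,
) -> BinaryLandscape:
    """Threshold a tree-height raster into a binary forest map.

    Cells with height >= ``threshold`` meters (inclusive, default 5 m —
    the FAO forest definition) become habitat unless masked by
    ``nonforest_mask`` (True where land is cropland, built-up, water,
    snow or ice); everything else is non-habitat.
    """
    height_grid = np.asarray(height_grid, dtype=float)
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if nonforest_mask is not None:
        nonforest_mask = np.asarray(nonforest_mask, dtype=bool)
        if nonforest_mask.shape != height_grid.shape:
            raise ValueError(
                f"mask shape {nonforest_mask.shape} != grid shape {height_grid.shape}"
            )
    unmasked = ~nonforest_mask if nonforest_mask is not None else np.ones_like(
        height_grid, dtype=bool
    )
    if not np.isfinite(height_grid[unmasked]).all():
        raise ValueError("height_grid must be finite where unmasked")
    habitat = (height_grid >= threshold) & unmasked
    return BinaryLandscape(habitat.astype(np.int8), cell_size, origin=origin)


def label_patches(ls: BinaryLandscape, connectivity: int = 8) -> PatchLabeling:
    """Label maximal habitat-connected components (patches).

    Two habitat cells belong to the same patch iff they are connected
    through habitat cells under rook (4) or queen (8) adjacency.
    """
    _check_connectivity(connectivity)
    labels, n = ndimage.label(ls.habitat_mask(), structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return PatchLabeling(labels=labels, n_patches=int(n), patch_sizes=sizes)


def remove_small_patches(
    ls: BinaryLandscape, max_cells: int = 0, connectivity: int = 8
) -> BinaryLandscape:
    """Reclassify every habitat patch of <= ``max_cells`` cells as non-habitat.

    ``max_cells=0`` (default) is a no-op; ``max_cells=1`` drops single
    isolated pixels, the usual salt-noise filter for classified imagery.
    """
    if max_cells < 0:
        raise ValueError(f"max_cells must be >= 0, got {max_cells}")
    if max_cells == 0:
        return dataclasses.replace(ls, cells=ls.cells.copy())
    labeling = label_patches(ls, connectivity)
    small = np.flatnonzero(labeling.patch_sizes <= max_cells) + 1
    cells = ls.cells.copy()
    cells[np.isin(labeling.labels, small)] = NONHABITAT
    return dataclasses.replace(ls, cells=cells)


def delineate_landscape(
    grid: BinaryLandscape, center: tuple[float, float], radius_m: float
) -> BinaryLandscape:
    """Cut a circular landscape of ``radius_m`` meters around ``center``.

    A cell is inside iff its center is within ``radius_m`` of the buffer
    center; all other cells become *outside*.  Raises if the circle is
    not fully contained in the source grid extent (landscapes are never
    silently truncated).
    """
    if not radius_m > 0:
        raise ValueError(f"radius_m must be > 0, got {radius_m}")
    nrows, ncols = grid.shape
    if grid.origin is None:
        x_min, y_max = 0.0, nrows * grid.cell_size
    else:
        x_min, y_max = grid.origin
    x_max = x_min + ncols * grid.cell_size
    y_min = y_max - nrows * grid.cell_size
    cx, cy = center
    if (
        cx - radius_m < x_min
        or cx + radius_m > x_max
        or cy - radius_m < y_min
        or cy + radius_m > y_max
    ):
        raise ValueError(
            f"circle of radius {radius_m} m at ({cx}, {cy}) exceeds the "
            f"grid extent [{x_min}, {x_max}] x [{y_min}, {y_max}]"
        )
    xx, yy = grid.cell_centers()
    inside = np.hypot(xx - cx, yy - cy) <= radius_m
    if not inside.any():
        raise ValueError("no cell center falls within radius_m of the center")
    cells = grid.cells.copy()
    cells[~inside] = OUTSIDE
    return BinaryLandscape(
        cells, grid.cell_size, origin=grid.origin, center=(cx, cy), radius_m=radius_m
    )


def proportion_habitat(ls: BinaryLandscape) -> float:
    """Fraction of inside cells that are habitat, in [0, 1]."""
    return ls.n_habitat / ls.n_inside


def _edge_segments(ls: BinaryLandscape, count_boundary: bool = False) -> int:
    """Number of rook-adjacent {habitat, non-habitat} cell pairs.

    With ``count_boundary`` the window boundary (outside cells and the
    array border) also contributes one segment per exposed habitat side,
    as if the landscape were surrounded by non-habitat.
    """
    c = ls.cells
    h = c == HABITAT
    n = c == NONHABITAT
    pairs = 0
    # horizontal then vertical neighbor pairs
    for a, b in ((c[:, :-1], c[:, 1:]), (c[:-1, :], c[1:, :])):
        pairs += int(((a == HABITAT) & (b == NONHABITAT)).sum())
        pairs += int(((a == NONHABITAT) & (b == HABITAT)).sum())
    if count_boundary:
        padded = np.pad(c, 1, constant_values=OUTSIDE)
        for a, b in (
            (padded[1:-1, :-1], padded[1:-1, 1:]),
            (padded[:-1, 1:-1], padded[1:, 1:-1]),
        ):
            pairs += int(((a == HABITAT) & (b == OUTSIDE)).sum())
            pairs += int(((a == OUTSIDE) & (b == HABITAT)).sum())
    return pairs


def edge_density(ls: BinaryLandscape, count_boundary: bool = False) -> float:
    """Meters of habitat/non-habitat edge per hectare of landscape.

    Each rook adjacency between a habitat and a non-habitat cell, both
    inside the window, contributes one segment of length ``cell_size``.
    By default the circular window boundary contributes no edge: an edge
    requires both classes to be observed (``count_boundary=True`` flips
    this for sensitivity analysis).
    """
    return _edge_segments(ls, count_boundary) * ls.cell_size / ls.area_ha


def mean_patch_size(labeling: PatchLabeling, cell_size: float) -> float:
    """Mean patch area in hectares; 0 when there are no patches.

    The zero convention for empty habitat keeps the conservation
    identity n_patches * MPS = p * area trivially true (0 = 0).
    """
    if labeling.n_patches == 0:
        return 0.0
    total_cells = int(labeling.patch_sizes.sum())
    return (total_cells / labeling.n_patches) * cell_size**2 / 1e4


def compute_metrics(
    ls: BinaryLandscape, connectivity: int = 8, count_boundary: bool = False
) -> FragMetrics:
    """Bundle the four measures, computed from a single labeling pass."""
    labeling = label_patches(ls, connectivity)
    return FragMetrics(
        p_habitat=proportion_habitat(ls),
        n_patches=labeling.n_patches,
        edge_density=edge_density(ls, count_boundary),
        mean_patch_size=mean_patch_size(labeling, ls.cell_size),
        landscape_area_ha=ls.area_ha,
    )
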