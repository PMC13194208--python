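"""Synthetic landscapes and habitat-loss scenarios.

Neutral landscape models stand in for real forest maps: a spectrally
synthesized random surface with power-law frequency decay (roughness
controls spatial autocorrelation) is rank-thresholded to a binary map
with an exactly controlled habitat proportion.  Parameterized loss
scenarios then remove habitat between the two time points in ways that
are known, by construction, to fragment or de-fragment:

* ``random`` — uniform salt-and-pepper removal;
* ``erosion`` — removal from patch edges inward;
* ``patch_removal`` — whole patches removed, smallest first (the
  canonical way loss *decreases* patch count);
* ``dissection`` — a straight strip cut through the map (roads,
  clearcut corridors), typically splitting patches;
* ``perforation`` — holes punched in patch interiors, creating new edge
  without splitting patches.

Everything is deterministic given the seeds, so paired-year cohorts are
reproducible across machines.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .landscape import (
    HABITAT,
    NONHABITAT,
    BinaryLandscape,
    compute_metrics,
    delineate_landscape,
    label_patches,
)

SCENARIO_KINDS = ("random", "erosion", "patch_removal", "dissection", "perforation")

#: The seven forested biomes used as categorical strata.
FORESTED_BIOMES = (
    "Tropical & Subtropical Moist Broadleaf Forests",
    "Tropical & Subtropical Dry Broadleaf Forests",
    "Tropical & Subtropical Coniferous Forests",
    "Temperate Broadleaf & Mixed Forests",
    "Temperate Conifer Forests",
    "Boreal Forests/Taiga",
    "Mediterranean Forests, Woodlands & Scrub",
)


@dataclasses.dataclass(frozen=True)
class LossScenario:
    """A named habitat-removal process linking t0 to t1."""

    kind: str
    target_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"kind must be one of {SCENARIO_KINDS}, got {self.kind!r}")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError(
                f"target_fraction must be in (0, 1), got {self.target_fraction}"
            )


def gen_fractal_landscape(
    n: int, cell_size: float, p: float, roughness: float, seed: int
) -> BinaryLandscape:
    """Spectrally synthesized binary landscape with habitat proportion ``p``.

    A Gaussian white-noise field is filtered in the Fourier domain with
    amplitude ~ f**(-roughness/2); roughness 0 is white noise, larger
    values give smoother, more aggregated pattern.  The surface is then
    rank-thresholded: the round(p * n**2) highest cells become habitat,
    so the realized proportion is within 1/n**2 of ``p``.
    """
    if n < 8:
        raise ValueError(f"n must be >= 8, got {n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if roughness < 0:
        raise ValueError(f"roughness must be >= 0, got {roughness}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n, n))
    fx = np.fft.fftfreq(n)
    freq = np.hypot(fx[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(freq > 0, freq ** (-roughness / 2.0), 0.0)
    surface = np.fft.ifft2(np.fft.fft2(white) * amp).real
    n_habitat = int(round(p * n * n))
    n_habitat = min(max(n_habitat, 1), n * n - 1)
    # stable argsort makes ties (none, in practice) row-major deterministic
    order = np.argsort(surface, axis=None, kind="stable")
    cells = np.zeros(n * n, dtype=np.int8)
    cells[order[-n_habitat:]] = HABITAT
    return BinaryLandscape(cells.reshape(n, n), cell_size)


_ROOK = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _remove_random(habitat: np.ndarray, target_cells: int, rng) -> None:
    idx = np.flatnonzero(habitat)
    chosen = rng.choice(idx, size=target_cells, replace=False)
    habitat.flat[chosen] = False


def _remove_erosion(habitat: np.ndarray, target_cells: int) -> None:
    """Peel habitat from the edges: repeatedly remove the habitat cell with
    the most rook non-habitat neighbors, ties broken in row-major order."""
    nrows, ncols = habitat.shape
    # count of rook neighbors that are non-habitat (in-grid only)
    nonhab = ~habitat
    counts = np.zeros_like(habitat, dtype=np.int16)
    counts[:-1, :] += nonhab[1:, :]
    counts[1:, :] += nonhab[:-1, :]
    counts[:, :-1] += nonhab[:, 1:]
    counts[:, 1:] += nonhab[:, :-1]
    for _ in range(target_cells):
        masked = np.where(habitat, counts, -1)
        flat = int(np.argmax(masked))  # first max = row-major tie-break
        r, c = divmod(flat, ncols)
        habitat[r, c] = False
        for dr, dc in _ROOK:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                counts[rr, cc] += 1


def _remove_patches(
    habitat: np.ndarray, target_fraction: float, n_habitat: int, connectivity: int
) -> int:
    """Remove whole patches, smallest first, while staying within the target.

    Returns the number of cells removed; warns if even the smallest
    patch exceeds the budget (nothing removed, never a partial patch).
    """
    ls = BinaryLandscape(habitat.astype(np.int8), 1.0)
    labeling = label_patches(ls, connectivity)
    order = sorted(range(labeling.n_patches), key=lambda k: (labeling.patch_sizes[k], k))
    budget = target_fraction * n_habitat
    removed = 0
    doomed = []
    for k in order:
        size = int(labeling.patch_sizes[k])
        if removed + size > budget:
            break
        doomed.append(k + 1)
        removed += size
    if removed == 0:
        warnings.warn(
            "patch_removal: smallest patch exceeds the removal target; "
            "no habitat removed",
            stacklevel=3,
        )
        return 0
    habitat[np.isin(labeling.labels, doomed)] = False
    return removed


def _remove_dissection(
    habitat: np.ndarray, target_cells: int, n_habitat: int, target_fraction: float, rng
) -> int:
    """Cut a full row or column strip through the map, clipped to the target."""
    nrows, ncols = habitat.shape
    n_side = nrows  # square grids in practice
    width = max(1, int(round(target_fraction * n_habitat / n_side)))
    horizontal = bool(rng.integers(2))
    extent = nrows if horizontal else ncols
    width = min(width, extent)
    start = int(rng.integers(0, extent - width + 1))
    strip = (
        habitat[start : start + width, :]
        if horizontal
        else habitat[:, start : start + width]
    )
    hit = np.flatnonzero(strip)  # row-major within the strip
    hit = hit[:target_cells]
    strip.flat[hit] = False
    return len(hit)


def _remove_perforation(habitat: np.ndarray, target_cells: int, rng) -> int:
    """Punch single-cell holes in patch interiors until the target is met
    or no interior cells remain."""
    padded = np.pad(habitat, 1, constant_values=False)
    interior = (
        habitat
        & padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    nrows, ncols = habitat.shape
    removed = 0
    while removed < target_cells:
        idx = np.flatnonzero(interior)
        if idx.size == 0:
            break
        flat = int(idx[rng.integers(idx.size)])
        r, c = divmod(flat, ncols)
        habitat[r, c] = False
        interior[r, c] = False
        for dr, dc in _ROOK:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                interior[rr, cc] = False  # a neighbor lost a habitat side
        removed += 1
    return removed


def apply_loss(
    ls: BinaryLandscape, scenario: LossScenario, connectivity: int = 8
) -> tuple[BinaryLandscape, float]:
    """Remove habitat from ``ls`` per the scenario; never create habitat.

    Returns the t1 landscape and the realized removed fraction
    (cells removed / habitat cells at t0).
    """
    n_habitat = ls.n_habitat
    if n_habitat == 0:
        raise ValueError("landscape has no habitat to remove")
    rng = np.random.default_rng(scenario.seed)
    habitat = ls.habitat_mask().copy()
    f = scenario.target_fraction
    target_cells = min(math.ceil(f * n_habitat), n_habitat - 0)
    if scenario.kind == "random":
        _remove_random(habitat, target_cells, rng)
        removed = target_cells
    elif scenario.kind == "erosion":
        _remove_erosion(habitat, target_cells)
        removed = target_cells
    elif scenario.kind == "patch_removal":
        removed = _remove_patches(habitat, f, n_habitat, connectivity)
    elif scenario.kind == "dissection":
        removed = _remove_dissection(habitat, target_cells, n_habitat, f, rng)
    elif scenario.kind == "perforation":
        removed = _remove_perforation(habitat, target_cells, rng)
    else:  # pragma: no cover - guarded by LossScenario
        raise ValueError(scenario.kind)
    cells = ls.cells.copy()
    cells[(ls.cells == HABITAT) & ~habitat] = NONHABITAT
    out = dataclasses.replace(ls, cells=cells)
    return out, removed / n_habitat


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    """Sampling design for a paired-year synthetic cohort.

    Each landscape draws a habitat proportion, a roughness, a loss
    scenario and a biome label, builds the t0 map, applies the loss, and
    is measured inside circular windows at every radius.  Per-landscape
    seeds are ``seed + index`` so any record can be regenerated alone.
    """

    n_landscapes: int = 500
    n_cells: int = 40
    cell_size: float = 30.0
    p_range: tuple[float, float] = (0.2, 0.8)
    roughness_range: tuple[float, float] = (0.5, 3.0)
    scenario_weights: dict[str, float] = dataclasses.field(
        default_factory=lambda: {k: 1.0 / len(SCENARIO_KINDS) for k in SCENARIO_KINDS}
    )
    loss_range: tuple[float, float] = (0.05, 0.3)
    radii: tuple[float, ...] = (250.0, 500.0)
    biomes: tuple[str, ...] = FORESTED_BIOMES
    connectivity: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landscapes <= 0 or self.n_cells < 8:
            raise ValueError("n_landscapes must be > 0 and n_cells >= 8")
        if not math.isclose(sum(self.scenario_weights.values()), 1.0, abs_tol=1e-9):
            raise ValueError("scenario_weights must sum to 1")
        unknown = set(self.scenario_weights) - set(SCENARIO_KINDS)
        if unknown:
            raise ValueError(f"unknown scenario kinds: {sorted(unknown)}")
        for lo, hi in (self.p_range, self.loss_range):
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("p_range and loss_range must lie within (0, 1)")
        if list(self.radii) != sorted(self.radii) or min(self.radii) <= 0:
            raise ValueError("radii must be positive and increasing")
        half_extent = self.n_cells * self.cell_size / 2.0
        if max(self.radii) > half_extent:
            raise ValueError(
                f"largest radius {max(self.radii)} m does not fit in a "
                f"{self.n_cells}-cell grid (half-extent {half_extent} m)"
            )


METRIC_COLUMNS = ("p_habitat", "patch_number", "edge_density", "mean_patch_size")


def _metric_row(metrics, suffix: str) -> dict[str, float]:
    return {
        f"p_habitat_{suffix}": metrics.p_habitat,
        f"patch_number_{suffix}": metrics.n_patches,
        f"edge_density_{suffix}": metrics.edge_density,
        f"mean_patch_size_{suffix}": metrics.mean_patch_size,
    }


def gen_cohort(
    config: SyntheticCohortConfig, return_landscapes: bool = False
):
    """Generate a paired-year cohort of measured landscapes.

    Returns a DataFrame with one row per landscape x radius carrying the
    draw parameters, the realized loss, and the four metrics at t0 and
    t1.  With ``return_landscapes`` also returns the list of
    ``(t0, t1)`` full-grid landscape pairs (for writing rasters).
    """
    kinds = sorted(config.scenario_weights)
    weights = np.array([config.scenario_weights[k] for k in kinds])
    center = (
        config.n_cells * config.cell_size / 2.0,
        config.n_cells * config.cell_size / 2.0,
    )
    rows = []
    pairs = []
    for i in range(config.n_landscapes):
        seed_i = int(config.seed + i)
        rng = np.random.default_rng(seed_i)
        p = float(rng.uniform(*config.p_range))
        roughness = float(rng.uniform(*config.roughness_range))
        kind = str(rng.choice(kinds, p=weights))
        f = float(rng.uniform(*config.loss_range))
        biome = str(rng.choice(config.biomes))
        t0 = gen_fractal_landscape(
            config.n_cells, config.cell_size, p, roughness, seed_i
        )
        scenario = LossScenario(kind=kind, target_fraction=f, seed=seed_i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # patch_removal budget misses are benign
            t1, realized = apply_loss(t0, scenario, config.connectivity)
        if return_landscapes:
            pairs.append((t0, t1))
        base = {
            "id": i,
            "seed": seed_i,
            "biome": biome,
            "scenario": kind,
            "target_fraction": f,
            "realized_fraction": realized,
            "p_draw": p,
            "roughness": roughness,
        }
        for radius in config.radii:
            m0 = compute_metrics(
                delineate_landscape(t0, center, radius), config.connectivity
            )
            m1 = compute_metrics(
                delineate_landscape(t1, center, radius), config.connectivity
            )
            rows.append(
                {
                    **base,
                    "radius_m": radius,
                    "landscape_area_ha": m0.landscape_area_ha,
                    **_metric_row(m0, "t0"),
                    **_metric_row(m1, "t1"),
                }
            )
    records = pd.DataFrame(rows)
    if return_landscapes:
        return records, pairs
    return records
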