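"""End-to-end pipeline stages and their CSV contracts.

Three stages, each independently runnable and connected by CSV:

1. ``run_metrics`` — rasters + points -> long metrics table (one row per
   landscape x radius x year).
2. ``run_change`` — paired-year metrics -> per-landscape change records
   (loss, deltas, composite index, classifications) + grouped outcome
   summaries.
3. ``run_simulate`` — synthetic cohort -> the same downstream outputs,
   with no input data at all.

Every stage logs candidate/retained/refused counts, and ``write_run``
drops a JSON metadata sidecar (config echo + seed) next to each output
so any file can be regenerated from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import change as chg
from .ffi import compute_ffi, fit_ffi_params
from .landscape import BinaryLandscape, compute_metrics, delineate_landscape, remove_small_patches
from .synthetic import SyntheticCohortConfig, gen_cohort, METRIC_COLUMNS
from .rasters import write_ascii_grid

logger = logging.getLogger("forestfrag")

DEFAULT_RADII = (250.0, 500.0, 1000.0, 2500.0, 5000.0, 10000.0)

YEARS = ("t0", "t1")


@dataclasses.dataclass
class RunConfig:
    """Knobs shared across pipeline stages (mirrors the CLI flags)."""

    radii: tuple[float, ...] = DEFAULT_RADII
    connectivity: int = 8
    fence_k: float = 1.5
    capped: bool = True
    lower_fence_sign: str = "minus"
    norm_mode: str = "per-year"
    eps: float = chg.DEFAULT_EPS
    min_patch_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if list(radii) != sorted(set(radii)) or min(radii) <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        self.radii = radii


def run_metrics(
    landscapes: dict[str, BinaryLandscape],
    points: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Measure every point x radius x year; refuse out-of-extent buffers.

    ``landscapes`` maps year keys ("t0", "t1") to full-extent binary
    rasters.  Returns the long metrics table; refused landscapes are
    logged with the reason and simply absent from the output.
    """
    config = config or RunConfig()
    if config.min_patch_cells > 0:
        landscapes = {
            yr: remove_small_patches(ls, config.min_patch_cells, config.connectivity)
            for yr, ls in landscapes.items()
        }
    rows = []
    refused = 0
    for pt in points.itertuples(index=False):
        for radius in config.radii:
            for year in YEARS:
                try:
                    window = delineate_landscape(
                        landscapes[year], (pt.x, pt.y), radius
                    )
                except ValueError as exc:
                    refused += 1
                    logger.warning(
                        "refused point %s at radius %g m (%s): %s",
                        pt.id, radius, year, exc,
                    )
                    continue
                m = compute_metrics(window, config.connectivity)
                rows.append(
                    {
                        "id": pt.id,
                        "biome": getattr(pt, "biome", "unknown"),
                        "radius_m": radius,
                        "year": year,
                        "p_habitat": m.p_habitat,
                        "patch_number": m.n_patches,
                        "edge_density": m.edge_density,
                        "mean_patch_size": m.mean_patch_size,
                        "landscape_area_ha": m.landscape_area_ha,
                    }
                )
    logger.info(
        "metrics: %d candidate measurements, %d computed, %d refused",
        len(points) * len(config.radii) * len(YEARS), len(rows), refused,
    )
    return pd.DataFrame(rows)


def _pivot_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Long (id, radius, year) metrics -> one wide row per id x radius."""
    need = {"id", "radius_m", "year"} | set(METRIC_COLUMNS)
    missing = need - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    keep_keys = ["id", "radius_m"] + (
        ["biome"] if "biome" in metrics.columns else []
    )
    value_cols = list(METRIC_COLUMNS) + (
        ["landscape_area_ha"] if "landscape_area_ha" in metrics.columns else []
    )
    wide = metrics.pivot_table(
        index=keep_keys, columns="year", values=value_cols, sort=False
    )
    wide.columns = [f"{m}_{yr}" for m, yr in wide.columns]
    wide = wide.reset_index()
    if "landscape_area_ha_t0" in wide.columns:
        wide = wide.rename(columns={"landscape_area_ha_t0": "landscape_area_ha"})
        wide = wide.drop(columns=["landscape_area_ha_t1"], errors="ignore")
    # keep only complete year pairs
    pair_cols = [f"{m}_{yr}" for m in METRIC_COLUMNS for yr in YEARS]
    return wide.dropna(subset=[c for c in pair_cols if c in wide.columns])


def run_change(
    metrics: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive change records and grouped summaries from paired-year metrics.

    Accepts either the long metrics table from ``run_metrics`` or an
    already-wide table with ``<metric>_t0`` / ``<metric>_t1`` columns.
    Only landscapes that lost habitat are retained; the composite
    fragmentation index is fitted on the retained cohort separately for
    each radius.  Raises if no landscape lost habitat.
    """
    config = config or RunConfig()
    wide = metrics if "p_habitat_t0" in metrics.columns else _pivot_metrics(metrics)
    records = chg.annotate_records(wide, eps=config.eps)
    n_candidates = len(records)
    records = chg.retain_losing(records).copy()
    if len(records) == 0:
        raise ValueError("no landscape lost habitat between the two years")
    logger.info(
        "change: %d candidate records, %d retained (lost habitat), %d dropped",
        n_candidates, len(records), n_candidates - len(records),
    )
    # composite index per radius, fences fitted on the later year
    for radius, grp in records.groupby("radius_m", sort=False):
        if len(grp) < 2:
            logger.warning(
                "radius %g m: only %d retained record(s); composite index skipped",
                radius, len(grp),
            )
            continue
        rename = {
            "patch_number": "patch_number",
            "edge_density": "edge_density",
            "mean_patch_size": "mean_patch_size",
        }
        cohorts = {
            yr: grp[[f"{m}_{yr}" for m in rename]].rename(
                columns={f"{m}_{yr}": m for m in rename}
            )
            for yr in YEARS
        }
        params = fit_ffi_params(
            cohorts["t1"],
            cohorts["t0"],
            fence_k=config.fence_k,
            capped=config.capped,
            lower_fence_sign=config.lower_fence_sign,
            norm_mode=config.norm_mode,
        )
        for yr in YEARS:
            vals = compute_ffi(params, cohorts[yr], yr)
            records.loc[grp.index, f"ffi_{yr}"] = vals["ffi"].to_numpy()
    if "ffi_t0" in records.columns:
        records["delta_ffi"] = records["ffi_t1"] - records["ffi_t0"]
        records["class_ffi"] = [
            chg.classify_change(d, "ffi", config.eps) if pd.notna(d) else pd.NA
            for d in records["delta_ffi"]
        ]
    summaries = pd.concat(
        [
            chg.summarize(records, group_by=g)
            for g in ("radius", "cover_bin", "loss_bin", "biome")
        ],
        ignore_index=True,
    )
    return records, summaries


def run_simulate(
    cohort_config: SyntheticCohortConfig,
    config: RunConfig | None = None,
    out_dir: str | None = None,
    write_rasters: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort and run the change analysis end to end.

    Returns (metrics records from the generator, change records,
    summaries).  With ``out_dir`` the three CSVs, a manifest and a
    metadata sidecar are written; ``write_rasters`` additionally dumps
    every t0/t1 grid as an ASCII raster under ``out_dir/rasters``.
    """
    config = config or RunConfig(radii=cohort_config.radii, seed=cohort_config.seed)
    result = gen_cohort(cohort_config, return_landscapes=write_rasters)
    cohort, pairs = result if write_rasters else (result, [])
    records, summaries = run_change(cohort, config)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = cohort.drop_duplicates("id")[
            ["id", "seed", "p_draw", "roughness", "scenario",
             "target_fraction", "realized_fraction", "biome"]
        ]
        write_run(
            out_dir,
            {"metrics": cohort, "records": records,
             "summaries": summaries, "manifest": manifest},
            {"cohort_config": dataclasses.asdict(cohort_config),
             "run_config": dataclasses.asdict(config)},
        )
        if write_rasters:
            rdir = os.path.join(out_dir, "rasters")
            os.makedirs(rdir, exist_ok=True)
            for i, (t0, t1) in enumerate(pairs):
                for yr, ls in (("t0", t0), ("t1", t1)):
                    write_ascii_grid(
                        ls.cells, os.path.join(rdir, f"landscape_{i:05d}_{yr}.asc"),
                        ls.cell_size,
                    )
    return cohort, records, summaries


def write_run(out_dir: str, tables: dict[str, pd.DataFrame], config_echo: dict) -> None:
    """Write each table as CSV plus one run_metadata.json sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
    meta = {"outputs": sorted(tables), "config": config_echo}
    with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
        fh.write("\n")
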