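"""Loss, per-metric change, and fragmentation-change classification.

Records pair two time points per landscape and radius.  Forest loss is
p(t0) - p(t1), so positive values mean net loss.  Each metric's change
is value(t1) - value(t0); for patch number, edge density and the
composite index a positive change means *more* fragmentation, while for
mean patch size the sign is reversed (smaller patches = more
fragmented).  Classifications are reported in fragmentation terms so
"increase" always means increased fragmentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Metrics that can be classified, with their fragmentation orientation.
#: +1: a positive delta means more fragmentation; -1: reversed.
METRIC_ORIENTATION = {
    "patch_number": 1,
    "edge_density": 1,
    "mean_patch_size": -1,
    "ffi": 1,
}

CLASS_LABELS = ("increase", "decrease", "no_change")

#: Default absolute tolerance below which a continuous change counts as
#: no change.  Patch number is integer-valued and always uses eps = 0.
DEFAULT_EPS = 1e-9


def forest_loss(p_t0: float, p_t1: float) -> float:
    """Net loss of habitat proportion: p(t0) - p(t1), in [-1, 1]."""
    for name, p in (("p_t0", p_t0), ("p_t1", p_t1)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return p_t0 - p_t1


def retain_losing(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only landscapes that lost habitat (forest_loss > 0), order preserved."""
    if "forest_loss" not in records.columns:
        raise KeyError("records must have a forest_loss column")
    return records[records["forest_loss"] > 0]


def classify_change(delta: float, metric: str, eps: float = DEFAULT_EPS) -> str:
    """Classify one metric change as increase/decrease/no_change in fragmentation.

    The delta is first oriented so positive always means more
    fragmentation (mean patch size is sign-flipped).  |oriented| <= eps
    is no change; eps is forced to 0 for the integer patch count.
    """
    if metric not in METRIC_ORIENTATION:
        raise ValueError(f"unknown metric: {metric!r}")
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    if metric == "patch_number":
        eps = 0.0
    oriented = METRIC_ORIENTATION[metric] * delta
    if abs(oriented) <= eps:
        return "no_change"
    return "increase" if oriented > 0 else "decrease"


def bin_cover(p: float, width: float = 0.2) -> str:
    """Bin a habitat proportion into half-open intervals of ``width``.

    Bins are [0, w), [w, 2w), ...; the top bin is closed so p = 1 falls
    in [1-w, 1.0].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    n_bins = int(round(1.0 / width))
    i = min(int(p / width), n_bins - 1)
    lo, hi = i * width, (i + 1) * width
    close = "]" if i == n_bins - 1 else ")"
    return f"[{lo:.1f}, {hi:.1f}{close}"


def bin_loss(loss: float, width: float = 0.1) -> str:
    """Bin a positive forest loss into half-open intervals of ``width`` on (0, 1]."""
    if not 0.0 < loss <= 1.0:
        raise ValueError(f"loss must be in (0, 1], got {loss}")
    n_bins = int(round(1.0 / width))
    # left-open bins (0, w], (w, 2w], ... so loss = w lands in the first bin
    i = min(int(np.ceil(loss / width)) - 1, n_bins - 1)
    lo, hi = i * width, (i + 1) * width
    return f"({lo:.1f}, {hi:.1f}]"


_GROUP_COLUMNS = {
    "radius": "radius_m",
    "cover_bin": "cover_bin",
    "loss_bin": "loss_bin",
    "biome": "biome",
}


def annotate_records(
    records: pd.DataFrame,
    eps: float = DEFAULT_EPS,
    cover_bin_width: float = 0.2,
    loss_bin_width: float = 0.1,
) -> pd.DataFrame:
    """Add loss, deltas, classifications and grouping bins to paired-year rows.

    ``records`` needs per-year metric columns ``<metric>_t0`` /
    ``<metric>_t1`` for patch_number, edge_density, mean_patch_size,
    optionally ffi, plus ``p_habitat_t0`` / ``p_habitat_t1``.  Returns a
    copy with ``forest_loss``, ``delta_<metric>``, ``class_<metric>``,
    ``cover_bin`` (on t0 cover) and ``loss_bin`` columns.
    """
    out = records.copy()
    out["forest_loss"] = out["p_habitat_t0"] - out["p_habitat_t1"]
    for metric in METRIC_ORIENTATION:
        c0, c1 = f"{metric}_t0", f"{metric}_t1"
        if c0 not in out.columns:
            continue
        out[f"delta_{metric}"] = out[c1] - out[c0]
        out[f"class_{metric}"] = [
            classify_change(d, metric, eps) for d in out[f"delta_{metric}"]
        ]
    out["cover_bin"] = [bin_cover(p, cover_bin_width) for p in out["p_habitat_t0"]]
    out["loss_bin"] = [
        bin_loss(l, loss_bin_width) if l > 0 else pd.NA for l in out["forest_loss"]
    ]
    return out


def summarize(
    records: pd.DataFrame,
    group_by: str = "radius",
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Outcome frequencies per group: % increase / decrease / no change.

    ``group_by`` is one of radius, cover_bin, loss_bin, biome.  Records
    must already be restricted to losing landscapes and annotated with
    ``class_<metric>`` columns.  Returns one row per group x metric with
    columns group_key, metric, pct_increase, pct_decrease,
    pct_no_change, n; percentages sum to 100 per row and empty groups
    are omitted.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    if group_by not in _GROUP_COLUMNS:
        raise ValueError(
            f"group_by must be one of {sorted(_GROUP_COLUMNS)}, got {group_by!r}"
        )
    col = _GROUP_COLUMNS[group_by]
    if metrics is None:
        metrics = tuple(
            m for m in METRIC_ORIENTATION if f"class_{m}" in records.columns
        )
    rows = []
    for key, grp in records.groupby(col, observed=True, dropna=True, sort=True):
        n = len(grp)
        for metric in metrics:
            counts = grp[f"class_{metric}"].value_counts()
            rows.append(
                {
                    "group_by": group_by,
                    "group_key": key,
                    "metric": metric,
                    "pct_increase": 100.0 * counts.get("increase", 0) / n,
                    "pct_decrease": 100.0 * counts.get("decrease", 0) / n,
                    "pct_no_change": 100.0 * counts.get("no_change", 0) / n,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
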