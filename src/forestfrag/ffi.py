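"""Composite forest fragmentation index (FFI) over a cohort of landscapes.

The index combines three of the four class metrics — patch number (PN),
edge density (ED) and mean patch area (MPA) — into a single value in
[0, 1]:

    FFI = (PN + ED + (1 - MPA)) / 3

where each component has first been winsorized at Tukey fences fitted on
the *later* year's cohort and then min-max normalized to [0, 1] within
each year.  Mean patch area enters reversed because larger patches mean
*less* fragmentation.  Fences are fitted once per landscape size on the
recent cohort and reused for the earlier year, so outliers in either
year are capped at the same thresholds.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

FFI_METRICS = ("patch_number", "edge_density", "mean_patch_size")

LowerFenceSign = Literal["minus", "plus"]
NormMode = Literal["per-year", "pooled"]


@dataclasses.dataclass(frozen=True)
class Fences:
    """Tukey fences for one metric: quartiles and the derived thresholds."""

    q1: float
    q3: float
    iqr: float
    q_lower: float
    q_upper: float
    fence_k: float = 1.5
    lower_fence_sign: LowerFenceSign = "minus"

    def __post_init__(self) -> None:
        if self.iqr < 0:
            raise ValueError("IQR must be >= 0")
        if self.lower_fence_sign == "minus" and self.q_lower > self.q_upper:
            raise ValueError("q_lower > q_upper")


@dataclasses.dataclass(frozen=True)
class FFIParams:
    """Fences and normalization bounds fitted on a cohort, reusable across years.

    ``fences[m]`` holds the Tukey fences for metric ``m`` (fitted on the
    later year); ``norm_bounds[(m, year)]`` the (lo, hi) min-max bounds of
    that year's capped values.  With ``capped=False`` no winsorization is
    applied and the bounds span the raw values.
    """

    fences: dict[str, Fences]
    norm_bounds: dict[tuple[str, str], tuple[float, float]]
    fence_k: float = 1.5
    capped: bool = True
    lower_fence_sign: LowerFenceSign = "minus"
    norm_mode: NormMode = "per-year"

    def transform(self, values: np.ndarray, metric: str, year: str) -> np.ndarray:
        """Winsorize (if capped) then normalize one metric for one year."""
        values = np.asarray(values, dtype=float)
        if self.capped:
            values = winsorize(values, self.fences[metric])
        lo, hi = self.norm_bounds[(metric, year)]
        return minmax_normalize(values, lo, hi)


@dataclasses.dataclass(frozen=True)
class FFIValue:
    """Normalized components and the composite index, all in [0, 1]."""

    pn_norm: float
    ed_norm: float
    mpa_norm: float
    index: float


def tukey_fences(
    values,
    fence_k: float = 1.5,
    lower_fence_sign: LowerFenceSign = "minus",
    quantile_method: str = "linear",
) -> Fences:
    """Quartiles and outlier fences of a sample.

    Q1/Q3 use linear interpolation between order statistics by default.
    The standard lower fence is Q1 - k*IQR; ``lower_fence_sign="plus"``
    selects the Q1 + k*IQR variant instead.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to fit fences")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if lower_fence_sign not in ("minus", "plus"):
        raise ValueError(f"unknown lower_fence_sign: {lower_fence_sign!r}")
    q1, q3 = np.quantile(values, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    sign = -1.0 if lower_fence_sign == "minus" else 1.0
    return Fences(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        q_lower=float(q1 + sign * fence_k * iqr),
        q_upper=float(q3 + fence_k * iqr),
        fence_k=fence_k,
        lower_fence_sign=lower_fence_sign,
    )


def winsorize(values, fences: Fences) -> np.ndarray:
    """Clamp values below/above the fences to the fence values."""
    values = np.asarray(values, dtype=float)
    lo, hi = fences.q_lower, fences.q_upper
    if lo > hi:  # the "plus" lower-fence variant can invert the band
        return np.where(values > hi, hi, np.where(values < lo, lo, values))
    return np.clip(values, lo, hi)


def minmax_normalize(values, lo: float, hi: float) -> np.ndarray:
    """Map values linearly so lo -> 0 and hi -> 1.

    A degenerate range (hi == lo, a constant metric) maps everything to
    0.5 so the component neither inflates nor deflates the index.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    values = np.asarray(values, dtype=float)
    if hi == lo:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def _metric_arrays(cohort) -> dict[str, np.ndarray]:
    """Accept a DataFrame with the three metric columns, or a mapping."""
    if isinstance(cohort, pd.DataFrame):
        missing = [m for m in FFI_METRICS if m not in cohort.columns]
        if missing:
            raise KeyError(f"cohort is missing metric columns: {missing}")
        return {m: cohort[m].to_numpy(dtype=float) for m in FFI_METRICS}
    return {m: np.asarray(cohort[m], dtype=float) for m in FFI_METRICS}


def fit_ffi_params(
    cohort_t1,
    cohort_t0,
    fence_k: float = 1.5,
    capped: bool = True,
    lower_fence_sign: LowerFenceSign = "minus",
    norm_mode: NormMode = "per-year",
    quantile_method: str = "linear",
) -> FFIParams:
    """Fit fences on the later year's cohort and normalization bounds per year.

    ``cohort_t1`` / ``cohort_t0`` hold the three metrics (columns
    ``patch_number``, ``edge_density``, ``mean_patch_size``) for every
    landscape at one landscape size, for the later and earlier year.
    Fences come from the later year only and cap both years; bounds are
    the per-year min/max of the capped values (``norm_mode="pooled"``
    pools both years instead, for cross-year comparability).
    """
    t1 = _metric_arrays(cohort_t1)
    t0 = _metric_arrays(cohort_t0)
    if t1[FFI_METRICS[0]].size == 0 or t0[FFI_METRICS[0]].size == 0:
        raise ValueError("cohorts must be non-empty")
    fences: dict[str, Fences] = {}
    bounds: dict[tuple[str, str], tuple[float, float]] = {}
    for m in FFI_METRICS:
        f = tukey_fences(t1[m], fence_k, lower_fence_sign, quantile_method)
        fences[m] = f
        v1 = winsorize(t1[m], f) if capped else t1[m]
        v0 = winsorize(t0[m], f) if capped else t0[m]
        if norm_mode == "pooled":
            pooled = np.concatenate([v0, v1])
            b = (float(pooled.min()), float(pooled.max()))
            bounds[(m, "t0")] = bounds[(m, "t1")] = b
        elif norm_mode == "per-year":
            bounds[(m, "t0")] = (float(v0.min()), float(v0.max()))
            bounds[(m, "t1")] = (float(v1.min()), float(v1.max()))
        else:
            raise ValueError(f"unknown norm_mode: {norm_mode!r}")
    return FFIParams(
        fences=fences,
        norm_bounds=bounds,
        fence_k=fence_k,
        capped=capped,
        lower_fence_sign=lower_fence_sign,
        norm_mode=norm_mode,
    )


def ffi(pn_norm: float, ed_norm: float, mpa_norm: float) -> FFIValue:
    """The composite index (PN + ED + (1 - MPA)) / 3 from normalized components."""
    for name, v in (("pn_norm", pn_norm), ("ed_norm", ed_norm), ("mpa_norm", mpa_norm)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return FFIValue(
        pn_norm=pn_norm,
        ed_norm=ed_norm,
        mpa_norm=mpa_norm,
        index=(pn_norm + ed_norm + (1.0 - mpa_norm)) / 3.0,
    )


def compute_ffi(params: FFIParams, cohort, year: str) -> pd.DataFrame:
    """Apply fitted params to a cohort's metrics for one year.

    Returns a DataFrame with columns ``pn_norm``, ``ed_norm``,
    ``mpa_norm``, ``ffi`` aligned with the input rows.  Normalized
    components are clipped to [0, 1] (an uncapped fit can push the other
    year's values slightly outside the fitted bounds).
    """
    arrays = _metric_arrays(cohort)
    comp = {}
    for m, col in zip(FFI_METRICS, ("pn_norm", "ed_norm", "mpa_norm")):
        comp[col] = np.clip(params.transform(arrays[m], m, year), 0.0, 1.0)
    out = pd.DataFrame(comp)
    out["ffi"] = (out["pn_norm"] + out["ed_norm"] + (1.0 - out["mpa_norm"])) / 3.0
    if isinstance(cohort, pd.DataFrame):
        out.index = cohort.index
    return out
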