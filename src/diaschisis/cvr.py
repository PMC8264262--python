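"""Voxelwise BOLD cerebrovascular reactivity (CVR) mapping.

CVR is the percent BOLD signal change per mmHg change in end-tidal CO2,
estimated per voxel as the ordinary-least-squares slope of the raw signal
time course on the CO2 regressor, normalized by the voxel's temporal-mean
signal:

    CVR_v = 100 * b_v / mean_t(S_v)   [%BOLD / mmHg]

The same module provides PET-style percent-difference indices between a
baseline and an acetazolamide (Diamox) perfusion map; PET values are treated
as relative units, so only ratio/difference indices are ever reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateStimulusError,
    EmptyRegionError,
    UndefinedRatioError,
)

__all__ = [
    "CO2Trace",
    "BoldSeries",
    "CvrMap",
    "resample_trace",
    "align_co2_to_bold",
    "compute_cvr_map",
    "roi_mean_cvr",
    "pet_percent_difference",
]


@dataclass(frozen=True)
class CO2Trace:
    """Sampled end-tidal CO2 partial pressure over time.

    times_s are sample midpoints, strictly increasing; values in mmHg > 0.
    """

    times_s: np.ndarray
    values_mmHg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values_mmHg, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("CO2 partial pressures must be positive")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values_mmHg", v)

    @property
    def sampling_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0]) if self.times_s.size > 1 else 0.0

    def mean(self) -> float:
        return float(self.values_mmHg.mean())


@dataclass
class BoldSeries:
    """4-D BOLD signal array (x, y, z, t) with repetition interval and voxel size."""

    data: np.ndarray
    tr_s: float
    voxel_dims_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[-1] < 3:
            raise ValueError("need at least 3 volumes for a slope with df >= 1")
        if self.tr_s <= 0:
            raise ValueError("repetition interval must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def volume_midpoints_s(self) -> np.ndarray:
        """Acquisition midpoints of each volume on the scanner clock."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr_s


@dataclass
class CvrMap:
    """3-D map of %BOLD per mmHg with a validity mask (finite & above background)."""

    data: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.data.shape != self.valid_mask.shape:
            raise ValueError("map and mask shapes differ")
        if not np.all(np.isfinite(self.data[self.valid_mask])):
            raise ValueError("CVR map must be finite wherever valid")


def resample_trace(co2: CO2Trace, n_volumes: int, tr_s: float, delay_s: float = 0.0) -> np.ndarray:
    """Linear interpolation of a (shifted) CO2 trace at volume midpoints."""
    query = (np.arange(n_volumes) + 0.5) * tr_s - delay_s
    t, v = co2.times_s, co2.values_mmHg
    lo, hi = float(t[0]), float(t[-1])
    # tolerate sub-millisecond rounding at the window edges
    if query[0] < lo - 1e-3 or query[-1] > hi + 1e-3:
        raise AlignmentError(
            f"CO2 trace [{lo:.2f}, {hi:.2f}] s does not cover BOLD window "
            f"[{query[0]:.2f}, {query[-1]:.2f}] s after {delay_s} s delay"
        )
    return np.interp(np.clip(query, lo, hi), t, v)


def align_co2_to_bold(co2: CO2Trace, series: BoldSeries, delay_s: float = 0.0) -> np.ndarray:
    """Resample a CO2 trace onto the BOLD volume time base.

    The trace is shifted by ``delay_s`` (positive = BOLD lags the gas trace)
    and linearly interpolated at each volume's acquisition midpoint. Raises
    :class:`AlignmentError` when the shifted trace does not cover the
    acquisition window.
    """
    return resample_trace(co2, series.n_volumes, series.tr_s, delay_s)


def compute_cvr_map(
    series: BoldSeries,
    regressor: np.ndarray,
    background_floor_frac: float = 0.10,
    baseline_epoch_s: tuple[float, float] | None = None,
) -> CvrMap:
    """Per-voxel OLS slope of raw signal on the CO2 regressor, percent-normalized.

    Normalization uses the whole-series temporal mean by default
    (protocol-independent); pass ``baseline_epoch_s=(start, end)`` to
    normalize by the mean over that acquisition window instead. Voxels whose
    normalizing mean falls below ``background_floor_frac`` times the robust
    (99th percentile) maximum of the mean image, or whose estimate is
    non-finite, are masked invalid (and set to 0).
    """
    x = np.asarray(regressor, dtype=float)
    if x.ndim != 1 or x.size != series.n_volumes:
        raise ValueError("regressor length must equal the number of volumes")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegenerateStimulusError("CO2 regressor has zero variance")

    data = series.data
    slope = data @ xc.astype(data.dtype) / sxx
    if baseline_epoch_s is None:
        mean_img = data.mean(axis=-1, dtype=np.float64)
    else:
        t0, t1 = baseline_epoch_s
        sel = (series.volume_midpoints_s() >= t0) & (series.volume_midpoints_s() <= t1)
        if not sel.any():
            raise ValueError("baseline epoch contains no volumes")
        mean_img = data[..., sel].mean(axis=-1, dtype=np.float64)
    robust_max = float(np.percentile(mean_img, 99))
    floor = background_floor_frac * robust_max
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr = 100.0 * slope / mean_img
    valid = (mean_img > floor) & np.isfinite(cvr)
    cvr = np.where(valid, cvr, 0.0)
    return CvrMap(data=cvr, valid_mask=valid, affine=series.affine)


def roi_mean_cvr(cvr: CvrMap, atlas, region_id: int) -> tuple[float, int]:
    """Mean CVR over the valid voxels of a labeled region.

    Returns ``(mean, n_valid)``; raises :class:`EmptyRegionError` when the
    region has no valid voxels on the map.
    """
    labels = atlas.data if hasattr(atlas, "data") else np.asarray(atlas)
    if labels.shape != cvr.data.shape:
        raise ValueError("atlas and CVR map grids differ")
    sel = (labels == region_id) & cvr.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyRegionError(f"region {region_id} has no valid voxels")
    return float(cvr.data[sel].mean()), n


def pet_percent_difference(
    baseline_map: np.ndarray,
    diamox_map: np.ndarray,
    atlas,
    region_id: int,
) -> float:
    """PET-CVR index: 100 * (mean_diamox - mean_baseline) / mean_baseline over a region."""
    base = np.asarray(baseline_map, dtype=float)
    diam = np.asarray(diamox_map, dtype=float)
    labels = atlas.data if hasattr(atlas, "data") else np.asarray(atlas)
    if base.shape != diam.shape or base.shape != labels.shape:
        raise ValueError("perfusion maps and atlas must share one grid")
    sel = labels == region_id
    if not sel.any():
        raise EmptyRegionError(f"region {region_id} absent from atlas")
    mb = float(base[sel].mean())
    if mb <= 0.0:
        raise UndefinedRatioError("non-positive baseline region mean")
    return 100.0 * (float(diam[sel].mean()) - mb) / mb
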