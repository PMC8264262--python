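"""Synthetic stroke-brain phantom cohorts.

Generates ground-truth subjects — label atlases, 4-D BOLD series driven by a
block hypercapnic CO2 protocol, and baseline/Diamox perfusion map pairs — so
the whole CVR/volumetry/classification pipeline can be exercised without any
real MRI or PET data.

Design notes
------------
* Two co-registered grids per subject: a 1 mm "anatomical" grid used for
  volumetry and a 3 mm BOLD grid (64 x 64 x 35) used for signal simulation
  and CVR extraction, mirroring a typical high-resolution T1 + EPI protocol.
* Regions are ellipsoids rasterized by exact voxel-count selection (the N
  voxels nearest to the centroid in ellipsoid-normalized distance), so the
  rasterized volume always matches the target within one voxel volume.
* The BOLD signal for a voxel of a region with reactivity ``cvr`` is

      S(t) = S0 * (1 + cvr/100 * (CO2(t) - <CO2>)) + drift*t + eps

  with the CO2 trace centered at its temporal mean, making S0 the mean
  signal level; downstream percent-of-mean OLS then recovers ``cvr``
  exactly in the noiseless case. Gaussian noise is per-subject seeded.
* Default cohort composition follows the study design the phantom emulates:
  17 chronic / 13 acute-subacute / 17 healthy subjects, 8 chronic with
  Wallerian degeneration (WD), 9 with ipsilateral thalamic diaschisis (ITD),
  7 with crossed cerebellar diaschisis (CCD). Group membership is assigned by
  exact counts shuffled by seed, and reference-index sets are moment-matched
  (normal quantiles rescaled to the stated sample mean/SD), so the
  composition is reproduced for any seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import norm, truncnorm

from .cvr import CO2Trace, BoldSeries, resample_trace
from .errors import GenerationError, InvalidProtocolError, SpecError
from .regions import REGION_IDS, LabelAtlas, volume_asymmetry_index

__all__ = [
    "DEFAULT_SEED",
    "Co2Protocol",
    "RegionSpec",
    "SubjectPhantomSpec",
    "CohortSpec",
    "PhantomGeometry",
    "SubjectData",
    "render_co2_trace",
    "rasterize_atlas",
    "rasterize_stroke_mask",
    "simulate_bold",
    "simulate_perfusion_pair",
    "generate_cohort_specs",
    "realize_subject",
    "generate_cohort",
    "default_cohort_spec",
]

#: Packaged fixture seed (any seed reproduces the cohort composition; this one
#: pins the default fixture bit-for-bit).
DEFAULT_SEED = 20210624

STROKE_CVR = 0.02  # %/mmHg inside the lesion
STROKE_CBF = 16.0  # relative perfusion units inside the lesion


# ---------------------------------------------------------------------------
# CO2 protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Co2Protocol:
    """Block hypercapnic end-tidal CO2 protocol.

    ``block_durations_s`` is an ordered list of (level, duration) epochs where
    level is "baseline", "hypercapnia", or an absolute mmHg value.
    """

    baseline_mmHg: float = 37.8
    step_mmHg: float = 9.4
    block_durations_s: tuple = (("baseline", 120.0), ("hypercapnia", 120.0), ("baseline", 120.0))
    sampling_interval_s: float = 2.0
    transition_tau_s: float = 0.0  # 0 = ideal steps

    def __post_init__(self) -> None:
        if self.baseline_mmHg <= 0:
            raise InvalidProtocolError("baseline CO2 must be positive")
        if self.step_mmHg < 0:
            raise InvalidProtocolError("step change must be non-negative")
        if self.sampling_interval_s <= 0:
            raise InvalidProtocolError("sampling interval must be positive")
        if self.total_duration_s <= 0:
            raise InvalidProtocolError("protocol must have positive total duration")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.block_durations_s))

    def level_mmHg(self, name) -> float:
        if isinstance(name, (int, float)):
            return float(name)
        if name == "baseline":
            return self.baseline_mmHg
        if name in ("hypercapnia", "hyper"):
            return self.baseline_mmHg + self.step_mmHg
        raise InvalidProtocolError(f"unknown epoch level {name!r}")


def render_co2_trace(protocol: Co2Protocol) -> CO2Trace:
    """Render a protocol to a sampled trace (sample midpoints).

    Piecewise-constant at the stated levels; an optional first-order
    exponential transition (time constant ``transition_tau_s``) smooths the
    level changes. Trace length is ceil(total duration / interval).
    """
    dt = protocol.sampling_interval_s
    n = math.ceil(protocol.total_duration_s / dt)
    times = (np.arange(n) + 0.5) * dt
    levels = np.empty(n)
    edges = np.cumsum([0.0] + [d for _, d in protocol.block_durations_s])
    epoch_levels = [protocol.level_mmHg(lv) for lv, _ in protocol.block_durations_s]
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(epoch_levels) - 1)
    levels[:] = np.asarray(epoch_levels)[idx]
    if protocol.transition_tau_s > 0:
        decay = math.exp(-dt / protocol.transition_tau_s)
        v = levels[0]
        smoothed = np.empty(n)
        for i, target in enumerate(levels):
            v = target + (v - target) * decay
            smoothed[i] = v
        levels = smoothed
    return CO2Trace(times_s=times, values_mmHg=levels)


# ---------------------------------------------------------------------------
# Subject / cohort specifications
# ---------------------------------------------------------------------------

REGION_NAMES = tuple(REGION_IDS) + ("stroke",)

#: Region centroids (mm) on the 192 x 192 x 105 mm field of view; left = lower x.
_CENTROIDS_MM: dict[str, tuple[float, float, float]] = {
    "peduncle_L": (84.0, 96.0, 30.0),
    "peduncle_R": (108.0, 96.0, 30.0),
    "thalamus_L": (80.0, 90.0, 48.0),
    "thalamus_R": (112.0, 90.0, 48.0),
    "cerebellum_L": (76.0, 130.0, 14.0),
    "cerebellum_R": (116.0, 130.0, 14.0),
    "hemisphere_L": (60.0, 96.0, 73.0),
    "hemisphere_R": (132.0, 96.0, 73.0),
}

#: Ellipsoid aspect ratios (relative semi-axes) per structure stem.
_ASPECTS: dict[str, tuple[float, float, float]] = {
    "peduncle": (0.55, 0.85, 1.5),
    "thalamus": (1.0, 1.0, 1.0),
    "cerebellum": (1.0, 1.0, 1.0),
    "hemisphere": (0.95, 1.55, 0.62),
    "corticospinal_roi": (1.4, 1.4, 0.5),
    "stroke": (1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class RegionSpec:
    """Ground truth for one region: placement, volume, CVR and perfusion."""

    region_id: int
    name: str
    target_volume_cm3: float
    centroid_mm: tuple[float, float, float]
    true_cvr: float = 0.0  # %BOLD/mmHg; may be negative (paradoxical reactivity)
    true_cbf_baseline: float = 0.0  # relative perfusion units
    true_cbf_diamox: float = 0.0
    radii_mm: tuple[float, float, float] | None = None  # explicit shape override

    def __post_init__(self) -> None:
        if self.name != "stroke" and self.target_volume_cm3 <= 0:
            raise SpecError(f"region {self.name}: volume must be positive")
        if self.target_volume_cm3 < 0:
            raise SpecError("stroke volume may be 0 (absent) but not negative")
        if self.true_cbf_baseline < 0 or self.true_cbf_diamox < 0:
            raise SpecError(f"region {self.name}: perfusion must be non-negative")


@dataclass(frozen=True)
class SubjectPhantomSpec:
    """Everything needed to deterministically realize one synthetic subject."""

    subject_id: str
    group: str  # healthy | acute | chronic
    stroke_side: str  # left | right | none
    wd_true: bool
    itd_true: bool
    ccd_true: bool
    regions: tuple[RegionSpec, ...]
    noise_sd: float = 10.0
    drift_per_volume: float = 0.0
    seed: int = 0
    s0: float = 1000.0
    co2: Co2Protocol = field(default_factory=Co2Protocol)
    cst_involved_true: bool = False
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "acute", "chronic"):
            raise SpecError(f"unknown group {self.group!r}")
        if self.group == "healthy" and (
            self.stroke_side != "none" or self.wd_true or self.itd_true or self.ccd_true
        ):
            raise SpecError("healthy subjects must have no stroke and no WD/ITD/CCD")
        if self.group != "healthy" and self.stroke_side not in ("left", "right"):
            raise SpecError("stroke subjects need a stroke side")
        names = {r.name for r in self.regions}
        for stem in ("peduncle", "thalamus", "cerebellum", "hemisphere"):
            if not {f"{stem}_L", f"{stem}_R"} <= names:
                raise SpecError(f"missing left/right homologue pair for {stem}")
        if self.wd_true:
            ipsi = "L" if self.stroke_side == "left" else "R"
            contra = "R" if ipsi == "L" else "L"
            ai = volume_asymmetry_index(
                self.region(f"peduncle_{ipsi}").target_volume_cm3,
                self.region(f"peduncle_{contra}").target_volume_cm3,
            )
            if ai >= -11.0:
                raise SpecError(
                    f"wd_true subject must have peduncular AI beyond the "
                    f"classification threshold by construction (got {ai:.1f}%)"
                )

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def has_stroke(self) -> bool:
        try:
            return self.region("stroke").target_volume_cm3 > 0
        except KeyError:
            return False


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and coupling parameters for the phantom generator."""

    n_healthy: int = 17
    n_acute: int = 13
    n_chronic: int = 17
    wd_fraction: float = 8.0 / 17.0
    itd_prob_given_wd: float = 7.0 / 8.0
    itd_prob_given_no_wd: float = 2.0 / 9.0
    ccd_prob: float = 7.0 / 17.0
    atrophy_coupling: float = 0.77
    cst_prob_given_wd: float = 1.0
    cst_prob_given_no_wd: float = 0.0
    noise_sd: float = 10.0
    drift_per_volume: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in (
            "wd_fraction",
            "itd_prob_given_wd",
            "itd_prob_given_no_wd",
            "ccd_prob",
            "cst_prob_given_wd",
            "cst_prob_given_no_wd",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{name} must be in [0, 1]")
        if min(self.n_healthy, self.n_acute, self.n_chronic) < 0:
            raise SpecError("cohort counts must be non-negative")
        if abs(self.atrophy_coupling) > 1:
            raise SpecError("|atrophy_coupling| must be <= 1")


def default_cohort_spec(seed: int = DEFAULT_SEED) -> CohortSpec:
    """The packaged default fixture: 17 chronic / 13 acute / 17 healthy."""
    return CohortSpec(seed=seed)


@dataclass(frozen=True)
class PhantomGeometry:
    """Co-registered anatomical (volumetry) and BOLD (CVR) grids."""

    anat_shape: tuple[int, int, int] = (192, 192, 105)
    anat_voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bold_shape: tuple[int, int, int] = (64, 64, 35)
    bold_voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0

    def affine(self, voxel_mm) -> np.ndarray:
        return np.diag(list(voxel_mm) + [1.0])


DEFAULT_GEOMETRY = PhantomGeometry()


@dataclass
class SubjectData:
    """One realized phantom subject (arrays in memory)."""

    spec: SubjectPhantomSpec
    anat_atlas: LabelAtlas
    bold_atlas: LabelAtlas
    stroke_mask_anat: np.ndarray
    stroke_mask_bold: np.ndarray
    co2: CO2Trace
    bold: BoldSeries
    pet_baseline: np.ndarray
    pet_diamox: np.ndarray


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _region_radii(region: RegionSpec) -> np.ndarray:
    if region.radii_mm is not None:
        return np.asarray(region.radii_mm, dtype=float)
    stem = region.name.rsplit("_", 1)[0] if region.name not in _ASPECTS else region.name
    aspect = np.asarray(_ASPECTS.get(stem, (1.0, 1.0, 1.0)), dtype=float)
    vol_mm3 = region.target_volume_cm3 * 1000.0
    iso = (3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return aspect * iso / float(np.prod(aspect)) ** (1.0 / 3.0)


def _select_region_voxels(region: RegionSpec, grid_shape, voxel_dims_mm) -> tuple[np.ndarray, ...]:
    """Indices of the N voxels nearest the centroid in ellipsoid-normalized
    distance, N = round(target volume / voxel volume). Deterministic."""
    dims = np.asarray(voxel_dims_mm, dtype=float)
    shape = np.asarray(grid_shape, dtype=int)
    c = np.asarray(region.centroid_mm, dtype=float)
    if np.any(c < 0) or np.any(c > shape * dims):
        raise GenerationError(f"region {region.name}: centroid outside grid")
    voxvol = float(np.prod(dims))
    n_target = max(1, int(round(region.target_volume_cm3 * 1000.0 / voxvol)))
    radii = _region_radii(region)

    for margin in (1.35, 1.8, 2.6, 4.0):
        lo = np.maximum(0, np.floor((c - radii * margin) / dims - 0.5)).astype(int)
        hi = np.minimum(shape, np.ceil((c + radii * margin) / dims + 0.5)).astype(int)
        axes = [np.arange(lo[k], hi[k]) for k in range(3)]
        if any(a.size == 0 for a in axes):
            continue
        coords = [(a + 0.5) * dims[k] for k, a in enumerate(axes)]
        d2 = (
            ((coords[0][:, None, None] - c[0]) / radii[0]) ** 2
            + ((coords[1][None, :, None] - c[1]) / radii[1]) ** 2
            + ((coords[2][None, None, :] - c[2]) / radii[2]) ** 2
        )
        flat = d2.ravel()
        if flat.size < n_target:
            continue
        order = np.argsort(flat, kind="stable")[:n_target]
        if flat[order[-1]] > margin**2:  # bbox truncated the candidate shell
            continue
        ii, jj, kk = np.unravel_index(order, d2.shape)
        return axes[0][ii], axes[1][jj], axes[2][kk]
    raise GenerationError(
        f"region {region.name}: cannot place {n_target} voxels inside the grid"
    )


def rasterize_atlas(
    spec: SubjectPhantomSpec,
    grid_shape=DEFAULT_GEOMETRY.anat_shape,
    voxel_dims_mm=DEFAULT_GEOMETRY.anat_voxel_mm,
) -> LabelAtlas:
    """Rasterize all labeled regions (not the stroke) as non-overlapping
    ellipsoids whose voxel count matches the target volume within one voxel."""
    labels = np.zeros(tuple(grid_shape), dtype=np.int16)
    for region in spec.regions:
        if region.name == "stroke" or region.target_volume_cm3 <= 0:
            continue
        idx = _select_region_voxels(region, grid_shape, voxel_dims_mm)
        if np.any(labels[idx] != 0):
            raise GenerationError(f"region {region.name} overlaps an earlier region")
        labels[idx] = region.region_id
    affine = np.diag(list(voxel_dims_mm) + [1.0])
    return LabelAtlas(data=labels, voxel_dims_mm=tuple(voxel_dims_mm), affine=affine)


def rasterize_stroke_mask(
    spec: SubjectPhantomSpec,
    grid_shape=DEFAULT_GEOMETRY.anat_shape,
    voxel_dims_mm=DEFAULT_GEOMETRY.anat_voxel_mm,
) -> np.ndarray:
    """Binary lesion mask (may overlap hemisphere labels and the CST ROI)."""
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    try:
        region = spec.region("stroke")
    except KeyError:
        return mask
    if region.target_volume_cm3 <= 0:
        return mask
    mask[_select_region_voxels(region, grid_shape, voxel_dims_mm)] = True
    return mask


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------


def _voxel_property_maps(atlas: LabelAtlas, spec: SubjectPhantomSpec, stroke_mask=None):
    """(s0, cvr, cbf_baseline, cbf_diamox) voxel maps from region ground truth."""
    cvr = np.zeros(atlas.data.shape)
    cbf_b = np.zeros(atlas.data.shape)
    cbf_d = np.zeros(atlas.data.shape)
    s0 = np.where(atlas.data > 0, spec.s0, 0.0)
    for region in spec.regions:
        if region.name == "stroke":
            continue
        sel = atlas.data == region.region_id
        cvr[sel] = region.true_cvr
        cbf_b[sel] = region.true_cbf_baseline
        cbf_d[sel] = region.true_cbf_diamox
    if stroke_mask is not None and stroke_mask.any():
        inside = stroke_mask & (atlas.data > 0)
        cvr[inside] = STROKE_CVR
        cbf_b[inside] = STROKE_CBF
        cbf_d[inside] = STROKE_CBF
    return s0, cvr, cbf_b, cbf_d


def simulate_bold(
    atlas: LabelAtlas,
    spec: SubjectPhantomSpec,
    co2: CO2Trace,
    tr_s: float = DEFAULT_GEOMETRY.tr_s,
    stroke_mask=None,
    n_volumes: int | None = None,
) -> BoldSeries:
    """Simulate a 4-D BOLD series on the atlas grid.

    Voxels of region r follow S(t) = S0*(1 + cvr_r/100*(CO2(t) - <CO2>)) +
    drift*t + N(0, noise_sd); voxels outside all regions have S0 = 0
    (background). Per-subject seeded, bit-reproducible.
    """
    if n_volumes is None:
        dt = co2.sampling_interval_s or tr_s
        n_volumes = int(round((float(co2.times_s[-1]) + dt / 2.0) / tr_s))
    x = resample_trace(co2, n_volumes, tr_s, delay_s=0.0)  # AlignmentError on gap
    xc = x - x.mean()

    s0, cvr, _, _ = _voxel_property_maps(atlas, spec, stroke_mask)
    # float32 when noisy (quantization ~1e-4 signal units, far below the noise
    # floor); float64 when noiseless so regression recovery is exact to 1e-6
    dtype = np.float64 if spec.noise_sd == 0 else np.float32
    amp = (s0 * cvr / 100.0).astype(dtype)
    data = s0.astype(dtype)[..., None] + amp[..., None] * xc.astype(dtype)
    if spec.drift_per_volume != 0.0:
        data += (spec.drift_per_volume * np.arange(n_volumes)).astype(dtype)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += spec.noise_sd * rng.standard_normal(size=data.shape, dtype=np.float32)
    affine = atlas.affine if atlas.affine is not None else np.diag(list(atlas.voxel_dims_mm) + [1.0])
    return BoldSeries(data=data, tr_s=tr_s, voxel_dims_mm=atlas.voxel_dims_mm, affine=affine)


def simulate_perfusion_pair(
    atlas: LabelAtlas,
    spec: SubjectPhantomSpec,
    stroke_mask=None,
    noise_sd: float = 1.0,
    smoothing_fwhm_mm: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and post-Diamox perfusion maps (relative units).

    Region-constant ground truth plus Gaussian noise, then Gaussian spatial
    smoothing (default FWHM 6 mm) to emulate PET's lower resolution.
    """
    _, _, cbf_b, cbf_d = _voxel_property_maps(atlas, spec, stroke_mask)
    rng = np.random.default_rng([spec.seed, 15])
    maps = []
    for vol in (cbf_b, cbf_d):
        out = vol.copy()
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=out.shape)
        if smoothing_fwhm_mm > 0:
            sigma = smoothing_fwhm_mm / 2.3548 / np.asarray(atlas.voxel_dims_mm)
            out = ndimage.gaussian_filter(out, sigma=sigma)
        maps.append(out)
    return maps[0], maps[1]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _quantile_set(rng, n: int, mean: float, sd: float) -> np.ndarray:
    """Normal-quantile set standardized to the exact sample mean/SD, permuted.

    Used for reference indices whose cohort mean/SD must be reproduced
    exactly (e.g. healthy peduncular AI 1.0 +/- 5.0 %)."""
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([mean])
    z = norm.ppf((np.arange(n) + 0.5) / n)
    z = (z - z.mean()) / z.std(ddof=1)
    return rng.permutation(mean + sd * z)


def _truncnorm_quantiles(rng, n: int, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Equiprobable quantiles of a truncated normal, permuted by seed."""
    if n == 0:
        return np.empty(0)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    p = (np.arange(n) + 0.5) / n
    return rng.permutation(truncnorm.ppf(p, a, b, loc=mean, scale=sd))


def _truncnorm_draws(rng, n: int, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _count_flags(rng, n: int, k: int) -> np.ndarray:
    """Boolean vector with exactly k True, placement shuffled by seed."""
    flags = np.zeros(n, dtype=bool)
    flags[: min(k, n)] = True
    return rng.permutation(flags)


def _round_count(p: float, n: int, what: str) -> int:
    raw = p * n
    k = int(round(raw))
    if abs(raw - k) > 1e-9:
        warnings.warn(f"{what}: {p:.3f} x {n} = {raw:.2f} not an integer; rounding to {k}")
    return k


def _cst_centroid(side: str) -> tuple[float, float, float]:
    x = 60.0 if side == "left" else 132.0
    return (x, 78.0, 99.0)


def _stroke_geometry(side: str, involved: bool, volume_cm3: float):
    """Lesion centroid and (oblate) radii; CST-involved lesions sit over the
    motor-cortex ROI, others lower in the hemisphere, never infratentorial."""
    hem_x = 60.0 if side == "left" else 132.0
    vol_mm3 = volume_cm3 * 1000.0
    iso = (3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if involved:
        centroid = (hem_x, 80.0, 97.0)
        rz = min(iso, 7.0)
    else:
        centroid = (hem_x, 110.0, 70.0)
        rz = min(iso, 10.0)
    rxy = math.sqrt(3.0 * vol_mm3 / (4.0 * math.pi * rz))
    return centroid, (rxy, rxy, rz)


class _PairValues:
    """Per-subject L/R values for one modality of one paired structure."""

    def __init__(self, ipsi: np.ndarray, contra: np.ndarray):
        self.ipsi = ipsi
        self.contra = contra

    def left(self, i: int, side: str) -> float:
        return float(self.ipsi[i] if side in ("left", "none") else self.contra[i])

    def right(self, i: int, side: str) -> float:
        return float(self.contra[i] if side in ("left", "none") else self.ipsi[i])


def _build_regions(i, side, pair_vals, stroke_vol, cst_involved):
    """Assemble the RegionSpec tuple for subject i from per-structure values.

    ``pair_vals[stem]`` maps modality -> _PairValues for the paired regions;
    hemisphere values double for the CST ROI.
    """
    regions = []
    for stem in ("peduncle", "thalamus", "cerebellum", "hemisphere"):
        for suffix in ("L", "R"):
            name = f"{stem}_{suffix}"
            pick = (lambda pv: pv.left(i, side)) if suffix == "L" else (lambda pv: pv.right(i, side))
            regions.append(
                RegionSpec(
                    region_id=REGION_IDS[name],
                    name=name,
                    target_volume_cm3=pick(pair_vals[stem]["vol"]),
                    centroid_mm=_CENTROIDS_MM[name],
                    true_cvr=pick(pair_vals[stem]["cvr"]),
                    true_cbf_baseline=pick(pair_vals[stem]["cbf_b"]),
                    true_cbf_diamox=pick(pair_vals[stem]["cbf_d"]),
                )
            )
    hemi = pair_vals["hemisphere"]
    cst_side = side if side in ("left", "right") else "left"
    regions.append(
        RegionSpec(
            region_id=REGION_IDS["corticospinal_roi"],
            name="corticospinal_roi",
            target_volume_cm3=4.2,
            centroid_mm=_cst_centroid(cst_side),
            true_cvr=hemi["cvr"].ipsi[i],
            true_cbf_baseline=hemi["cbf_b"].ipsi[i],
            true_cbf_diamox=hemi["cbf_d"].ipsi[i],
        )
    )
    if stroke_vol > 0:
        centroid, radii = _stroke_geometry(side, cst_involved, stroke_vol)
        regions.append(
            RegionSpec(
                region_id=0,
                name="stroke",
                target_volume_cm3=stroke_vol,
                centroid_mm=centroid,
                true_cvr=STROKE_CVR,
                true_cbf_baseline=STROKE_CBF,
                true_cbf_diamox=STROKE_CBF,
                radii_mm=radii,
            )
        )
    return tuple(regions)


def _hemodynamic_pair(rng_vals_contra, ai_percent) -> _PairValues:
    """ipsi = contra * (1 - AI/100): deficit-positive convention."""
    contra = np.asarray(rng_vals_contra, dtype=float)
    ipsi = contra * (1.0 - np.asarray(ai_percent, dtype=float) / 100.0)
    return _PairValues(ipsi=ipsi, contra=contra)


def _volume_pair_from_ai(contra, ai_percent) -> _PairValues:
    """ipsi = contra * (1 + AI/100): volume-AI convention (atrophy negative)."""
    contra = np.asarray(contra, dtype=float)
    ipsi = contra * (1.0 + np.asarray(ai_percent, dtype=float) / 100.0)
    return _PairValues(ipsi=ipsi, contra=contra)


def _perfusion_block(rng, n, base_level, itd_like_flags, ai_pos, ai_neg):
    """Baseline/Diamox CBF pairs with deficit-linked asymmetry indices."""
    flags = np.asarray(itd_like_flags, dtype=bool)
    base_contra = _truncnorm_draws(rng, n, base_level, base_level * 0.06, base_level * 0.8, base_level * 1.2)
    ai_b = np.where(flags, _truncnorm_draws(rng, n, *ai_pos), _truncnorm_draws(rng, n, *ai_neg))
    ai_d = np.where(flags, _truncnorm_draws(rng, n, *ai_pos), _truncnorm_draws(rng, n, *ai_neg))
    diamox_contra = base_contra * _truncnorm_draws(rng, n, 1.30, 0.05, 1.15, 1.45)
    return (
        _hemodynamic_pair(base_contra, ai_b),
        _hemodynamic_pair(diamox_contra, ai_d),
    )


def _demographics(rng, n, age_mean, age_sd, male_frac, risk_rates):
    out = {
        "age": _quantile_set(rng, n, age_mean, age_sd),
        "sex_male": _count_flags(rng, n, int(round(male_frac * n))),
    }
    for name, rate in risk_rates.items():
        out[name] = _count_flags(rng, n, int(round(rate * n)))
    return out


def _orthogonal_noise(rng, zz: np.ndarray) -> np.ndarray:
    """Unit-sample-SD noise orthogonalized against zz, so a linear mix
    rho*zz + sqrt(1-rho^2)*eps has sample correlation exactly rho with zz."""
    n = zz.size
    eps = rng.standard_normal(n)
    eps = eps - eps.mean()
    denom = float(zz @ zz)
    if denom > 0:
        eps = eps - (float(eps @ zz) / denom) * zz
    sd = eps.std(ddof=1)
    if sd == 0:
        raise GenerationError("degenerate coupling noise")
    return eps / sd


def generate_cohort_specs(cohort: CohortSpec) -> list[SubjectPhantomSpec]:
    """Generate all subject specifications (chronic, then acute, then healthy).

    Deterministic for a fixed CohortSpec: group sizes, WD/ITD/CCD counts and
    the reference-index sample moments are exact by construction; the seed
    only shuffles which subject receives which value.
    """
    rng = np.random.default_rng(cohort.seed)
    seed_seq = np.random.SeedSequence(cohort.seed)
    specs: list[SubjectPhantomSpec] = []

    def subject_seed(child) -> int:
        return int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)

    children = iter(seed_seq.spawn(cohort.n_chronic + cohort.n_acute + cohort.n_healthy))

    # --- chronic group -----------------------------------------------------
    n = cohort.n_chronic
    if n > 0:
        wd_count = _round_count(cohort.wd_fraction, n, "wd_fraction x n_chronic")
        wd = _count_flags(rng, n, wd_count)
        n_wd, n_nwd = int(wd.sum()), n - int(wd.sum())

        # peduncular volumes: WD+ ipsilateral volumes have exact mean 1.51 cm3
        ped_ai = np.empty(n)
        ped_ipsi = np.empty(n)
        ped_contra = np.empty(n)
        ai_wd = _truncnorm_quantiles(rng, n_wd, -20.33, 7.71, -36.0, -13.5)
        ipsi_wd = _quantile_set(rng, n_wd, 1.51, 0.27)
        ped_ai[wd] = ai_wd
        ped_ipsi[wd] = ipsi_wd
        ped_contra[wd] = ipsi_wd / (1.0 + ai_wd / 100.0)
        ai_nwd = _truncnorm_quantiles(rng, n_nwd, -2.71, 3.95, -9.5, 5.5)
        contra_nwd = _quantile_set(rng, n_nwd, 2.01, 0.21)
        ped_ai[~wd] = ai_nwd
        ped_contra[~wd] = contra_nwd
        ped_ipsi[~wd] = contra_nwd * (1.0 + ai_nwd / 100.0)

        # thalamic volume AI coupled to peduncular AI at exactly rho
        rho = cohort.atrophy_coupling
        if n >= 3:
            zz = (ped_ai - ped_ai.mean()) / ped_ai.std(ddof=1)
            eps = _orthogonal_noise(rng, zz)
            thal_ai = -19.2 + 16.6 * (rho * zz + math.sqrt(1.0 - rho * rho) * eps)
        else:
            thal_ai = np.full(n, -19.2)
        thal_ai = np.clip(thal_ai, -80.0, 40.0)
        thal_contra = _quantile_set(rng, n, 0.69, 0.08)

        itd = np.zeros(n, dtype=bool)
        itd[wd] = _count_flags(rng, n_wd, _round_count(cohort.itd_prob_given_wd, n_wd, "ITD | WD+"))
        itd[~wd] = _count_flags(
            rng, n_nwd, _round_count(cohort.itd_prob_given_no_wd, n_nwd, "ITD | WD-")
        )
        ccd = _count_flags(rng, n, _round_count(cohort.ccd_prob, n, "CCD"))

        # CVR asymmetries: diaschisis-positive subjects clear the healthy 2SD
        # cutoff by a wide margin, negatives stay well below it.
        thal_cvr_ai = np.where(
            itd,
            _truncnorm_draws(rng, n, 38.0, 6.0, 31.0, 58.0),
            _truncnorm_draws(rng, n, 4.0, 5.0, -9.0, 10.0),
        )
        cereb_cvr_ai = np.where(
            ccd,
            _truncnorm_draws(rng, n, 21.0, 5.0, 16.0, 33.0),
            _truncnorm_draws(rng, n, 0.0, 4.0, -8.0, 8.0),
        )
        ped_cvr_ai = _truncnorm_draws(rng, n, 1.0, 12.0, -30.0, 30.0)
        hemi_cvr_ai = _truncnorm_draws(rng, n, 20.0, 8.0, 0.0, 45.0)

        pairs = {
            "peduncle": {
                "vol": _PairValues(ped_ipsi, ped_contra),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n, 0.18, 0.06, 0.06, 0.32), ped_cvr_ai
                ),
            },
            "thalamus": {
                "vol": _volume_pair_from_ai(thal_contra, thal_ai),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n, 0.18, 0.05, 0.10, 0.30), thal_cvr_ai
                ),
            },
            "cerebellum": {
                "vol": _volume_pair_from_ai(
                    _quantile_set(rng, n, 5.79, 0.60),
                    _truncnorm_draws(rng, n, -1.5, 5.0, -12.0, 10.0),
                ),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n, 0.19, 0.04, 0.10, 0.28), cereb_cvr_ai
                ),
            },
            "hemisphere": {
                "vol": _volume_pair_from_ai(
                    _quantile_set(rng, n, 120.0, 3.0), _truncnorm_draws(rng, n, 0.0, 2.0, -5.0, 5.0)
                ),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n, 0.17, 0.03, 0.08, 0.25), hemi_cvr_ai
                ),
            },
        }
        pairs["thalamus"]["cbf_b"], pairs["thalamus"]["cbf_d"] = _perfusion_block(
            rng, n, 55.0, itd, (15.0, 5.0, 4.0, 28.0), (4.0, 5.0, -8.0, 14.0)
        )
        pairs["cerebellum"]["cbf_b"], pairs["cerebellum"]["cbf_d"] = _perfusion_block(
            rng, n, 50.0, ccd, (8.0, 4.0, 0.0, 18.0), (3.0, 4.0, -6.0, 12.0)
        )
        pairs["peduncle"]["cbf_b"], pairs["peduncle"]["cbf_d"] = _perfusion_block(
            rng, n, 28.0, np.zeros(n, bool), (6.0, 4.0, -6.0, 16.0), (6.0, 4.0, -6.0, 16.0)
        )
        pairs["hemisphere"]["cbf_b"], pairs["hemisphere"]["cbf_d"] = _perfusion_block(
            rng, n, 45.0, np.ones(n, bool), (8.0, 5.0, -4.0, 20.0), (8.0, 5.0, -4.0, 20.0)
        )

        cst = np.zeros(n, dtype=bool)
        cst[wd] = _count_flags(rng, n_wd, _round_count(cohort.cst_prob_given_wd, n_wd, "CST | WD+"))
        cst[~wd] = _count_flags(
            rng, n_nwd, _round_count(cohort.cst_prob_given_no_wd, n_nwd, "CST | WD-")
        )
        sides = np.where(_count_flags(rng, n, n // 2), "right", "left")
        stroke_vols = np.clip(rng.lognormal(math.log(3.2), 1.0, size=n), 0.3, 30.0)
        co2_base = _quantile_set(rng, n, 37.8, 2.67)
        co2_step = _quantile_set(rng, n, 9.4, 1.3)
        demo = _demographics(
            rng,
            n,
            58.3,
            12.9,
            13.0 / 17.0,
            {
                "smoking": 12.0 / 17.0,
                "hypertension": 12.0 / 17.0,
                "hypercholesterolemia": 5.0 / 17.0,
                "obesity": 2.0 / 17.0,
                "diabetes": 1.0 / 17.0,
            },
        )
        weeks = np.clip(rng.lognormal(math.log(25.0), 0.9, size=n), 3.5, 250.0)

        for i in range(n):
            regions = _build_regions(i, str(sides[i]), pairs, float(stroke_vols[i]), bool(cst[i]))
            specs.append(
                SubjectPhantomSpec(
                    subject_id=f"chronic-{i + 1:02d}",
                    group="chronic",
                    stroke_side=str(sides[i]),
                    wd_true=bool(wd[i]),
                    itd_true=bool(itd[i]),
                    ccd_true=bool(ccd[i]),
                    regions=regions,
                    noise_sd=cohort.noise_sd,
                    drift_per_volume=cohort.drift_per_volume,
                    seed=subject_seed(next(children)),
                    co2=Co2Protocol(baseline_mmHg=float(co2_base[i]), step_mmHg=float(co2_step[i])),
                    cst_involved_true=bool(cst[i]),
                    demographics={
                        "age": float(demo["age"][i]),
                        "sex_male": int(demo["sex_male"][i]),
                        "smoking": int(demo["smoking"][i]),
                        "hypertension": int(demo["hypertension"][i]),
                        "hypercholesterolemia": int(demo["hypercholesterolemia"][i]),
                        "obesity": int(demo["obesity"][i]),
                        "diabetes": int(demo["diabetes"][i]),
                        "time_after_stroke_weeks": float(weeks[i]),
                    },
                )
            )

    # --- acute/subacute and healthy groups ---------------------------------
    for group, n_g in (("acute", cohort.n_acute), ("healthy", cohort.n_healthy)):
        if n_g == 0:
            continue
        ped_ai = _quantile_set(rng, n_g, 1.0, 5.0)
        thal_cvr_ai = _quantile_set(rng, n_g, 4.1, 8.0)
        cereb_cvr_ai = _quantile_set(rng, n_g, 1.0, 5.5)
        ped_contra = _quantile_set(rng, n_g, 2.08, 0.25)  # right peduncle for healthy
        thal_ipsi_vol = _quantile_set(rng, n_g, 0.74, 0.09)
        thal_contra_vol = _quantile_set(rng, n_g, 0.67, 0.06)

        pairs = {
            "peduncle": {
                "vol": _volume_pair_from_ai(ped_contra, ped_ai),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n_g, 0.195, 0.05, 0.08, 0.32),
                    _truncnorm_draws(rng, n_g, 2.0, 10.0, -25.0, 25.0),
                ),
            },
            "thalamus": {
                "vol": _PairValues(thal_ipsi_vol, thal_contra_vol),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n_g, 0.18, 0.04, 0.10, 0.28), thal_cvr_ai
                ),
            },
            "cerebellum": {
                "vol": _volume_pair_from_ai(
                    _quantile_set(rng, n_g, 5.75, 0.60),
                    _truncnorm_draws(rng, n_g, 0.0, 3.0, -8.0, 8.0),
                ),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n_g, 0.19, 0.04, 0.10, 0.28), cereb_cvr_ai
                ),
            },
            "hemisphere": {
                "vol": _volume_pair_from_ai(
                    _quantile_set(rng, n_g, 120.0, 3.0),
                    _truncnorm_draws(rng, n_g, 0.0, 2.0, -5.0, 5.0),
                ),
                "cvr": _hemodynamic_pair(
                    _truncnorm_draws(rng, n_g, 0.19, 0.03, 0.10, 0.28),
                    _truncnorm_draws(rng, n_g, 0.0, 6.0, -15.0, 15.0),
                ),
            },
        }
        none_flags = np.zeros(n_g, bool)
        pairs["thalamus"]["cbf_b"], pairs["thalamus"]["cbf_d"] = _perfusion_block(
            rng, n_g, 55.0, none_flags, (0, 1, 0, 1), (2.0, 4.0, -8.0, 12.0)
        )
        pairs["cerebellum"]["cbf_b"], pairs["cerebellum"]["cbf_d"] = _perfusion_block(
            rng, n_g, 50.0, none_flags, (0, 1, 0, 1), (2.0, 4.0, -8.0, 12.0)
        )
        pairs["peduncle"]["cbf_b"], pairs["peduncle"]["cbf_d"] = _perfusion_block(
            rng, n_g, 28.0, none_flags, (0, 1, 0, 1), (2.0, 4.0, -8.0, 12.0)
        )
        pairs["hemisphere"]["cbf_b"], pairs["hemisphere"]["cbf_d"] = _perfusion_block(
            rng, n_g, 45.0, none_flags, (0, 1, 0, 1), (2.0, 4.0, -8.0, 12.0)
        )

        if group == "acute":
            sides = np.where(_count_flags(rng, n_g, n_g // 2), "right", "left")
            stroke_vols = np.clip(rng.lognormal(math.log(3.0), 1.0, size=n_g), 0.3, 30.0)
            cst = rng.random(n_g) < 0.3
            weeks = rng.uniform(0.3, 2.0, size=n_g)
            demo = _demographics(
                rng, n_g, 58.0, 12.0, 0.7, {"smoking": 0.6, "hypertension": 0.6}
            )
        else:
            sides = np.array(["none"] * n_g)
            stroke_vols = np.zeros(n_g)
            cst = np.zeros(n_g, bool)
            weeks = np.full(n_g, np.nan)
            demo = _demographics(
                rng, n_g, 59.4, 11.1, 12.0 / 17.0, {"smoking": 1.0 / 17.0, "hypertension": 3.0 / 17.0}
            )
        co2_base = _quantile_set(rng, n_g, 37.8, 2.67)
        co2_step = _quantile_set(rng, n_g, 9.4, 1.3)

        for i in range(n_g):
            regions = _build_regions(i, str(sides[i]), pairs, float(stroke_vols[i]), bool(cst[i]))
            demographics = {k: (float(v[i]) if k == "age" else int(v[i])) for k, v in demo.items()}
            if group == "acute":
                demographics["time_after_stroke_weeks"] = float(weeks[i])
            specs.append(
                SubjectPhantomSpec(
                    subject_id=f"{group}-{i + 1:02d}",
                    group=group,
                    stroke_side=str(sides[i]),
                    wd_true=False,
                    itd_true=False,
                    ccd_true=False,
                    regions=regions,
                    noise_sd=cohort.noise_sd,
                    drift_per_volume=cohort.drift_per_volume,
                    seed=subject_seed(next(children)),
                    co2=Co2Protocol(baseline_mmHg=float(co2_base[i]), step_mmHg=float(co2_step[i])),
                    cst_involved_true=bool(cst[i]),
                    demographics=demographics,
                )
            )

    return specs


def realize_subject(
    spec: SubjectPhantomSpec, geometry: PhantomGeometry = DEFAULT_GEOMETRY
) -> SubjectData:
    """Rasterize atlases and simulate BOLD + perfusion for one subject."""
    anat_atlas = rasterize_atlas(spec, geometry.anat_shape, geometry.anat_voxel_mm)
    bold_atlas = rasterize_atlas(spec, geometry.bold_shape, geometry.bold_voxel_mm)
    stroke_anat = rasterize_stroke_mask(spec, geometry.anat_shape, geometry.anat_voxel_mm)
    stroke_bold = rasterize_stroke_mask(spec, geometry.bold_shape, geometry.bold_voxel_mm)
    co2 = render_co2_trace(replace(spec.co2, sampling_interval_s=geometry.tr_s))
    bold = simulate_bold(bold_atlas, spec, co2, tr_s=geometry.tr_s, stroke_mask=stroke_bold)
    pet_b, pet_d = simulate_perfusion_pair(bold_atlas, spec, stroke_mask=stroke_bold)
    return SubjectData(
        spec=spec,
        anat_atlas=anat_atlas,
        bold_atlas=bold_atlas,
        stroke_mask_anat=stroke_anat,
        stroke_mask_bold=stroke_bold,
        co2=co2,
        bold=bold,
        pet_baseline=pet_b,
        pet_diamox=pet_d,
    )


def generate_cohort(cohort: CohortSpec, geometry: PhantomGeometry = DEFAULT_GEOMETRY):
    """Yield realized subjects one at a time (a full subject holds a 4-D BOLD
    array; lazy realization keeps a 47-subject cohort within modest memory)."""
    for spec in generate_cohort_specs(cohort):
        yield realize_subject(spec, geometry)
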