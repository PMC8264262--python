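"""ROI volumetry, lateralization asymmetry indices, stroke volume and
corticospinal-tract involvement.

Two sign conventions coexist, matching how such indices are reported:

* volume AI      = 100 * (ipsi - contra) / contra   (atrophy -> negative)
* hemodynamic AI = 100 * (contra - ipsi) / contra   (ipsilateral CVR or
  perfusion deficit -> positive)

"Ipsilateral" resolves through the subject's stroke side; healthy subjects
use left-as-ipsilateral, which keeps the reference distribution symmetric in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRegionError, UndefinedRatioError

__all__ = [
    "REGION_IDS",
    "PAIRED_REGIONS",
    "LabelAtlas",
    "SubjectMetrics",
    "region_volume",
    "volume_asymmetry_index",
    "hemodynamic_asymmetry_index",
    "stroke_volume",
    "corticospinal_involvement",
    "resolve_sides",
]

#: Integer labels shared by every atlas the package writes. The stroke lesion
#: lives in a separate binary mask (it may overlap the corticospinal ROI).
REGION_IDS: dict[str, int] = {
    "peduncle_L": 1,
    "peduncle_R": 2,
    "thalamus_L": 3,
    "thalamus_R": 4,
    "cerebellum_L": 5,
    "cerebellum_R": 6,
    "hemisphere_L": 7,
    "hemisphere_R": 8,
    "corticospinal_roi": 9,
}

#: Left/right homologue pairs, keyed by structure stem.
PAIRED_REGIONS: tuple[str, ...] = ("peduncle", "thalamus", "cerebellum", "hemisphere")


@dataclass
class LabelAtlas:
    """3-D integer region-label volume on a known voxel grid."""

    data: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    affine: np.ndarray | None = None
    names: dict[str, int] = field(default_factory=lambda: dict(REGION_IDS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label atlas must be 3-D")
        if any(d <= 0 for d in self.voxel_dims_mm):
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))

    def id_of(self, name: str) -> int:
        return self.names[name]

    def mask(self, name: str) -> np.ndarray:
        return self.data == self.names[name]


@dataclass
class SubjectMetrics:
    """Per-subject derived quantities: volumes, ROI CVR/PET means, AIs."""

    subject_id: str
    group: str
    stroke_side: str
    volume_cm3: dict[str, float] = field(default_factory=dict)
    cvr_mean: dict[str, float] = field(default_factory=dict)
    pet_baseline_mean: dict[str, float] = field(default_factory=dict)
    pet_diamox_mean: dict[str, float] = field(default_factory=dict)
    volume_ai: dict[str, float] = field(default_factory=dict)
    cvr_ai: dict[str, float] = field(default_factory=dict)
    pet_baseline_ai: dict[str, float] = field(default_factory=dict)
    pet_diamox_ai: dict[str, float] = field(default_factory=dict)
    stroke_volume_cm3: float = 0.0
    cst_involved: bool = False
    extra: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flatten to one tidy row (for the metrics TSV)."""
        row: dict = {
            "subject_id": self.subject_id,
            "group": self.group,
            "stroke_side": self.stroke_side,
            "stroke_volume_cm3": self.stroke_volume_cm3,
            "cst_involved": int(self.cst_involved),
        }
        for prefix, d in (
            ("volume_cm3", self.volume_cm3),
            ("cvr", self.cvr_mean),
            ("pet_baseline", self.pet_baseline_mean),
            ("pet_diamox", self.pet_diamox_mean),
            ("volume_ai", self.volume_ai),
            ("cvr_ai", self.cvr_ai),
            ("pet_baseline_ai", self.pet_baseline_ai),
            ("pet_diamox_ai", self.pet_diamox_ai),
        ):
            for k, v in d.items():
                row[f"{prefix}_{k}"] = v
        row.update(self.extra)
        return row


def resolve_sides(stroke_side: str) -> tuple[str, str]:
    """Map a stroke side to (ipsilateral, contralateral) hemisphere suffixes.

    Healthy subjects (side 'none') use left as ipsilateral.
    """
    if stroke_side == "right":
        return "R", "L"
    if stroke_side in ("left", "none"):
        return "L", "R"
    raise ValueError(f"unknown stroke side {stroke_side!r}")


def region_volume(atlas: LabelAtlas, region_id: int, voxel_dims_mm=None) -> float:
    """Voxel count x voxel volume, in cm^3. Empty regions have volume 0."""
    dims = voxel_dims_mm if voxel_dims_mm is not None else atlas.voxel_dims_mm
    labels = atlas.data if hasattr(atlas, "data") else np.asarray(atlas)
    n = int((labels == region_id).sum())
    return n * float(np.prod(dims)) / 1000.0


def volume_asymmetry_index(ipsi_cm3: float, contra_cm3: float) -> float:
    """100 * (ipsi - contra) / contra; negative when the ipsilateral side is smaller."""
    if contra_cm3 <= 0:
        raise UndefinedRatioError("contralateral volume must be positive")
    return 100.0 * (ipsi_cm3 - contra_cm3) / contra_cm3


def hemodynamic_asymmetry_index(
    ipsi_value: float, contra_value: float, convention: str = "deficit-positive"
) -> float:
    """Asymmetry index for CVR / perfusion values.

    Default convention makes an ipsilateral deficit positive:
    100 * (contra - ipsi) / contra. ``convention='signed'`` uses the raw
    volume-style formula 100 * (ipsi - contra) / contra instead.
    """
    if contra_value == 0:
        raise UndefinedRatioError("contralateral value must be nonzero")
    if convention == "deficit-positive":
        return 100.0 * (contra_value - ipsi_value) / contra_value
    if convention == "signed":
        return 100.0 * (ipsi_value - contra_value) / contra_value
    raise ValueError(f"unknown AI convention {convention!r}")


def stroke_volume(stroke_masks, voxel_dims_mm) -> float:
    """Total lesion volume in cm^3 over one or more binary masks.

    Multiple lesion masks are combined by voxelwise union so overlapping
    outlines are never double-counted (volume is a measure on voxels).
    """
    masks = list(stroke_masks)
    if not masks:
        return 0.0
    union = np.zeros_like(np.asarray(masks[0], dtype=bool))
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != union.shape:
            raise ValueError("all lesion masks must share one grid")
        union |= m
    return int(union.sum()) * float(np.prod(voxel_dims_mm)) / 1000.0


def corticospinal_involvement(stroke_mask, cst_roi_mask) -> bool:
    """True iff the lesion and the corticospinal ROI share at least one voxel."""
    s = np.asarray(stroke_mask, dtype=bool)
    c = np.asarray(cst_roi_mask, dtype=bool)
    if s.shape != c.shape:
        raise ValueError("masks must share one grid")
    return bool(np.any(s & c))
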