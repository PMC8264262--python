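"""End-to-end pipeline: phantom generation or manifest ingestion -> voxelwise
CVR mapping -> volumetry and asymmetry indices -> healthy-reference
thresholds -> WD/ITD/CCD classification -> group statistics tables.

The pipeline is deterministic for a fixed configuration and seed; every
output directory carries a JSON run report with the seed and a configuration
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import HealthyReference, classify_diaschisis, classify_wd, derive_threshold
from .cvr import CvrMap, align_co2_to_bold, compute_cvr_map, pet_percent_difference
from .errors import DiaschisisError, ManifestError, SpecError
from .io import MANIFEST_COLUMNS, load_atlas, load_bold, load_nifti, read_co2_tsv, save_nifti
from .phantom import (
    DEFAULT_GEOMETRY,
    CohortSpec,
    PhantomGeometry,
    SubjectData,
    generate_cohort,
    default_cohort_spec,
)
from .regions import (
    PAIRED_REGIONS,
    REGION_IDS,
    SubjectMetrics,
    corticospinal_involvement,
    hemodynamic_asymmetry_index,
    region_volume,
    resolve_sides,
    stroke_volume,
    volume_asymmetry_index,
)
from .stats import build_cohort_tables, correlate

logger = logging.getLogger("diaschisis")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "compute_subject_metrics",
    "run_pipeline",
    "read_subject_manifest",
    "reproduce_default_cohort",
]


@dataclass
class PipelineConfig:
    """Pipeline configuration; exactly one input source (phantom XOR manifest)."""

    phantom: CohortSpec | None = None
    manifest: str | None = None
    out_dir: str | None = None
    delay_s: float = 0.0
    ai_convention: str = "deficit-positive"  # hemodynamic AIs; volumes always signed
    background_floor_frac: float = 0.10
    baseline_epoch_s: tuple[float, float] | None = None  # default: whole-series mean
    require_atrophy: bool = True
    welch: bool = False
    save_maps: bool = False
    seed: int | None = None  # overrides the phantom cohort seed
    geometry: PhantomGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.manifest is None):
            raise SpecError("configure exactly one input source: phantom spec XOR manifest")
        if self.phantom is not None and self.seed is not None:
            self.phantom = dataclasses.replace(self.phantom, seed=int(self.seed))
        if self.phantom is not None:
            total = self.phantom.n_healthy + self.phantom.n_acute + self.phantom.n_chronic
            if total == 0:
                raise SpecError("empty cohort: all group sizes are zero")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom = raw.pop("phantom", None)
        geometry = raw.pop("geometry", None)
        kwargs = dict(raw)
        if phantom is not None:
            kwargs["phantom"] = CohortSpec(**phantom)
        if geometry is not None:
            kwargs["geometry"] = PhantomGeometry(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in geometry.items()}
            )
        return cls(**kwargs)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            return obj

        blob = json.dumps(encode(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    classifications: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    references: dict[str, HealthyReference]
    correlation: object | None
    report: dict
    errors: list[tuple[str, str]]


def _co2_block_stats(values: np.ndarray) -> tuple[float, float, float]:
    """Baseline / hypercapnia / step estimates from a block trace (midrange split)."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) < 1e-9:
        m = float(v.mean())
        return m, m, 0.0
    mid = (v.max() + v.min()) / 2.0
    base = float(v[v <= mid].mean())
    hyper = float(v[v > mid].mean())
    return base, hyper, hyper - base


def compute_subject_metrics(
    data: SubjectData,
    delay_s: float = 0.0,
    ai_convention: str = "deficit-positive",
    background_floor_frac: float = 0.10,
    baseline_epoch_s: tuple[float, float] | None = None,
) -> tuple[SubjectMetrics, CvrMap]:
    """All per-subject derived quantities from one realized/loaded subject."""
    spec = data.spec
    sid = spec.subject_id if spec is not None else data.subject_id
    group = spec.group if spec is not None else data.group
    side = spec.stroke_side if spec is not None else data.stroke_side
    ipsi_sfx, contra_sfx = resolve_sides(side)

    regressor = align_co2_to_bold(data.co2, data.bold, delay_s)
    cvr_map = compute_cvr_map(data.bold, regressor, background_floor_frac, baseline_epoch_s)

    m = SubjectMetrics(subject_id=sid, group=group, stroke_side=side)

    # volumetry on the anatomical grid
    for name, rid in REGION_IDS.items():
        m.volume_cm3[name] = region_volume(data.anat_atlas, rid)
    for stem in PAIRED_REGIONS:
        m.volume_cm3[f"{stem}_ipsi"] = m.volume_cm3[f"{stem}_{ipsi_sfx}"]
        m.volume_cm3[f"{stem}_contra"] = m.volume_cm3[f"{stem}_{contra_sfx}"]
        m.volume_ai[stem] = volume_asymmetry_index(
            m.volume_cm3[f"{stem}_ipsi"], m.volume_cm3[f"{stem}_contra"]
        )

    # ROI CVR on the BOLD grid
    labels = data.bold_atlas.data
    valid = cvr_map.valid_mask
    for name, rid in REGION_IDS.items():
        sel = (labels == rid) & valid
        m.cvr_mean[name] = float(cvr_map.data[sel].mean()) if sel.any() else np.nan
    brain = (labels > 0) & valid
    m.cvr_mean["whole_brain"] = float(cvr_map.data[brain].mean()) if brain.any() else np.nan
    for stem in PAIRED_REGIONS:
        m.cvr_mean[f"{stem}_ipsi"] = m.cvr_mean[f"{stem}_{ipsi_sfx}"]
        m.cvr_mean[f"{stem}_contra"] = m.cvr_mean[f"{stem}_{contra_sfx}"]
        m.cvr_ai[stem] = hemodynamic_asymmetry_index(
            m.cvr_mean[f"{stem}_ipsi"], m.cvr_mean[f"{stem}_contra"], ai_convention
        )

    # PET difference indices (relative units; region means only)
    if data.pet_baseline is not None and data.pet_diamox is not None:
        for name, rid in REGION_IDS.items():
            sel = labels == rid
            m.pet_baseline_mean[name] = float(data.pet_baseline[sel].mean()) if sel.any() else np.nan
            m.pet_diamox_mean[name] = float(data.pet_diamox[sel].mean()) if sel.any() else np.nan
        for stem in PAIRED_REGIONS:
            for d, src in (
                (m.pet_baseline_ai, m.pet_baseline_mean),
                (m.pet_diamox_ai, m.pet_diamox_mean),
            ):
                d[stem] = hemodynamic_asymmetry_index(
                    src[f"{stem}_{ipsi_sfx}"], src[f"{stem}_{contra_sfx}"], ai_convention
                )
        for stem in PAIRED_REGIONS:
            m.extra[f"pet_cvr_{stem}_ipsi"] = pet_percent_difference(
                data.pet_baseline, data.pet_diamox, data.bold_atlas, REGION_IDS[f"{stem}_{ipsi_sfx}"]
            )
            m.extra[f"pet_cvr_{stem}_contra"] = pet_percent_difference(
                data.pet_baseline, data.pet_diamox, data.bold_atlas, REGION_IDS[f"{stem}_{contra_sfx}"]
            )

    # stroke volume and corticospinal involvement on the anatomical grid
    if data.stroke_mask_anat is not None:
        m.stroke_volume_cm3 = stroke_volume(
            [data.stroke_mask_anat], data.anat_atlas.voxel_dims_mm
        )
        cst_mask = data.anat_atlas.data == REGION_IDS["corticospinal_roi"]
        m.cst_involved = corticospinal_involvement(data.stroke_mask_anat, cst_mask)

    base, hyper, step = _co2_block_stats(data.co2.values_mmHg)
    m.extra.update(
        {"co2_baseline_mmHg": base, "co2_hypercapnia_mmHg": hyper, "co2_step_mmHg": step}
    )
    if spec is not None:
        m.extra.update(spec.demographics)
        m.extra.update(
            {
                "wd_true": int(spec.wd_true),
                "itd_true": int(spec.itd_true),
                "ccd_true": int(spec.ccd_true),
            }
        )
    return m, cvr_map


@dataclass
class _ManifestSubject:
    """Lazy loader for one manifest row (duck-typed like SubjectData)."""

    subject_id: str
    group: str
    stroke_side: str
    paths: dict[str, Path]

    def load(self) -> SubjectData:
        anat = load_atlas(self.paths["atlas_anat"])
        bold_atlas = load_atlas(self.paths["atlas_bold"])
        bold = load_bold(self.paths["bold"])
        co2 = read_co2_tsv(self.paths["co2"])
        if bold_atlas.data.shape != bold.data.shape[:3]:
            raise ManifestError(
                f"{self.subject_id}: BOLD atlas grid {bold_atlas.data.shape} does not "
                f"match BOLD series {bold.data.shape[:3]}"
            )
        pet_b = pet_d = None
        if self.paths.get("pet_baseline") and self.paths.get("pet_diamox"):
            pet_b = np.asarray(load_nifti(self.paths["pet_baseline"])[0], dtype=float)
            pet_d = np.asarray(load_nifti(self.paths["pet_diamox"])[0], dtype=float)
        stroke_anat = np.zeros(anat.data.shape, dtype=bool)
        if self.paths.get("stroke_mask_anat"):
            stroke_anat = np.asarray(load_nifti(self.paths["stroke_mask_anat"])[0]) > 0
        stroke_bold = np.zeros(bold_atlas.data.shape, dtype=bool)
        if self.paths.get("stroke_mask_bold"):
            stroke_bold = np.asarray(load_nifti(self.paths["stroke_mask_bold"])[0]) > 0
        data = SubjectData(
            spec=None,
            anat_atlas=anat,
            bold_atlas=bold_atlas,
            stroke_mask_anat=stroke_anat,
            stroke_mask_bold=stroke_bold,
            co2=co2,
            bold=bold,
            pet_baseline=pet_b,
            pet_diamox=pet_d,
        )
        data.subject_id = self.subject_id
        data.group = self.group
        data.stroke_side = self.stroke_side
        return data


def read_subject_manifest(path) -> tuple[list[_ManifestSubject], list[tuple[str, str]]]:
    """Validate a TSV manifest; returns (records, per-row errors).

    Relative paths resolve against the manifest's directory. Rows with a
    missing file or a missing required field are rejected individually.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty:
        raise ManifestError("empty manifest")
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing columns: {sorted(missing_cols)}")

    root = path.parent
    records, errors = [], []
    for idx, row in df.iterrows():
        sid = row["subject_id"] or f"row-{idx}"
        try:
            if not row["subject_id"]:
                raise ManifestError("missing subject_id")
            if row["group"] not in ("healthy", "acute", "chronic"):
                raise ManifestError(f"unknown group {row['group']!r}")
            if row["stroke_side"] not in ("left", "right", "none"):
                raise ManifestError(f"unknown stroke side {row['stroke_side']!r}")
            paths: dict[str, Path] = {}
            for col in ("atlas_anat", "atlas_bold", "bold", "co2"):
                if not row[col]:
                    raise ManifestError(f"missing required path column {col}")
                p = root / row[col]
                if not p.exists():
                    raise ManifestError(f"file not found: {p}")
                paths[col] = p
            for col in ("pet_baseline", "pet_diamox", "stroke_mask_anat", "stroke_mask_bold"):
                if col in row.index and row[col]:
                    p = root / row[col]
                    if not p.exists():
                        raise ManifestError(f"file not found: {p}")
                    paths[col] = p
            records.append(
                _ManifestSubject(
                    subject_id=row["subject_id"],
                    group=row["group"],
                    stroke_side=row["stroke_side"],
                    paths=paths,
                )
            )
        except (ManifestError, KeyError) as exc:
            errors.append((sid, str(exc)))
    return records, errors


def _iter_subjects(config: PipelineConfig):
    if config.phantom is not None:
        yield from generate_cohort(config.phantom, config.geometry)
    else:
        records, row_errors = read_subject_manifest(config.manifest)
        for sid, msg in row_errors:
            yield sid, ManifestError(msg)
        for rec in records:
            try:
                yield rec.load()
            except (DiaschisisError, OSError, ValueError) as exc:
                yield rec.subject_id, exc


def derive_references(metrics: pd.DataFrame) -> dict[str, HealthyReference]:
    """Healthy-cohort mean/SD references for the three classification indices."""
    healthy = metrics[metrics["group"] == "healthy"]
    return {
        "peduncle_volume_ai": derive_threshold(
            healthy["volume_ai_peduncle"], "peduncle_volume_ai"
        ),
        "thalamus_cvr_ai": derive_threshold(healthy["cvr_ai_thalamus"], "thalamus_cvr_ai"),
        "cerebellum_cvr_ai": derive_threshold(healthy["cvr_ai_cerebellum"], "cerebellum_cvr_ai"),
    }


def classify_cohort(
    metrics: pd.DataFrame,
    references: dict[str, HealthyReference],
    require_atrophy: bool = True,
) -> pd.DataFrame:
    """Apply the 2SD rules to every subject (all groups, for validity checks)."""
    rows = []
    for _, r in metrics.iterrows():
        rows.append(
            {
                "subject_id": r["subject_id"],
                "group": r["group"],
                "stroke_side": r["stroke_side"],
                "wd_positive": int(
                    classify_wd(r["volume_ai_peduncle"], references["peduncle_volume_ai"], require_atrophy)
                ),
                "itd_positive": int(
                    classify_diaschisis(r["cvr_ai_thalamus"], references["thalamus_cvr_ai"])
                ),
                "ccd_positive": int(
                    classify_diaschisis(r["cvr_ai_cerebellum"], references["cerebellum_cvr_ai"])
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; writes TSV/JSON outputs when out_dir is set.

    Per-subject failures are recorded and skipped; the run report carries the
    error count (a non-empty error list should map to a non-zero exit in CLI
    use).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        if config.save_maps:
            (out_dir / "cvr_maps").mkdir(exist_ok=True)

    rows, errors = [], []
    for item in _iter_subjects(config):
        if isinstance(item, tuple):  # (subject_id, error)
            sid, exc = item
            logger.warning("subject %s failed: %s", sid, exc)
            errors.append((sid, str(exc)))
            continue
        subject = item
        sid = subject.spec.subject_id if subject.spec is not None else subject.subject_id
        try:
            metrics, cvr_map = compute_subject_metrics(
                subject,
                delay_s=config.delay_s,
                ai_convention=config.ai_convention,
                background_floor_frac=config.background_floor_frac,
                baseline_epoch_s=config.baseline_epoch_s,
            )
        except DiaschisisError as exc:
            logger.warning("subject %s failed: %s", sid, exc)
            errors.append((sid, str(exc)))
            continue
        rows.append(metrics.as_row())
        if out_dir and config.save_maps:
            save_nifti(
                cvr_map.data.astype(np.float32), cvr_map.affine, out_dir / "cvr_maps" / f"{sid}_cvr.nii.gz"
            )
        logger.info("subject %s done", sid)

    if not rows:
        raise SpecError("no subject could be processed")
    metrics_df = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)

    references = derive_references(metrics_df)
    classifications = classify_cohort(metrics_df, references, config.require_atrophy)
    merged = metrics_df.merge(
        classifications[["subject_id", "wd_positive", "itd_positive", "ccd_positive"]],
        on="subject_id",
    )

    chronic = merged[merged["group"] == "chronic"]
    correlation = None
    if len(chronic) >= 3:
        correlation = correlate(chronic["volume_ai_peduncle"], chronic["volume_ai_thalamus"])

    tables = build_cohort_tables(merged)

    ref_rows = [
        {
            "index_name": ref.index_name,
            "mean": ref.mean,
            "sd": ref.sd,
            "n": ref.n,
            "threshold": ref.threshold,
            "upper_cutoff": ref.upper_cutoff,
        }
        for ref in references.values()
    ]
    summary = {
        g: {
            "n": int((classifications["group"] == g).sum()),
            "wd_positive": int(classifications.loc[classifications["group"] == g, "wd_positive"].sum()),
            "itd_positive": int(classifications.loc[classifications["group"] == g, "itd_positive"].sum()),
            "ccd_positive": int(classifications.loc[classifications["group"] == g, "ccd_positive"].sum()),
        }
        for g in classifications["group"].unique()
    }
    report = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.phantom.seed if config.phantom is not None else config.seed,
        "n_subjects": int(len(metrics_df)),
        "n_errors": len(errors),
        "errors": errors,
        "healthy_reference": ref_rows,
        "classification_summary": summary,
        "atrophy_correlation": None
        if correlation is None
        else {
            "method": correlation.method,
            "r": correlation.r,
            "r_squared": correlation.r_squared,
            "p_value": correlation.p_value,
            "n": correlation.n,
        },
    }

    if out_dir:
        metrics_df.to_csv(out_dir / "subject_metrics.tsv", sep="\t", index=False, float_format="%.6g")
        classifications.to_csv(out_dir / "classifications.tsv", sep="\t", index=False)
        pd.DataFrame(ref_rows).to_csv(out_dir / "healthy_reference.tsv", sep="\t", index=False, float_format="%.6g")
        tables["healthy"].to_csv(out_dir / "table1_healthy_cohort.tsv", sep="\t", index=False)
        tables["clinical"].to_csv(out_dir / "table2_clinical.tsv", sep="\t", index=False)
        tables["findings"].to_csv(out_dir / "table3_findings.tsv", sep="\t", index=False)
        with open(out_dir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2)

    return PipelineResult(
        metrics=merged,
        classifications=classifications,
        tables=tables,
        references=references,
        correlation=correlation,
        report=report,
        errors=errors,
    )


def reproduce_default_cohort(out_dir=None, seed: int | None = None) -> PipelineResult:
    """Run the packaged default phantom cohort end-to-end."""
    cohort = default_cohort_spec() if seed is None else default_cohort_spec(seed)
    config = PipelineConfig(phantom=cohort, out_dir=str(out_dir) if out_dir else None)
    return run_pipeline(config)
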