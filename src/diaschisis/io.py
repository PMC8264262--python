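"""NIfTI-1, CO2-trace TSV and manifest I/O (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cvr import BoldSeries, CO2Trace
from .errors import ManifestError
from .regions import LabelAtlas

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_co2_tsv",
    "read_co2_tsv",
    "save_subject_niftis",
    "MANIFEST_COLUMNS",
]

#: Required manifest columns; the remaining path columns are optional.
MANIFEST_COLUMNS = ("subject_id", "group", "stroke_side", "atlas_anat", "atlas_bold", "bold", "co2")
OPTIONAL_COLUMNS = ("pet_baseline", "pet_diamox", "stroke_mask_anat", "stroke_mask_bold")


def save_nifti(data: np.ndarray, affine: np.ndarray | None, path, tr_s: float | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), affine)
    if tr_s is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_s
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return path


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine), img.header.get_zooms()


def write_co2_tsv(co2: CO2Trace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": co2.times_s, "petco2_mmHg": co2.values_mmHg}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_co2_tsv(path) -> CO2Trace:
    df = pd.read_csv(path, sep="\t")
    missing = {"time_s", "petco2_mmHg"} - set(df.columns)
    if missing:
        raise ManifestError(f"CO2 trace {path}: missing columns {sorted(missing)}")
    return CO2Trace(
        times_s=df["time_s"].to_numpy(dtype=float),
        values_mmHg=df["petco2_mmHg"].to_numpy(dtype=float),
    )


def save_subject_niftis(subject, out_dir) -> dict[str, str]:
    """Write one realized phantom subject to disk; returns a manifest row.

    Files: label atlases on both grids, the 4-D BOLD series, the perfusion
    pair, lesion masks and the CO2 trace, all under ``out_dir/<subject_id>/``.
    """
    sid = subject.spec.subject_id
    sdir = Path(out_dir) / sid
    sdir.mkdir(parents=True, exist_ok=True)

    def rel(name: str) -> str:
        return f"{sid}/{name}"

    anat, bold_atlas = subject.anat_atlas, subject.bold_atlas
    save_nifti(anat.data.astype(np.int16), anat.affine, sdir / "atlas_anat.nii.gz")
    save_nifti(bold_atlas.data.astype(np.int16), bold_atlas.affine, sdir / "atlas_bold.nii.gz")
    save_nifti(
        subject.bold.data.astype(np.float32),
        subject.bold.affine,
        sdir / "bold.nii.gz",
        tr_s=subject.bold.tr_s,
    )
    save_nifti(subject.pet_baseline.astype(np.float32), bold_atlas.affine, sdir / "pet_baseline.nii.gz")
    save_nifti(subject.pet_diamox.astype(np.float32), bold_atlas.affine, sdir / "pet_diamox.nii.gz")
    save_nifti(subject.stroke_mask_anat.astype(np.uint8), anat.affine, sdir / "stroke_anat.nii.gz")
    save_nifti(subject.stroke_mask_bold.astype(np.uint8), bold_atlas.affine, sdir / "stroke_bold.nii.gz")
    write_co2_tsv(subject.co2, sdir / "co2.tsv")

    return {
        "subject_id": sid,
        "group": subject.spec.group,
        "stroke_side": subject.spec.stroke_side,
        "atlas_anat": rel("atlas_anat.nii.gz"),
        "atlas_bold": rel("atlas_bold.nii.gz"),
        "bold": rel("bold.nii.gz"),
        "co2": rel("co2.tsv"),
        "pet_baseline": rel("pet_baseline.nii.gz"),
        "pet_diamox": rel("pet_diamox.nii.gz"),
        "stroke_mask_anat": rel("stroke_anat.nii.gz"),
        "stroke_mask_bold": rel("stroke_bold.nii.gz"),
    }


def load_atlas(path) -> LabelAtlas:
    data, affine, zooms = load_nifti(path)
    return LabelAtlas(
        data=np.asarray(data).astype(np.int16),
        voxel_dims_mm=tuple(float(z) for z in zooms[:3]),
        affine=affine,
    )


def load_bold(path) -> BoldSeries:
    data, affine, zooms = load_nifti(path)
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldSeries(
        data=np.asarray(data, dtype=float),
        tr_s=tr,
        voxel_dims_mm=tuple(float(z) for z in zooms[:3]),
        affine=affine,
    )
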