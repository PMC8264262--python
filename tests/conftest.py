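import numpy as np
import pytest

from diaschisis.phantom import (
    Co2Protocol,
    PhantomGeometry,
    RegionSpec,
    SubjectPhantomSpec,
    generate_cohort_specs,
    default_cohort_spec,
)
from diaschisis.pipeline import reproduce_default_cohort
from diaschisis.regions import REGION_IDS

#: Small co-registered grid (72 x 72 x 48 mm FOV) for fast unit tests.
TINY_GEOMETRY = PhantomGeometry(
    anat_shape=(36, 36, 24),
    anat_voxel_mm=(2.0, 2.0, 2.0),
    bold_shape=(36, 36, 24),
    bold_voxel_mm=(2.0, 2.0, 2.0),
    tr_s=2.0,
)

_TINY_CENTROIDS = {
    "peduncle_L": (18.0, 14.0, 12.0),
    "peduncle_R": (54.0, 14.0, 12.0),
    "thalamus_L": (18.0, 32.0, 12.0),
    "thalamus_R": (54.0, 32.0, 12.0),
    "cerebellum_L": (18.0, 50.0, 12.0),
    "cerebellum_R": (54.0, 50.0, 12.0),
    "hemisphere_L": (18.0, 32.0, 36.0),
    "hemisphere_R": (54.0, 32.0, 36.0),
    "corticospinal_roi": (18.0, 14.0, 38.0),
}


def tiny_subject_spec(
    cvr: float | dict = 0.20,
    noise_sd: float = 0.0,
    seed: int = 0,
    volume_cm3: float = 0.40,
    co2: Co2Protocol | None = None,
    cbf: tuple[float, float] = (50.0, 60.0),
    drift_per_volume: float = 0.0,
) -> SubjectPhantomSpec:
    """A healthy mini-subject with all homologue pairs on the tiny grid.

    ``cvr`` may be a single value or a per-region-name dict.
    """
    regions = []
    for name, centroid in _TINY_CENTROIDS.items():
        regions.append(
            RegionSpec(
                region_id=REGION_IDS[name],
                name=name,
                target_volume_cm3=volume_cm3,
                centroid_mm=centroid,
                true_cvr=cvr.get(name, 0.2) if isinstance(cvr, dict) else cvr,
                true_cbf_baseline=cbf[0],
                true_cbf_diamox=cbf[1],
            )
        )
    return SubjectPhantomSpec(
        subject_id="tiny-01",
        group="healthy",
        stroke_side="none",
        wd_true=False,
        itd_true=False,
        ccd_true=False,
        regions=tuple(regions),
        noise_sd=noise_sd,
        drift_per_volume=drift_per_volume,
        seed=seed,
        co2=co2 or Co2Protocol(),
    )


@pytest.fixture(scope="session")
def fixture_result():
    """Full end-to-end run of the packaged default phantom cohort."""
    return reproduce_default_cohort()


@pytest.fixture(scope="session")
def fixture_specs():
    return generate_cohort_specs(default_cohort_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
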