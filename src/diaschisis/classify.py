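"""Healthy-reference thresholds and classification of Wallerian degeneration
(WD) and diaschisis (ipsilateral thalamic / crossed cerebellar).

The rule is the classical reference-cohort one: an index is abnormal when it
exceeds the healthy-cohort mean by more than two standard deviations. For WD
the implementation additionally requires the peduncular volume AI to be
negative (ipsilateral atrophy), because a 2SD exceedance with the *larger*
peduncle on the stroke side is not degeneration; a magnitude-only mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientReferenceError

__all__ = ["HealthyReference", "derive_threshold", "classify_wd", "classify_diaschisis"]

VALID_INDEX_NAMES = ("peduncle_volume_ai", "thalamus_cvr_ai", "cerebellum_cvr_ai")


@dataclass(frozen=True)
class HealthyReference:
    """Mean/SD of one asymmetry index in a healthy cohort, plus the 2SD threshold."""

    index_name: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientReferenceError("reference needs at least 2 subjects")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def threshold(self) -> float:
        """Magnitude threshold |mean| + 2*sd (used for the volume-AI WD rule)."""
        return abs(self.mean) + 2.0 * self.sd

    @property
    def upper_cutoff(self) -> float:
        """One-sided cutoff mean + 2*sd (used for the diaschisis rule)."""
        return self.mean + 2.0 * self.sd


def derive_threshold(healthy_values, index_name: str = "peduncle_volume_ai") -> HealthyReference:
    """Sample mean and SD (n-1 denominator) of healthy index values.

    With the healthy peduncular volume AI at 1.0 +/- 5.0 % this yields the
    11 % Wallerian-degeneration threshold.
    """
    v = np.asarray(list(healthy_values), dtype=float)
    if v.size < 2:
        raise InsufficientReferenceError(f"need >= 2 reference values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("reference values must be finite")
    return HealthyReference(
        index_name=index_name,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        n=int(v.size),
    )


def classify_wd(
    volume_ai_peduncle: float,
    ref: HealthyReference,
    require_atrophy: bool = True,
) -> bool:
    """Wallerian degeneration: |AI| strictly exceeds |mean| + 2*SD of the
    healthy cohort and (by default) the ipsilateral peduncle is the smaller one."""
    exceeds = abs(volume_ai_peduncle) > ref.threshold
    if require_atrophy:
        return bool(exceeds and volume_ai_peduncle < 0)
    return bool(exceeds)


def classify_diaschisis(cvr_ai: float, ref: HealthyReference) -> bool:
    """Diaschisis: deficit-positive CVR AI strictly above mean + 2*SD of the
    healthy cohort."""
    return bool(cvr_ai > ref.upper_cutoff)
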