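"""Exception hierarchy for the diaschisis pipeline."""


class DiaschisisError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(DiaschisisError):
    """A CO2 protocol violates its invariants (e.g. non-positive sampling interval)."""


class GenerationError(DiaschisisError):
    """Phantom generation failed (region out of grid, overlapping labels, ...)."""


class SpecError(DiaschisisError):
    """A phantom subject/cohort specification violates its invariants."""


class AlignmentError(DiaschisisError):
    """CO2 trace does not cover the BOLD acquisition window after shifting."""


class DegenerateStimulusError(DiaschisisError):
    """Regressor has zero variance; the CVR slope is undefined."""


class EmptyRegionError(DiaschisisError):
    """A region has no (valid) voxels on the requested grid/map."""


class UndefinedRatioError(DiaschisisError):
    """Denominator of an asymmetry index or percent difference is non-positive/zero."""


class InsufficientReferenceError(DiaschisisError):
    """Fewer than two healthy reference values; mean/SD threshold undefined."""


class DegenerateInputError(DiaschisisError):
    """Statistical routine received degenerate input (constant vector, empty group)."""


class ManifestError(DiaschisisError):
    """Subject manifest is missing, empty, or malformed."""
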