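"""Exception hierarchy shared across the pipeline."""


class RhizogeoError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(RhizogeoError, ValueError):
    """Malformed alignment: ragged rows, duplicate ids, illegal characters."""


class StrainMismatchError(RhizogeoError, ValueError):
    """Loci or matrices do not share the strain set they are required to share."""


class UndefinedDistanceError(RhizogeoError, ValueError):
    """A pairwise distance cannot be computed (no comparable sites, saturation)."""


class UnbalancedDesignError(RhizogeoError, ValueError):
    """The greenhouse design is not a balanced randomized complete block."""
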