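"""Exception hierarchy shared across the package."""


class DiatomHTError(Exception):
    """Base class for all package errors."""


class ValidationError(DiatomHTError, ValueError):
    """Input data violates a documented contract (range, shape, monotonicity)."""


class MetadataError(DiatomHTError, ValueError):
    """Required acquisition metadata (e.g. voxel size) is missing or inconsistent."""


class ConfigError(DiatomHTError, ValueError):
    """A configuration object is internally inconsistent or references unknown labels."""


class SizingError(DiatomHTError, ValueError):
    """A phantom grid is too small to contain the requested geometry."""


class EmptyCellError(DiatomHTError, ValueError):
    """A segmentation produced no foreground; metrics on it would be meaningless."""


class IntegrityError(DiatomHTError, ValueError):
    """A table violates an integrity constraint (e.g. duplicate cell ids)."""
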