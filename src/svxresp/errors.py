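"""Exception types shared across pipeline stages."""


class SvxrespError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SvxrespError, ValueError):
    """A configuration value or input volume violates a stated contract."""


class GeometryError(SvxrespError, ValueError):
    """Volumes that must share one voxel grid do not."""


class SizingError(SvxrespError, ValueError):
    """A simulated tumor does not fit inside the brain/geometry."""


class DegenerateInputError(SvxrespError, ValueError):
    """An input is too degenerate to process (empty mask, flat curve, ...)."""
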