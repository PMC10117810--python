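"""Exception and warning types shared across the package."""


class FilamentryError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FilamentryError, ValueError):
    """A spec/config describes geometry or parameters that cannot be realised."""


class InputError(FilamentryError, ValueError):
    """An input image or table is unreadable, empty, or malformed."""


class NoColonyFound(FilamentryError, RuntimeError):
    """Segmentation produced an all-foreground or all-background mask."""


class OpeningTooAggressive(FilamentryError, RuntimeError):
    """Morphological opening erased the entire colony object."""


class InferenceError(FilamentryError, ValueError):
    """A statistical routine received groups it cannot test (e.g. an empty group)."""


class UndefinedChangeError(FilamentryError, ValueError):
    """Relative change requested against a non-positive baseline mean."""


class RunError(FilamentryError, RuntimeError):
    """A batch run failed (empty manifest or too many per-image failures)."""


class DegenerateScaleWarning(UserWarning):
    """MAD of a group is zero; the modified z-score cannot flag outliers."""


class SegmentationWarning(UserWarning):
    """A segmentation-quality precondition was only loosely satisfied."""
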