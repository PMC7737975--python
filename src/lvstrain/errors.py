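"""Exception hierarchy.

``ConfigurationError`` covers invalid user input (bad phantom parameters,
malformed CLI options); ``DataError`` covers structurally broken datasets
(missing slices/frames, mismatched groups).  The CLI maps the former to
exit code 1 and the latter to exit code 2.
"""


class LVStrainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LVStrainError):
    """Invalid configuration or parameter value."""


class GenerationError(LVStrainError):
    """Phantom generation produced an impossible geometry."""


class DataError(LVStrainError):
    """Input data is incomplete or inconsistent."""


class MeasurementError(DataError):
    """A contour or mask cannot be measured."""
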