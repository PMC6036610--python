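"""Exception hierarchy shared by all stages of the pipeline."""


class ResidualSTLError(Exception):
    """Base class for errors raised by this package."""


class FormatError(ResidualSTLError):
    """A file does not conform to its declared format."""


class GeometryError(ResidualSTLError):
    """Physical geometry is inconsistent (grid mismatch, oblique axes, ...)."""


class ParameterError(ResidualSTLError, ValueError):
    """An argument or configuration value violates a precondition."""
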