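"""Exception hierarchy shared across the pipeline."""


class CytoQFError(Exception):
    """Base class for all package errors."""


class FormatError(CytoQFError):
    """A file could not be parsed as the format it claims to be."""


class EmptyInputError(CytoQFError):
    """An operation received zero events / an empty cluster."""


class InsufficientDataError(CytoQFError):
    """Too few events (or channels) for the requested operation."""


class DegenerateAxisError(CytoQFError):
    """An axis has zero variance where spread is required."""


class ParameterError(CytoQFError):
    """Invalid transform or configuration parameters."""


class InvalidSplitError(CytoQFError):
    """A two-way split with an empty side."""


class ValidationError(CytoQFError):
    """Inputs that disagree with each other (e.g. labels vs events)."""
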