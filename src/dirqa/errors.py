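"""Exception hierarchy."""


class DirqaError(Exception):
    """Base class for all package errors."""


class ValidationError(DirqaError, ValueError):
    """Invalid argument or inconsistent domain object."""


class GeometryError(DirqaError):
    """Incompatible or unsupported grid geometry."""


class FormatError(DirqaError):
    """Malformed input file."""


class IntegrityError(DirqaError):
    """Case-bundle manifest and payload disagree."""


class NotEvaluableError(DirqaError):
    """A metric has no defined value for the given input (e.g. empty surface)."""
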