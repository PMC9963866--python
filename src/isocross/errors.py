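"""Exception hierarchy shared across the package."""


class IsocrossError(Exception):
    """Base class for all package errors."""


class ValidationError(IsocrossError):
    """Invalid input data (malformed rows, broken invariants)."""


class AnalysisError(IsocrossError):
    """A computation could not be carried out on valid inputs."""
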