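"""Named exception types raised by the analysis pipeline.

Per-metabolite failures are caught by the pipeline and recorded in the
``status`` column of the consolidated output; only configuration/IO errors
abort a run.
"""


class PolynovaError(Exception):
    """Base class for all package errors."""


class InputError(PolynovaError):
    """Malformed or inconsistent input table / configuration."""


class MissingColumnError(InputError):
    """A declared factor/exclude/ignore column is absent from the header."""


class ResponseParseError(InputError):
    """A response cell holds a non-numeric token other than the missing code."""


class TransformDomainError(PolynovaError):
    """A value lies outside the domain of the requested transformation."""


class DesignError(PolynovaError):
    """The design is degenerate for a metabolite (empty cell, single level...)."""


class NotEstimableError(PolynovaError):
    """A contrast or effect is not estimable from the available data."""


class ExportError(PolynovaError):
    """Result files could not be written."""
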