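"""Exception types shared across the package."""


class InfermapError(Exception):
    """Base class for package errors."""


class ValidationError(InfermapError, ValueError):
    """A configuration or input value violates a documented invariant.

    The message always names the offending field.
    """


class SchemaError(InfermapError, ValueError):
    """A session file is present but structurally invalid."""


class CoverageError(InfermapError, ValueError):
    """A requested time window is not covered by the available trace."""


class DesignError(InfermapError, ValueError):
    """A regression design is rank deficient or otherwise unusable."""
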