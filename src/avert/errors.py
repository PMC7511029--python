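"""Exception hierarchy for the averted-births pipeline."""


class AvertError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(AvertError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(AvertError):
    """An input table is missing required columns or has the wrong types."""


class ReferentialIntegrityError(AvertError):
    """A child record points at a parent that does not exist."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class ValidationError(AvertError):
    """One or more rows violate a declared invariant.

    ``rows`` holds 1-based data-row numbers (header excluded) of every
    offending record; validation never silently drops rows.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class EstimationError(AvertError):
    """An estimator cannot produce a defined result for this input."""
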