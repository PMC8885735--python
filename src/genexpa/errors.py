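"""Machine-readable errors raised by the pipeline.

Every error carries a short ``code`` suitable for programmatic handling and,
where relevant, the offending coordinates (sample, replicate, gene).
"""

from __future__ import annotations


class GenexpaError(Exception):
    """Base class; ``code`` identifies the failure mode."""

    code = "error"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


class TableFormatError(GenexpaError):
    """Malformed or incomplete input table."""

    code = "table_format"


class IncompleteTableError(TableFormatError):
    code = "incomplete_table"


class DuplicateReplicateError(TableFormatError):
    code = "duplicate_replicate"


class NonPositiveQuantityError(TableFormatError):
    code = "non_positive_quantity"


class ValidationError(GenexpaError):
    """Run configuration or cross-table consistency failure."""

    code = "validation"


class PoolExhaustedError(ValidationError):
    """Candidate pool would drop below NormFinder's 3-gene minimum."""

    code = "pool_exhausted"


class UniverseTooSmallError(ValidationError):
    code = "universe_too_small"


class InsufficientReplicatesError(ValidationError):
    code = "insufficient_replicates"
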