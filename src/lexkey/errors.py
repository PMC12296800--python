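"""Exception hierarchy shared across the package."""

from __future__ import annotations


class LexkeyError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LexkeyError):
    """A required column or header is missing from an input table."""


class RowValidationError(LexkeyError):
    """A single data row failed validation and was quarantined."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


class ConlluParseError(LexkeyError):
    """A token-table line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class AmbiguousAliasError(LexkeyError):
    """The same alias is claimed by more than one de-identification entity."""

    def __init__(self, collisions: dict[str, list[str]]):
        self.collisions = dict(collisions)
        pairs = "; ".join(
            f"{alias!r} -> {sorted(ids)}" for alias, ids in sorted(collisions.items())
        )
        super().__init__(f"aliases shared between entities: {pairs}")


class KeynessDomainError(LexkeyError):
    """Degenerate counts make the log-odds statistic undefined."""


class PipelineStageError(LexkeyError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.__cause__ = cause
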