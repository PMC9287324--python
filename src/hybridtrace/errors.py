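"""Exception hierarchy shared across the pipeline."""


class HybridTraceError(Exception):
    """Base class for all package errors."""


class AlignmentGeometryError(HybridTraceError):
    """Rows of unequal length, or an operation mixing alignments of different width."""


class AlphabetError(HybridTraceError):
    """A sequence contains a symbol outside the IUPAC+gap alphabet."""

    def __init__(self, message: str, record: str | None = None, column: int | None = None):
        super().__init__(message)
        self.record = record
        self.column = column  # 1-based alignment column


class GapStateError(HybridTraceError):
    """A gap character reached the IUPAC set algebra, which is defined only on base codes."""


class ValidationError(HybridTraceError):
    """Malformed metadata or configuration."""


class UndefinedStatisticError(HybridTraceError):
    """A summary statistic has an empty denominator."""
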