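"""Exception hierarchy shared across the pipeline."""


class CliqueScreenError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(CliqueScreenError):
    """An input file is missing required columns or is otherwise malformed."""


class RowError(CliqueScreenError):
    """One or more data rows are invalid; the message lists the line numbers."""

    def __init__(self, message: str, lines=()):
        self.lines = tuple(lines)
        if self.lines:
            message = f"{message} (lines {', '.join(map(str, self.lines))})"
        super().__init__(message)


class ParameterError(CliqueScreenError):
    """A caller-supplied parameter is out of its valid range."""


class ValidationError(CliqueScreenError):
    """A data structure violates one of its invariants."""


class UndefinedDensityError(CliqueScreenError):
    """Density is undefined for networks with fewer than two nodes."""


class UndefinedRateError(CliqueScreenError):
    """An inclusion rate has a zero denominator (no biomarkers in the network)."""


class InsufficientDataError(CliqueScreenError):
    """Too few observations to run the requested statistical procedure."""


class ConsistencyError(CliqueScreenError):
    """Cross-table bookkeeping failed (e.g. a gene ranked by one metric only)."""


class CoverageError(CliqueScreenError):
    """Required per-gene inputs are missing; the message lists the genes."""

    def __init__(self, message: str, genes=()):
        self.genes = tuple(sorted(genes))
        if self.genes:
            message = f"{message}: {', '.join(self.genes)}"
        super().__init__(message)


class DegenerateSplitError(CliqueScreenError):
    """A median split produced a group too small to test."""


class ExcludedNodeError(CliqueScreenError):
    """The node is degree-0 and excluded from score calculation."""
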