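"""Exception hierarchy shared across the package."""


class WgdTimingError(Exception):
    """Base class for all package errors."""


class FastaParseError(WgdTimingError):
    """Malformed FASTA input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NewickParseError(WgdTimingError):
    """Malformed Newick input; carries a 0-based character position when known."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)


class NeighborhoodTableError(WgdTimingError):
    """Malformed gene-neighbourhood table."""


class TreeError(WgdTimingError):
    """Invalid tree operation (unknown node, degenerate structure, ...)."""


class UncomparablePairError(WgdTimingError):
    """A sequence pair shares no valid (ungapped, unambiguous) column."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        names = ", ".join(f"{a}/{b}" for a, b in self.pairs)
        super().__init__(f"no valid columns for sequence pair(s): {names}")


class SaturationError(WgdTimingError):
    """A distance correction left its valid domain (too many differences)."""


class SaturatedMatrixError(WgdTimingError):
    """A distance matrix contains saturated cells and cannot feed NJ."""


class NonMonophyleticOutgroupError(TreeError):
    """The requested outgroup does not form a clade; names intruding tips."""

    def __init__(self, outgroup, conflicting):
        self.conflicting = sorted(conflicting)
        super().__init__(
            "outgroup {%s} is not monophyletic; conflicting tips: %s"
            % (", ".join(sorted(outgroup)), ", ".join(self.conflicting))
        )


class TimingError(WgdTimingError):
    """The timing statistic is undefined on this tree/labeling."""


class ScenarioError(WgdTimingError):
    """Invalid or degenerate simulation scenario."""


class PipelineError(WgdTimingError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
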