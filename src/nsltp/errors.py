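"""Exception hierarchy shared across the package."""


class NsltpError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(NsltpError):
    """Malformed sequence or pattern input."""


class NoRecordsError(ParseError):
    """An input that should contain sequence records contained none."""


class AlignmentShapeError(NsltpError):
    """Alignment members do not share a common column count."""


class PatternSyntaxError(ParseError):
    """Invalid Prosite pattern syntax; message carries the character offset."""


class MotifExplosionError(NsltpError):
    """Cysteine-rich input produced more motif candidates than allowed."""

    def __init__(self, cysteine_count: int, max_candidates: int):
        self.cysteine_count = cysteine_count
        self.max_candidates = max_candidates
        super().__init__(
            f"more than {max_candidates} candidate 8-Cys motifs "
            f"(sequence has {cysteine_count} cysteines); raise max_candidates "
            "or pre-filter the sequence"
        )


class InsufficientDataError(NsltpError):
    """Not enough alignment members (or informative columns) to induce a pattern."""


class SimulationError(NsltpError):
    """A decoy or fixture could not be generated from the given input."""
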