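"""Exception hierarchy for pitescan.

Every error raised by the library derives from :class:`PitescanError`, so
callers (and the CLI) can catch one base class.
"""


class PitescanError(Exception):
    """Base class for all pitescan errors."""


class InvalidAlphabet(PitescanError):
    """A sequence contains a character outside {A, C, G, T, N} (after U→T)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            "(allowed: A, C, G, T, N; U is mapped to T)"
        )


class SeedOutOfRange(PitescanError):
    """The seed window does not fit on the piRNA."""


class HeaderParseError(PitescanError):
    """A TE FASTA header could not be parsed (empty or malformed name)."""


class EmptyReference(PitescanError):
    """A TE reference with zero records was supplied."""


class MalformedRow(PitescanError):
    """A tabular input row (rmsk TSV, chromosome table) is malformed."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class UnknownChromosome(PitescanError):
    """A BED interval names a chromosome absent from the genome."""


class IntervalOutOfBounds(PitescanError):
    """A BED interval extends past the end of its chromosome."""


class OffsetOutOfRange(PitescanError):
    """A claimed seed-match offset does not fit inside the TE sequence."""


class NothingToPlot(PitescanError):
    """A plot was requested but there is no plottable data."""


class ConfigInfeasible(PitescanError):
    """A synthetic-fixture configuration cannot be realised (e.g. TE packing)."""
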