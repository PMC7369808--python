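"""Exception hierarchy.

All user-facing failures derive from :class:`RepairGuideError` so the CLI can
catch one type and print a single-line diagnostic.
"""


class RepairGuideError(Exception):
    """Base class for all errors raised by repairguide."""


class FastaParseError(RepairGuideError):
    """Malformed or empty FASTA input."""


class AlphabetError(RepairGuideError):
    """Sequence contains characters outside the accepted nucleotide alphabet."""

    def __init__(self, offending: set[str], context: str = ""):
        self.offending = sorted(offending)
        where = f" in {context}" if context else ""
        super().__init__(
            f"non-ACGTU characters{where}: {', '.join(repr(c) for c in self.offending)}"
        )


class CoordinateError(RepairGuideError):
    """A transcript/codon coordinate falls outside the sequence."""


class DesignError(RepairGuideError):
    """A spacer design request violates its geometric or policy constraints."""


class EditError(RepairGuideError):
    """An A-to-G edit was requested at a position that does not hold an A."""


class TraceError(RepairGuideError):
    """Invalid trace data or trace-quantification request."""
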