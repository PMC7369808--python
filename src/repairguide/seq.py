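"""Transcript records, FASTA I/O, and ORF translation.

The substrate of every downstream computation is a :class:`TranscriptRecord`:
a cDNA/mRNA sequence plus the 1-based transcript coordinate of the first base
of codon 1 (``orf_start``). All public interfaces speak 1-based, inclusive
coordinates; RNA input (U) is accepted everywhere and normalised to the DNA
alphabet (T) internally.

IUPAC ambiguity codes are rejected rather than expanded: a spacer designed
against an ambiguous base would silently be wrong, so we fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, CoordinateError, FastaParseError

__all__ = [
    "TranscriptRecord",
    "ProteinTranslation",
    "normalize_sequence",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "translate_orf",
    "to_rna",
]

_DNA = frozenset("ACGT")


def normalize_sequence(raw: str, context: str = "") -> str:
    """Uppercase, map U->T, and reject anything outside {A,C,G,T,U}."""
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - _DNA
    if bad:
        raise AlphabetError(bad, context)
    return seq


def to_rna(seq: str) -> str:
    """Render a DNA-alphabet sequence in the RNA alphabet (T->U)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class TranscriptRecord:
    """A named nucleotide sequence with an annotated ORF start.

    Parameters
    ----------
    id
        Record name (FASTA header up to the first whitespace).
    sequence
        Nucleotide sequence; U and lower case are accepted and normalised.
    orf_start
        1-based transcript coordinate of the first base of codon 1.
    """

    id: str
    sequence: str
    orf_start: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=f"record {self.id!r}")
        )
        if len(self.sequence) < 3:
            raise CoordinateError(
                f"record {self.id!r}: sequence shorter than one codon ({len(self.sequence)} nt)"
            )
        if not 1 <= self.orf_start <= len(self.sequence) - 2:
            raise CoordinateError(
                f"record {self.id!r}: orf_start {self.orf_start} leaves no full codon "
                f"in a {len(self.sequence)} nt sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based transcript coordinate."""
        if not 1 <= position <= len(self.sequence):
            raise CoordinateError(
                f"position {position} outside record {self.id!r} (1..{len(self.sequence)})"
            )
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence between 1-based inclusive coordinates."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise CoordinateError(
                f"span {start}..{end} outside record {self.id!r} (1..{len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]

    def with_sequence(self, sequence: str) -> "TranscriptRecord":
        return dataclasses.replace(self, sequence=sequence)


@dataclass(frozen=True)
class ProteinTranslation:
    """Translation of an ORF up to (not including) the first stop codon.

    ``stop_index`` is the 1-based codon index of the first in-frame stop, or
    ``None`` if no stop occurs before the end of the sequence. ``complete`` is
    true when that first stop is also the last in-frame stop of the transcript,
    i.e. translation ran to the terminal stop without hitting a premature one.
    """

    residues: str
    stop_index: int | None
    complete: bool


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA-alphabet string."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _DNA
    if bad:
        raise AlphabetError(bad, "reverse_complement input")
    return str(Seq(seq).reverse_complement())


def _orf_codons(record: TranscriptRecord) -> list[str]:
    """Full codons from orf_start to the end of the sequence (trailing partial
    codon ignored)."""
    seq = record.sequence[record.orf_start - 1 :]
    n_full = len(seq) // 3
    return [seq[3 * i : 3 * i + 3] for i in range(n_full)]


def _stop_codon_indices(record: TranscriptRecord) -> list[int]:
    """1-based codon indices of every in-frame stop codon."""
    aa = str(Seq("".join(_orf_codons(record))).translate())
    return [i + 1 for i, r in enumerate(aa) if r == "*"]


def terminal_stop_index(record: TranscriptRecord) -> int | None:
    """Codon index of the terminal stop: the *last* in-frame stop of the
    transcript.

    Without an explicit ORF-end annotation this is the only computable
    convention; it is exact for ORF-spanning cDNAs (the inputs this tool is
    designed for) but misreads transcripts whose 3' UTR happens to contain
    in-frame stops — trim such inputs to the ORF.
    """
    stops = _stop_codon_indices(record)
    return stops[-1] if stops else None


def translate_orf(record: TranscriptRecord) -> ProteinTranslation:
    """Translate from ``orf_start`` with the standard genetic code until the
    first stop codon or the end of the sequence."""
    codons = _orf_codons(record)
    if not codons:
        raise CoordinateError(
            f"record {record.id!r}: no full codon downstream of orf_start {record.orf_start}"
        )
    aa = str(Seq("".join(codons)).translate())
    first = aa.find("*")
    if first == -1:
        return ProteinTranslation(residues=aa, stop_index=None, complete=False)
    last = aa.rfind("*")
    return ProteinTranslation(residues=aa[:first], stop_index=first + 1, complete=first == last)


def read_fasta(path: str | Path, orf_start: int = 1) -> list[TranscriptRecord]:
    """Read a (multi-record) FASTA file into transcript records.

    ``orf_start`` applies to every record (override per record downstream if
    needed). U is normalised to T; case is normalised; ambiguity codes are
    rejected with the offending symbols named.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header starting with '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: no records (empty file)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(TranscriptRecord(id=rec.id, sequence=str(rec.seq), orf_start=orf_start))
    if not records:
        raise FastaParseError(f"{path}: no records")
    return records


def write_fasta(
    records: Iterable[TranscriptRecord],
    path: str | Path,
    width: int = 60,
    rna: bool = False,
) -> None:
    """Write records as FASTA; ``rna=True`` renders T as U."""
    with open(path, "w") as fh:
        for rec in records:
            seq = to_rna(rec.sequence) if rna else rec.sequence
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
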