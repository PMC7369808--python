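"""Premature termination codon (PTC) scanning and coordinate rendering.

A PTC is an in-frame stop codon strictly upstream of the transcript's terminal
stop. Each site is annotated with its editable adenosines and the minimal
A->G edit plan that converts it back to a sense codon:

* opal  (TGA): edit the 3rd base  -> TGG (Trp)
* amber (TAG): edit the 2nd base  -> TGG (Trp)
* ochre (TAA): needs both the 2nd and 3rd base -> TGG (Trp); single-site
  deamination cannot rescue it, so it is flagged ``requires_two_edits``.

The stop-to-Trp outcome is forced by the genetic code: TGG is the only codon
reachable from any stop by A->G substitution at its adenosine(s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import CoordinateError
from .seq import TranscriptRecord, _stop_codon_indices, normalize_sequence

__all__ = ["PtcSite", "StopClassification", "classify_stop", "codon_to_nt", "scan_ptcs"]

_STOP_CLASS = {"TGA": "opal", "TAG": "amber", "TAA": "ochre"}
# within-codon offsets (1-based) of the adenosines that must become G for TGG
_EDIT_OFFSETS = {"TGA": (3,), "TAG": (2,), "TAA": (2, 3)}


@dataclass(frozen=True)
class StopClassification:
    stop_class: str  # opal | amber | ochre | none
    edit_offsets: tuple[int, ...]  # within-codon offsets (1-based) to edit
    restored_codon: str
    restored_residue: str


def classify_stop(codon: str) -> StopClassification:
    """Classify a codon as a stop (opal/amber/ochre) and give its A->G rescue.

    Sense codons come back with ``stop_class='none'``, an empty edit plan and
    themselves as the "restored" codon.
    """
    codon = normalize_sequence(codon, context="codon")
    if len(codon) != 3:
        raise CoordinateError(f"codon must be 3 nt, got {len(codon)} ({codon!r})")
    if codon in _STOP_CLASS:
        return StopClassification(
            stop_class=_STOP_CLASS[codon],
            edit_offsets=_EDIT_OFFSETS[codon],
            restored_codon="TGG",
            restored_residue="W",
        )
    return StopClassification(
        stop_class="none",
        edit_offsets=(),
        restored_codon=codon,
        restored_residue=str(Seq(codon).translate()),
    )


def codon_to_nt(
    codon_index: int, orf_start: int = 1, sequence_length: int | None = None
) -> tuple[int, int]:
    """Transcript coordinates (1-based, inclusive) spanned by a codon.

    ``start = orf_start + 3*(codon_index - 1)``; ``end = start + 2``.
    """
    if codon_index < 1:
        raise CoordinateError(f"codon_index must be >= 1, got {codon_index}")
    if orf_start < 1:
        raise CoordinateError(f"orf_start must be >= 1, got {orf_start}")
    start = orf_start + 3 * (codon_index - 1)
    end = start + 2
    if sequence_length is not None and end > sequence_length:
        raise CoordinateError(
            f"codon {codon_index} spans {start}..{end}, beyond sequence length {sequence_length}"
        )
    return start, end


@dataclass(frozen=True)
class PtcSite:
    """A located premature stop codon and its A->G rescue plan.

    ``g_notation`` renders the presumed G>A origin of the stop in
    record-relative coordinates (base 1 of the record), e.g. ``g.3846G>A``;
    ``c_notation`` is the same position in CDS coordinates (c.1 = orf_start).
    Both are only defined when the rescue is a single edit (the restored codon
    differs from the stop at exactly one position).
    """

    record_id: str
    codon_index: int
    codon_seq: str
    stop_class: str
    adenosine_positions: tuple[int, ...]
    edit_plan: tuple[int, ...]
    restored_codon: str
    restored_residue: str
    g_notation: str | None
    c_notation: str | None
    requires_two_edits: bool


def _build_site(record: TranscriptRecord, codon_index: int) -> PtcSite:
    start, end = codon_to_nt(codon_index, record.orf_start, len(record))
    codon = record.slice(start, end)
    cls = classify_stop(codon)
    adenosines = tuple(start + i for i, b in enumerate(codon) if b == "A")
    edit_plan = tuple(start + off - 1 for off in cls.edit_offsets)
    g_notation = c_notation = None
    if len(edit_plan) == 1:
        pos = edit_plan[0]
        g_notation = f"g.{pos}G>A"
        c_notation = f"c.{pos - record.orf_start + 1}G>A"
    return PtcSite(
        record_id=record.id,
        codon_index=codon_index,
        codon_seq=codon,
        stop_class=cls.stop_class,
        adenosine_positions=adenosines,
        edit_plan=edit_plan,
        restored_codon=cls.restored_codon,
        restored_residue=cls.restored_residue,
        g_notation=g_notation,
        c_notation=c_notation,
        requires_two_edits=len(cls.edit_offsets) > 1,
    )


def scan_ptcs(record: TranscriptRecord, include_terminal: bool = False) -> list[PtcSite]:
    """Locate every premature stop codon in the ORF.

    The terminal stop (the last in-frame stop of the transcript) is excluded
    unless ``include_terminal`` is set. If the frame contains no stop at all,
    an empty list is returned with a warning that the ORF may be truncated.
    """
    stops = _stop_codon_indices(record)
    if not stops:
        warnings.warn(
            f"record {record.id!r}: no in-frame stop codon found; the ORF may be truncated",
            stacklevel=2,
        )
        return []
    reported = stops if include_terminal else stops[:-1]
    return [_build_site(record, idx) for idx in reported]
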