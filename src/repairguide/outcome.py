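"""Predicted consequences of A-to-I editing on a transcript.

Inosine is read as guanosine by both the ribosome and sequencing polymerases,
so an edit is modeled as an in-place A->G substitution; no inosine-specific
alphabet is introduced. Editing efficiency is not modeled here (per-population
edited fractions live in :mod:`repairguide.sanger`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import EditError
from .scan import PtcSite
from .seq import ProteinTranslation, TranscriptRecord, translate_orf

__all__ = ["EditOutcome", "apply_editing", "predict_outcome"]


def apply_editing(record: TranscriptRecord, positions: Iterable[int]) -> TranscriptRecord:
    """Return a new record with A->G applied at each 1-based position.

    Every position must currently hold an A; re-application at an
    already-edited position therefore errors (the base is no longer A).
    """
    seq = list(record.sequence)
    for pos in positions:
        base = record.base(pos)  # range check
        current = seq[pos - 1]
        if current != "A":
            raise EditError(
                f"position {pos} of {record.id!r} holds {current}, not A; cannot deaminate"
            )
        seq[pos - 1] = "G"
    return record.with_sequence("".join(seq))


@dataclass(frozen=True)
class EditOutcome:
    """Repair outcome of applying a PTC's edit plan.

    ``full_length`` is true when translation of the edited transcript runs to
    the terminal stop (no remaining premature stop).
    """

    record_id: str
    edited_sequence: str
    edited_positions: tuple[int, ...]
    restored_residue_index: int | None
    restored_residue: str | None
    premature_stop_removed: bool
    full_length: bool
    protein_before: ProteinTranslation
    protein_after: ProteinTranslation


def predict_outcome(
    record: TranscriptRecord, ptc: PtcSite, allow_multi_edit: bool = False
) -> EditOutcome:
    """Apply a PTC's edit plan, re-translate, and report the repair outcome.

    Ochre (TAA) sites need two simultaneous deaminations, which is outside
    single-site editing scope; they raise unless ``allow_multi_edit`` is set.
    """
    if not ptc.edit_plan:
        raise EditError(f"PTC at codon {ptc.codon_index} has no edit plan")
    if ptc.requires_two_edits and not allow_multi_edit:
        raise EditError(
            f"{ptc.stop_class} PTC at codon {ptc.codon_index} is not single-edit rescuable "
            "(requires two A->G edits); pass allow_multi_edit=True to override"
        )
    edited = apply_editing(record, ptc.edit_plan)
    before = translate_orf(record)
    after = translate_orf(edited)

    removed = after.stop_index is None or (
        before.stop_index is not None and after.stop_index > before.stop_index
    )
    restored_index = restored = None
    if len(after.residues) >= ptc.codon_index:
        restored_index = ptc.codon_index
        restored = after.residues[ptc.codon_index - 1]
    return EditOutcome(
        record_id=record.id,
        edited_sequence=edited.sequence,
        edited_positions=tuple(ptc.edit_plan),
        restored_residue_index=restored_index,
        restored_residue=restored,
        premature_stop_removed=removed,
        full_length=after.complete,
        protein_before=before,
        protein_after=after,
    )
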