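"""Bystander-adenosine consequence enumeration.

Every adenosine inside a spacer's hybridisation window is a candidate for
collateral deamination by the tethered ADAR domain. This module enumerates
them and annotates the protein consequence of each single A->G substitution,
one position at a time (combinatorial multi-site editing is out of scope, and
no editing-propensity model is assigned: the report is pure consequence
enumeration).

Consequence classes:

* ``intended-PTC-repair`` -- the design's target adenosine, when its codon is
  a stop and the edit converts it to a sense codon.
* ``synonymous`` -- residue unchanged (includes the stop-to-stop case, which
  for A->G can only arise inside ochre/amber codons).
* ``missense`` -- residue changed, neither side a stop.
* ``stop-lost`` -- a *non-target* stop codon converted to sense.
* ``stop-introducing`` -- a sense codon converted to a stop (unreachable for
  single A->G edits under the standard code, kept for completeness).
* ``outside-ORF`` -- the adenosine lies upstream of codon 1 or downstream of
  the terminal stop (noncoding in this transcript).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .design import GuideDesign
from .scan import codon_to_nt
from .seq import TranscriptRecord, terminal_stop_index

__all__ = ["BystanderEntry", "BystanderReport", "assess_bystanders"]

CONSEQUENCE_CLASSES = (
    "intended-PTC-repair",
    "synonymous",
    "missense",
    "stop-lost",
    "stop-introducing",
    "outside-ORF",
)

_STOPS = {"TGA", "TAG", "TAA"}


@dataclass(frozen=True)
class BystanderEntry:
    position: int  # transcript coordinate of the adenosine
    codon_index: int | None  # None when outside the ORF
    codon_offset: int | None  # 1..3 within the codon
    codon_before: str | None
    codon_after: str | None
    residue_before: str | None
    residue_after: str | None
    consequence: str


@dataclass(frozen=True)
class BystanderReport:
    record_id: str
    target_a: int
    window: tuple[int, int]
    entries: tuple[BystanderEntry, ...]
    counts: dict[str, int]


def _residue(codon: str) -> str:
    return str(Seq(codon).translate())


def assess_bystanders(record: TranscriptRecord, design: GuideDesign) -> BystanderReport:
    """Annotate the consequence of editing each adenosine in the design window."""
    w_start, w_end = design.window
    record.slice(w_start, w_end)  # range check
    terminal = terminal_stop_index(record)
    if terminal is not None:
        orf_end = codon_to_nt(terminal, record.orf_start)[1]
    else:  # open-ended ORF: coding through the last full codon
        orf_end = record.orf_start + 3 * ((len(record) - record.orf_start + 1) // 3) - 1

    entries: list[BystanderEntry] = []
    for pos in range(w_start, w_end + 1):
        if record.base(pos) != "A":
            continue
        if pos < record.orf_start or pos > orf_end:
            entries.append(
                BystanderEntry(pos, None, None, None, None, None, None, "outside-ORF")
            )
            continue
        codon_index = (pos - record.orf_start) // 3 + 1
        c_start, _ = codon_to_nt(codon_index, record.orf_start, len(record))
        offset = pos - c_start + 1
        before = record.slice(c_start, c_start + 2)
        after = before[: offset - 1] + "G" + before[offset:]
        res_before, res_after = _residue(before), _residue(after)
        if before in _STOPS and after not in _STOPS:
            consequence = (
                "intended-PTC-repair" if pos == design.target_a else "stop-lost"
            )
        elif res_before == res_after:
            consequence = "synonymous"
        elif after in _STOPS:
            consequence = "stop-introducing"
        else:
            consequence = "missense"
        entries.append(
            BystanderEntry(
                pos, codon_index, offset, before, after, res_before, res_after, consequence
            )
        )
    counts = dict(Counter(e.consequence for e in entries))
    return BystanderReport(
        record_id=record.id,
        target_a=design.target_a,
        window=design.window,
        entries=tuple(entries),
        counts=counts,
    )
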