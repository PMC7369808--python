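"""Antisense spacer construction and cloning-oligo emission.

A spacer is the guide segment complementary to the mRNA window surrounding the
target adenosine; it is followed 3' by the dCas13b scaffold hairpin. Geometry
is parameterised by the spacer length ``L`` and the mismatch distance ``d``:
the position of the deliberately mispaired C, counted from the spacer 3' end
with the 3'-terminal base as position 1. Because the scaffold abuts the spacer
3' end, ``d`` equals the distance between the target adenosine and the first
scaffold nucleotide.

Conventions (an off-by-one here silently shifts the edited base, so they are
spelled out):

* The spacer 3' end pairs with the *lowest* transcript coordinate of the
  window; the window is ``[target_A - d + 1, target_A + L - d]`` (1-based,
  inclusive, length L).
* The spacer is the reverse complement of the window with the base opposite
  the target A replaced by C, giving the single C:A mismatch in the
  gRNA/mRNA hybrid.
* The spacer 5' base must be G (efficient U6 transcription). Policy
  ``substitute`` overwrites the 5' base (preserving L and d, the default);
  ``prepend`` adds a G (length L+1); ``require`` errors unless the 5' base is
  already G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .errors import DesignError
from .seq import TranscriptRecord, reverse_complement, normalize_sequence

__all__ = [
    "DesignParams",
    "GuideDesign",
    "OligoPair",
    "DesignBatch",
    "Issue",
    "design_spacer",
    "enumerate_designs",
    "emit_oligo_pair",
    "validate_design",
    "BBSI_SITES",
    "DEFAULT_OVERHANGS",
]

BBSI_SITES = ("GAAGAC", "GTCTTC")  # BbsI recognition site, both strands
# Golden-gate style directional-cloning overhangs; provisional defaults, fully
# configurable -- the duplex round-trip is what is guaranteed, not these bases.
DEFAULT_OVERHANGS = ("CACC", "CAAC")
GUIDE_MIN_LENGTH = 25
GUIDE_MAX_LENGTH = 80

_POLICIES = ("substitute", "prepend", "require")


@dataclass(frozen=True)
class DesignParams:
    """Spacer geometry: length, mismatch distance and 5'-G policy.

    Bounds are validated when a design is attempted (not at construction) so
    that invalid grid entries can be collected as per-entry failures.
    """

    length: int
    mismatch_distance: int
    five_prime_policy: str = "substitute"
    min_length: int = GUIDE_MIN_LENGTH
    max_length: int = GUIDE_MAX_LENGTH

    def validate(self) -> None:
        if self.five_prime_policy not in _POLICIES:
            raise DesignError(
                f"unknown five_prime_policy {self.five_prime_policy!r}; choose from {_POLICIES}"
            )
        if not self.min_length <= self.length <= self.max_length:
            raise DesignError(
                f"spacer length {self.length} outside guide bounds "
                f"[{self.min_length}, {self.max_length}]"
            )
        if not 1 <= self.mismatch_distance <= self.length:
            raise DesignError(
                f"mismatch distance {self.mismatch_distance} outside [1, length={self.length}]"
            )


@dataclass(frozen=True)
class GuideDesign:
    """One designed spacer with its geometry and provenance."""

    record_id: str
    target_a: int  # transcript coordinate of the adenosine to edit
    params: DesignParams
    window: tuple[int, int]  # transcript span the spacer hybridises to
    spacer: str  # 5'->3', DNA alphabet
    mismatch_pos_from_3prime: int
    five_prime_base_modified: bool
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class OligoPair:
    """Annealing-ready complementary oligos with directional-cloning overhangs."""

    name: str
    top_oligo: str
    bottom_oligo: str
    top_overhang: str
    bottom_overhang: str
    enzyme: str = "BbsI"


class Issue(NamedTuple):
    code: str
    message: str


def _sequence_warnings(spacer: str) -> list[str]:
    warns = []
    for site in BBSI_SITES:
        if site in spacer:
            warns.append(f"spacer contains internal BbsI site {site}")
    run_base, run_len = "", 0
    for b in spacer:
        run_len = run_len + 1 if b == run_base else 1
        run_base = b
        if run_len == 6:
            warns.append(f"homopolymer run >= 6 ({b * 6}...)")
            break
    return warns


def design_spacer(
    record: TranscriptRecord, target_a: int, params: DesignParams
) -> GuideDesign:
    """Build the antisense spacer for one target adenosine.

    Raises :class:`DesignError` if the target base is not A, the window does
    not fit the record, or the parameters violate their bounds.
    """
    params.validate()
    L, d = params.length, params.mismatch_distance
    base = record.base(target_a)
    if base != "A":
        raise DesignError(
            f"target position {target_a} of {record.id!r} is not an adenosine (found {base})"
        )
    w_start, w_end = target_a - d + 1, target_a + L - d
    if w_start < 1 or w_end > len(record):
        raise DesignError(
            f"window {w_start}..{w_end} (L={L}, d={d}) outside record "
            f"{record.id!r} (1..{len(record)})"
        )
    spacer = list(reverse_complement(record.slice(w_start, w_end)))
    # spacer index L-d (0-based from 5') sits opposite target_a
    spacer[L - d] = "C"

    modified = False
    if params.five_prime_policy == "substitute":
        if L - d == 0:
            raise DesignError(
                "mismatch C sits at the spacer 5' end (d == L); the substitute 5'-G policy "
                "would destroy the C:A mismatch -- use policy 'prepend'"
            )
        if spacer[0] != "G":
            spacer[0] = "G"
            modified = True
    elif params.five_prime_policy == "prepend":
        spacer.insert(0, "G")
        modified = True
    elif spacer[0] != "G":  # require
        raise DesignError(
            f"five_prime_policy='require': spacer 5' base is {spacer[0]}, not G"
        )

    spacer_str = "".join(spacer)
    return GuideDesign(
        record_id=record.id,
        target_a=target_a,
        params=params,
        window=(w_start, w_end),
        spacer=spacer_str,
        mismatch_pos_from_3prime=d,
        five_prime_base_modified=modified,
        warnings=tuple(_sequence_warnings(spacer_str)),
    )


@dataclass
class DesignBatch:
    """Result of a grid enumeration: successful designs plus per-entry failures."""

    designs: list[GuideDesign] = field(default_factory=list)
    failures: list[tuple[DesignParams, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.designs)

    def __iter__(self):
        return iter(self.designs)


def enumerate_designs(
    record: TranscriptRecord, target_a: int, param_grid: Sequence[DesignParams]
) -> DesignBatch:
    """Design one spacer per parameter set, in grid order.

    Individual failures are collected (with the offending parameters and the
    error text) without aborting the remaining entries.
    """
    if not param_grid:
        raise DesignError("empty parameter grid")
    batch = DesignBatch()
    for params in param_grid:
        try:
            batch.designs.append(design_spacer(record, target_a, params))
        except DesignError as exc:
            batch.failures.append((params, str(exc)))
    return batch


def emit_oligo_pair(
    design: GuideDesign,
    overhangs: tuple[str, str] = DEFAULT_OVERHANGS,
    enzyme: str = "BbsI",
) -> OligoPair:
    """Emit the annealing-ready top/bottom oligos for golden-gate cloning.

    top = top_overhang + spacer; bottom = bottom_overhang + revcomp(spacer).
    Stripping the overhangs and annealing reconstructs the spacer duplex.
    """
    top_oh, bottom_oh = overhangs
    for oh in (top_oh, bottom_oh):
        if oh:
            normalize_sequence(oh, context="overhang")
    name = (
        f"{design.record_id}_A{design.target_a}_"
        f"{design.params.length}-{design.params.mismatch_distance}"
    )
    return OligoPair(
        name=name,
        top_oligo=top_oh + design.spacer,
        bottom_oligo=bottom_oh + reverse_complement(design.spacer),
        top_overhang=top_oh,
        bottom_overhang=bottom_oh,
        enzyme=enzyme,
    )


def design_to_dict(design: GuideDesign) -> dict:
    """JSON-serialisable form of a design (inverse of :func:`design_from_dict`)."""
    return {
        "record_id": design.record_id,
        "target_a": design.target_a,
        "params": {
            "length": design.params.length,
            "mismatch_distance": design.params.mismatch_distance,
            "five_prime_policy": design.params.five_prime_policy,
            "min_length": design.params.min_length,
            "max_length": design.params.max_length,
        },
        "window": list(design.window),
        "spacer": design.spacer,
        "mismatch_pos_from_3prime": design.mismatch_pos_from_3prime,
        "five_prime_base_modified": design.five_prime_base_modified,
        "warnings": list(design.warnings),
    }


def design_from_dict(d: dict) -> GuideDesign:
    return GuideDesign(
        record_id=d["record_id"],
        target_a=int(d["target_a"]),
        params=DesignParams(**d["params"]),
        window=(int(d["window"][0]), int(d["window"][1])),
        spacer=d["spacer"],
        mismatch_pos_from_3prime=int(d["mismatch_pos_from_3prime"]),
        five_prime_base_modified=bool(d["five_prime_base_modified"]),
        warnings=tuple(d.get("warnings", ())),
    )


def validate_design(design: GuideDesign, record: TranscriptRecord | None = None) -> list[Issue]:
    """Machine-readable post-hoc checks on a design; an empty list means clean.

    Never raises: every problem is returned as an :class:`Issue`.
    """
    issues: list[Issue] = []
    p = design.params
    L = len(design.spacer)
    if L < p.min_length:
        issues.append(Issue("length_below_min", f"spacer length {L} below minimum {p.min_length}"))
    if L > p.max_length:
        issues.append(Issue("length_above_max", f"spacer length {L} above maximum {p.max_length}"))
    for site in BBSI_SITES:
        if site in design.spacer:
            issues.append(Issue("bbsi_site", f"internal BbsI site {site} in spacer"))
    d = design.mismatch_pos_from_3prime
    if not 1 <= d <= L:
        issues.append(Issue("mismatch_out_of_range", f"mismatch distance {d} outside spacer"))
    elif design.spacer[L - d] != "C":
        issues.append(
            Issue("mismatch_not_C", f"base at mismatch position is {design.spacer[L - d]}, not C")
        )
    if record is not None:
        try:
            base = record.base(design.target_a)
        except Exception:
            issues.append(Issue("target_out_of_range", f"target {design.target_a} outside record"))
        else:
            if base != "A":
                issues.append(
                    Issue("target_not_A", f"target base at {design.target_a} is {base}, not A")
                )
    for w in _sequence_warnings(design.spacer):
        if "homopolymer" in w:
            issues.append(Issue("homopolymer", w))
    return issues
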