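"""Synthetic ORF generation and reference design-parameter grids.

The two experimental systems this toolkit is aimed at -- an H2B-GFP reporter
carrying the W190X opal stop and a CFTR cDNA carrying W1282X (g.3846G>A) --
are defined entirely by a codon index and a stop codon identity: every
coordinate the designer and scanner compute (570, 3846, ...) follows from the
arithmetic ``3 x codon_index``, not from the particular sense codons around
it. Synthetic ORFs with the stop planted at the right codon therefore
reproduce all coordinate-level behaviour without bundling any real cDNA
(user-suppliable via FASTA when needed).

Generated ORFs start with ATG, end with a terminal TAA, contain no internal
stop other than the requested PTC, and are deterministic under their seed.
The neighbourhood of the PTC is resampled if it happens to create a BbsI
recognition site, so that designed spacers are clonable without warnings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from .design import BBSI_SITES, DesignParams
from .errors import CoordinateError
from .seq import TranscriptRecord

__all__ = [
    "FixtureSpec",
    "generate_orf",
    "preset_orf",
    "design_grids",
    "PRESETS",
]

_STOPS = ("TGA", "TAG", "TAA")
_SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic ORF with one optional premature stop codon."""

    n_codons: int
    ptc_codon_index: int | None = None
    ptc_codon: str = "TGA"
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 3:
            raise CoordinateError(f"n_codons must be >= 3, got {self.n_codons}")
        if self.ptc_codon_index is not None and not 1 < self.ptc_codon_index < self.n_codons:
            raise CoordinateError(
                f"ptc_codon_index must lie strictly inside the ORF "
                f"(2..{self.n_codons - 1}), got {self.ptc_codon_index}"
            )
        if self.ptc_codon not in _STOPS:
            raise CoordinateError(f"ptc_codon must be a stop codon, got {self.ptc_codon!r}")
        if not 0 <= self.gc_content <= 1:
            raise CoordinateError(f"gc_content must be in [0, 1], got {self.gc_content}")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_sense_codon(rng: np.random.Generator, probs: np.ndarray) -> str:
    bases = np.array(list("ACGT"))
    while True:
        codon = "".join(rng.choice(bases, size=3, p=probs))
        if codon not in _STOPS:
            return codon


def generate_orf(spec: FixtureSpec, record_id: str | None = None) -> TranscriptRecord:
    """Generate a synthetic ORF transcript for a fixture spec (orf_start = 1)."""
    rng = np.random.default_rng(spec.seed)
    probs = _base_probs(spec.gc_content)
    codons = [_random_sense_codon(rng, probs) for _ in range(spec.n_codons)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    fixed = {0, spec.n_codons - 1}
    if spec.ptc_codon_index is not None:
        codons[spec.ptc_codon_index - 1] = spec.ptc_codon
        fixed.add(spec.ptc_codon_index - 1)

    # resample codons that create BbsI sites (keeping fixed codons intact)
    for _ in range(1000):
        seq = "".join(codons)
        hit = min(
            (pos for site in BBSI_SITES if (pos := seq.find(site)) != -1),
            default=-1,
        )
        if hit == -1:
            break
        overlapping = [c for c in range(hit // 3, (hit + 5) // 3 + 1) if c < spec.n_codons]
        resampled = False
        for c in overlapping:
            if c not in fixed:
                codons[c] = _random_sense_codon(rng, probs)
                resampled = True
        if not resampled:  # site spans only fixed codons; cannot occur for stop triplets
            break
    if record_id is None:
        ptc = (
            f"_{spec.ptc_codon}@{spec.ptc_codon_index}"
            if spec.ptc_codon_index is not None
            else ""
        )
        record_id = f"synthetic_orf_{spec.n_codons}c{ptc}"
    return TranscriptRecord(id=record_id, sequence="".join(codons), orf_start=1)


# The two modeled systems: an H2B-GFP reporter with the W190X opal stop
# (editable A at transcript position 570) and a CFTR cDNA with W1282X
# (g.3846G>A). Sequences are synthetic stand-ins; only the codon geometry is
# meaningful.
PRESETS: dict[str, FixtureSpec] = {
    "h2bgfp-opal": FixtureSpec(n_codons=400, ptc_codon_index=190, ptc_codon="TGA", seed=1),
    "cftr-w1282x": FixtureSpec(n_codons=1500, ptc_codon_index=1282, ptc_codon="TGA", seed=1),
}


def preset_orf(name: str, seed: int | None = None) -> TranscriptRecord:
    """Generate one of the named preset fixtures (optionally reseeded)."""
    if name not in PRESETS:
        raise CoordinateError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return generate_orf(spec, record_id=name.replace("-", "_"))


def design_grids() -> dict[str, list[DesignParams]]:
    """The reference spacer-geometry grids for the two modeled campaigns.

    "GFP": three 50-nt spacers with the C:A mismatch 32, 34 or 35 nt from the
    3' end plus one 30-nt spacer with the mismatch at 25 nt; "CFTR": the three
    50-nt geometries only.
    """
    fifties = [DesignParams(50, d) for d in (32, 34, 35)]
    return {
        "GFP": fifties + [DesignParams(30, 25)],
        "CFTR": list(fifties),
    }
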