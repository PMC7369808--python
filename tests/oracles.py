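"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: pairing is verified
base-by-base with a literal complement table, and codon consequences by
re-translating whole sequences with Biopython.
"""

from Bio.Seq import Seq

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def antiparallel_mismatches(spacer: str, window_seq: str, window_start: int) -> list[int]:
    """Transcript coordinates where the spacer fails to pair with the window.

    The spacer is 5'->3'; its 3' end pairs with the lowest window coordinate,
    so spacer base i (0-based from 5') sits opposite window coordinate
    ``window_start + len(spacer) - 1 - i``. Spacers longer than the window
    (prepended 5' G) leave their extra 5' base unpaired.
    """
    mismatches = []
    w_len = len(window_seq)
    for i, s in enumerate(spacer):
        offset = len(spacer) - 1 - i  # 0 at the spacer 3' end
        if offset >= w_len:
            continue  # overhanging 5' base, unpaired
        target = window_seq[offset]
        if s != _COMPLEMENT[target]:
            mismatches.append(window_start + offset)
    return mismatches


def translate_from(seq: str, orf_start: int) -> str:
    """Full in-frame translation (stops as '*') using Biopython directly."""
    coding = seq[orf_start - 1 :]
    coding = coding[: 3 * (len(coding) // 3)]
    return str(Seq(coding).translate())
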