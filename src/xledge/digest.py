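"""In-silico tryptic digestion and crosslinkable-peptide enumeration.

Trypsin cleaves C-terminal to Lys/Arg except when the next residue is
proline (the Keil rule). Only fully tryptic products are produced, with
0..max_missed retained internal cleavage sites. A peptide is
"crosslinkable" when it contains at least one internal lysine — a lysine
that is not the C-terminal residue, i.e. a missed cleavage site where the
crosslinker stump blocked trypsin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "DigestPeptide",
    "tryptic_digest",
    "enumerate_crosslinkable",
    "has_internal_lysine",
]

_CLEAVAGE = re.compile(r"(?<=[KR])(?!P)")


@dataclass(frozen=True)
class DigestPeptide:
    """A fully tryptic peptide with 1-based inclusive protein coordinates."""

    sequence: str
    protein_id: str
    start_pos: int
    end_pos: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end_pos - self.start_pos + 1 != len(self.sequence):
            raise ValueError("start/end positions inconsistent with sequence length")


def tryptic_digest(protein_seq: str, max_missed: int, protein_id: str = "") -> list[DigestPeptide]:
    """All fully tryptic peptides with up to ``max_missed`` missed cleavages.

    Returns peptides ordered by start position then length; an empty
    sequence yields an empty list.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not protein_seq:
        return []
    # 0-based boundaries of the zero-missed-cleavage products
    cuts = [0] + [m.start() for m in _CLEAVAGE.finditer(protein_seq)]
    if cuts[-1] != len(protein_seq):
        cuts.append(len(protein_seq))
    peptides: list[DigestPeptide] = []
    nseg = len(cuts) - 1
    for i in range(nseg):
        for j in range(i, min(i + max_missed + 1, nseg)):
            start, end = cuts[i], cuts[j + 1]
            peptides.append(
                DigestPeptide(
                    sequence=protein_seq[start:end],
                    protein_id=protein_id,
                    start_pos=start + 1,
                    end_pos=end,
                    missed_cleavages=j - i,
                )
            )
    return peptides


def has_internal_lysine(sequence: str) -> bool:
    """True when the peptide has a Lys anywhere but its C terminus."""
    return "K" in sequence[:-1]


def enumerate_crosslinkable(peptides: list[DigestPeptide]) -> list[DigestPeptide]:
    """Retain peptides that can carry a crosslinker stump (internal Lys)."""
    return [p for p in peptides if has_internal_lysine(p.sequence)]
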