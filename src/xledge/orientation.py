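"""Dimer orientation classification for elongated (rod-domain) proteins.

Intermediate-filament proteins pair through a central alpha-helical rod;
in a parallel dimer equivalent rod positions lie side by side, in an
antiparallel tetramer they are inverted. A crosslink between two rod
sites is therefore parallel-consistent when the fractional rod positions
agree within a tolerance delta, and antiparallel-consistent when one
agrees with the reverse of the other. Sites satisfying both (near rod
midpoints) or neither are ambiguous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Orientation", "RodAlignment", "classify_orientation"]


class Orientation(str, enum.Enum):
    PARALLEL = "parallel"
    ANTIPARALLEL = "antiparallel"
    AMBIGUOUS = "ambiguous"
    OUTSIDE_ROD = "outside_rod"


@dataclass(frozen=True)
class RodAlignment:
    """Rod-domain spans (1-based inclusive) of two partner proteins."""

    protein_a: str
    protein_b: str
    rod_a: tuple[int, int]
    rod_b: tuple[int, int]
    tolerance: float = 0.15

    def __post_init__(self) -> None:
        for start, end in (self.rod_a, self.rod_b):
            if start >= end:
                raise ValueError(f"degenerate rod span ({start}, {end})")
        if not 0 < self.tolerance < 0.5:
            raise ValueError("tolerance must be in (0, 0.5)")


def _fractional_position(site: int, rod: tuple[int, int]) -> float | None:
    start, end = rod
    if site < start or site > end:
        return None
    return (site - start) / (end - start)


def classify_orientation(site_a: int, site_b: int, aln: RodAlignment) -> Orientation:
    """Classify one crosslink as parallel / antiparallel / ambiguous.

    Fractional positions pA, pB of the sites within their rods are
    compared: parallel-consistent iff |pA - pB| <= delta,
    antiparallel-consistent iff |pA - (1 - pB)| <= delta; both or
    neither -> ambiguous. A site outside its rod span -> outside_rod.
    """
    pa = _fractional_position(site_a, aln.rod_a)
    pb = _fractional_position(site_b, aln.rod_b)
    if pa is None or pb is None:
        return Orientation.OUTSIDE_ROD
    parallel = abs(pa - pb) <= aln.tolerance
    antiparallel = abs(pa - (1.0 - pb)) <= aln.tolerance
    if parallel and not antiparallel:
        return Orientation.PARALLEL
    if antiparallel and not parallel:
        return Orientation.ANTIPARALLEL
    return Orientation.AMBIGUOUS
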