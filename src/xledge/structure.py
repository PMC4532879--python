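"""Mapping crosslinked lysine pairs onto atomic structures.

Crosslink sites are located on a structure chain by exact substring
matching of the tryptic peptide into the chain's one-letter sequence
(or via a user-supplied residue offset table) and validated by the
Euclidean distance between the two lysine alpha carbons. For NMR
ensembles model 1 is used; altloc 'A' is preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "StructureMapping",
    "chain_sequence",
    "map_site",
    "ca_distance",
    "distance_report",
    "DistanceReport",
]

MIN_PEPTIDE_LENGTH = 6


@dataclass(frozen=True)
class StructureMapping:
    """A crosslink placed on a structure with its Calpha-Calpha distance."""

    pair_key: str
    structure_id: str
    chain_a: str
    chain_b: str
    residue_a: int
    residue_b: int
    ca_distance: float
    mapping_method: str = "exact-substring"

    def __post_init__(self) -> None:
        if self.ca_distance < 0:
            raise ValueError("ca_distance must be >= 0")


def chain_sequence(chain: gemmi.Chain) -> tuple[str, list[int]]:
    """One-letter sequence of a polymer chain plus author residue numbers."""
    letters: list[str] = []
    numbers: list[int] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        letters.append(info.one_letter_code.upper())
        numbers.append(res.seqid.num)
    return "".join(letters), numbers


def map_site(
    peptide_seq: str,
    site_in_peptide: int,
    chain: gemmi.Chain,
    offset: int | None = None,
) -> tuple[int, str] | None:
    """Translate a crosslink site to the chain's author numbering.

    With ``offset`` given, the site's protein coordinate is shifted
    directly (offset-table method). Otherwise the peptide must occur
    exactly once as a substring of the chain sequence and be at least 6
    residues long; ambiguous or absent peptides return None.
    Returns (author residue number, method) or None.
    """
    seq, numbers = chain_sequence(chain)
    if offset is not None:
        target = site_in_peptide + offset
        return (target, "offset-table") if target in numbers else None
    if len(peptide_seq) < MIN_PEPTIDE_LENGTH:
        return None
    first = seq.find(peptide_seq)
    if first < 0 or seq.find(peptide_seq, first + 1) >= 0:
        return None
    return numbers[first + site_in_peptide - 1], "exact-substring"


def _find_ca(structure: gemmi.Structure, chain_name: str, res_num: int) -> gemmi.Atom | None:
    if len(structure) == 0:
        return None
    model = structure[0]  # model 1 for NMR ensembles
    chain = model.find_chain(chain_name)
    if chain is None:
        return None
    for res in chain:
        if res.seqid.num == res_num:
            best = None
            for atom in res:
                # gemmi encodes "no altloc" as '\0'
                if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                    if best is None or atom.altloc != "A":
                        best = atom
            return best
    return None


def ca_distance(
    structure: gemmi.Structure,
    chain_a: str,
    res_a: int,
    chain_b: str,
    res_b: int,
) -> float:
    """Euclidean Calpha-Calpha distance in angstroms (symmetric)."""
    atoms = []
    for chain_name, res_num in ((chain_a, res_a), (chain_b, res_b)):
        atom = _find_ca(structure, chain_name, res_num)
        if atom is None:
            raise ValueError(f"no CA atom for chain {chain_name!r} residue {res_num}")
        atoms.append(atom)
    return atoms[0].pos.dist(atoms[1].pos)


@dataclass(frozen=True)
class DistanceReport:
    n_mapped: int
    n_unmapped: int
    median: float
    histogram_counts: tuple[int, ...]
    histogram_edges: tuple[float, ...]


def distance_report(
    mappings: list[StructureMapping | None], bin_width: float = 5.0
) -> DistanceReport:
    """Summary statistics over mapped crosslinks; None entries count as unmapped."""
    dists = [m.ca_distance for m in mappings if m is not None]
    n_unmapped = sum(1 for m in mappings if m is None)
    if not dists:
        return DistanceReport(0, n_unmapped, math.nan, (), ())
    top = max(dists)
    edges = np.arange(0.0, (math.floor(top / bin_width) + 2) * bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    return DistanceReport(
        n_mapped=len(dists),
        n_unmapped=n_unmapped,
        median=float(np.median(dists)),
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges=tuple(float(e) for e in edges),
    )
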