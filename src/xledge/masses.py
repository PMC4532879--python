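"""Peptide mass chemistry and the PIR mass-relationship solver.

A protein interaction reporter (PIR) crosslinker cleaves in MS2 into a
reporter ion plus the two released peptides, each still carrying a stump
modification on its crosslinked lysine. For a genuine crosslinked species
the three neutral masses sum to the precursor neutral mass:

    M_precursor = M_reporter + M_peptide1 + M_peptide2

``check_pir_relationship`` solves this relation over an observed fragment
list within a ppm tolerance, optionally allowing 13C isotopologue offsets
of the precursor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .constants import (
    C13_SPACING,
    HEAVY_ARG_SHIFT,
    HEAVY_LYS_SHIFT,
    PROTON_MASS,
    RESIDUE_MASSES,
    STANDARD_MOD_TABLE,
    WATER_MASS,
)

__all__ = [
    "ModificationSpec",
    "PeptideSpecies",
    "PrecursorIon",
    "PirMatch",
    "standard_mod",
    "peptide_mass",
    "silac_shift",
    "mz_from_mass",
    "mass_from_mz",
    "check_pir_relationship",
]


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass modification with its target residues.

    ``targets`` is a comma-separated list of one-letter residue codes;
    the token ``nterm`` marks the protein N terminus.
    """

    name: str
    delta_mass: float
    targets: str
    static_flag: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise ValueError(f"delta_mass must be finite, got {self.delta_mass}")
        if not self.targets:
            raise ValueError("targets must be non-empty")


def standard_mod(name: str) -> ModificationSpec:
    """Look up a modification from the standard table by name."""
    delta, targets, static = STANDARD_MOD_TABLE[name]
    return ModificationSpec(name, delta, targets, static)


@dataclass(frozen=True)
class PeptideSpecies:
    """A modified, isotope-labelled peptide with protein provenance.

    Positions are 1-based: ``start_pos`` within the protein,
    ``crosslink_site`` and modification positions within the peptide.
    The crosslink site, when set, must be a lysine.
    """

    sequence: str
    mods: tuple[tuple[int, ModificationSpec], ...] = ()
    label_state: str = "light"
    protein_ids: tuple[str, ...] = ()
    start_pos: int = 1
    crosslink_site: int | None = None

    def __post_init__(self) -> None:
        if self.label_state not in ("light", "heavy"):
            raise ValueError(f"label_state must be light|heavy, got {self.label_state!r}")
        if self.start_pos < 1:
            raise ValueError("start_pos must be >= 1")
        n = len(self.sequence)
        for pos, mod in self.mods:
            if not 1 <= pos <= n:
                raise ValueError(f"modification position {pos} outside peptide of length {n}")
        if self.crosslink_site is not None:
            if not 1 <= self.crosslink_site <= n:
                raise ValueError(f"crosslink_site {self.crosslink_site} outside peptide")
            if self.sequence[self.crosslink_site - 1] != "K":
                raise ValueError(
                    f"crosslink_site residue is {self.sequence[self.crosslink_site - 1]!r}, must be K"
                )

    @property
    def end_pos(self) -> int:
        return self.start_pos + len(self.sequence) - 1

    def with_label(self, label_state: str) -> "PeptideSpecies":
        return replace(self, label_state=label_state)

    def site_in_protein(self) -> int | None:
        """Crosslink site translated to 1-based protein coordinates."""
        if self.crosslink_site is None:
            return None
        return self.start_pos + self.crosslink_site - 1


@dataclass(frozen=True)
class PrecursorIon:
    """An observed precursor with m/z, charge and retention time (s)."""

    mz: float
    charge: int
    retention_time: float = 0.0

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")

    @property
    def neutral_mass(self) -> float:
        return self.charge * (self.mz - PROTON_MASS)


@dataclass(frozen=True)
class PirMatch:
    """A fragment pair satisfying the PIR mass relationship."""

    precursor: PrecursorIon
    reporter_mass: float
    pep1_mass: float
    pep2_mass: float
    ppm_error: float
    c13_offset: int = 0
    spectrum_id: str | None = field(default=None, compare=False)


def peptide_mass(p: PeptideSpecies) -> float:
    """Monoisotopic neutral mass of a peptide species.

    Sum of residue masses plus water plus modification deltas, plus the
    SILAC label shifts on every K and R when the species is heavy.
    Raises ``ValueError`` naming the offending residue and position for
    non-standard letters.
    """
    total = WATER_MASS
    for i, aa in enumerate(p.sequence, start=1):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i}") from None
    total += sum(mod.delta_mass for _, mod in p.mods)
    if p.label_state == "heavy":
        total += silac_shift(p)
    return total


def silac_shift(p: PeptideSpecies | str) -> float:
    """Heavy-minus-light mass shift: 8.014199 per Lys + 6.020129 per Arg."""
    seq = p if isinstance(p, str) else p.sequence
    return seq.count("K") * HEAVY_LYS_SHIFT + seq.count("R") * HEAVY_ARG_SHIFT


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return charge * (mz - PROTON_MASS)


def check_pir_relationship(
    precursor: PrecursorIon,
    fragment_masses: list[float],
    reporter_mass: float,
    tol_ppm: float = 20.0,
    max_c13: int = 0,
    allow_self_pair: bool = False,
    mass_offset: float = 0.0,
    spectrum_id: str | None = None,
) -> list[PirMatch]:
    """Find fragment pairs satisfying the PIR mass relationship.

    Every unordered pair (f_i, f_j) of neutral fragment masses is tested
    against

        |reporter + f_i + f_j + mass_offset + k*1.00335 - M| / M * 1e6 <= tol_ppm

    for each 13C offset k in 0..max_c13, where M is the precursor neutral
    mass. ppm error is signed (observed sum relative to precursor) and
    results are sorted by absolute ppm error. A fragment pairs with itself
    only when ``allow_self_pair`` is set (homodimeric species whose two
    released peptides coincide in mass).
    """
    if reporter_mass <= 0:
        raise ValueError("reporter_mass must be positive")
    target = precursor.neutral_mass
    matches: list[PirMatch] = []
    n = len(fragment_masses)
    for i in range(n):
        j0 = i if allow_self_pair else i + 1
        for j in range(j0, n):
            total = reporter_mass + fragment_masses[i] + fragment_masses[j] + mass_offset
            for k in range(max_c13 + 1):
                ppm = (total + k * C13_SPACING - target) / target * 1e6
                if abs(ppm) <= tol_ppm:
                    matches.append(
                        PirMatch(
                            precursor=precursor,
                            reporter_mass=reporter_mass,
                            pep1_mass=fragment_masses[i],
                            pep2_mass=fragment_masses[j],
                            ppm_error=ppm,
                            c13_offset=k,
                            spectrum_id=spectrum_id,
                        )
                    )
    matches.sort(key=lambda m: abs(m.ppm_error))
    return matches
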