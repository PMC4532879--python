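"""Monoisotopic mass constants and the standard modification table.

All masses are monoisotopic and in daltons. Residue masses come from
pyteomics; the physical constants (proton, water, the 13C-12C spacing)
are fixed here so that every module shares one set of values.
"""

from __future__ import annotations

from pyteomics import mass as _pt_mass

#: Mass of a proton (charge carrier), Da.
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of water (peptide condensation terminus), Da.
WATER_MASS = 18.0105646863

#: Spacing between a 13C and a 12C isotopologue peak, Da.
C13_SPACING = 1.00335

#: SILAC heavy-label shifts: Lys-13C6-15N2 and Arg-13C6, Da.
HEAVY_LYS_SHIFT = 8.014199
HEAVY_ARG_SHIFT = 6.020129

#: Residual "stump" mass the cleaved PIR crosslinker leaves on the
#: crosslinked lysine (and protein N termini), Da.
STUMP_MASS = 197.0324

#: Monoisotopic residue (not free amino acid) masses for the 20 standard
#: residues, keyed by one-letter code.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Modification deltas used throughout: name -> (delta Da, target residues,
#: static flag). Targets use one-letter residue codes; "nterm" marks the
#: protein N terminus as an additional target.
STANDARD_MOD_TABLE: dict[str, tuple[float, str, bool]] = {
    "stump": (STUMP_MASS, "K,nterm", False),
    "carbamidomethyl": (57.021464, "C", True),
    "oxidation": (15.9949, "M", False),
    "methyl": (14.015650, "K,R", False),
    "dimethyl": (28.031300, "K", False),
    "dimethyl_r": (28.031300, "R", False),
    "acetyl": (42.010556, "K", False),
    "trimethyl": (42.046950, "K", False),
}
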