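"""Crosslinked peptide pair assembly and target/decoy FDR.

PSMs (peptide-spectrum matches from any search engine) are filtered to a
peptide-level FDR by score thresholding against reversed-sequence decoys,
then mapped onto PIR mass relationships by matching released-peptide
masses. A reported pair requires both peptides to carry the crosslinker
stump on an internal lysine. Pair-level FDR is the fraction of reported
pairs containing at least one decoy peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import PROTON_MASS, WATER_MASS, RESIDUE_MASSES, HEAVY_LYS_SHIFT, HEAVY_ARG_SHIFT
from .masses import PeptideSpecies, PirMatch, peptide_mass

__all__ = [
    "PsmRecord",
    "CrosslinkPairId",
    "AssemblyResult",
    "build_decoy_db",
    "filter_psms_fdr",
    "assemble_pairs",
    "pair_fdr",
    "naive_fragment_score",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class PsmRecord:
    spectrum_id: str
    peptide: PeptideSpecies
    score: float
    is_decoy: bool = False


@dataclass(frozen=True)
class CrosslinkPairId:
    """An identified crosslinked peptide pair for one spectrum."""

    spectrum_id: str
    pep_a: PeptideSpecies
    pep_b: PeptideSpecies
    pir_match: PirMatch
    n_decoy_peptides: int

    def __post_init__(self) -> None:
        if self.n_decoy_peptides not in (0, 1, 2):
            raise ValueError("n_decoy_peptides must be 0, 1 or 2")


@dataclass
class AssemblyResult:
    """Primary pair list plus ambiguous spectra reported separately."""

    pairs: list[CrosslinkPairId]
    ambiguous: list[str]


def build_decoy_db(records: list[tuple[str, str]], decoy_prefix: str = DECOY_PREFIX) -> list[tuple[str, str]]:
    """Concatenated target+decoy database: each protein plus its reverse.

    Output size is exactly twice the input. Duplicate accessions are
    rejected.
    """
    seen: set[str] = set()
    for acc, _ in records:
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r}")
        seen.add(acc)
    return list(records) + [(decoy_prefix + acc, seq[::-1]) for acc, seq in records]


def filter_psms_fdr(psms: list[PsmRecord], psm_fdr: float = 0.05) -> list[PsmRecord]:
    """Score-threshold target/decoy filtering.

    PSMs are sorted by descending score; the accepted set is the largest
    score-ordered prefix whose decoy/target ratio is <= ``psm_fdr``.
    """
    if not 0 <= psm_fdr < 1:
        raise ValueError("psm_fdr must be in [0, 1)")
    ordered = sorted(psms, key=lambda p: p.score, reverse=True)
    best = -1
    n_decoy = n_target = 0
    for i, p in enumerate(ordered):
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        if n_target > 0 and n_decoy / n_target <= psm_fdr:
            best = i
    return ordered[: best + 1]


def _stump_site_ok(p: PeptideSpecies) -> bool:
    """Peptide carries a stump mod on an internal (non C-terminal) Lys."""
    for pos, mod in p.mods:
        if mod.name == "stump" and pos < len(p.sequence) and p.sequence[pos - 1] == "K":
            return True
    return False


def _peptide_key(p: PeptideSpecies) -> tuple:
    return (p.sequence, tuple((pos, m.name) for pos, m in p.mods), p.crosslink_site)


def assemble_pairs(
    psms: list[PsmRecord],
    pir_matches: list[PirMatch],
    psm_fdr: float = 0.05,
    mass_tol_ppm: float = 10.0,
) -> AssemblyResult:
    """Map FDR-filtered PSMs onto PIR relationships to form pairs.

    For each PIR match, the released-peptide masses pep1/pep2 are matched
    against the masses of surviving stump-bearing PSMs from the same
    spectrum within ``mass_tol_ppm``. A pair is emitted only when each
    slot resolves to exactly one distinct peptide; spectra with multiple
    or no consistent assignments are flagged ambiguous and excluded from
    the primary list.
    """
    survivors = filter_psms_fdr(psms, psm_fdr)
    by_spectrum: dict[str, list[PsmRecord]] = {}
    for p in survivors:
        if _stump_site_ok(p.peptide):
            by_spectrum.setdefault(p.spectrum_id, []).append(p)

    pairs: list[CrosslinkPairId] = []
    ambiguous: list[str] = []
    for match in pir_matches:
        sid = match.spectrum_id
        cands = by_spectrum.get(sid, []) if sid is not None else []
        if not cands:
            continue

        def slot(target_mass: float) -> list[PsmRecord]:
            found: dict[tuple, PsmRecord] = {}
            for psm in cands:
                m = peptide_mass(psm.peptide)
                if abs(m - target_mass) / target_mass * 1e6 <= mass_tol_ppm:
                    found.setdefault(_peptide_key(psm.peptide), psm)
            return list(found.values())

        c1, c2 = slot(match.pep1_mass), slot(match.pep2_mass)
        if len(c1) == 1 and len(c2) == 1:
            a, b = c1[0], c2[0]
            if _peptide_key(a.peptide) == _peptide_key(b.peptide) and abs(
                match.pep1_mass - match.pep2_mass
            ) / match.pep1_mass * 1e6 > mass_tol_ppm:
                # one peptide cannot fill two slots of different mass
                ambiguous.append(sid)
                continue
            pa, pb = sorted((a, b), key=lambda p: _peptide_key(p.peptide))
            pairs.append(
                CrosslinkPairId(
                    spectrum_id=sid,
                    pep_a=pa.peptide,
                    pep_b=pb.peptide,
                    pir_match=match,
                    n_decoy_peptides=int(a.is_decoy) + int(b.is_decoy),
                )
            )
        else:
            ambiguous.append(sid)
    return AssemblyResult(pairs=pairs, ambiguous=ambiguous)


def pair_fdr(pairs: list[CrosslinkPairId]) -> float:
    """Fraction of pairs with >= 1 decoy peptide (crosslink-level FDR)."""
    if not pairs:
        raise ValueError("pair_fdr undefined for an empty pair list")
    return sum(1 for p in pairs if p.n_decoy_peptides >= 1) / len(pairs)


def _residue_mass_array(p: PeptideSpecies) -> list[float]:
    masses = [RESIDUE_MASSES[aa] for aa in p.sequence]
    for pos, mod in p.mods:
        masses[pos - 1] += mod.delta_mass
    if p.label_state == "heavy":
        for i, aa in enumerate(p.sequence):
            if aa == "K":
                masses[i] += HEAVY_LYS_SHIFT
            elif aa == "R":
                masses[i] += HEAVY_ARG_SHIFT
    return masses


def theoretical_by_ions(p: PeptideSpecies) -> list[float]:
    """Singly charged b- and y-ion m/z values (b1..b(n-1), y1..y(n-1))."""
    masses = _residue_mass_array(p)
    n = len(masses)
    ions: list[float] = []
    acc = 0.0
    for i in range(n - 1):
        acc += masses[i]
        ions.append(acc + PROTON_MASS)  # b ion
    acc = 0.0
    for i in range(n - 1, 0, -1):
        acc += masses[i]
        ions.append(acc + WATER_MASS + PROTON_MASS)  # y ion
    return ions


def naive_fragment_score(spectrum_peaks: list[float], peptide: PeptideSpecies, frag_tol: float) -> float:
    """Fraction of theoretical singly charged b/y ions present in the spectrum.

    Deterministic test plumbing for synthetic spectra only; not a
    replacement for a real search-engine score.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    ions = theoretical_by_ions(peptide)
    if not ions:
        return 0.0
    hit = sum(1 for ion in ions if any(abs(ion - mz) <= frag_tol for mz in spectrum_peaks))
    return hit / len(ions)
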