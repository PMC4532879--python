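"""Seeded synthetic-data generator for the whole pipeline.

Emulates, at desk scale, the structure of a quantitative in vivo
crosslinking experiment: a small random proteome; planted intra/inter/
homodimer crosslinks (default 75% intra, mirroring the observed
partition); five SILAC replicates including a label swap (replicates
1-3 forward = resistant heavy, 4-5 reverse); MS1 light/heavy isotope-pair
chromatograms whose areas encode per-replicate log2(R/S) ratios; and MS2
fragment events containing reporter + released-peptide masses plus noise
fragments. Null pairs draw their true log2 ratio from Normal(0, 1.25)
(the observed across-pair spread); per-replicate measurement noise is a
separate parameter. Everything is deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import enumerate_crosslinkable, tryptic_digest
from .masses import PeptideSpecies, PrecursorIon, mz_from_mass, peptide_mass, silac_shift, standard_mod
from .network import CrosslinkRecord, LinkClass

__all__ = ["SimConfig", "PlantedPair", "GroundTruth", "Ms2Event", "SimData",
           "generate_proteome", "plant_crosslinks", "render_ms_data", "proteome_to_fasta"]

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K and R sampled separately


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_proteins: int = 20
    protein_length_mean: int = 240
    protein_length_sd: int = 40
    n_crosslinks: int = 40
    intra_fraction: float = 0.75
    homodimer_fraction: float = 0.06
    n_decoy_pairs: int = 0
    n_replicates: int = 5
    n_forward: int = 3
    null_sd: float = 1.25
    replicate_sd: float = 1.25 / math.sqrt(5)
    planted_effects: tuple[tuple[int, float], ...] = ()
    reporter_mass: float = 752.41312
    precursor_charge: int = 4
    mass_noise_ppm: float = 0.0
    base_intensity: float = 1e6
    intensity_sigma: float = 0.3
    n_noise_fragments: int = 3
    n_noise_peaks: int = 50
    n_decoy_psms: int = 10
    k_freq: float = 0.09
    r_freq: float = 0.05

    def __post_init__(self) -> None:
        for name in ("intra_fraction", "homodimer_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.intra_fraction + self.homodimer_fraction > 1:
            raise ValueError("intra_fraction + homodimer_fraction must be <= 1")
        if not 0 <= self.n_forward <= self.n_replicates:
            raise ValueError("n_forward must be within n_replicates")


@dataclass(frozen=True)
class PlantedPair:
    index: int
    pep_a: PeptideSpecies
    pep_b: PeptideSpecies
    link_class: LinkClass
    true_log2: float
    is_decoy: bool = False

    def record(self, spectrum_id: str = "", ppm_error: float = 0.0) -> CrosslinkRecord:
        a, b = self.pep_a, self.pep_b
        return CrosslinkRecord(
            spectrum_id=spectrum_id,
            pep_a=a.sequence, site_a=a.crosslink_site, protein_a=a.protein_ids[0], start_a=a.start_pos,
            pep_b=b.sequence, site_b=b.crosslink_site, protein_b=b.protein_ids[0], start_b=b.start_pos,
            mods_a=_mods_str(a), mods_b=_mods_str(b),
            n_decoy=int(self.is_decoy), ppm_error=ppm_error,
        )

    @property
    def pair_key(self) -> str:
        return self.record().pair_key


def _mods_str(p: PeptideSpecies) -> str:
    return ";".join(f"{pos}:{mod.name}" for pos, mod in p.mods)


@dataclass
class GroundTruth:
    proteome: list[tuple[str, str]]
    pairs: list[PlantedPair]
    cfg: SimConfig

    def records(self) -> list[CrosslinkRecord]:
        return [p.record(spectrum_id=f"scan{p.index:05d}") for p in self.pairs]

    def true_effects(self) -> dict[str, float]:
        return {p.pair_key: p.true_log2 for p in self.pairs}

    def classes(self) -> dict[str, LinkClass]:
        return {p.pair_key: p.link_class for p in self.pairs}


@dataclass(frozen=True)
class Ms2Event:
    spectrum_id: str
    precursor: PrecursorIon
    fragment_masses: tuple[float, ...]


@dataclass
class SimData:
    ms1: dict[str, pd.DataFrame]           # replicate_id -> (rt, mz, intensity)
    ms2_events: list[Ms2Event]
    psms: list  # list[identify.PsmRecord]; imported lazily to avoid a cycle
    orientations: dict[str, str]
    truth: GroundTruth = field(repr=False, default=None)


def generate_proteome(cfg: SimConfig) -> list[tuple[str, str]]:
    """Random proteome with boosted K/R frequency for tryptic peptides."""
    rng = np.random.default_rng(cfg.seed)
    other = np.array(list(AMINO_ACIDS))
    p_other = (1.0 - cfg.k_freq - cfg.r_freq) / len(other)
    letters = np.concatenate([other, np.array(["K", "R"])])
    probs = np.concatenate([np.full(len(other), p_other), [cfg.k_freq, cfg.r_freq]])
    records = []
    for i in range(cfg.n_proteins):
        length = max(50, int(round(rng.normal(cfg.protein_length_mean, cfg.protein_length_sd))))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append((f"SYN{i:04d}", seq))
    return records


def proteome_to_fasta(proteome: list[tuple[str, str]]) -> str:
    return "".join(f">{acc}\n{seq}\n" for acc, seq in proteome)


def _make_species(pep, site: int, decoy: bool = False) -> PeptideSpecies:
    return PeptideSpecies(
        sequence=pep.sequence,
        mods=((site, standard_mod("stump")),),
        label_state="light",
        protein_ids=(pep.protein_id,),
        start_pos=pep.start_pos,
        crosslink_site=site,
    )


def _crosslinkable_peptides(acc: str, seq: str, rng: np.random.Generator, max_missed: int = 3):
    peps = enumerate_crosslinkable(tryptic_digest(seq, max_missed, protein_id=acc))
    return [p for p in peps if 6 <= len(p.sequence) <= 30]


def _pick_site(pep, rng: np.random.Generator) -> int:
    internal_ks = [i + 1 for i, aa in enumerate(pep.sequence[:-1]) if aa == "K"]
    return int(rng.choice(internal_ks))


def plant_crosslinks(proteome: list[tuple[str, str]], cfg: SimConfig) -> GroundTruth:
    """Select site pairs realizing the configured class fractions.

    True log2(R/S) effects: pairs named in ``planted_effects`` get their
    stated effect; all others draw from Normal(0, null_sd). Raises when
    the proteome lacks enough crosslinkable peptides.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    pools = {acc: _crosslinkable_peptides(acc, seq, rng) for acc, seq in proteome}
    usable = {acc: peps for acc, peps in pools.items() if peps}
    total_peps = sum(len(v) for v in usable.values())
    if total_peps < 2 * cfg.n_crosslinks:
        raise ValueError(
            f"insufficient crosslinkable peptides: {total_peps} for {cfg.n_crosslinks} crosslinks"
        )
    seqs = dict(proteome)
    n_homo = int(round(cfg.n_crosslinks * cfg.homodimer_fraction))
    n_intra = int(round(cfg.n_crosslinks * cfg.intra_fraction))
    n_inter = cfg.n_crosslinks - n_intra - n_homo
    if n_inter < 0:  # integer rounding overshoot
        n_intra += n_inter
        n_inter = 0

    effects = dict(cfg.planted_effects)
    accs = sorted(usable)
    pairs: list[PlantedPair] = []
    used_keys: set[str] = set()

    def true_effect(idx: int) -> float:
        return effects.get(idx, float(rng.normal(0.0, cfg.null_sd)))

    def add(pep_a, site_a, pep_b, site_b, link_class, decoy=False):
        idx = len(pairs)
        pp = PlantedPair(
            index=idx,
            pep_a=_make_species(pep_a, site_a),
            pep_b=_make_species(pep_b, site_b),
            link_class=link_class,
            true_log2=true_effect(idx),
            is_decoy=decoy,
        )
        if pp.pair_key in used_keys:
            return False
        used_keys.add(pp.pair_key)
        pairs.append(pp)
        return True

    def attempt(kind: str) -> bool:
        if kind == "homodimer":
            acc = accs[rng.integers(len(accs))]
            pep = usable[acc][rng.integers(len(usable[acc]))]
            if seqs[acc].count(pep.sequence) != 1:
                return False
            site = _pick_site(pep, rng)
            return add(pep, site, pep, site, LinkClass.HOMODIMER_UNAMBIGUOUS)
        if kind == "intra":
            acc = accs[rng.integers(len(accs))]
            peps = usable[acc]
            if len(peps) < 2:
                return False
            ia, ib = rng.choice(len(peps), size=2, replace=False)
            pa, pb = peps[ia], peps[ib]
            if pa.start_pos <= pb.end_pos and pb.start_pos <= pa.end_pos:
                return False  # overlapping would not classify intra
            return add(pa, _pick_site(pa, rng), pb, _pick_site(pb, rng), LinkClass.INTRA)
        # inter
        if len(accs) < 2:
            return False
        ia, ib = rng.choice(len(accs), size=2, replace=False)
        pa = usable[accs[ia]][rng.integers(len(usable[accs[ia]]))]
        pb = usable[accs[ib]][rng.integers(len(usable[accs[ib]]))]
        return add(pa, _pick_site(pa, rng), pb, _pick_site(pb, rng), LinkClass.INTER)

    for kind, n in (("intra", n_intra), ("inter", n_inter), ("homodimer", n_homo)):
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise ValueError(f"could not place {n} {kind} crosslinks")
            if attempt(kind):
                placed += 1

    # decoy pairs: one peptide from a reversed protein, emulating FDR leakage
    for d in range(cfg.n_decoy_pairs):
        acc = accs[int(rng.integers(len(accs)))]
        rev_acc, rev_seq = "rev_" + acc, seqs[acc][::-1]
        rev_peps = _crosslinkable_peptides(rev_acc, rev_seq, rng)
        if not rev_peps:
            continue
        pd_ = rev_peps[int(rng.integers(len(rev_peps)))]
        acc2 = accs[int(rng.integers(len(accs)))]
        pt = usable[acc2][int(rng.integers(len(usable[acc2])))]
        add(pt, _pick_site(pt, rng), pd_, _pick_site(pd_, rng), LinkClass.INTER, decoy=True)

    return GroundTruth(proteome=proteome, pairs=pairs, cfg=cfg)


def _pair_masses(pp: PlantedPair, reporter_mass: float) -> tuple[float, float, float, float]:
    """(mass_a, mass_b, light precursor mass, heavy precursor mass)."""
    ma = peptide_mass(pp.pep_a)
    mb = peptide_mass(pp.pep_b)
    light = reporter_mass + ma + mb
    heavy = light + silac_shift(pp.pep_a) + silac_shift(pp.pep_b)
    return ma, mb, light, heavy


def render_ms_data(truth: GroundTruth, cfg: SimConfig | None = None) -> SimData:
    """Render MS1 peak streams per replicate plus MS2 fragment events.

    MS1: each species appears as a short triangular elution profile; the
    heavy/light area ratio encodes the replicate's observed log2(R/S)
    under its label orientation. MS2: one event per pair whose fragment
    list holds the two released-peptide masses (one entry for homodimers,
    whose peptides coincide in mass) plus random noise fragments.
    """
    from .identify import PsmRecord  # local import: identify depends on masses only

    cfg = cfg or truth.cfg
    rng = np.random.default_rng([cfg.seed, 2])
    replicate_ids = [f"rep{r + 1}" for r in range(cfg.n_replicates)]
    orientations = {
        rid: ("forward" if r < cfg.n_forward else "reverse")
        for r, rid in enumerate(replicate_ids)
    }
    offsets = np.linspace(-8.0, 8.0, 9)
    profile = 1.0 - np.abs(offsets) / 10.0
    profile /= np.trapezoid(profile, offsets)  # unit-area elution shape

    ms1_rows: dict[str, list] = {rid: [] for rid in replicate_ids}
    ms2_events: list[Ms2Event] = []
    psms: list[PsmRecord] = []

    for pp in truth.pairs:
        ma, mb, light_mass, heavy_mass = _pair_masses(pp, cfg.reporter_mass)
        z = cfg.precursor_charge
        light_mz, heavy_mz = mz_from_mass(light_mass, z), mz_from_mass(heavy_mass, z)
        rt_center = 120.0 + 60.0 * pp.index
        sid = f"scan{pp.index:05d}"

        for rid in replicate_ids:
            obs = pp.true_log2 + rng.normal(0.0, cfg.replicate_sd) if cfg.replicate_sd else pp.true_log2
            rs = 2.0**obs
            hl = rs if orientations[rid] == "forward" else 1.0 / rs
            light_area = cfg.base_intensity * rng.lognormal(0.0, cfg.intensity_sigma)
            heavy_area = light_area * hl
            for mz, area in ((light_mz, light_area), (heavy_mz, heavy_area)):
                jitter = rng.normal(0.0, cfg.mass_noise_ppm) * 1e-6 if cfg.mass_noise_ppm else 0.0
                for dt, w in zip(offsets, profile):
                    ms1_rows[rid].append((rt_center + dt, mz * (1.0 + jitter), area * w))

        frags = [ma] if abs(ma - mb) < 1e-9 else [ma, mb]
        noise = rng.uniform(400.0, 4000.0, size=cfg.n_noise_fragments)
        jitter = rng.normal(0.0, cfg.mass_noise_ppm) * 1e-6 if cfg.mass_noise_ppm else 0.0
        ms2_events.append(
            Ms2Event(
                spectrum_id=sid,
                precursor=PrecursorIon(mz=light_mz * (1.0 + jitter), charge=z, retention_time=rt_center),
                fragment_masses=tuple(frags) + tuple(noise),
            )
        )
        seen = set()
        for pep, decoy in ((pp.pep_a, False), (pp.pep_b, pp.is_decoy)):
            key = (pep.sequence, pep.crosslink_site)
            if key in seen:
                continue
            seen.add(key)
            psms.append(PsmRecord(sid, pep, score=float(rng.uniform(3.0, 4.0)), is_decoy=decoy))

    # low-scoring decoy PSMs on their own spectra (FDR machinery fodder)
    seqs = dict(truth.proteome)
    accs = sorted(seqs)
    for d in range(cfg.n_decoy_psms):
        acc = accs[int(rng.integers(len(accs)))]
        rev = seqs[acc][::-1]
        peps = _crosslinkable_peptides("rev_" + acc, rev, rng)
        if not peps:
            continue
        pep = peps[int(rng.integers(len(peps)))]
        sp = _make_species(pep, _pick_site(pep, rng))
        psms.append(PsmRecord(f"decoyscan{d:04d}", sp, score=float(rng.uniform(0.0, 2.0)), is_decoy=True))

    # background MS1 noise peaks
    for rid in replicate_ids:
        rt_max = 120.0 + 60.0 * len(truth.pairs)
        for _ in range(cfg.n_noise_peaks):
            ms1_rows[rid].append(
                (float(rng.uniform(0.0, rt_max)), float(rng.uniform(300.0, 1500.0)),
                 float(rng.uniform(0.0, 0.05 * cfg.base_intensity)))
            )

    ms1 = {
        rid: pd.DataFrame(rows, columns=["rt", "mz", "intensity"]).sort_values(
            ["rt", "mz"], kind="mergesort", ignore_index=True
        )
        for rid, rows in ms1_rows.items()
    }
    return SimData(ms1=ms1, ms2_events=ms2_events, psms=psms, orientations=orientations, truth=truth)
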