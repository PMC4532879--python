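"""Readers, writers and pipeline configuration.

The crosslink-pair TSV (spectrum_id, pep_a, site_a, protein_a, start_a,
pep_b, site_b, protein_b, start_b, mods_a, mods_b, n_decoy, ppm_error)
is the lingua franca between the identification stage and everything
downstream. Modification strings are ``pos:name`` tokens joined by
semicolons, with names from the standard modification table.

All residue coordinates are 1-based inclusive internally; the histone
reporting convention (UniProt index minus one, so marks read as e.g.
H3K27) is applied only at report boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masses import ModificationSpec, PeptideSpecies, standard_mod
from .network import CrosslinkRecord
from .quantify import QuantRecord, QuantSummary

__all__ = [
    "parse_mods", "format_mods",
    "read_fasta", "write_fasta",
    "read_crosslink_table", "write_crosslink_table",
    "read_psm_table", "write_psm_table",
    "read_peak_table", "write_peak_table",
    "read_known_ppi",
    "write_quant_records", "write_quant_summaries", "read_quant_summaries",
    "read_modification_table", "write_modification_table",
    "PipelineConfig",
    "convert_residue_numbering", "is_histone",
]

CROSSLINK_COLUMNS = [
    "spectrum_id", "pep_a", "site_a", "protein_a", "start_a",
    "pep_b", "site_b", "protein_b", "start_b",
    "mods_a", "mods_b", "n_decoy", "ppm_error",
]


def parse_mods(text: str) -> tuple[tuple[int, ModificationSpec], ...]:
    """Parse a ``pos:name;pos:name`` modification string."""
    if not text or (isinstance(text, float)):
        return ()
    out = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        pos_s, name = token.split(":", 1)
        out.append((int(pos_s), standard_mod(name)))
    return tuple(out)


def format_mods(mods: tuple[tuple[int, ModificationSpec], ...]) -> str:
    return ";".join(f"{pos}:{mod.name}" for pos, mod in mods)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in records],
        str(path),
        "fasta",
    )


def write_crosslink_table(records: list[CrosslinkRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CROSSLINK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_crosslink_table(path: str | Path) -> list[CrosslinkRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CrosslinkRecord(
                spectrum_id=str(row.spectrum_id),
                pep_a=row.pep_a, site_a=int(row.site_a),
                protein_a=row.protein_a, start_a=int(row.start_a),
                pep_b=row.pep_b, site_b=int(row.site_b),
                protein_b=row.protein_b, start_b=int(row.start_b),
                mods_a=str(row.mods_a), mods_b=str(row.mods_b),
                n_decoy=int(row.n_decoy), ppm_error=float(row.ppm_error),
            )
        )
    return out


def write_psm_table(psms, path: str | Path) -> None:
    rows = []
    for p in psms:
        pep = p.peptide
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "sequence": pep.sequence,
                "mods": format_mods(pep.mods),
                "protein": pep.protein_ids[0] if pep.protein_ids else "",
                "start": pep.start_pos,
                "site": pep.crosslink_site if pep.crosslink_site is not None else "",
                "label": pep.label_state,
                "score": p.score,
                "decoy": int(p.is_decoy),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path):
    from .identify import PsmRecord

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        site = int(row.site) if str(row.site) != "" else None
        pep = PeptideSpecies(
            sequence=row.sequence,
            mods=parse_mods(row.mods),
            label_state=row.label,
            protein_ids=(row.protein,) if row.protein else (),
            start_pos=int(row.start),
            crosslink_site=site,
        )
        out.append(PsmRecord(str(row.spectrum_id), pep, float(row.score), bool(int(row.decoy))))
    return out


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["rt", "mz", "intensity"]].to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_known_ppi(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_quant_records(records: list[QuantRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def write_quant_summaries(summaries: dict[str, QuantSummary], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()]).to_csv(
        path, sep="\t", index=False
    )


def read_quant_summaries(path: str | Path) -> dict[str, QuantSummary]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[row.pair_key] = QuantSummary(
            pair_key=row.pair_key,
            n_replicates=int(row.n_replicates),
            mean_log2_rs=float(row.mean_log2_rs),
            ci_width=float(row.ci_width),
            significant=bool(row.significant),
        )
    return out


def write_modification_table(mods: list[ModificationSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": m.name, "delta_mass": m.delta_mass, "targets": m.targets,
             "static_flag": int(m.static_flag)}
            for m in mods
        ]
    ).to_csv(path, sep="\t", index=False)


def read_modification_table(path: str | Path) -> list[ModificationSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        ModificationSpec(row.name, float(row.delta_mass), row.targets, bool(int(row.static_flag)))
        for row in df.itertuples(index=False)
    ]


@dataclass
class PipelineConfig:
    """All tolerances and thresholds, with the published search defaults."""

    precursor_tol_ppm: float = 25.0
    max_c13_offsets: int = 3
    pir_tol_ppm: float = 20.0
    fragment_tol_crosslink: float = 0.36
    fragment_tol_global: float = 1.0005
    xic_tol_ppm: float = 10.0
    max_missed_crosslink: int = 3
    max_missed_global: int = 2
    psm_fdr: float = 0.05
    alpha: float = 0.05
    ratio_threshold: float = 1.0
    ci_threshold: float = 1.0
    reporter_mass: float = 752.41312
    seed: int = 0
    histone_patterns: tuple[str, ...] = ("HIST", "H2A", "H2B", "H3", "H4", "H1")

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name != "seed" and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["histone_patterns"] = list(d["histone_patterns"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d["histone_patterns"] = tuple(d.get("histone_patterns", ()))
        return cls(**d)


def is_histone(protein_id: str, patterns: tuple[str, ...] = PipelineConfig().histone_patterns) -> bool:
    """Heuristic histone-family membership from the accession/name."""
    up = protein_id.upper()
    return any(re.search(rf"(^|[_|]){re.escape(p)}", up) for p in patterns)


def convert_residue_numbering(protein_id: str, residue: int, histone_flag: bool) -> int:
    """Report-boundary residue numbering.

    Histone proteins are reported in canonical histone-mark nomenclature
    (UniProt index minus one, discounting the initiator Met); all other
    proteins keep their UniProt index.
    """
    if residue < 1:
        raise ValueError("residue index must be >= 1")
    if not histone_flag:
        return residue
    if residue == 1:
        raise ValueError("initiator Met of a histone has no mark-nomenclature index")
    return residue - 1
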