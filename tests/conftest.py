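import gemmi
import pytest

from xledge import pipeline as pl
from xledge.simulate import SimConfig, generate_proteome, plant_crosslinks, render_ms_data

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_pdb(chains: dict[str, list[tuple[int, str, tuple[float, float, float]]]]) -> gemmi.Structure:
    """Hand-built structure: chain -> [(author resnum, one-letter aa, CA xyz)]."""
    lines = []
    serial = 0
    for chain_name, residues in chains.items():
        for resnum, aa, (x, y, z) in residues:
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  CA  {AA3[aa]:<3s} {chain_name}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
    lines.append("END")
    st = gemmi.read_pdb_string("\n".join(lines))
    st.setup_entities()
    return st


@pytest.fixture(scope="session")
def noiseless_sim():
    """Deterministic noise-free study: 20 planted crosslinks, 5 replicates."""
    cfg = SimConfig(seed=7, n_crosslinks=20, replicate_sd=0.0, mass_noise_ppm=0.0)
    proteome = generate_proteome(cfg)
    truth = plant_crosslinks(proteome, cfg)
    sim = render_ms_data(truth, cfg)
    return cfg, proteome, truth, sim


@pytest.fixture(scope="session")
def noiseless_identification(noiseless_sim):
    cfg, proteome, truth, sim = noiseless_sim
    result = pl.identify_from_sim(sim, cfg.reporter_mass)
    records = pl.pairs_to_records(result.pairs)
    return cfg, proteome, truth, sim, result, records
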