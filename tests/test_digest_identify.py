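"""Digestion, decoys, pair assembly and target/decoy FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xledge.digest import enumerate_crosslinkable, has_internal_lysine, tryptic_digest
from xledge.identify import (
    PsmRecord,
    assemble_pairs,
    build_decoy_db,
    filter_psms_fdr,
    naive_fragment_score,
    pair_fdr,
    theoretical_by_ions,
)
from xledge.masses import (
    PeptideSpecies,
    PirMatch,
    PrecursorIon,
    mz_from_mass,
    peptide_mass,
    standard_mod,
)

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200)


def oracle_digest(seq: str, max_missed: int) -> set[tuple[int, int, int]]:
    """Brute force: every substring that is fully tryptic with <= max_missed
    retained internal cleavage sites (Keil rule)."""

    def is_site(p: int) -> bool:  # cleavage between p and p+1 (0-based)
        return seq[p] in "KR" and (p + 1 == len(seq) or seq[p + 1] != "P")

    out = set()
    n = len(seq)
    for i in range(n):
        if not (i == 0 or is_site(i - 1)):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or is_site(j - 1)):
                continue
            missed = sum(1 for p in range(i, j - 1) if is_site(p))
            if missed <= max_missed:
                out.add((i + 1, j, missed))
    return out


class TestTrypticDigest:
    def test_basic_cleavage_no_missed(self):
        peps = tryptic_digest("AKRG", 0)
        assert [(p.sequence, p.start_pos, p.end_pos) for p in peps] == [
            ("AK", 1, 2), ("R", 3, 3), ("G", 4, 4),
        ]

    def test_one_missed_cleavage_adds_joined_products(self):
        got = {(p.sequence, p.start_pos, p.end_pos, p.missed_cleavages)
               for p in tryptic_digest("AKRG", 1)}
        assert got == {
            ("AK", 1, 2, 0), ("R", 3, 3, 0), ("G", 4, 4, 0),
            ("AKR", 1, 3, 1), ("RG", 3, 4, 1),
        }

    def test_proline_suppresses_cleavage(self):
        peps = tryptic_digest("AKPGR", 0)
        assert [p.sequence for p in peps] == ["AKPGR"]

    def test_no_cleavage_sites_returns_whole_protein(self):
        peps = tryptic_digest("AGGLM", 2)
        assert len(peps) == 1 and peps[0].sequence == "AGGLM"

    def test_empty_sequence(self):
        assert tryptic_digest("", 3) == []

    def test_zero_missed_products_concatenate_to_protein(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVK"
        parts = [p.sequence for p in tryptic_digest(seq, 0)]
        assert "".join(parts) == seq

    @settings(derandomize=True, max_examples=40)
    @given(proteins, st.integers(min_value=0, max_value=3))
    def test_matches_brute_force_oracle(self, seq, max_missed):
        got = {(p.start_pos, p.end_pos, p.missed_cleavages)
               for p in tryptic_digest(seq, max_missed)}
        assert got == oracle_digest(seq, max_missed)


class TestEnumerateCrosslinkable:
    def test_internal_lysine_retained(self):
        assert has_internal_lysine("AKR")

    def test_terminal_lysine_excluded(self):
        assert not has_internal_lysine("AK")

    @settings(derandomize=True, max_examples=25)
    @given(proteins)
    def test_count_matches_filter_oracle(self, seq):
        peps = tryptic_digest(seq, 3)
        kept = enumerate_crosslinkable(peps)
        assert len(kept) == sum(1 for p in peps if "K" in p.sequence[:-1])


class TestDecoyDatabase:
    def test_output_doubles_input(self):
        db = build_decoy_db([("P1", "AKRG"), ("P2", "MKV"), ("P3", "GG")])
        assert len(db) == 6
        assert ("rev_P1", "GRKA") in db

    def test_reversing_twice_is_identity(self):
        fwd = [("P1", "MKTAYIAK")]
        twice = build_decoy_db(build_decoy_db(fwd))
        assert ("rev_rev_P1", "MKTAYIAK") in twice

    def test_reversed_sequence_preserves_mass(self):
        seq = "MKTAYIAK"
        assert peptide_mass(PeptideSpecies(seq)) == pytest.approx(
            peptide_mass(PeptideSpecies(seq[::-1]))
        )

    def test_duplicate_accession_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_decoy_db([("P1", "AK"), ("P1", "GR")])


def _species(seq, site, protein="P1", start=1):
    return PeptideSpecies(
        seq, mods=((site, standard_mod("stump")),),
        protein_ids=(protein,), start_pos=start, crosslink_site=site,
    )


def _pir_for(pep1, pep2, reporter=700.0, spectrum_id="s1"):
    m1, m2 = peptide_mass(pep1), peptide_mass(pep2)
    prec = PrecursorIon(mz=mz_from_mass(reporter + m1 + m2, 4), charge=4)
    return PirMatch(prec, reporter, m1, m2, ppm_error=0.0, spectrum_id=spectrum_id)


class TestAssemblePairs:
    def test_two_targets_form_pair_with_zero_decoys(self):
        a, b = _species("AAKGR", 3), _species("MLKSTK", 3, protein="P2")
        psms = [PsmRecord("s1", a, 3.5), PsmRecord("s1", b, 3.2)]
        res = assemble_pairs(psms, [_pir_for(a, b)])
        assert len(res.pairs) == 1
        assert res.pairs[0].n_decoy_peptides == 0
        assert res.ambiguous == []

    def test_target_plus_decoy_counts_one_decoy(self):
        a, b = _species("AAKGR", 3), _species("MLKSTK", 3, protein="rev_P2")
        # enough high-scoring targets that one decoy stays within 5% FDR
        filler = [PsmRecord(f"f{i}", _species("AAKGR", 3), 5.0) for i in range(19)]
        psms = filler + [PsmRecord("s1", a, 3.5), PsmRecord("s1", b, 3.2, is_decoy=True)]
        res = assemble_pairs(psms, [_pir_for(a, b)])
        assert len(res.pairs) == 1 and res.pairs[0].n_decoy_peptides == 1

    def test_peptide_without_stump_site_cannot_pair(self):
        a = _species("AAKGR", 3)
        b = PeptideSpecies("MLKSTK", protein_ids=("P2",))  # no stump mod
        psms = [PsmRecord("s1", a, 3.5), PsmRecord("s1", b, 3.2)]
        res = assemble_pairs(psms, [_pir_for(a, b)])
        assert res.pairs == []

    def test_shared_mass_assignment_flagged_ambiguous(self):
        a, b = _species("AAKGR", 3), _species("MLKSTK", 3, protein="P2")
        # second candidate at (essentially) the same mass as a: permuted sequence
        a2 = _species("AKAGR", 2, protein="P3")
        psms = [PsmRecord("s1", a, 3.5), PsmRecord("s1", b, 3.2), PsmRecord("s1", a2, 3.0)]
        res = assemble_pairs(psms, [_pir_for(a, b)])
        assert res.pairs == [] and res.ambiguous == ["s1"]


class TestPairFdr:
    def test_no_decoys(self):
        a, b = _species("AAKGR", 3), _species("MLKSTK", 3, protein="P2")
        pairs = assemble_pairs(
            [PsmRecord("s1", a, 3.0), PsmRecord("s1", b, 3.0)], [_pir_for(a, b)]
        ).pairs
        assert pair_fdr(pairs) == 0.0

    def test_fraction_with_any_decoy(self):
        a, b = _species("AAKGR", 3), _species("MLKSTK", 3, protein="P2")
        base = assemble_pairs(
            [PsmRecord("s1", a, 3.0), PsmRecord("s1", b, 3.0)], [_pir_for(a, b)]
        ).pairs[0]
        from dataclasses import replace

        pairs = [replace(base, n_decoy_peptides=0)] * 198
        pairs += [replace(base, n_decoy_peptides=1), replace(base, n_decoy_peptides=2)]
        assert pair_fdr(pairs) == pytest.approx(0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pair_fdr([])

    def test_monotone_under_score_threshold_tightening(self):
        """On scores where decoys sit below targets, the estimated pair FDR
        never increases as the acceptance threshold tightens."""
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.uniform(1.0, 2.0, 300), rng.uniform(0.0, 1.0, 60)])
        decoy = np.concatenate([np.zeros(300, bool), np.ones(60, bool)])
        order = np.argsort(-scores)
        scores, decoy = scores[order], decoy[order]
        fdrs = []
        for threshold in np.linspace(0.0, 1.9, 25):
            keep = scores >= threshold
            if keep.sum() == 0:
                continue
            fdrs.append(decoy[keep].mean())
        # thresholds ascend = tightening; estimated FDR must not increase
        assert all(b <= a + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestPsmFdrFilter:
    def test_accepts_largest_prefix_within_fdr(self):
        pep = _species("AAKGR", 3)
        psms = [PsmRecord(f"t{i}", pep, 10.0 - i * 0.1) for i in range(40)]
        psms += [PsmRecord("d0", pep, 5.0, is_decoy=True)]  # 1/40 = 2.5% <= 5%
        psms += [PsmRecord("d1", pep, 0.5, is_decoy=True)]  # 2/40 = 5% <= 5%
        psms += [PsmRecord("d2", pep, 0.4, is_decoy=True)]  # 3/40 = 7.5% > 5%
        kept = filter_psms_fdr(psms, 0.05)
        assert len(kept) == 42 and sum(p.is_decoy for p in kept) == 2

    def test_all_decoys_yields_empty(self):
        pep = _species("AAKGR", 3)
        assert filter_psms_fdr([PsmRecord("d", pep, 1.0, is_decoy=True)], 0.05) == []


class TestNaiveFragmentScore:
    def test_exact_theoretical_spectrum_scores_one(self):
        pep = _species("AAKGR", 3)
        ions = theoretical_by_ions(pep)
        assert naive_fragment_score(ions, pep, 0.01) == 1.0

    def test_empty_spectrum_scores_zero(self):
        assert naive_fragment_score([], _species("AAKGR", 3), 0.01) == 0.0

    def test_half_spectrum_scores_half(self):
        pep = _species("AAKGR", 3)
        ions = theoretical_by_ions(pep)
        assert naive_fragment_score(ions[: len(ions) // 2], pep, 0.01) == pytest.approx(0.5)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            naive_fragment_score([], _species("AAKGR", 3), 0.0)
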