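"""Tryptic digestion and circRNA-unique peptide filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circtrans.digest import (
    build_peptide_db,
    collapse_il,
    digest,
    filter_unique_peptides,
    write_search_database,
)
from circtrans.orf import find_circular_orfs
from circtrans.types import CircSequence

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80)


class TestDigestion:
    def test_cleaves_after_k_and_r(self):
        assert {p.sequence for p in digest("MKRAPK", max_missed=0)} == {
            "MK", "R", "APK",
        }

    def test_k_before_p_is_not_a_site(self):
        assert {p.sequence for p in digest("AKPGR", max_missed=0)} == {"AKPGR"}

    def test_one_missed_cleavage_enumeration(self):
        assert {p.sequence for p in digest("MKR", max_missed=1)} == {
            "MK", "R", "MKR",
        }
        by_seq = {p.sequence: p for p in digest("MKR", max_missed=1)}
        assert by_seq["MKR"].missed_cleavages == 1
        assert by_seq["MK"].missed_cleavages == 0

    def test_empty_protein_gives_empty_list(self):
        assert digest("") == []

    def test_positions_recorded(self):
        by_seq = {p.sequence: p for p in digest("MKRAPK", max_missed=0)}
        assert by_seq["APK"].start_aa == 3

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(proteins)
    def test_zero_missed_concatenation_reconstructs_protein(self, protein):
        pieces = [p for p in digest(protein, max_missed=0)]
        pieces.sort(key=lambda p: p.start_aa)
        assert "".join(p.sequence for p in pieces) == protein

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(proteins)
    def test_zero_missed_products_are_fully_tryptic(self, protein):
        for p in digest(protein, max_missed=0):
            internal = p.sequence[:-1]
            for i, residue in enumerate(internal):
                if residue in "KR":
                    assert p.sequence[i + 1] == "P"


class TestUniquenessFilter:
    def test_reference_substring_removed(self):
        peps = digest("MAGICPEPTIDEK", max_missed=0)
        reference = {"ref1": "XXXMAGICPEPTIDEKXXX"}
        assert filter_unique_peptides(peps, reference) == []

    def test_empty_reference_retains_all(self):
        peps = digest("MAGICPEPTIDEK", max_missed=0)
        survivors = filter_unique_peptides(peps, {})
        assert [p.sequence for p in survivors] == ["MAGICPEPTIDEK"]
        assert all(p.unique_vs_reference for p in survivors)

    def test_il_equivalence_toggles_removal(self):
        peps = digest("MAGICPEPTIDEK", max_missed=0)
        # reference differs only by I -> L
        reference = {"r": "MAGICPEPTLDEK"}
        assert filter_unique_peptides(peps, reference, il_equivalence=True) == []
        kept = filter_unique_peptides(peps, reference, il_equivalence=False)
        assert [p.sequence for p in kept] == ["MAGICPEPTIDEK"]

    def test_length_bounds_applied(self):
        peps = digest("MKMAGICPEPTIDEK", max_missed=0)
        survivors = filter_unique_peptides(peps, {}, min_len=7, max_len=52)
        assert "MK" not in [p.sequence for p in survivors]

    def test_enlarging_reference_never_adds_survivors(self):
        peps = digest("MAGICPEPTIDEKSECRETPEPTIDEK", max_missed=1)
        small = {"a": "SECRETPEPTIDEK"}
        big = dict(small, b="MAGICPEPTIDEK")
        kept_small = {p.sequence
                      for p in filter_unique_peptides(list(peps), small)}
        kept_big = {p.sequence
                    for p in filter_unique_peptides(list(peps), big)}
        assert kept_big <= kept_small

    def test_survivors_absent_by_direct_scan(self):
        reference = {"r1": "MKLVDERTYPLK", "r2": "GGHHWWEETTK"}
        peps = digest("MKLVDERTYPMNQWERTYK", max_missed=2)
        for pep in filter_unique_peptides(peps, reference):
            for ref in reference.values():
                assert collapse_il(pep.sequence) not in collapse_il(ref)


class TestJunctionFlag:
    def test_rolling_orf_peptides_crossing_offset_zero_flagged(self):
        (orf,) = find_circular_orfs(
            CircSequence(circ_id="c", sequence="ATGGCTGCTA"), min_aa=1
        )
        peps = digest(orf.protein, max_missed=2, parent_orf=orf)
        # coding region is 18 nt on a 10-nt circle: full-protein peptides
        # must cross the junction
        full = [p for p in peps if p.start_aa == 0 and len(p.sequence) == 6]
        assert full and all(p.spans_junction for p in full)

    def test_single_pass_orf_peptides_not_flagged(self):
        (orf,) = find_circular_orfs(
            CircSequence(circ_id="c", sequence="ATGGCTTAAGCC"), min_aa=1
        )
        peps = digest(orf.protein, max_missed=2, parent_orf=orf)
        assert peps and not any(p.spans_junction for p in peps)


class TestSearchDatabase:
    def _orfs(self):
        a = find_circular_orfs(
            CircSequence(circ_id="circA", sequence="ATGGCTGCTA"), min_aa=1
        )
        b = find_circular_orfs(
            CircSequence(circ_id="circB", sequence="ATGGCTTAAGCC"), min_aa=1
        )
        return a + b

    def test_reference_first_circ_entries_last(self, tmp_path):
        reference = {"sp|P1|X": "MKLV", "sp|P2|X": "GGHH", "sp|P3|X": "WWEE"}
        out = tmp_path / "db.fa"
        n = write_search_database(self._orfs(), reference, out)
        assert n == 5
        lines = [l for l in out.read_text().splitlines() if l.startswith(">")]
        assert lines[:3] == [">sp|P1|X", ">sp|P2|X", ">sp|P3|X"]
        assert all(l.startswith(">CIRC|") for l in lines[3:])

    def test_rerun_is_byte_identical(self, tmp_path):
        reference = {"sp|P1|X": "MKLV"}
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_search_database(self._orfs(), reference, p1)
        write_search_database(self._orfs(), reference, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_accession_collision_raises(self, tmp_path):
        orfs = self._orfs()
        from circtrans.orf import orf_fasta_header

        reference = {f"CIRC|{orf_fasta_header(orfs[0])}": "MKLV"}
        with pytest.raises(ValueError, match="collision"):
            write_search_database(orfs, reference, tmp_path / "x.fa")

    def test_planted_orfs_each_appear_once(self, study, tmp_path):
        _outdir, manifest = study
        orfs = []
        for spec in manifest["circles"]:
            if spec["kind"] == "infinite":
                continue
            orfs.extend(
                find_circular_orfs(
                    CircSequence(circ_id=spec["circ_id"],
                                 sequence=spec["sequence"]),
                    min_aa=1,
                )
            )
        out = tmp_path / "db.fa"
        write_search_database(orfs, manifest["reference_proteins"], out)
        headers = [l for l in out.read_text().splitlines()
                   if l.startswith(">CIRC|")]
        assert len(headers) == len(orfs)
        assert len(set(headers)) == len(headers)


def test_build_peptide_db_excludes_periodic_orfs():
    orfs = find_circular_orfs(
        CircSequence(circ_id="inf", sequence="ATGAAAAAA"), min_aa=1
    )
    assert orfs[0].termination == "none"
    assert build_peptide_db(orfs, {}, min_len=1) == []
    assert build_peptide_db(orfs, {}, min_len=1,
                            include_nonterminating=True) != []
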