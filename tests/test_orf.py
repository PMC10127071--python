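"""Circular ORF prediction against an independent linear-scan oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from circtrans.orf import (
    classify_junction_spanning,
    find_circular_orfs,
    select_longest_junction_spanning,
)
from circtrans.types import CircSequence

STOPS = {"TAA", "TAG", "TGA"}


def circ(seq, cid="c"):
    return CircSequence(circ_id=cid, sequence=seq)


def linear_oracle(seq, min_aa=1):
    """Reference: scan the (P+1)-fold linearization with a plain ORF scan.

    Any ORF that terminates on the circle must find its stop within P*L nt
    of its start; the extra copy guarantees full codons at the end.
    """
    L = len(seq)
    period = 1 if L % 3 == 0 else 3
    lin = seq * (period + 1)
    found = set()
    for i in range(L):
        if lin[i:i + 3] != "ATG":
            continue
        for j in range(i, len(lin) - 2, 3):
            if lin[j:j + 3] in STOPS:
                protein = str(Seq(lin[i:j]).translate())
                if len(protein) >= min_aa:
                    found.add((i, protein))
                break
    return found


class TestFrozenExamples:
    def test_smallest_terminating_circle(self):
        (orf,) = find_circular_orfs(circ("ATGTAA"), min_aa=1)
        assert orf.protein == "M"
        assert orf.passes == 0
        assert orf.termination == "stop"
        assert not orf.junction_spanning

    def test_rolling_circle_stop_on_third_pass(self):
        # L=10 not divisible by 3: frame shifts each pass
        (orf,) = find_circular_orfs(circ("ATGGCTGCTA"), min_aa=1)
        assert orf.protein == "MAANGC"
        assert orf.coding_length == 18
        assert orf.junction_spanning
        assert linear_oracle("ATGGCTGCTA") == {(0, "MAANGC")}

    def test_periodic_orf_truncated_at_one_period(self):
        # L=9, frame 0 never hits a stop: period is one pass
        (orf,) = find_circular_orfs(circ("ATGAAAAAA"), min_aa=1)
        assert orf.termination == "none"
        assert orf.protein == "MKK"
        assert orf.stop_offset is None

    def test_start_codon_mutation_removes_orf(self):
        assert find_circular_orfs(circ("ATGGCTGCTA"), min_aa=1)
        assert find_circular_orfs(circ("CTGGCTGCTA"), min_aa=1) == []

    def test_n_codons_translate_to_x_and_never_stop(self):
        (orf,) = find_circular_orfs(circ("ATGTNATAA"), min_aa=1)
        assert orf.protein == "MX"

    def test_nested_orfs_share_stop_offset(self):
        orfs = find_circular_orfs(circ("ATGATGGCTTAA"), min_aa=1)
        assert len(orfs) == 2
        assert orfs[0].stop_offset == orfs[1].stop_offset == 9

    def test_min_aa_filters_short_orfs(self):
        assert find_circular_orfs(circ("ATGTAA"), min_aa=2) == []

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            find_circular_orfs(circ("AT"))
        with pytest.raises(ValueError):
            find_circular_orfs(circ("ATGXZA"))


class TestOracleEquivalence:
    def test_sampled_random_circles_match_linear_oracle(
        self, random_circle_corpus
    ):
        for seq in random_circle_corpus[:100]:
            got = {
                (o.start_offset, o.protein)
                for o in find_circular_orfs(circ(seq), min_aa=1)
                if o.termination == "stop"
            }
            assert got == linear_oracle(seq), seq

    def test_rotation_invariance_of_protein_multiset(self, rng):
        for _ in range(25):
            L = int(rng.integers(6, 120))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            base = sorted(
                o.protein for o in find_circular_orfs(circ(seq), min_aa=1)
            )
            r = int(rng.integers(1, L))
            rotated = seq[r:] + seq[:r]
            rot = sorted(
                o.protein for o in find_circular_orfs(circ(rotated), min_aa=1)
            )
            assert rot == base

    def test_rotation_shifts_start_offsets(self):
        seq = "ATGGCTGCTA"
        (orf,) = find_circular_orfs(circ(seq), min_aa=1)
        r = 4
        (rot,) = find_circular_orfs(circ(seq[r:] + seq[:r]), min_aa=1)
        assert rot.start_offset == (orf.start_offset - r) % len(seq)

    def test_protein_length_bounds(self, random_circle_corpus):
        for seq in random_circle_corpus[:100]:
            L = len(seq)
            for o in find_circular_orfs(circ(seq), min_aa=1):
                if o.termination == "stop":
                    if L % 3 == 0:
                        assert len(o.protein) <= L // 3 - 1
                    else:
                        assert len(o.protein) <= L - 1
                else:
                    # periodic ORF truncated at one frame period
                    assert len(o.protein) == (1 if L % 3 == 0 else 3) * L // 3


class TestJunctionSpanning:
    def test_orf_within_one_pass_is_not_spanning(self):
        seq = "ATGGCTTAAGCC"  # L=12, ORF [0,6) well inside
        (orf,) = find_circular_orfs(circ(seq), min_aa=1)
        spanning, crossings = classify_junction_spanning(orf, circ(seq))
        assert not spanning
        assert crossings == []

    def test_crossing_count_equals_passes(self):
        seq = "ATGGCTGCTA"
        (orf,) = find_circular_orfs(circ(seq), min_aa=1)
        spanning, crossings = classify_junction_spanning(orf, circ(seq))
        assert spanning
        assert len(crossings) == orf.passes == 1
        assert crossings == [10]

    def test_against_linearized_coordinate_oracle(self, rng):
        n_checked = 0
        for _ in range(200):
            L = int(rng.integers(6, 90))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            c = circ(seq)
            for orf in find_circular_orfs(c, min_aa=1):
                spanning, crossings = classify_junction_spanning(orf, c)
                begin = orf.start_offset
                end = begin + orf.coding_length
                oracle = [m * L for m in range(1, end // L + 1) if m * L < end]
                assert crossings == oracle
                assert spanning == (end > L)
                n_checked += 1
        assert n_checked > 100

    def test_orf_of_wrong_circle_rejected(self):
        (orf,) = find_circular_orfs(circ("ATGTAA", cid="a"), min_aa=1)
        with pytest.raises(ValueError):
            classify_junction_spanning(orf, circ("ATGTAA", cid="b"))


def test_select_longest_junction_spanning_policy():
    orfs = find_circular_orfs(circ("ATGGCTGCTA"), min_aa=1)
    orfs += find_circular_orfs(circ("ATGGCTTAAGCC", cid="d"), min_aa=1)
    selected = select_longest_junction_spanning(orfs)
    assert [o.circ_id for o in selected] == ["c"]
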