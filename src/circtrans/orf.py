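"""ORF prediction on circular sequences, including rolling-circle reading.

Translation on a circle is defined on the infinite repetition of its
sequence: from a start codon the ribosome reads codons until the first
in-frame stop, crossing the back-splice junction as often as needed. The
reading frame at any offset recurs after P passes, where P = 1 if
L mod 3 == 0 and P = 3 otherwise, so scanning P*L nucleotides from a start
decides every ORF: a stop inside that window terminates the ORF; no stop
means the ORF is periodic (it can never terminate) and its protein is
reported truncated at P*L nucleotides.

This is how a 322-nt circle can encode a 161-aa protein: 322 is not a
multiple of 3, the frame shifts at each junction crossing, and the stop is
only reached on a later pass.
"""

from __future__ import annotations

from typing import FrozenSet, List, Tuple

from Bio.Data import CodonTable

from .types import CircORF, CircSequence

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: FrozenSet[str] = frozenset(STANDARD_TABLE.stop_codons)

_VALID_BASES = set("ACGTN")


def _codon_table(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def translate_codon(codon: str, forward_table=None) -> str:
    """One codon to one residue; any N yields 'X' (and never a stop)."""
    if forward_table is None:
        forward_table = STANDARD_TABLE.forward_table
    if "N" in codon:
        return "X"
    return forward_table[codon]


def find_circular_orfs(
    circ: CircSequence,
    min_aa: int = 20,
    start_codons: FrozenSet[str] = frozenset({"ATG"}),
    genetic_code: int = 1,
) -> List[CircORF]:
    """Predict all ORFs on a circle, rolling-circle translation included.

    Every occurrence of a start codon (default ATG) at circle offsets
    0..L-1 opens a candidate ORF; codons are read on the infinite repeat
    until the first in-frame stop or until P*L nucleotides have been
    scanned (P = 1 if L % 3 == 0 else 3), whichever comes first. ORFs with
    no stop in the window are periodic: ``termination="none"`` with the
    protein truncated at P*L nt. Codons containing N translate to X and
    never count as stop.

    Nested ORFs in the same frame read into the same stop codon; they all
    carry the same ``stop_offset`` so downstream stages can collapse them.
    Only ORFs with at least ``min_aa`` residues are returned, sorted by
    start offset.
    """
    seq = circ.sequence
    L = len(seq)
    if L < 3:
        raise ValueError(f"{circ.circ_id}: circle length {L} < 3")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"{circ.circ_id}: invalid characters in sequence: {sorted(bad)}"
        )
    forward, stops = _codon_table(genetic_code)

    period_passes = 1 if L % 3 == 0 else 3
    n_codons = period_passes * L // 3
    doubled = seq + seq  # windows never wrap more than once per codon

    def codon_at(pos: int) -> str:
        p = pos % L
        return doubled[p:p + 3]

    orfs: List[CircORF] = []
    for start in range(L):
        if codon_at(start) not in start_codons:
            continue
        residues: List[str] = []
        stop_offset = None
        for k in range(n_codons):
            codon = codon_at(start + 3 * k)
            if "N" not in codon and codon in stops:
                stop_offset = (start + 3 * k) % L
                break
            residues.append(translate_codon(codon, forward))
        protein = "".join(residues)
        if len(protein) < min_aa:
            continue
        coding_length = 3 * len(protein)
        termination = "stop" if stop_offset is not None else "none"
        passes = (start + coding_length - 1) // L if coding_length else 0
        spanning = coding_length > L - start
        orfs.append(
            CircORF(
                circ_id=circ.circ_id,
                start_offset=start,
                coding_length=coding_length,
                protein=protein,
                passes=passes,
                junction_spanning=spanning,
                termination=termination,
                circ_length=L,
                stop_offset=stop_offset,
                orf_id=None,
            )
        )
    orfs.sort(key=lambda o: o.start_offset)
    return [
        CircORF(**{**o.__dict__, "orf_id": f"{o.circ_id}|orf{i}"})
        for i, o in enumerate(orfs, start=1)
    ]


def classify_junction_spanning(
    orf: CircORF, circ: CircSequence
) -> Tuple[bool, List[int]]:
    """Does the coding region cross the back-splice junction, and where?

    True iff translated codons (stop excluded) leave the first pass, i.e.
    the coding region [start_offset, start_offset + coding_length) on the
    linearized read contains a multiple of L. Returns the linear positions
    of every crossing; their count equals ``passes``.
    """
    if orf.circ_id != circ.circ_id:
        raise ValueError("ORF does not belong to this circle")
    L = circ.length
    begin = orf.start_offset
    end = begin + orf.coding_length
    crossings = [m * L for m in range(1, end // L + 1) if m * L < end]
    return (orf.coding_length > L - orf.start_offset, crossings)


def select_longest_junction_spanning(orfs: List[CircORF]) -> List[CircORF]:
    """Policy helper: one ORF per circle, the longest junction-spanning one.

    Mirrors selecting the rolling-circle product a junction-spanning
    peptide would prove. Stop-terminated ORFs only; ties broken by
    smallest start offset.
    """
    best = {}
    for orf in orfs:
        if orf.termination != "stop" or not orf.junction_spanning:
            continue
        cur = best.get(orf.circ_id)
        if cur is None or (len(orf.protein), -orf.start_offset) > (
            len(cur.protein), -cur.start_offset
        ):
            best[orf.circ_id] = orf
    return [best[k] for k in sorted(best)]


def orf_fasta_header(orf: CircORF) -> str:
    """``circ_id|orf<k>|start=<nt>|len_aa=<n>|passes=<p>|span=<bool>|term=...``

    ``L`` (circle length) is appended so ORFs are fully reconstructable
    from the header alone.
    """
    k = (orf.orf_id or "orf?").rsplit("orf", 1)[-1]
    return (
        f"{orf.circ_id}|orf{k}|start={orf.start_offset}|"
        f"len_aa={len(orf.protein)}|passes={orf.passes}|"
        f"span={str(orf.junction_spanning).lower()}|term={orf.termination}|"
        f"L={orf.circ_length}"
    )
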