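"""In-silico tryptic digestion and circRNA-unique peptide filtering.

The proteogenomic trick: digest every predicted circle protein with the
same enzyme the bench used (trypsin), throw away every peptide that also
occurs anywhere in the reference proteome, and what is left can only come
from a circRNA. Because leucine and isoleucine are isobaric and cannot be
told apart by standard MS, uniqueness is decided with I and L collapsed to
one symbol by default — the conservative choice when claiming novel
evidence.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from pyteomics import parser as _pyt_parser

from .types import CircORF, PeptideRecord

logger = logging.getLogger(__name__)

# Cleave C-terminal of K or R unless the next residue is P.
TRYPSIN_RULE = r"[KR](?=[^P])"

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# I/L are isobaric: collapse both to 'J' for uniqueness comparisons.
_IL_TABLE = str.maketrans("IL", "JJ")


def collapse_il(sequence: str) -> str:
    """Map I and L to a single symbol (J), the MS-indistinguishable form."""
    return sequence.translate(_IL_TABLE)


def digest(
    protein: str,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    parent_orf: Optional[CircORF] = None,
) -> List[PeptideRecord]:
    """Tryptic digestion with up to ``max_missed`` missed cleavages.

    Cleavage is C-terminal of K/R except before P. Each product records
    its start position in the parent protein and its internal missed
    cleavage count. When ``parent_orf`` is given, peptides whose codon
    span crosses the back-splice junction are flagged
    ``spans_junction=True``.
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not protein:
        return []
    bad = set(protein) - _ALPHABET
    if bad:
        raise ValueError(f"invalid residues in protein: {sorted(bad)}")

    records: List[PeptideRecord] = []
    for start, pep in _pyt_parser.icleave(
        protein, TRYPSIN_RULE, missed_cleavages=max_missed, regex=True
    ):
        missed = _count_internal_sites(pep)
        records.append(
            PeptideRecord(
                sequence=pep,
                start_aa=start,
                missed_cleavages=missed,
                parent_orf=parent_orf,
                spans_junction=(
                    peptide_spans_junction(parent_orf, start, len(pep))
                    if parent_orf is not None
                    else False
                ),
            )
        )
    records.sort(key=lambda r: (r.start_aa, len(r.sequence)))
    return records


def _count_internal_sites(peptide: str) -> int:
    """Missed cleavages = internal K/R-not-before-P sites in the peptide."""
    n = 0
    for i in range(len(peptide) - 1):
        if peptide[i] in "KR" and peptide[i + 1] != "P":
            n += 1
    return n


def peptide_spans_junction(orf: CircORF, start_aa: int, length_aa: int) -> bool:
    """True iff the peptide's codon span crosses circle offset 0.

    The peptide occupies linearized nucleotides
    [orf.start_offset + 3*start_aa, + 3*length_aa); it spans the junction
    iff that interval contains a positive multiple of the circle length.
    """
    L = orf.circ_length
    begin = orf.start_offset + 3 * start_aa
    end = begin + 3 * length_aa
    # smallest m*L with m >= 1 and m*L >= begin; spans iff it lies before end
    m = max(1, -(-begin // L))
    return m * L < end


def filter_unique_peptides(
    peptides: Sequence[PeptideRecord],
    reference_proteome: Mapping[str, str],
    il_equivalence: bool = True,
    min_len: int = 7,
    max_len: int = 52,
) -> List[PeptideRecord]:
    """Keep peptides absent from the reference proteome.

    A peptide is removed if its sequence — with I/L collapsed when
    ``il_equivalence`` is on — occurs as a substring of any reference
    protein (substring, not tryptic-set, matching: stricter, and immune to
    semi-tryptic false uniqueness). Peptides outside [min_len, max_len]
    are dropped as not MS-observable. Survivors are marked
    ``unique_vs_reference=True``.
    """
    key = collapse_il if il_equivalence else (lambda s: s)
    # one haystack with a separator that can never occur inside a peptide
    haystack = "\n".join(key(seq.upper()) for seq in reference_proteome.values())
    survivors: List[PeptideRecord] = []
    for pep in peptides:
        if not (min_len <= len(pep.sequence) <= max_len):
            continue
        if key(pep.sequence) in haystack:
            pep.unique_vs_reference = False
            continue
        pep.unique_vs_reference = True
        survivors.append(pep)
    return survivors


def write_search_database(
    orfs: Sequence[CircORF],
    reference_proteome: Mapping[str, str],
    path,
    include_nonterminating: bool = False,
) -> int:
    """Write the combined MS search database FASTA.

    Reference entries are written unchanged and first; each ORF follows as
    one entry whose accession is prefixed ``CIRC|`` so downstream tools can
    partition hits. Periodic (never-terminating) ORFs are excluded unless
    ``include_nonterminating``. Returns the number of entries written.
    Deterministic: rerunning on the same input gives a byte-identical file.
    """
    from .orf import orf_fasta_header

    entries: List[Tuple[str, str]] = [
        (acc, seq) for acc, seq in reference_proteome.items()
    ]
    seen = {acc for acc, _ in entries}
    for orf in orfs:
        if orf.termination == "none" and not include_nonterminating:
            continue
        acc = f"CIRC|{orf_fasta_header(orf)}"
        if acc in seen:
            raise ValueError(f"accession collision in search database: {acc}")
        seen.add(acc)
        entries.append((acc, orf.protein))

    from .io import write_fasta

    write_fasta(entries, path)
    return len(entries)


def build_peptide_db(
    orfs: Sequence[CircORF],
    reference_proteome: Mapping[str, str],
    max_missed: int = 2,
    il_equivalence: bool = True,
    min_len: int = 7,
    max_len: int = 52,
    include_nonterminating: bool = False,
) -> List[PeptideRecord]:
    """Digest every ORF and keep the circRNA-unique peptides.

    The one-call route from predicted ORFs to the unique-peptide table the
    evidence stage consumes.
    """
    all_peptides: List[PeptideRecord] = []
    for orf in orfs:
        if orf.termination == "none" and not include_nonterminating:
            continue
        all_peptides.extend(digest(orf.protein, max_missed=max_missed,
                                   parent_orf=orf))
    return filter_unique_peptides(
        all_peptides,
        reference_proteome,
        il_equivalence=il_equivalence,
        min_len=min_len,
        max_len=max_len,
    )


def write_peptide_report(peptides: Sequence[PeptideRecord], path) -> None:
    """TSV report: peptide, circ_id, orf_id, start_aa, missed, junction, unique."""
    with open(path, "w") as fh:
        fh.write(
            "peptide\tcirc_id\torf_id\tstart_aa\tmissed_cleavages\t"
            "spans_junction\tunique\n"
        )
        for pep in peptides:
            orf = pep.parent_orf
            fh.write(
                f"{pep.sequence}\t{orf.circ_id if orf else '.'}\t"
                f"{orf.orf_id if orf else '.'}\t{pep.start_aa}\t"
                f"{pep.missed_cleavages}\t{pep.spans_junction}\t"
                f"{pep.unique_vs_reference}\n"
            )
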