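"""Core domain types shared across the pipeline.

All genomic intervals use one internal convention: 0-based, half-open
``[start, end)``, regardless of the dialect they were read from. Circle
positions ("offsets") are 0-based on the circle, with offset 0 defined as
the first base downstream of the back-splice junction (the acceptor-side
base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class BackspliceJunction:
    """One back-splice junction call: the boundary of a circRNA.

    ``start``/``end`` bracket the genomic span of the circle
    (0-based half-open). ``caller_id`` names the tool the call came from;
    ``junction_reads`` is its back-splice read support, if reported.
    """

    chrom: str
    start: int
    end: int
    strand: str
    caller_id: Optional[str] = None
    junction_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid junction interval {self.start}..{self.end} "
                f"(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} (need + or -)")
        if self.junction_reads is not None and self.junction_reads < 0:
            raise ValueError("junction_reads must be non-negative")

    @property
    def key(self) -> Tuple[str, int, int, str]:
        """Identity of the circle: (chrom, start, end, strand)."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered, non-overlapping exons on one strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"invalid exon {s}..{e}")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from an upstream search engine."""

    peptide: str
    accessions: Tuple[str, ...] = ()
    q_value: Optional[float] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("PSM peptide must be non-empty")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")


@dataclass(frozen=True)
class ConsensusCircRNA:
    """A circle supported by at least ``min_callers`` independent tools."""

    junction: BackspliceJunction
    supporting_callers: frozenset
    total_junction_reads: int


@dataclass(frozen=True)
class CircSequence:
    """The spliced circular sequence of a circRNA, in transcript orientation.

    Offset 0 on the circle is the acceptor-side base: the start of the most
    upstream included exon in transcript orientation. The back-splice joins
    the last base of the sequence back to offset 0.
    """

    circ_id: str
    sequence: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    exon_structure: Tuple[Tuple[int, int], ...] = ()
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("circle sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            raise ValueError("circle sequence must be uppercase")
        if self.exon_structure:
            exonic = sum(e - s for s, e in self.exon_structure)
            if exonic != len(self.sequence):
                raise ValueError(
                    f"sequence length {len(self.sequence)} != exonic "
                    f"length {exonic}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CircORF:
    """A predicted ORF on a circle, possibly crossing the junction.

    ``start_offset`` is the circle offset of the A of the initiator codon.
    ``coding_length`` counts translated nucleotides (stop excluded), so it
    always equals ``3 * len(protein)``. ``passes`` counts how many times the
    coding region crosses circle offset 0; rolling-circle translation gives
    passes >= 1. ``termination`` is "stop" for stop-terminated ORFs and
    "none" for periodic ORFs that never reach a stop (protein then truncated
    at one full frame period). ``stop_offset`` is the circle offset of the
    stop codon; nested ORFs reading into the same stop share it.
    """

    circ_id: str
    start_offset: int
    coding_length: int
    protein: str
    passes: int
    junction_spanning: bool
    termination: str
    circ_length: int
    stop_offset: Optional[int] = None
    orf_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.coding_length != 3 * len(self.protein):
            raise ValueError("coding_length must equal 3 * len(protein)")
        if self.termination not in ("stop", "none"):
            raise ValueError("termination must be 'stop' or 'none'")
        if self.termination == "none" and self.stop_offset is not None:
            raise ValueError("non-terminating ORF cannot carry a stop offset")

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class PeptideRecord:
    """A tryptic peptide from a circRNA ORF (or a bare digestion product)."""

    sequence: str
    start_aa: int
    missed_cleavages: int
    parent_orf: Optional[CircORF] = None
    spans_junction: bool = False
    unique_vs_reference: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")

    @property
    def circ_id(self) -> Optional[str]:
        return self.parent_orf.circ_id if self.parent_orf else None


@dataclass(frozen=True)
class PRMMeasurement:
    """Transition-level light/heavy peak areas for one peptide in one sample.

    ``transitions`` is a sequence of (fragment_id, endogenous_area,
    heavy_area); areas are non-negative. Quantification requires at least
    three transitions.
    """

    peptide: str
    sample_id: str
    transitions: Tuple[Tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for frag, light, heavy in self.transitions:
            if light < 0 or heavy < 0:
                raise ValueError(
                    f"negative peak area on transition {frag!r}"
                )


@dataclass
class TranslatableCircRNA:
    """A circle nominated as translated: >=1 unique peptide seen by MS.

    Every hit is flagged for human review; the pipeline never auto-accepts
    an identification.
    """

    circ_id: str
    supporting_unique_peptides: list = field(default_factory=list)
    best_q_value: Optional[float] = None
    n_spectra: int = 0
    flagged_for_review: bool = True
    ambiguous_peptides: list = field(default_factory=list)
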