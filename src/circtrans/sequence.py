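"""Assembly of spliced circular sequences from genome + annotation.

A back-splice junction whose boundaries coincide with annotated exon
boundaries is assembled from the exon chain of the matching transcript:
exons inside the circle span are concatenated in transcript order, and
minus-strand circles are reverse-complemented. Offset 0 of the resulting
circle is the acceptor-side base — the start of the most upstream included
exon in transcript orientation — so ORF coordinates are reproducible.
"""

from __future__ import annotations

import logging
from typing import List, Mapping, Optional, Sequence

from Bio.Seq import reverse_complement

from .types import BackspliceJunction, CircSequence, GeneModel

logger = logging.getLogger(__name__)


class AssemblyError(ValueError):
    """The circle cannot be assembled from the given genome/annotation."""


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract genome[chrom][start:end) from a pyfaidx.Fasta or mapping."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise AssemblyError(f"chromosome {chrom!r} absent from genome") from exc
    fragment = record[start:end]
    seq = fragment.seq if hasattr(fragment, "seq") else str(fragment)
    return seq.upper()


def _matching_transcripts(
    junction: BackspliceJunction, models: Sequence[GeneModel]
) -> List[GeneModel]:
    """Transcripts with exon boundaries at both junction ends."""
    hits = []
    for model in models:
        if model.chrom != junction.chrom or model.strand != junction.strand:
            continue
        has_acceptor = any(s == junction.start for s, _ in model.exons)
        has_donor = any(e == junction.end for _, e in model.exons)
        if has_acceptor and has_donor:
            hits.append(model)
    return hits


def _exons_in_span(model: GeneModel, junction: BackspliceJunction):
    return tuple(
        (s, e)
        for s, e in model.exons
        if s >= junction.start and e <= junction.end
    )


def assemble_circ_sequence(
    junction: BackspliceJunction,
    genome: Mapping,
    models: Sequence[GeneModel],
    circ_id: Optional[str] = None,
    fallback_genomic: bool = True,
) -> CircSequence:
    """Build the spliced circular sequence for one back-splice junction.

    The transcript whose exon boundaries match both junction ends is used;
    among several, the one with most exons inside the span wins, then the
    lexicographically smallest transcript_id (a deterministic rule — the
    biology does not pick one for us). If no transcript matches, the
    unspliced genomic span is used with a warning, unless
    ``fallback_genomic`` is off, in which case this is an error.
    """
    if circ_id is None:
        circ_id = (
            f"{junction.chrom}:{junction.start}-{junction.end}"
            f"({junction.strand})"
        )
    candidates = _matching_transcripts(junction, models)
    if candidates:
        chosen = max(
            candidates,
            key=lambda m: (len(_exons_in_span(m, junction)),),
        )
        # deterministic tie-break on transcript_id among equally exon-rich
        best_n = len(_exons_in_span(chosen, junction))
        chosen = min(
            (m for m in candidates
             if len(_exons_in_span(m, junction)) == best_n),
            key=lambda m: m.transcript_id,
        )
        exons = _exons_in_span(chosen, junction)
        if not exons:
            raise AssemblyError(
                f"{circ_id}: matching transcript {chosen.transcript_id} has "
                f"no exon inside the circle span"
            )
        transcript_id: Optional[str] = chosen.transcript_id
    elif fallback_genomic:
        logger.warning(
            "%s: no transcript matches the junction boundaries; "
            "falling back to the unspliced genomic span",
            circ_id,
        )
        exons = ((junction.start, junction.end),)
        transcript_id = None
    else:
        raise AssemblyError(
            f"{circ_id}: junction does not match annotated exon boundaries "
            f"and genomic fallback is disabled"
        )

    spliced = "".join(_fetch(genome, junction.chrom, s, e) for s, e in exons)
    if junction.strand == "-":
        spliced = reverse_complement(spliced)
    return CircSequence(
        circ_id=circ_id,
        sequence=spliced,
        chrom=junction.chrom,
        start=junction.start,
        end=junction.end,
        strand=junction.strand,
        exon_structure=exons,
        transcript_id=transcript_id,
    )


def circ_fasta_header(circ: CircSequence) -> str:
    """Header convention: ``circ_id|chrom:start-end(strand)|L=<nt>``."""
    return (
        f"{circ.circ_id}|{circ.chrom}:{circ.start}-{circ.end}"
        f"({circ.strand})|L={circ.length}"
    )
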