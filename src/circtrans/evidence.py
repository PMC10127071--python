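"""Mapping peptide-spectrum matches back to circRNA ORFs.

A circle is nominated as translatable when at least one confidently
identified peptide (q-value at or below threshold) matches one of its
circRNA-unique peptides. Matching uses the same I/L-collapsed comparison
as the uniqueness filter, so the evidence chain is consistent end to end.
Every nomination is flagged for human review — the pipeline produces a
machine-readable report for curation, it never auto-accepts hits.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

from .digest import collapse_il
from .types import PeptideRecord, PSMRecord, TranslatableCircRNA

logger = logging.getLogger(__name__)


def map_psms_to_circrnas(
    psms: Sequence[PSMRecord],
    peptide_db: Sequence[PeptideRecord],
    q_threshold: float = 0.01,
    il_equivalence: bool = True,
) -> List[TranslatableCircRNA]:
    """Attach confident PSMs to circles via their unique peptides.

    PSMs with q <= threshold (PSMs without a q-value are assumed
    pre-filtered upstream and pass) whose peptide matches a
    unique-vs-reference circRNA peptide support that circle. A peptide
    matching the unique set of more than one circle supports all of them
    and is flagged ambiguous. Output is sorted by descending spectrum
    count, then circ_id.
    """
    key = collapse_il if il_equivalence else (lambda s: s)

    index: Dict[str, List[PeptideRecord]] = {}
    for pep in peptide_db:
        if not pep.unique_vs_reference or pep.parent_orf is None:
            continue
        index.setdefault(key(pep.sequence), []).append(pep)

    hits: Dict[str, TranslatableCircRNA] = {}
    for psm in psms:
        if psm.q_value is not None and psm.q_value > q_threshold:
            continue
        matches = index.get(key(psm.peptide))
        if not matches:
            continue
        circ_ids = sorted({p.parent_orf.circ_id for p in matches})
        ambiguous = len(circ_ids) > 1
        if ambiguous:
            logger.warning(
                "PSM peptide %s matches unique peptides of %d circles: %s",
                psm.peptide, len(circ_ids), circ_ids,
            )
        for pep in matches:
            circ_id = pep.parent_orf.circ_id
            rec = hits.setdefault(circ_id, TranslatableCircRNA(circ_id=circ_id))
            rec.n_spectra += 1
            if pep.sequence not in [
                p.sequence for p in rec.supporting_unique_peptides
            ]:
                rec.supporting_unique_peptides.append(pep)
            if psm.q_value is not None:
                if rec.best_q_value is None or psm.q_value < rec.best_q_value:
                    rec.best_q_value = psm.q_value
            if ambiguous and key(psm.peptide) not in rec.ambiguous_peptides:
                rec.ambiguous_peptides.append(key(psm.peptide))

    out = list(hits.values())
    out.sort(key=lambda r: (-r.n_spectra, r.circ_id))
    return out


def write_evidence_report(
    results: Sequence[TranslatableCircRNA], summary_path, detail_path=None
) -> None:
    """Summary TSV of translatable circles + per-peptide review detail.

    The detail table carries what a curator needs: peptide, junction
    span, parent ORF context, spectra counts and ambiguity flags.
    """
    with open(summary_path, "w") as fh:
        fh.write(
            "circ_id\tn_unique_peptides\tn_spectra\tbest_q_value\t"
            "flagged_for_review\tambiguous\n"
        )
        for rec in results:
            q = "" if rec.best_q_value is None else f"{rec.best_q_value:g}"
            fh.write(
                f"{rec.circ_id}\t{len(rec.supporting_unique_peptides)}\t"
                f"{rec.n_spectra}\t{q}\t{rec.flagged_for_review}\t"
                f"{bool(rec.ambiguous_peptides)}\n"
            )
    if detail_path is not None:
        with open(detail_path, "w") as fh:
            fh.write(
                "circ_id\tpeptide\tspans_junction\torf_id\torf_start\t"
                "orf_len_aa\torf_passes\tambiguous\n"
            )
            for rec in results:
                for pep in rec.supporting_unique_peptides:
                    orf = pep.parent_orf
                    fh.write(
                        f"{rec.circ_id}\t{pep.sequence}\t{pep.spans_junction}\t"
                        f"{orf.orf_id}\t{orf.start_offset}\t"
                        f"{len(orf.protein)}\t{orf.passes}\t"
                        f"{collapse_il(pep.sequence) in rec.ambiguous_peptides}\n"
                    )
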