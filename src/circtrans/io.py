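"""Readers and writers for every external format the pipeline touches.

Caller outputs come in three dialects with different coordinate
conventions: CIRI2 tables are 1-based inclusive, CIRCexplorer2 and
find_circ are BED-style 0-based half-open. Everything is normalized to
0-based half-open on the way in. Parsers stream row-wise; a malformed row
is logged and skipped unless ``strict`` is set, in which case it raises.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import OrderedDict
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .types import BackspliceJunction, GeneModel, PSMRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

# Default CIRI2 result-table columns (CIRI2 writes a commented header line).
CIRI2_COLUMNS = {
    "chrom": "chr",
    "start": "circRNA_start",
    "end": "circRNA_end",
    "strand": "strand",
    "reads": "#junction_reads",
}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class RowError(ValueError):
    """A single malformed row (carries the 1-based line number)."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def parse_ciri2(
    path: Union[str, Path],
    column_map: Optional[Dict[str, str]] = None,
    caller_id: str = "ciri2",
    strip_chr_prefix: bool = False,
    strict: bool = False,
) -> List[BackspliceJunction]:
    """Parse a CIRI2 result table (TSV, 1-based inclusive coordinates).

    Coordinates are converted to 0-based half-open: a CIRI2 row with
    circRNA_start=100, circRNA_end=200 becomes (start=99, end=200).
    """
    cols = dict(CIRI2_COLUMNS)
    if column_map:
        cols.update(column_map)
    junctions: List[BackspliceJunction] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a CIRI2 header")
        # CIRI2 prefixes its header with 'circRNA_ID'; tolerate leading '#'.
        header = [h.lstrip("#") if i == 0 else h for i, h in enumerate(header)]
        lookup = {name: i for i, name in enumerate(header)}
        required = [cols["chrom"], cols["start"], cols["end"], cols["strand"]]
        # read-count column keeps its '#': match against raw header too.
        raw_lookup = {name: i for i, name in enumerate(header)}
        missing = [c for c in required if c.lstrip("#") not in lookup
                   and c not in raw_lookup]
        if missing:
            raise FormatError(
                f"{path}: missing required CIRI2 columns {missing}; "
                f"found {header}"
            )

        def col(row: Sequence[str], name: str) -> str:
            idx = raw_lookup.get(name, lookup.get(name.lstrip("#")))
            if idx is None or idx >= len(row):
                raise ValueError(f"missing field {name!r}")
            return row[idx]

        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                chrom = col(row, cols["chrom"])
                if strip_chr_prefix and chrom.startswith("chr"):
                    chrom = chrom[3:]
                start1 = int(col(row, cols["start"]))
                end1 = int(col(row, cols["end"]))
                strand = col(row, cols["strand"])
                reads: Optional[int] = None
                try:
                    reads = int(col(row, cols["reads"]))
                except (ValueError, KeyError):
                    reads = None
                junctions.append(
                    BackspliceJunction(
                        chrom=chrom,
                        start=start1 - 1,  # 1-based inclusive -> 0-based
                        end=end1,
                        strand=strand,
                        caller_id=caller_id,
                        junction_reads=reads,
                    )
                )
            except ValueError as exc:
                err = RowError(lineno, str(exc))
                if strict:
                    raise err from exc
                logger.warning("%s: skipping malformed CIRI2 row: %s", path, err)
    return junctions


BED_DIALECTS = ("circexplorer2", "find_circ")


def parse_bed_caller(
    path: Union[str, Path],
    dialect: str,
    strip_chr_prefix: bool = False,
    strict: bool = False,
) -> List[BackspliceJunction]:
    """Parse a BED-style caller output (0-based half-open).

    ``circexplorer2`` reads the back-splice read count from column 13
    (CIRCexplorer2's readNumber field) when present, falling back to the
    BED score column; ``find_circ`` reads it from the score column.
    Rows with start >= end or strand '.' are rejected with a warning
    (circle orientation is required for translation).
    """
    if dialect not in BED_DIALECTS:
        raise FormatError(
            f"unknown BED dialect {dialect!r}; expected one of {BED_DIALECTS}"
        )
    junctions: List[BackspliceJunction] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError(f"expected >=6 BED columns, got {len(fields)}")
                chrom, start_s, end_s, _name, score_s, strand = fields[:6]
                if strip_chr_prefix and chrom.startswith("chr"):
                    chrom = chrom[3:]
                start, end = int(start_s), int(end_s)
                if start >= end:
                    raise ValueError(f"degenerate interval {start}..{end}")
                if strand == ".":
                    raise ValueError("strand '.' not allowed: orientation required")
                if dialect == "circexplorer2" and len(fields) >= 13:
                    reads = int(round(float(fields[12])))
                else:
                    reads = int(round(float(score_s)))
                junctions.append(
                    BackspliceJunction(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        caller_id=dialect,
                        junction_reads=reads,
                    )
                )
            except ValueError as exc:
                err = RowError(lineno, str(exc))
                if strict:
                    raise err from exc
                logger.warning("%s: rejecting %s row: %s", path, dialect, err)
    return junctions


def junction_to_ciri2_coords(j: BackspliceJunction) -> Tuple[int, int]:
    """Internal 0-based half-open -> CIRI2's 1-based inclusive pair."""
    return j.start + 1, j.end


def read_fasta(path: Union[str, Path]) -> "OrderedDict[str, str]":
    """Read a FASTA file into an ordered {id: sequence} mapping.

    IDs are the header up to the first whitespace. Duplicate IDs raise.
    """
    records: "OrderedDict[str, str]" = OrderedDict()
    duplicates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            duplicates.append(rec.id)
        else:
            records[rec.id] = str(rec.seq)
    if duplicates:
        raise FormatError(f"{path}: duplicate FASTA ids: {sorted(set(duplicates))}")
    return records


def write_fasta(
    records: Union[Dict[str, str], Iterable[Tuple[str, str]]],
    path: Union[str, Path],
    wrap: int = 60,
) -> None:
    """Write (id, sequence) records to FASTA with a fixed line wrap."""
    items = records.items() if isinstance(records, dict) else records
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecords)


class PSMParseResult(NamedTuple):
    records: List[PSMRecord]
    rejected: List[Tuple[int, str]]  # (line number, reason)


PSM_COLUMNS = {
    "peptide": "peptide",
    "accessions": "proteins",
    "q_value": "q_value",
    "score": "score",
}

_NON_AA = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYX]")


def parse_psm_table(
    path: Union[str, Path],
    column_map: Optional[Dict[str, str]] = None,
) -> PSMParseResult:
    """Parse a peptide-spectrum-match TSV into PSMRecords.

    Peptides are uppercased; rows with an empty peptide or non-amino-acid
    characters are rejected (returned with line number and reason, and
    logged).
    """
    cols = dict(PSM_COLUMNS)
    if column_map:
        cols.update(column_map)
    records: List[PSMRecord] = []
    rejected: List[Tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or cols["peptide"] not in reader.fieldnames:
            raise FormatError(
                f"{path}: missing peptide column {cols['peptide']!r}; "
                f"found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            raw = (row.get(cols["peptide"]) or "").strip()
            if not raw:
                rejected.append((lineno, "empty peptide"))
                continue
            peptide = raw.upper()
            bad = _NON_AA.search(peptide)
            if bad:
                rejected.append(
                    (lineno, f"non-amino-acid character {bad.group()!r}")
                )
                continue
            acc_raw = (row.get(cols["accessions"]) or "").strip()
            accessions = tuple(a for a in acc_raw.split(";") if a)
            q_value = _opt_float(row.get(cols["q_value"]))
            if q_value is not None and not (0.0 <= q_value <= 1.0):
                rejected.append((lineno, f"q_value {q_value} outside [0, 1]"))
                continue
            records.append(
                PSMRecord(
                    peptide=peptide,
                    accessions=accessions,
                    q_value=q_value,
                    score=_opt_float(row.get(cols["score"])),
                )
            )
    for lineno, reason in rejected:
        logger.warning("%s: rejected PSM row at line %d: %s", path, lineno, reason)
    return PSMParseResult(records, rejected)


def _opt_float(value: Optional[str]) -> Optional[float]:
    if value is None or value == "":
        return None
    return float(value)


def parse_gene_models(
    path: Union[str, Path],
    gene_key: str = "gene_id",
    transcript_key: str = "transcript_id",
) -> List[GeneModel]:
    """Load transcript models from a GTF/GFF3 file (via gffutils).

    Exon coordinates are converted from GTF's 1-based inclusive to the
    internal 0-based half-open convention.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: "OrderedDict[str, dict]" = OrderedDict()
    for exon in db.features_of_type("exon"):
        try:
            tid = exon.attributes[transcript_key][0]
            gid = exon.attributes[gene_key][0]
        except KeyError as exc:
            raise FormatError(
                f"{path}: exon at {exon.seqid}:{exon.start} missing "
                f"attribute {exc}"
            ) from exc
        entry = grouped.setdefault(
            tid, {"gene": gid, "chrom": exon.seqid, "strand": exon.strand,
                  "exons": []}
        )
        entry["exons"].append((exon.start - 1, exon.end))
    models = []
    for tid, entry in grouped.items():
        models.append(
            GeneModel(
                gene_id=entry["gene"],
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=tuple(sorted(entry["exons"])),
            )
        )
    return models


def write_consensus_bed(
    consensus: Sequence,
    bed_path: Union[str, Path],
    sidecar_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write consensus circles as BED6 plus a TSV sidecar of supporters.

    BED name is ``circ_<index>``; score is the total junction-read count.
    """
    with open(bed_path, "w") as fh:
        for i, rec in enumerate(consensus, start=1):
            j = rec.junction
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\tcirc_{i}\t"
                f"{rec.total_junction_reads}\t{j.strand}\n"
            )
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write("name\tchrom\tstart\tend\tstrand\tcallers\ttotal_reads\n")
            for i, rec in enumerate(consensus, start=1):
                j = rec.junction
                callers = ",".join(sorted(rec.supporting_callers))
                fh.write(
                    f"circ_{i}\t{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t"
                    f"{callers}\t{rec.total_junction_reads}\n"
                )
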