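"""Stage orchestration: consensus -> sequence -> ORFs -> peptide DB ->
PSM evidence -> (optional) PRM quantification.

One flat configuration drives every stage; the run report echoes the
configuration and the record counts in and out of each stage, mirroring
the funnel (candidate circles -> ORFs -> unique peptides -> supported
circles) a study of this kind publishes. Re-running a completed pipeline
rewrites identical output content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pyfaidx
import yaml

from . import consensus as _consensus
from . import digest  # noqa: F401
from .digest import build_peptide_db, write_peptide_report, write_search_database
from . import evidence as _evidence
from . import io as _io
from . import orf as _orf
from . import prm as _prm
from . import sequence as _sequence
from .sequence import AssemblyError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat key-value configuration for a full run."""

    # inputs
    ciri2: Optional[str] = None
    circexplorer2: Optional[str] = None
    find_circ: Optional[str] = None
    genome: Optional[str] = None
    annotation: Optional[str] = None
    proteome: Optional[str] = None
    psms: Optional[str] = None
    prm: Optional[str] = None
    outdir: str = "circtrans_out"
    # parameters
    min_callers: int = 2
    slack: int = 0
    min_aa: int = 20
    start_codons: List[str] = field(default_factory=lambda: ["ATG"])
    max_missed: int = 2
    il_equivalence: bool = True
    min_peptide_len: int = 7
    max_peptide_len: int = 52
    q_threshold: float = 0.01
    strip_chr_prefix: bool = False
    strict: bool = False
    seed: int = 0
    prm_group_a: List[str] = field(default_factory=list)
    prm_group_b: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if self.slack < 0:
            raise ValueError("slack must be >= 0")
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if not (0 < self.min_peptide_len <= self.max_peptide_len):
            raise ValueError("need 0 < min_peptide_len <= max_peptide_len")
        if not (0.0 <= self.q_threshold <= 1.0):
            raise ValueError("q_threshold must lie in [0, 1]")
        for codon in self.start_codons:
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ValueError(f"invalid start codon {codon!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require_inputs(config: PipelineConfig, names: List[str]) -> None:
    missing = []
    for name in names:
        path = getattr(config, name)
        if path is None:
            missing.append(f"{name} (not configured)")
        elif not Path(path).exists():
            missing.append(f"{name} ({path} does not exist)")
    if missing:
        raise PipelineError("inputs", "missing inputs: " + "; ".join(missing))


def _load_genome(path: str):
    try:
        return pyfaidx.Fasta(path)
    except Exception:
        # uncompressed small genomes also work as a plain mapping
        return _io.read_fasta(path)


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage in order; returns the run report.

    Record counts of each stage land in the report; intermediate files
    are persisted under ``config.outdir``. A stage failure raises
    PipelineError with partial outputs retained.
    """
    caller_inputs = [n for n in ("ciri2", "circexplorer2", "find_circ")
                     if getattr(config, n) is not None]
    required = caller_inputs + ["genome", "annotation", "proteome", "psms"]
    _require_inputs(config, required)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    # --- consensus ---------------------------------------------------
    try:
        calls = []
        if config.ciri2:
            calls.extend(_io.parse_ciri2(
                config.ciri2, strip_chr_prefix=config.strip_chr_prefix,
                strict=config.strict))
        if config.circexplorer2:
            calls.extend(_io.parse_bed_caller(
                config.circexplorer2, "circexplorer2",
                strip_chr_prefix=config.strip_chr_prefix,
                strict=config.strict))
        if config.find_circ:
            calls.extend(_io.parse_bed_caller(
                config.find_circ, "find_circ",
                strip_chr_prefix=config.strip_chr_prefix,
                strict=config.strict))
        chrom_names = {c.chrom for c in calls}
        prefixed = {c for c in chrom_names if c.startswith("chr")}
        if prefixed and prefixed != chrom_names:
            logger.warning(
                "mixed chromosome naming across callers: %s",
                sorted(chrom_names),
            )
        consensus = _consensus.build_consensus(
            calls, min_callers=config.min_callers, slack=config.slack
        )
        _io.write_consensus_bed(
            consensus, outdir / "consensus.bed", outdir / "consensus_callers.tsv"
        )
        report["stages"]["consensus"] = {
            "calls_in": len(calls),
            "circles_out": len(consensus),
        }
    except PipelineError:
        raise
    except Exception as exc:
        report["stages"]["consensus"] = {"error": str(exc)}
        _write_report(report, outdir)
        raise PipelineError("consensus", str(exc)) from exc

    # --- sequence assembly -------------------------------------------
    try:
        genome = _load_genome(config.genome)
        models = _io.parse_gene_models(config.annotation)
        circles = []
        n_failed = 0
        for rec in consensus:
            try:
                circles.append(
                    _sequence.assemble_circ_sequence(rec.junction, genome,
                                                     models)
                )
            except AssemblyError as exc:
                n_failed += 1
                logger.warning("skipping circle: %s", exc)
        _io.write_fasta(
            [(_sequence.circ_fasta_header(c), c.sequence) for c in circles],
            outdir / "circles.fa",
        )
        report["stages"]["sequence"] = {
            "circles_in": len(consensus),
            "assembled": len(circles),
            "failed": n_failed,
        }
    except Exception as exc:
        report["stages"]["sequence"] = {"error": str(exc)}
        _write_report(report, outdir)
        raise PipelineError("sequence", str(exc)) from exc

    # --- ORF prediction ----------------------------------------------
    try:
        orfs = []
        for circ in circles:
            orfs.extend(
                _orf.find_circular_orfs(
                    circ,
                    min_aa=config.min_aa,
                    start_codons=frozenset(config.start_codons),
                )
            )
        _io.write_fasta(
            [(_orf.orf_fasta_header(o), o.protein) for o in orfs],
            outdir / "orfs.fa",
        )
        with open(outdir / "orfs.tsv", "w") as fh:
            fh.write(
                "circ_id\torf_id\tstart\tlen_aa\tpasses\tjunction_spanning\t"
                "termination\n"
            )
            for o in orfs:
                fh.write(
                    f"{o.circ_id}\t{o.orf_id}\t{o.start_offset}\t"
                    f"{len(o.protein)}\t{o.passes}\t{o.junction_spanning}\t"
                    f"{o.termination}\n"
                )
        report["stages"]["orfs"] = {
            "circles_in": len(circles),
            "orfs_out": len(orfs),
            "junction_spanning": sum(1 for o in orfs if o.junction_spanning),
        }
    except Exception as exc:
        report["stages"]["orfs"] = {"error": str(exc)}
        _write_report(report, outdir)
        raise PipelineError("orfs", str(exc)) from exc

    # --- peptide DB ---------------------------------------------------
    try:
        reference = _io.read_fasta(config.proteome)
        unique_peptides = build_peptide_db(
            orfs,
            reference,
            max_missed=config.max_missed,
            il_equivalence=config.il_equivalence,
            min_len=config.min_peptide_len,
            max_len=config.max_peptide_len,
        )
        write_peptide_report(unique_peptides,
                                     outdir / "unique_peptides.tsv")
        n_db = write_search_database(
            orfs, reference, outdir / "search_db.fa"
        )
        report["stages"]["peptide_db"] = {
            "orfs_in": len(orfs),
            "unique_peptides": len(unique_peptides),
            "search_db_entries": n_db,
        }
    except Exception as exc:
        report["stages"]["peptide_db"] = {"error": str(exc)}
        _write_report(report, outdir)
        raise PipelineError("peptide_db", str(exc)) from exc

    # --- PSM evidence -------------------------------------------------
    try:
        psm_result = _io.parse_psm_table(config.psms)
        translatable = _evidence.map_psms_to_circrnas(
            psm_result.records,
            unique_peptides,
            q_threshold=config.q_threshold,
            il_equivalence=config.il_equivalence,
        )
        _evidence.write_evidence_report(
            translatable,
            outdir / "translatable_circrnas.tsv",
            outdir / "evidence_detail.tsv",
        )
        report["stages"]["evidence"] = {
            "psms_in": len(psm_result.records),
            "psms_rejected": len(psm_result.rejected),
            "translatable_circles": len(translatable),
        }
        report["translatable_circ_ids"] = [t.circ_id for t in translatable]
    except Exception as exc:
        report["stages"]["evidence"] = {"error": str(exc)}
        _write_report(report, outdir)
        raise PipelineError("evidence", str(exc)) from exc

    # --- PRM (optional) ----------------------------------------------
    if config.prm:
        try:
            measurements = _prm.read_prm_table(config.prm)
            ratios = _prm.quantify_all(measurements)
            comparisons = None
            if config.prm_group_a and config.prm_group_b:
                comparisons = _prm.compare_conditions(
                    ratios, config.prm_group_a, config.prm_group_b
                )
            _prm.write_prm_report(
                ratios, outdir / "prm_ratios.tsv", comparisons,
                outdir / "prm_comparisons.tsv",
            )
            report["stages"]["prm"] = {
                "measurements": len(measurements),
                "peptides": int(ratios["peptide"].nunique()),
            }
        except Exception as exc:
            report["stages"]["prm"] = {"error": str(exc)}
            _write_report(report, outdir)
            raise PipelineError("prm", str(exc)) from exc

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")
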