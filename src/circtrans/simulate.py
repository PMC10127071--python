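"""Seed-deterministic synthetic fixtures with known ground truth.

The generator emulates the shape of a translatable-circRNA study without
any raw reads or spectra: a small random genome with planted multi-exon
genes, circles whose sole ORF has a designed length and termination
behaviour (single-pass, rolling-circle, or periodic/never-terminating),
caller output files written in each tool's native coordinate dialect,
a PSM table mixing circRNA-unique, reference-only and decoy rows, and a
PRM transition table with a known endogenous/heavy ratio under
multiplicative lognormal noise.

Everything derives from one integer seed; the manifest records every
planted fact so each pipeline stage can be checked against ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import reverse_complement

from .digest import build_peptide_db, collapse_il
from .digest import digest as digest_protein
from . import orf as _orf
from .types import CircSequence

STOP_CODONS = ("TAA", "TAG", "TGA")
CALLERS = ("ciri2", "circexplorer2", "find_circ")

# residue pool for random reference proteins; K/R enriched so tryptic
# digestion yields MS-sized peptides
_AA_POOL = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = np.array(
    [7, 2, 5, 6, 4, 7, 2, 5, 7, 9, 2, 4, 5, 4, 7, 7, 6, 6, 1, 3], float
)
_AA_WEIGHTS /= _AA_WEIGHTS.sum()


def _rand_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA_POOL), size=n, p=_AA_WEIGHTS))


# ---------------------------------------------------------------------------
# circle design


def plant_circle_with_orf(
    rng: np.random.Generator,
    kind: str,
    L: int,
    target_aa: Optional[int] = None,
    max_iter: int = 20000,
) -> str:
    """Design a circle whose sole ATG-initiated ORF has a known length.

    kinds:
      single_pass — stop within the first pass (3*target_aa + 3 <= L)
      rolling     — L % 3 != 0, coding crosses the junction
                    (L < 3*target_aa + 3 and target_aa <= L - 1)
      infinite    — no stop within one frame period; the ORF never
                    terminates

    The start codon sits at offset 0; for terminating kinds the stop is
    placed at coding offset 3*target_aa. Remaining bases start random and
    are repaired by seeded single-base mutations until no premature
    in-frame stop and no second ATG (in any frame, junction windows
    included) remain. Raises on infeasible requests or non-convergence.
    """
    if L < 6:
        raise ValueError(f"circle length {L} too small to design")
    period = 1 if L % 3 == 0 else 3
    if kind == "single_pass":
        if target_aa is None or 3 * target_aa + 3 > L:
            raise ValueError(
                f"single_pass needs 3*target_aa+3 <= L (aa={target_aa}, L={L})"
            )
    elif kind == "rolling":
        if target_aa is None:
            raise ValueError("rolling requires target_aa")
        if L % 3 == 0:
            raise ValueError("rolling requires L % 3 != 0")
        if not (L < 3 * target_aa + 3):
            raise ValueError("rolling requires 3*target_aa + 3 > L")
        if target_aa > L - 1:
            raise ValueError(
                f"target {target_aa} aa exceeds the L-1 bound for L={L}"
            )
    elif kind == "infinite":
        target_aa = period * L // 3
    else:
        raise ValueError(f"unknown circle kind {kind!r}")

    required: Dict[int, str] = {0: "A", 1: "T", 2: "G"}
    if kind != "infinite":
        placed = False
        for stop in rng.permutation(STOP_CODONS):
            pos_map = {(3 * target_aa + i) % L: stop[i] for i in range(3)}
            if all(required.get(p, b) == b for p, b in pos_map.items()):
                required.update(pos_map)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"no stop codon placeable at coding offset {3 * target_aa} "
                f"on a circle of length {L}"
            )

    # stop codons all begin with T, so a near-T-free start helps the
    # dense 'infinite' constraint set converge immediately
    init_alphabet = "ACG" if kind == "infinite" else "ACGT"
    bases = list(_rand_dna(rng, L, init_alphabet))
    for p, b in required.items():
        bases[p] = b
    protected = set(required)

    if kind == "infinite":
        nonstop_starts = {(3 * k) % L for k in range(1, period * L // 3)}
    else:
        nonstop_starts = {(3 * k) % L for k in range(1, target_aa)}
    nonstop_starts.discard(0)

    def window(p: int) -> str:
        return bases[p] + bases[(p + 1) % L] + bases[(p + 2) % L]

    def first_violation() -> Optional[int]:
        for p in range(L):
            w = window(p)
            if p != 0 and w == "ATG":
                return p
            if p in nonstop_starts and w in STOP_CODONS:
                return p
        return None

    for _ in range(max_iter):
        p = first_violation()
        if p is None:
            break
        mutable = [q for q in (p, (p + 1) % L, (p + 2) % L)
                   if q not in protected]
        if not mutable:
            raise ValueError(
                f"circle design infeasible: constrained window at {p} "
                f"violates the ORF plan"
            )
        q = mutable[int(rng.integers(len(mutable)))]
        choices = [b for b in "ACGT" if b != bases[q]]
        bases[q] = choices[int(rng.integers(len(choices)))]
    else:
        raise RuntimeError("circle design did not converge")

    seq = "".join(bases)
    _verify_design(seq, kind, target_aa)
    return seq


def _verify_design(seq: str, kind: str, target_aa: int) -> None:
    """Independent check of the designed circle's ORF structure."""
    L = len(seq)
    doubled = seq + seq
    atg_positions = [p for p in range(L) if doubled[p:p + 3] == "ATG"]
    if atg_positions != [0]:
        raise RuntimeError(f"design check failed: ATGs at {atg_positions}")
    period = 1 if L % 3 == 0 else 3
    n_codons = period * L // 3
    first_stop = None
    for k in range(n_codons):
        p = (3 * k) % L
        if doubled[p:p + 3] in STOP_CODONS:
            first_stop = k
            break
    if kind == "infinite":
        if first_stop is not None:
            raise RuntimeError("design check failed: unexpected stop")
    elif first_stop != target_aa:
        raise RuntimeError(
            f"design check failed: first stop at codon {first_stop}, "
            f"wanted {target_aa}"
        )


# ---------------------------------------------------------------------------
# study planning


DEFAULT_KIND_CYCLE = ("rolling", "single_pass", "rolling", "infinite",
                      "single_pass")


def plan_study(
    seed: int,
    n_circles: int = 30,
    n_reference_proteins: int = 40,
    translated_fraction: float = 0.6,
    prm_true_ratio: float = 0.5,
    prm_cv: float = 0.10,
    prm_samples_per_group: int = 3,
    prm_transitions: int = 4,
) -> dict:
    """Plan a full synthetic study; returns the serializable manifest.

    The first planted circle reproduces the structure of the study's
    flagship case: a 322-nt rolling-circle circle encoding a 161-aa
    protein. The rest cycle through single-pass, rolling and
    never-terminating designs on alternating strands. Caller membership
    is drawn with a realistic agreement profile (about half of the
    circles seen by all three tools, the rest by two or one), and a
    random subset of the consensus, stop-terminating circles is planted
    with supporting PSMs — those are the study's ground-truth
    translatable circles.
    """
    rng = np.random.default_rng([int(seed), 0])

    circles: List[dict] = []
    for i in range(n_circles):
        if i == 0:
            kind, L, target = "rolling", 322, 161
        else:
            kind = DEFAULT_KIND_CYCLE[i % len(DEFAULT_KIND_CYCLE)]
            if kind == "single_pass":
                target = int(rng.integers(25, 61))
                L = 3 * target + 3 + int(rng.integers(12, 40))
            elif kind == "rolling":
                target = int(rng.integers(40, 121))
                L = 2 * target + 1 + int(rng.integers(0, 2))
                while L % 3 == 0:
                    L += 1
            else:  # infinite
                L = int(rng.integers(60, 151))
                if L % 3 == 0:
                    L += 1
                target = None
        seq = plant_circle_with_orf(rng, kind, L, target)
        strand = "+" if i % 2 == 0 else "-"
        circles.append(
            {
                "name": f"planted_{i + 1:03d}",
                "kind": kind,
                "L": L,
                "target_aa": target,
                "strand": strand,
                "sequence": seq,
            }
        )

    # caller membership: ~50% all three, ~35% exactly two, rest one
    for circ in circles:
        u = rng.random()
        if u < 0.50:
            members = list(CALLERS)
        elif u < 0.85:
            members = sorted(
                str(c) for c in rng.choice(CALLERS, size=2, replace=False)
            )
        else:
            members = [str(rng.choice(CALLERS))]
        circ["callers"] = list(members)
        circ["reads"] = {
            c: int(rng.integers(10, 150)) for c in circ["callers"]
        }

    _place_genes(rng, circles)
    manifest: dict = {
        "seed": int(seed),
        "n_circles": n_circles,
        "circles": circles,
        "chrom_lengths": _chrom_lengths(circles),
    }

    manifest["reference_proteins"] = {
        f"sp|REF{i + 1:04d}|SYN": _rand_protein(rng, int(rng.integers(120, 301)))
        for i in range(n_reference_proteins)
    }

    _plan_proteogenomics(rng, manifest, translated_fraction)
    _plan_prm(rng, manifest, prm_true_ratio, prm_cv,
              prm_samples_per_group, prm_transitions)
    return manifest


def _place_genes(rng: np.random.Generator, circles: List[dict]) -> None:
    """Embed each circle in a 4-exon gene on one of two chromosomes."""
    cursors = {"chr1": 150, "chr2": 150}
    for i, circ in enumerate(circles):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        seq, strand = circ["sequence"], circ["strand"]
        half = len(seq) // 2
        t_exons = [
            _rand_dna(rng, int(rng.integers(40, 80))),  # t1, upstream
            seq[:half],                                 # t2, circle 5' part
            seq[half:],                                 # t3, circle 3' part
            _rand_dna(rng, int(rng.integers(40, 80))),  # t4, downstream
        ]
        introns = [_rand_dna(rng, int(rng.integers(70, 150)))
                   for _ in range(3)]
        if strand == "+":
            genomic_seqs = t_exons
        else:
            genomic_seqs = [reverse_complement(s) for s in reversed(t_exons)]
        pos = cursors[chrom]
        intervals = []
        for j, es in enumerate(genomic_seqs):
            intervals.append((pos, pos + len(es)))
            pos += len(es)
            if j < 3:
                pos += len(introns[j])
        # circle spans the two middle genomic exons on either strand
        start = intervals[1][0]
        end = intervals[2][1]
        circ.update(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "circ_id": f"{chrom}:{start}-{end}({strand})",
                "gene_id": f"gene_{i + 1:03d}",
                "transcript_id": f"tx_{i + 1:03d}",
                "exon_intervals": intervals,
                "exon_seqs_genomic": genomic_seqs,
                "intron_seqs": introns,
            }
        )
        cursors[chrom] = pos + int(rng.integers(120, 300))


def _chrom_lengths(circles: Sequence[dict]) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    for circ in circles:
        last = circ["exon_intervals"][-1][1]
        lengths[circ["chrom"]] = max(lengths.get(circ["chrom"], 0), last + 200)
    return lengths


def _circle_orf(circ: dict) -> "_orf.CircORF":
    cs = CircSequence(circ_id=circ["circ_id"], sequence=circ["sequence"])
    orfs = _orf.find_circular_orfs(cs, min_aa=1)
    assert len(orfs) == 1, f"planted circle {circ['name']} has {len(orfs)} ORFs"
    return orfs[0]


def _plan_proteogenomics(
    rng: np.random.Generator, manifest: dict, translated_fraction: float
) -> None:
    """Choose the ground-truth translated circles and build the PSM rows."""
    circles = manifest["circles"]
    reference = manifest["reference_proteins"]

    consensus_ids = sorted(
        c["circ_id"] for c in circles if len(c["callers"]) >= 2
    )
    manifest["consensus_ids"] = consensus_ids

    # candidates: consensus circles with a terminating ORF and >=1 unique
    # peptide mapping to them alone
    unique_by_circle: Dict[str, List[str]] = {}
    seen_everywhere: Dict[str, List[str]] = {}
    orf_by_circle = {}
    for circ in circles:
        if circ["kind"] == "infinite":
            continue
        orf = _circle_orf(circ)
        orf_by_circle[circ["circ_id"]] = orf
        circ["protein"] = orf.protein
        peptides = build_peptide_db([orf], reference, max_missed=2)
        for pep in peptides:
            key = collapse_il(pep.sequence)
            seen_everywhere.setdefault(key, []).append(circ["circ_id"])
            unique_by_circle.setdefault(circ["circ_id"], []).append(
                pep.sequence
            )

    def unambiguous(circ_id: str) -> List[str]:
        return sorted(
            p for p in unique_by_circle.get(circ_id, [])
            if len(set(seen_everywhere[collapse_il(p)])) == 1
        )

    candidates = [cid for cid in consensus_ids if unambiguous(cid)]
    n_translated = max(1, int(round(translated_fraction * len(candidates))))
    chosen = sorted(
        rng.choice(candidates, size=min(n_translated, len(candidates)),
                   replace=False).tolist()
    )
    manifest["translated_ids"] = chosen

    psms: List[dict] = []
    for cid in chosen:
        peptides = unambiguous(cid)
        picks = peptides[: int(rng.integers(1, min(2, len(peptides)) + 1))]
        for pep in picks:
            for _ in range(int(rng.integers(1, 4))):
                psms.append(
                    {
                        "peptide": pep,
                        "proteins": f"CIRC|{cid}",
                        "q_value": round(float(rng.uniform(1e-4, 5e-3)), 6),
                        "score": round(float(rng.uniform(80, 160)), 2),
                        "kind": "circ_unique",
                        "circ_id": cid,
                    }
                )

    # reference-only PSMs: real tryptic peptides of reference proteins
    ref_items = sorted(reference.items())
    for acc, protein in ref_items[:6]:
        products = digest_protein(protein, max_missed=0)
        usable = [p.sequence for p in products if 7 <= len(p.sequence) <= 30]
        for pep in usable[:2]:
            psms.append(
                {
                    "peptide": pep,
                    "proteins": acc,
                    "q_value": round(float(rng.uniform(1e-4, 5e-3)), 6),
                    "score": round(float(rng.uniform(80, 160)), 2),
                    "kind": "reference",
                    "circ_id": None,
                }
            )

    # decoys absent from both databases, with failing q-values
    haystack = "\n".join(
        collapse_il(s)
        for s in list(reference.values())
        + [c.get("protein", "") for c in circles]
    )
    n_decoys = 0
    while n_decoys < 5:
        pep = _rand_protein(rng, int(rng.integers(9, 18)))
        if collapse_il(pep) in haystack:
            continue
        psms.append(
            {
                "peptide": pep,
                "proteins": "DECOY",
                "q_value": round(float(rng.uniform(0.05, 0.3)), 6),
                "score": round(float(rng.uniform(10, 40)), 2),
                "kind": "decoy",
                "circ_id": None,
            }
        )
        n_decoys += 1
    manifest["psms"] = psms


def simulate_prm_rows(
    rng: np.random.Generator,
    peptide: str,
    sample: str,
    true_ratio: float,
    cv: float,
    n_transitions: int = 4,
    heavy_scale: Tuple[float, float] = (1e5, 1e6),
) -> List[dict]:
    """Transition rows for one peptide in one sample.

    Heavy areas are uniform on ``heavy_scale``; light = heavy * ratio *
    a multiplicative lognormal factor with coefficient of variation
    ``cv`` (sigma = sqrt(ln(1 + cv^2)); cv=0 gives exact ratios).
    """
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    rows = []
    for t in range(n_transitions):
        heavy = float(rng.uniform(*heavy_scale))
        noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
        light = heavy * true_ratio * noise
        rows.append(
            {
                "peptide": peptide,
                "sample": sample,
                "fragment": f"y{t + 3}",
                "light_area": round(light, 3),
                "heavy_area": round(heavy, 3),
            }
        )
    return rows


def _plan_prm(
    rng: np.random.Generator,
    manifest: dict,
    true_ratio: float,
    cv: float,
    samples_per_group: int,
    n_transitions: int,
) -> None:
    """PRM table: group A at ratio 1.0, group B at the configured ratio."""
    peptides = []
    for psm in manifest["psms"]:
        if psm["kind"] == "circ_unique" and psm["peptide"] not in peptides:
            peptides.append(psm["peptide"])
        if len(peptides) >= 3:
            break
    groups = {
        "wt": [f"wt_{i + 1}" for i in range(samples_per_group)],
        "ko": [f"ko_{i + 1}" for i in range(samples_per_group)],
    }
    ratios = {"wt": 1.0, "ko": float(true_ratio)}
    rows: List[dict] = []
    for pep in peptides:
        for group, samples in groups.items():
            for sample in samples:
                rows.extend(
                    simulate_prm_rows(
                        rng, pep, sample, ratios[group], cv, n_transitions
                    )
                )
    manifest["prm"] = {
        "true_ratios": ratios,
        "cv": cv,
        "groups": groups,
        "n_transitions": n_transitions,
        "rows": rows,
    }


# ---------------------------------------------------------------------------
# fixture emission


def generate_genome_and_annotation(manifest: dict, outdir) -> None:
    """Write genome.fa and genes.gtf from the planted gene plan.

    Background bases are drawn from a generator seeded by the manifest
    seed, so regeneration from the same manifest is byte-identical.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng([int(manifest["seed"]), 1])
    chrom_seqs = {
        chrom: list(_rand_dna(rng, length))
        for chrom, length in sorted(manifest["chrom_lengths"].items())
    }
    for circ in manifest["circles"]:
        chrom = chrom_seqs[circ["chrom"]]
        for (s, e), seq in zip(circ["exon_intervals"],
                               circ["exon_seqs_genomic"]):
            chrom[s:e] = list(seq)
        # introns too, so divergent designs cannot collide by chance
        for j, intron in enumerate(circ["intron_seqs"]):
            s = circ["exon_intervals"][j][1]
            chrom[s:s + len(intron)] = list(intron)

    from .io import write_fasta

    write_fasta(
        [(chrom, "".join(seq)) for chrom, seq in sorted(chrom_seqs.items())],
        outdir / "genome.fa",
    )

    with open(outdir / "genes.gtf", "w") as fh:
        for circ in manifest["circles"]:
            gid, tid = circ["gene_id"], circ["transcript_id"]
            strand = circ["strand"]
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            for s, e in circ["exon_intervals"]:
                fh.write(
                    f"{circ['chrom']}\tcirctrans_sim\texon\t{s + 1}\t{e}\t."
                    f"\t{strand}\t.\t{attrs}\n"
                )


def emit_caller_files(manifest: dict, outdir) -> None:
    """Write ciri2.tsv, ce2.bed and findcirc.bed in native dialects.

    CIRI2 coordinates are written 1-based inclusive; the BED files
    0-based half-open — deliberately un-normalized, so the parsers'
    off-by-one handling is exercised.
    """
    outdir = Path(outdir)
    circles = manifest["circles"]

    with open(outdir / "ciri2.tsv", "w") as fh:
        fh.write(
            "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
            "circRNA_type\tgene_id\tstrand\n"
        )
        for circ in circles:
            if "ciri2" not in circ["callers"]:
                continue
            fh.write(
                f"{circ['chrom']}:{circ['start'] + 1}|{circ['end']}\t"
                f"{circ['chrom']}\t{circ['start'] + 1}\t{circ['end']}\t"
                f"{circ['reads']['ciri2']}\texon\t{circ['gene_id']}\t"
                f"{circ['strand']}\n"
            )

    with open(outdir / "ce2.bed", "w") as fh:
        for circ in circles:
            if "circexplorer2" not in circ["callers"]:
                continue
            s, e = circ["start"], circ["end"]
            fh.write(
                f"{circ['chrom']}\t{s}\t{e}\tcircular_RNA/{circ['name']}\t0\t"
                f"{circ['strand']}\t{s}\t{e}\t0,0,0\t2\t100,100\t0,100\t"
                f"{circ['reads']['circexplorer2']}\n"
            )

    with open(outdir / "findcirc.bed", "w") as fh:
        for circ in circles:
            if "find_circ" not in circ["callers"]:
                continue
            fh.write(
                f"{circ['chrom']}\t{circ['start']}\t{circ['end']}\t"
                f"{circ['name']}\t{circ['reads']['find_circ']}\t"
                f"{circ['strand']}\n"
            )


def emit_psm_and_prm_tables(manifest: dict, outdir) -> None:
    """Write proteome.fa, psms.tsv and prm.csv from the manifest plan."""
    outdir = Path(outdir)
    from .io import write_fasta

    write_fasta(
        sorted(manifest["reference_proteins"].items()),
        outdir / "proteome.fa",
    )

    with open(outdir / "psms.tsv", "w") as fh:
        fh.write("peptide\tproteins\tq_value\tscore\n")
        for psm in manifest["psms"]:
            fh.write(
                f"{psm['peptide']}\t{psm['proteins']}\t{psm['q_value']}\t"
                f"{psm['score']}\n"
            )

    with open(outdir / "prm.csv", "w") as fh:
        fh.write("peptide,sample,fragment,light_area,heavy_area\n")
        for row in manifest["prm"]["rows"]:
            fh.write(
                f"{row['peptide']},{row['sample']},{row['fragment']},"
                f"{row['light_area']},{row['heavy_area']}\n"
            )


def write_fixtures(manifest: dict, outdir) -> None:
    """Emit every fixture file plus manifest.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    generate_genome_and_annotation(manifest, outdir)
    emit_caller_files(manifest, outdir)
    emit_psm_and_prm_tables(manifest, outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=False)
        fh.write("\n")


def simulate_study(seed: int, n_circles: int = 30, outdir=None, **kwargs) -> dict:
    """Plan a study and (optionally) write its fixture directory."""
    manifest = plan_study(seed, n_circles=n_circles, **kwargs)
    if outdir is not None:
        write_fixtures(manifest, outdir)
    return manifest
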