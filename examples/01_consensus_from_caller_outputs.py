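"""Consensus back-splice calling from three circRNA callers.

Builds a tiny synthetic study, parses each caller's file in its native
coordinate dialect (CIRI2 is 1-based inclusive; the BED callers are
0-based half-open), and keeps circles reported by at least 2 of the 3
tools.
"""

import tempfile
from pathlib import Path

from circtrans import build_consensus, parse_bed_caller, parse_ciri2
from circtrans.simulate import simulate_study

with tempfile.TemporaryDirectory() as tmp:
    fixture = Path(tmp)
    manifest = simulate_study(seed=1, n_circles=10, outdir=fixture)

    calls = (
        parse_ciri2(fixture / "ciri2.tsv")
        + parse_bed_caller(fixture / "ce2.bed", "circexplorer2")
        + parse_bed_caller(fixture / "findcirc.bed", "find_circ")
    )
    consensus = build_consensus(calls, min_callers=2)

print(f"{len(calls)} caller rows -> {len(consensus)} consensus circles")
for rec in consensus[:5]:
    j = rec.junction
    print(
        f"  {j.chrom}:{j.start}-{j.end}({j.strand})  "
        f"callers={sorted(rec.supporting_callers)}  "
        f"reads={rec.total_junction_reads}"
    )
# Each line is one circle seen by >=2 independent tools; 'reads' sums the
# back-splice read support each caller contributed. Circles reported by a
# single tool are dropped as likely artifacts.
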