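"""circRNA-unique peptide database construction.

Digests a predicted circle protein with trypsin in silico, removes every
peptide that also occurs in the reference proteome (with isobaric I/L
collapsed), and writes the combined MS search database.
"""

import tempfile
from pathlib import Path

import numpy as np

from circtrans import build_peptide_db, find_circular_orfs, write_search_database
from circtrans.simulate import plant_circle_with_orf
from circtrans.types import CircSequence

# a rolling-circle circle: 100 nt encoding a 40-aa junction-spanning ORF
rng = np.random.default_rng(5)
circ = CircSequence(
    circ_id="chr1:100-200(+)",
    sequence=plant_circle_with_orf(rng, "rolling", L=100, target_aa=40),
)
orfs = find_circular_orfs(circ, min_aa=10)
protein = orfs[0].protein
reference = {
    "sp|Q00001|SYN": "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGEEHFK",
    # shares its first tryptic peptide with the ORF -> that one is removed
    "sp|Q00002|SYN": protein[:12],
}

peptides = build_peptide_db(orfs, reference, max_missed=2, min_len=7)
print(f"{len(orfs)} ORF(s) digested -> {len(peptides)} circRNA-unique peptides")
for pep in peptides[:8]:
    print(f"  {pep.sequence:<30} junction={pep.spans_junction} "
          f"missed={pep.missed_cleavages}")

with tempfile.TemporaryDirectory() as tmp:
    db = Path(tmp) / "search_db.fa"
    n = write_search_database(orfs, reference, db)
    print(f"search database: {n} entries "
          f"({len(reference)} reference + {n - len(reference)} CIRC|)")
# Peptides also present in the reference proteome are removed: only the
# survivors can serve as evidence that the circle itself is translated.
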