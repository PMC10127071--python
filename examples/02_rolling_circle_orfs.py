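"""Rolling-circle ORF prediction on a 322-nt circle.

On a circle whose length is not a multiple of 3, the reading frame
shifts at every pass across the back-splice junction, so translation can
run longer than one lap: a 322-nt circle can encode a 161-aa protein
(161 * 3 = 483 nt > 322 nt). This script designs such a circle and
predicts its ORF.
"""

import numpy as np

from circtrans import find_circular_orfs
from circtrans.simulate import plant_circle_with_orf
from circtrans.types import CircSequence

rng = np.random.default_rng(0)
seq = plant_circle_with_orf(rng, kind="rolling", L=322, target_aa=161)
circ = CircSequence(circ_id="demo_circle", sequence=seq)

(orf,) = find_circular_orfs(circ, min_aa=20)
print(f"circle length       : {circ.length} nt (322 mod 3 = {322 % 3})")
print(f"protein length      : {len(orf.protein)} aa")
print(f"coding length       : {orf.coding_length} nt")
print(f"junction crossings  : {orf.passes}")
print(f"junction-spanning   : {orf.junction_spanning}")
print(f"termination         : {orf.termination}")
print(f"protein (first 40)  : {orf.protein[:40]}...")
# The coding region (483 nt) exceeds the circle (322 nt), so translation
# crosses the junction once before reaching its stop codon: this is the
# rolling-circle mechanism, and the junction-spanning protein region is
# what makes the product provably circRNA-derived.
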