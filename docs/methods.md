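# Methods

## Coordinate model

Every genomic interval inside the package is 0-based half-open
`[start, end)`. CIRI2 tables are converted from 1-based inclusive on
input (`start - 1`, `end` unchanged); CIRCexplorer2 and find_circ BED
files are already half-open. Conversion back to CIRI2's convention is the
exact inverse, so round trips are the identity. Chromosome-name
normalization (stripping a `chr` prefix) is available but off by
default; mixed naming across callers is reported, never silently fixed.
Parsers stream row-wise and skip malformed rows with a logged line
number; `strict=True` turns any malformed row into an error. BED rows
with strand `.` are rejected because circle orientation decides the
coding strand.

## Consensus calling

Circle identity is `(chrom, start, end, strand)`; strand is part of the
key because sense and antisense circles are distinct molecules. A caller
counts once per circle regardless of duplicate rows (its best-supported
row is used); circles backed by at least `min_callers` tools (default 2)
are kept. By default boundaries must match exactly: no tolerance is
assumed where none is established, and exact matching is reproducible.
An optional `slack` (nt) enables greedy complete-linkage clustering per
chrom/strand over sorted calls, so all pairwise boundary differences in
a cluster stay within the tolerance and the result does not depend on
input order. Canonical cluster coordinates come from the highest-read
call, ties broken by smallest `(start, end)` — determinism is required
for testing, and read support is the natural vote.

## Circle sequence assembly

A junction whose boundaries coincide with annotated exon boundaries is
spliced from the matching transcript: exons inside `[start, end)` are
concatenated in genomic order and reverse-complemented for minus-strand
circles. When several transcripts match both boundaries, the one with
most exons inside the span wins, then the lexicographically smallest
transcript id — any rule would be defensible; this one is deterministic
and favours the most complete exon chain. If no transcript matches, the
unspliced genomic span is used with a warning (or an error when the
fallback is disabled). Offset 0 of the circle is fixed at the
acceptor-side base (start of the most upstream included exon in
transcript orientation): every rotation of a circle is biologically
equivalent, but one must be pinned for reproducible ORF coordinates.
`N` bases are allowed; codons containing `N` translate to `X` and never
count as stop, so ambiguity cannot fabricate a termination.

## Circular ORF prediction

Translation is defined on the infinite repetition of the circle. For a
circle of length *L*, the reading frame at a given offset recurs after
*P* passes, with *P* = 1 when *L* mod 3 = 0 and *P* = 3 otherwise
(3 and *L* are then coprime). Scanning *P·L* nt from a start codon
therefore decides every ORF: a stop inside the window terminates the
ORF; no stop means the ORF is periodic and can never terminate
(`termination="none"`), and its protein is reported truncated at *P·L*
nt. Consequences used as test oracles:

* a stop-terminated ORF satisfies `|protein| <= L - 1` when
  *L* mod 3 ≠ 0 and `|protein| <= L/3 - 1` when *L* mod 3 = 0 (the stop
  consumes one codon of the window); a truncated periodic ORF has
  exactly *P·L*/3 residues;
* every stop-terminated ORF equals a conventional linear ORF scan of the
  circle repeated *P* + 1 times (the extra copy supplies complete codons
  at the window edge);
* the protein multiset is invariant under rotation of the circle
  representation, with start offsets shifting by −*r* mod *L*.

All ATG occurrences are candidate starts; selecting e.g. the longest
junction-spanning ORF per circle is a policy layered on top
(`select_longest_junction_spanning`), not baked into the finder.
Near-cognate starts are out of scope, but the start-codon set is a
parameter. `passes` counts crossings of circle offset 0 by translated
codons; the stop codon is excluded from this count — either convention
is defensible, coding-residues-only is used and documented because the
junction-spanning flag feeds the peptide evidence class. Periodic ORFs
are excluded from the peptide database by default (a product that never
terminates is not a defined protein) and can be included with a flag.
`min_aa` defaults to 20, a typical floor for an MS-detectable product.

## Peptide database

Digestion follows the trypsin rule — cleave C-terminal of K/R except
before P — via `pyteomics.parser.icleave` with up to 2 missed cleavages
by default. With 0 missed cleavages the products concatenate back to the
protein exactly, and no product contains an internal uncleaved site;
both are asserted in tests. Uniqueness against the reference proteome is
decided by *substring* matching, not tryptic-set matching: stricter, and
immune to semi-tryptic false uniqueness. I and L are collapsed to one
symbol before matching by default, since they are isobaric and
indistinguishable by standard MS — the conservative choice when claiming
circRNA-unique evidence. Peptides outside 7–52 aa are dropped as not
MS-observable (configurable). The search database writes reference
entries unchanged first, then one `CIRC|`-prefixed entry per ORF, so
downstream tools can partition hits; N-terminal-Met-removed variants are
not generated.

## PSM evidence

PSMs with q ≤ 0.01 (the standard FDR operating point) whose peptide
matches a unique circRNA peptide — under the same I/L rule as the filter,
keeping the evidence chain consistent — support that circle. PSMs without
a q-value are assumed pre-filtered upstream and pass. A peptide matching
the unique sets of several circles supports all of them and is flagged
ambiguous. Peptides shared with the reference are absent from the unique
set by construction, so razor-peptide logic is unnecessary. Every
nominated circle is `flagged_for_review`: manual curation is represented
as a machine-readable report (peptide, junction span, ORF context,
spectra), never auto-acceptance.

## PRM quantification

Relative expression is `sum(endogenous areas) / sum(heavy areas)` over
the shared transition set — ratio of sums, the default behaviour of the
Skyline processing this layout mirrors, robust to one weak transition.
Fewer than three usable transitions is a refusal, not a number;
transitions present in only one channel are dropped pairwise with a
warning; an all-zero heavy channel is an undefined-ratio error. Group
comparisons use fold change of mean ratios and a two-tailed unpaired
t-test, Welch's variant by default (pooled available); groups with < 2
samples get a fold change but no p-value, and a zero denominator mean is
flagged degenerate rather than propagated.

## Synthetic-data generator

The generator emulates the *structure* of a circRNA-translation study:
what carries information for the pipeline (coordinate dialects, exon
chains, caller agreement, peptide uniqueness, transition ratios) is
modelled; what does not (read-level sequencing noise, spectra, retention
times, real codon usage) is not. Passing tests therefore demonstrate
correctness of the computation, not performance on real data.

* **Circle design.** A planted circle has its sole ATG at offset 0 and,
  for terminating kinds, its first in-frame stop exactly at coding
  offset 3×`target_aa`. On rolling circles later passes re-read bases
  fixed by earlier passes, so free codon drawing is inconsistent;
  instead bases start random (seeded) and a stochastic repair loop
  mutates one base inside the first violating window (a spurious ATG in
  any frame, or a premature in-frame stop) until no violations remain,
  then an independent checker verifies the design. Never-terminating
  circles start from a T-poor alphabet so the dense no-stop constraint
  set converges immediately. Infeasible requests (e.g. `target_aa`
  beyond the *L* − 1 cap) raise.
* **Study plan.** Default 30 circles; the first reproduces the flagship
  structure (322 nt, 161 aa, rolling), the rest cycle through
  single-pass, rolling and periodic designs on alternating strands, each
  embedded as the two middle exons of a 4-exon gene (introns 70–150 nt)
  on one of two chromosomes. Caller membership: ~50% of circles seen by
  all three tools, ~35% by two, the rest by one — so the 2-of-3 rule has
  real work to do. ~60% of eligible consensus circles receive PSMs
  (q below threshold) on peptides verified unique to exactly one circle;
  reference-only PSMs and shuffled decoys with failing q-values are
  mixed in. PRM areas: heavy uniform on 1e5–1e6, light = heavy × ratio ×
  lognormal with CV 10% (σ = √ln(1+CV²)), 4 transitions, two groups of 3
  samples at ratios 1.0 and 0.5.
* **Determinism.** All randomness flows from one integer seed through
  named substreams; fixtures regenerate byte-identically from the
  manifest, and caller files are emitted in native (un-normalized)
  dialects precisely to exercise the parsers' off-by-one handling.

## Problem sizes and numerical choices

The test corpus uses 500 random circles with *L* ∈ [3, 600] for the
ORF-finder oracle and invariance checks, a 30-circle study for
end-to-end recovery, 100 random proteins for digestion/uniqueness
soundness, and 500 Monte-Carlo replicates for PRM recovery — sizes at
which every property is exhaustively checkable in seconds. Ratios and
fold changes are plain floating point; no tolerance tighter than
documented test assertions is claimed.

## Known limitations

* Internal alternative splicing within a circle is not predicted; an
  intron-retaining or longer isoform is handled as a distinct annotated
  exon chain, not discovered de novo.
* Coding-potential scoring, IRES/m6A start evidence and ribosome
  profiling are out of scope; the ORF finder is complete, not selective.
* The uniqueness filter trusts the supplied reference proteome; an
  incomplete proteome inflates "unique" peptides exactly as it would in
  a real proteogenomic search.
* PRM support covers transition-area tables (Skyline-style exports), not
  chromatogram extraction from raw/mzML files.
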