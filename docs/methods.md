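# Methods

## Problem setting

De novo transcriptome assemblies of non-model organisms systematically
over-count genes: allelic variants, splice isoforms, fragmented transcripts
and outright assembly artifacts all surface as separate contigs.  Two
artifact classes are directly repairable from homology evidence alone —
chimeric joins of unrelated transcripts, and short contigs wholly contained
in longer near-identical ones — while the remaining excess can only be
*characterized* (redundancy spectra, completeness, coding content).  This
package implements that curation-and-characterization loop as deterministic,
seedable library code.

## Curation stages

**Chimera detection.**  Input is a tabular protein-homology search result
(12-column outfmt-6 dialect, 1-based inclusive coordinates).  Per contig,
hits with e-value strictly below `chimera_evalue_max` (default 1e-20) are
grouped by subject protein; each subject's query envelope is
(min qstart, max qend).  Only the two strongest subjects by summed bitscore
are compared (ties: min e-value, then subject id), because one breakpoint
per contig is the repair model — a chimera of three transcripts would be
handled on a second pass.  With envelopes ordered left/right, the gap is
`qstart_right − qend_left − 1`.  Gap ≥ `chimera_min_gap` (default 100 bp)
⇒ split at the 0-based offset `⌊(qend_left + qstart_right)/2⌋`; 0 < gap
< 100 ⇒ manual review (the evidence is real but the cut point is
unreliable); overlap ⇒ keep.  Splitting conserves sequence exactly: the
two pieces concatenate to the input, ids suffixed `.1`/`.2`.

**Containment purge.**  A contig Q is purged iff some *strictly longer*
contig S matches it at ≥ `purge_min_identity` (default 0.90) over
≥ `purge_min_coverage` (default 0.50) of Q's length.  Equal lengths never
purge (there is no "longer" partner, and removing one of an equal pair
would be arbitrary).  Coverage uses the single best HSP by default;
`summed_coverage=True` pools HSP lengths per subject — both readings of
"over half their length" are defensible, and the single-HSP default is the
stricter one.  Decisions are made against the full input set and applied at
once, which makes the result order-independent and idempotent (a second run
purges nothing: the retained set is a subset of the set each survivor
already survived against).

**Internal matcher.**  When no contig-vs-contig hit table is supplied, an
internal surrogate finds candidate pairs by shared exact 11-bp words
(both strands) and scores them with a local alignment
(match +2 / mismatch −3 / gap open −5 / extend −2, Bio.Align).  Identity is
identities over alignment columns; coverage is alignment columns over the
shorter contig.  The word-size prefilter means truly unrelated random
contigs are usually never aligned at all, which is both a speed and a
precision device.

**Greedy clustering.**  A cd-hit-est-style surrogate: contigs sorted
longest-first (ties by id), each joining the first cluster whose
representative matches at ≥ 90% *identical bases over the shorter
sequence* (cd-hit's identity definition), both strands, else founding a
cluster.  The canonical internal ordering makes output invariant to input
shuffling.  Strand handling and the 0.9 threshold are configurable since
upstream tools vary.

**Length filter and statistics.**  Contigs < 200 bp are dropped (database
submission floor).  N50 is the length at which the descending cumulative
sum first reaches half the total; GC is pooled over unambiguous bases.

## Characterization

**K-mer spectra.**  Counts-of-counts of length-k words (default k = 21),
tabulated per contig (windows never span contigs), windows with ambiguous
bases skipped.  Canonical (strand-merged) counting is available but off by
default, matching plain invocation of the usual counting tools.  The
occurrence-class table (classes 1..7 plus "> 7") is the comparison unit: a
redundant assembly shifts mass out of class 1.

**Best hits and completeness.**  Best hit = max bitscore, ties by min
e-value then lexicographic subject id; the map is row-order invariant.
Core-gene completeness counts a core protein as detected when any hit
reaches e ≤ 1e-15 — deliberately non-reciprocal, since many fragmented
contigs may legitimately detect one locus.  All e-value comparisons in the
characterization modules are inclusive (≤), so boundary hits count;
chimera detection keeps the strict < of its definition.

**ORFs.**  Longest stop-to-stop codon run over all six frames, measured in
nucleotides, no start-codon requirement (transcript fragments routinely
truncate starts).  Frames are scanned +1,+2,+3,−1,−2,−3 and ties keep the
earlier frame.  Translation of that run feeds the family screen.

**GO conservation.**  For each term annotated to ≥ 20 distinct genes of a
well-annotated comparator species, the proportion of those genes whose
protein is the best hit of ≥ 1 contig.  Best-hit semantics is the default
("matched" = appears in the best-hit map) for consistency with the
coverage tables; an any-hit mode is a caller-side choice of the matched
set.  Genes are counted once per term; the global summary is
(matched annotated genes, total annotated genes).

## Expansion screen

Families are seeded by reference proteins that are the best hit of ≥ 10
contigs — the skew signature that motivates a phylogenetic look.  Focal
members are the longest-ORF translations; comparator homologs of the seed
protein enter at e ≤ 1e-20; members lacking the family's modal domain
accession (domain hits accepted at E ≤ 0.05) are dropped in a single pass
(the mode is computed once, so removals cannot retroactively change it);
families under 4 members are discarded.  An objective surrogate replaces
by-eye alignment triage: members whose mean pairwise p-distance exceeds
0.85 are dropped.

Distances are Kimura-corrected protein distances d = −ln(1 − p − p²/5)
from global alignments (BLOSUM62, gap open −10, each further gap column
−0.5, terminal gaps penalized), capped at 10 when the correction
saturates (p ≳ 0.85).  Trees are standard neighbor joining with
deterministic tie-breaking by label order; a negative branch length is
clamped to zero with the deficit moved to its sister, preserving the
pair's summed length.  NJ-on-distances replaces likelihood tree search
deliberately: the downstream statistic is a coarse topological
classification, robust to tree method at the simulated divergences, and
no support values are computed.

**Lineage clustering.**  On the unrooted tree, every edge defines a
bipartition; *both* sides are examined, and leaf sets that are all one
species are candidate clusters, of which the maximal ones are reported per
species.  Examining only the smaller side — a tempting canonicalization —
silently misses exactly the interesting case where the focal species'
expansion makes up most of the tree's leaves, so it is not used.  A
species is flagged as expanded when some cluster reaches
`min_cluster_size` (default 4; there is no field-standard numeric
criterion, and 4 is the smallest size that cannot arise from a single
duplication plus a stray placement).

## Synthetic data: what it emulates and what it does not

The generator's defaults define the test conditions; they are not tuned
per experiment.

- **Coding contigs** carry one reverse-translated block (50–120 aa) of a
  distinct source protein between random flanks.  Codon choice is uniform
  per amino acid — codon bias affects none of the statistics tested.
  Source proteins are drawn **without replacement**, so non-planted
  contigs are mutually dissimilar by construction and purge/cluster
  precision is well-defined.
- **Chimeras** are two such blocks from distinct proteins separated by a
  100–180 bp spacer; the recorded breakpoint is the gap midpoint, i.e.
  exactly what a correct detector should produce.
- **Spacers and noncoding contigs** must not contain long ORFs.  They are
  built constructively: random chunks interleaved with a 12-bp motif
  (`TTAATTAATTAA`) that contains a stop codon at every phase on both
  strands, spaced so no frame run reaches the ceiling (150 bp in spacers,
  300 bp in noncoding contigs; 300–700 bp of fully random DNA almost
  always contains a ~200 bp frame run, so a tighter ceiling would distort
  composition more).  Consequence: noncoding contigs are mildly AT-rich.
- **Contained pairs** are substrings (40–70% of a 500–800 bp partner)
  mutated at 3% of sites (~97% identity), comfortably inside the 90%/50%
  purge rule.
- **Families** follow a species-split + post-duplication model: one
  ancestor; the comparator lineage diverges at the spec's `mutation_rate`
  per site (calibrated default 0.15); each retained copy in either
  species then diverges by a third of that rate.  This yields ~0.10
  within-species versus ~0.25 cross-species p-distances — clearly
  separated but far from saturation.
- **Reads** are single-end windows prefixed with a fixed 14-bp exogenous
  tag, base quality ~36 with a decay to ~5 over the last 12 cycles,
  phred+33.

Not emulated: realistic sequencing error models, paired ends, allelic
polymorphism beyond point mutations, splice isoforms, composition bias of
real genomes, and real homology-search score statistics (planted e-values
are drawn, not computed).  Passing the planted-truth suites therefore
demonstrates the *logic* of each stage — thresholds, coordinates,
bookkeeping, determinism — not performance on real search output, where
envelope overlap, repeats and domain shuffling make chimera calls
genuinely ambiguous.

## Numerical and interface choices

- Hit tables are 1-based inclusive (BLAST convention); internal sequence
  coordinates 0-based half-open; the conversion happens in exactly one
  place (chimera breakpoints).
- Tie-breaks are total everywhere (bitscore desc, e-value asc, id asc;
  length desc then id for orderings), so every operation is deterministic
  given its inputs.
- Quality trimming is the Mott maximal-scoring segment with score
  q − floor; ties resolved leftmost-then-longest, and a non-empty
  zero-score segment beats the empty read.  The operation is idempotent.
- `quality_trim`, `longest_orf`, N50, the k-mer spectrum, NJ, the pairwise
  aligners and the lineage statistic are all checked against independent
  brute-force or third-party oracles in the test suite.
- Degenerate inputs: empty contig sets yield defined-empty statistics;
  empty reads survive the trim chain and are discarded by the length
  filter; a one-or-two-member family cannot form a tree and is discarded
  upstream by the 4-member floor.
- Pipeline stage order is cluster → split → purge → length filter.  A
  practical consequence: planted contained duplicates are usually absorbed
  at the clustering stage (97% identity > 90% threshold) before the purge
  ever sees them; the purge remains the safety net and is exercised
  directly in its own tests.
- Problem sizes in the test and acceptance runs (tens-to-hundreds of
  contigs of 300–700 bp, 100 seeded family simulations of 4–8 members of
  ~160–220 aa) were chosen so every planted-recovery experiment is exact
  and the full suite runs comfortably on a single CPU.

## Known limitations

- The internal matcher's word-size prefilter can miss a true containment
  whose identity is high but whose longest exact match is under 11 bp —
  irrelevant at the 90% threshold (a 200 bp match at 90% contains ~11-bp
  exact stretches with near certainty) but a real floor for more divergent
  matching.
- Greedy clustering is O(n²) alignments in the worst case; it is meant for
  post-assembly contig counts after word-filtering, not for read-scale
  input.
- The expansion flag is a surrogate for a visual judgment; its
  `min_cluster_size` is a stated convention, not an inference.
- The manual-review chimera channel is reported, never auto-resolved.
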