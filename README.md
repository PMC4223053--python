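# transcurate

Post-assembly curation and characterization of de novo transcriptome
assemblies, built for the situation every non-model-organism RNA-seq project
faces: a short-read assembler emits far more contigs than there are genes,
and the excess must be diagnosed and curated before the catalog is usable.
The motivating system is a freshwater mussel mantle transcriptome — a taxon
with no reference genome, where the curated contig set is the genomic
resource — but every stage is generic.

The package implements, as tested library code plus a CLI:

- **Read preprocessing** — fixed 5′ trim of exogenous bases, Mott
  maximal-scoring-segment quality trimming at a phred floor, and a
  length/ambiguity filter (defaults: trim 14 bp, Q20, keep ≥ 50 bp with
  ≤ 2 ambiguous bases).
- **Chimera splitting** — a contig with protein-level hits (e-value
  < 10⁻²⁰) to two distinct proteins whose query-coordinate envelopes are
  separated by a gap g ≥ 100 bp is an assembly chimera; it is cut at the
  midpoint ⌊(qend_left + qstart_right)/2⌋ and replaced by the two pieces.
  Gaps 0 < g < 100 bp are routed to manual review.
- **Containment purging** — a contig is removed iff a strictly longer
  contig matches it at ≥ 90% identity over ≥ 50% of its length
  (single-best-HSP coverage by default; summed-HSP behind a flag).
- **Greedy identity clustering** — cd-hit-est-style incremental clustering,
  longest-first, joining at ≥ 90% identical bases over the shorter
  sequence, both strands.
- **Assembly statistics** — N50 (first descending-cumulative length
  reaching half the total), GC, length tallies.
- **K-mer redundancy spectra** — counts-of-counts of 21-mers; the
  proportion of distinct k-mers occurring 1..7 and > 7 times indexes
  sequence redundancy across assemblies.
- **Homology characterization** — per-reference best-hit maps (best = max
  bitscore, ties by e-value then subject id), reference-coverage rows,
  core-gene completeness at e ≤ 10⁻¹⁵ (non-reciprocal), six-frame longest
  stop-to-stop ORF statistics (no start codon required), and per-GO-term
  conservation proportions for terms with ≥ 20 annotated genes.
- **Gene-family expansion screen** — families seeded by ≥ 10 contigs
  best-hitting one reference protein, grown with comparator homologs at
  e ≤ 10⁻²⁰, filtered to members sharing the modal protein domain,
  converted to a neighbor-joining tree on Kimura-corrected distances
  d = −ln(1 − p − p²/5), and scanned for single-species edge-defined
  clusters (expansion flag at cluster size ≥ 4).
- **Synthetic data generator** — proteomes, contig sets with planted
  chimeras / contained duplicates / paralog families / noncoding contigs,
  consistent hit tables, and reads with a fixed exogenous prefix, all with
  exact ground-truth labels and byte-level determinism under a seed.

## Worked example

```bash
transcurate simulate --outdir demo --seed 5
# wrote 45 contigs to demo
printf '%s\n' 'contigs: demo/contigs.fasta' 'protein_hits: demo/hits.tsv' \
  'reads: demo/reads.fastq' 'outdir: demo/out' > demo/run.yaml
transcurate run --config demo/run.yaml
```

The simulated set contains 20 single-gene contigs, 5 planted chimeras,
5 contained near-duplicate pairs and 10 noncoding contigs (45 contigs
total).  The run report shows each stage's input/output counts:

```
cluster        45 -> 40   (5 contained duplicates absorbed at ~97% identity)
split          40 -> 45   (5 chimeras detected, each replaced by 2 pieces)
purge          45 -> 45   (nothing left to purge after clustering)
length_filter  45 -> 45
```

Every planted chimera is cut at exactly its true breakpoint, and the
curated N50 drops from 510 bp to 419 bp because each chimera's single long
contig is replaced by its two genuine fragments.  `demo/out/` holds the
curated FASTA, split/purge/cluster logs, annotation and k-mer tables, a
JSON run report, and a sha256 manifest (two runs with the same seed are
byte-identical).

Other subcommands: `transcurate trim` (FASTQ preprocessing) and
`transcurate kmer-spectrum` (redundancy comparison tables).

## Layout

```
src/transcurate/
  readqc.py      read trimming and filtering
  curation.py    chimera split / purge / cluster / length filter / stats
  kmers.py       k-mer counts-of-counts spectra
  annotation.py  best hits, completeness, ORFs, GO conservation
  phylo.py       family assembly, protein distances, NJ, lineage clusters
  synthetic.py   seeded generators with planted ground truth
  pipeline.py    stage orchestration, config validation, manifests
  cli.py         click entry points
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
the limits of what the synthetic benchmarks demonstrate.
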