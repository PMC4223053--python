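"""Synthetic data with planted ground truth for every curation stage.

Generates toy reference proteomes, contig sets containing planted chimeras
(two coding blocks from distinct proteins separated by a spacer), contained
near-duplicate contigs, paralogous gene families with lineage-specific
duplications, noncoding contigs, consistent tabular hit files, and reads
carrying a fixed-length exogenous 5' prefix with quality-degraded ends.
Every planted feature is recorded in a GroundTruth object so downstream
recall/precision is measurable exactly.

Determinism: each generator call draws all randomness from a single
``numpy.random.default_rng`` seeded from its arguments; identical seeds
yield byte-identical outputs.

Reverse translation picks codons uniformly per amino acid: codon bias is
irrelevant to every statistic tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .curation import Contig, reverse_complement
from .io import OUTFMT6_COLUMNS
from .phylo import FamilyMember

__all__ = [
    "ReferenceProteome",
    "FamilySpec",
    "SimConfig",
    "PlantedBlock",
    "GroundTruth",
    "generate_proteome",
    "generate_transcriptome",
    "simulate_family",
    "emit_hits",
    "emit_family_resources",
    "generate_reads",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

# codon choices per amino acid, sorted for determinism
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)

DEFAULT_EXOGENOUS_TAG = "TACGGTAGCAGTCG"  # 14 bp


@dataclass(frozen=True)
class ReferenceProteome:
    """Toy stand-in for a reference species' protein set."""

    proteins: tuple[tuple[str, str], ...]  # (protein_id, aa sequence)
    species_label: str

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.proteins]
        if len(ids) != len(set(ids)):
            raise ValueError("protein ids must be unique")
        for pid, seq in self.proteins:
            if not seq or not set(seq) <= set(AA_ALPHABET):
                raise ValueError(f"protein {pid}: nonempty 20-letter sequence required")
        object.__setattr__(self, "proteins", tuple(self.proteins))

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    n_focal_copies: int
    n_comparator_copies: int
    mutation_rate: float  # per-site divergence at the species split

    def __post_init__(self) -> None:
        if self.n_focal_copies < 0 or self.n_comparator_copies < 0:
            raise ValueError("copy counts must be nonnegative")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_normal: int = 20
    n_chimera: int = 5
    n_contained: int = 5
    n_noncoding: int = 10
    family_spec: tuple[FamilySpec, ...] = ()
    contig_length_range: tuple[int, int] = (300, 700)
    read_length: int = 100
    prefix_length: int = 14
    coverage: float = 2.0
    seed: int = 0
    exogenous_tag: str = DEFAULT_EXOGENOUS_TAG
    focal_label: str = "Ecom"
    comparator_label: str = "Cgig"

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_chimera, self.n_contained,
               self.n_noncoding) < 0:
            raise ValueError("counts must be nonnegative")
        lo, hi = self.contig_length_range
        if lo > hi or lo <= 0:
            raise ValueError("contig_length_range must satisfy 0 < min <= max")
        object.__setattr__(self, "family_spec", tuple(self.family_spec))


@dataclass(frozen=True)
class PlantedBlock:
    """One planted coding block: determines exactly one emitted hit record."""

    protein_id: str
    qstart: int  # 1-based inclusive, contig nucleotides
    qend: int
    sstart: int  # 1-based inclusive, protein residues
    send: int
    evalue: float
    pident: float


@dataclass
class GroundTruth:
    chimera_breakpoints: dict[str, int] = field(default_factory=dict)
    contained_pairs: list[tuple[str, str]] = field(default_factory=list)
    family_members: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    noncoding_ids: set[str] = field(default_factory=set)
    planted_hit_blocks: dict[str, list[PlantedBlock]] = field(default_factory=dict)
    # plumbing beyond the labels themselves:
    family_proteins: dict[str, list[FamilyMember]] = field(default_factory=dict)
    family_seeds: dict[str, str] = field(default_factory=dict)

    def contig_ids_referenced(self) -> set[str]:
        ids = set(self.chimera_breakpoints) | set(self.planted_hit_blocks)
        ids |= self.noncoding_ids
        for short_id, long_id in self.contained_pairs:
            ids.add(short_id)
            ids.add(long_id)
        return ids

    def validate(self, contigs: Sequence[Contig]) -> None:
        by_id = {c.contig_id: c for c in contigs}
        missing = self.contig_ids_referenced() - set(by_id)
        if missing:
            raise ValueError(f"truth references unknown contigs: {sorted(missing)[:5]}")
        for cid, bp in self.chimera_breakpoints.items():
            if not (0 < bp < by_id[cid].length):
                raise ValueError(f"breakpoint {bp} not inside {cid}")
        for short_id, long_id in self.contained_pairs:
            if by_id[short_id].length >= by_id[long_id].length:
                raise ValueError(f"{short_id} not strictly shorter than {long_id}")


# ---------------------------------------------------------------------------
# low-level sequence generators
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=n))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in DNA if b != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, aa_seq: str) -> str:
    parts = []
    for aa in aa_seq:
        codons = _CODONS_FOR[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


# Contains a stop codon at every start phase mod 3 on both strands
# (TAA at offsets 1, 5, 9; TTA = minus-strand stop at offsets 0, 4, 8),
# so any reading frame crossing it is interrupted.
_STOP_MOTIF = "TTAATTAATTAA"


def _orf_free_dna(rng: np.random.Generator, n: int, max_orf_bp: int) -> str:
    """Random DNA of length n with no stop-free frame run >= max_orf_bp.

    Built as random chunks interleaved with a stop-rich motif spaced
    closely enough that every frame on either strand hits a stop well
    before the ceiling.
    """
    spacing = max(3, max_orf_bp // 2 - 2 * len(_STOP_MOTIF))
    parts: list[str] = []
    total = 0
    while total < n:
        chunk = _random_dna(rng, spacing)
        parts.append(chunk)
        parts.append(_STOP_MOTIF)
        total += spacing + len(_STOP_MOTIF)
    return "".join(parts)[:n]


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    species_label: str,
    seed: int,
) -> ReferenceProteome:
    """Uniform random proteome; deterministic under the seed."""
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    lo, hi = length_range
    if lo > hi or lo <= 0:
        raise ValueError("length_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(seed)
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteins.append((f"{species_label}_p{i:05d}", _random_protein(rng, length)))
    return ReferenceProteome(tuple(proteins), species_label)


# ---------------------------------------------------------------------------
# transcriptome with planted features
# ---------------------------------------------------------------------------

def _coding_block(
    rng: np.random.Generator, protein: tuple[str, str], min_aa: int, max_aa: int
) -> tuple[str, PlantedBlock]:
    """Reverse-translated block of a protein plus its (offset-free) hit record."""
    pid, pseq = protein
    block_aa = int(rng.integers(min_aa, max_aa + 1))
    block_aa = min(block_aa, len(pseq))
    sstart = int(rng.integers(0, len(pseq) - block_aa + 1))
    cds = _reverse_translate(rng, pseq[sstart : sstart + block_aa])
    block = PlantedBlock(
        protein_id=pid,
        qstart=1,  # caller shifts by the 5' flank
        qend=3 * block_aa,
        sstart=sstart + 1,
        send=sstart + block_aa,
        evalue=float(10.0 ** -rng.uniform(25.0, 60.0)),
        pident=float(np.round(rng.uniform(96.0, 100.0), 1)),
    )
    return cds, block


def _shift_block(block: PlantedBlock, offset: int) -> PlantedBlock:
    return PlantedBlock(
        block.protein_id, block.qstart + offset, block.qend + offset,
        block.sstart, block.send, block.evalue, block.pident,
    )


def _diverged_copies(
    rng: np.random.Generator, spec: FamilySpec, length_range=(160, 220)
) -> tuple[list[str], list[str], str]:
    """(focal copies, comparator copies, comparator ancestor) amino-acid sets.

    Model: one ancestral protein; the comparator lineage diverges by the
    species-split rate, then each retained copy in either species diverges
    further by a third of that rate (post-duplication divergence).
    """
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    ancestor = _random_protein(rng, length)
    comp_anc = _mutate_protein(rng, ancestor, spec.mutation_rate)
    copy_rate = spec.mutation_rate / 3.0
    focal = [_mutate_protein(rng, ancestor, copy_rate)
             for _ in range(spec.n_focal_copies)]
    comparator = [_mutate_protein(rng, comp_anc, copy_rate)
                  for _ in range(spec.n_comparator_copies)]
    return focal, comparator, comp_anc


def generate_transcriptome(
    proteome: ReferenceProteome, cfg: SimConfig
) -> tuple[list[Contig], GroundTruth]:
    """Contig set with planted chimeras, contained pairs, families, noncoding.

    Chimeric contigs carry two reverse-translated coding blocks from
    distinct proteins separated by a >= 100 bp ORF-broken spacer, with the
    true midpoint breakpoint recorded.  Contained contigs are mutated
    substrings (~97% identity) of a longer partner.  Family contigs encode
    focal-lineage paralogs diverged per the family spec.  Noncoding
    contigs are compositionally random with stops planted so no frame has
    a long ORF.  Source proteins for normal and chimera blocks are drawn
    without replacement (so unrelated contigs stay mutually dissimilar);
    this requires n_normal + 2*n_chimera <= proteome size.
    """
    rng = np.random.default_rng(cfg.seed)
    n_coding_sources = cfg.n_normal + 2 * cfg.n_chimera
    if n_coding_sources > 0 and len(proteome) == 0:
        raise ValueError("coding contigs requested from an empty proteome")
    if cfg.n_chimera > 0 and len(proteome) < 2:
        raise ValueError("chimeras need at least 2 proteins")
    if n_coding_sources > len(proteome):
        raise ValueError(
            f"need {n_coding_sources} distinct source proteins, "
            f"proteome has {len(proteome)}"
        )
    order = rng.permutation(len(proteome))
    sources = [proteome.proteins[i] for i in order]

    contigs: list[Contig] = []
    truth = GroundTruth()
    cl_lo, cl_hi = cfg.contig_length_range

    # --- normal single-gene contigs
    for i in range(cfg.n_normal):
        protein = sources.pop()
        utr5 = _random_dna(rng, int(rng.integers(30, 81)))
        cds, block = _coding_block(rng, protein, 50, 120)
        utr3 = _random_dna(rng, int(rng.integers(30, 81)))
        cid = f"norm_{i:04d}"
        contigs.append(Contig(cid, utr5 + cds + utr3))
        truth.planted_hit_blocks[cid] = [_shift_block(block, len(utr5))]

    # --- chimeric contigs
    for i in range(cfg.n_chimera):
        pa, pb = sources.pop(), sources.pop()
        utr5 = _random_dna(rng, int(rng.integers(10, 41)))
        cds_a, block_a = _coding_block(rng, pa, 40, 100)
        spacer_len = int(rng.integers(100, 181))
        spacer = _orf_free_dna(rng, spacer_len, 150)
        cds_b, block_b = _coding_block(rng, pb, 40, 100)
        utr3 = _random_dna(rng, int(rng.integers(10, 41)))
        cid = f"chim_{i:04d}"
        contigs.append(Contig(cid, utr5 + cds_a + spacer + cds_b + utr3))
        a = _shift_block(block_a, len(utr5))
        b = _shift_block(block_b, len(utr5) + len(cds_a) + spacer_len)
        truth.planted_hit_blocks[cid] = [a, b]
        truth.chimera_breakpoints[cid] = (a.qend + b.qstart) // 2

    # --- contained near-duplicate pairs
    for i in range(cfg.n_contained):
        long_len = int(rng.integers(max(500, cl_lo), max(800, cl_hi) + 1))
        long_seq = _random_dna(rng, long_len)
        short_len = int(rng.integers(int(0.4 * long_len), int(0.7 * long_len)))
        start = int(rng.integers(0, long_len - short_len + 1))
        short_seq = _mutate_dna(rng, long_seq[start : start + short_len], 0.03)
        long_id, short_id = f"cont_long_{i:04d}", f"cont_short_{i:04d}"
        contigs.append(Contig(long_id, long_seq))
        contigs.append(Contig(short_id, short_seq))
        truth.contained_pairs.append((short_id, long_id))

    # --- gene families with focal-lineage duplications
    for spec in cfg.family_spec:
        focal, comparator, comp_anc = _diverged_copies(rng, spec)
        seed_id = f"{spec.family_id}:seed"
        truth.family_seeds[spec.family_id] = seed_id
        members: list[tuple[str, str]] = []
        proteins: list[FamilyMember] = []
        for j, aa in enumerate(focal):
            cid = f"fam_{spec.family_id}_ec{j:03d}"
            utr5 = _random_dna(rng, int(rng.integers(20, 61)))
            utr3 = _random_dna(rng, int(rng.integers(20, 61)))
            contigs.append(Contig(cid, utr5 + _reverse_translate(rng, aa) + utr3))
            truth.planted_hit_blocks[cid] = [
                PlantedBlock(
                    seed_id, len(utr5) + 1, len(utr5) + 3 * len(aa),
                    1, len(aa),
                    float(10.0 ** -rng.uniform(30.0, 60.0)),
                    float(np.round(rng.uniform(80.0, 95.0), 1)),
                )
            ]
            members.append((cid, cfg.focal_label))
            proteins.append(FamilyMember(cid, cfg.focal_label, aa))
        for j, aa in enumerate(comparator):
            pid = f"fam_{spec.family_id}_cg{j:03d}"
            members.append((pid, cfg.comparator_label))
            proteins.append(FamilyMember(pid, cfg.comparator_label, aa))
        proteins.append(FamilyMember(seed_id, cfg.comparator_label, comp_anc))
        truth.family_members[spec.family_id] = members
        truth.family_proteins[spec.family_id] = proteins

    # --- noncoding contigs
    for i in range(cfg.n_noncoding):
        length = int(rng.integers(cl_lo, cl_hi + 1))
        seq = _orf_free_dna(rng, length, 300)
        cid = f"nc_{i:04d}"
        contigs.append(Contig(cid, seq))
        truth.noncoding_ids.add(cid)

    truth.validate(contigs)
    return contigs, truth


def simulate_family(
    family_id: str,
    n_focal: int,
    n_comparator: int,
    mutation_rate: float,
    seed: int,
    focal_label: str = "Ecom",
    comparator_label: str = "Cgig",
) -> list[FamilyMember]:
    """Protein-level family under the species-split + duplication model.

    Used for expansion-screen recovery experiments: ``n_focal`` copies
    duplicated after the split (an expansion when > 1) versus
    ``n_comparator`` comparator-lineage copies.
    """
    rng = np.random.default_rng(seed)
    spec = FamilySpec(family_id, n_focal, n_comparator, mutation_rate)
    focal, comparator, _ = _diverged_copies(rng, spec)
    members = [
        FamilyMember(f"{family_id}_ec{j:03d}", focal_label, aa)
        for j, aa in enumerate(focal)
    ]
    members += [
        FamilyMember(f"{family_id}_cg{j:03d}", comparator_label, aa)
        for j, aa in enumerate(comparator)
    ]
    return members


# ---------------------------------------------------------------------------
# hit tables / family resources / reads
# ---------------------------------------------------------------------------

def emit_hits(
    contigs: Sequence[Contig],
    proteome: Optional[ReferenceProteome],
    truth: GroundTruth,
    noise: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein hit table (outfmt-6 dialect) implied by the planted blocks.

    With noise off, each planted coding block yields exactly one record
    whose query coordinates equal the planted block and whose e-value is
    below 1e-20.  With noise on, spurious records with e-values uniform in
    [1e-5, 1] are added (they fail both the 1e-20 and 1e-15 thresholds);
    the spurious set is deterministic under the seed.
    """
    truth.validate(contigs)
    rows = []
    for cid in sorted(truth.planted_hit_blocks):
        for b in truth.planted_hit_blocks[cid]:
            aa_len = b.send - b.sstart + 1
            mismatch = int(round(aa_len * (1.0 - b.pident / 100.0)))
            rows.append(
                (cid, b.protein_id, b.pident, aa_len, mismatch, 0,
                 b.qstart, b.qend, b.sstart, b.send, b.evalue, 2.0 * aa_len)
            )
    if noise:
        rng = np.random.default_rng(seed)
        subjects = (
            [pid for pid, _ in proteome.proteins]
            if proteome is not None and len(proteome) else ["spurious_prot"]
        )
        n_spurious = max(1, len(contigs) // 3)
        for _ in range(n_spurious):
            c = contigs[int(rng.integers(0, len(contigs)))]
            sid = subjects[int(rng.integers(0, len(subjects)))]
            aa_len = int(rng.integers(15, 40))
            qstart = int(rng.integers(1, max(2, c.length - 3 * aa_len)))
            rows.append(
                (c.contig_id, sid, float(np.round(rng.uniform(55.0, 75.0), 1)),
                 aa_len, int(aa_len * 0.35), 1, qstart, qstart + 3 * aa_len - 1,
                 1, aa_len, float(rng.uniform(1e-5, 1.0)),
                 float(np.round(rng.uniform(20.0, 34.0), 1)))
            )
    df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    return df.sort_values(
        by=["qseqid", "evalue", "sseqid", "qstart"], kind="mergesort"
    ).reset_index(drop=True)


def emit_family_resources(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[dict[str, dict[str, str]], dict[str, pd.DataFrame], pd.DataFrame]:
    """Comparator proteomes, seed-vs-comparator hit tables, and a domain table.

    The comparator proteome holds each family's comparator copies plus the
    seed protein; hit tables record the seed's matches to those copies at
    strong e-values; the domain table assigns every family member (focal
    contigs included, keyed by the ids their translations will carry) a
    family-specific domain accession.
    """
    proteome: dict[str, str] = {}
    hit_rows = []
    dom_rows = []
    for fid, members in truth.family_proteins.items():
        seed_id = truth.family_seeds[fid]
        for m in members:
            dom_rows.append((m.seq_id, f"DOM_{fid}", 1e-6))
            if m.species == cfg.comparator_label:
                proteome[m.seq_id] = m.sequence
                if m.seq_id != seed_id:
                    length = min(len(m.sequence), 200)
                    hit_rows.append(
                        (seed_id, m.seq_id, 85.0, length, int(0.15 * length), 0,
                         1, length, 1, length, 1e-30, 2.0 * length)
                    )
    hits = pd.DataFrame(hit_rows, columns=OUTFMT6_COLUMNS)
    domains = pd.DataFrame(dom_rows, columns=["seq_id", "domain", "evalue"])
    return (
        {cfg.comparator_label: proteome},
        {cfg.comparator_label: hits},
        domains,
    )


def generate_reads(
    contigs: Sequence[Contig], cfg: SimConfig
) -> list[tuple[str, str, list[int]]]:
    """Single-end reads with a fixed exogenous 5' prefix and decaying tails.

    Every read begins with the configured ``exogenous_tag`` (length must
    equal ``prefix_length``); the insert is a uniformly placed contig
    window; terminal qualities decay toward phred ~5 over the last 12
    bases.  Returns (read_id, sequence, phred qualities) triples.
    """
    if cfg.read_length <= cfg.prefix_length:
        raise ValueError("read_length must exceed prefix_length")
    if len(cfg.exogenous_tag) != cfg.prefix_length:
        raise ValueError(
            f"exogenous_tag length {len(cfg.exogenous_tag)} != "
            f"prefix_length {cfg.prefix_length}"
        )
    rng = np.random.default_rng(cfg.seed)
    insert = cfg.read_length - cfg.prefix_length
    reads: list[tuple[str, str, list[int]]] = []
    tail = 12
    for contig in contigs:
        if contig.length < insert:
            continue
        n_reads = int(round(cfg.coverage * contig.length / insert))
        for r in range(n_reads):
            start = int(rng.integers(0, contig.length - insert + 1))
            seq = cfg.exogenous_tag + contig.sequence[start : start + insert]
            quals = 36 + rng.integers(-2, 4, size=cfg.read_length)
            for j in range(1, tail + 1):  # decay toward the final base
                cap = 5 + int(28 * (j - 1) / tail)
                idx = cfg.read_length - j
                quals[idx] = min(quals[idx], cap + int(rng.integers(0, 3)))
            quals = np.clip(quals, 2, 40)
            reads.append(
                (f"{contig.contig_id}|r{r:04d}", seq, [int(q) for q in quals])
            )
    return reads
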