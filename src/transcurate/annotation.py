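"""Homology-based characterization of a curated assembly.

Best-hit assignment against each reference set, reference-coverage rows,
core-gene completeness (CEGMA-style, non-reciprocal), six-frame longest
stop-to-stop ORF statistics, and GO-category conservation proportions
mapped from an annotated model organism.

Threshold comparisons on e-values are inclusive (<=) throughout this
module, so boundary hits count as detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .curation import Contig, reverse_complement

__all__ = [
    "BestHit",
    "BestHitMap",
    "CoverageRow",
    "CompletenessReport",
    "OrfStats",
    "OrfGroupSummary",
    "GoConservationRow",
    "best_hits",
    "reference_coverage",
    "completeness",
    "longest_orf",
    "longest_orf_translation",
    "orf_fraction_summary",
    "go_conservation",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    bitscore: float
    evalue: float


@dataclass(frozen=True)
class BestHitMap:
    """Per-contig best subject against one reference set."""

    reference_name: str
    per_contig: Mapping[str, BestHit]

    @property
    def subjects(self) -> set[str]:
        return {h.subject_id for h in self.per_contig.values()}

    @property
    def n_contigs_matched(self) -> int:
        return len(self.per_contig)


@dataclass(frozen=True)
class CoverageRow:
    reference_name: str
    n_contigs_matched: int
    n_subjects_hit: int
    reference_size: int
    mean_contigs_per_subject: float


@dataclass(frozen=True)
class CompletenessReport:
    core_set_size: int
    n_detected: int
    fraction: float
    evalue_max: float


@dataclass(frozen=True)
class OrfStats:
    contig_id: str
    frame: str
    longest_orf_bp: int
    orf_fraction: float


@dataclass(frozen=True)
class OrfGroupSummary:
    mean_fraction_matched: Optional[float]
    mean_fraction_unmatched: Optional[float]
    mean_length_matched: Optional[float]
    mean_length_unmatched: Optional[float]


@dataclass(frozen=True)
class GoConservationRow:
    term_id: str
    term_name: str
    namespace: str
    n_genes: int
    n_matched: int
    proportion: float


def best_hits(hit_table: pd.DataFrame, reference_name: str) -> BestHitMap:
    """Assign each contig its strongest subject in one reference.

    Best = max bitscore, ties broken by min e-value then lexicographic
    subject id; invariant to hit-table row order.
    """
    if hit_table.empty:
        return BestHitMap(reference_name, {})
    ranked = hit_table.sort_values(
        by=["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates(subset="qseqid", keep="first")
    per_contig = {
        row.qseqid: BestHit(row.sseqid, float(row.bitscore), float(row.evalue))
        for row in ranked.itertuples()
    }
    return BestHitMap(reference_name, per_contig)


def reference_coverage(best_map: BestHitMap, reference_size: int) -> CoverageRow:
    """How much of a reference set is covered by best hits.

    Reports the number of contigs with a best hit, the number of distinct
    reference sequences that are the best hit of at least one contig, the
    reference size, and the mean contigs per hit subject.
    """
    n_subjects = len(best_map.subjects)
    if reference_size < n_subjects:
        raise ValueError(
            f"reference_size {reference_size} < observed subjects {n_subjects}"
        )
    mean = best_map.n_contigs_matched / n_subjects if n_subjects else 0.0
    return CoverageRow(
        best_map.reference_name,
        best_map.n_contigs_matched,
        n_subjects,
        reference_size,
        mean,
    )


def completeness(
    hit_table: pd.DataFrame, core_ids: set[str], evalue_max: float = 1e-15
) -> CompletenessReport:
    """Fraction of a conserved core-gene set detected in the assembly.

    A core protein counts as detected when at least one hit to it has
    e-value <= ``evalue_max``.  Deliberately non-reciprocal: many contigs
    may detect the same core gene.
    """
    if not core_ids:
        raise ValueError("core_ids must be nonempty")
    if hit_table.empty:
        detected: set[str] = set()
    else:
        ok = hit_table[hit_table["evalue"] <= evalue_max]
        detected = set(ok["sseqid"]) & set(core_ids)
    return CompletenessReport(
        core_set_size=len(core_ids),
        n_detected=len(detected),
        fraction=len(detected) / len(core_ids),
        evalue_max=evalue_max,
    )


def _frame_strings(sequence: str) -> list[tuple[str, str]]:
    seq = sequence.upper()
    rc = reverse_complement(seq)
    return [
        ("+1", seq), ("+2", seq[1:]), ("+3", seq[2:]),
        ("-1", rc), ("-2", rc[1:]), ("-3", rc[2:]),
    ]


def _longest_stop_free_run(frame_seq: str) -> tuple[int, int]:
    """(longest run in codons, 0-based codon start of that run)."""
    n_codons = len(frame_seq) // 3
    best = 0
    best_start = 0
    run = 0
    for i in range(n_codons):
        if frame_seq[3 * i : 3 * i + 3] in STOP_CODONS:
            run = 0
        else:
            run += 1
            if run > best:
                best = run
                best_start = i - run + 1
    return best, best_start


def longest_orf(contig: Contig) -> OrfStats:
    """Longest stop-to-stop open reading frame over all six frames.

    In each frame the longest run of codons free of TAA/TAG/TGA is
    measured in nucleotides (no start codon required; sequence ends
    delimit runs).  Frames are scanned in the order +1,+2,+3,-1,-2,-3 and
    ties keep the earlier frame.
    """
    best_len = 0
    best_frame = "+1"
    for frame, fseq in _frame_strings(contig.sequence):
        run, _ = _longest_stop_free_run(fseq)
        if 3 * run > best_len:
            best_len = 3 * run
            best_frame = frame
    return OrfStats(
        contig.contig_id, best_frame, best_len, best_len / contig.length
    )


def longest_orf_translation(contig: Contig) -> str:
    """Amino-acid translation of the longest stop-to-stop ORF."""
    from Bio.Seq import Seq

    best = (0, "+1", 0, "")
    for frame, fseq in _frame_strings(contig.sequence):
        run, start = _longest_stop_free_run(fseq)
        if 3 * run > best[0]:
            best = (3 * run, frame, start, fseq)
    length, _, start, fseq = best
    if length == 0:
        return ""
    nt = fseq[3 * start : 3 * start + length]
    return str(Seq(nt).translate())


def orf_fraction_summary(
    orf_stats: Sequence[OrfStats], matched_flags: Mapping[str, bool]
) -> OrfGroupSummary:
    """Group means of ORF fraction/length for matched vs unmatched contigs.

    ``matched_flags`` must flag every contig in ``orf_stats``; an empty
    group is reported as None rather than NaN.
    """
    missing = [s.contig_id for s in orf_stats if s.contig_id not in matched_flags]
    if missing:
        raise ValueError(f"flags missing for contigs: {missing[:5]}")
    groups: dict[bool, list[OrfStats]] = {True: [], False: []}
    for s in orf_stats:
        groups[bool(matched_flags[s.contig_id])].append(s)

    def mean(values: list[float]) -> Optional[float]:
        return sum(values) / len(values) if values else None

    return OrfGroupSummary(
        mean_fraction_matched=mean([s.orf_fraction for s in groups[True]]),
        mean_fraction_unmatched=mean([s.orf_fraction for s in groups[False]]),
        mean_length_matched=mean([float(s.longest_orf_bp) for s in groups[True]]),
        mean_length_unmatched=mean([float(s.longest_orf_bp) for s in groups[False]]),
    )


def go_conservation(
    matched_genes: set[str],
    annotations: pd.DataFrame,
    min_genes: int = 20,
) -> tuple[list[GoConservationRow], tuple[int, int]]:
    """Per-GO-term conservation proportions plus a global summary.

    ``annotations`` needs columns gene_id and term_id (term_name and
    namespace are carried through when present).  For every term annotated
    to at least ``min_genes`` distinct genes, the proportion of those
    genes matched by at least one contig is reported; rows are sorted by
    ascending proportion (ties by term id).  The global summary is
    (matched annotated genes, total annotated genes).  Matched genes
    absent from the table contribute nothing.
    """
    if annotations.empty:
        raise ValueError("annotations table is empty")
    ann = annotations.drop_duplicates(subset=["gene_id", "term_id"])
    rows: list[GoConservationRow] = []
    for term_id, grp in ann.groupby("term_id", sort=True):
        genes = set(grp["gene_id"])
        if len(genes) < min_genes:
            continue
        n_matched = len(genes & matched_genes)
        first = grp.iloc[0]
        rows.append(
            GoConservationRow(
                term_id=term_id,
                term_name=str(first["term_name"]) if "term_name" in grp.columns else "",
                namespace=str(first["namespace"]) if "namespace" in grp.columns else "",
                n_genes=len(genes),
                n_matched=n_matched,
                proportion=n_matched / len(genes),
            )
        )
    rows.sort(key=lambda r: (r.proportion, r.term_id))
    all_genes = set(ann["gene_id"])
    summary = (len(all_genes & matched_genes), len(all_genes))
    return rows, summary
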