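"""Post-assembly contig curation.

Implements the curation stages applied to a de novo transcriptome assembly:
detection and midpoint splitting of chimeric contigs (contigs carrying
homology blocks to two distinct proteins separated by a gap), purging of
contigs contained within longer near-identical contigs, greedy incremental
identity clustering (a cd-hit-est-style surrogate), a minimum-length filter,
and standard assembly statistics (N50, GC content).

Coordinate conventions
----------------------
Tabular hit files use 1-based inclusive coordinates (the BLAST outfmt-6
convention).  Internal sequence coordinates are 0-based half-open.  The only
conversion happens inside :func:`detect_chimeras`, which consumes 1-based
envelopes and emits a 0-based cut offset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

__all__ = [
    "Contig",
    "CurationConfig",
    "SplitDecision",
    "MatchRecord",
    "Cluster",
    "AssemblyStats",
    "detect_chimeras",
    "split_contig",
    "apply_split_decisions",
    "pairwise_identity",
    "purge_contained",
    "greedy_cluster",
    "length_filter",
    "assembly_stats",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """An assembled transcript sequence, the unit of curation."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        seq = self.sequence.upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (seq.count("G") + seq.count("C")) / acgt


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds for every curation stage.

    Defaults: chimera hits must have e-value < 1e-20 and the two protein
    envelopes must be separated by >= 100 bp; containment purging requires
    90% identity over at least half of the shorter contig; greedy clustering
    joins at 90% identity over the shorter sequence; contigs shorter than
    200 bp are excluded.
    """

    chimera_evalue_max: float = 1e-20
    chimera_min_gap: int = 100
    purge_min_identity: float = 0.90
    purge_min_coverage: float = 0.50
    cluster_identity: float = 0.90
    min_contig_length: int = 200
    kmer_seed_size: int = 11

    def __post_init__(self) -> None:
        for name in ("purge_min_identity", "purge_min_coverage", "cluster_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_contig_length <= 0 or self.kmer_seed_size <= 0 or self.chimera_min_gap <= 0:
            raise ValueError("lengths must be positive")
        if self.chimera_evalue_max <= 0:
            raise ValueError("chimera_evalue_max must be positive")


@dataclass(frozen=True)
class SplitDecision:
    """Outcome of chimera screening for one contig.

    ``status`` is ``"split"`` (breakpoint present, strictly internal),
    ``"manual_review"`` (two disjoint envelopes but a gap below the
    threshold) or ``"keep"``.
    """

    contig_id: str
    status: str
    breakpoint: Optional[int] = None
    left_protein: Optional[str] = None
    right_protein: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("split", "manual_review", "keep"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "split") != (self.breakpoint is not None):
            raise ValueError("breakpoint present iff status is 'split'")


@dataclass(frozen=True)
class MatchRecord:
    """Best local match between two contigs (internal MegaBLAST surrogate)."""

    pct_identity: float
    aln_length: int
    n_identical: int
    coverage_shorter: float
    strand: str  # "+" or "-"
    score: float


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    n_ge_1kb: int
    gc_fraction: float
    mean_length: float
    max_length: int


# ---------------------------------------------------------------------------
# chimera detection / splitting
# ---------------------------------------------------------------------------

def _normalize_query_coords(hits: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with qstart <= qend (plus-strand query envelopes)."""
    out = hits.copy()
    flip = out["qstart"] > out["qend"]
    if flip.any():
        qs = out.loc[flip, "qend"].to_numpy()
        qe = out.loc[flip, "qstart"].to_numpy()
        out.loc[flip, "qstart"] = qs
        out.loc[flip, "qend"] = qe
    return out


def detect_chimeras(
    hits: pd.DataFrame,
    contigs: Optional[Sequence[Contig]] = None,
    cfg: CurationConfig = CurationConfig(),
) -> list[SplitDecision]:
    """Screen contigs for chimeric joins of two distinct proteins.

    For each query contig, hits with e-value below ``cfg.chimera_evalue_max``
    are grouped by subject protein and each subject's query-coordinate
    envelope (min qstart, max qend; 1-based inclusive) is formed.  The two
    strongest subjects by summed bitscore are compared: disjoint envelopes
    separated by at least ``cfg.chimera_min_gap`` bp yield a ``split``
    decision with the cut placed on the midpoint of the inter-envelope gap;
    a smaller positive gap yields ``manual_review``; anything else ``keep``.

    When ``contigs`` is given, hits naming unknown contigs raise ValueError
    and breakpoints are checked to be strictly internal.

    Returns one decision per query contig present in ``hits`` (plus explicit
    ``keep`` decisions for hit-less contigs when ``contigs`` is given).
    """
    lengths: Optional[dict[str, int]] = None
    if contigs is not None:
        lengths = {c.contig_id: c.length for c in contigs}
        unknown = set(hits["qseqid"].unique()) - set(lengths)
        if unknown:
            raise ValueError(f"hits reference unknown contigs: {sorted(unknown)[:5]}")

    hits = _normalize_query_coords(hits)
    strong = hits[hits["evalue"] < cfg.chimera_evalue_max]

    decisions: list[SplitDecision] = []
    seen: set[str] = set()
    for qid, grp in strong.groupby("qseqid", sort=True):
        seen.add(qid)
        # per-subject envelope and strength
        env = grp.groupby("sseqid").agg(
            qstart=("qstart", "min"),
            qend=("qend", "max"),
            sum_bit=("bitscore", "sum"),
            min_e=("evalue", "min"),
        )
        if len(env) < 2:
            decisions.append(SplitDecision(qid, "keep"))
            continue
        # two strongest subjects: summed bitscore desc, e-value asc, id asc
        env = env.sort_values(
            by=["sum_bit", "min_e", "sseqid"], ascending=[False, True, True],
            kind="mergesort",
        )
        top2 = env.iloc[:2].sort_values(by=["qstart", "qend"], kind="mergesort")
        left, right = top2.iloc[0], top2.iloc[1]
        gap = int(right["qstart"]) - int(left["qend"]) - 1  # 1-based inclusive
        if gap >= cfg.chimera_min_gap:
            # midpoint of the gap, expressed as a 0-based cut offset
            breakpoint = (int(left["qend"]) + int(right["qstart"])) // 2
            if lengths is not None and not (0 < breakpoint < lengths[qid]):
                raise ValueError(
                    f"breakpoint {breakpoint} outside contig {qid} "
                    f"(length {lengths[qid]})"
                )
            decisions.append(
                SplitDecision(qid, "split", breakpoint, top2.index[0], top2.index[1])
            )
        elif gap > 0:
            decisions.append(
                SplitDecision(
                    qid, "manual_review",
                    left_protein=top2.index[0], right_protein=top2.index[1],
                )
            )
        else:
            decisions.append(SplitDecision(qid, "keep"))

    if lengths is not None:
        for cid in sorted(set(lengths) - seen):
            decisions.append(SplitDecision(cid, "keep"))
    return decisions


def split_contig(contig: Contig, breakpoint: int) -> tuple[Contig, Contig]:
    """Cut ``contig`` at a 0-based offset; pieces are suffixed ``.1``/``.2``.

    Concatenating the two pieces reproduces the input sequence exactly.
    """
    if not (0 < breakpoint < contig.length):
        raise ValueError(
            f"breakpoint {breakpoint} not strictly inside contig of length {contig.length}"
        )
    return (
        Contig(contig.contig_id + ".1", contig.sequence[:breakpoint]),
        Contig(contig.contig_id + ".2", contig.sequence[breakpoint:]),
    )


def apply_split_decisions(
    contigs: Sequence[Contig], decisions: Iterable[SplitDecision]
) -> tuple[list[Contig], list[Contig]]:
    """Substitute split contigs with their two pieces.

    Returns ``(revised contig set, replacement pieces)``; contigs with
    ``keep``/``manual_review`` status pass through unchanged.
    """
    by_id = {d.contig_id: d for d in decisions}
    out: list[Contig] = []
    pieces: list[Contig] = []
    for c in contigs:
        d = by_id.get(c.contig_id)
        if d is not None and d.status == "split":
            a, b = split_contig(c, d.breakpoint)
            out.extend((a, b))
            pieces.extend((a, b))
        else:
            out.append(c)
    return out, pieces


# ---------------------------------------------------------------------------
# pairwise matcher (MegaBLAST surrogate)
# ---------------------------------------------------------------------------

def _seed_words(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _local_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-5,
        extend_gap_score=-2,
    )


def pairwise_identity(
    a: Contig, b: Contig, seed_size: int = 11
) -> Optional[MatchRecord]:
    """Best local alignment between two contigs, or None when unrelated.

    Shared exact ``seed_size``-bp words (checking both strands of ``b``)
    act as a prefilter; strands with at least one shared seed are aligned
    locally (match +2 / mismatch -3 / gap open -5, extend -2) and the best
    scoring alignment is reported.  ``pct_identity`` is identities over
    alignment columns; ``coverage_shorter`` is alignment columns over the
    shorter contig's length (capped at 1).
    """
    if seed_size < 1:
        raise ValueError("seed_size must be >= 1")
    sa = a.sequence.upper()
    words = _seed_words(sa, seed_size)
    candidates: list[tuple[str, str]] = []
    fwd = b.sequence.upper()
    rev = reverse_complement(fwd)
    if words & _seed_words(fwd, seed_size):
        candidates.append(("+", fwd))
    if words & _seed_words(rev, seed_size):
        candidates.append(("-", rev))
    if not candidates:
        return None

    aligner = _local_aligner()
    best: Optional[MatchRecord] = None
    for strand, sb in candidates:
        alns = aligner.align(sa, sb)
        aln = alns[0]
        c = aln.counts()
        aln_len = c.identities + c.mismatches + c.internal_gaps
        if aln_len == 0:
            continue
        rec = MatchRecord(
            pct_identity=100.0 * c.identities / aln_len,
            aln_length=aln_len,
            n_identical=c.identities,
            coverage_shorter=min(1.0, aln_len / min(a.length, b.length)),
            strand=strand,
            score=float(aln.score),
        )
        if best is None or rec.score > best.score:
            best = rec
    return best


# ---------------------------------------------------------------------------
# containment purge
# ---------------------------------------------------------------------------

def purge_contained(
    contigs: Sequence[Contig],
    cfg: CurationConfig = CurationConfig(),
    nuc_hits: Optional[pd.DataFrame] = None,
    summed_coverage: bool = False,
) -> tuple[list[Contig], list[dict]]:
    """Remove contigs matching a strictly longer contig at high identity.

    A contig Q is purged iff some strictly longer contig S matches it at
    >= ``purge_min_identity`` identity over >= ``purge_min_coverage`` of
    Q's length.  Matches come from ``nuc_hits`` (contig-vs-contig table,
    1-based outfmt-6 dialect; self-hits ignored) when given, else from the
    internal all-vs-all matcher.  Coverage uses the single best HSP by
    default; ``summed_coverage=True`` pools each subject's HSP lengths.

    Purge decisions are made against the full input set and applied at
    once, so the result is independent of input order and re-running on
    the retained set removes nothing further.
    """
    lengths = {c.contig_id: c.length for c in contigs}
    purge_log: list[dict] = []
    doomed: set[str] = set()

    if nuc_hits is not None:
        hits = nuc_hits[nuc_hits["qseqid"] != nuc_hits["sseqid"]]
        unknown = (set(hits["qseqid"]) | set(hits["sseqid"])) - set(lengths)
        if unknown:
            raise ValueError(f"hits reference unknown contigs: {sorted(unknown)[:5]}")
        for (qid, sid), grp in hits.groupby(["qseqid", "sseqid"], sort=True):
            if lengths[sid] <= lengths[qid]:
                continue
            ok = grp[grp["pident"] >= 100.0 * cfg.purge_min_identity]
            if ok.empty:
                continue
            if summed_coverage:
                aln = int(ok["length"].sum())
                ident = float(ok["pident"].max())
            else:
                row = ok.sort_values(
                    by=["length", "pident"], ascending=False, kind="mergesort"
                ).iloc[0]
                aln = int(row["length"])
                ident = float(row["pident"])
            if aln >= cfg.purge_min_coverage * lengths[qid]:
                if qid not in doomed:
                    doomed.add(qid)
                    purge_log.append(
                        {"purged_id": qid, "kept_id": sid,
                         "pct_identity": ident,
                         "coverage": min(1.0, aln / lengths[qid])}
                    )
    else:
        ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
        for i, q in enumerate(ordered):
            for s in ordered:
                if s.length <= q.length:
                    break  # ordered by decreasing length
                rec = pairwise_identity(q, s, cfg.kmer_seed_size)
                if rec is None:
                    continue
                if (
                    rec.pct_identity >= 100.0 * cfg.purge_min_identity
                    and rec.aln_length >= cfg.purge_min_coverage * q.length
                ):
                    doomed.add(q.contig_id)
                    purge_log.append(
                        {"purged_id": q.contig_id, "kept_id": s.contig_id,
                         "pct_identity": rec.pct_identity,
                         "coverage": rec.coverage_shorter}
                    )
                    break

    retained = [c for c in contigs if c.contig_id not in doomed]
    return retained, purge_log


# ---------------------------------------------------------------------------
# greedy clustering (cd-hit-est surrogate)
# ---------------------------------------------------------------------------

def greedy_cluster(
    contigs: Sequence[Contig],
    identity_threshold: float = 0.90,
    seed_size: int = 11,
) -> list[Cluster]:
    """Greedy incremental clustering in decreasing length order.

    Contigs are processed longest-first (ties by id); each joins the first
    existing cluster whose representative matches it at
    >= ``identity_threshold`` identical bases over the shorter sequence
    (both strands considered), otherwise it founds a new cluster.  The
    representative is always the cluster's longest member.  The canonical
    ordering makes the result invariant to input shuffling.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    clusters: list[Cluster] = []
    reps: list[Contig] = []
    for c in ordered:
        placed = False
        for cl, rep in zip(clusters, reps):
            rec = pairwise_identity(c, rep, seed_size)
            if rec is None:
                continue
            shorter = min(c.length, rep.length)
            if rec.n_identical / shorter >= identity_threshold:
                cl.member_ids.append(c.contig_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(c.contig_id, [c.contig_id]))
            reps.append(c)
    return clusters


def length_filter(contigs: Sequence[Contig], min_length: int = 200) -> list[Contig]:
    """Retain exactly the contigs of length >= ``min_length``."""
    return [c for c in contigs if c.length >= min_length]


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """N50, GC and size statistics for a contig set.

    N50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the total length.  GC is
    pooled over all contigs, counting unambiguous bases only.
    """
    if not contigs:
        return AssemblyStats(0, 0, 0, 0, 0.0, 0.0, 0)
    lengths = np.sort(np.array([c.length for c in contigs]))[::-1]
    total = int(lengths.sum())
    csum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(csum, total / 2.0)])
    counts = Counter()
    for c in contigs:
        counts.update(c.sequence.upper())
    acgt = sum(counts[b] for b in "ACGT")
    gc = (counts["G"] + counts["C"]) / acgt if acgt else 0.0
    return AssemblyStats(
        n_contigs=len(contigs),
        total_length=total,
        n50=n50,
        n_ge_1kb=int((lengths >= 1000).sum()),
        gc_fraction=gc,
        mean_length=total / len(contigs),
        max_length=int(lengths[0]),
    )
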