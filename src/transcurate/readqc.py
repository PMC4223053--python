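"""Read preprocessing: fixed 5' trim, quality trimming, length/ambiguity filter.

The pipeline order is fixed: prefix trim, then quality trim, then the
length/ambiguity filter.  Quality trimming uses the Mott maximal-scoring
segment: each base scores ``q - floor`` and the kept segment is the
contiguous stretch maximizing the summed score (leftmost, then longest, on
ties; empty when every base scores negative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

__all__ = [
    "ReadRecord",
    "TrimPolicy",
    "FilterResult",
    "trim_fixed_prefix",
    "quality_trim",
    "filter_read",
    "process_read",
    "process_reads",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        object.__setattr__(self, "qualities", tuple(self.qualities))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimPolicy:
    """Defaults: trim first 14 bp, Q20 floor, keep >= 50 bp with <= 2 Ns."""

    fixed_prefix: int = 14
    quality_floor: int = 20
    min_length: int = 50
    max_ambiguous: int = 2

    def __post_init__(self) -> None:
        if min(self.fixed_prefix, self.quality_floor, self.min_length,
               self.max_ambiguous) < 0:
            raise ValueError("policy fields must be nonnegative")


@dataclass(frozen=True)
class FilterResult:
    keep: bool
    reason: Optional[str] = None  # "length" | "ambiguity" when discarded


def trim_fixed_prefix(read: ReadRecord, n: int) -> ReadRecord:
    """Drop the first ``n`` bases (and qualities); over-trimming empties the read."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return replace(read, sequence=read.sequence[n:], qualities=read.qualities[n:])


def quality_trim(read: ReadRecord, quality_floor: int = 20) -> ReadRecord:
    """Keep the maximal-scoring segment under score ``q - quality_floor``.

    Ties among equal-score segments are broken leftmost-first, then
    longest; a non-empty zero-score segment beats the empty read.  The
    operation is idempotent.
    """
    best_score = 0.0
    best: Optional[tuple[int, int]] = None  # half-open (start, end)
    cur = 0.0
    cur_start = 0
    for i, q in enumerate(read.qualities):
        cur += q - quality_floor
        if cur < 0:
            cur = 0.0
            cur_start = i + 1
            continue
        if (
            cur > best_score
            or (cur == best_score
                and (best is None
                     or cur_start < best[0]
                     or (cur_start == best[0] and i + 1 > best[1])))
        ):
            best_score = cur
            best = (cur_start, i + 1)
    if best is None:
        return replace(read, sequence="", qualities=())
    s, e = best
    return replace(read, sequence=read.sequence[s:e], qualities=read.qualities[s:e])


def filter_read(read: ReadRecord, policy: TrimPolicy) -> FilterResult:
    """Length then ambiguity check on an already-trimmed read."""
    if len(read) < policy.min_length:
        return FilterResult(False, "length")
    seq = read.sequence.upper()
    n_ambiguous = sum(1 for b in seq if b not in "ACGT")
    if n_ambiguous > policy.max_ambiguous:
        return FilterResult(False, "ambiguity")
    return FilterResult(True)


def process_read(read: ReadRecord, policy: TrimPolicy) -> tuple[ReadRecord, FilterResult]:
    """Fixed trim -> quality trim -> filter, in that order."""
    r = trim_fixed_prefix(read, policy.fixed_prefix)
    r = quality_trim(r, policy.quality_floor)
    return r, filter_read(r, policy)


def process_reads(
    reads: Iterable[ReadRecord], policy: TrimPolicy
) -> tuple[list[ReadRecord], dict]:
    """Apply the full policy; returns kept reads plus a tally by outcome."""
    kept: list[ReadRecord] = []
    summary = {"n_in": 0, "n_kept": 0, "discarded": {"length": 0, "ambiguity": 0}}
    for read in reads:
        summary["n_in"] += 1
        trimmed, result = process_read(read, policy)
        if result.keep:
            kept.append(trimmed)
            summary["n_kept"] += 1
        else:
            summary["discarded"][result.reason] += 1
    return kept, summary
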