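"""K-mer counts-of-counts spectra and redundancy proportions.

The redundancy index of an assembly is the proportion of distinct length-k
words occurring more than once.  Spectra are tabulated per contig (windows
never span contigs), windows containing ambiguous bases are skipped, and
canonical mode merges each k-mer with its reverse complement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .curation import Contig, reverse_complement

__all__ = ["KmerSpectrum", "count_kmers", "frequency_spectrum", "compare_spectra"]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class KmerSpectrum:
    """Counts-of-counts table for length-k words.

    ``counts_of_counts[m]`` is the number of distinct k-mers observed
    exactly ``m`` times.  Invariants: sum(m * n_m) == total_kmers and
    sum(n_m) == distinct_kmers.
    """

    k: int
    counts_of_counts: dict[int, int] = field(default_factory=dict)
    total_kmers: int = 0
    distinct_kmers: int = 0
    canonical: bool = False

    def __post_init__(self) -> None:
        mass = sum(m * n for m, n in self.counts_of_counts.items())
        if mass != self.total_kmers:
            raise ValueError(
                f"count mass {mass} != total_kmers {self.total_kmers}"
            )
        if sum(self.counts_of_counts.values()) != self.distinct_kmers:
            raise ValueError("distinct_kmers does not match counts_of_counts")


def count_kmers(
    contigs: Sequence[Contig], k: int = 21, canonical: bool = False
) -> KmerSpectrum:
    """Tabulate all length-``k`` windows of a contig set.

    Windows containing a non-ACGT symbol are skipped.  With
    ``canonical=True`` each word is merged with its reverse complement
    (lexicographically smaller form kept).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for contig in contigs:
        seq = contig.sequence.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if not _VALID.issuperset(word):
                continue
            if canonical:
                word = min(word, reverse_complement(word))
            counts[word] += 1
    coc = Counter(counts.values())
    return KmerSpectrum(
        k=k,
        counts_of_counts=dict(sorted(coc.items())),
        total_kmers=sum(counts.values()),
        distinct_kmers=len(counts),
        canonical=canonical,
    )


def frequency_spectrum(spectrum: KmerSpectrum, max_class: int = 7) -> pd.DataFrame:
    """Proportion of distinct k-mers per occurrence class 1..``max_class``.

    K-mers occurring more often are pooled into a ``>max_class`` class.
    Proportions sum to 1; an empty spectrum yields an empty table.
    """
    if max_class < 1:
        raise ValueError("max_class must be >= 1")
    if spectrum.distinct_kmers == 0:
        return pd.DataFrame(columns=["occurrence_class", "n_distinct", "proportion"])
    rows = []
    pooled = 0
    for m, n in spectrum.counts_of_counts.items():
        if m > max_class:
            pooled += n
    for m in range(1, max_class + 1):
        n = spectrum.counts_of_counts.get(m, 0)
        rows.append((str(m), n, n / spectrum.distinct_kmers))
    rows.append((f">{max_class}", pooled, pooled / spectrum.distinct_kmers))
    return pd.DataFrame(rows, columns=["occurrence_class", "n_distinct", "proportion"])


def compare_spectra(
    named_spectra: Sequence[tuple[str, KmerSpectrum]], max_class: int = 7
) -> pd.DataFrame:
    """Long-format (dataset, occurrence_class, proportion) comparison table."""
    ks = {s.k for _, s in named_spectra}
    if len(ks) > 1:
        raise ValueError(f"spectra must share k, got {sorted(ks)}")
    frames = []
    for name, spectrum in named_spectra:
        tbl = frequency_spectrum(spectrum, max_class)
        tbl.insert(0, "dataset", name)
        frames.append(tbl)
    if not frames:
        return pd.DataFrame(columns=["dataset", "occurrence_class", "n_distinct", "proportion"])
    return pd.concat(frames, ignore_index=True)
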