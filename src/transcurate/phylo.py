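"""Gene-family expansion screen.

Families are seeded from clusters of contigs sharing the same best-hit
reference protein, grown with comparator-species homologs gathered at a
strict e-value threshold, filtered to sequences sharing the family's modal
protein domain, and summarized as a distance-based gene tree.  A
lineage-clustering statistic on the unrooted tree flags families whose
focal-species members group together — the signature of duplications after
speciation.

Tree building uses neighbor joining on Kimura-corrected protein distances;
ML inference is deliberately out of scope since the downstream statistic
is a topological classification that is robust to tree method at the
divergences involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "FamilyMember",
    "FamilyCluster",
    "DistanceMatrix",
    "FamilyTree",
    "LineageClusterReport",
    "seed_families",
    "assemble_family",
    "drop_divergent_members",
    "protein_alignment_stats",
    "pairwise_protein_distance",
    "distance_matrix",
    "nj_tree",
    "lineage_clusters",
]

DOMAIN_EVALUE_MAX = 0.05  # domain-hit acceptance, inclusive
MAX_PROTEIN_DISTANCE = 10.0  # cap when the Kimura correction saturates


@dataclass(frozen=True)
class FamilyMember:
    seq_id: str
    species: str
    sequence: str  # amino-acid sequence (may be empty pre-translation)


@dataclass
class FamilyCluster:
    family_id: str
    seed_subject_id: str
    members: list[FamilyMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.seq_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"family {self.family_id}: duplicate member ids")

    @property
    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m.species] = counts.get(m.species, 0) + 1
        return counts


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))


class _Node:
    """Tree node; the top node of a FamilyTree is an unrooted trifurcation."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list[tuple["_Node", float]]] = None):
        self.label = label
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{length:.6f}" for child, length in self.children
        )
        return f"({inner})"


@dataclass
class FamilyTree:
    """Unrooted species-labeled gene tree (top node is a trifurcation)."""

    root: _Node
    species: dict[str, str]  # leaf label -> species label

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick() + ";"

    def bipartitions(self) -> list[frozenset[str]]:
        """One leaf set per edge (the side below the edge's child node)."""
        out: list[frozenset[str]] = []

        def walk(node: _Node) -> list[str]:
            if node.is_leaf:
                out.append(frozenset([node.label]))
                return [node.label]
            leaves: list[str] = []
            for child, _ in node.children:
                sub = walk(child)
                leaves.extend(sub)
                if not child.is_leaf:
                    out.append(frozenset(sub))
            return leaves

        walk(self.root)
        # the root itself has no parent edge; drop the duplicate it produces
        all_leaves = frozenset(self.root.leaves())
        return [b for b in out if b != all_leaves]


@dataclass(frozen=True)
class LineageClusterReport:
    """Per-species maximal single-species cluster sizes and expansion flags."""

    clusters: Mapping[str, tuple[int, ...]]  # species -> sizes, descending
    expansion_flag: Mapping[str, bool]
    min_cluster_size: int


# ---------------------------------------------------------------------------
# family seeding / assembly
# ---------------------------------------------------------------------------

def seed_families(
    best_map,
    species_label: str,
    min_members: int = 10,
    contig_sequences: Optional[Mapping[str, str]] = None,
) -> list[FamilyCluster]:
    """One family per reference protein with >= ``min_members`` best-hit contigs.

    Members carry the focal species label; sequences stay empty (nucleotide
    contigs are translated later via the longest stop-to-stop ORF) unless
    ``contig_sequences`` supplies them.
    """
    by_subject: dict[str, list[str]] = {}
    for contig_id, hit in best_map.per_contig.items():
        by_subject.setdefault(hit.subject_id, []).append(contig_id)
    families: list[FamilyCluster] = []
    for subject in sorted(by_subject):
        contig_ids = sorted(by_subject[subject])
        if len(contig_ids) < min_members:
            continue
        members = [
            FamilyMember(
                cid, species_label,
                contig_sequences.get(cid, "") if contig_sequences else "",
            )
            for cid in contig_ids
        ]
        families.append(FamilyCluster(f"fam_{subject}", subject, members))
    return families


def assemble_family(
    cluster: FamilyCluster,
    comparator_hits: Mapping[str, pd.DataFrame],
    comparator_proteomes: Mapping[str, Mapping[str, str]],
    domain_table: Optional[pd.DataFrame] = None,
    evalue_max: float = 1e-20,
    min_members: int = 4,
) -> Optional[FamilyCluster]:
    """Add comparator homologs of the seed and apply the shared-domain filter.

    For each comparator species, proteins hit by the seed protein at
    e-value <= ``evalue_max`` (rows with qseqid == seed) are added with
    their species label.  The modal domain accession among all members
    (domain hits accepted at E <= 0.05) is then identified and members
    lacking it are dropped in a single pass.  Families falling below
    ``min_members`` are discarded (None).  A missing domain table skips
    the filter.
    """
    members = list(cluster.members)
    for species in sorted(comparator_hits):
        hits = comparator_hits[species]
        proteome = comparator_proteomes.get(species, {})
        ok = hits[(hits["qseqid"] == cluster.seed_subject_id)
                  & (hits["evalue"] <= evalue_max)]
        for sid in sorted(set(ok["sseqid"])):
            members.append(FamilyMember(sid, species, proteome.get(sid, "")))

    if domain_table is not None and not domain_table.empty:
        accepted = domain_table[domain_table["evalue"] <= DOMAIN_EVALUE_MAX]
        domains_of: dict[str, set[str]] = {}
        for row in accepted.itertuples():
            domains_of.setdefault(row.seq_id, set()).add(row.domain)
        tally: dict[str, int] = {}
        for m in members:
            for dom in domains_of.get(m.seq_id, ()):  # once per member per domain
                tally[dom] = tally.get(dom, 0) + 1
        if tally:
            modal = min(
                tally, key=lambda dom: (-tally[dom], dom)
            )  # most frequent, ties lexicographic
            members = [m for m in members if modal in domains_of.get(m.seq_id, ())]

    if len(members) < min_members:
        return None
    return FamilyCluster(cluster.family_id, cluster.seed_subject_id, members)


def drop_divergent_members(
    cluster: FamilyCluster, p_distance_ceiling: float = 0.85
) -> FamilyCluster:
    """Objective surrogate for by-eye removal of poorly aligned sequences.

    Drops members whose mean pairwise p-distance to the rest of the family
    exceeds the ceiling.
    """
    n = len(cluster.members)
    if n < 3:
        return cluster
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, pij, _ = protein_alignment_stats(
                cluster.members[i].sequence, cluster.members[j].sequence
            )
            p[i, j] = p[j, i] = pij
    mean_p = p.sum(axis=1) / (n - 1)
    kept = [m for m, mp in zip(cluster.members, mean_p) if mp <= p_distance_ceiling]
    return replace_members(cluster, kept)


def replace_members(cluster: FamilyCluster, members: list[FamilyMember]) -> FamilyCluster:
    return FamilyCluster(cluster.family_id, cluster.seed_subject_id, members)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="global")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def protein_alignment_stats(a: str, b: str) -> tuple[float, float, int]:
    """Global-alignment (score, p-distance, aligned columns) for two proteins.

    BLOSUM62 with affine gaps (first gap column -10, each further -0.5),
    terminal gaps penalized.  p is the mismatch fraction over aligned
    (non-gap) columns.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aln = _protein_aligner().align(a, b)[0]
    c = aln.counts()
    aligned = c.identities + c.mismatches
    p = c.mismatches / aligned if aligned else 1.0
    return float(aln.score), p, aligned


def pairwise_protein_distance(a: str, b: str,
                              max_distance: float = MAX_PROTEIN_DISTANCE) -> float:
    """Kimura-corrected protein distance d = -ln(1 - p - p^2/5).

    Saturated pairs (argument of the log <= 0, p around 0.85 and beyond)
    are capped at ``max_distance``.
    """
    _, p, _ = protein_alignment_stats(a, b)
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return max_distance
    return min(max_distance, -math.log(arg))


def distance_matrix(members: Sequence[FamilyMember]) -> DistanceMatrix:
    n = len(members)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_protein_distance(
                members[i].sequence, members[j].sequence
            )
    return DistanceMatrix(tuple(m.seq_id for m in members), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix,
            species: Optional[Mapping[str, str]] = None) -> FamilyTree:
    """Standard neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the (label-order) index pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the pair's summed length.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 labels for a tree")
    d = dm.d.copy()
    nodes: list[_Node] = [_Node(label) for label in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li  # transfer deficit to the sister branch
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]

    # closed-form three-point finish
    (da, db, dc) = (d[0, 1], d[0, 2], d[1, 2])
    la = max(0.0, 0.5 * (da + db - dc))
    lb = max(0.0, 0.5 * (da + dc - db))
    lc = max(0.0, 0.5 * (db + dc - da))
    root = _Node(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])
    return FamilyTree(root, dict(species) if species else {})


# ---------------------------------------------------------------------------
# lineage clustering statistic
# ---------------------------------------------------------------------------

def lineage_clusters(tree: FamilyTree, min_cluster_size: int = 4) -> LineageClusterReport:
    """Single-species clusters defined by edges of the unrooted tree.

    Both leaf sets of every edge bipartition are examined; sets whose
    leaves all share one species are candidate clusters, and maximal
    candidates (not contained in a larger one) are reported per species.
    ``expansion_flag`` is true for a species with some cluster of size
    >= ``min_cluster_size``.
    """
    leaves = tree.leaf_labels
    unlabeled = [x for x in leaves if x not in tree.species]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled[:5]}")
    all_leaves = frozenset(leaves)

    candidates: set[frozenset[str]] = set()
    for side in tree.bipartitions():
        for s in (side, all_leaves - side):
            if s and len({tree.species[x] for x in s}) == 1:
                candidates.add(s)

    maximal = [
        s for s in candidates
        if not any(s < other for other in candidates)
    ]
    clusters: dict[str, list[int]] = {}
    for s in maximal:
        sp = tree.species[next(iter(s))]
        clusters.setdefault(sp, []).append(len(s))
    report_clusters = {
        sp: tuple(sorted(sizes, reverse=True)) for sp, sizes in clusters.items()
    }
    flags = {
        sp: any(size >= min_cluster_size for size in sizes)
        for sp, sizes in report_clusters.items()
    }
    for sp in set(tree.species.values()) - set(flags):
        report_clusters[sp] = ()
        flags[sp] = False
    return LineageClusterReport(report_clusters, flags, min_cluster_size)
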