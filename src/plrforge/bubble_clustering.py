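"""Bubble-vector extraction, consistency distance, and clustering.

Variant co-occurrence is recovered from *bubble-linking* fragments: reads
(or paired-end fragments, treated as one unit) that span two or more bubble
columns with retained alleles.  Each linking fragment i is represented as a
vector V_i = (v_i1, ..., v_iB) over the container's B bubble columns, with
v_ij in {A, C, G, T, '-'} and '-' marking a column the fragment does not
inform.

The consistency distance between two vectors counts positions where both
are informative and disagree; two vectors sharing no informative position
are non-comparable and receive a fixed sentinel distance larger than 1
(B + 1 here), which keeps them in different clusters.  Hierarchical
agglomerative clustering cut at distance 0 is then exactly the connected
components of the zero-distance relation; they are computed with union-find
for determinism and speed.

Each cluster is condensed into one *bubble combination*: per column the
common allele of the cluster's members, or '-' where no member is
informative.  Clusters are assumed conflict-free (all members agree wherever
they overlap); transitive conflicts, which can arise on real data, are
resolved by multiplicity-weighted majority and logged.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .plr_graph import PLRGraph

logger = logging.getLogger(__name__)

#: Symbol for "no linking information at this bubble column".
GAP = "-"


@dataclass(frozen=True)
class BubbleVector:
    """One linking fragment's alleles over the B bubble columns.

    Identical element lists are collapsed into one vector with summed
    ``multiplicity``; ``fragment_id`` then names one representative.
    """

    fragment_id: str
    elements: Tuple[str, ...]
    multiplicity: int = 1

    @property
    def first_informative(self) -> int:
        for i, e in enumerate(self.elements):
            if e != GAP:
                return i
        return len(self.elements)

    def n_informative(self) -> int:
        return sum(e != GAP for e in self.elements)


@dataclass(frozen=True)
class BubbleCombination:
    """A cluster-consensus allele assignment; seeds one PLR path."""

    elements: Tuple[str, ...]
    support: int
    n_conflicts: int = 0


def non_comparable_distance(n_bubbles: int) -> int:
    """Sentinel distance for vector pairs sharing no informative position."""
    return n_bubbles + 1


def vector_distance(v1: BubbleVector, v2: BubbleVector) -> int:
    """Consistency distance D(V_i, V_j).

    Sum over columns of 1 where both elements are informative and unequal.
    Pairs with no shared informative column get the sentinel
    :func:`non_comparable_distance` (> 1), separating them into different
    clusters at cutoff 0.
    """
    if len(v1.elements) != len(v2.elements):
        raise ValueError(
            f"bubble vectors of unequal length: {len(v1.elements)} vs {len(v2.elements)}"
        )
    comparable = False
    d = 0
    for a, b in zip(v1.elements, v2.elements):
        if a == GAP or b == GAP:
            continue
        comparable = True
        if a != b:
            d += 1
    if not comparable:
        return non_comparable_distance(len(v1.elements))
    return d


def extract_bubble_vectors(graph: PLRGraph) -> List[BubbleVector]:
    """Build bubble vectors from the fragments crossing bubble columns.

    A fragment's element at bubble column j is its base there if that base
    is a retained allele of the column; a fragment covering a column only
    with a filtered-out (low-frequency) allele is uninformative ('-') there.
    Only fragments informative at >= 2 bubble columns qualify as linking
    units.  With fewer than two bubble columns there is nothing to link and
    the result is empty.
    """
    bubbles = graph.bubble_columns
    if len(bubbles) < 2:
        return []
    per_fragment: Dict[str, Dict[int, str]] = defaultdict(dict)
    for j, bc in enumerate(bubbles):
        col = graph.container.columns[bc.col_index]
        retained = bc.alleles
        for frag, base in col.contributors.items():
            if base in retained:
                per_fragment[frag][j] = base

    collapsed: Dict[Tuple[str, ...], List[str]] = defaultdict(list)
    for frag, hits in per_fragment.items():
        if len(hits) < 2:
            continue
        elements = tuple(hits.get(j, GAP) for j in range(len(bubbles)))
        collapsed[elements].append(frag)

    vectors = [
        BubbleVector(
            fragment_id=min(frags), elements=elements, multiplicity=len(frags)
        )
        for elements, frags in collapsed.items()
    ]
    vectors.sort(key=lambda v: (v.first_informative, v.elements))
    return vectors


def cluster_vectors(vectors: Sequence[BubbleVector]) -> List[List[BubbleVector]]:
    """Agglomerate vectors at distance cutoff 0.

    With cutoff 0 single-linkage agglomeration merges exactly the pairs at
    distance 0 and their transitive closure, i.e. the connected components
    of the zero-distance graph; computed here via union-find.

    Cluster order is deterministic: ascending minimum first-informative
    position of the members, ties broken by descending total multiplicity,
    then by the sorted member element strings.
    """
    n = len(vectors)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if vector_distance(vectors[i], vectors[j]) == 0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups: Dict[int, List[BubbleVector]] = defaultdict(list)
    for i, v in enumerate(vectors):
        groups[find(i)].append(v)

    def sort_key(cluster: List[BubbleVector]):
        return (
            min(v.first_informative for v in cluster),
            -sum(v.multiplicity for v in cluster),
            tuple(sorted("".join(v.elements) for v in cluster)),
        )

    clusters = sorted(groups.values(), key=sort_key)
    return [
        sorted(c, key=lambda v: (v.first_informative, v.elements, v.fragment_id))
        for c in clusters
    ]


def build_combinations(
    clusters: Sequence[Sequence[BubbleVector]],
    n_bubbles: int,
    context: str = "",
) -> List[BubbleCombination]:
    """Condense each cluster into one bubble combination.

    Per bubble position the combination takes the common informative
    element of the member vectors; positions no member informs get '-'
    (rendered as 'N' in sequences).  If no linking vectors exist at all —
    including the degenerate n_bubbles in {0, 1} case — a single all-'-'
    combination is emitted so the container still yields one PLR.

    Clusters should be conflict-free by construction; a transitive conflict
    (members disagreeing at a shared position despite pairwise zero links)
    is resolved by multiplicity-weighted majority, ties to the
    lexicographically smallest base, and logged as a warning.
    """
    if not clusters:
        return [BubbleCombination(elements=(GAP,) * n_bubbles, support=0)]

    out: List[BubbleCombination] = []
    for cluster in clusters:
        members = sorted(cluster, key=lambda v: (v.first_informative, v.elements))
        elements: List[str] = []
        n_conflicts = 0
        for j in range(n_bubbles):
            votes: Counter = Counter()
            for v in members:
                if v.elements[j] != GAP:
                    votes[v.elements[j]] += v.multiplicity
            if not votes:
                elements.append(GAP)
            elif len(votes) == 1:
                elements.append(next(iter(votes)))
            else:
                n_conflicts += 1
                top = max(votes.values())
                base = min(b for b, c in votes.items() if c == top)
                elements.append(base)
                logger.warning(
                    "transitive conflict at bubble %d%s: votes=%s, kept %s",
                    j,
                    f" ({context})" if context else "",
                    dict(votes),
                    base,
                )
        out.append(
            BubbleCombination(
                elements=tuple(elements),
                support=sum(v.multiplicity for v in members),
                n_conflicts=n_conflicts,
            )
        )
    return out
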