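"""Bubble vectors, the consistency distance, clustering, and combinations."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plrforge.bubble_clustering import (
    GAP,
    BubbleVector,
    build_combinations,
    cluster_vectors,
    extract_bubble_vectors,
    non_comparable_distance,
    vector_distance,
)
from plrforge.pipeline import process_container
from plrforge.plr_graph import build_graph

from conftest import container_from_reads


def vec(*elements, mult=1, name="f"):
    return BubbleVector(fragment_id=name, elements=tuple(elements), multiplicity=mult)


class TestVectorDistance:
    def test_identity_is_zero(self):
        v = vec("T", "A", "-", "-")
        assert vector_distance(v, v) == 0

    def test_single_disagreement(self):
        assert vector_distance(vec("T", "A", "-", "-"), vec("C", "A", "-", "-")) == 1

    def test_gap_positions_do_not_count(self):
        assert vector_distance(vec("T", "A", "-", "-"), vec("-", "A", "C", "-")) == 0

    def test_non_comparable_pair_gets_sentinel(self):
        d = vector_distance(vec("T", "A", "-", "-"), vec("-", "-", "T", "T"))
        assert d == non_comparable_distance(4)
        assert d > 1

    def test_symmetric(self):
        a, b = vec("T", "A", "C", "-"), vec("C", "A", "-", "G")
        assert vector_distance(a, b) == vector_distance(b, a)

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError, match="unequal length"):
            vector_distance(vec("A", "C"), vec("A", "C", "G"))


def brute_force_clusters(vectors):
    """Independent oracle: full pairwise distance matrix + connected components."""
    g = nx.Graph()
    g.add_nodes_from(range(len(vectors)))
    for i, j in itertools.combinations(range(len(vectors)), 2):
        if vector_distance(vectors[i], vectors[j]) == 0:
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def random_vectors(rng, n_bubbles, n):
    """Random vector sets mixing haplotype-derived windows and noise."""
    haplotypes = ["".join(rng.choice(list("ACGT"), n_bubbles)) for _ in range(2)]
    out = []
    for i in range(n):
        if rng.random() < 0.7:
            h = haplotypes[rng.integers(2)]
            lo = rng.integers(0, n_bubbles - 1)
            hi = rng.integers(lo + 2, n_bubbles + 1)
            elements = tuple(
                h[j] if lo <= j < hi else GAP for j in range(n_bubbles)
            )
        else:
            k = rng.integers(2, n_bubbles + 1)
            info = rng.choice(n_bubbles, size=k, replace=False)
            elements = tuple(
                rng.choice(list("ACGT")) if j in info else GAP
                for j in range(n_bubbles)
            )
        out.append(BubbleVector(f"f{i}", elements))
    return out


class TestClusterVectors:
    def test_worked_example_two_clusters(self, worked_example_vectors):
        clusters = cluster_vectors(worked_example_vectors)
        assert len(clusters) == 2
        members = [{v.fragment_id for v in c} for c in clusters]
        assert members == [{"r1", "r2", "r3", "r4"}, {"r5", "r6", "r7", "r8"}]

    def test_identical_vectors_one_cluster(self):
        clusters = cluster_vectors([vec("T", "A", "-", "-"), vec("T", "A", "-", "-")])
        assert len(clusters) == 1

    def test_distance_one_separates(self):
        clusters = cluster_vectors([vec("T", "A", "-", "-"), vec("C", "A", "-", "-")])
        assert len(clusters) == 2

    def test_empty_input(self):
        assert cluster_vectors([]) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n_bubbles = int(rng.integers(2, 9))
            n = int(rng.integers(1, 51))
            vectors = random_vectors(rng, n_bubbles, n)
            ours = {
                frozenset(vectors.index(v) for v in cluster)
                for cluster in cluster_vectors(vectors)
            }
            assert ours == brute_force_clusters(vectors)

    def test_conserves_vectors(self):
        rng = np.random.default_rng(7)
        vectors = random_vectors(rng, 6, 30)
        clusters = cluster_vectors(vectors)
        assert sum(len(c) for c in clusters) == len(vectors)

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(11)
        vectors = random_vectors(rng, 5, 20)
        base = cluster_vectors(vectors)
        for seed in range(3):
            perm = list(vectors)
            np.random.default_rng(seed).shuffle(perm)
            assert cluster_vectors(perm) == base


class TestBuildCombinations:
    def test_chained_linking_reads_integrate(self):
        cluster = [vec("T", "A", "-", "-"), vec("-", "A", "C", "-"), vec("-", "-", "C", "G")]
        combos = build_combinations([cluster], 4)
        assert combos[0].elements == ("T", "A", "C", "G")
        assert combos[0].support == 3

    def test_unlinked_positions_stay_gap(self):
        combos = build_combinations([[vec("T", "A", "-", "-")]], 4)
        assert combos[0].elements == ("T", "A", "-", "-")

    def test_single_bubble_yields_all_gap(self):
        combos = build_combinations([], 1)
        assert [c.elements for c in combos] == [(GAP,)]

    def test_no_linking_vectors_yields_all_gap(self):
        combos = build_combinations([], 3)
        assert [c.elements for c in combos] == [(GAP, GAP, GAP)]

    def test_conflict_resolved_by_weighted_majority(self, caplog):
        cluster = [
            vec("T", "A", "-", mult=3),
            vec("-", "A", "C", mult=1),
            vec("G", "-", "C", mult=1),  # conflicts with T at position 0
        ]
        with caplog.at_level("WARNING"):
            combos = build_combinations([cluster], 3)
        assert combos[0].elements == ("T", "A", "C")
        assert combos[0].n_conflicts == 1
        assert "transitive conflict" in caplog.text

    def test_conflict_tie_breaks_lexicographically(self):
        cluster = [vec("T", "A", "-"), vec("-", "A", "C"), vec("G", "-", "C")]
        combos = build_combinations([cluster], 3)
        assert combos[0].elements[0] == "G"  # G < T on equal weight

    def test_worked_example_combinations(self, worked_example_vectors):
        combos = build_combinations(cluster_vectors(worked_example_vectors), 4)
        assert [c.elements for c in combos] == [
            ("T", "A", "C", "G"),
            ("C", "G", "T", "T"),
        ]


class TestExtractBubbleVectors:
    def reads(self):
        # two haplotypes over 9 columns differing at offsets 2 and 6
        return [
            ("h1a", 0, "AATAAATAA"),
            ("h1b", 0, "AATAAATAA"),
            ("h2a", 0, "AACAAACAA"),
            ("h2b", 0, "AACAAACAA"),
        ]

    def test_fragments_spanning_two_bubbles(self):
        graph = build_graph(container_from_reads(self.reads()))
        vectors = extract_bubble_vectors(graph)
        assert {v.elements for v in vectors} == {("T", "T"), ("C", "C")}
        assert all(v.multiplicity == 2 for v in vectors)

    def test_fragment_covering_one_bubble_excluded(self):
        reads = self.reads() + [("short", 0, "AAT")]  # covers bubble 0 only
        graph = build_graph(container_from_reads(reads))
        vectors = extract_bubble_vectors(graph)
        assert all(v.fragment_id != "short" for v in vectors)
        assert sum(v.multiplicity for v in vectors) == 4

    def test_paired_mates_share_one_vector(self):
        # fragment "pair" covers bubble 0 with mate 1 and bubble 1 with mate 2
        reads = self.reads() + [("pair", 0, "AATA"), ("pair", 5, "ATAA")]
        graph = build_graph(container_from_reads(reads))
        vectors = extract_bubble_vectors(graph)
        tt = next(v for v in vectors if v.elements == ("T", "T"))
        assert tt.multiplicity == 3  # h1a, h1b, pair collapsed

    def test_filtered_allele_gives_gap(self):
        # at offset 6 fragment "odd" carries a singleton G against T:3/C:2,
        # below half the maximum -> filtered -> '-' there -> "odd" informs
        # only one bubble and is not a linking fragment
        reads = [
            ("h1a", 0, "AATAAATAA"),
            ("h1b", 0, "AATAAATAA"),
            ("h1c", 0, "AATAAATAA"),
            ("h2a", 0, "AACAAACAA"),
            ("h2b", 0, "AACAAACAA"),
            ("odd", 0, "AATAAAGAA"),
        ]
        graph = build_graph(container_from_reads(reads))
        assert graph.bubble_offsets == (2, 6)  # G filtered: 1 < 0.5 * 3
        vectors = extract_bubble_vectors(graph)
        assert all(v.fragment_id != "odd" for v in vectors)

    def test_fewer_than_two_bubbles_no_vectors(self):
        graph = build_graph(container_from_reads([("a", 0, "ATA"), ("b", 0, "ACA")]))
        assert graph.n_bubbles == 1
        assert extract_bubble_vectors(graph) == []
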