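"""PLR graph construction: normal nodes and bubble columns.

Each container's column alignment is converted into an ordered graph of two
node types.  A *normal node* is a maximal run of columns each occupied by a
single nucleotide after frequency filtering; a *bubble column* is a column
where two or more nucleotides survive the filter (each surviving nucleotide
is one bubble node).  Node order along the container defines the directed
edges implicitly.

The frequency filter drops alleles whose count is strictly below
``min_rel_freq`` times the count of the most frequent allele in the column
(default 0.5; a count at exactly the boundary is retained).  A column whose
alleles are reduced to one by the filter joins the flanking normal run.

Normal-node sequence is the consensus *aligned* base, not the reference
base: the reference only supplies coordinates, so a column where every read
disagrees with the reference contributes the read base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

from .alignment_pileup import PileupColumn
from .container_builder import PLRContainer

DEFAULT_MIN_REL_FREQ = 0.5


@dataclass
class BubbleColumn:
    """A container-relative column with >= 2 retained alleles."""

    col_index: int  # 0-based offset within the container
    alleles: Dict[str, int]


@dataclass
class NormalNode:
    """A maximal run of single-allele columns [start, end) within the container."""

    start: int
    end: int
    sequence: str


@dataclass
class PLRGraph:
    container: PLRContainer
    normal_nodes: List[NormalNode] = field(default_factory=list)
    bubble_columns: List[BubbleColumn] = field(default_factory=list)

    @property
    def n_bubbles(self) -> int:
        return len(self.bubble_columns)

    @property
    def bubble_offsets(self) -> Tuple[int, ...]:
        return tuple(b.col_index for b in self.bubble_columns)


def classify_column(
    col: PileupColumn, min_rel_freq: float = DEFAULT_MIN_REL_FREQ
) -> Union[str, Dict[str, int]]:
    """Apply the relative-frequency rule to one column.

    Returns the single retained base (str) for a monoallelic outcome, or a
    dict of retained ``base -> count`` when >= 2 alleles survive.  An allele
    is retained iff ``count >= min_rel_freq * max_count`` (boundary
    inclusive: only ratios strictly below the cutoff are discarded).
    """
    counts = col.counts
    if not counts:
        raise ValueError(f"column {col.ref_id}:{col.pos} has no counted bases")
    m = max(counts.values())
    retained = {b: c for b, c in sorted(counts.items()) if c >= min_rel_freq * m}
    if len(retained) == 1:
        return next(iter(retained))
    return retained


def build_graph(
    container: PLRContainer, min_rel_freq: float = DEFAULT_MIN_REL_FREQ
) -> PLRGraph:
    """Convert a container into its PLR graph.

    Bubble columns appear in position order; normal nodes are the maximal
    single-base runs between them.  A container with no bubble columns
    yields a single normal node spanning the whole container, from which a
    single PLR sequence will be generated.
    """
    graph = PLRGraph(container=container)
    run_start: int | None = None
    run_bases: List[str] = []

    for offset, col in enumerate(container.columns):
        outcome = classify_column(col, min_rel_freq)
        if isinstance(outcome, str):
            if run_start is None:
                run_start = offset
            run_bases.append(outcome)
        else:
            if run_start is not None:
                graph.normal_nodes.append(
                    NormalNode(run_start, offset, "".join(run_bases))
                )
                run_start, run_bases = None, []
            graph.bubble_columns.append(BubbleColumn(offset, outcome))
    if run_start is not None:
        graph.normal_nodes.append(
            NormalNode(run_start, len(container.columns), "".join(run_bases))
        )
    return graph
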