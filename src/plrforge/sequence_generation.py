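"""PLR path assembly, N-masking, and FASTA output.

A PLR path walks its container left to right, copying normal-node bases and
substituting one bubble combination's allele at each bubble column ('-'
becomes 'N': the bubble could not be linked).  Every path therefore has the
container's exact length, and paths of one container differ only at bubble
offsets.

N-PLRs are the variant-blind counterpart used for comparisons: one sequence
per container with 'N' at *every* bubble offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

from .bubble_clustering import GAP, BubbleCombination
from .plr_graph import PLRGraph

logger = logging.getLogger(__name__)

DEFAULT_LINE_WIDTH = 70


@dataclass(frozen=True)
class PLRSequence:
    """One emitted pseudo-long read.

    ``sequence`` spans exactly [container_start, container_end) on the
    reference; 'N' appears only at bubble offsets whose combination element
    was '-'.  ``support`` is the total multiplicity of the linking vectors
    behind this path (0 for an unlinked/degenerate path).
    """

    ref_id: str
    container_start: int
    container_end: int
    path_index: int
    sequence: str
    bubble_offsets: Tuple[int, ...]
    support: int

    @property
    def n_variant_positions(self) -> int:
        return len(self.bubble_offsets)

    @property
    def name(self) -> str:
        return (
            f"{self.ref_id}:{self.container_start + 1}-{self.container_end}"
            f"|plr{self.path_index}|support={self.support}"
            f"|vars={self.n_variant_positions}"
        )


def assemble_paths(
    graph: PLRGraph, combinations: Sequence[BubbleCombination]
) -> List[PLRSequence]:
    """Convert each bubble combination into one PLR sequence.

    Paths are numbered from 1 in combination (cluster) order, keeping
    output byte-stable across runs.  A graph without bubbles yields exactly
    one sequence — the single normal node.
    """
    container = graph.container
    length = len(container)
    template = [""] * length
    for node in graph.normal_nodes:
        template[node.start : node.end] = node.sequence
    offsets = graph.bubble_offsets

    out: List[PLRSequence] = []
    for k, combo in enumerate(combinations, start=1):
        if len(combo.elements) != len(offsets):
            raise ValueError(
                f"combination length {len(combo.elements)} != number of "
                f"bubble columns {len(offsets)}"
            )
        chars = list(template)
        for off, element in zip(offsets, combo.elements):
            chars[off] = "N" if element == GAP else element
        out.append(
            PLRSequence(
                ref_id=container.ref_id,
                container_start=container.start,
                container_end=container.end,
                path_index=k,
                sequence="".join(chars),
                bubble_offsets=offsets,
                support=combo.support,
            )
        )
    return out


def mask_to_nplr(plrs: Sequence[PLRSequence]) -> List[PLRSequence]:
    """Collapse each container's V-PLRs into a single N-masked PLR.

    Every bubble offset becomes 'N'; normal bases are kept.  Input may mix
    containers; each container group collapses to one record.
    """
    groups: Dict[Tuple[str, int, int], List[PLRSequence]] = {}
    for p in plrs:
        groups.setdefault((p.ref_id, p.container_start, p.container_end), []).append(p)

    out: List[PLRSequence] = []
    for (ref_id, start, end), group in groups.items():
        lengths = {len(p.sequence) for p in group}
        if len(lengths) != 1:
            raise ValueError(
                f"V-PLRs of container {ref_id}:{start}-{end} have unequal lengths"
            )
        first = group[0]
        chars = list(first.sequence)
        for off in first.bubble_offsets:
            chars[off] = "N"
        out.append(
            PLRSequence(
                ref_id=ref_id,
                container_start=start,
                container_end=end,
                path_index=1,
                sequence="".join(chars),
                bubble_offsets=first.bubble_offsets,
                support=sum(p.support for p in group),
            )
        )
    return out


def write_fasta(
    plrs: Sequence[PLRSequence],
    out_path: Union[str, Path],
    line_width: int = DEFAULT_LINE_WIDTH,
) -> None:
    """Write PLRs as FASTA, headers ``ref:start-end|plrK|support=s|vars=n``.

    Coordinates in headers are 1-based inclusive.  An empty input produces
    an empty (valid) FASTA with a warning.
    """
    if not plrs:
        logger.warning("no PLR sequences to write; %s will be empty", out_path)
    with open(out_path, "w") as handle:
        for p in plrs:
            handle.write(f">{p.name}\n")
            for i in range(0, len(p.sequence), line_width):
                handle.write(p.sequence[i : i + line_width] + "\n")


def write_manifest(plrs: Sequence[PLRSequence], out_path: Union[str, Path]) -> None:
    """Write a TSV manifest, one row per PLR."""
    with open(out_path, "w") as handle:
        handle.write(
            "ref_id\tstart\tend\tpath_index\tlength\tn_variant_positions\tsupport\n"
        )
        for p in plrs:
            handle.write(
                f"{p.ref_id}\t{p.container_start}\t{p.container_end}"
                f"\t{p.path_index}\t{len(p.sequence)}"
                f"\t{p.n_variant_positions}\t{p.support}\n"
            )
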