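"""Shared fixtures: in-memory SAM construction and hand-built containers."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import pysam
import pytest

from plrforge.alignment_pileup import PileupColumn
from plrforge.container_builder import PLRContainer


def make_header(refs: Dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": rid, "LN": len(seq)} for rid, seq in refs.items()],
        }
    )


def make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    ref: str,
    pos: int,
    seq: str,
    mapq: int = 30,
    flag: int = 0,
    cigar: str | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = list(header.references).index(ref)
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    return a


def write_sam(path, refs: Dict[str, str], reads: Sequence[tuple]) -> None:
    """reads: tuples (name, ref, pos, seq[, mapq[, flag[, cigar]]]) sorted by pos."""
    header = make_header(refs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            out.write(make_segment(header, *r))


def container_from_reads(
    reads: Sequence[Tuple[str, int, str]], ref_id: str = "r1", start: int = 0
) -> PLRContainer:
    """Build a fully covered container from (fragment_id, start, bases) reads.

    Reads must jointly cover a contiguous interval beginning at ``start``.
    """
    per_pos: Dict[int, Dict[str, str]] = {}
    for frag, rstart, bases in reads:
        for i, b in enumerate(bases):
            per_pos.setdefault(rstart + i, {})[frag] = b
    positions = sorted(per_pos)
    assert positions[0] == start and positions[-1] - start == len(positions) - 1, (
        "reads must cover a contiguous interval"
    )
    columns = [
        PileupColumn(ref_id=ref_id, pos=p, contributors=per_pos[p]) for p in positions
    ]
    return PLRContainer(
        ref_id=ref_id, start=start, end=positions[-1] + 1, columns=columns
    )


@pytest.fixture
def worked_example_vectors():
    """Eight linking-read vectors over four bubble columns: two haplotype
    groups (TACG and CGTT) connected by partially overlapping reads."""
    from plrforge.bubble_clustering import BubbleVector

    elems = [
        ("T", "A", "-", "-"),
        ("-", "A", "C", "-"),
        ("-", "-", "C", "G"),
        ("T", "A", "C", "-"),
        ("C", "G", "-", "-"),
        ("-", "G", "T", "-"),
        ("-", "-", "T", "T"),
        ("-", "-", "T", "T"),
    ]
    return [BubbleVector(f"r{i + 1}", e) for i, e in enumerate(elems)]
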