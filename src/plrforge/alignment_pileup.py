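"""Alignment ingestion and per-fragment pileup construction.

Reads coordinate-sorted SAM/BAM against one or more microbial reference
genomes, applies the standard mpileup-style read filters (mapping quality,
unmapped/QC-fail/duplicate/secondary), and piles passing base calls onto
reference positions.  Unlike a textual pileup, every column remembers *which
fragment* contributed *which base*: downstream micro-haplotype phasing needs
per-fragment identity, because a paired-end fragment is the unit that links
variant alleles at distant columns.

Conventions
-----------
* Coordinates are 0-based half-open throughout.
* Both mates of a pair share one ``fragment_id`` (the query name).  If the
  mates overlap a column with the same base the fragment is counted once; if
  they disagree the fragment contributes nothing there (conflicting
  evidence).
* Insertions relative to the reference have no reference coordinate and are
  ignored.  A read carrying a deletion or an ``N`` at a column is treated as
  not covering that column.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Union

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Bases that may enter pileup counts (the bubble alphabet).
COUNTED_BASES = frozenset("ACGT")

#: Characters permitted in a reference sequence (after upper-casing).
_REF_ALPHABET = frozenset("ACGTN")

#: Marker for a fragment whose two mates disagree at a column.
_CONFLICT = object()

DEFAULT_MIN_MAPQ = 20


@dataclass
class PileupColumn:
    """One covered reference position.

    Attributes
    ----------
    ref_id : str
        Reference sequence name.
    pos : int
        0-based reference position.
    contributors : dict
        ``fragment_id -> base`` for every fragment contributing a single
        unambiguous base in :data:`COUNTED_BASES` at this position.
    """

    ref_id: str
    pos: int
    contributors: Dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> Counter:
        """Allele counts: the multiset of contributor bases."""
        return Counter(self.contributors.values())

    @property
    def depth(self) -> int:
        return len(self.contributors)


def load_reference(fasta_path: Union[str, Path]) -> Dict[str, str]:
    """Load a (multi-)FASTA of reference replicons.

    The reference identifier is the first whitespace-delimited token of the
    header line.  Sequences are upper-cased; anything outside ``ACGTN`` is a
    fatal error, as are duplicate identifiers and empty files.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"reference FASTA not found: {fasta_path}")
    refs: Dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        ref_id = record.id
        if ref_id in refs:
            raise ValueError(f"duplicate reference identifier {ref_id!r} in {fasta_path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _REF_ALPHABET
        if bad:
            raise ValueError(
                f"reference {ref_id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        refs[ref_id] = seq
    if not refs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return refs


def filter_alignment(seg: pysam.AlignedSegment, min_mapq: int = DEFAULT_MIN_MAPQ) -> bool:
    """Return True iff the alignment passes the pileup read filters.

    Mirrors ``samtools mpileup -q <min_mapq> --ff UNMAP,QCFAIL,DUP,SECONDARY``
    (the mapq bound is inclusive).  Supplementary alignments are excluded as
    well so a fragment can contribute at most one base per column.
    """
    if seg.is_unmapped or seg.is_qcfail or seg.is_duplicate:
        return False
    if seg.is_secondary or seg.is_supplementary:
        return False
    return seg.mapping_quality >= min_mapq


def _iter_segments(
    alignments: Union[str, Path, pysam.AlignmentFile, Iterable[pysam.AlignedSegment]],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as handle:
            yield from handle
    else:
        yield from alignments


def build_pileup(
    alignments: Union[str, Path, pysam.AlignmentFile, Iterable[pysam.AlignedSegment]],
    refs: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Dict[str, List[PileupColumn]]:
    """Pile filtered reads up on reference positions, fragment-aware.

    Parameters
    ----------
    alignments
        Path to a coordinate-sorted SAM/BAM, an open
        :class:`pysam.AlignmentFile`, or an iterable of aligned segments
        (coordinate-sorted within each reference).
    refs
        ``ref_id -> sequence`` as returned by :func:`load_reference`.
    min_mapq
        Minimum mapping quality (inclusive).

    Returns
    -------
    dict
        ``ref_id -> list of PileupColumn`` ordered by position.  Positions
        with zero passing coverage are absent; references with no coverage
        map to empty lists.
    """
    # per reference: pos -> {fragment_id -> base | _CONFLICT}
    raw: Dict[str, Dict[int, Dict[str, object]]] = {rid: {} for rid in refs}
    last_start: Dict[str, int] = {}
    finished: set = set()
    current_ref: str | None = None

    for seg in _iter_segments(alignments):
        if not filter_alignment(seg, min_mapq):
            continue
        rid = seg.reference_name
        if rid not in raw:
            raise ValueError(
                f"alignment {seg.query_name!r} references unknown sequence {rid!r}"
            )
        if rid != current_ref:
            if rid in finished:
                raise ValueError(f"input not coordinate-sorted: {rid!r} reappears")
            if current_ref is not None:
                finished.add(current_ref)
            current_ref = rid
        start = seg.reference_start
        if start < last_start.get(rid, 0):
            raise ValueError(
                f"input not coordinate-sorted: {rid}:{start} after "
                f"{rid}:{last_start[rid]}"
            )
        last_start[rid] = start

        seq = seg.query_sequence
        if seq is None:
            continue
        frag = seg.query_name
        columns = raw[rid]
        for qpos, rpos in seg.get_aligned_pairs(matches_only=False):
            if rpos is None:  # insertion or soft clip: no reference coordinate
                continue
            if qpos is None:  # deletion: read does not cover this column
                continue
            base = seq[qpos].upper()
            if base not in COUNTED_BASES:  # N etc.: treated as not covering
                continue
            col = columns.setdefault(rpos, {})
            prev = col.get(frag)
            if prev is None:
                col[frag] = base
            elif prev is not _CONFLICT and prev != base:
                col[frag] = _CONFLICT  # overlapping mates disagree

    out: Dict[str, List[PileupColumn]] = {}
    for rid in refs:
        cols: List[PileupColumn] = []
        for pos in sorted(raw[rid]):
            contributors = {
                f: b for f, b in raw[rid][pos].items() if b is not _CONFLICT
            }
            if contributors:
                cols.append(PileupColumn(ref_id=rid, pos=pos, contributors=contributors))
        out[rid] = cols
    return out
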