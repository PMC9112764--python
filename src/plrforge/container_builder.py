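"""Segmentation of covered reference regions into PLR containers.

A PLR container is a maximal reference interval with contiguous read
coverage; the reference is broken at every position without a single mapped
base.  Containers shorter than a minimum length (default 100 bp) are
discarded — too short to be worth elongating.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Union

from .alignment_pileup import PileupColumn

DEFAULT_MIN_CONTAINER_LEN = 100


@dataclass
class PLRContainer:
    """A maximal contiguously covered reference interval [start, end)."""

    ref_id: str
    start: int
    end: int
    columns: List[PileupColumn]

    def __len__(self) -> int:
        return self.end - self.start


def build_containers(
    columns: Mapping[str, List[PileupColumn]],
    min_container_len: int = DEFAULT_MIN_CONTAINER_LEN,
) -> List[PLRContainer]:
    """Break each reference at uncovered positions into containers.

    Runs of consecutive covered positions become containers; any run shorter
    than ``min_container_len`` is dropped (strictly shorter: a run of exactly
    the cutoff length survives).  Output is sorted by (ref_id, start) with
    ref_ids in input-mapping order.
    """
    out: List[PLRContainer] = []
    for ref_id, cols in columns.items():
        if not cols:
            continue
        run: List[PileupColumn] = [cols[0]]
        for col in cols[1:]:
            if col.pos == run[-1].pos + 1:
                run.append(col)
            else:
                _flush(out, ref_id, run, min_container_len)
                run = [col]
        _flush(out, ref_id, run, min_container_len)
    return out


def _flush(
    out: List[PLRContainer],
    ref_id: str,
    run: List[PileupColumn],
    min_container_len: int,
) -> None:
    if len(run) >= min_container_len:
        out.append(
            PLRContainer(
                ref_id=ref_id,
                start=run[0].pos,
                end=run[-1].pos + 1,
                columns=list(run),
            )
        )


def write_bed(containers: List[PLRContainer], out_path: Union[str, Path]) -> None:
    """Write container intervals as BED (0-based half-open)."""
    with open(out_path, "w") as handle:
        for k, c in enumerate(containers, start=1):
            handle.write(f"{c.ref_id}\t{c.start}\t{c.end}\tcontainer_{k}\n")
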