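"""End-to-end PLR generation: pileup -> containers -> graphs -> PLRs.

`run_plr_gen` is the file-level entry point the CLI wraps; `generate_plrs`
and `process_container` are the in-memory building blocks tests and library
users compose directly.  Each reference is processed independently; output
order is references in FASTA order, containers by start, paths in cluster
order — so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .alignment_pileup import build_pileup, load_reference
from .bubble_clustering import (
    build_combinations,
    cluster_vectors,
    extract_bubble_vectors,
)
from .container_builder import PLRContainer, build_containers, write_bed
from .plr_graph import PLRGraph, build_graph
from .sequence_generation import (
    PLRSequence,
    assemble_paths,
    mask_to_nplr,
    write_fasta,
    write_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One PLR generation run; defaults match the published tool's."""

    bam_path: Union[str, Path]
    ref_fasta: Union[str, Path]
    out_fasta: Union[str, Path]
    min_mapq: int = 20
    min_container_len: int = 100
    min_rel_freq: float = 0.5
    min_cluster_support: int = 1
    bed_path: Optional[Union[str, Path]] = None
    manifest_path: Optional[Union[str, Path]] = None
    nplr_mode: bool = False
    drop_n: bool = False
    log_level: str = "INFO"


def process_container(
    container: PLRContainer,
    min_rel_freq: float = 0.5,
    min_cluster_support: int = 1,
) -> Tuple[PLRGraph, List[PLRSequence]]:
    """Run graph construction through path assembly for one container."""
    graph = build_graph(container, min_rel_freq=min_rel_freq)
    vectors = extract_bubble_vectors(graph)
    clusters = cluster_vectors(vectors)
    if min_cluster_support > 1:
        clusters = [
            c
            for c in clusters
            if sum(v.multiplicity for v in c) >= min_cluster_support
        ]
    context = f"{container.ref_id}:{container.start}-{container.end}"
    combos = build_combinations(clusters, graph.n_bubbles, context=context)
    return graph, assemble_paths(graph, combos)


def generate_plrs(
    alignments,
    refs: Dict[str, str],
    min_mapq: int = 20,
    min_container_len: int = 100,
    min_rel_freq: float = 0.5,
    min_cluster_support: int = 1,
) -> Tuple[List[PLRContainer], List[PLRSequence]]:
    """In-memory pipeline: alignments + references -> containers and V-PLRs."""
    columns = build_pileup(alignments, refs, min_mapq=min_mapq)
    containers = build_containers(columns, min_container_len=min_container_len)
    plrs: List[PLRSequence] = []
    for container in containers:
        _, paths = process_container(
            container,
            min_rel_freq=min_rel_freq,
            min_cluster_support=min_cluster_support,
        )
        plrs.extend(paths)
    return containers, plrs


def run_plr_gen(cfg: RunConfig) -> int:
    """Execute a full run; returns 0 on success (also with zero PLRs)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    refs = load_reference(cfg.ref_fasta)
    containers, plrs = generate_plrs(
        cfg.bam_path,
        refs,
        min_mapq=cfg.min_mapq,
        min_container_len=cfg.min_container_len,
        min_rel_freq=cfg.min_rel_freq,
        min_cluster_support=cfg.min_cluster_support,
    )
    per_ref: Dict[str, int] = {}
    for c in containers:
        per_ref[c.ref_id] = per_ref.get(c.ref_id, 0) + 1
    for rid in refs:
        n_plr = sum(p.ref_id == rid for p in plrs)
        logger.info(
            "%s: %d containers, %d PLRs", rid, per_ref.get(rid, 0), n_plr
        )

    if cfg.nplr_mode:
        plrs = mask_to_nplr(plrs)
    if cfg.drop_n:
        plrs = [p for p in plrs if "N" not in p.sequence]
    if not plrs:
        logger.warning("no PLR sequences generated")

    write_fasta(plrs, cfg.out_fasta)
    if cfg.bed_path:
        write_bed(containers, cfg.bed_path)
    if cfg.manifest_path:
        write_manifest(plrs, cfg.manifest_path)
    return 0
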