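"""Self-contained community simulator for testing the PLR pipeline.

Emulates, at desk scale, the setting the pipeline targets: several
microbial replicons, each carried by one or more strain haplotypes that
differ at point substitutions, sequenced as ~100 bp paired-end reads at a
chosen fold-coverage with a uniform substitution error rate.  Everything —
reference FASTA, strain truth, paired FASTQ, and perfect-knowledge SAM
alignments — is generated deterministically from a seed, so the whole
pipeline is testable without downloads or an external aligner.

The perfect-knowledge aligner places every read at its true origin on the
*base* reference (strains are substitution-only, so coordinates map 1:1)
with a full-match CIGAR and mapping quality 60.  It deliberately has none
of a real aligner's failure modes (multi-mapping, clipping, indel
ambiguity); an end-to-end run through a real short-read aligner is an
optional extra, not the test path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pysam

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """Study conditions for one simulated community.

    depth is fold-coverage per strain; read_length defaults to 101 bp
    (paired 2 x 101).  snv_rate is the per-bp between-strain substitution
    rate; with max_snv_spacing set, SNV gaps are drawn from the same
    geometric law truncated to that bound, guaranteeing linkable spacing.
    """

    seed: int = 0
    n_refs: int = 1
    ref_length: int = 10_000
    n_strains_per_ref: int = 2
    snv_rate: float = 0.005
    read_length: int = 101
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 30.0
    error_rate: float = 0.0
    max_snv_spacing: Optional[int] = None

    def validate(self) -> None:
        for name in ("snv_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_refs", "ref_length", "n_strains_per_ref", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.insert_mean < self.read_length:
            raise ValueError(
                "insert_mean shorter than read_length: fragments cannot hold a read"
            )
        if self.ref_length < self.read_length:
            raise ValueError("reference shorter than a read")


@dataclass
class ReadPair:
    """One sequenced fragment: mate coordinates on the base reference.

    seq1/seq2 are stored in reference-forward orientation (mate 2 is
    sequenced reverse-complemented).
    """

    name: str
    ref_id: str
    strain_index: int
    pos1: int
    pos2: int
    seq1: str
    seq2: str
    insert: int


@dataclass
class TruthSet:
    """Ground truth: strain haplotypes, SNV table, and read origins."""

    strains: Dict[str, List[str]] = field(default_factory=dict)
    # ref_id -> list of (pos, per-strain alleles)
    snvs: Dict[str, List[Tuple[int, Tuple[str, ...]]]] = field(default_factory=dict)
    reads: List[ReadPair] = field(default_factory=list)


@dataclass
class Community:
    cfg: SimConfig
    refs: Dict[str, str]
    truth: TruthSet

    # -- writers ---------------------------------------------------------
    def write_reference(self, path: Union[str, Path], width: int = 70) -> None:
        _write_fasta(self.refs.items(), path, width)

    def write_strains(self, path: Union[str, Path], width: int = 70) -> None:
        records = (
            (f"{rid}_strain{i + 1}", seq)
            for rid, strains in self.truth.strains.items()
            for i, seq in enumerate(strains)
        )
        _write_fasta(records, path, width)

    def write_reads(self, path1: Union[str, Path], path2: Union[str, Path]) -> None:
        qual = "I" * self.cfg.read_length
        with open(path1, "w") as h1, open(path2, "w") as h2:
            for rp in self.truth.reads:
                h1.write(f"@{rp.name}/1\n{rp.seq1}\n+\n{qual}\n")
                h2.write(f"@{rp.name}/2\n{revcomp(rp.seq2)}\n+\n{qual}\n")

    def write_truth(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            handle.write("ref_id\tpos\tstrain_alleles\n")
            for rid, snvs in self.truth.snvs.items():
                for pos, alleles in snvs:
                    handle.write(f"{rid}\t{pos}\t{','.join(alleles)}\n")


def _write_fasta(records, path, width: int) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _draw_snv_positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """SNV positions along one replicon.

    Default: iid Bernoulli(snv_rate) per position.  With max_snv_spacing
    set, inter-SNV gaps follow the same geometric law with gaps capped at
    max_snv_spacing, and SNVs keep one insert length away
    from the replicon ends — edge variants cannot be spanned by a linking
    fragment, so they have no place in a linkability-guaranteed layout.
    """
    if cfg.snv_rate == 0 or cfg.n_strains_per_ref < 2:
        return np.empty(0, dtype=int)
    if cfg.max_snv_spacing is None:
        mask = rng.random(cfg.ref_length) < cfg.snv_rate
        return np.flatnonzero(mask)
    margin = int(np.ceil(cfg.insert_mean))
    positions: List[int] = []
    pos = margin - 1
    while True:
        gap = min(int(rng.geometric(cfg.snv_rate)), cfg.max_snv_spacing)
        pos += gap
        if pos >= cfg.ref_length - margin:
            break
        positions.append(pos)
    return np.asarray(positions, dtype=int)


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_community(cfg: SimConfig) -> Community:
    """Generate references, strain haplotypes, and paired-end reads.

    References are drawn uniformly over {A,C,G,T}; each strain substitutes
    a uniformly chosen different base at its SNV positions.  Fragments are
    placed uniformly along each strain with normal insert sizes truncated
    to [read_length, ref_length]; the per-strain fragment count realises
    ``depth`` fold read coverage.  Byte-identical outputs under a fixed
    seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    refs: Dict[str, str] = {}
    truth = TruthSet()

    for r in range(cfg.n_refs):
        rid = f"ref{r + 1}"
        base = rng.choice(_BASES, size=cfg.ref_length).tobytes().decode()
        refs[rid] = base

        positions = _draw_snv_positions(rng, cfg)
        strain_arrays = [
            np.frombuffer(base.encode(), dtype="S1").copy()
            for _ in range(cfg.n_strains_per_ref)
        ]
        snv_table: List[Tuple[int, Tuple[str, ...]]] = []
        for pos in positions:
            ref_base = base[pos]
            alleles = [ref_base]
            # strains beyond the first receive a non-reference allele; the
            # first strain keeps the reference base
            for s in range(1, cfg.n_strains_per_ref):
                alt = rng.choice(_BASES[_BASES != ref_base.encode()])
                strain_arrays[s][pos] = alt
                alleles.append(alt.decode())
            snv_table.append((int(pos), tuple(alleles)))
        strains = [a.tobytes().decode() for a in strain_arrays]
        truth.strains[rid] = strains
        truth.snvs[rid] = snv_table

        rl = cfg.read_length
        n_frags = int(round(cfg.depth * cfg.ref_length / (2 * rl)))
        for s, strain in enumerate(strains):
            for i in range(n_frags):
                insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
                insert = max(rl, min(insert, cfg.ref_length))
                start = int(rng.integers(0, cfg.ref_length - insert + 1))
                frag = strain[start : start + insert]
                seq1 = _mutate(rng, frag[:rl], cfg.error_rate)
                seq2 = _mutate(rng, frag[-rl:], cfg.error_rate)
                truth.reads.append(
                    ReadPair(
                        name=f"{rid}_s{s + 1}_{i}",
                        ref_id=rid,
                        strain_index=s,
                        pos1=start,
                        pos2=start + insert - rl,
                        seq1=seq1,
                        seq2=seq2,
                        insert=insert,
                    )
                )
    return Community(cfg=cfg, refs=refs, truth=truth)


def simulate_alignments(community: Community, out_sam: Union[str, Path]) -> None:
    """Write perfect-knowledge alignments of all reads as coordinate-sorted SAM.

    Each mate is placed at its true origin on the base reference with a
    full-match CIGAR, mapping quality 60, and proper-pair flags (mate 2 on
    the reverse strand).
    """
    refs = community.refs
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": rid, "LN": len(seq)} for rid, seq in refs.items()],
        }
    )
    rl = community.cfg.read_length
    records: List[Tuple[str, int, pysam.AlignedSegment]] = []
    for rp in community.truth.reads:
        for mate, (pos, seq, flag) in enumerate(
            [
                (rp.pos1, rp.seq1, 0x1 | 0x2 | 0x20 | 0x40),  # paired, proper, mate-rev, first
                (rp.pos2, rp.seq2, 0x1 | 0x2 | 0x10 | 0x80),  # paired, proper, rev, last
            ]
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = rp.name
            a.query_sequence = seq
            a.flag = flag
            a.reference_id = list(refs).index(rp.ref_id)
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.next_reference_id = a.reference_id
            a.next_reference_start = rp.pos2 if mate == 0 else rp.pos1
            a.template_length = rp.insert if mate == 0 else -rp.insert
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            records.append((rp.ref_id, pos, a))

    order = {rid: i for i, rid in enumerate(refs)}
    records.sort(key=lambda t: (order[t[0]], t[1], t[2].query_name, t[2].flag))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for _, _, a in records:
            out.write(a)
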