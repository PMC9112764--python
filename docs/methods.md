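# Methods

## Model and assumptions

`plrforge` treats a reference genome as a coordinate frame, not as truth.
Short-read alignments supply per-column base evidence; contiguously covered
intervals (*containers*) are the templates from which long sequences are
synthesized. Within a container the only variation modelled is the
single-column substitution: a column with two or more well-supported
nucleotides becomes a *bubble*, and the co-occurrence of bubble alleles is
resolved by fragments that physically span several bubbles. Indels and
structural variation are out of scope: insertions against the reference have
no coordinate and are dropped; a read deleting a column simply does not cover
it. Consequently every PLR has exactly the length of its container, and two
PLRs of one container differ only at bubble columns.

The phasing step assumes that reads from one DNA fragment are error-free at
bubble columns often enough for identical vectors to dominate. Clustering at
distance cutoff 0 is deliberately conservative: a single disagreement
separates two linking vectors, and alleles that cannot be linked to anything
are emitted as `N` rather than guessed.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `min_mapq` | 20 | minimum mapping quality, inclusive; together with the UNMAP/QCFAIL/DUP/SECONDARY flag filter this mirrors standard mpileup read filtering. Supplementary alignments are also excluded so one fragment contributes at most one base per column. |
| `min_container_len` | 100 bp | containers strictly shorter are discarded (a 100 bp container survives). |
| `min_rel_freq` | 0.5 | an allele is kept iff count ≥ min_rel_freq × (column maximum); the boundary is inclusive, so a 5-vs-10 column stays biallelic while 4-vs-10 collapses to the major allele. A column reduced to one allele joins the flanking normal node. |
| `min_cluster_support` | 1 | optional floor on the total linking-fragment multiplicity of a cluster; default keeps everything. |

Base qualities are not used. Coordinates are 0-based half-open internally;
FASTA headers and the manifest use 1-based inclusive spans.

## Numerical and tie-break choices

* **Overlapping mates**: same base → counted once (fragment-level evidence);
  different bases → the fragment contributes nothing at that column.
* **Normal-node sequence** is the consensus aligned base, never the reference
  base: a column where every read carries X ≠ reference contributes X.
* **Non-comparable vectors** (no shared informative position) receive the
  sentinel distance B + 1; any constant > 1 behaves identically at cutoff 0.
* **Clustering** at cutoff 0 is computed as connected components of the
  zero-distance relation via union-find — exactly what single-linkage
  agglomeration cut at 0 produces — because it is deterministic and O(n²B)
  on collapsed vectors. Identical vectors are collapsed with multiplicity
  first, which provably cannot change the components.
* **Transitive conflicts** (A≡B, B≡C at distance 0, but A and C disagree at a
  shared column) cannot occur with error-free data but do on real data. The
  combination then takes the multiplicity-weighted majority allele, ties
  broken to the lexicographically smallest base, and a warning is logged with
  the container span.
* **Determinism**: vectors, clusters and paths carry total orders (position
  of first informative element, then elements, then fragment id; clusters by
  minimum first-bubble position, descending support, member strings), so
  reruns on identical inputs are byte-identical.
* **Degenerate containers**: B = 0 yields the single normal-node sequence;
  B = 1 or no linking fragments yield one all-`N`-at-bubbles PLR — an
  isolated bubble cannot be phased and is never enumerated per allele, which
  would explode combinatorially.

## Synthetic data

The simulator emulates the target setting at desk scale: uniform-random
replicons, 1–3 strain haplotypes per replicon differing only at point
substitutions (per-bp rate `snv_rate`), paired 2 × 101 bp reads with
normal insert sizes (truncated to at least one read length), per-strain fold
coverage `depth`, and uniform per-base substitution errors. A
perfect-knowledge aligner places each read at its true origin on the base
reference (mapq 60, full-match CIGAR, proper-pair flags), so the pipeline is
exercised without network access or an external aligner.

Two SNV placement modes exist. The default draws iid Bernoulli(`snv_rate`)
positions. With `max_snv_spacing` set, inter-SNV gaps are geometric with the
same rate but capped at the bound, and SNVs keep one mean insert length away
from replicon ends; this guarantees every adjacent variant pair is spannable
by a fragment, which the haplotype-recovery tests require (an edge variant or
an over-long gap is structurally unlinkable, regardless of depth).

What the simulator does *not* model: indels, quality-dependent or
strand-biased errors, abundance skew between strains, contamination,
repeats, and real aligner artefacts (multi-mapping, clipping). Passing tests
therefore demonstrate the algorithm's correctness on substitution-only strain
mixtures with ideal placement, not robustness to alignment noise on real
metagenomes.

Problem sizes used by the tests — replicons of 3–10 kb, depths 20–40×, a few
dozen to ~100 SNVs, 200 random vector sets for the clustering oracle — keep
the whole suite in the tens of seconds while still exercising every code
path including conflicts and degenerate containers.

## Known limitations

* Exact haplotype recovery requires every bubble to stay biallelic after the
  0.5 relative-frequency filter. With two strains at equal 30× coverage, a
  balanced site loses its minor allele (minor < half of major by sampling
  noise) with probability ≈ 1%; over ~70 sites a run recovers both
  haplotypes exactly on most but not all seeds. The seeded recovery tests pin
  a seed; the structural outcome (one container, exactly two PLR paths) holds
  across all seeds tried.
* Only single-column substitutions become bubbles; nearby indel variation in
  real data will be flattened onto the reference coordinates.
* Containers are never merged across coverage gaps, so a single uncovered
  base splits an otherwise continuous PLR in two.
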