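# plrforge

Reference-guided generation of **pseudo-long reads (PLRs)** from metagenomic
short-read alignments.

Metagenomic assembly from short reads alone struggles to resolve repeats and
to separate near-identical genomes of related strains and species. Long reads
help, but cost more to sequence. `plrforge` synthesizes artificial long
sequences from the short reads you already have: given coordinate-sorted
alignments of short reads against microbial reference genomes, it tiles the
covered reference intervals into long, variant-aware sequences that can be fed
to any hybrid or long-read assembler. It is aimed at microbiome researchers
who have short-read data and a set of (predicted or known) reference genomes.

## Method

1. **Pileup** — alignments are filtered (mapping quality ≥ 20 by default;
   unmapped, QC-fail, duplicate, secondary and supplementary records are
   skipped) and piled onto each reference, keeping per-fragment base identity.
   Both mates of a pair count as one fragment.
2. **Containers** — each reference is broken at positions with no coverage;
   every maximal contiguously covered interval is a *PLR container*
   (intervals < 100 bp are discarded).
3. **Graph** — each container's column alignment becomes a graph of *normal
   nodes* (runs of single-nucleotide columns) and *bubble columns* (columns
   with ≥ 2 nucleotides after dropping alleles whose count is below half the
   column maximum).
4. **Bubble combinations** — every fragment spanning ≥ 2 bubble columns is a
   *bubble-linking* fragment, represented as a vector
   V_i = (v_i1, …, v_iB), v_ij ∈ {A, C, G, T, −}, over the container's B
   bubble columns ('−' = no information). The consistency distance
   D(V_i, V_j) = Σ_b d_b counts positions where both vectors are informative
   and disagree (pairs sharing no informative position get a sentinel > 1).
   Hierarchical agglomerative clustering cut at distance 0 — equivalently,
   connected components of the zero-distance relation — groups consistent
   vectors; each cluster is condensed into one consensus allele combination.
5. **Sequences** — each combination is walked left-to-right across the
   container, copying normal bases and substituting the combination's allele
   at each bubble ('−' becomes `N`): one PLR per combination, all with the
   container's exact length. An *N-PLR* variant masks every bubble position
   with `N` instead (useful as a variant-blind baseline).

## Worked example

The bundled simulator creates a community (here: one 5 kb replicon carried by
two strains differing at point substitutions, 2 × 101 bp pairs at 30× per
strain) together with perfect-knowledge alignments, so the full pipeline runs
without an external aligner:

```
$ plrforge simulate --seed 0 --ref-length 5000 --strains 2 --snv-rate 0.005 \
      --depth 30 --insert-mean 300 --insert-sd 25 --max-snv-spacing 200 \
      --out-dir demo
$ plrforge run --bam demo/alignments.sam --ref demo/reference.fa \
      --out demo/plr.fa --manifest demo/plr.tsv
INFO:plrforge.pipeline:ref1: 1 containers, 2 PLRs
$ cat demo/plr.tsv
ref_id  start  end   path_index  length  n_variant_positions  support
ref1    1      4999  1           4998    31                   331
ref1    1      4999  2           4998    31                   314
```

The covered interval forms a single 4,998 bp container with 31 bubble columns
(the engineered strain differences). Linking fragments cluster into two
groups, so two PLRs are emitted — one per strain haplotype, each ~50× longer
than the input reads, supported by 331 and 314 linking fragments:

```
$ head -2 demo/plr.fa
>ref1:2-4999|plr1|support=331|vars=31
GGCCAAAATGTGGTGGGGTCTGACTGATGTAATAGACCCCAAAAGGGCGTCCTTTCGTGTGGCTAGGTGC
```

Headers are `ref:start-end|plrK|support=s|vars=n` with 1-based inclusive
coordinates. For real data, map reads first (e.g.
`bowtie2 -x ref -1 R1.fq -2 R2.fq | samtools sort -o sorted.bam`) and pass
the sorted BAM with the same reference FASTA.

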