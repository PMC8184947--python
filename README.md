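# mitocomp

Comparative analysis of annotated animal mitochondrial genomes, built for
the kind of study done on gastropod (e.g. Strombidae) mitogenomes: profile
one genome's architecture and composition, quantify variation between
conspecific mitogenome lineages, and compare a cohort of congeneric or
confamilial species. A seeded synthetic-mitogenome simulator with
replayable truth logs makes every stage of the pipeline testable at desk
scale, without touching real data.

It is aimed at molecular ecologists and systematists who have annotated
mitogenomes (GenBank flat files, or FASTA plus a feature table) and want
the standard descriptive battery reproducibly, from a library or a shell.

## What it computes

**Genome partitions.** A record is partitioned into the whole molecule,
the concatenated protein-coding genes (PCG), tRNAs, rRNAs, the heavy- and
light-strand gene sets (each gene 5′→3′ in coding orientation), and the
non-coding remainder. Intergenic regions and gene overlaps are reported on
the circle, including features spanning the origin; overlapping positions
count in both genes, while genome coverage counts the union once.

**Composition and skews.** For any partition, base counts (N excluded),
AT/GC content, and the strand-asymmetry statistics

    AT skew = (A − T) / (A + T)        GC skew = (G − C) / (G + C)

with AT skew > 0 meaning A-rich and GC skew > 0 meaning G-rich. Undefined
denominators give flagged nulls, never silent zeros.

**Codon usage.** Translation and start/stop-codon tables under the
invertebrate mitochondrial code (NCBI table 5; ATA = Met, TGA = Trp,
AGA/AGG = Ser, alternative starts like GTG), with incomplete stop codons
(T–) flagged rather than rejected. Relative synonymous codon usage is

    RSCU_c = n_c · k / Σ n_i

for a codon *c* in a synonymous family of *k* codons; families follow the
(amino acid, first-two-bases) split, so leucine reports as Leu1 (CUN) and
Leu2 (UUR), serine as Ser1 (AGN) and Ser2 (UCN).

**Variation.** DnaSP-style accounting on alignments: SNP counts, indel
sites vs indel events (a maximal gap run with a constant gapped-row set is
one event), nucleotide diversity π (average per-site pairwise difference,
gap/N columns excluded by complete deletion), divergence k (average
pairwise difference count), synonymous/nonsynonymous classification of
codon columns, per-gene variation profiles with a ranking by π, pairwise
divergence matrices, and neighbor-joining trees. Pairs are aligned
internally (exact affine-gap Needleman–Wunsch/Gotoh for moderate lengths,
an edit-distance path for genome-scale pairs); multiple alignments are
accepted as input, never computed.

**Simulation.** `simulate_mitogenome` builds a circular ~15.5 kb genome
from a configurable gene-order template (13 PCGs + 22 tRNAs + 2 rRNAs,
light-strand tRNA block, short spacers, three small overlaps) with AT-rich
composition and a negative PCG AT skew; `evolve` applies a
transition-biased two-parameter substitution process (expected *d*
substitutions/site, multiple hits allowed) plus rare non-coding indels,
logging every event; `simulate_clade` evolves the root along a Newick
tree. Truth logs replay exactly.

## Worked example

```python
from mitocomp import *
from mitocomp.composition import skew_profile, skew_profile_tsv
from mitocomp.variation import align_pair, snp_fraction_in_class

genome, _ = simulate_mitogenome(SimulationConfig(seed=42))
print(skew_profile_tsv(skew_profile(genome)))
```

```
partition  length  A     C     G     T     at_content  gc_content  at_skew  gc_skew
WHOLE      15460   4483  2485  2618  5874  67.0        33.0        -0.134   0.026
PCG        11259   3073  1893  1861  4432  66.7        33.3        -0.181   -0.009
TRNA       1491    464   200   300   527   66.5        33.5        -0.064   0.200
RRNA       2367    800   305   450   812   68.1        31.9        -0.007   0.192
HEAVY      14575   4162  2333  2503  5577  66.8        33.2        -0.145   0.035
LIGHT      542     175   65    108   194   68.1        31.9        -0.051   0.249
```

The genome is 15,460 bp with a 66–68% AT-rich composition in every
compartment, a clearly T-biased protein-coding strand (PCG AT skew −0.181)
and G-biased structural RNAs — the pattern the simulator's defaults
emulate. Now evolve a second intraspecific lineage at 0.75% expected
substitutions/site and measure the divergence back:

```python
lineage2, log = evolve(genome, EvolutionConfig(d=0.0075, seed=43))
aln = align_pair(genome.sequence, lineage2.sequence)
pi, k, n = nucleotide_diversity(aln)
print(f"pi={pi:.4f} k={k:.1f} over {n} sites")
print(f"SNPs in PCGs: {100*snp_fraction_in_class(genome, aln):.1f}%")
profile, ranking = per_gene_profile([genome, lineage2])
print("most variable genes:", ranking[:3])
```

```
pi=0.0077 k=119.0 over 15459 sites
SNPs in PCGs: 75.6%
most variable genes: ['NAD6', 'ATP8', 'CYTB']
```

π lands on the simulated divergence (0.0077 vs the multiple-hit-corrected
expectation 0.0075), about three quarters of SNPs fall in protein-coding
genes (their share of the genome under a uniform rate), and the per-gene
table ranks genes by diversity, with synonymous/nonsynonymous counts and
the amino-acid-change proportion per gene.

The same workflow is available from the shell:

```
mitocomp simulate --seed 42 -o out/
mitocomp profile out/SIM42.gb -o out/profile/
mitocomp compare a.gb b.gb -o out/intra/
mitocomp cohort sp1.gb sp2.gb sp3.gb -o out/cohort/
```

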