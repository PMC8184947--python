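# Methods

This note records the models, conventions and numerical choices behind
`mitocomp`, and what the synthetic-data validation does and does not
establish about behaviour on real mitogenomes.

## Coordinates and the genome model

Internally all coordinates are 0-based half-open on the heavy strand;
GenBank flat files and TSV feature tables use 1-based inclusive
coordinates, with `complement(...)` for light-strand genes and a
two-part `join(...)` for features spanning the origin of a circular
molecule. A wrapped feature is stored as `start ≥ end` covering
`[start, L) ∪ [0, end)`. Light-strand gene sequences are always reported
5′→3′ in coding orientation (the reverse complement of the genome
slice), which is what makes start/stop-codon tables and codon counting
strand-agnostic.

Gene names are canonicalized through a shipped synonym table
(`data/gene_synonyms.tsv`, extensible per call) because public records
freely mix ND/NAD, COI/COX1, rrnS/12S and trnX spellings; the two
leucine and serine tRNAs are disambiguated by anticodon
(tRNA-Leu(TAG)=CUN family, tRNA-Leu(TAA)=UUR, tRNA-Ser(GCT)=AGN,
tRNA-Ser(TGA)=UCN). Unrecognized names pass through unchanged.

Partition bookkeeping distinguishes two conventions deliberately:
positions shared by two overlapping genes contribute to *both* genes'
partitions (so summed partition lengths can exceed genome coverage),
while the coverage fraction uses the union of feature positions. Strand
statistics (HEAVY/LIGHT rows of the skew table) are computed over
strand-encoded *gene sets* in coding orientation, not over full genome
strands — full strands are reverse complements of each other and would
trivially share AT content, which would make strand comparison
meaningless. N bases are accepted in sequences but excluded from every
composition count; an empty or all-N partition is a flagged error, and a
skew whose denominator is zero is a flagged null, never 0.

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial). Translation is frame-0; a trailing 1–2 nt remainder is
reported as an incomplete stop (polyadenylation-completed in
mitochondrial transcripts), and internal stops are reported with their
codon index rather than raised, since both occur in real annotations.

RSCU is count × family-size / family-total. Synonymous families are
defined by the active code and split by the first two codon bases, so
table 5's six leucine codons form Leu1 (CUN, k=4) and Leu2 (UUR, k=2)
and its eight serine codons form Ser1 (AGN, k=4) and Ser2 (UCN, k=4).
This is the split used when mitochondrial codon-usage rankings report
"Leu2 (UUA)" or "Ser2 (UCU)" as separate families; it also keeps every
family's RSCU values summing exactly to the family size, the invariant
the tests enforce. Codons containing N and the terminal stop codon of
each CDS are excluded from counts; stop codons get counts but no RSCU
(a compatibility flag `include_stops` gives them their own family).
Ranked codon lists break ties by higher RSCU, then higher raw count,
then alphabetical codon, making reports deterministic. Whether usage
should be pooled over the 13 PCGs or computed per gene is genuinely
open; pooling is the default (`rscu`), per-gene mode is available
(`rscu_per_gene`).

## Variation statistics

π is the average over row pairs of pairwise differences per compared
column; k is the average pairwise difference count. The default gap
treatment is complete deletion — any column containing a gap or N in any
row is excluded for every pair — matching the DnaSP convention;
pairwise deletion is available via `gap_mode="pairwise"`. For two
sequences k = π × compared columns exactly, an identity under test. SNP
columns involving N are excluded, conservatively. An indel *site* is any
gapped column; an indel *event* is a maximal run of gapped columns whose
set of gapped rows is constant — if the gapped-row set changes mid-run
the run splits into multiple events. This run-length definition is
deterministic and matches the intuition that one insertion/deletion of
length ℓ in one sequence is one event.

Synonymous/nonsynonymous classification works per gap-free codon column
of a frame-0 codon alignment: a variable column is synonymous when all
rows translate identically, nonsynonymous otherwise. The
amino-acid-change proportion is nonsynonymous columns over gap-free
codon columns by default; because "proportion of amino-acid change" can
also be read per substitution, a `per_substitution` mode (nonsynonymous
over variable columns) is implemented as well. Alignments whose length
is not a multiple of 3 are rejected with an instruction to supply a
codon-aware alignment; per-gene profiles trim trailing partial codons.

Pairwise alignment is a full affine-gap Gotoh DP with a gap of length ℓ
costing `gap_open + (ℓ−1)·gap_extend` (defaults +1/−1/−2/−1 for
match/mismatch/open/extend). Tie-breaking among co-optimal tracebacks
prefers match/mismatch over a gap in the first sequence over a gap in
the second, so output is deterministic. The DP is exact and is verified
against exhaustive enumeration of alignments; since it is quadratic in
time and memory, sequence pairs where both sides exceed 3,000 nt (whole
mitogenomes) route to an edit-distance global alignment (edlib) instead
— at mitogenome-scale divergences the unit-cost path is an adequate
homology map for column-wise counting, and per-gene analyses still use
the exact aligner. Multi-sequence alignment is never computed
internally; pre-aligned FASTA is accepted.

Neighbor joining is the canonical Q-criterion agglomeration with the
three-point formula at the final join. Ties in Q resolve to the earliest
pair in taxon order; negative branch lengths are clamped to zero with a
warning (the underlying estimate, not the display, drives subsequent
distance updates). Divergence matrices are emitted both as raw average
difference counts (k) and per-site (k / compared columns), since either
scale may be wanted; NJ uses the per-site matrix by default.

## The simulator

`simulate_mitogenome` draws a genome from a gene-order template
(a data file, `data/gene_order_template.tsv`, not hard-coded) that
emulates a typical caenogastropod architecture: 13 PCGs, 22 tRNAs, 2
rRNAs summing to 15,117 bp of genes, a light-strand block of eight tRNAs
(MYCWQGE + Thr), two larger spacers (54 and 41 bp) flanking COX3, three
small overlaps (each with a tRNA upstream, so the overwriting order
never corrupts a coding sequence), total length 15,460 bp. Defaults:
whole-genome AT target 0.66, PCG AT skew target −0.18, mildly positive
tRNA/rRNA skews with G-rich GC skew (+0.13), non-coding AT 0.70. PCG
bodies are sampled codon-wise with stop codons rejected; because the
rejected codons are TA-leading, sampling frequencies are first passed
through a fixed-point correction so the *conditional* (non-stop) codon
distribution hits the composition targets in expectation — without it
the realized PCG AT skew overshoots by ≈0.03. One gene (NAD4) starts
with GTG and four NAD genes stop with TAG, mirroring the start/stop
variation the profiler must handle. Identical seeds give byte-identical
GenBank output.

`evolve` implements a K80-like two-parameter jump process: the event
count is Poisson(L·d), each event hits a uniform site and substitutes
the transition partner with probability κ/(κ+2) (default κ=2), otherwise
one of the two transversions. This is rate-homogeneous across sites and
strand-symmetric, with multiple hits arising naturally, so the expected
ancestor–derivative difference fraction has the closed K80 form
(`expected_difference_fraction`), which the recovery tests check to
within 3 Monte-Carlo standard errors at d ∈ {0.002, 0.01, 0.05, 0.1}
(20 replicates, 15.5 kb genomes). Indels are Poisson over non-coding
sites (default 10⁻⁴ events/site — rare, as observed in coding-region
comparisons), geometric(0.5) lengths, insertions and deletions equally
likely, deletions clipped to their non-coding run so gene boundaries are
never crossed; annotation coordinates shift accordingly. Every event is
logged (substitutions with gene, codon index and a synonymous flag
evaluated in context at event time; indels with position, length and
content) and the log replays against the ancestor to the exact derived
sequence. `simulate_clade` evolves the root along a Newick tree, branch
lengths in substitutions/site, leaf logs concatenating the root-to-leaf
event path.

## What passing the synthetic tests does and does not show

The simulator reproduces the *statistical* structure the analyses
assume — genome architecture, compositional bias, transition-biased
divergence at realistic intra- (~0.007) and interspecific (~0.1–0.2)
scales, rare non-coding indels — so the tests demonstrate that
partition accounting, composition, codon usage, π/k, classification and
NJ are internally correct and mutually consistent on data of exactly
that shape. They do not demonstrate robustness to what real records
add: annotation errors and nonstandard feature keys (handled, but only
lightly exercised), heterogeneous substitution rates across sites and
genes (the simulator is rate-homogeneous, so per-gene rankings on
synthetic data reflect sampling noise unless variation is injected
deliberately), selection (synonymous and nonsynonymous events occur at
the neutral rates implied by the code), gene rearrangements, and
composition drift at deep divergences. The two reproduction test
classes against the deposited *A. gigas* records close part of that gap
when those flat files are provided.

## Problem sizes

The test suite and the acceptance script run on full-size synthetic
genomes (15,460 bp, 37 genes). Monte-Carlo components use 20 replicates
(divergence calibration, clade topology recovery) or 50 seeds
(composition targets); the aligner-vs-enumeration check covers all
binary-alphabet pairs to length 6 in the suite and length 5 in the
acceptance script. These sizes give standard errors comfortably inside
the asserted tolerances while keeping a full run in tens of seconds.
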