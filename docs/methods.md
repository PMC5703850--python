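# Methods

## Scope

`strtwell` reimplements the data-processing chain of a dual-index
microwell 5′ UMI RNA-seq platform (STRT-style chemistry on a 9600-well
plate): demultiplexing, read QC, transcript-model construction, alignment
post-processing with splice-junction rescue, multiread assignment, UMI
molecule counting with collision correction, two-species doublet analysis,
and the pre-clustering QC filters. Clustering itself (BackSPIN-style
biclustering, tSNE) is out of scope; only its documented input filters are
implemented.

## Read model and QC chain

A cDNA read is 45 bp: a 6 bp UMI, three non-templated guanosines added by
the template-switching reverse transcriptase, then 5′-proximal transcript
sequence. Two index reads of 8 bp (subarray) and 5 bp (well) jointly
address one of 9600 wells (96 subarrays × 100 wells). The QC chain runs in
a fixed order: instrument invalid-flag drop; trim of the terminal run of
B-quality bases (Phred 2, regardless of ASCII offset; FASTQ is assumed
Phred+33 with a config switch for Phred+64); a Phred ≥ 17 gate on all six
UMI bases; a requirement that bases 7–9 be G, with the G run trimmed up to
nine G total (a tenth G is treated as transcript); terminal poly(A)
trimming with discard below 25 remaining bases; and a low-complexity
filter (fewer than six non-A bases, or a perfect dinucleotide repeat of
≥ 10 bases with fewer than six other bases at both ends). Defaults the
protocol leaves unquantified are exposed as config: the minimal terminal
A-run that counts as poly(A) (5), the minimal dinucleotide repeat length
(10), and the demultiplexing mismatch tolerance (0, optionally 1 with
ambiguous assignments rejected). The trimmed remainder of a poly(A) read
is kept and aligned (it is the alignable 5′ sequence), rather than used
only as a discard test.

Instrument barcode sequences are proprietary, so the package ships deterministic
generated sets (96 8-mers, 32 5-mers) found by a seeded greedy search with
minimum pairwise Hamming distance 3, which makes one-mismatch correction
well defined.

## Reference model

Transcript variants of a gene are merged into one locus model (interval
union of exons, grouped by gene name, chromosome and strand). To absorb
incomplete cap-site knowledge, each model's 5′ end is extended by up to
100 bases, clamped at the chromosome boundary and stopping exactly at the
3′ end of the nearest same-strand exon of another gene when that exon end
lies inside the window ("not beyond" is read as abutting, not overlapping;
antisense exons never constrain). All coordinates are 0-based half-open,
matching refFlat.

The junction reference contains, for every exon pair of a locus
(genomically ordered; both orientations are served because alignment
checks both strands), a contig of (read length − 1) = 44 bases of flank
from each side, truncated at short exons. A per-contig lift table
translates junction-local alignments back to one or two genomic blocks.

## Alignment contract

The mapping contract mirrors an ungapped Bowtie-1-style run: up to three
mismatches, up to 24 alternative mappings, with reads exceeding the cap
suppressed entirely. The built-in aligner is exact for this contract on
toy-scale references: it splits the read into four disjoint seeds
(pigeonhole over the mismatch budget), looks seeds up in an exact k-mer
index, and verifies candidates by Hamming distance; N counts as a mismatch
on either side. Reads that fail genomic alignment are realigned on the
junction reference and lifted back; hits from different contigs lifting to
identical genomic blocks are deduplicated. Production-scale data should
use an external aligner; alignments flow in through SAM with well and UMI
recovered from the `...:WELL:s01w001:UMI:ACGTAC` read-ID convention, NM
tags filtered at 3 and the 24-hit cap applied on ingest.

## Assignment, counting, correction

Annotation runs separately per well, with the RNG seeded from (global
seed, well address) so serial and parallel runs agree. The multiread
hierarchy: (1) any mapping in a repeat outside exons → random repeat
mapping, no gene; (2) else any exonic mapping → the gene whose (extended)
5′ end is closest to the read's 5′ base, ties broken randomly; (3) else a
random mapping, no gene. A unique non-exonic, non-repeat mapping is
recorded as featureless. Repeat intervals are optional; without them rule
(1) never fires.

Molecules per (gene, 5′ position, strand) are distinct UMIs after
excluding UMIs seen in a single read (PCR/sequencing artifacts). Junction-
derived and genomic alignments are pooled before the singleton test. Gene
counts sum positions; the collision-corrected count is computed per
(gene, well) from its UMI count k as −K·ln(1 − k/K), K = 4⁶ — the
inversion of expected uniform occupancy of the UMI space. Correction at
the aggregate level (rather than per position) is a deliberate choice:
per-position counts are tiny and the correction would be numerically
irrelevant there. Nuclei mode flips feature membership from extended
exons to the whole locus (5′ extension through last exon, introns
included), reflecting abundant unspliced nuclear RNA.

## Two-species analysis

Both transcriptomes are restricted to case-insensitively shared gene
names, giving equally sized name sets. A read belongs unequivocally to a
species iff it matches that species' transcripts perfectly and has no hit
within three mismatches in the other. Per-well species molecule counts use
the same UMI rules. A well below `min_total` (default 100) molecules is
empty; a well whose minor species reaches `minor_fraction_threshold`
(default 0.2) is a doublet; otherwise it is a singlet of the majority
species. Any quoted doublet percentage is threshold-dependent, so both
thresholds are echoed in every output. Background contamination is
summarized as the minor-species molecule count over singlet wells.

## Noise model and pre-clustering filters

Across wells, a gene with mean molecule count m has CV = m^(−1/2) under
pure Poisson sampling; observed data follow an offset Poisson,
Log₂ CV = Log₂(m^(−1/2) + c). The fit fixes the exponent at −1/2 and
estimates only c ≥ 0 by least squares on log₂ CV (bounded scalar
minimization); genes with zero mean or variance are excluded. The filters:
whole-cell bounds on total molecules (defaults 800–2000) plus a
molecules/genes ratio > 1.2; a nuclei minimum of 500 molecules; gene
prevalence within [20 cells, 60% of cells]; per-cell normalization to
3000 molecules (proportion-preserving; zero-total wells excluded); and
marker-based doublet exclusion — a well expressing markers of ≥ 2 disjoint
cell classes (defaults: Stmn2/neurons, Mog/oligodendrocytes,
Aqp4/astrocytes, Fn1/endothelial, C1qc/microglia) at ≥ 1 molecule is
flagged. The whole-cell bounds look tight against typical per-cell totals
of deep experiments and are therefore plain config, not constants.

## Synthetic data

The generator emulates the chemistry's read structure with full
provenance: negative-binomial expression per (well, gene) (mean 2,
dispersion 2 at the desk-scale defaults), distinct UMIs per (well, gene)
unless collisions are requested, geometrically decaying 5′ start offsets
(p = 0.3, capped at 50) capturing the 5′ bias, ≥ 2 reads per molecule
(minimum 2 plus a geometric tail) so singleton exclusion removes nothing
unless singletons are injected explicitly, and a configurable fraction
(default 0.15) of molecules on multi-exon genes placed to span a splice
junction. Junction-spanning placements are rejection-sampled so the
payload is invariant under G-/poly(A)-trimming and has no ungapped genomic
alignment within three mismatches — otherwise a chance intron match
absorbs the read at a shifted position and exact recovery is impossible by
construction, not by implementation error. Defect decoys (one per QC
discard class) are appended outside the truth matrix. Toy references pack
non-overlapping random genes with ≥ 150-base intergenic headroom; repeat
sites duplicate an exonic 45-mer into intergenic space, creating true
multireads recorded in the repeat BED.

What the generator does not emulate: quality-dependent or indel error
profiles, PCR amplification bias beyond duplicate counts, ambient RNA for
the single-species simulator, and genome-scale repeat structure. Passing
recovery tests therefore demonstrates the correctness of the bookkeeping
(demultiplexing, trimming, lift-back, hierarchy, UMI rules), not
robustness to real-data artifacts.

The CV–mean generator draws negative-binomial counts with size parameter
r = 1/(2c·m^(−1/2) + c²), which gives CV(m) = m^(−1/2) + c exactly, then
lets estimation noise at 500 cells enter the fit.

## Problem sizes and numerics

Tests run at desk scale by design: end-to-end recovery uses 50 wells × 50
genes on a 400 kb four-chromosome genome (~15k reads); doublet calling
uses 1000 count-level wells; Monte-Carlo checks of the collision formula
use 60–80 trials per point. The collision formula uses `log1p` for small
k/K; it errors (rather than clamps) at k ≥ K. Interval queries use
interval trees; ties and random assignments draw from the per-well RNG
only, so identical inputs and seed give byte-identical outputs.

## Known limitations

The built-in aligner indexes the reference in memory and is intended for
toy scale; there is no UMI sequence-error network correction (directional
graph methods), no saturation analysis, and no spliced/unspliced
separation. Single-gene loci spanning two chromosomes are split with a
warning rather than reconciled. The demultiplexer treats index reads
independently; a joint (index1, index2) error model is not attempted.
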