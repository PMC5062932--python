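# Methods

This note documents the models, procedures and numerical choices behind
`anchorforge`, and what the synthetic test bed does and does not show
about real capture data.

## The design pipeline

**Locus selection.** A candidate locus is a per-locus ortholog
alignment. It is retained when it has at least `min_taxa` (default 6)
rows and at least one sliding window of `window` columns (default 120,
the probe length) whose *mean pairwise identity* strictly exceeds
`min_identity` (default 0.5). Pairwise identity of two rows is the
fraction of matching positions among positions where both rows are
non-gap; pairs with no comparable position are excluded from the mean.
Gaps are excluded rather than counted as mismatches because the
downstream target constraints already exclude gapped regions, and
gap-as-mismatch would double-penalise indel-rich alignments. Windows
slide with step 1. The mean (not the minimum) over pairs is used;
`window_identity` is a pure function, so a minimum-over-pairs variant
is a one-line wrapper if a stricter criterion is wanted.

**Exon boundaries.** Capture probes must not straddle an intron —
half the probe would not hybridise to genomic DNA. Boundaries are
detected two ways:

* *Genome k-mers* (`map_exons_by_kmer`): exact `k`-mer matches
  (default k = 40) of the transcript against both genome strands are
  grouped into maximal diagonal blocks and chained colinearly by a
  dynamic program maximising transcript coverage. A boundary is
  reported where consecutive chained blocks are adjacent in the
  transcript but separated by at least one base (the intron) in the
  genome. Blocks may overlap by up to k−1 bases: when an intron flank
  base equals the adjacent exon base, the block extends one base past
  the true splice point and the junction becomes ambiguous *in
  principle* — no mapper can place it exactly. The chain tolerates such
  overlaps and places the boundary at the start of the downstream
  block. The simulator plants junctions whose intron flank bases differ
  from the adjacent exon bases (the analogue of real GT…AG intron
  ends), so planted junctions are identifiable and recovered exactly;
  the test suite checks identifiability explicitly before asserting
  exact recovery, because branch mutations occasionally re-create the
  ambiguity at a tip.

* *Read discordance* (`map_exons_by_reads`): genomic reads are mapped
  to the transcript by best infix alignment (edlib, both strands). A
  position p is a candidate boundary when at least `min_reads`
  (default 5) reads spanning p ± `flank` (default 30 bp) have per-base
  mismatch rate ≤ `mismatch_frac` (default 0.2) on one side of p and
  above it on the other — the signature of a read crossing a splice
  junction. Adjacent candidates merge to the position of maximal side
  contrast. The three read-side defaults are toolkit choices exposed in
  the config; they are deliberately permissive (a 150-bp read crossing
  a junction mid-read shows a near-0 / near-1 contrast, far from the
  0.2 threshold).

**Target regions.** Within each locus, the selected probe regions are
the maximal alignment intervals that are (A) at least `min_target_len`
(150) columns wide, (B) free of exon boundaries, and (C) free of gap
characters in every retained row (rows that are entirely gap/missing
are dropped first). Constraint C is enforced in its strictest reading —
one gap character in one row disqualifies a column — because a probe
tiled across an indel column would carry sequence absent from some
lineages. Boundaries detected in transcript coordinates are lifted into
alignment columns through the gapped row of the species they came from,
and unioned across species, so constraint B holds for every lineage.

**Homolog scan.** Each target's reference row is aligned against every
transcript of every species (edlib infix alignment, both strands);
match fraction is identity over the aligned span, and the best hit is
kept when it reaches `min_match` (default 0.55; the threshold is
inclusive — only strictly lower best hits are rejected). Identity over
the aligned span, rather than over the full target length, was chosen
because infix alignment spans are the denominator the aligner actually
guarantees; the alternative is a config switch away by wrapping the
aligner callable. Loci must contain the configured anchor taxa
(`required_taxa`, a config tuple, not hard-coded genus names), and loci
where more than `max_short` (2) of the remaining species have ungapped
transcripts shorter than `len_fraction` (0.8) of the longest
required-taxon transcript are dropped — a guard against loci
represented mostly by fragments.

**Repeat masking.** Large, repeat-rich genomes degrade capture:
a probe overlapping a microsatellite or transposable element pulls down
the whole repeat family. The screen: every `kmer_repeat`-mer (15) in
every row of every probe-region alignment, plus all 45
Hamming-distance-1 substitution neighbours (45 = 3k; indel neighbours
are excluded — they would inflate the table ~k-fold for little gain),
maps to the alignment column of its first base. Genomes are scanned
exhaustively on both strands (probes hybridise double-stranded
targets) and exact hits tallied per column. Columns whose tally
strictly exceeds `repeat_threshold` in *any* genome are masked in all
rows. The production default of 100,000 counts is calibrated to
multi-gigabase genomes; the simulated study conditions use 2,000
against planted tracts of 4,000 motif copies — same mechanism, scaled
to a ~30-kb synthetic genome. Masking is per-column (the minimal
faithful policy); bases are preserved in memory, masked cells are
written as `N`.

**Tiling and replication.** Probes of `probe_len` (120) start every
`round(probe_len / density)` bases (30 at 4.0×), with the final probe
shifted left to end flush with the region end; any probe overlapping a
masked position is discarded. Every species row of the region is tiled
(a probe set representing the clade's sequence diversity captures
divergent lineages far better than a single reference) and probes are
deduplicated by exact sequence. Unused kit capacity is then filled by
replicating probes of short loci — extra replicate counts are dealt one
at a time, cycling probe-by-probe in shortest-locus-first order, until
the replicate total equals `capacity`. The round-robin rule is a
toolkit choice (any rule biased toward short loci would do); it is
deterministic and exactly exhausts capacity.

## The process pipeline

**Read-support filter.** Consensus sequences assembled from fewer than
`min_reads` (35) reads are removed; such contigs are typically products
of low-level index hopping between multiplexed libraries rather than
real loci. The assembler contract upstream is documented, not
implemented: assemblies arrive as FASTA with a `reads=N` header token,
with gene copies above ~5 % divergence already split into separate
records.

**k-mer distance.** A sequence's profile is the set union of its
contiguous 20-mers and its "every third position" 20-mers (bases at
p, p+3, …, p+57), the latter so that synonymous third-codon variation
in exonic sequence does not erase all shared k-mers between diverged
orthologs. The distance between two sequences is 1 − |A∩B|/|A∪B| over
their profiles. The union denominator formalises "k-mers observed in
the two sequences"; a smaller-set denominator is available by
substituting the distance function. k-mers are not canonicalised by
default (assembled consensus sequences are reference-oriented); a
`canonical` flag covers unoriented input. Two empty profiles give
distance 1 with a warning.

**Species-constrained clustering.** Agglomerative, unweighted average
linkage: at each step the admissible pair of clusters with minimum
average inter-cluster distance merges, where *admissible* means the
union still contains at most one sequence per species. Merging stops
when no admissible pair remains (no distance ceiling by default — the
species constraint is the stopping rule) or when `max_distance` is set
and exceeded. Ties break on the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest member id), so
results are independent of input order. The behaviour under
duplication falls out of the constraint: a duplication predating the
clade yields parallel full clusters, one per copy; a duplication inside
the clade yields one full cluster plus a partial cluster holding the
descendant species' second copies. Clusters occupying fewer than
`min_occupancy` (0.75) of the sampled species are dropped (a cluster at
exactly 75 % is kept). The constraint is enforced per *species*;
treating conspecific specimens as distinct units is done by supplying a
sample map that says so.

**Trimming.** Three rules, applied in order: a column is *good* when
the modal non-gap base exceeds `min_similarity` (0.70, strict) of the
column's non-gap characters (modal-base fraction is the similarity
definition; columns with fewer than two usable characters are never
good); every sliding window of `trim_window` (20) columns containing
fewer than `min_good` (10) good columns is masked across all rows (a
column is masked if *any* covering window triggers; an alignment
narrower than the window is one window); columns left with fewer than
`min_unmasked` (10) unmasked, non-gap characters are removed. The
absolute count of 10 is kept regardless of taxon number; consequently
alignments of fewer than 10 sequences are annihilated by the third
rule, which is why desk-scale runs use ≥ 12 species or a lowered
`min_unmasked`. The full pipeline is idempotent, and per-column (not
per-row) masking is the default with the row-wise variant reachable by
applying the mask per row.

**Supermatrix and statistics.** Trimmed loci are concatenated in
locus-id order with absent taxa filled with `N`; partitions are
recorded 1-based inclusive and written in RAxML format next to a
relaxed PHYLIP matrix. A column is *variable* with ≥ 2 distinct
unambiguous bases and *parsimony-informative* with ≥ 2 distinct bases
each occurring ≥ 2 times (gap/N/missing excluded — the standard PIC
definition). Percent missing counts gap, N and absent-taxon fill over
all cells; the absent-taxon fill alone is also reported separately,
since published "total missing" figures rarely say which they count.
The PIC-vs-length regression is ordinary least squares of per-locus PIC
count on locus length with adjusted R² = 1 − (1−R²)(n−1)/(n−2) and a
two-sided t-test on the slope. Positional PIC profiles count, at each
offset from the anchor centre (the probe-region midpoint carried in
locus metadata, falling back to the alignment midpoint), the loci with
≥ 1 informative site and the loci with any character at that offset.
Tree inference (RAxML GTR+Γ with 1000 random-addition and 1000
bootstrap replicates; ASTRAL over per-locus gene trees) is emitted as
JSON runner manifests, never executed in-process.

## The simulator

`simulate_clade` draws a birth–death species tree (or accepts a fixed
newick), rescales it to `tree_height`, and evolves each locus — exons
and introns laid out explicitly — down the tree under a Jukes–Cantor
transition kernel: over a branch of length t a site changes with
probability ¾(1 − e^(−4μt/3)), uniformly to another base, with introns
evolving `intron_rate_factor` (3×) faster than exons. Defaults
(`subs_rate` 0.05/unit, height 1.0) put tip-to-tip exon divergence
near 10 %, the regime AHE targets at the within-order scale.
Duplications are planted on the branch subtending a named tip set and
diverge by an extra `divergence` (0.15) before continuing down the
tree; a duplication naming all tips predates the clade and both copies
descend in parallel. Genomes are the evolved genes embedded in random
intergenic sequence plus an optional planted microsatellite tract;
transcriptomes are the spliced exons; consensus sets carry one record
per (sample, locus, copy) with uniform read support from
`support_range` (40–400). Reads are uniform-start, both-strand, with
i.i.d. substitution errors. All randomness derives from one seed via
named substreams (`substream(seed, stage)`), so stages are
independently reproducible and identical specs are byte-identical.

What the simulator does *not* emulate — and what passing tests
therefore do not show about real data: capture dropout and
taxon-specific locus loss (simulated matrices have near-zero
missingness, unlike the 7–16 % typical of real capture datasets),
indels (alignment is trivial, so MAFFT behaviour is untested by
construction), rate heterogeneity beyond the exon/intron split, base
composition bias, chimeric assembly, and contamination. The planted
repeat is a pure microsatellite; diverged transposon families would
stress the 1-mismatch 15-mer neighbourhood more than the tests do.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on simulated data:
typically 6–12 species, 8–20 loci of 150–1,100 bp, ~25–40 kb genomes,
50 seeded replicates for recovery rates and ≥ 200 randomized instances
per brute-force oracle comparison. These sizes keep a full run in tens
of seconds while exercising every threshold; the pipelines themselves
are linear in total sequence length except ortholog clustering
(O(n³) in sequences per locus, n ≤ ~30 here) and the 40-mer genome
index (dict-based, fine to tens of megabases).

Numerical conventions: internal coordinates are 0-based half-open,
all on-disk coordinates 1-based inclusive; all comparisons at printed
thresholds keep the printed strictness (e.g. *more than* 100,000
counts masks, *fewer than* 35 reads drops, exactly 75 % occupancy is
kept); ambiguity codes other than N normalise to N with a warning;
probe start spacing uses banker's-free `round(probe_len/density)`;
ties in clustering and probe ordering break lexicographically.
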