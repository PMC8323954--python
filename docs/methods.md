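# Methods

## Data model and coordinates

All user-facing coordinates are 1-based inclusive. Circular genomes are
plain uppercase DNA strings over {A,C,G,T,N}; wrap-around gene intervals are
written `start > end` and handled arithmetically, never by duplicating
sequence. Alignments carry a coordinate-reference record whose ungapped
positions define the reporting coordinate system; columns where the
reference holds a gap map to the preceding reference position. Rotation of a
circular genome to a common start uses a deterministic anchor motif: the
first occurrence of the anchor (forward strand, then reverse complement)
becomes position 1. This replaces maximal-rotation tools with an auditable
contract — the rotation index is logged, rotating twice with the same anchor
is a no-op, and an absent anchor is an error rather than a silent guess.

Circular spacing statistics (mean and population SD of gaps between sorted
positions) include the wrap-around gap by default, which fixes the mean at
exactly L/n; the `circular` flag switches to linear gaps because published
spacing figures are sometimes computed without the wrap (for 186 sites on a
15,989 bp genome the two conventions differ only in the first decimal:
86.0 circular vs ≈85.9 linear).

## Polymorphic sites

A polymorphic site is an alignment column with at least two observed
alleles. A gap is an allele (indel-containing sites are real sites); N is
excluded from both the allele counts and the frequency denominator, and
all-N columns are skipped. The default frequency denominator is the number
of non-N sequences at the column; a switch (`gap_in_denominator=False`)
removes gap-carrying sequences from the denominator for users who consider
them unsampled — only the default is used in the shipped reports.

Reference designation follows three rules: the majority allele is the
reference; a bi-allelic 50/50 tie yields a single variant, with the tie
broken in favour of the allele carried by the coordinate-reference record
(lexicographically smallest allele if neither matches — deterministic and
auditable, since any choice is scientifically arbitrary); in tri- and
tetra-allelic sites the most frequent allele is the reference and all others
are variants. Designation guarantees no variant exceeds 50% frequency, a
precondition the binning code enforces as an internal consistency check.

Type flags are computed per reference↔variant pair — transition for A↔G and
C↔T, transversion for purine↔pyrimidine, indel when a gap is involved — and
may combine (e.g. transition+transversion at a tri-allelic site), so the
'+'-joined categories partition the sites exhaustively.

The weighted frequency-bin table gives each site unit weight split equally
over its k variant alleles, accumulated into left-open right-closed
percentage bins (0,10], (10,20], …; the grand total therefore equals the
number of contributing sites, checked on every run. Per-gene tables for an
n-sequence panel bin variants into the attainable frequency classes k/n
(25% and 50% for a quartet); VI uses the polymorphic-site count, so the two
agree whenever all sites are bi-allelic. Adjacent gap columns are counted as
independent sites in alignment analyses — indel merging happens only at the
pileup level, where the caller emits multi-base alleles. Report rounding: VI
to 1 decimal in segment tables, 2 decimals in per-gene tables; weighted
counts to 1 decimal.

## Conserved and variable segments

Column conservation is the share of sequences carrying the modal non-N,
non-gap character; gaps and N count as mismatches. At the default 100%
threshold a conserved column is simply one where every sequence agrees. A
conserved segment is a maximal run of conserved columns of length ≥ the
minimum window (default 20 bp); each run is assigned the exact probability
that a fixed window of its length contains none of the S polymorphic columns
placed uniformly among the L columns, p = C(L−w, S)/C(L, S), and kept when
p < α (default 0.05). This hypergeometric window null was chosen because it
is exact, testable by enumeration, and monotone in both w and S; an optional
Bonferroni factor (L−w+1 window placements) is available but off by default,
as the maximal-run scan is not a window sweep. When S = 0 the null is
degenerate (p = 1 for every window), so a fully conserved alignment still
reports its run rather than discarding it. All maximal qualifying runs are
reported; there is no selection among ties.

Variable segments are the complement of the conserved segments within the
alignment span, including leading/trailing stretches, so CS and VS tile the
region exactly (checked: lengths sum to the alignment width). Segment GC is
computed over the non-gap, non-N characters of columns that are not
indel-containing sites, pooled across sequences (pooling and per-sequence
averaging differ negligibly; pooling is simpler and weight-consistent when
gaps are uneven). Coordinates are reported in reference positions via the
coordinate map.

Hypervariable grouping splits the ordered per-VS polymorphic-count profile
at the minimum between its two largest strict local maxima; the valley
segment starts the second group. A unimodal profile yields one group with a
warning, and an explicit split index can override the automatic choice.

## Heteroplasmy

The pileup parser implements the samtools text dialect (`.`/`,` reference
matches, case-insensitive base calls, `+n<seq>`/`-n<seq>` indels, `^q`/`$`
read-boundary markers, `*` deletion placeholders), reporting malformed lines
with their line number. Calling follows VarScan-style thresholds: every
non-reference observation with ≥ `min_var_reads` (default 4) supporting
reads and frequency ≥ `min_var_freq` (default 0) is emitted; frequency
≥ `min_freq_for_hom` (default 0.5) is labelled consensus rather than
heteroplasmic. The p-value is a one-sided binomial tail of the supporting
reads against a flat sequencing-error rate e = 0.01 — a deterministic,
documented stand-in for read-level exact tests, monotone in support at fixed
coverage. Calls with p ≥ α = 0.05 are retained in the VCF but flagged
`not_called` and excluded from all summaries.

Indels are anchored ref/alt strings (deletion of A after anchor C is CA→C;
the matching insertion C→CA), positioned at the anchor. Each indel is
annotated with the homopolymer run length of its first indel base around the
anchor — context for downstream filtering, deliberately never used to filter
here, since A/T-run indels dominate real mitochondrial heteroplasmy and
removing them silently would change the counts the reports are about.

Per-gene summaries cover called variants inside annotated genes only
(intergenic positions are excluded from the table, matching the reporting
universe of genes plus control-region segments). Rows carry 10%-wide
frequency bins up to 60%, VI, and a frequency-occupancy pattern label:
*progressive* when occupied bins form a prefix starting at (0,10],
*lone_high* for a single occupied bin above the lowest, *gapped* otherwise.
Invariable regions are the positional gaps between consecutive called
variants, wrap-around included.

## Distances and trees

Pairwise distances use pairwise deletion (columns with a gap or N in either
sequence are dropped per pair). Implemented models: p-distance, TN93 and
T92 in their standard closed forms, each with an optional gamma-rates
correction (−c·ln w terms become c·a·(w^(−1/a) − 1); shape 0.18 is the
conventional control-region setting). Base and GC frequencies are estimated
from the compared columns of each pair. Saturated pairs (a log argument
≤ 0) are set to a configurable ceiling (default 5.0) with a warning rather
than returning infinity. Bit-for-bit agreement with any particular desktop
phylogenetics package is not attempted: the published closed forms are the
contract, and topology is what the tests compare.

UPGMA uses Lance-Williams average-linkage updates with join height d/2 and a
deterministic smallest-index tie-break; the result is ultrametric by
construction (verified to 1e-9). Bootstrap support resamples alignment
columns with replacement, rebuilds the tree, and reports the fraction of
replicates containing each clade; runs are reproducible under a fixed seed.
An independent naive implementation (cluster means recomputed from the
original matrix each step) serves as the test oracle.

## Comparison report

Per-gene VI tables from the inter- and intra-individual analyses are joined
over a name universe (default: union of both tables) after normalising the
spelling variants that occur in practice ("VS 3" vs "VS3", "COX1 gene",
rRNA aliases). Each entry is categorised inter-only / intra-only / both /
neither; the four categories always partition the universe, and swapping the
two inputs swaps the corresponding categories. No statistical test of the
inter/intra difference is performed — the report is descriptive.

## Synthetic data

The generators define the study conditions rather than idealised toys:

* **Control-region panel** (default 45 haplotypes, ~1 kb, AT-rich ≈12% GC):
  seven conserved blocks of 40/27/23/20/27/35/24 bp interleaved with seven
  variable blocks of 55/89/354/110/11/130/56 bp carrying
  7/19/95/18/3/26/14 planted polymorphic columns — the reported segment
  structure used as generator parameters. Variant columns are spaced evenly
  within each variable block, including both edges, so recovered segment
  boundaries coincide with planted ones whenever planted runs meet the
  window minimum. Allele frequencies are planted as exact carrier counts
  (census ratios, as alignment frequencies are), drawn from a
  singleton-heavy pool so most variants are low-frequency; site types follow
  the observed mix (≈79% transition, 9% transversion, 6% combined, 6%
  indel-involving). Indel carriers never include the coordinate-reference
  haplotype, keeping reference positions equal to alignment columns.
* **Mitogenome quartet** (15,989 bp, ≈32% GC): one ancestor mutated into
  four descendants with per-gene planted singleton (25%) and doubleton
  (2 vs 2, 50%) substitutions following the reported per-gene table
  (168 singletons + 44 doubletons = 212 sites over 27 genes/segments laid
  out with intergenic spacers). The reference genome keeps the ancestral
  allele everywhere, so 50/50 ties resolve to the ancestor.
* **Heteroplasmic pileup** (15,989 bp): per-site coverage from a negative
  binomial matched to mean 128.4 / SD 51.3 with a floor of 70× (the floor
  keeps four supporting reads attainable at the lowest planted fractions);
  186 planted variants distributed over genes and frequency bins per the
  reported intra-individual table, with the reported indel composition
  (66 +T, 44 +A, 36 −T, 20 −A, 9 −C, 6 −G, three 2-bp events, two
  transitions). Planted fractions are drawn inside each target bin but kept
  ≥ 6%; read support is binomial at the planted fraction by default, or
  exact (`round(f·depth)`, the "noise off" mode) for identity tests and the
  acceptance script. Single-base indels are embedded in a 3–6 bp homopolymer
  run of their base with probability 0.7, emulating the A/T-run context of
  real indel heteroplasmy. One intergenic spacer is widened so a variant-free
  stretch of ≥ 548 bp exists by construction. The single tRNA-Ser gene is
  68 bp (real genomes carry two serine tRNAs; published tables sometimes
  average them to 68.5 — VI 1.47% vs 1.46%, a divergence we accept).

What the generators do **not** emulate: alignment uncertainty (planted
alignments are exact, so segment-boundary recovery says nothing about
aligner-induced boundary noise), read-level errors and strand bias (noise is
pileup-level), NUMT contamination, and recombination-free but
non-tree-like haplotype structure. Passing tests therefore demonstrate the
correctness of the statistics given a correct alignment/pileup, not
robustness to upstream artefacts; real-data runs additionally need an
aligner and curated annotations.

## Problem sizes and numerical choices

Default test and acceptance runs use the full synthetic scales (45 × ~1 kb
panel, 4 × 16 kb quartet, 16 kb pileup) plus reduced designs for
stochastic-recovery checks (100 loci at 100× constant depth) and bootstrap
demonstrations (6 taxa × 400 columns, 100 replicates) — sizes chosen so the
whole suite completes in seconds while every planted quantity is recovered
exactly. Frequency-bin membership uses a 1e-9 tolerance at the right edge;
hypergeometric p-values are computed with exact integer binomials; all
randomness flows from `numpy.random.default_rng` seeds and is reproducible.

## Known limitations

Real-dataset reproduction (the deposited haplotype panel, mitogenomes and
read set) requires repository downloads and an external aligner and is out
of scope for the offline test suite; outputs on such data are expected to be
comparable, not identical, since segment boundaries are sensitive to
alignment parameters. The window-null p-value is this package's own exact
model, not a re-derivation of any particular desktop tool's undocumented
formula; likewise the binomial error test replaces read-level exact tests.
Published segment tables occasionally contain internally inconsistent rows
(overlapping printed coordinates); the segment finder enforces tiling and
cannot reproduce such rows literally.
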