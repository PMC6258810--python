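# Methods

This note documents the models and procedures implemented in `bacseq`, the
parameters that matter, the design choices made where the design was open,
and the known limitations.

## Transcription-unit calling from coverage

The caller assumes that within one transcription unit the per-base coverage
fluctuates around a constant level, and that biologically meaningful
boundaries (TSSs, terminators, processing sites) appear as steps between
levels. It makes no attempt to distinguish processing sites from true
transcript ends; every surviving step is reported as a TSS or terminator by
its direction.

**Step detection.** Coverage is smoothed with a centered moving average of
`smooth_window` positions (default 3 nt; 1 disables smoothing), and the
discrete derivative d[i] = c̄[i] − c̄[i−1] is scanned for local extremes with
|d| ≥ `min_magnitude` (default 5 coverage units). A small window suppresses
single-position jitter without displacing step positions by more than a
nucleotide or two; larger windows trade boundary precision for robustness on
sparse data.

**Interval merging.** The candidate boundaries partition the genome into
intervals. The significance of a boundary is
|mean(A) − mean(B)| / max(sd(A), sd(B), sd_floor) for its two flanking
intervals, and the boundary is removable when this statistic is at most
`sd_threshold` (default 2.0). At each iteration the globally least
significant boundary is removed (ties broken leftmost, for deterministic
output) and the two intervals joined; iteration stops when every remaining
boundary is significant. Means and standard deviations come from prefix
sums, and a lazy heap over boundaries makes the whole merge
O(n log n) in the number of candidate steps, so genome-scale tracks are
processed in seconds. `sd_floor` (default 1.0) keeps zero-variance intervals
— exactly constant stretches, common in noise-free or zero regions — from
blocking every merge. The significance rule is a plug-in point
(`significance=` argument), so a count-model test (e.g. a quasi-Poisson
variant) can replace the standard-deviation rule without touching the
merging machinery.

**TU assembly.** Maximal runs of merged intervals with mean coverage at or
above `expression_threshold` (default 10) become TUs; the run's entry
boundary is the TSS and its exit the terminator, with the labels swapped on
the minus strand. Stranded tracks are processed independently; unstranded
tracks yield TUs whose TSS/terminator assignment relies on step direction
alone. Genes are attached to a TU by coordinate overlap when an annotation
is supplied.

**Single-base TSS calling.** On first-nucleotide coverage, position p is
called when (i) c[p] is the maximum of the window [p−w, p+w] (leftmost wins
ties), (ii) c[p] ≥ `min_height` (default 10 reads), and (iii)
c[p] > mean + k·sd of the window excluding p (defaults w = 50 nt, k = 5).
The windowed mean + k·sd is the "dynamic noise" estimate: promoters sit in
regions of very different background, so a global threshold either floods
low-coverage regions or misses TSSs inside highly expressed ones. The exact
derivative estimator and the noise formula are declared defaults of this
implementation, not reconstructions of any particular prior tool.

## Coverage representations and normalization

`full_read` coverage increments every reference position a read aligns to
(CIGAR-aware: deletions and soft clips get nothing); `first_nucleotide`
increments only the read's 5′-most aligned base — the rightmost for
reverse-strand reads — which is the representation 5′-enriched libraries
need. Secondary and supplementary alignments are skipped, so multi-mapping
reads count once through their primary alignment. Two conservation
invariants pin the implementation down: the first-nucleotide track sums to
the number of usable reads, the full-read track to the number of aligned
bases.

Normalization scales to per-million units of either total genome coverage or
coverage restricted to CDS positions; the CDS variant exists because rRNA and
tRNA dominate total coverage in many libraries and would otherwise compress
every mRNA value. FPKM for a feature is count · 10⁹ / (length · normalizer),
where the count is the base-coverage sum divided by the mean read length when
one is known (from the alignment stream, or the `--mean-read-length` flag for
native-format input); without a read length the raw base sum is used and the
output flags the unit change. The native track format is deliberately
trivial: a single header line (genome, strand, mode, length) and one value
per line, plus a TSV table variant bundling several tracks by
(sample, strand, mode).

## The coverage simulator

The simulator writes counts directly per position rather than placing reads:
TU layouts are packed left to right with lengths and gaps drawn uniformly
from configurable ranges (defaults 500–2000 nt and 100–500 nt), each TU's
target mean is drawn from Normal(center, sd) — sd defaults to 0.25 × center
— and per-position counts are NB2 with mean μ and variance μ + μ²/r
(dispersion r defaults to 10; `None` switches to the Poisson limit).
Intergenic positions receive NB2 counts around a background of 1 read/nt so
the caller always faces nonzero noise. Everything is driven by one integer
seed; identical seeds give byte-identical tracks.

What this emulates is the count noise and between-transcript abundance
spread of a bulk prokaryotic RNA-seq library. What it does not emulate:
read-length autocorrelation (adjacent positions in real pileups share
reads), coverage ramps near transcript ends, antisense and overlapping
transcription, rRNA dominance, or mapping artifacts. Passing the benchmark
therefore demonstrates the caller's statistical behavior on idealized
plateaus, not performance on any particular real library.

**Benchmark.** A truth TU counts as recovered when one called TU matches
both boundaries within ±20 nt (one-to-one greedy matching by total boundary
distance). The acceptance run uses ten 200 kb libraries of 100 TUs at a
mean-coverage center of 300 reads/nt clipped to [20, 400]; these sizes keep
the whole benchmark under ten seconds on one CPU while leaving ~1000 truth
TUs behind the sensitivity estimate. Sensitivity rises steeply with mean
coverage (≈0.7 at 20 reads/nt, ≈1.0 from ~100 reads/nt on under these
conditions).

## Sequence tools

GC skew is (G−C)/(G+C) per window, defined as 0 for G+C-free windows to
avoid a division by zero. ORF prediction scans all six frames and reports,
per stop codon and frame, the ORF from the first start codon (default ATG,
GTG, TTG) after the previous stop — the "longest ORF per stop" convention —
with the stop codon included in the coordinates; circular genomes are
scanned across the origin and origin-spanning ORFs carry explicit two-part
locations. The k-word search indexes the query's k-mers (default k = 11),
chains co-diagonal seed matches into candidate regions, and closes each
region with a global Needleman–Wunsch alignment (defaults +1/−1/−2, linear
gaps); overlapping hits are deduplicated keeping the highest score. Seeds on
different diagonals are not chained together, so alignments with indels
larger than the seed-gap limit are reported as separate hits. Repeat
finding is exact and exhaustive over all spacers up to K_max, vectorized per
(unit length, spacer) pair. Restriction mapping compiles IUPAC sites to
regular expressions with overlap-aware lookahead, searches both strands, and
reports palindromic sites once.

## Motifs

PWMs use pseudocounted frequencies (default pseudocount 0.5), per-column
Shannon entropy H and information 2 − H bits, and two scan scores: the
frequency sum Σ f[base, j] (bounded by the width, simple to threshold by
eye) and the log-odds sum against a background (default: the scanned
genome's base composition). The text format — `#PWM name width` plus four
labeled rows — is meant to be edited by hand.

De novo discovery is expectation-maximization under a
one-occurrence-per-sequence model: the E-step computes posterior site
positions from the current PWM versus background, the M-step re-estimates
the PWM from expected counts (with pseudocounts). Starts matter more than
iterations for this objective, so initialization screens every k-mer of one
randomly chosen anchor sequence plus `n_starts` random k-mers with a
three-iteration EM run, then polishes the best few to convergence and
returns the highest-likelihood motif. The run is deterministic for a seed,
and the data log-likelihood is non-decreasing across iterations (asserted in
tests to numerical tolerance). Only the one-occurrence model is implemented;
zero-or-one and multi-occurrence variants are extension points.

## Thermodynamics

DNA duplex ΔH/ΔS sum the 16 dinucleotide propagation steps of the unified
nearest-neighbor parameter set plus per-end initiation terms (G·C ends
0.1 kcal/mol, −2.8 cal/mol·K; A·T ends 2.3, 4.1) and a −1.4 cal/mol·K
symmetry entropy for self-complementary oligos. Tm = 1000·ΔH/(ΔS +
R·ln(C_T/x)) − 273.15 with x = 4 (x = 1 when self-complementary); the
default strand concentration is 0.25 µM. Parameters live in editable TSV
data files, and a monovalent-salt entropy correction
(0.368·(N−1)·ln[Na⁺] cal/mol·K) is available behind a flag but off by
default, so results refer to the tables' reference salt conditions.

Dimer analysis slides one strand against the other across all antiparallel
offsets and scores the maximal complementary runs (≥2 bp) at each offset
with stacking plus run-end initiation; loops and mismatches between runs are
not penalized, which makes the perfect-complement case exactly reproduce the
duplex calculation. Hairpins enumerate every fully complementary stem with a
loop of at least 3 nt; the stem is scored by stacking and the loop by a
size-dependent initiation penalty — tabulated RNA values with
Jacobson–Stockmayer extrapolation beyond 9 nt, a single declared default of
3.5 kcal/mol for DNA loops. Genome-wide hairpin scanning vectorizes the
stem search per (stem length, loop length) over the whole sequence with RNA
parameters on both strands, reports candidates below a ΔG₃₇ threshold
(default −5 kcal/mol) and deduplicates overlaps keeping the most stable;
this is a terminator-candidate screen, not a minimum-free-energy structure
prediction (no bulges, internal loops, or multi-branch structures).

## Molecular-biology utilities

Primer design enumerates every subsequence in the length range, filters each
candidate on Tm, GC fraction and the stability of its most stable hairpin
and self-dimer (a structure *more* stable, i.e. with ΔG below the
`max_*_dg` bound, rejects the candidate), pairs survivors subject to the
amplicon-length range, and ranks pairs by |Tm_f − Tm_r| then by least stable
secondary structure. Per-filter rejection counts are always returned so an
empty result explains itself. A 3′-run filter (no four identical terminal
bases) exists but is off by default. The OD calculator implements
c = OD / (nA·15200 + nG·12010 + nC·7050 + nT·8400 + M) with M taken from an
editable modification table seeded with common fluorophores and quenchers at
literature absorbance values. Codon optimization re-encodes each residue
with its most frequent codon from a supplied usage table (ties broken
alphabetically) and verifies the translation round trip.

## Proteins

Net charge sums Henderson–Hasselbalch occupancies: positive groups
(N-terminus, K, R, H) contribute 1/(1+10^(pH−pK)), negative groups
(C-terminus, D, E, C, Y) contribute −1/(1+10^(pK−pH)). Q(pH) is strictly
decreasing, so the isoelectric point is the unique root, found by bisection
on [0, 14] to |Q| < 10⁻⁴ by default; note that the stopping rule bounds the
residual charge, not the pH itself, so shallow titration curves can place pI
a few hundredths of a unit from the grid-search optimum. The pKa table is
an EMBOSS-style default shipped as editable TSV; published tables differ by
several tenths of a unit per group and pI values shift accordingly.
Molecular weights are average (not monoisotopic) masses, matching gel
conventions, and the theoretical 2D map is simply (pI, MW) per translatable
CDS.

## Numerical and interface conventions

All internal coordinates are 0-based half-open; GenBank and GFF3 conversion
happens only in parsers/writers. GFF strand "." is stored as "+" with an
`unstranded` qualifier and excluded from strand-sensitive logic. CDS lengths
not divisible by three are truncated to whole codons with a warning.
Ambiguity codes beyond ACGTN are rejected unless explicitly allowed.
`simulate_coverage` writes each TU's drawn target mean back into the truth
layout so downstream scoring can see realized abundances. Every stochastic
entry point takes an integer seed and is reproducible bit-for-bit; CLI
outputs are written atomically via a temp file and rename.
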