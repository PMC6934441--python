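# Methods

## Tandem-repeat detection from reads

Microsatellite content is measured without assembly: each read is scanned
for tandem arrays of repeat units of 1–20 bp that span at least `min_span`
bp (default 50; 10 for the short-locus variant). Because the span
threshold is fixed in base pairs, the minimum number of units scales as
⌈min_span / k⌉ — 50 copies for a homopolymer, 10 for a 5-mer — and
arrays shorter than the threshold are invisible, so reported content is a
defined subsample of the genome's true repeat content.

Detection is seed-framed: a candidate array is anchored by its first k
bases, and each subsequent non-overlapping k-window must match the seed
within the per-unit mismatch budget. The budget is
`min(mismatch_per_unit, k − 1)` — a window cannot be pure mismatch, which
in particular means homopolymers must match exactly. Mismatched bases
count toward the span and their window counts as a unit; a trailing
partial unit extends the span (not the unit count) while it matches the
seed prefix exactly; `N` never matches and terminates extension.

Overlapping candidates (different seeds/unit lengths claiming the same
bases) are resolved deterministically by most matched bases
(span − mismatches), then fewest mismatches, smaller k, lexicographically
smaller canonical unit, leftmost start. The matched-bases key is what
prevents degenerate claims: a 2-mer seed that only survives by spending
its mismatch budget in every window (e.g. `AG` walking across an `AGAT`
array) always loses to the true unit.

Units are reported in canonical form: the lexicographic minimum over all
rotations of the primitive root and of its reverse complement. Each read
is scanned in the lexicographically smaller of its two orientations, which
makes library-level quantification exactly invariant to reverse
complementing the input — a property we verify, not merely approximate.

The comparison frame for mismatches (fixed seed vs. sliding consensus) is
underdetermined in the detection literature; the fixed-seed frame used
here is the simplest deterministic choice, and the brute-force oracle in
the test suite implements the same contract independently.

## Depth normalization

Raw counts scale with sequencing depth, and depth is GC-biased. Counts
are divided by the median per-base depth of the GC bin matching the
motif's own GC fraction, with bins
{0–0.3, 0.3–0.35, 0.4…, 0.55–0.6, 0.6–1} — wider at the extremes where
genomes have few bases. Bins are half-open `[lo, hi)` with the top bin
closed; the local GC of a base is computed over a 150 bp centered window
(read-scale GC is what biases coverage; the width is configurable).
Medians over an even count average the two central values; an unpopulated
(or zero-depth) bin is flagged unusable and normalizing a motif against it
is a named error rather than a silent NaN.

The result approximates copies per 1× coverage. One artifact is retained
deliberately for comparability with prior repeat-content estimates: reads
that overlap an array by less than `min_span` detect nothing yet still
count toward depth, so e.g. a homopolymer array of exactly 50 bp
normalizes to ~30–40 copies, below its true 50. The acceptance harness
reproduces this overcorrection rather than correcting it.

## Rate estimation

Mutation is defined as net change in a motif's total genome-wide copy
number — gains and losses summed over every array — not as a per-locus
length change. For MA line *i* and motif *j*:

- genomic rate `U_ij = (c_ij − c_SC,j) / g_i` (copies/generation),
- per-copy rate `u_ij = U_ij / c_SC,j` (copies/copy/generation).

`|U|` correlates strongly with ancestral abundance (bigger mutational
target); dividing by `c_SC,j` removes that dependence, which the test
suite checks directly. Motifs enter the analysis only with ≥ 6 copies in
the SC and ≥ 2 copies in every MA line; EC lines are included in that
filter by default (`filter_ec` disables this, giving the looser variant).
Thresholds apply to the real-valued normalized copy numbers without
rounding. Genotype-level rates are unweighted means over MA lines; the
magnitude measure `|u|_j` averages `|u_ij|`. EC lines are processed
identically — their generation count defaults to experiment duration
(830 days) divided by a 10-day generation time, i.e. 83 generations; the
generation time is a required user choice with no universal default — but
EC aggregates are never mixed into MA means.

## Landscape analysis

The shared-motif matrix holds copy numbers of every motif with nonzero
copy number in all lines (columns sorted lexicographically). PCA is
column-centered with a deterministic sign convention (each component's
largest-magnitude loading is made positive); unit-variance scaling and a
log10(x+1) transform are available as flags. Clustering uses PAM
(k-medoids, BUILD-by-random-seeding + SWAP, best of 20 restarts per k) on
Euclidean distances over the first 10 PCs, selecting k ∈ [2, 12] by
maximum mean silhouette width.

The pipeline clusters on log10(x+1) copy numbers by default
(`pca_log`). Copy numbers span several orders of magnitude, and on the
raw scale both the PCA and the silhouette criterion are dominated by the
one or two most abundant motifs, which makes the selected k an artifact of
a single coordinate; the log scale lets every shared motif inform the
partition. `pca_scores` itself defaults to the raw scale so the
sensitivity of any result to this choice can be checked with one flag.

Motif-feature analyses: per-genotype OLS of `u_j` on unit length k;
GC content of the ten highest- vs ten lowest-`|u_j|` motifs among motifs
longer than 3 bp (shorter units have degenerate GC; `min_k` is a flag);
two-way ANOVA (type II, with interaction) of GC on genotype × rate
category; Kruskal–Wallis (ties-corrected, chi-square p) across groups,
with the all-tied degenerate case defined as H = 0; pairwise Pearson
correlations of `u_j` between genotypes on shared motifs, with an option
to drop named motifs to probe single-motif leverage.

## Synthetic data

The generator emulates the target study design: 3 populations × 2
genotypes, each genotype one SC, 2 EC and 7–8 MA lines (47 MA in total,
65 lines), MA durations drawn from [2, 26] generations with mean 12.4
(a Beta(2, ·)-stretched integer draw), EC kept 83 generations. Motif
landscapes are lognormal (log-mean 5, log-sd 1 in copies) over a pool of
30 canonical motifs spanning k = 1–10 and the full GC range, with
multiplicative lognormal offsets at the population and genotype level
(both log-sd 1.2). These offsets are deliberately large relative to
mutational drift: the regime being emulated is one where each wild
genotype carries a distinctive landscape and lines cluster by genotype,
while rates still vary strongly among sibling lines (per-line rates are
drawn around the genotype-level rate, both at sd 0.02/generation).

Copy-number evolution is a compound Poisson birth–death process: per
generation, gains ~ Pois(b·(φ + max(u*, 0))) and losses ~
Pois(b·(φ + max(−u*, 0))) with symmetric churn φ = 0.01, so the expected
net change is u*·b. The reference copy number b is the ancestral value by
default, which makes the planted u* exactly the quantity the net-change
estimator targets — the simplest process whose expectation matches the
estimator; with `reference="current"` the process compounds
multiplicatively (expected copy number `c₀(1+u*)^g`), in which case the
estimator's expectation is `((1+u*)^g − 1)/g` and recovery tests must
compare against that. Copy number is floored at zero, so strong sustained
loss rates (|u*| ≈ 0.1) drive motifs to extinction — and below the
abundance filter — within ~10 generations; the estimator-recovery harness
therefore uses short lineages (2–8 generations). EC mode accepts each
generation's proposed change with probability exp(−s·|Δ|/(1+σ)) (σ the
Poisson scale, strength s = 3), a mechanism-agnostic stand-in for
selection that attenuates realized rates by roughly two orders of
magnitude.

Planted genomes embed one locus per motif in random background that is
rejection-checked with the scanner to contain no detectable array; flank
bases at array boundaries are adjusted so no frame of the array can extend
into the flank within the mismatch budget, and the assembled contig is
itself rescanned until the planted (motif, units) multiset is recovered
exactly. Reads are single-end, uniform-start (optionally GC-biased), with
uniform substitution errors; the emitted depth table is computed from the
reads actually generated. Measured line profiles add mean-one lognormal
noise (sd 0.02) emulating residual normalization error.

What the simulation does *not* model: paired-end structure, indel or
context-dependent sequencing error, mappability, per-locus array-length
dynamics (only genome-wide totals evolve), interruption/death of arrays by
substitution, and linkage between motifs. Passing recovery tests
therefore demonstrates correctness of the estimators and pipeline plumbing
under the stated generative model, not robustness to real-data artifacts
upstream of the depth table.

## Problem sizes and numerical choices

Validation workloads are sized for a single CPU: scanner-oracle agreement
uses 1,000 structured-random reads (≤ 120 bp, units ≤ 4 bp); read-level
recovery uses ~26 kb genomes at 20–50× with 150 bp reads; rate recovery
uses 200 replicate MA lines over 24 motifs; clustering uses the full
65-line design in profile-only mode (no reads), 10 PAM seeds × 20
restarts. All randomness flows from explicit seeds; PAM label order is
fixed by sorting medoid indices; PCA signs by the largest-loading
convention; silhouette of a single-cluster labelling is treated as −∞
rather than an error. Floats round-trip through TSV via `%.17g` printing
and round-trip parsing.

## Known limitations

- The exact mismatch bookkeeping of legacy repeat scanners is not
  published; other tools may count borderline mismatched or partial units
  slightly differently. All counts here follow the contract above.
- Net-change rates cannot distinguish one large event from many small
  ones, and say nothing about per-locus expansion/contraction.
- With real data the depth table's mappability filter is the caller's
  responsibility; the package consumes whatever table it is given.
- Silhouette-based k selection on raw copy-number scale is unstable for
  abundance data; use the default log scale unless you have a reason not
  to.
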