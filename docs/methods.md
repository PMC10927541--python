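# Methods

## Data model and conventions

The ingestion contract is a long-form count table: one record per
(cell, transcript, position, condition) holding read coverage and
mutated-read count, with condition `treated` (chemical probe) or
`control` (mock/DMSO). "Mutated" aggregates mismatches and indels into a
single count; upstream mutation callers do not separate them in any
formula the pipeline consumes, so keeping one number avoids a spurious
distinction. All coordinates are transcript-space, 0-based, half-open
everywhere inside the package; the two formats that are 1-based by their
own standards (CT structure files and two-column SHAPE files) are
converted in `io` and nowhere else, so any off-by-one bug has a single
possible home.

Every per-position vector carries a boolean mask (True = value defined).
Masked positions hold NaN and no operation ever reads them; functions
intersect masks rather than imputing.

## Cell quality control

A cell passes when it has ≥ 5,000 detected genes (expression > 0) and a
mitochondrial expression fraction ≤ 5 %. The filter removes cells with
*fewer than* 5,000 genes or *more than* 5 %, so both boundaries are
inclusive on the passing side: exactly 5,000 genes and exactly 5.0 %
pass. The mitochondrial denominator is whatever the supplied expression
table contains (reads, TPM, normalized counts); the package does not
guess a normalization, it documents that the choice travels with the
input table.

## Reactivity

Per-base reactivity is treated-rate minus control-rate on the mask
intersection. Negative values are kept by default — the subtraction
defines them, and the gene-level cosine statistic is sign-sensitive — and
clamping at zero is an explicit flag. Pseudobulk profiles sum counts over
cells and then divide (equivalent to merging the libraries), not the mean
of per-cell rates; the two differ whenever coverage varies across cells,
and count-summing weights cells by the evidence they carry.

Treated and control are typically disjoint cell populations, so a single
treated cell has no matched control. Per-cell profiles therefore subtract
the control *pseudobulk* rate unless the cell happens to carry its own
control records (the simulator emits both channels per cell, in which
case the cell's own control is used).

Two normalizations are provided. Gene-level (2–8 %) normalization — drop
the top 2 % of a transcript's reactivities as outliers, divide by the
mean of the next 8 % — is the community-standard SHAPE scaling, here
requiring ≥ 10 unmasked positions and rejecting a nonpositive scale
factor. Quantile normalization across cells replaces each cell's
unmasked values by the cross-cell mean quantile curve at the value's
rank; cells may cover different position sets, so the reference curve is
the mean of per-cell empirical quantile functions on a common grid
(linear interpolation), ties take average ranks and hence the average of
the reference values over the tied ranks. Identical cells are an exact
fixed point.

Depth subsampling thins each record binomially (each read kept with
probability p) and then draws the retained mutated reads
hypergeometrically given the retained coverage — reads are exchangeable,
so the expected mutation rate is preserved exactly.

## Window-level heterogeneity

Windows are 10 nt, tiled from position 0, trailing remainder dropped;
detection requires total coverage strictly greater than 600 reads
(chosen upstream from replicate-correlation saturation) and per-cell
coverage > 0 in at least 50 % of cells. Per-cell detection is "any
coverage in the window", the weakest defensible reading; the stricter
per-cell 600-read alternative would interact with the coverage filter
and is not used.

The fit is ordinary least squares of window-summed mutant counts against
window-summed depth across cells, *with* intercept — the regression
routine the statistic is defined through fits one, even though the
conceptual model runs through the origin; the divergence is deliberate
and documented here. R² is the squared Pearson correlation and
adj R² = 1 − (1 − R²)(n − 1)/(n − 2) with one predictor. Windows with
fewer than 4 covered cells, or zero variance in depth or mutant, are
flagged undefined, never coerced to 0 or 1 — silent coercion would leak
undefined windows into the quantile classes.

## Gene-level heterogeneity

After quantile normalization (caller's responsibility, matching the
processing order), each cell's profile is compared to the pseudobulk on
the positions unmasked in both, requiring ≥ 10 shared positions;
D_i = 1 − cos(R_i, R_pseudo) and heterogeneity = √(mean D_i²).
Zero-norm restricted vectors are excluded with a warning; fewer than two
usable cells is an error. Quartile classification uses
linear-interpolation percentiles; values exactly on a boundary go to the
extreme class, and an all-equal input is classed intermediate with a
warning since the extremes are undecidable.

## Region assignment, metagene, trajectory clustering

A window's region (5′UTR/CDS/3′UTR) is the region of its midpoint
⌊(start+end)/2⌋ under the half-open CDS convention. Metagene enrichment
places windows by midpoint offset from the start or stop codon, bins the
span ±300 nt (20 bins by default), and tests each bin with the upper-tail
hypergeometric (background = all anchored windows); empty bins report
density 0 and p = 1.

Trajectory clustering of per-window heterogeneity across differentiation
stages is k-means (default k = 6) under dynamic-time-warping distance
with DBA (DTW barycenter averaging) centroids. DTW uses the classic
dynamic program with squared local cost and the match/insert/delete step
pattern; the k-means loop runs 10 seeded restarts and keeps the lowest
within-cluster sum of squared DTW distances, making results deterministic
under the seed. Both algorithms are implemented in the package and the
DTW distance is validated in the tests against exhaustive alignment-path
enumeration.

## Structure benchmarking

Unpaired bases are labeled True. When a 2′-OH solvent-accessibility table
is supplied, bases below 3 Å² are excluded from *both* classes — a buried
unpaired base cannot be modified, and a buried paired base contributes no
information either; without a table all bases are included (the in-vitro
mode). AUC is computed from rank sums (ties get ½ credit), identical to
the trapezoidal area under the swept ROC curve, and is checked in the
tests against an O(n²) pair-count oracle and against scikit-learn.
The paired-vs-unpaired comparison is a two-sided Mann–Whitney U: exact
enumeration when both classes have ≤ 8 values and no ties, otherwise the
normal approximation with tie correction.

## Enrichment statistics

Feature overlap is nonempty half-open intersection. Enrichment is the
upper-tail hypergeometric P(X ≥ k) with population = background windows,
successes = background windows overlapping the feature, draws = interest
windows; Bonferroni across the features tested in the call (the family
is the call's feature set); enriched ⇔ adjusted P ≤ 0.05. Depletion via
the lower tail is available but off by default. Expression-quartile bins
split cells into four equal-count groups by stable sort (ties broken by
cell id, bin sizes differ by ≤ 1). The q4-vs-q1 contrast uses Welch's
unequal-variance t-test — quartile cell counts and variances need not
match — and log2((m₄ + c)/(m₁ + c)) with pseudocount c = 0.01 to keep the
ratio defined near zero; with strongly negative mean reactivities the
fold change is undefined (NaN) rather than fabricated.

## Simulator

The generator emulates the measurement process: per cell, one
conformation per transcript drawn from mixture weights; coverage per base
negative-binomial (dispersion 10 by default — single-cell depth is
overdispersed relative to Poisson) with mean decaying exponentially with
distance from the 3′ end (default 1/1000 per base, mirroring libraries
that read ~1 kb from the 3′ end); treated mutations
Binomial(coverage, modification probability + background error, capped at
1) with background 0.002; control mutations Binomial(coverage,
background); whole cell × transcript observations drop out with
probability 0.1 by default. Modification probabilities default to the
low-percent range of MaP chemistry (3 % base rate, up to ~0.13 at
heterogeneous hot positions).

What it does *not* emulate: read-level structure (fragment lengths, UMI
duplicates, sequencing error profiles), correlated coverage between
channels, transcript-abundance variation across cells beyond dropout,
and co-occurring conformations within one cell (each cell draws exactly
one conformation per transcript). Passing recovery tests therefore shows
the statistics behave correctly under the stated generative model, not
that real libraries satisfy that model.

The two-conformation panel places the requested numbers of homogeneous
and heterogeneous 10-nt windows on one transcript; heterogeneous windows
differ by the rate gap at 5 of 10 positions, conformations mix 50/50, and
a small per-window jitter (±0.005) keeps windows from being carbon
copies. The reference fixture draws the requested number of paired
positions and nests them (i-th chosen position from the left pairs with
i-th from the right), giving a valid, symmetric, pseudoknot-free
structure; unpaired bases get modification probability 0.08, paired 0.01.
It is a synthetic stand-in for a solved structure, adequate for testing
label recovery, not a thermodynamically plausible fold.

## Problem sizes and numerical choices

Validation experiments run at: 1,000 random windows for the least-squares
oracle (agreement to 1e−10), every hypergeometric population N ≤ 30
against combinatorial enumeration, 500 ROC instances ≤ 200 positions
against the pair-count oracle, recovery panels of 200 windows × 40 cells
at 1,000× depth, and 2,000 null simulations for test calibration
(type-I in [3.5 %, 6.5 %] at α = 0.05). The demo dataset bundled by
`scshape simulate` uses a few hundred positions and tens of cells so a
full end-to-end run finishes in seconds; all of these are package
choices sized to make the checks sharp but cheap.

Degenerate inputs are errors or flagged results, never silent defaults:
empty cell sets, single-class labels, zero-variance fits, nonpositive
normalizers, all-equal quantile inputs, and overlapping contrast groups
all raise or warn explicitly.

## Known limitations

- The stratified per-cell reactivity uses a window-aggregate rate minus a
  control pseudobulk; with very low per-cell coverage the per-cell values
  are noisy and the Welch test loses power (it stays calibrated).
- DTW k-means is exact but O(T²) per distance with Python-level loops; it
  is intended for the short stage-trajectories it was designed for (a few
  stages, thousands of windows), not long time series.
- Quantile normalization across cells with very unequal coverage
  interpolates the reference curve; rank information is preserved but
  extreme-tail values in sparsely covered cells are smoothed.
- The enrichment Bonferroni family is per call; callers testing several
  window classes against the same features should correct across calls
  themselves if they want a global family.
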