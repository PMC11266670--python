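# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED dialect) internally; GTF input
is converted on read. Two regions overlap when their intersection covers at
least one base, so abutting intervals such as [100,200) and [200,300) do
not overlap and are not merged. The overlap threshold is configurable
(`min_overlap`, default 1 bp) because published peak-comparison work rarely
states whether a 1 bp or reciprocal-fraction criterion was used; the 1 bp
default is the most permissive and the one the rest of the pipeline
assumes. Overlap and merge operations delegate to pyranges; every interval
result is cross-checked in the test suite against a quadratic
all-versus-all scan. Signal tables are non-negative matrices (regions or
genes × samples); per-million scaling multiplies each sample by
1e6 / library size and is exactly linear in the counts.

## Trajectory classification (CO/OC groups)

A locus universe is built by overlap-merging every peak set of a condition
(all course timepoints plus the MEF start and ESC destination references).
A locus is *open* at a timepoint iff it overlaps a called peak there;
presence is binary from peak calls rather than a signal threshold, because
the grouping is defined on open/closed state, not on signal magnitude.

Each locus trajectory — (MEF, t₁..t_T, ESC) with T = 8 course timepoints by
default — is labelled by nearest-template matching:

* references (closed, open) select the closed→open orientation; the
  candidate templates are the step patterns "open from timepoint k",
  k = 1..T+1, where k = T+1 is the terminal group (CO9 with the default
  grid: open only in the destination state);
* references (open, closed) mirror this for open→closed (OC1 = closed from
  the first timepoint, OC9 = closed only in the destination state);
* equal references give static_open/static_closed when the course deviates
  at no more than `flicker_tolerance` timepoints, otherwise complex;
* within an orientation the label is the template with the fewest
  mismatching timepoints, the earliest transition winning ties; a nearest
  distance above `flicker_tolerance` (default 1 timepoint) is complex.

The tolerance absorbs single-timepoint dropouts and spurious calls typical
of peak calling. A stricter "persistently open" rule (exact openness at the
transition and final timepoints) was considered and rejected: it handles
interior dropouts but misclassifies static loci and final-timepoint
dropouts as complex, which measurably hurts recovery under flicker noise.
The two rules agree exactly on noise-free data. Raising the tolerance never
increases the number of complex loci. The rule is exercised exhaustively:
the test suite enumerates all 2^10 possible presence vectors against an
independently written template-table oracle.

Genuinely ambiguous flickers remain ambiguous by design: a single spurious
open call at timepoint k−1 of a CO_k locus produces data identical to an
ideal CO_{k−1} locus, so roughly a quarter of single-timepoint flips shift
the label by one group. At the default study conditions (200 loci per
group, 2% flicker) about 95% of loci recover their planted label.

## Trajectory comparison (failed-to-open / failed-to-close)

The comparison focusses on the groups that transition during the course:
CO1–CO8 and OC2–OC9 by default (the terminal CO9/OC1 groups are endpoint
effects, not reprogramming dynamics). A locus is *failed-to-open* when its
condition-B label is in the CO scope while its condition-A label is CO9 or
static_closed — A never opened it by the final timepoint. Failed-to-close
mirrors this (A label OC9 or static_open), with identical B/A labels
excluded so that a locus closing only in the destination state in both
conditions is not called a failure. Loci are matched across conditions
positionally when the universes are identical (the pipeline builds one
joint universe) and by ≥ 1 bp overlap otherwise; a B locus absent from A's
universe was never called open in any A sample and is treated as
static_closed. The "early" failure fraction is reported over the first
five groups by default (`early_max_group`), the boundary being exposed
because "early" is a presentation choice, not a property of the data.

## Co-occupancy codes

The merged universe of the four binding peak sets is coded by per-set
overlap in the fixed bit order (NANOG_WT, NANOG_BiD, BRG1_WT, BRG1_BiD);
this is the only bit order consistent with reading 0101/0100 as the
engineered-condition NANOG group and 1101/1100 as the NANOG-common group.
"Strong/weak" BRG1 is peak presence/absence, not a signal quantile — an
interpretive choice; a quantile mode exists but is off by default. Signal
per region is the mean over the region. Class summaries report median,
quartiles and 1.5×IQR whiskers, with a two-sided Welch t-test between
condition pairs per class (identical samples are reported as p = 1 rather
than NaN). Annotation stratification reports the overlap fraction of each
class in each annotation space plus the permutation z-score described
below.

## Enrichment statistics

**Permutation z.** The observed statistic is the number of query regions
overlapping the fixed reference set. The null relocates every query region
uniformly within its own chromosome, preserving length and chromosome but
not inter-region spacing (the cited regioneR-style default), for
`n_permutations` ≥ 100 draws (default 1000); z = (obs − μ₀)/σ₀. The null
mean converges on the closed-form expected overlap for uniform placement;
the tests assert agreement within 3 null sd at 1000 permutations and
calibration (|z| < 4 on independent uniform sets in ≥ 19/20 seeded runs).

**Motif enrichment.** Target and background windows are summit ± 25 bp
(midpoint when no summit is recorded); background windows overlapping any
target window are removed so the contrast is target versus genuine
background. A window is a hit when it overlaps at least one motif
occurrence. p is the hypergeometric right tail of the target hit count
(verified against exact rational summation to 1e-12 relative error), fold
is the ratio of hit rates with an all-target/no-background fold capped at
2^20 so results stay finite and sortable. A motif is reported at
fold ≥ 3 (inclusive — the source material states "at least 3-fold" in one
place and "> 3" in another; the inclusive reading is the default and the
threshold is a parameter) and p < 1e-5.

**PWM scanning.** When occurrence BED files are not supplied, windows can
be scanned directly: log2-odds against a uniform background on both
strands, hits at score ≥ threshold, probabilities floored at 1e-9 before
the log. Windows above 10% non-ACGT content are skipped with a warning.

**Regulator ranking.** The genome is tiled into fixed bins (default
1 kb) and each compendium factor cross-tabulated against the query by bin
membership. The Fisher test is right-tailed (enrichment only); the odds
ratio uses the Haldane–Anscombe 0.5 correction when any cell is zero, p is
floored at 1e-300 and log2(OR) clipped at ±20. The composite score
(−log₁₀ p)·log₂(OR) is exactly 0 at OR = 1, invariant to factor ordering
and monotone in planted overlap. This bin-based contingency is an
approximation of interval-indexing overlap scorers, which differ in
indexing details; at desk scale the bin construction is exact and
transparent.

## Region–gene association

Distances are signed along the gene (negative upstream of the TSS). A
region is associated with a gene when any covered base is within 100 kb of
the TSS; the relation is promoter_overlap (region intersects TSS ± 2 kb),
else upstream (within 5 kb upstream) or downstream (within 2 kb
downstream), else distal. With the default parameters the downstream
window is contained in the promoter window, so the downstream relation
only surfaces when the promoter half-width is configured smaller. On the
miniature synthetic genome the 100 kb distal cap makes association dense;
the cap is a parameter for that reason.

## Expression and proteomics

The DE score is log2((mean_b + 1)/(mean_a + 1)) with a strict |score| >
0.5 call — a deliberately simple, antisymmetric stand-in for posterior
fold-change callers, swappable behind the same interface; the pipeline's
contribution is the threshold chain, not the fold-change estimator.
Clustering is k-means (25 restarts, fixed seed) on per-gene z-scored
profiles (sd floored at 1e-8 with a warning for constant genes), making it
invariant to uniform FPKM scaling; cluster ids are relabelled by
decreasing size for stability. The default cluster count is 12 to match
the analysis this reimplements; the synthetic recovery checks use k = 3
well-separated trends.

The interactor chain requires detection (> 0 intensity) in every replicate
of a condition, mean log2 enrichment over control strictly > 1.2, and a
two-sided Welch t-test on log2 intensities versus control with p < 0.05.
The Welch test replaces the imputation-based workflow of dedicated
proteomics DE packages — an approximation, and the test is configurable.
Candidates partition into WT-specific, BiD-specific and shared statuses.
With two replicates per condition, a planted log2 effect of 3.0 at 5%
replicate CV is recovered exactly.

## Synthetic data: what it emulates, and what it does not

The generator emits the exact formats the readers accept, with planted
truth for every stage. Open loci draw signal from Normal(5, noise_sd) and
closed from Normal(0.5, noise_sd), truncated at zero — separable but
overlappable, enough to exercise thresholding without modelling read
counts. Loci are non-overlapping fixed-width 500 bp windows on a seeded
slot grid; both conditions share one timepoint grid
(MEF, D0, D1, D3, D5, D7, D8, D10, D12, ESC) and one pair of reference
states. Failures are planted only where the shared references permit them:
failed-to-open loci are CO1–CO8 in condition B and CO9 in A; failed-to-
close are OC2–OC8 in B and OC9 in A. Default failure fractions are 50% of
each CO group and 8% of each OC group, mirroring the observed asymmetry of
the system this models (the engineered condition roughly doubles the
course-opening loci; under 10% of closing loci differ). Flicker flips
single-timepoint presence independently per condition at the given rate.

The default expression trends span 4–12 FPKM (several-fold swings typical
of differential genes) with Gaussian noise at 0.25× the amplitude;
pull-down intensities are lognormal around a per-protein base with planted
interactor counts of 19 engineered-specific, 2 wild-type-specific and 531
shared.

What passing on this data does **not** show: the generator has no read-level
sampling noise, no peak-caller artefacts beyond independent single-
timepoint flicker, no correlated replicate structure, no GC or mappability
bias, and motif occurrences are planted as region sets rather than scanned
from sequence. Recovery rates here are upper bounds on what identically
parameterised real data would give; the value of the tests is exactness of
the logic (round trips, rule tables, calibration), not biological effect
sizes.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere (numpy `default_rng`); identical seeds give
byte-identical outputs, including the pipeline manifest hashes. Ties in
nearest-template matching go to the earliest transition; ties in regulator
ranking break lexicographically on factor id. Degenerate inputs fail fast
with named errors: inverted intervals, regions past chromosome ends,
zero library sizes, empty locus universes, missing contrast samples or
control conditions, permutation counts below 100, regions longer than
their chromosome, non-probability PWM columns.

## Scale of the shipped verification runs

The packaged checks run on miniature genomes (2–4 chromosomes of 1–3 Mb):
4,000 loci for trajectory recovery, ~540 coded binding regions, 20×1000
permutation draws for null calibration, 600 genes for clustering and 1,000
proteins for the interactor chain. These sizes were chosen so the entire
suite and the acceptance script each complete in seconds on one CPU while
keeping every statistic in a regime where its expected behaviour is
unambiguous.

## Known limitations

Quantitative (signal-threshold) dynamic calling is out of scope; grouping
is strictly binary. The regulator score approximates interval-indexed
overlap scoring with genome bins. GO/annotation-database enrichment is not
included (results from external tools can be joined on the emitted gene
lists). The pipeline orchestrates the synthetic dataset end-to-end;
file-based inputs are supported through the library functions and the
config's `inputs` section for the dynamics stage.
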