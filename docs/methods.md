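# Methods

## The problem

Water sampled from a rearing tank (or the wild) carries environmental DNA
(eDNA) shed by the organisms living in it.  Nanopore sequencing of that
DNA preserves base modifications, so per-site methylation levels can be
summarized directly from the reads.  In fish larvae, methylation at a set
of mitogenomic sites changes rapidly and reproducibly over the first weeks
post-hatch, which makes an *epigenetic clock* possible: a penalized linear
regression that predicts chronological age (days post-hatch, DPH) from the
methylation levels of those "aging sites".  This package implements the
full desk-side pipeline — methylation-summary ingestion, aging-site
detection, grouped penalized clock fitting with objective model selection,
prediction, and gene-importance reporting — together with a synthetic-data
generator that emulates the statistical structure of such an experiment so
every stage is testable without sequencing data.

## Inputs and site reconciliation

The pipeline consumes bedMethyl summaries (as produced by `modbam2bed`),
one file per sample x calling submodel.  Three submodels are expected:
`5mC` (cytosine methylation in all contexts), `5mCG_5hmCG` (5mC/5hmC in
CpG context) and `6mA` (adenine methylation).  Each record carries the
coverage (valid calls), the percent modified, and a 0-1000 score treated
as a 0-1 *reliability* (fraction of unambiguous modification calls).
Coordinates are normalized to 1-based single-base positions at ingestion;
records on opposite strands are distinct sites unless strand collapsing is
requested.

A site is *characterized* as 5mC when the 5mC submodel reports an `m` call
with a nonzero level at any age, and as 5hmC when the CpG submodel reports
a nonzero `h` call.  Reconciliation rules:

* adenine calls -> 6mA;
* characterized 5mC but not 5hmC -> 5mC; characterized 5hmC but not
  5mC -> 5hmC;
* modified cytosines characterized as neither -> "other modC";
* characterized as **both** 5mC and 5hmC -> contradictory; the site is
  dropped and counted.

For "other modC" sites, the level vector is taken from the available
cytosine records in a fixed precedence order (ambiguous-`C` records first,
then CpG-context calls), so the choice is deterministic; the same record
supplies coverage and reliability.  A site keyed with both adenine and
cytosine codes is a data error, not a category.

Sites must be covered (>= `min_coverage`, default 1, configurable) at
*every* age of interest — differential methylation is undefined otherwise.
An **aging site** is then any remaining site whose level vector is not
constant across ages.  This is deliberate literal inequality at the parsed
2-decimal precision, not a statistical test: at coverage near 3x a
per-site test would be meaningless, and the detection step is a filter
whose false positives are subsequently shrunk by the penalized fit.
All-zero sites are non-differential, not errors.

Gene labels come from the GenBank feature table of the reference
mitogenome: CDS, tRNA, rRNA and D-loop features are extracted with 1-based
inclusive coordinates, overlaps are resolved with precedence
CDS > tRNA > rRNA > D-loop (within a kind the shorter feature wins, which
handles the ATP8/ATP6 and ND4L/ND4 overlaps sensibly), origin-spanning
features are split, and every unannotated position is assigned to an
`NC<k>` ("non-coding") gap numbered left to right.  The resulting
intervals partition the sequence, so gene annotation is total.

## The clock model

Let `y` be the vector of ages (DPH) and `X` the samples x aging-sites
matrix of methylation levels (%).  For a grouping `g` of sites and
penalty-mixing factor `alpha` (0 = ridge, 1 = lasso / group lasso) the
clock solves

    min_{b0, beta}  (1/2n) * ||y - b0 - X beta||^2
        + lambda * sum_g w_g * [ alpha * ||beta_g||_2
                                 + (1 - alpha)/2 * ||beta_g||_2^2 ]

with group weights `w_g = sqrt(|g|)`.  With every site its own group this
is the standard elastic net.  Columns are standardized internally (zero-
variance columns are frozen at coefficient 0); coefficients are reported
on the original scale (days per percentage point).

Groups are built by *pasting*: each site carries four features — gene,
modification type, mean coverage (rounded to the nearest integer) and mean
reliability (rounded to 1 decimal) — and a grouping scheme is any of the
16 subsets of those features, the chosen feature values joined into one
string label.  Sites sharing a label are penalized as one group.  The
quantitative features must be discretized before pasting; the rounding
granularity is a package choice.

### Solver

Warm-started block coordinate descent along a descending lambda path:
each block update is a proximal step with the block Lipschitz constant
(exact coordinate minimization for standardized singletons), with
glmnet-style active-set cycling (iterate nonzero groups to stability, then
a full pass over all groups to check the rest).  `lambda_max =
max_g ||X_g'(y - ybar)|| / (n * max(alpha, 0.001) * w_g)` is the smallest
lambda with an all-zero solution; the path is 100 log-spaced values down
to `0.01 * lambda_max` (ratio chosen for p >> n).  For `alpha = 0` the
problem is a weighted ridge regression and is solved exactly per lambda
through the n x n Woodbury identity instead of iterating.

Numerical tolerances: the exhaustive grid uses a coefficient-change
tolerance of 1e-3 (prediction error well below 0.01 days on the scale of
the MAE landscape, verified against tight solves); one-off fits accept a
`tol` argument, and the solver-equivalence tests run at 1e-12 against an
independent FISTA minimizer of the same objective.

### Cross-validation, "bootstrap", and selection

MAE is the **median** absolute error everywhere.  Cross-validation uses
k = 3 folds for the six-age design (each training fold then holds 4
samples; larger k would leave single-sample folds).  The lambda path is
computed once on the full data and shared across folds; out-of-fold
predictions are pooled over all n samples per lambda (a per-fold-averaged
variant is available via `pooling="per_fold"`), and `lambda*` is the curve
minimum, ties to the more regularized end.

Fold assignment at n = 6 is highly influential, so every candidate is
refitted under B = 10 independent re-randomizations of the fold partition
("bootstrap iterations", seed = base seed + iteration).  Resampling the
six samples *with replacement* would duplicate response values and break
the 3-fold design, so fold re-randomization is the implemented reading of
the bootstrap; it is a documented interpretation, exposed as the iteration
seed.

The grid is exhaustive: alpha in {0.00, 0.01, ..., 1.00} x 16 schemes x
fold options x B iterations.  Every candidate records its cross-validated
MAE (at lambda*) and the training MAE of the full-data refit at lambda*.
Selection is the dual standardized-MAE criterion: within a candidate pool,
z-score both metrics (ddof 1; a zero-variance metric contributes 0), sum
them, and take the minimum, breaking ties by lower CV-MAE, then lower
alpha, then lower iteration index.  The per-scheme optima are selected
this way within each scheme, and the final clock per dataset variant is
selected among those optima.  The criterion is invariant under any common
affine transform of both metrics.

Clocks are fitted on three dataset variants: all aging sites (`full`),
cytosine modifications only (`modC`: 5mC + 5hmC + other modC) and adenine
modifications only (`modA`: 6mA).

### Reporting

Per-gene importance is the sum of |coefficients| over the gene's sites as
a fraction of the total (more stable than counting selected sites, which
tracks alpha), alongside selected-site counts.  The range-scaled MAE,
`mae / (age_max - age_min)` reported to 2 decimals, makes clocks with
different age ranges comparable.

## Alignment QC

Two read-level metrics from CIGAR operation counts: read **accuracy** =
matches / alignment length (mismatches and gap bases in the denominator)
and read **identity** = matches / aligned bases (gaps excluded), so
identity >= accuracy with equality exactly for gap-free alignments.
Soft/hard clips and reference skips are excluded from both denominators
(skips are not expected in genomic DNA mappings).  When a CIGAR uses `M`,
mismatches are recovered from the NM tag (minus indel bases); explicit
`=`/`X` wins over NM when both are present.  The per-sample summary
reports median accuracy, median identity and the median error-rate proxy
`1 - median identity`.

## The synthetic generator

The generator emulates the study conditions the pipeline assumes: six ages
at 10, 12, 14, 17, 19 and 24 DPH; a 16.6 kb mitogenome-like reference with
real mitochondrial gene names (synthetic coordinates, including the
canonical CDS overlaps); coverage 1 + Poisson(2) per site and age (mean
3x); uniform reliability scores in [0.8, 1]; and a modification mixture
skewed toward 6mA with 5mC dominating the cytosine fraction.  Methylation
trajectories come in the families seen on real aging sites — *spikes*
(100% at exactly one age, biased toward the youngest stage, 0 elsewhere)
and *ramps* (3-6 percentage points per day) — plus constant,
incompletely-covered and conflict (5mC-vs-5hmC contradiction) sites as
negative controls.  Noise on emitted levels is additive Gaussian clipped
to [0, 100]; real calling noise is not characterized, so this is a stated
generator assumption.

Two fixed presets anchor the tests: the noise-free planted-trajectory
preset (5 spike + 5 ramp + 90 constant + 10 incomplete + 6 conflict
sites), on which the pipeline must recover the planted counts *exactly*;
and the linear-signal preset (20 ramp + 480 nuisance sites, noise sd 5),
on which the grid-searched clock must reach CV-MAE <= 3 days in at least
16 of 20 generator seeds.

What the generator does **not** emulate: read-level data behind the
summaries (levels are drawn directly, not from binomial sampling of
reads), spatial autocorrelation along the genome, age-dependent coverage
drift, nuclear background sites, or any dependence between reliability and
the emitted level.  Passing tests therefore demonstrate the correctness of
the pipeline's logic and the recoverability of planted signal under the
stated noise — not clock accuracy on real sequencing runs.

## Problem sizes and determinism

The exhaustive grid on a 6 x 500 design (101 alphas x 16 schemes x 10
iterations x 3 folds) runs in a few minutes on one CPU; the recovery
benchmark uses the documented reduced grid (alpha step 0.05, B = 5) over
20 generator seeds.  All randomness — generator draws, fold permutations —
flows from explicit seeds, and identical inputs plus base seed give
byte-identical candidate tables and clock files.

## Known limitations

* With six samples, CV-MAE is a noisy estimate; the B re-randomizations
  quantify but cannot remove fold-assignment sensitivity.
* The aging-site filter is a literal-inequality screen; at higher coverage
  or more samples a statistical DMR test would be preferable.
* The bootstrap-as-fold-re-randomization reading and the pooled (rather
  than per-fold-averaged) CV-MAE are documented choices with config
  switches where alternatives exist.
* Group structure treats pasted labels as flat groups; no overlap or
  hierarchy between groups is modeled.
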