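# Methods

This note documents the generative model behind the synthetic cohorts, the
estimators and tests the pipeline applies, the numerical choices that matter,
and what the passing test suite does and does not establish about real data.

## Why within-cell-line mutations

On the male non-pseudoautosomal X and Y, a germline allele is carried by
every cell; a site with both reference and alternative reads in one cell
line's sequencing ("within-cell-line mutation") implies an alternative allele
in a subset of cells, i.e. a somatic or in-vitro origin. Counts of such
mutations are therefore untouched by the nongenetic confounders (paternal
age, demography, culture history differences between populations) that
complicate the interpretation of phylogenetic branch lengths. Dividing the
Y-chromosome K2P distance of these mutations by the X-chromosome distance
cancels sample-level factors common to both chromosomes — donor age, culture
time, depth — leaving a Y-specific relative somatic mutation rate `R`.

## Synthetic cohort model

`CohortConfig` fully parameterizes a cohort; `simulate_cohort` is a
deterministic function of `master_seed`, which spawns named substreams
(tree, germline, somatic, timing, depth, errors) so stages can be
re-rendered independently.

**Tree.** Each haplogroup's samples coalesce under a Kingman process
(relative scale `within_haplogroup_fraction`, default 0.5); haplogroup
ancestors then coalesce at deeper times, which forces haplogroup monophyly
and ultrametricity. An outgroup sample ("OUT") diverges at
`outgroup_depth_factor` (default 1.4) times the ingroup root height; because
it is sampled at the present, the full tree remains ultrametric and a
clock-simulated cohort really satisfies the clock null. Heights are rescaled
so the root sits at `tree_height` substitutions/site (default 0.01), or so
the expected number of germline mutations matches `target_variable_sites`
when set.

**Germline sequences.** `n_sites` (default 50,000) sites evolve site by site
under K2P (κ default 2) along the tree. A haplogroup's
`germline_rate_multiplier` scales every branch private to its clade,
including the stem. Biallelic variable columns become the truth alignment;
their Y positions are drawn with per-window probability ∝
(1 − `placement_coupling` × timing), the same coupling used for somatic
placement, so germline density also declines with earlier replication. The
defaults give a 6×20 cohort roughly 3–4k variable sites and terminal
branches of order ten mutations — the same order of information per terminal
branch as high-coverage Y resequencing panels.

**Somatic mutations.** Per sample, Poisson burdens with mean
`base_somatic_burden` (default 40) on X and `base_somatic_burden ×
somatic_multiplier_Y[h]` on Y; positions on Y drawn with the timing coupling
above; each mutation carried by a Beta(`cell_fraction_params`) fraction of
cells (default Beta(2, 4), mean 1/3 — a clonal-expansion-like,
low-fraction-skewed law; the real cell lines' clonal structure is unknown,
so this is an explicit modeling assumption, exposed in the config).
Alternative alleles are transitions with probability κ/(κ+2), matching the
germline process, so germline and somatic spectra agree by construction.

**Rendering.** Per-window Y depth ~ Poisson(`mean_depth` × (1 +
`timing_amplitude` × timing) × (1 + `gc_amplitude` × standardized GC)); the
GC track varies mostly window to window (fine-scale), unlike the
band-limited timing curve — deliberately so, since two equally smooth tracks
would be collinear by chance and GC correction would then remove timing
signal, which is a property of the simulation design rather than of real
data. Site depths are Poisson around the window expectation. At somatic
sites, alt reads ~ Binomial(depth, cell fraction); germline derived alleles
render at allele fraction ≈ 1 (minus a Binomial error loss); sequencing
errors inject alt reads at `seq_error_rate` per base per read (default 1e-4,
an effective post-filter miscall rate) at depth-weighted random positions. A
record enters the call table only when at least one alternative read was
sampled, so the only somatic loss mechanism is a zero draw. Reference bases
at arbitrary positions come from a position-hash, keeping REF consistent
across samples without storing a genome.

Callable lengths default to 2 Mb per chromosome with 10 kb windows (200
windows). These are deliberate desk-scale sizes: they preserve the
statistical structure (tens of mutations per sample, hundreds of windows)
at a fraction of real chromosome lengths.

## Detection

A call is accepted as a within-cell-line mutation iff it lies in the
callable region minus masks, depth ≥ 6, alt reads ≥ 3, and allele fraction
in [0.05, 0.8]. The three-read rule is the core criterion; the AF ceiling
separates partial-fraction somatic alleles from fixed germline alleles on a
haploid chromosome; the exact supplementary filter set of the motivating
analyses is not public, so the remaining thresholds are config-exposed
stand-ins. A cross-sample recurrence filter then removes sites accepted in
more than 2% of cohort samples *and* at least two samples (a site private to
one sample cannot be "recurrent"; without this qualifier the fraction rule
degenerates for cohorts under 50 samples). Every rejection carries an
enumerated reason.

## Rates and tests

K2P distances use the closed form with P, Q computed against each
chromosome's own callable length, which makes `R = d_Y/d_X`
length-corrected by construction. Samples with `d_X = 0` are excluded (not
pseudocounted — a ratio prior would bias low-burden samples) and counted.
Kruskal–Wallis (scipy, midranks + tie correction) compares `R` across
haplogroups with more than ten valid samples; the spread statistic is
`100 × (max median − min median)/min median`. p-values are reported raw;
with three headline tests no multiplicity correction is applied.

## Phylogeny

Topology: neighbor joining on pairwise K2P distances (deterministic
lowest-index tie-break, negative branch lengths clamped), rooted on the
designated outgroup. Branch lengths are then re-optimized by maximum
likelihood — NJ topology + ML lengths rather than a full ML topology search,
because the target quantities are branch lengths and rates, and topology at
haplogroup resolution is robust.

Likelihoods use Felsenstein pruning under K2P with per-pattern scaling.
Because alignments contain variable sites only, all model fits condition on
site variability (dividing each site likelihood by 1 − P(constant));
without this ascertainment correction the clock test is mis-specified and
grossly over-rejects. The raw, uncorrected likelihood is exposed for oracle
comparisons.

Optimization is coordinate ascent with cached upward/downward conditional
likelihoods, so one-dimensional branch updates cost O(patterns). The clock
model optimizes node heights the same way, plus a global height-scale line
search per sweep: the likelihood surface's softest direction rescales the
whole tree, and pure coordinate ascent converges too slowly along it —
slow enough to bias the LRT statistic upward by several log-units if
stopped early (convergence tolerance 1e-5 log-units, up to 200 sweeps).
The LRT statistic is 2(lnL_free − lnL_clock), df = n − 2 (2n − 3
identifiable free branch lengths vs n − 1 heights), κ profiled in both
models; if the free fit ever falls below the clock fit it is restarted from
the clock solution, so the statistic is non-negative by construction.

The clock test is calibrated **on one-sample-per-haplogroup subsamples**
(deep, well-resolved splits), which is also how the headline analysis is
run. On full cohort trees with many near-identical within-haplogroup
samples, NJ topology errors penalize the constrained model and inflate the
type-I error (~13% at 30 tips / 1,000 sites in our experiments, versus
nominal 5% on the true topology) — a topology-uncertainty artifact users
should be aware of when applying the LRT to dense trees.

Terminal branch rates use a RelTime-style recursion: at each internal node
the two descendant lineages' relative rates are proportional to the mean
node-to-tip path length within each subtree (normalized by their geometric
mean), and lineage rates propagate multiplicatively from the root. Lineage
depths are floored at 1e-3 of tree depth so a zero-length cherry cannot
send its sibling's rate to infinity. Rates are normalized to mean exactly 1
over retained samples; outliers are removed by a median-centered scaled-MAD
rule (5 MADs) — centered on the median, not on 1, because one extreme tip
drags the normalization mean and a deviation-from-1 rule then flags the
whole cohort — with removal capped at 20% of samples, after which the
remainder is renormalized. The exact outlier criterion of the motivating
analyses is unpublished; this one is a documented stand-in.

## Replication timing

Per sample: window depth / sample mean → mask windows beyond 3 scaled MADs
from the median → subtract a lowess fit on window GC (frac 0.3) → Gaussian
smoothing (SD 3 windows) → standardize to mean 0, variance 1. Higher value
= earlier replication (more copies in an unsynchronized proliferating
population). Samples with under 20 usable windows or zero variance are
flagged flat. The consensus is the per-window mean over non-flat samples,
masked where fewer than half contribute. Windows are ranked by consensus
timing into 25 equal-size quantile bins (equal counts stabilize per-bin
means); the trend is the least-squares slope across bin means, with a
window-level Spearman correlation alongside. Because both tracks are
autocorrelated along the chromosome, significance uses a circular-shift
permutation of the mutation track (default 1,000 shifts) rather than an
analytic p-value.

## Association

Per-haplogroup medians of `R` and of the normalized branch rate are joined
for haplogroups with more than ten samples and compared by Spearman
correlation; p is exact (full permutation enumeration) for n ≤ 9 haplogroups
and t-approximate otherwise.

## Problem sizes used by the tests and acceptance script

Chosen as the package's standard desk-scale configurations:

* clock-LRT calibration/power: 200 (resp. 50) cohorts of 6 haplogroups × 5
  samples, ~1,000 variable sites, LRT on the per-haplogroup subsample;
* multiplier recovery: 5 haplogroups × 30 samples at 30×, multipliers
  0.6–1.5, 300,000 simulated germline sites (~20k variable) so terminal
  branches carry ~20–30 mutations — comparable information per branch to
  real high-coverage Y panels;
* timing recovery: 50 samples × 200 windows at amplitude 0.3;
* null cleanliness: 50 cohorts of 6 × 12 with all multipliers 1.

## What passing tests do and do not show

The generator reproduces the *structure* of LCL cohort data — haploid
rendering, clonal fractions, depth fluctuation, error noise — but not its
full messiness: no mapping artifacts beyond a recurrence model, no batch
effects between cohorts, no read-level errors correlated along reads, no
reference bias, and GC bias that is generated orthogonal to timing.
Parameter-recovery results therefore demonstrate correctness of the
estimators under the stated model, not robustness to every real-data
artifact. Absolute rate calibration (per year or per generation) is out of
scope: `R` is strictly relative, and branch rates are normalized to mean 1.

## Degenerate inputs and tie-breaks

NJ Q-matrix ties join the lowest-index pair; quantile-bin ties follow the
stable argsort order; all-identical Kruskal–Wallis groups return H = 0;
zero-depth calls are rejected as `no_coverage`, never raised; a saturated
K2P distance raises a dedicated error; `d_X = 0` samples are flagged, not
dropped silently; flat depth profiles are flagged per sample rather than
failing the cohort.
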