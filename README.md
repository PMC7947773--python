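# lineage-clockwork

Analysis pipeline for **Y-chromosome haplogroup mutation-rate heterogeneity**,
built around within-cell-line mutations in male lymphoblastoid cell lines
(LCLs).

Dating patrilineal events from Y-chromosome sequence assumes one mutation rate
for every haplogroup, yet Y phylogenies show strong terminal-branch-length
heterogeneity between haplogroups. Branch lengths confound mutation rate with
nongenetic factors (paternal age, demography), so this package implements a
confounder-free proxy: mutations that are *polymorphic within a single cell
line* on the male non-pseudoautosomal X and Y. These chromosomes are haploid
in males, so a true germline allele is fixed — a site with both reference and
alternative reads arose somatically or in vitro, after any influence of
paternal age or culture history that would differ between haplogroups.

The package is aimed at population geneticists who want to (re)run this style
of analysis end to end, and at methodologists who want a fully simulated
test-bed in which every downstream statistic has a known generative truth.

## The quantities it computes

For sample *i*, within-cell-line mutation counts on each chromosome are
converted to Kimura two-parameter (K2P) distances,

```
d = -1/2 · ln[(1 - 2P - Q) · sqrt(1 - 2Q)] ,
```

with `P` and `Q` the transition and transversion proportions per callable
site, and the **relative Y somatic mutation rate** is

```
R_i = d_Y(i) / d_X(i) .
```

The X-chromosome denominator absorbs everything Y-unspecific (donor age,
culture time, coverage). The pipeline then:

* tests `R` for interhaplogroup variation (Kruskal–Wallis on midranks) and
  reports the percent spread between extreme haplogroup medians;
* builds the Y phylogeny (neighbor joining on K2P distances, outgroup-rooted,
  branch lengths re-optimized by maximum likelihood under K2P with a
  variable-sites ascertainment correction), runs the **molecular-clock
  likelihood-ratio test** (free vs ultrametric branch lengths, 2ΔlnL ~ χ²
  with n − 2 df, κ profiled) on a one-sample-per-haplogroup subsample, and
  computes **RelTime-style normalized terminal branch rates** (mean 1 over
  retained samples);
* infers **Y replication timing** per cell line from windowed read-depth
  fluctuation (normalize → MAD outlier mask → lowess GC correction →
  Gaussian smoothing → standardize; higher = earlier), averages profiles into
  a consensus, and relates timing to mutation density through 25 equal-size
  timing bins with a circular-shift permutation test;
* correlates per-haplogroup median `R` with median branch rate (Spearman,
  exact p for n ≤ 9).

A first-class synthetic-data module generates cohorts with
haplogroup-monophyletic coalescent trees, per-clade germline rate
multipliers, Beta-distributed somatic cell fractions, a latent
replication-timing curve that modulates depth, and binomial allele-depth
rendering with sequencing error — so every statistic above can be checked
against its generative truth.

## Worked example

```python
import lineage_clockwork as lc
from lineage_clockwork.report import run_pipeline

mult = (0.6, 0.8, 1.0, 1.2, 1.5)          # per-haplogroup rate multipliers
cfg = lc.CohortConfig(
    n_haplogroups=5, samples_per_haplogroup=15,
    germline_rate_multiplier=mult, somatic_multiplier_y=mult,
    n_sites=100_000, master_seed=7,
)
result = run_pipeline(cfg, min_samples=11)
print(result.rate_test.summary())
print(f"median spread: {result.spread_percent:.1f}%")
print(result.lrt.summary())
```

prints

```
Kruskal-Wallis test of R across haplogroups
  H = 52.3093  df = 4  P = 1.189e-10
  per-haplogroup medians:
    H01: median R = 0.5667 (n = 15)
    H02: median R = 0.7368 (n = 15)
    H03: median R = 1.0930 (n = 15)
    H04: median R = 1.1163 (n = 15)
    H05: median R = 1.6098 (n = 15)
median spread: 184.1%

Molecular clock likelihood-ratio test (K2P)
  tips                6
  lnL (free)          -18722.6213   kappa = 2.052
  lnL (clock)         -18847.5597   kappa = 2.049
  2*dlnL              249.8767
  df                  4
  P (chi-square)      6.920e-53
```

The per-haplogroup medians of `R` track the simulated multipliers
(0.6 … 1.5), the Kruskal–Wallis test rejects homogeneity, and the clock test
rejects rate homogeneity on the subsampled tree. In the same run the
rate-vs-branch-rate Spearman correlation is ρ = 1.00 (P = 0.017) and the
within-cell-line mutation density declines with earlier replication timing
(negative bin-level slope), mirroring the qualitative structure of the real
cohort analyses at desk scale.

## Command line

```bash
lineage-clockwork simulate --seed 7 --out cohort/       # VCFs, BEDs, truth tables
lineage-clockwork detect --vcf-dir cohort/vcf \
    --callable cohort/callable_Y.bed --callable cohort/callable_X.bed \
    --samples cohort/samples.tsv --out wcl.tsv
lineage-clockwork rate --wcl wcl.tsv --callable-y cohort/callable_Y.bed \
    --callable-x cohort/callable_X.bed --samples cohort/samples.tsv --out rates.tsv
lineage-clockwork reptime --depth cohort/depth_Y.tsv \
    --windows cohort/windows_Y.tsv --mutations wcl.tsv --out rt
lineage-clockwork run --seed 7 --out results/           # full pipeline
```

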