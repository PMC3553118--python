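# Methods

## Problem and model

`cnatai` quantifies the genomic instability of tumour samples from
probe-level DNA copy-number data (array log2 tumour/normal ratios) and
relates that burden to clinical outcome. The pipeline has four statistical
stages.

### Piecewise-constant segmentation (PCF)

Each sample's log2 ratios are segmented chromosome by chromosome by exact
penalized least squares. For an ordered series $y_1,\dots,y_n$ a
segmentation $S$ into contiguous segments has cost

$$\mathrm{cost}(S) = \sum_{\text{segments } I \in S}\sum_{i \in I}
(y_i - \bar y_I)^2 \;+\; \gamma\,(|S| - 1),$$

and the fit is the global minimizer subject to each segment containing at
least `min_probes_per_segment` probes (default 3; a chromosome with fewer
probes than that becomes a single segment rather than being discarded). The
minimizer is found by dynamic programming over the last breakpoint with
prefix sums — exact $O(n^2)$, no pruning heuristics, which is cheap at
array scale (≤ ~5,000 probes per chromosome). Ties in cost are broken
toward fewer segments, then toward the earlier breakpoint, so output is
deterministic. Correctness is pinned by an exhaustive-enumeration oracle on
short series in the test suite.

The penalty $\gamma$ is charged per breakpoint and applies to the series
*after* dividing by a robust per-sample noise estimate, the median absolute
consecutive difference rescaled by $\sqrt2\,\Phi^{-1}(3/4)$ (differences
taken within chromosomes only). Noise-normalizing lets one default,
$\gamma = 40$, serve platforms with different noise levels; both the value
and the normalization are exposed in `PipelineConfig`. Segment means are
always reported on the original scale. An optional per-sample median
centering (default on) makes the log2 baseline "diploid = 0" explicit.

Segment bp boundaries: a segment initially spans first-to-last member
probe; adjacent segments are then extended to meet at the midpoint between
flanking probes, so chromosome coverage is gap-free and the total covered
span does not jitter with breakpoint placement. Spans are inclusive bp
counts (`end − start + 1`). Missing probe values are dropped per sample and
chromosome before fitting (the fit needs a gap-free ordered series); a
chromosome with no finite probes is omitted with a warning.

### Total Aberration Index

For one sample with segments $i = 1..k$, spans $L_i$ (bp) and segment mean
log2 ratios $\bar y_i$,

$$\mathrm{TAI} = \frac{\sum_i L_i\,|\bar y_i|}{\sum_i L_i}.$$

TAI is the genome-length-weighted average absolute deviation from the
diploid state: 0 for a flat profile, bounded above by $\max_i |\bar y_i|$.
The denominator is the span covered by the platform's segmented probes, not
a fixed genome length; the two normalisations are monotone-equivalent
within a platform, so the median split and every downstream statistic are
unaffected, but absolute TAI values are not comparable across platforms.
Chromosome X (encoded 23) contributes like an autosome; Y is never
modelled.

Cohorts are dichotomised at the median TAI (midpoint of central order
statistics for even n); samples exactly at the median go to the low group,
flagged in the log when ties occur. For continuous modelling TAI enters as
its cohort z-score (SD with $n-1$), so Cox hazard ratios read "per 1 SD
increase of TAI".

### Frequency and grid tracks

Per-probe gain/loss states are called on segment means with strict
thresholds (defaults ±0.1 log2, configurable; published cohort tables never
depend on the default). Cohort frequency tracks count the fraction of
samples gained/lost at each probe, excluding samples whose segmentation
does not cover the probe. For cross-cohort comparison, loci are placed
every `grid_spacing_bp` (default 1 Mb) from each chromosome's first covered
bp and the cohort mean segmented log2 is reported per locus; the locus
count is platform-dependent by design.

### Group and survival statistics

Two conventions are fixed because together they reproduce the published
serous-ovarian cohort test battery to three decimals (verified in the test
suite against the printed contingency counts):

* **Fisher's exact test**, two-sided, as the sum of point hypergeometric
  probabilities ≤ the observed one (relative slack 1e-7 to absorb
  rounding); degenerate margins give p = 1 with a warning.
* **Mann–Whitney on grouped ordinal codes** with midranks, tie-corrected
  variance
  $\sigma^2 = \frac{n_1 n_2}{12}\bigl[(N+1) - \sum_t (t^3-t)/(N(N-1))\bigr]$,
  0.5 continuity correction, and the normal approximation.

No multiple-testing adjustment is applied, matching conventional
clinicopathological tables. Survival uses the Kaplan–Meier product-limit
estimator with log-log median CIs, the standard two-group log-rank test,
and Cox proportional-hazards regression (Efron tie handling — month-
resolution times tie heavily; Wald CIs and p-values). Stage and grade enter
multivariate models as numeric ordinals. The statistical primitives behind
these stages are scipy and lifelines; the test suite cross-checks them
against independent oracles (exact-rational hypergeometric enumeration,
exhaustive U-statistic permutation, a hand-written partial-likelihood grid
search, and direct O/E/V log-rank computation).

## Synthetic cohort generator

The generator emulates an array study of advanced serous ovarian cancer
with known truth at every level.

* **Genome / probes**: 23 chromosomes (X = 23) with hg-like length
  proportions scaled to 3.1 Gb; default 20,000 probes allocated
  proportionally to chromosome length at uniform-random positions.
* **Aberrations**: per sample, K ~ Poisson(25) non-overlapping intervals
  (rejection sampling with a retry cap; a sample that cannot be placed is
  regenerated with a warning), lengths log-uniform on 2–200 Mb, amplitudes
  drawn from discrete log2 levels {±0.58, ±1.0, −3.3} with probabilities
  {0.3, 0.3, 0.15, 0.2, 0.05} — single-copy gains/losses dominate, with
  occasional two-copy gains and rare homozygous deletions. These rates give
  roughly a third of the genome altered per sample and true TAI values of
  order 0.03–0.2, the burden regime of heavily rearranged high-grade serous
  tumours.
* **Purity dilution**: each sample draws a tumour-cell fraction
  tf ~ Uniform(0.2, 0.9) and every aberrant level is attenuated as
  `log2(tf·2^level + (1 − tf))`, reproducing the compressed ratios of
  impure specimens. True TAI is computed from the clean diluted segment
  profile by the same span-weighted formula the estimator uses.
* **Noise**: i.i.d. Gaussian per probe, default SD 0.15 (typical array
  noise after preprocessing).
* **Outcomes**: overall survival is exponential with rate
  `baseline_hazard · exp(beta_tai · z)`, z the cohort z-score of true TAI;
  defaults `baseline_hazard = 1/40` per month (median OS ≈ 28 months
  untreated by covariates) and `beta_tai = −0.5` (higher burden →
  longer survival, hazard ratio ≈ 0.61 per SD). Censoring is an independent
  Exponential(0.01/month) time; PFS is OS scaled by Uniform(0.3, 1) under
  the same censoring time — adequate for exercising the survival stage's
  plumbing, not a semi-competing-risks model. Platinum sensitivity is
  Bernoulli(logistic(0.8·z)); age ~ Normal(58, 11) truncated to 23–81,
  stage {III: 0.8, IV: 0.2}, grade {1: 0.05, 2: 0.3, 3: 0.65}.

What the generator does **not** emulate: allele-specific copy number,
whole-genome duplication/ploidy shifts, wavy GC artefacts, batch effects,
probe-specific variances, or informative censoring. Passing calibration
tests therefore shows the pipeline recovers truth under an idealised but
structurally faithful data model, not that it is robust to every real-array
artefact.

## Numerical choices and degenerate inputs

* DP cost ties are resolved exactly (float equality) toward fewer segments;
  the constructed-tie case (penalty exactly equal to the SSE saving) is
  exercised in tests.
* Segment means must equal member-probe means to 1e-9; TAI of a clean
  profile matches the truth formula to 1e-9.
* Zero TAI variance makes z-scores an error; an all-identical cohort median
  split labels everything "low" with a warning.
* Fisher with a zero margin returns p = 1 with a warning; Mann–Whitney with
  a single pooled level likewise.
* Cox fits require ≥ 2 events and non-constant covariates; lifelines
  convergence failures (e.g. monotone likelihood under separation) surface
  as `ValueError` advising group collapse.
* Probe tables with unsorted positions are sorted with a warning; duplicate
  probe ids and negative survival times are hard errors.

## Problem sizes used in the checks

The oracle comparisons run on 50 random series of length ≤ 14
(segmentation), 200 random 2×2 tables with total ≤ 30 (Fisher), and 30
untied two-group samples with group sizes 5–7 (Mann–Whitney; for groups of
3–4 the normal approximation itself deviates from the exact permutation
distribution by up to 0.037, so agreement to 0.02 is only a meaningful
implementation check from group size 5). Calibration studies use 100
cohorts of n = 500 for Cox per-SD recovery, 500 cohorts of n = 80 for null
log-rank uniformity, and one cohort of 100 samples × 20,000 probes for
TAI fidelity (Pearson r vs truth).

## Known limitations

* Absolute TAI values depend on platform coverage and on γ; only
  within-cohort contrasts (median split, per-SD hazard ratios) are
  meaningful deliverables.
* The exact DP is quadratic per chromosome; for multi-million-probe
  sequencing profiles a pruned PCF would be needed.
* PFS generation is a scaled copy of OS, so joint PFS/OS dependence is
  stronger than in real cohorts.
* Stage/grade ordinal coding in multivariate Cox is a convention; indicator
  coding would change coefficient interpretation.
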