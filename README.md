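# cnatai

Copy-number aberration burden and outcome analysis for tumour cohorts:
exact piecewise-constant segmentation of probe-level log2 ratios, the
**Total Aberration Index** (TAI) as a per-sample genomic-instability score,
and the statistical battery that relates TAI to clinicopathological
variables and survival.

## Who this is for

Researchers with probe-level DNA copy-number profiles (aCGH or SNP-array
log2 tumour/normal ratios) and clinical follow-up who want a reproducible
path from raw probe tables to: per-sample aberration burden, cohort
gain/loss landscapes, group comparisons (Fisher exact, tie-corrected
Mann–Whitney), and survival analysis (Kaplan–Meier, log-rank, Cox per SD of
TAI). A synthetic-cohort generator with known truth makes every stage
testable without any array download.

## The model in brief

Each sample's log2 ratios are segmented per chromosome by exact penalized
least squares: the segmentation $S$ minimises

$$\sum_{I \in S}\sum_{i \in I}(y_i-\bar y_I)^2 + \gamma(|S|-1),$$

subject to ≥ 3 probes per segment, solved exactly by dynamic programming.
With segment spans $L_i$ (bp) and means $\bar y_i$, the Total Aberration
Index is the length-weighted mean absolute deviation from diploid,

$$\mathrm{TAI}=\frac{\sum_i L_i\,|\bar y_i|}{\sum_i L_i},$$

i.e. a numeric measure of the abundance *and genomic size* of copy-number
changes. Cohorts are split at the median TAI for group tests and
Kaplan–Meier/log-rank comparisons; Cox models use TAI as a continuous
z-scored covariate, so hazard ratios read "per 1 SD increase of TAI". See
`docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a 30-sample cohort (20,000 probes, purity-diluted aberrations,
survival linked to true TAI), then run the full pipeline:

```sh
cnatai simulate --n-samples 30 --seed 1 --out sim/
cnatai run sim/probes.tsv sim/clinical.csv --out results/
```

which prints

```
wrote synthetic cohort (n=30, 20000 probes) to sim
pipeline artifacts -> results/
```

and leaves under `results/`: `segments.tsv` (BED-like per-sample segments),
`tai.tsv`, `frequency.tsv`, `grid.tsv`, `table1.tsv` + `table1_pvalues.json`,
`table2.tsv`, and `manifest.json`. The TAI table starts:

```
sample_id  tai                   group  z
S0000      0.15873847680269804   high    0.69806409825205462
S0001      0.023644325397383131  low    -1.5489433822205216
S0002      0.11892522903525554   high    0.035854338430936293
```

`tai` is the length-weighted mean |log2| deviation (0 = flat diploid
profile; this cohort spans 0.018–0.25), `group` the cohort median split,
`z` the per-SD scale used by the Cox models. `table2.tsv` holds, per
endpoint (PFS, OS), the median-split log-rank test and univariate +
multivariate Cox hazard ratios with 95% CIs; with the generator's default
protective effect (log-hazard −0.5 per SD of true TAI) this run's
univariate PFS row reads

```
endpoint  analysis  term  estimate  ci_low  ci_high  p
pfs       cox_uni   z     0.481     0.278   0.832    0.0088
```

i.e. an estimated hazard ratio of 0.48 per SD of TAI — higher aberration
burden, lower progression hazard, as simulated.

Every stage is also available separately (`segment`, `tai`, `freq`,
`stats`, `survival`) and as library functions (`cnatai.pcf_segment`,
`cnatai.total_aberration_index`, `cnatai.build_table2`, ...).

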