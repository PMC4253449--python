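# Methods

## The procedure

`cohortvote` implements a vote-counting meta-analysis for finding genes
upregulated in recurrent/metastatic ("secondary") tumors relative to primary
tumors across many independent expression cohorts profiled on heterogeneous
platforms.

For each cohort *c* and gene *g* with linear-scale expression values, the
ranking statistic is the **median fold change**

&nbsp;&nbsp;&nbsp;&nbsp;FC<sub>c</sub>(g) = median<sub>secondary</sub>(x) / median<sub>primary</sub>(x),

the ratio of group medians on the linear scale.  This is the only sensible
reading of "median fold change" for unpaired groups (a per-pair ratio is
undefined without sample pairing) and is robust to outlying arrays.  Genes
with FC > 1 are ranked by FC descending, ties broken by gene symbol ascending
so lists are reproducible across platforms and runs; the top *N* = 1000 form
the cohort's upregulated list.

The integration statistic is the **duplication count**: the number of
cohorts whose top-N list contains the gene, counted against all *C* cohorts
(a gene not measured by a platform simply cannot vote there; the number of
measuring cohorts is reported alongside so coverage gaps stay visible).
Genes with duplication ≥ 5 of 8 — strictly "more than four" cohorts — form
the integrated signature, ranked by duplication count descending, then by
the median of the gene's per-cohort FCs over the cohorts where it made the
list, then by symbol.

### Null model for duplication counts

Under the null that each cohort's top-N list is an independent uniform
N-subset of its measured universe of G genes, a fixed gene's duplication
count is Binomial(C, N/G); when universes differ in size the tail is
Poisson-binomial over per-cohort membership probabilities N/G<sub>c</sub>,
computed by direct convolution (C ≤ 32 terms).  Per-gene p-values use as
many trials as cohorts that measured the gene; Benjamini–Hochberg step-up
converts them to q-values.  Because real list membership is weakly
negatively dependent across genes (lists have fixed size), the binomial tail
is slightly conservative per gene.  An empirical alternative permutes
primary/secondary labels **within each cohort** — the exchangeability unit
of the design, preserving per-cohort group sizes — and re-runs the whole
ranking pipeline per replicate (default B = 200, a lower bound for stable
tail estimates rather than a recommendation).

With the default design (C = 8, N = 1000, G = 10,000, threshold 5), the
null expectation is G·P(Bin(8, 0.1) ≥ 5) ≈ 4.3 genes passing the filter by
chance.  This number is worth keeping in mind when reading any signature of
tens of genes produced by this procedure.

### Clinical validation

A candidate marker is validated in annotated cohorts two ways:

- **Survival**: expression is dichotomized at the median (ties to "low";
  numeric override available), Kaplan–Meier product-limit curves are
  estimated per group, and the two-sided two-group log-rank test (1-df
  chi-square; exact label permutation available for small n) compares them.
  At tied event/censoring times, censored subjects remain in the risk set —
  the standard convention, matching `R survival::survfit` and lifelines.
- **Ordinal trend**: association of expression with an ordered clinical
  grade (e.g. a Gleason-derived category) uses the Jonckheere–Terpstra
  statistic — the sum of pairwise Mann–Whitney counts over ordered level
  pairs, ties mid-counted at 0.5 — with a tie-corrected normal approximation
  and one-sided (increasing) alternative, since the scientific claim is
  directional.  Full enumeration of the permutation null is available for
  n ≤ 12.

KM, log-rank and Jonckheere–Terpstra are implemented in-package;
`lifelines` is used in the test suite only, as an independent cross-check.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth, so every stage is testable at desk scale:

- *C* independent cohorts with the case counts of the eight published
  discovery series (20, 19, 52, 171, 167, 164, 104, 79) and a configurable
  secondary fraction (default 0.35 — secondary disease is the minority class
  in such series).
- Per-gene baselines uniform on log2 ∈ [4, 10] (the usual intensity range of
  normalized arrays) drawn once for the shared 10,000-gene universe; each
  cohort measures an independent Bernoulli(coverage) subset, so pairwise
  overlaps behave hypergeometrically.  The default coverage is 1.0: since
  duplication is counted against all cohorts, the default study conditions
  (penetrance 0.8, threshold 5 of 8) are only coherent when a planted gene
  can in principle appear in every list; partial coverage is a first-class
  option used when platform heterogeneity itself is under study.
- Expression is log-normal: 2^(baseline + effect·[secondary] + noise) with
  additive Gaussian log2 noise (default SD 0.6, a typical residual spread
  for between-sample microarray variation).  Values are strictly positive;
  there are no missing values, batch effects, probe-level structure, or
  two-channel ratio artifacts — so passing tests demonstrate correctness of
  the statistics, not robustness to those real-data pathologies.
- 50 planted genes carry multiplicative effects drawn uniformly from
  [2, 4] per (cohort, gene) pair, each penetrant with probability 0.8 —
  so duplication counts below C arise naturally, as they did for the genes
  that motivated this design.
- Seeding: one root seed spawns a per-cohort seed sequence (cohort *i* uses
  child *i* + 1), so adding cohorts never perturbs earlier ones and
  identical configs are bit-identical.
- Linked clinical cohorts (default n = 400, the scale of the larger
  validation series): a standard-normal latent marker level z per sample
  gives log-normal marker expression 2^(7 + z); ordinal grade and stage in
  {1..4} come from a proportional-odds draw with latent shift
  marker_effect·z and logistic-quartile cutpoints; survival is exponential
  with baseline mean 24 months and hazard multiplied by exp(marker_effect·z),
  censored by an independent exponential with mean 48 months.  With
  marker_effect = 0 the marker is independent of everything — the
  calibration null.

## Numerical and design choices

- **Probe collapsing**: per symbol, keep the probe with the greatest median
  intensity across samples (max-median), ties broken by probe id; symbols
  are upper-cased before cross-cohort matching.  Max-median is a common
  summarization convention; alternatives (mean, first) change real-data
  results but none is canonical.
- **log2/linear auto-detection**: a matrix whose maximum is below 30 is
  treated as log2 and exponentiated (log2 intensities rarely exceed ~16,
  linear maxima rarely fall below ~30); the decision is logged and can be
  forced either way.
- **Zero medians**: with the default pseudocount of 0, a gene with a zero
  group median has no defined ratio and is excluded (logged); configuring a
  positive pseudocount ε switches to (m₂+ε)/(m₁+ε).
- **Missing values**: matrix rows containing missing cells are dropped on
  read with a logged count; no imputation.
- **Determinism**: all floats are written at 6 significant digits with fixed
  separators, and every source of randomness descends from one seed, so a
  run directory can be reproduced byte for byte from its resolved config.

## Problem sizes

The standard experiment battery runs on one CPU in about a minute: 20 seeded
replicates of the full default discovery design for recovery/precision; 10⁶
Monte-Carlo replicates for the binomial tail check; a 200-shuffle
permutation null on pure-noise cohorts (8 cohorts × 14 samples, G = 2000,
N = 200 — smaller than the discovery design so the per-replicate re-ranking
stays cheap, with N/G = 0.1 preserved); 500 null replicates (n = 80) for
log-rank calibration and 200 replicates (n = 400) for power.

## Known limitations

- Vote counting ignores the magnitude of evidence within each cohort beyond
  list membership; a gene at rank 1 and rank 1000 vote equally.
- The binomial null assumes independent cohorts and uniform list draws; it
  has no notion of inter-gene correlation, and the three chips derived from
  one patient series in the motivating design violate independence in ways
  the generator does not model.
- Under the default conditions the null expectation of ~4.3 false genes
  against ~48 recovered planted genes caps the signature's precision near
  93%; raising the duplication threshold or shrinking N trades recall for
  precision.
- Real-data reproduction additionally depends on normalization and probe
  summarization choices upstream of this pipeline, which published analyses
  rarely state.
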