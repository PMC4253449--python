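# cohortvote

Cross-cohort **vote-counting meta-analysis** of upregulated genes, for
transcriptomics studies that compare primary versus recurrent/metastatic
("secondary") tumors across several independent expression cohorts profiled
on heterogeneous microarray platforms.

Integrating such cohorts at the level of expression values is hopeless —
different platforms, gene universes and normalizations.  The approach
implemented here integrates at the level of *ranked lists* instead:

1. **Per cohort**: rank genes by median fold change
   FC(g) = median(secondary) / median(primary) on the linear scale, and keep
   the top *N* = 1000 upregulated genes (FC > 1).
2. **Across cohorts**: count each gene's *duplication times* — the number of
   cohorts whose top-N list contains it — and retain genes found in more
   than four of the eight cohorts (duplication ≥ 5).
3. **Calibrate**: under a null of independent uniform top-N lists, a gene's
   duplication count is Binomial(C, N/G); the package attaches exact tail
   p-values (Poisson-binomial when universes differ), BH q-values, and an
   empirical within-cohort label-permutation null.
4. **Validate**: a candidate marker is checked in annotated cohorts by
   Kaplan–Meier / log-rank survival comparison of median-split expression
   groups and a Jonckheere–Terpstra ordinal trend test against clinical
   grade (both implemented from first principles).

A seeded synthetic multi-cohort generator with planted upregulated genes
provides ground truth, so the whole pipeline is testable at desk scale.
See `docs/methods.md` for models, assumptions and parameter rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; small outputs land in `results/`, bulky generated matrices in
`scratch/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_rank_and_integrate.py
python analysis/03_calibrate_null.py
python analysis/04_validate_marker.py
```

which prints, among other lines:

```text
wrote 8 cohorts to .../scratch/cohorts
  sample counts: [20, 19, 52, 171, 167, 164, 104, 79]
  planted genes: 50, marker gene: G04097
signature: 51 genes in > 4 of 8 cohorts -> .../results/signature.tsv
  top gene G07851: duplication 8/8, median FC 3.90, q = 7.29e-08
  recovery: 48/50 planted genes; precision 94.1%
expected null genes at duplication >= 5 (C=8, N=1000, G=10000): 4.32
  log-rank: chi2 = 137.1, p = 1.13e-31
  trend (grade): J = 44494, one-sided p = 1.74e-31
```

Reading: of 50 truly upregulated genes planted across 8 cohorts (fold
change 2–4, 80% penetrance), 48 survive the more-than-four-cohorts filter;
the top-ranked gene appears in all 8 lists with a median fold change of
3.9.  The binomial null says ~4.3 genes reach the filter by chance alone —
which is exactly the handful of false positives in the 51-gene signature.
In the linked 400-sample clinical cohort, high marker expression is strongly
associated with shorter survival and with higher ordinal grade.

The same stages are available as a CLI (`cohortvote simulate / de /
integrate / calibrate / validate / run-all / summarize`) and as library
functions (`cohortvote.median_fold_change`, `count_duplication`,
`binom_tail`, `logrank_test`, ...).

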