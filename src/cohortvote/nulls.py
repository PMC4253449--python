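"""Null models for cross-cohort duplication counts.

Under the null, each cohort's top-N list is an independent uniform N-subset
of its measured universe, so a fixed gene's membership in one cohort's list
is Bernoulli(N/G).  Its duplication count across C cohorts is then
Binomial(C, N/G) — or Poisson-binomial when cohorts measure universes of
different sizes.  An empirical alternative shuffles group labels within each
cohort and re-runs the full ranking pipeline.  Benjamini–Hochberg adjustment
turns per-gene tail probabilities into q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import median_fold_change, select_top_n, top_n_set
from .integration import count_duplication
from .io import ExpressionCohort

__all__ = [
    "binom_tail",
    "poisson_binomial_tail",
    "expected_count",
    "bh_adjust",
    "calibrate_signature",
    "PermutationNull",
    "permutation_null",
]


def binom_tail(C: int, N: int, G: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(C, N/G).

    The probability that a gene lands in at least ``k`` of ``C`` independent
    uniform top-``N`` lists drawn from a universe of ``G`` genes.  Stable for
    membership probabilities as small as 1e-6 (scipy's regularized incomplete
    beta under the hood).
    """
    if not 1 <= N <= G:
        raise ValueError("require 1 <= N <= G")
    if C < 1:
        raise ValueError("C must be a positive count")
    if not 0 <= k <= C:
        raise ValueError("require 0 <= k <= C")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, C, N / G))


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """Upper tail P(X >= k) of a sum of independent Bernoulli(p_c) draws.

    Used when cohorts have different universe sizes, hence different
    membership probabilities.  Computed by direct convolution over the
    cohorts (C is small, typically <= 32).
    """
    p = np.asarray(probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 <= k <= len(p):
        raise ValueError("require 0 <= k <= number of cohorts")
    pmf = np.array([1.0])
    for pc in p:
        pmf = np.convolve(pmf, [1.0 - pc, pc])
    return float(pmf[k:].sum())


def expected_count(C: int, N: int, G: int, k: int) -> float:
    """Expected number of universe genes reaching duplication >= k by chance."""
    return G * binom_tail(C, N, G, k)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def calibrate_signature(
    signature: pd.DataFrame,
    top_n: int,
    universe_sizes: int | Mapping[str, int],
    n_cohorts: int | None = None,
) -> pd.DataFrame:
    """Fill the ``p_binom`` and ``q_bh`` columns of an integrated signature.

    Each gene's null duplication count uses as many Bernoulli trials as
    cohorts that measured it (its ``cohorts_measured``).  With a single
    ``universe_sizes`` integer all trials share p = top_n/G; with a mapping of
    per-cohort sizes the tail is Poisson-binomial over the per-cohort
    membership probabilities (the gene-to-cohort assignment being unknown at
    this stage, the ``cohorts_measured`` largest universes are used, a
    conservative choice).
    """
    sig = signature.copy()
    if sig.empty:
        return sig
    if isinstance(universe_sizes, Mapping):
        sizes = sorted(universe_sizes.values())
        probs_all = [min(1.0, top_n / g) for g in sizes]
        p_vals = []
        for m, k in zip(sig["cohorts_measured"], sig["duplication_times"]):
            probs = probs_all[-m:] if m else []
            p_vals.append(poisson_binomial_tail(probs, int(k)) if m else 1.0)
    else:
        G = int(universe_sizes)
        p_vals = [
            binom_tail(int(m), top_n, G, int(k)) if m else 1.0
            for m, k in zip(sig["cohorts_measured"], sig["duplication_times"])
        ]
    sig["p_binom"] = p_vals
    sig["q_bh"] = bh_adjust(p_vals)
    return sig


@dataclass
class PermutationNull:
    """Duplication-count histograms over label permutations.

    ``replicate_counts[b, k]`` is the number of genes with duplication count
    ``k`` in replicate ``b``; ``counts`` sums over replicates and
    ``mean_counts`` averages them.
    """

    replicate_counts: np.ndarray
    n_cohorts: int
    n_genes_total: int

    @property
    def B(self) -> int:
        return self.replicate_counts.shape[0]

    @property
    def counts(self) -> np.ndarray:
        return self.replicate_counts.sum(axis=0)

    @property
    def mean_counts(self) -> np.ndarray:
        return self.replicate_counts.mean(axis=0)

    def stderr_counts(self) -> np.ndarray:
        """Monte-Carlo standard error of ``mean_counts`` per bin."""
        return self.replicate_counts.std(axis=0, ddof=1) / np.sqrt(self.B)


def _duplication_histogram(
    cohorts: Sequence[ExpressionCohort], top_n: int
) -> np.ndarray:
    lists, universes = {}, {}
    for cohort in cohorts:
        table = select_top_n(median_fold_change(cohort), n=top_n)
        lists[cohort.cohort_id] = top_n_set(table)
        universes[cohort.cohort_id] = set(cohort.gene_ids)
    dup = count_duplication(lists, universes)["duplication_times"].to_numpy()
    return np.bincount(dup, minlength=len(cohorts) + 1)


def permutation_null(
    cohorts: Sequence[ExpressionCohort],
    top_n: int,
    B: int = 200,
    seed: int = 0,
    identity: bool = False,
) -> PermutationNull:
    """Empirical duplication-count null by within-cohort label shuffling.

    For each of ``B`` replicates the primary/secondary labels are permuted
    independently within every cohort (preserving group sizes — the
    exchangeability unit of the design), the median-fold-change ranking and
    top-``top_n`` selection are re-run, and the histogram of per-gene
    duplication counts over the union universe is accumulated.  Seeded and
    reproducible.  ``identity=True`` skips the shuffle (diagnostic: the
    histogram then equals the observed one, replicated B times).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    for cohort in cohorts:
        for label in ("primary", "secondary"):
            if len(cohort.samples_in_group(label)) < 2:
                raise ValueError(
                    f"{cohort.cohort_id}: need >= 2 samples per group to "
                    "permute labels meaningfully"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    replicate_counts = np.zeros((B, len(cohorts) + 1), dtype=np.int64)
    union: set[str] = set()
    for cohort in cohorts:
        union |= set(cohort.gene_ids)
    for b in range(B):
        replicate = []
        for cohort in cohorts:
            labels = cohort.group.to_numpy()
            if not identity:
                labels = rng.permutation(labels)
            replicate.append(
                ExpressionCohort(
                    cohort_id=cohort.cohort_id,
                    values=cohort.values,
                    group=pd.Series(labels, index=cohort.sample_ids),
                )
            )
        replicate_counts[b] = _duplication_histogram(replicate, top_n)
    return PermutationNull(
        replicate_counts=replicate_counts,
        n_cohorts=len(cohorts),
        n_genes_total=len(union),
    )
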