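"""Desk-scale calibration and recovery experiments.

These drive the package end to end under the default study conditions and
measure the quantities that characterize the method: planted-gene recovery
and precision of the integrated signature, agreement of the closed-form
binomial null with Monte-Carlo and permutation references, and power /
calibration of the survival and trend validation stages.  They are shared by
the analysis drivers, the acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import differential, integration, nulls, simulate, survival

__all__ = [
    "run_discovery",
    "recovery_experiment",
    "binom_tail_mc_check",
    "permutation_vs_binomial",
    "logrank_null_uniformity",
    "logrank_power",
    "trend_power",
]


def run_discovery(
    config: simulate.SimulationConfig,
    top_n: int = 1000,
    min_duplication: int = 5,
):
    """Generate cohorts and run ranking + integration; returns
    (signature, truth, universes)."""
    cohorts, truth = simulate.generate_multi_cohort(config)
    fc_tables, top_lists, universes = {}, {}, {}
    for cohort in cohorts:
        table = differential.select_top_n(
            differential.median_fold_change(cohort), n=top_n
        )
        fc_tables[cohort.cohort_id] = table
        top_lists[cohort.cohort_id] = differential.top_n_set(table)
        universes[cohort.cohort_id] = set(cohort.gene_ids)
    dup = integration.count_duplication(top_lists, universes)
    signature = integration.build_signature(
        dup, fc_tables, min_duplication=min_duplication
    )
    return signature, truth, universes


def recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    top_n: int = 1000,
    min_duplication: int = 5,
    **config_overrides,
) -> dict:
    """Planted-gene recovery and precision of the integrated signature.

    Runs the default discovery simulation (eight cohorts with the published
    case counts, G = 10,000, 50 planted genes with fold change in [2, 4] at
    penetrance 0.8) over ``n_seeds`` seeds and reports per-seed recovery
    (fraction of planted genes in the signature) and precision (fraction of
    signature genes that are planted), plus their medians.
    """
    recoveries, precisions, sizes, top_is_planted = [], [], [], []
    for s in range(n_seeds):
        config = simulate.SimulationConfig(
            seed=base_seed + s, **config_overrides
        )
        signature, truth, _ = run_discovery(
            config, top_n=top_n, min_duplication=min_duplication
        )
        found = set(signature["gene"])
        planted = set(truth.planted_genes)
        recoveries.append(len(found & planted) / len(planted))
        precisions.append(
            len(found & planted) / len(found) if found else np.nan
        )
        sizes.append(len(found))
        if len(signature):
            top_is_planted.append(signature.iloc[0]["gene"] in planted)
    return {
        "recovery": recoveries,
        "precision": precisions,
        "signature_size": sizes,
        "median_recovery": float(np.median(recoveries)),
        "median_precision": float(np.nanmedian(precisions)),
        "top_gene_planted_fraction": float(np.mean(top_is_planted)),
        "n_seeds": n_seeds,
    }


def binom_tail_mc_check(
    C: int = 8,
    N: int = 1000,
    G: int = 10_000,
    n_replicates: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Closed-form binomial tail vs Monte-Carlo duplication counts.

    Simulates ``n_replicates`` genes, each independently a member of each of
    ``C`` uniform top-``N`` lists with probability N/G, and compares the
    empirical tail frequency P(X >= k) with :func:`nulls.binom_tail` for
    every k, in units of the Monte-Carlo standard error.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.binomial(C, N / G, size=n_replicates)
    out = []
    for k in range(1, C + 1):
        exact = nulls.binom_tail(C, N, G, k)
        mc = float((draws >= k).mean())
        se = max(np.sqrt(exact * (1 - exact) / n_replicates), 1e-300)
        out.append({
            "k": k, "exact": exact, "mc": mc, "se": se,
            "z": (mc - exact) / se,
        })
    return {
        "per_k": out,
        "max_abs_z": float(max(abs(row["z"]) for row in out)),
        "n_replicates": n_replicates,
    }


def permutation_vs_binomial(
    n_cohorts: int = 8,
    cases_per_cohort: tuple[int, ...] = (14, 14, 14, 14, 14, 14, 14, 14),
    G: int = 2000,
    top_n: int = 200,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Permutation null vs Binomial(C, N/G) on pure-noise cohorts.

    Generates cohorts with no planted effects and full platform coverage,
    accumulates the permutation duplication histogram over ``B`` label
    shuffles, and compares each bin's mean count with its exact expectation
    ``G * pmf_Binomial(C, N/G)(k)`` in units of the empirical Monte-Carlo
    standard error across replicates.
    """
    config = simulate.SimulationConfig(
        n_cohorts=n_cohorts,
        cases_per_cohort=cases_per_cohort,
        gene_universe_size=G,
        platform_coverage=1.0,
        n_planted=0,
        seed=seed,
    )
    cohorts, _ = simulate.generate_multi_cohort(config)
    perm = nulls.permutation_null(cohorts, top_n=top_n, B=B, seed=seed + 1)
    pmf = stats.binom.pmf(np.arange(n_cohorts + 1), n_cohorts, top_n / G)
    expected = G * pmf
    se = perm.stderr_counts()
    # guard the far-tail bins where nothing is ever observed
    se = np.maximum(se, np.sqrt(np.maximum(expected, 1e-12) / B))
    z = (perm.mean_counts - expected) / se
    return {
        "mean_counts": perm.mean_counts.tolist(),
        "expected": expected.tolist(),
        "z": z.tolist(),
        "max_abs_z": float(np.max(np.abs(z))),
        "B": B,
    }


def _split_logrank_p(clinical) -> float:
    groups = survival.dichotomize(clinical["marker_expression"], "median")
    high = clinical[groups == "high"]
    low = clinical[groups == "low"]
    result = survival.logrank_test(
        (high["time"], high["event"]), (low["time"], low["event"])
    )
    return result.p_value


def logrank_null_uniformity(
    n_replicates: int = 500, n_samples: int = 80, seed: int = 0
) -> dict:
    """Log-rank p-value calibration under a null marker (effect 0).

    With ``marker_effect = 0`` the median-split groups share one survival
    law, so the log-rank p-values should be uniform; returns the
    Kolmogorov–Smirnov p against Uniform(0, 1) over the replicates.
    """
    config = simulate.SimulationConfig()
    p_values = [
        _split_logrank_p(
            simulate.generate_clinical(config, 0.0, seed=seed + r,
                                       n_samples=n_samples)
        )
        for r in range(n_replicates)
    ]
    ks = stats.kstest(p_values, "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "mean_p": float(np.mean(p_values)),
        "n_replicates": n_replicates,
    }


def logrank_power(
    marker_effect: float = 1.5,
    n_samples: int = 400,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the median-split log-rank test under a strong marker."""
    config = simulate.SimulationConfig()
    rejections = 0
    for r in range(n_replicates):
        clinical = simulate.generate_clinical(
            config, marker_effect, seed=seed + r, n_samples=n_samples
        )
        if _split_logrank_p(clinical) < alpha:
            rejections += 1
    return {
        "power": rejections / n_replicates,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "n_samples": n_samples,
    }


def trend_power(
    marker_effect: float = 1.5,
    n_samples: int = 400,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the ordinal trend test (marker expression vs grade)."""
    config = simulate.SimulationConfig()
    rejections = 0
    for r in range(n_replicates):
        clinical = simulate.generate_clinical(
            config, marker_effect, seed=seed + r, n_samples=n_samples
        )
        _, p = survival.ordinal_trend_test(
            clinical["marker_expression"], clinical["grade"], method="normal"
        )
        if p < alpha:
            rejections += 1
    return {
        "power": rejections / n_replicates,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "n_samples": n_samples,
    }
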