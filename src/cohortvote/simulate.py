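"""Synthetic multi-cohort expression data with planted upregulated genes.

The generator emulates the structure of a multi-platform prostate-cancer
meta-analysis: several independent case series, each profiled on a different
array (so each measures only a subset of a shared gene universe), each with a
primary-tumor group and a recurrent/metastatic ("secondary") group.  A small
set of planted genes is truly upregulated in the secondary group, with
cohort-variable effect sizes and incomplete penetrance, so that cross-cohort
duplication counts below the cohort total arise naturally.

Expression is log-normal: ``value = 2 ** (baseline + effect * [secondary] +
noise)``, with per-gene baselines drawn once for the whole universe and
additive Gaussian noise on the log2 scale.  A linked clinical generator
produces validation cohorts in which one designated marker gene drives an
ordinal clinical grade and an exponential survival hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionCohort

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_multi_cohort",
    "generate_clinical",
]

#: Table of discovery-cohort sample counts the default configuration mirrors
#: (eight published case series ranging from 19 to 171 cases).
DEFAULT_CASES = (20, 19, 52, 171, 167, 164, 104, 79)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic multi-cohort study.

    Attributes
    ----------
    n_cohorts
        Number of discovery cohorts to generate.
    cases_per_cohort
        Sample count of each cohort; length must equal ``n_cohorts``.
    secondary_fraction
        Fraction of each cohort's samples labeled ``secondary`` (recurrent or
        metastatic disease); the remainder are ``primary``.
    gene_universe_size
        Size ``G`` of the shared gene universe.
    platform_coverage
        Probability that any universe gene is measured by a given cohort's
        platform; genes are sampled independently per cohort, so pairwise
        cohort overlap is hypergeometric-like.
    n_planted
        Number of truly upregulated genes.
    effect_fc_range
        ``(lo, hi)`` multiplicative fold-change range for planted effects,
        ``lo > 1``; each penetrant (cohort, gene) pair draws its own fold
        change uniformly from this range.
    effect_penetrance
        Probability a planted gene carries its effect in any given cohort.
    noise_sd_log2
        Standard deviation of the additive log2-scale Gaussian noise.
    baseline_log2_range
        ``(lo, hi)`` range of per-gene baseline log2 intensities.
    seed
        Root seed; a per-cohort seed sequence is derived from it so adding
        cohorts never perturbs earlier ones.
    """

    n_cohorts: int = 8
    cases_per_cohort: tuple[int, ...] = DEFAULT_CASES
    secondary_fraction: float = 0.35
    gene_universe_size: int = 10_000
    platform_coverage: float = 1.0
    n_planted: int = 50
    effect_fc_range: tuple[float, float] = (2.0, 4.0)
    effect_penetrance: float = 0.8
    noise_sd_log2: float = 0.6
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cases_per_cohort", tuple(int(c) for c in self.cases_per_cohort)
        )
        object.__setattr__(self, "effect_fc_range", tuple(self.effect_fc_range))
        object.__setattr__(
            self, "baseline_log2_range", tuple(self.baseline_log2_range)
        )
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be a positive count")
        if len(self.cases_per_cohort) != self.n_cohorts:
            raise ValueError(
                "cases_per_cohort must have length n_cohorts "
                f"({len(self.cases_per_cohort)} != {self.n_cohorts})"
            )
        if any(c < 2 for c in self.cases_per_cohort):
            raise ValueError("cases_per_cohort entries must be at least 2")
        if not 0.0 < self.secondary_fraction < 1.0:
            raise ValueError("secondary_fraction must lie in (0, 1)")
        if self.gene_universe_size < 1:
            raise ValueError("gene_universe_size must be a positive count")
        if not 0.0 < self.platform_coverage <= 1.0:
            raise ValueError("platform_coverage must lie in (0, 1]")
        if self.n_planted < 0 or self.n_planted > self.gene_universe_size:
            raise ValueError(
                "n_planted must lie in [0, gene_universe_size]"
            )
        lo, hi = self.effect_fc_range
        if not (lo > 1.0 and hi >= lo):
            raise ValueError("effect_fc_range must satisfy 1 < lo <= hi")
        if not 0.0 < self.effect_penetrance <= 1.0:
            raise ValueError("effect_penetrance must lie in (0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be nonnegative")
        blo, bhi = self.baseline_log2_range
        if bhi < blo:
            raise ValueError("baseline_log2_range must satisfy lo <= hi")


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic run, for recovery assessment.

    ``per_cohort_effects`` maps ``(cohort_id, gene)`` to the applied linear
    fold change for every planted gene measured by that cohort (1.0 when the
    effect was not penetrant there).  ``marker_gene`` is the planted gene with
    the largest applied fold change, used as the survival-associated marker in
    linked validation cohorts (None when nothing is planted).
    """

    planted_genes: frozenset[str]
    per_cohort_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    marker_gene: str | None = None

    def max_fold_change(self, gene: str) -> float:
        return max(
            (fc for (c, g), fc in self.per_cohort_effects.items() if g == gene),
            default=1.0,
        )


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_multi_cohort(
    config: SimulationConfig,
) -> tuple[list[ExpressionCohort], SimulationTruth]:
    """Generate ``config.n_cohorts`` expression cohorts plus ground truth.

    Identical config (including seed) yields bit-identical output.  Each
    cohort draws its measured gene subset, group labels, penetrance flags,
    effect sizes and noise from its own child seed, so runs differing only in
    ``n_cohorts`` agree on the shared prefix of cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    # child 0 drives universe-level draws; children 1..n_cohorts the cohorts
    children = root.spawn(config.n_cohorts + 1)
    global_rng = np.random.default_rng(children[0])

    G = config.gene_universe_size
    genes = np.asarray(_gene_ids(G))
    blo, bhi = config.baseline_log2_range
    baselines = global_rng.uniform(blo, bhi, size=G)
    planted_idx = np.sort(
        global_rng.choice(G, size=config.n_planted, replace=False)
    )
    planted = frozenset(genes[planted_idx])

    fc_lo, fc_hi = config.effect_fc_range
    cohorts: list[ExpressionCohort] = []
    effects: dict[tuple[str, str], float] = {}

    for c in range(config.n_cohorts):
        rng = np.random.default_rng(children[c + 1])
        cohort_id = f"cohort{c + 1}"
        n = config.cases_per_cohort[c]

        if config.platform_coverage < 1.0:
            measured_mask = rng.random(G) < config.platform_coverage
            if not measured_mask.any():  # pathological tiny-G corner
                measured_mask[rng.integers(G)] = True
        else:
            measured_mask = np.ones(G, dtype=bool)
        measured_genes = genes[measured_mask]

        n_secondary = max(1, min(n - 1, round(n * config.secondary_fraction)))
        n_primary = n - n_secondary
        group = np.array(["primary"] * n_primary + ["secondary"] * n_secondary)
        sample_ids = [f"{cohort_id}_s{j + 1:03d}" for j in range(n)]

        log2 = baselines[measured_mask][:, None] + rng.normal(
            0.0, config.noise_sd_log2, size=(measured_mask.sum(), n)
        )

        # planted effects: per-(cohort, gene) penetrance flag and fold change
        measured_pos = {g: i for i, g in enumerate(measured_genes)}
        for gene in genes[planted_idx]:
            if gene not in measured_pos:
                continue
            penetrant = rng.random() < config.effect_penetrance
            fc = rng.uniform(fc_lo, fc_hi) if penetrant else 1.0
            effects[(cohort_id, gene)] = float(fc)
            if penetrant:
                log2[measured_pos[gene], n_primary:] += math.log2(fc)

        values = pd.DataFrame(
            np.exp2(log2), index=measured_genes, columns=sample_ids
        )
        cohorts.append(
            ExpressionCohort(
                cohort_id=cohort_id,
                values=values,
                group=pd.Series(group, index=sample_ids),
            )
        )

    marker = None
    if planted:
        # most strongly and consistently upregulated planted gene
        best = max(
            sorted(planted),
            key=lambda g: max(
                (fc for (c, gg), fc in effects.items() if gg == g), default=1.0
            ),
        )
        marker = best
    truth = SimulationTruth(
        planted_genes=planted, per_cohort_effects=effects, marker_gene=marker
    )
    return cohorts, truth


def generate_clinical(
    config: SimulationConfig,
    marker_effect: float,
    seed: int,
    n_samples: int = 400,
    endpoint: str = "OS",
    baseline_hazard_months: float = 24.0,
    censoring_hazard_months: float = 48.0,
) -> pd.DataFrame:
    """Generate a validation cohort linking a marker gene to grade and survival.

    Each sample carries a standardized latent marker level ``z`` ~ N(0, 1):

    * ``marker_expression`` = ``2 ** (mu + z)`` with ``mu`` the midpoint of the
      configured baseline range (strictly positive, log-normal);
    * ordinal ``grade`` and ``stage`` in {1..4} from a proportional-odds draw
      whose latent location is shifted by ``marker_effect * z``;
    * survival ``time`` exponential with hazard multiplied by
      ``exp(marker_effect * z)``, independently exponentially censored;
      ``event`` is 1 when the event precedes censoring.

    With ``marker_effect = 0`` the marker is independent of grade, stage and
    survival.  Returns a DataFrame indexed by sample id with columns
    ``marker_expression, grade, stage, time, event``; the endpoint label is
    stored in ``.attrs["endpoint"]``.
    """
    if marker_effect < 0:
        raise ValueError("marker_effect must be nonnegative")
    if n_samples < 1:
        raise ValueError("n_samples must be a positive count")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    z = rng.standard_normal(n_samples)
    blo, bhi = config.baseline_log2_range
    mu = 0.5 * (blo + bhi)
    marker = np.exp2(mu + z)

    # proportional-odds ordinal draws: logistic quartile cutpoints under null
    cuts = np.array([math.log(1 / 3), 0.0, math.log(3.0)])
    grade = np.searchsorted(cuts, marker_effect * z + rng.logistic(size=n_samples))
    grade = (grade + 1).astype(int)
    stage = np.searchsorted(cuts, marker_effect * z + rng.logistic(size=n_samples))
    stage = (stage + 1).astype(int)

    hazard_scale = baseline_hazard_months * np.exp(-marker_effect * z)
    event_time = rng.exponential(hazard_scale)
    censor_time = rng.exponential(censoring_hazard_months, size=n_samples)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    table = pd.DataFrame(
        {
            "marker_expression": marker,
            "grade": grade,
            "stage": stage,
            "time": time,
            "event": event,
        },
        index=pd.Index(
            [f"v_s{j + 1:03d}" for j in range(n_samples)], name="sample_id"
        ),
    )
    table.attrs["endpoint"] = endpoint
    return table


def write_truth(path, truth: SimulationTruth) -> None:
    """Write ground truth as a two-column TSV (gene, max applied fold change)."""
    rows = [
        {"gene": g, "max_fold_change": truth.max_fold_change(g)}
        for g in sorted(truth.planted_genes)
    ]
    pd.DataFrame(rows, columns=["gene", "max_fold_change"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
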