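"""Synthetic cohort generator: determinism, structure, planted effects."""

import numpy as np
import pytest
from scipy import stats

from cohortvote.simulate import (
    SimulationConfig,
    generate_clinical,
    generate_multi_cohort,
)


def small_config(**overrides):
    defaults = dict(
        n_cohorts=3,
        cases_per_cohort=(20, 19, 30),
        gene_universe_size=400,
        n_planted=5,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(n_cohorts=0, cases_per_cohort=()), "n_cohorts"),
            (dict(cases_per_cohort=(20, 19)), "cases_per_cohort"),
            (dict(secondary_fraction=1.5), "secondary_fraction"),
            (dict(platform_coverage=0.0), "platform_coverage"),
            (dict(effect_fc_range=(0.5, 2.0)), "effect_fc_range"),
            (dict(effect_penetrance=0.0), "effect_penetrance"),
            (dict(n_planted=10_000), "n_planted"),
            (dict(noise_sd_log2=-0.1), "noise_sd_log2"),
        ],
    )
    def test_invalid_field_named_in_error(self, overrides, field):
        with pytest.raises(ValueError, match=field):
            small_config(**overrides)

    def test_default_mirrors_published_case_counts(self):
        config = SimulationConfig()
        assert config.n_cohorts == 8
        assert config.cases_per_cohort == (20, 19, 52, 171, 167, 164, 104, 79)


class TestGenerateMultiCohort:
    def test_sample_counts_match_config(self):
        cohorts, _ = generate_multi_cohort(small_config())
        assert [len(c.sample_ids) for c in cohorts] == [20, 19, 30]

    def test_both_groups_present(self):
        cohorts, _ = generate_multi_cohort(small_config())
        for cohort in cohorts:
            assert (cohort.group == "primary").sum() >= 1
            assert (cohort.group == "secondary").sum() >= 1

    def test_no_planted_genes_means_no_effects(self):
        _, truth = generate_multi_cohort(small_config(n_planted=0))
        assert truth.planted_genes == frozenset()
        assert truth.per_cohort_effects == {}
        assert truth.marker_gene is None

    def test_seeded_determinism(self):
        a, _ = generate_multi_cohort(small_config(seed=3))
        b, _ = generate_multi_cohort(small_config(seed=3))
        c, _ = generate_multi_cohort(small_config(seed=4))
        for x, y in zip(a, b):
            assert x.values.equals(y.values)
            assert (x.group == y.group).all()
        assert not a[0].values.equals(c[0].values)

    def test_adding_cohorts_preserves_earlier_ones(self):
        three, _ = generate_multi_cohort(small_config())
        four, _ = generate_multi_cohort(
            small_config(n_cohorts=4, cases_per_cohort=(20, 19, 30, 12))
        )
        for a, b in zip(three, four[:3]):
            assert a.values.equals(b.values)

    def test_strictly_positive_and_finite(self):
        cohorts, _ = generate_multi_cohort(small_config())
        for cohort in cohorts:
            values = cohort.values.to_numpy()
            assert (values > 0).all()
            assert np.isfinite(values).all()

    def test_partial_coverage_subsets_universe(self):
        config = small_config(platform_coverage=0.5)
        cohorts, _ = generate_multi_cohort(config)
        sizes = [len(c.gene_ids) for c in cohorts]
        assert all(0 < s < config.gene_universe_size for s in sizes)
        # different cohorts draw different platforms
        assert set(cohorts[0].gene_ids) != set(cohorts[1].gene_ids)

    def test_applied_fold_changes_recorded(self):
        config = small_config(effect_penetrance=1.0)
        cohorts, truth = generate_multi_cohort(config)
        lo, hi = config.effect_fc_range
        assert truth.per_cohort_effects
        for fc in truth.per_cohort_effects.values():
            assert fc == 1.0 or lo <= fc <= hi

    def test_planted_group_median_ratio_near_applied_fold_change(self):
        """Empirical secondary/primary median ratio within 10% of the planted
        fold change for a penetrant gene with >= 100 samples per group."""
        config = SimulationConfig(
            n_cohorts=1,
            cases_per_cohort=(1000,),
            secondary_fraction=0.5,
            gene_universe_size=50,
            n_planted=3,
            effect_penetrance=1.0,
            noise_sd_log2=0.6,
            seed=123,
        )
        cohorts, truth = generate_multi_cohort(config)
        cohort = cohorts[0]
        sec = cohort.samples_in_group("secondary")
        pri = cohort.samples_in_group("primary")
        for gene in truth.planted_genes:
            applied = truth.per_cohort_effects[("cohort1", gene)]
            ratio = (
                cohort.values.loc[gene, sec].median()
                / cohort.values.loc[gene, pri].median()
            )
            assert ratio == pytest.approx(applied, rel=0.10)

    def test_null_genes_have_matched_group_distributions(self):
        """Two-sample KS on non-planted genes should not reject en masse."""
        config = small_config(
            n_planted=0, cases_per_cohort=(60, 60, 60), seed=99
        )
        cohorts, _ = generate_multi_cohort(config)
        cohort = cohorts[0]
        sec = cohort.samples_in_group("secondary")
        pri = cohort.samples_in_group("primary")
        p_values = [
            stats.ks_2samp(
                cohort.values.loc[g, sec], cohort.values.loc[g, pri]
            ).pvalue
            for g in list(cohort.gene_ids)[:100]
        ]
        # under the null ~5% of KS tests reject at 0.05
        assert np.mean(np.array(p_values) < 0.05) < 0.15


class TestGenerateClinical:
    def test_negative_marker_effect_rejected(self):
        with pytest.raises(ValueError, match="marker_effect"):
            generate_clinical(small_config(), -0.5, seed=1)

    def test_schema_and_positivity(self):
        table = generate_clinical(small_config(), 1.0, seed=2, n_samples=50)
        assert len(table) == 50
        assert (table["time"] > 0).all()
        assert table["event"].isin((0, 1)).all()
        assert table["grade"].between(1, 4).all()
        assert table["stage"].between(1, 4).all()
        assert (table["marker_expression"] > 0).all()
        assert table.attrs["endpoint"] == "OS"

    def test_determinism(self):
        a = generate_clinical(small_config(), 1.0, seed=5)
        b = generate_clinical(small_config(), 1.0, seed=5)
        assert a.equals(b)

    def test_null_marker_independent_of_grade(self):
        table = generate_clinical(small_config(), 0.0, seed=11,
                                  n_samples=600)
        rho, p = stats.spearmanr(table["marker_expression"], table["grade"])
        assert abs(rho) < 0.12

    def test_strong_marker_shifts_grade_distribution(self):
        table = generate_clinical(small_config(), 2.0, seed=11,
                                  n_samples=600)
        rho, p = stats.spearmanr(table["marker_expression"], table["grade"])
        assert rho > 0.4 and p < 1e-6
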