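"""Binomial/Poisson-binomial nulls, BH adjustment, permutation null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortvote.nulls import (
    bh_adjust,
    binom_tail,
    calibrate_signature,
    expected_count,
    permutation_null,
    poisson_binomial_tail,
)
from cohortvote.integration import build_signature, count_duplication
from cohortvote.simulate import SimulationConfig, generate_multi_cohort
from cohortvote import experiments


class TestBinomTail:
    def test_k_zero_is_certain(self):
        assert binom_tail(8, 1000, 10000, 0) == 1.0
        assert binom_tail(3, 1, 10**6, 0) == 1.0

    def test_two_fair_lists(self):
        # two cohorts, one-gene lists from a two-gene universe: p = 1/2 each
        assert binom_tail(2, 1, 2, 2) == pytest.approx(0.25)

    def test_non_increasing_in_k(self):
        tails = [binom_tail(8, 1000, 10000, k) for k in range(9)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_non_decreasing_in_n(self):
        assert binom_tail(8, 2000, 10000, 4) >= binom_tail(8, 1000, 10000, 4)

    def test_stable_for_tiny_membership_probability(self):
        p = binom_tail(8, 1, 10**6, 2)
        # closed form: C(8,2) p^2 q^6 + smaller terms ~ 2.8e-11
        assert p == pytest.approx(28 * 1e-12, rel=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binom_tail(8, 11, 10, 1)
        with pytest.raises(ValueError):
            binom_tail(8, 5, 10, 9)

    def test_matches_monte_carlo(self):
        check = experiments.binom_tail_mc_check(n_replicates=200_000, seed=3)
        assert check["max_abs_z"] < 3.0


class TestPoissonBinomial:
    def test_reduces_to_binomial_for_equal_probabilities(self):
        for k in range(6):
            assert poisson_binomial_tail([0.1] * 5, k) == pytest.approx(
                binom_tail(5, 1000, 10000, k)
            )

    def test_matches_enumeration(self, rng):
        probs = rng.random(4)
        # brute-force over all 2^4 outcomes
        exact = np.zeros(5)
        for mask in range(16):
            bits = [(mask >> i) & 1 for i in range(4)]
            prob = np.prod([p if b else 1 - p for p, b in zip(probs, bits)])
            exact[sum(bits)] += prob
        for k in range(5):
            assert poisson_binomial_tail(probs, k) == pytest.approx(
                exact[k:].sum()
            )


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_equal_inputs_unchanged(self):
        assert bh_adjust([0.01, 0.01, 0.01]) == pytest.approx([0.01] * 3)

    def test_matches_step_up_hand_computation(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_order_invariance(self, rng):
        p = rng.random(20)
        order = rng.permutation(20)
        assert bh_adjust(p)[order] == pytest.approx(bh_adjust(p[order]))

    def test_q_at_least_p(self, rng):
        p = rng.random(30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_step_up_properties_hold_for_arbitrary_inputs(self, p):
        """q >= p elementwise, q <= 1, and the sorted step-up output is
        monotone for any valid p-value vector."""
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=50, derandomize=True)
    @given(
        st.integers(1, 12), st.integers(1, 50), st.integers(50, 500),
        st.integers(0, 12),
    )
    def test_binom_tail_is_a_valid_tail(self, C, N, G, k):
        if k > C:
            return
        tail = binom_tail(C, N, G, k)
        assert 0.0 <= tail <= 1.0
        if k < C:
            assert tail >= binom_tail(C, N, G, k + 1)


class TestExpectedCount:
    def test_bounded_by_universe(self):
        for k in range(9):
            assert expected_count(8, 1000, 10000, k) <= 10000


def _noise_cohorts(seed=0, n_cohorts=3, G=300):
    config = SimulationConfig(
        n_cohorts=n_cohorts,
        cases_per_cohort=(12,) * n_cohorts,
        gene_universe_size=G,
        platform_coverage=1.0,
        n_planted=0,
        seed=seed,
    )
    return generate_multi_cohort(config)[0]


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed_histogram(self):
        cohorts = _noise_cohorts()
        perm = permutation_null(cohorts, top_n=30, B=1, identity=True)
        from cohortvote.nulls import _duplication_histogram

        assert np.array_equal(
            perm.counts, _duplication_histogram(cohorts, 30)
        )

    def test_same_seed_is_reproducible(self):
        cohorts = _noise_cohorts()
        a = permutation_null(cohorts, top_n=30, B=5, seed=42)
        b = permutation_null(cohorts, top_n=30, B=5, seed=42)
        assert np.array_equal(a.replicate_counts, b.replicate_counts)

    def test_matches_binomial_on_pure_noise(self):
        check = experiments.permutation_vs_binomial(
            n_cohorts=4, cases_per_cohort=(12,) * 4, G=400, top_n=40, B=40,
            seed=5,
        )
        assert check["max_abs_z"] < 3.0

    def test_small_groups_rejected(self):
        config = SimulationConfig(
            n_cohorts=1, cases_per_cohort=(3,), gene_universe_size=50,
            n_planted=0, secondary_fraction=0.3, seed=0,
        )
        cohorts, _ = generate_multi_cohort(config)
        with pytest.raises(ValueError, match="2 samples per group"):
            permutation_null(cohorts, top_n=5, B=1)


class TestCalibrateSignature:
    def test_fills_p_and_q_consistently(self):
        universes = {f"c{i}": {"A", "B"} for i in range(4)}
        lists = {f"c{i}": {"A"} for i in range(4)}
        dup = count_duplication(lists, universes)
        import pandas as pd

        tables = {
            f"c{i}": pd.DataFrame(
                {"median_fc": [2.0, 0.5], "in_top_n": [True, False]},
                index=pd.Index(["A", "B"], name="gene"),
            )
            for i in range(4)
        }
        sig = build_signature(dup, tables, min_duplication=1)
        out = calibrate_signature(sig, top_n=1, universe_sizes=2)
        row = out[out["gene"] == "A"].iloc[0]
        assert row["p_binom"] == pytest.approx(binom_tail(4, 1, 2, 4))
        assert (out["q_bh"] >= out["p_binom"] - 1e-12).all()
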