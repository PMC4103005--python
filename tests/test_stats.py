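"""Tests for the randomization test, BHY adjustment, and mutant calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import bhy_stepup, exact_permutation_p

from myxphen.core import TraitTable, TraitTableError
from myxphen.stats import (
    bhy_adjust,
    call_mutants,
    pleiotropy_summary,
    randomization_test,
)
from myxphen.synthetic import SimulationConfig, simulate_trait_table


class TestRandomizationTest:
    def test_identical_groups_give_p_one(self):
        obs, p = randomization_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert obs == 0.0 and p == 1.0

    def test_fully_separated_3v3_exact_enumeration(self):
        obs, p = randomization_test([10, 10, 10], [0, 0, 0])
        assert obs == 10.0
        assert p == pytest.approx(2 / 20)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            randomization_test([1.0], [1.0, 2.0])

    def test_exact_matches_independent_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            _, p = randomization_test(x, y, method="exact")
            assert p == pytest.approx(exact_permutation_p(x, y), abs=1e-12)

    def test_monte_carlo_close_to_exact(self, rng):
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            p_exact = exact_permutation_p(x, y)
            _, p_mc = randomization_test(
                x, y, n_iterations=1000, method="monte-carlo",
                rng_seed=int(rng.integers(2**31)))
            se = np.sqrt(p_exact * (1 - p_exact) / 1000)
            assert abs(p_mc - p_exact) <= 3 * se + 1e-3

    def test_p_strictly_positive_and_at_most_one(self, rng):
        for _ in range(5):
            x = rng.normal(5, 0.1, size=3)
            y = rng.normal(0, 0.1, size=30)
            _, p = randomization_test(x, y, rng_seed=0)
            assert 0 < p <= 1


class TestBHY:
    def test_single_p_unchanged(self):
        assert bhy_adjust([0.2]) == pytest.approx([0.2])

    def test_hand_computed_stepup(self):
        # m=3, c(3)=11/6: all three collapse to 0.03*3*(11/6)/3 = 0.055
        np.testing.assert_allclose(
            bhy_adjust([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055],
            atol=1e-12)

    def test_empty_and_invalid_inputs(self):
        assert bhy_adjust([]).size == 0
        with pytest.raises(ValueError):
            bhy_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bhy_adjust([1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_direct_stepup_and_dominates_bh(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = bhy_adjust(ps)
        np.testing.assert_allclose(ours, bhy_stepup(ps), atol=1e-12)
        bh = multipletests(ps, method="fdr_bh")[1]
        assert (ours >= bh - 1e-12).all()
        assert (ours >= np.asarray(ps) - 1e-12).all()

    def test_permutation_equivariance(self, rng):
        ps = rng.uniform(0.001, 1.0, size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bhy_adjust(ps)[perm], bhy_adjust(ps[perm]),
                                   atol=1e-14)


class TestCallMutants:
    def test_deterministic_under_fixed_seed(self, small_table):
        table, _ = small_table
        r1 = call_mutants(table, n_iterations=300, rng_seed=7)
        r2 = call_mutants(table, n_iterations=300, rng_seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_only_replicated_traits_tested(self, small_table):
        table, _ = small_table
        res = call_mutants(table, n_iterations=200, rng_seed=0)
        assert set(res["trait"]) == {"area", "circularity", "grayness",
                                     "soft", "hard", "sporulation"}
        assert len(res) == 6 * len(table.mutants)

    def test_result_invariants(self, small_table):
        table, _ = small_table
        res = call_mutants(table, alpha=0.05, n_iterations=200, rng_seed=0)
        assert ((res["p_raw"] > 0) & (res["p_raw"] <= 1)).all()
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()
        assert (res["significant"] == (res["p_adj"] <= 0.05)).all()

    def test_missing_wildtype_rejected(self, small_table):
        table, _ = small_table
        df = table.df[table.df["strain"] != table.wildtype]
        with pytest.raises(TraitTableError, match="DK1622"):
            TraitTable(df)

    def test_large_planted_effects_all_detected(self):
        cfg = SimulationConfig(n_strains=101, per_trait_effect_prob=0.3,
                               effect_size_sd=5.0, rng_seed=11)
        table, truth = simulate_trait_table(cfg)
        # 3000 iterations exceed C(27,3)=2925 distinct reassignments, so the
        # test switches to exact enumeration and detection is deterministic
        res = call_mutants(table, n_iterations=3000, rng_seed=3)
        assert res["exact"].all()
        res = res.set_index(["strain", "trait"])
        for strain in table.mutants:
            for trait in ("area", "circularity", "grayness", "soft", "hard"):
                if truth.affected.loc[strain, trait]:
                    assert res.loc[(strain, trait), "significant"]

    def test_fdr_family_all_is_more_conservative_overall(self, small_table):
        table, _ = small_table
        per_trait = call_mutants(table, n_iterations=200, rng_seed=0)
        joint = call_mutants(table, n_iterations=200, rng_seed=0, family="all")
        assert joint["significant"].sum() <= per_trait["significant"].sum() + 2


class TestPleiotropySummary:
    def _results(self, sig_map):
        rows = [
            {"strain": s, "trait": t, "significant": sig}
            for s, traits in sig_map.items()
            for t, sig in traits.items()
        ]
        return pd.DataFrame(rows)

    def test_no_significant_gives_zero_fractions(self):
        res = self._results({"a": {"x": False}, "b": {"x": False}})
        _, fr = pleiotropy_summary(res)
        assert fr["frac_ge1"] == 0.0 and fr["frac_ge2"] == 0.0

    def test_two_trait_strain_counts_in_both_fractions(self):
        res = self._results({
            "a": {"x": True, "y": True},
            "b": {"x": False, "y": False},
        })
        per_strain, fr = pleiotropy_summary(res)
        assert per_strain.set_index("strain").loc["a",
                                                  "n_significant_traits"] == 2
        assert fr["frac_ge1"] == 0.5 and fr["frac_ge2"] == 0.5

    def test_recovers_planted_pleiotropy_fraction(self):
        cfg = SimulationConfig(n_strains=151, per_trait_effect_prob=0.25,
                               effect_size_sd=5.0, rng_seed=21)
        table, truth = simulate_trait_table(cfg)
        res = call_mutants(table, n_iterations=1000, rng_seed=5)
        _, fr = pleiotropy_summary(res)
        planted = truth.affected.drop(index=table.wildtype)[
            ["area", "circularity", "grayness", "soft", "hard", "sporulation"]]
        planted_ge2 = (planted.sum(axis=1) >= 2).mean()
        assert abs(fr["frac_ge2"] - planted_ge2) < 0.12
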