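"""Two-sample tests, ranks, BH adjustment, and cohort comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from idionet.compare import (
    bh_adjust,
    compare_cohort,
    rank_centralities,
    two_sample_tests,
)
from idionet.metrics import CentralityProfile, DensityMetrics
from idionet.variability import SymptomVariability

from conftest import bh_oracle


def profile(pid, strengths, closenesses=None, betweennesses=None):
    items = [f"i{k}" for k in range(len(strengths))]
    values = pd.DataFrame(
        {
            "strength": strengths,
            "closeness": closenesses if closenesses is not None
            else np.asarray(strengths) / 10,
            "betweenness": betweennesses if betweennesses is not None
            else np.zeros(len(strengths)),
        },
        index=items,
    )
    return CentralityProfile(pid, values)


class TestRanks:
    def test_rank_one_is_most_central(self):
        r = rank_centralities(profile("A", [0.9, 0.2, 0.5]))
        assert r["strength"].tolist() == [1.0, 3.0, 2.0]

    def test_ties_get_average_ranks(self):
        r = rank_centralities(profile("A", [0.5, 0.5, 0.2]))
        assert r["strength"].tolist() == [1.5, 1.5, 3.0]

    def test_all_equal_ranks_midpoint(self):
        r = rank_centralities(profile("A", [0.3, 0.3, 0.3, 0.3]))
        assert (r["strength"] == 2.5).all()

    def test_rank_invariant_to_monotone_transform(self):
        s = [0.9, 0.2, 0.5, 0.7]
        r1 = rank_centralities(profile("A", s))
        r2 = rank_centralities(profile("A", list(np.exp(s))))
        assert r1["strength"].tolist() == r2["strength"].tolist()


class TestTwoSampleTests:
    def test_exact_ranksum_small_groups(self):
        # all C(4,2)=6 assignments; {1,2} vs {3,4} is one of the two most
        # extreme splits, so the exact two-sided p is 2/6 = 1/3
        res = two_sample_tests([1, 2], [3, 4])
        assert res.wilcoxon_pvalue == pytest.approx(1 / 3)

    def test_identical_groups_t_zero_p_one(self):
        res = two_sample_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.t_pvalue == pytest.approx(1.0)

    def test_constant_equal_groups_convention(self):
        res = two_sample_tests([2.0, 2.0], [2.0, 2.0])
        assert res.t_statistic == 0.0 and res.t_pvalue == 1.0

    def test_huge_shift_attains_minimum_p(self):
        a = [100.0, 101.0, 102.0]
        b = [0.0, 1.0, 2.0]
        res = two_sample_tests(a, b)
        # minimum attainable exact two-sided rank-sum p for 3 vs 3 is 2/C(6,3)
        assert res.wilcoxon_pvalue == pytest.approx(2 / 20)
        assert res.t_pvalue < 1e-4

    def test_antisymmetry_under_group_swap(self):
        a = [1.0, 3.0, 2.5, 4.0]
        b = [2.0, 5.0, 6.0]
        r1 = two_sample_tests(a, b)
        r2 = two_sample_tests(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.t_pvalue == pytest.approx(r2.t_pvalue)
        assert r1.wilcoxon_pvalue == pytest.approx(r2.wilcoxon_pvalue)

    def test_group_too_small_raises(self):
        with pytest.raises(ValueError):
            two_sample_tests([1.0], [2.0, 3.0])


class TestBHAdjust:
    def test_worked_example(self):
        adjusted, reject = bh_adjust([0.002, 0.019, 0.024, 0.4], q=0.10)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_no_rejections(self):
        adjusted, reject = bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any()
        assert (adjusted == 1.0).all()

    def test_single_p_below_q_rejected(self):
        adjusted, reject = bh_adjust([0.05], q=0.10)
        assert reject.tolist() == [True]

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, size=20)
        adjusted, _ = bh_adjust(p)
        assert (adjusted >= p - 1e-15).all()

    def test_matches_oracle_on_grid_vectors(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 1.0]
        for length in range(1, 6):
            for p in itertools.combinations_with_replacement(grid, length):
                adjusted, reject = bh_adjust(list(p), q=0.10)
                o_adj, o_rej = bh_oracle(list(p), q=0.10)
                np.testing.assert_allclose(adjusted, o_adj, atol=1e-12)
                assert reject.tolist() == o_rej.tolist()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_rejections_monotone_in_q(self, p):
        _, r1 = bh_adjust(p, q=0.05)
        _, r2 = bh_adjust(p, q=0.20)
        assert (r1 <= r2).all()

    def test_nan_pvalues_pass_through(self):
        adjusted, reject = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adjusted[1]) and not reject[1]


def tiny_cohort_inputs(effect=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    profiles, varis, dens, labels = {}, {}, {}, {}
    for k in range(8):
        pid = f"P{k}"
        relapsed = k < 4
        base = rng.normal(0.5, 0.1, size=3) + (effect if relapsed else 0.0)
        profiles[pid] = profile(pid, base)
        varis[pid] = SymptomVariability(
            pid,
            pd.DataFrame(
                {"sd": rng.uniform(0.5, 1.5, 3), "rmssd": rng.uniform(0.5, 1.5, 3)},
                index=[f"i{j}" for j in range(3)],
            ),
        )
        dens[pid] = DensityMetrics(pid, 8 + rng.normal(), 0.5 + 0.05 * rng.normal(), 1.0)
        labels[pid] = relapsed
    return profiles, varis, dens, labels


class TestCompareCohort:
    def test_blocked_families_and_columns(self):
        profiles, varis, dens, labels = tiny_cohort_inputs()
        table = compare_cohort(profiles, varis, dens, labels).to_frame()
        # 3 items x 3 indices x {raw, rank} + 3 items x {sd, rmssd} + 2 density
        assert len(table) == 18 + 6 + 2
        assert set(table["family"]) == {
            "strength_raw", "strength_rank", "closeness_raw", "closeness_rank",
            "betweenness_raw", "betweenness_rank", "variability", "density",
        }
        assert (table["p_t_adj"] >= table["p_t"] - 1e-12).all()

    def test_single_group_errors(self):
        profiles, varis, dens, labels = tiny_cohort_inputs()
        labels = {p: True for p in labels}
        with pytest.raises(ValueError, match="2 participants per group"):
            compare_cohort(profiles, varis, dens, labels)

    def test_global_family_mode(self):
        profiles, varis, dens, labels = tiny_cohort_inputs()
        table = compare_cohort(
            profiles, varis, dens, labels, family_mode="global"
        ).to_frame()
        assert set(table["family"]) == {"all"}

    def test_strong_effect_detected(self):
        profiles, varis, dens, labels = tiny_cohort_inputs(effect=2.0)
        table = compare_cohort(profiles, varis, dens, labels).to_frame()
        raw_strength = table[table["family"] == "strength_raw"]
        assert raw_strength["rejected_t"].all()

    def test_deterministic(self):
        profiles, varis, dens, labels = tiny_cohort_inputs()
        t1 = compare_cohort(profiles, varis, dens, labels).to_frame()
        t2 = compare_cohort(profiles, varis, dens, labels).to_frame()
        pd.testing.assert_frame_equal(t1, t2)
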