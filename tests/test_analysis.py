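"""Analysis-layer tests: best-PEEP selection, recovery metric, RTE and
rank-sum against brute-force enumeration, cohort summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ventsim.analysis import (
    best_peep,
    cohort_summary,
    deviation_from_lavage,
    group_best_peep,
    rank_sum_test,
    relative_treatment_effect,
)
from ventsim.protocol import PeepTrialResult, PeepTrialStep


def make_trial(curve, attr="crs"):
    steps = []
    for peep, val in curve:
        kw = dict(peep=peep, pao2=100.0, paco2=50.0, crs=20.0, co=4.0,
                  do2=400.0, pf_ratio=100.0)
        kw[attr] = val
        if attr == "pao2":
            kw["pf_ratio"] = val
        steps.append(PeepTrialStep(**kw))
    return PeepTrialResult(steps=steps, terminated_reason="min_peep")


class TestBestPeep:
    def test_unique_max(self):
        t = make_trial([(12, 20.0), (10, 25.0), (8, 22.0)])
        r = best_peep(t, "max_crs")
        assert r.best_peep == 10 and r.best_value == 25.0

    def test_tie_breaks_toward_lower_peep(self):
        t = make_trial([(12, 20.0), (10, 25.0), (8, 25.0)])
        assert best_peep(t, "max_crs").best_peep == 8

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            best_peep(PeepTrialResult(), "max_crs")

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            best_peep(make_trial([(10, 1.0)]), "max_ph")

    def test_permutation_invariance_and_monotone_rescale(self):
        curve = [(24, 10.0), (16, 30.0), (12, 28.0), (8, 15.0)]
        r0 = best_peep(make_trial(curve), "max_crs")
        for perm in itertools.permutations(curve):
            assert best_peep(make_trial(list(perm)), "max_crs").best_peep == r0.best_peep
        rescaled = [(p, 2.0 * v + 5.0) for p, v in curve]
        assert best_peep(make_trial(rescaled), "max_crs").best_peep == r0.best_peep

    def test_group_mean_curve_restricted_to_common_levels(self):
        # pig A measured down to 8, pig B stopped at 12
        a = make_trial([(16, 20.0), (14, 22.0), (12, 24.0), (10, 30.0), (8, 18.0)])
        b = make_trial([(16, 24.0), (14, 25.0), (12, 26.0)])
        r = group_best_peep([a, b], "max_crs")
        assert {p for p, _ in r.per_step_curve} == {12.0, 14.0, 16.0}
        assert r.best_peep == 12  # mean curve peaks at 12 among common levels


class TestDeviationFromLavage:
    def test_zero_change(self):
        assert deviation_from_lavage(20.0, 20.0) == 0.0

    def test_group_a_table_values(self):
        # dynamic compliance 11.7 -> 29.8 mL/cmH2O is a +154.7 % recovery
        assert deviation_from_lavage(29.8, 11.7) == pytest.approx(154.7, abs=0.1)

    def test_negative_sign(self):
        assert deviation_from_lavage(8.0, 10.0) < 0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            deviation_from_lavage(10.0, 0.0)


def brute_force_rte(values, labels, group):
    """Pairwise-count oracle: P(pooled < member) + 0.5 P(pooled == member)."""
    sub = [x for x, g in zip(values, labels) if g == group]
    n = len(values)
    total = 0.0
    for y in sub:
        for x in values:
            total += (x < y) + 0.5 * (x == y)
    return total / (n * len(sub))


class TestRTE:
    def test_two_identical_subgroups(self):
        res = relative_treatment_effect([1, 2, 3, 1, 2, 3], list("AAABBB"))
        assert all(r.rte == pytest.approx(0.5) for r in res)

    def test_separated_subgroups(self):
        res = {r.label: r.rte for r in relative_treatment_effect([1, 2, 3, 4], list("AABB"))}
        assert res["A"] == pytest.approx(0.25)
        assert res["B"] == pytest.approx(0.75)

    def test_all_ties(self):
        res = relative_treatment_effect([5.0] * 6, list("AAABBB"))
        assert all(r.rte == pytest.approx(0.5) for r in res)

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_matches_pairwise_oracle_and_weighted_mean(self, values):
        labels = ["A" if i % 2 == 0 else "B" for i in range(len(values))]
        res = relative_treatment_effect(values, labels)
        for r in res:
            assert r.rte == pytest.approx(
                brute_force_rte(values, labels, r.label), abs=1e-12
            )
        weighted = sum(r.rte * r.n for r in res) / len(values)
        assert weighted == pytest.approx(0.5, abs=1e-12)

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError):
            relative_treatment_effect([1.0], ["A"])


def exact_perm_p(a, b):
    """Full-enumeration oracle for the two-sided permutation p of U."""
    pooled = list(a) + list(b)
    na, n = len(a), len(a) + len(b)
    mid = na * len(b) / 2.0

    def u_of(sample_idx):
        ranks = sps.rankdata(pooled)
        # recompute ranks of the subsample within the pooled mid-ranks
        return sum(ranks[i] for i in sample_idx) - na * (na + 1) / 2.0

    obs = u_of(range(na))
    dev = abs(obs - mid)
    hits = total = 0
    for comb in itertools.combinations(range(n), na):
        total += 1
        if abs(u_of(comb) - mid) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_separated_pairs(self):
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
    )
    @settings(max_examples=40, deadline=None)
    def test_u_identity(self, a, b):
        ua, _ = rank_sum_test(a, b)
        ub, _ = rank_sum_test(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
    )
    @settings(max_examples=30, deadline=None)
    def test_exact_branch_matches_full_enumeration(self, a, b):
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_perm_p(a, b), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 20)
        u, p = rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


@pytest.fixture(scope="module")
def small_logs():
    import ventsim as v
    from ventsim import protocol as P

    logs = []
    for arm in ("protective", "injurious"):
        for i, pig in enumerate(v.make_cohort(2, seed=4)):
            logs.append(
                P.run_full_experiment(arm, pig, pig_id=i, phase_hours=0.1,
                                      baseline_minutes=5)
            )
    return logs


class TestCohortSummary:

    def test_instants_table_shape(self, small_logs):
        tables = cohort_summary(small_logs)
        instants = tables["instants"]
        assert {"protective", "injurious"} == set(
            instants.index.get_level_values("arm")
        )
        assert ("crs", "mean") in instants.columns
        assert ("crs", "std") in instants.columns

    def test_single_pig_sd_zero(self, small_logs):
        tables = cohort_summary(small_logs[:1])
        assert (tables["instants"].xs("std", axis=1, level=1).fillna(0) == 0).all().all()

    def test_phase_hours_present(self, small_logs):
        phases = cohort_summary(small_logs)["phases"]
        assert set(phases.index.get_level_values("phase")) == {"phase1", "phase2"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])
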