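"""Agent-based simulator: primitives, year-step invariants, run behavior."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cultrans import (
    NAIVE,
    ABMParams,
    AgeSchedule,
    Population,
    adoption_probs,
    migration_contrast,
    run_simulation,
    step_year,
    survival_prob,
)

from oracles import adoption_probs_bruteforce


class TestSurvivalProb:
    def test_closed_form_values(self):
        assert survival_prob(0, 0.5) == 1.0
        assert survival_prob(37, 0.0) == 1.0
        assert survival_prob(20, 0.05) == pytest.approx(np.exp(-1.0))

    def test_monotone_nonincreasing_in_age(self):
        ages = np.arange(0, 80)
        p = survival_prob(ages, 0.03)
        assert np.all(np.diff(p) <= 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            survival_prob(-1, 0.1)
        with pytest.raises(ValueError):
            survival_prob(1, -0.1)


class TestAdoptionProbs:
    @pytest.mark.parametrize(
        "counts,theta,expected",
        [
            ({"A": 20, "B": 10}, 1.0, {"A": 2 / 3, "B": 1 / 3}),
            ({"A": 20, "B": 10}, 2.0, {"A": 0.8, "B": 0.2}),
            ({"A": 16, "B": 4}, 0.5, {"A": 2 / 3, "B": 1 / 3}),
        ],
    )
    def test_frequency_dependence(self, counts, theta, expected):
        probs = adoption_probs(counts, theta)
        for v, p in expected.items():
            assert probs[v] == pytest.approx(p)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            adoption_probs({"A": 0, "B": 0}, 1.0)

    @given(
        st.dictionaries(
            st.integers(0, 30), st.integers(0, 50), min_size=1, max_size=8
        ).filter(lambda d: any(v > 0 for v in d.values())),
        st.floats(0.1, 4.0),
    )
    def test_matches_bruteforce_normalization(self, counts, theta):
        probs = adoption_probs(counts, theta)
        oracle = adoption_probs_bruteforce(counts, theta)
        assert set(probs) == set(oracle)
        for v in probs:
            assert probs[v] == pytest.approx(oracle[v])
        assert sum(probs.values()) == pytest.approx(1.0)


class TestStepInvariants:
    def test_sizes_ages_and_naivety(self, tiny_params):
        rng = np.random.default_rng(0)
        pop = Population.initial(tiny_params)
        for _ in range(15):
            pop.step(tiny_params, rng, learning=False)
        pop.assign_unique_variants()
        for _ in range(15):
            before_ids = pop.ids.copy()
            before_ages = pop.ages.copy()
            tallies, _ = step_year(pop, tiny_params, rng)
            # exact group sizes at every year boundary
            assert len(pop.ids) == tiny_params.n_agents
            assert np.all(np.bincount(pop.groups) == tiny_params.group_size)
            # survivors aged exactly one year; newborns entered at (now) age 1
            survivors = np.isin(pop.ids, before_ids)
            prev_age = dict(zip(before_ids, before_ages))
            for pid, age in zip(pop.ids[survivors], pop.ages[survivors]):
                assert age == prev_age[pid] + 1
            assert tallies["births"] == tallies["deaths"]

    def test_innovation_ids_globally_unique(self, tiny_params):
        params = dataclasses.replace(tiny_params, mu=0.5)
        rec = run_simulation(params, seed=4)
        total_innov = rec.tallies["innovations"].sum()
        assert total_innov > 0
        # novel variants come from an increasing counter, never recycled:
        # every variant id lies below n_groups + #innovations, and the
        # counter advanced by exactly one per innovation event
        assert rec.snapshot["variant"].max() < params.n_groups + total_innov

    def test_closed_system_stays_fixed_and_cfst_one(self, tiny_params):
        params = dataclasses.replace(tiny_params, mu=0.0, migration=0.0, record_years=40)
        rec = run_simulation(params, seed=1)
        assert np.allclose(rec.cfst, 1.0)

    def test_all_zero_age_schedule_means_no_migration(self, tiny_params):
        sched = AgeSchedule(boundaries=(0, 5), rates=(0.0, 0.0))
        params = dataclasses.replace(tiny_params, migration=sched)
        rec = run_simulation(params, seed=2)
        assert rec.tallies["migrations"].sum() == 0

    def test_full_mixing_erodes_diversity(self, tiny_params):
        params = dataclasses.replace(
            tiny_params, migration=1.0, theta=1.0, record_years=60
        )
        rec = run_simulation(params, seed=3)
        assert rec.cfst[-1] < 0.2

    def test_fixed_seed_bit_identical(self, tiny_params):
        a = run_simulation(tiny_params, seed=9)
        b = run_simulation(tiny_params, seed=9)
        np.testing.assert_array_equal(a.cfst, b.cfst)
        assert a.snapshot.equals(b.snapshot)
        assert a.tallies.equals(b.tallies)

    def test_cfst_exactly_one_at_assignment(self, tiny_params):
        rec = run_simulation(dataclasses.replace(tiny_params, record_years=0), seed=5)
        assert len(rec.cfst) == 1
        assert rec.cfst[0] == 1.0

    def test_partner_count_must_fit_group(self):
        with pytest.raises(ValueError):
            ABMParams(n_partners=50, group_size=50)


class TestVectorizedAdoptionSampling:
    def test_sampling_distribution_matches_adoption_probs(self):
        """The in-simulator adoption draw agrees with the scalar rule.

        One group, majority/minority variants, theta = 2: newborn learners'
        adoption frequencies must match n_i**theta normalization among their
        sampled partners. Uses a single step over many replicate populations.
        """
        params = ABMParams(
            n_groups=2, group_size=30, n_partners=29, theta=2.0, mu=0.0,
            migration=0.0, r_S=0.0, burn_in_years=0, record_years=0,
        )
        rng = np.random.default_rng(42)
        adopted = []
        for _ in range(400):
            pop = Population.initial(params)
            pop.variants[:30] = np.array([0] * 20 + [1] * 10)
            pop.variants[30:] = 2
            # exactly one learner: slot 0 at age 0 (always learns), everyone
            # else too old to relearn; r_S = 0 so nobody dies
            pop.ages[:] = 10_000
            pop.ages[0] = 0
            pop.step(params, rng)
            adopted.append(int(pop.variants[np.argmin(pop.ages)]))
        adopted = np.array(adopted)
        # learner holds variant 0 with 19 partners on 0, 10 on 1 (sampling is
        # exhaustive: 29 partners of 29 possible) plus self -> counts 20 vs 10
        expected = adoption_probs({0: 20, 1: 10}, 2.0)
        observed = np.array([(adopted == 0).mean(), (adopted == 1).mean()])
        chi2 = sps.chisquare(
            [np.sum(adopted == 0), np.sum(adopted == 1)],
            [400 * expected[0], 400 * expected[1]],
        )
        assert chi2.pvalue > 0.001


class TestMigrationContrast:
    def test_equal_rates_give_zero_effect(self, tiny_params):
        diffs = migration_contrast(1.0, 0.1, 0.1, tiny_params, 3, seed=0)
        np.testing.assert_allclose(diffs, 0.0)
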