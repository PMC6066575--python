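from collections import Counter

import numpy as np
import pytest
from scipy import stats

import fairplay
from fairplay import ModelParams, run_simulation
from fairplay.engine import (
    age_phase,
    fission_phase,
    forage_phase,
    mature_phase,
    play_phase,
    pool_phase,
    reproduce_phase,
    step,
)
from conftest import make_population


def juv(**kw):
    return {"adult": False, "age": 2, "gene": True, **kw}


class TestPlayPhase:
    def test_lone_gene_carrier_finds_no_partner(self, small_params, rng):
        pop = make_population(small_params, [
            juv(),
            juv(gene=False), juv(gene=False),
        ])
        bouts, deaths = play_phase(pop, rng)
        assert (bouts, deaths) == (0, 0)
        assert np.all(pop.bouts == 0)

    def test_pair_plays_one_bout_each(self, small_params, rng):
        pop = make_population(small_params.replace(c=0.0), [juv(), juv()])
        bouts, deaths = play_phase(pop, rng)
        assert (bouts, deaths) == (1, 0)
        assert list(pop.bouts) == [1, 1]
        assert pop.ever_played.all()
        assert pop.played_juveniles_total == 2

    def test_certain_mortality_kills_both_participants(self, small_params, rng):
        pop = make_population(small_params.replace(c=1.0), [juv(), juv()])
        bouts, deaths = play_phase(pop, rng)
        assert (bouts, deaths) == (1, 2)
        assert pop.size == 0 and pop.play_deaths_total == 2

    def test_gene_off_juveniles_and_adults_never_play(self, small_params, rng):
        pop = make_population(small_params.replace(c=1.0), [
            juv(gene=False), juv(gene=False),
            {"adult": True, "gene": True},
        ])
        assert play_phase(pop, rng) == (0, 0)
        assert pop.size == 3

    def test_pairing_respects_group_boundaries(self, small_params, rng):
        pop = make_population(small_params, [juv(group=0), juv(group=1)])
        assert play_phase(pop, rng) == (0, 0)

    def test_odd_group_leaves_exactly_one_unpaired(self, small_params, rng):
        pop = make_population(small_params.replace(c=0.0),
                              [juv() for _ in range(5)])
        bouts, _ = play_phase(pop, rng)
        assert bouts == 2
        assert sorted(pop.bouts) == [0, 1, 1, 1, 1]

    def test_partner_choice_is_uniform(self, small_params):
        # 3 eligible juveniles admit 3 possible bouts; the juvenile left
        # without a partner identifies which pair played, and each pairing
        # should occur with probability 1/3 (chi-square goodness of fit).
        params = small_params.replace(c=0.0)
        rng = np.random.default_rng(7)
        counts = Counter()
        n_trials = 3000
        for _ in range(n_trials):
            pop = make_population(params, [juv() for _ in range(3)])
            bouts, _ = play_phase(pop, rng)
            assert bouts == 1
            (left_out,) = pop.uid[pop.bouts == 0]
            counts[int(left_out)] += 1
        observed = [counts[u] for u in (0, 1, 2)]
        chi2 = stats.chisquare(observed).pvalue
        assert chi2 > 1e-3


class TestMaturePhase:
    def test_learned_fairness_at_maturation(self, small_params, rng):
        pop = make_population(small_params, [
            juv(age=5, bouts=2),            # alpha = 2 -> fair
            juv(age=5, bouts=1),            # below alpha
            juv(age=5, bouts=3, gene=False),  # no gene
        ])
        matured, cap_deaths = mature_phase(pop, rng)
        assert (matured, cap_deaths) == (3, 0)
        assert pop.adult.all()
        assert list(pop.is_fair) == [True, False, False]

    def test_control_condition_never_learns(self, small_params, rng):
        pop = make_population(small_params.replace(learn_fairness=False),
                              [juv(age=5, bouts=5)])
        mature_phase(pop, rng)
        assert pop.adult[0] and not pop.is_fair[0]

    def test_cap_kills_surplus_juveniles(self, rng):
        params = ModelParams(K=2, G=5, f=2, g=1, j=5, alpha=2, T=10.0, d=0,
                             n_init_groups=1, n_init_per_group=1,
                             init_age_range=(5, 9), tau=10, burn_in=5)
        pop = make_population(params, [
            {"adult": True}, {"adult": True},
            juv(age=5), juv(age=5),
        ])
        matured, cap_deaths = mature_phase(pop, rng)
        assert (matured, cap_deaths) == (0, 2)
        assert pop.n_adults == 2

    def test_room_below_cap_is_filled_without_bias(self, rng):
        params = ModelParams(K=3, G=5, f=3, g=1, j=5, alpha=2, T=10.0, d=0,
                             n_init_groups=1, n_init_per_group=1,
                             init_age_range=(5, 9), tau=10, burn_in=5)
        pop = make_population(params, [
            {"adult": True}, {"adult": True},
            juv(age=5), juv(age=5), juv(age=5),
        ])
        matured, cap_deaths = mature_phase(pop, rng)
        assert (matured, cap_deaths) == (1, 2)
        assert pop.n_adults == 3


class TestForagePhase:
    def test_zero_success_probability(self, small_params, rng):
        pop = make_population(small_params.replace(p=0.0),
                              [{"adult": True} for _ in range(100)])
        assert np.all(forage_phase(pop, rng) == 0.0)

    def test_juveniles_never_forage(self, small_params, rng):
        pop = make_population(small_params.replace(p=1.0),
                              [juv(), {"adult": True}])
        gains = forage_phase(pop, rng)
        assert gains[0] == 0.0 and gains[1] > 0.0

    def test_certain_success_draws_near_R(self, small_params, rng):
        pop = make_population(small_params.replace(p=1.0, R=40.0),
                              [{"adult": True} for _ in range(2000)])
        gains = forage_phase(pop, rng)
        assert np.all(gains > 0)
        assert gains.mean() == pytest.approx(40.0, abs=3 * 4.0 / np.sqrt(2000))
        assert gains.std() == pytest.approx(4.0, rel=0.15)

    def test_monte_carlo_mean_intake_is_pR(self):
        # R = 40, p = 0.0875: expected intake 3.5 units per step
        params = ModelParams(R=40.0, p=0.0875)
        pop = make_population(params, [{"adult": True} for _ in range(10_000)])
        rng = np.random.default_rng(3)
        draws = np.concatenate([forage_phase(pop, rng) for _ in range(100)])
        se = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(3.5, abs=3 * se)


class TestPoolPhase:
    def test_pool_of_one_is_identity(self, small_params):
        pop = make_population(small_params, [{"is_fair": True}])
        credits = pool_phase(pop, np.array([40.0]))
        assert credits[0] == pytest.approx(40.0)
        assert pop.resources[0] == pytest.approx(40.0)

    def test_two_fair_adults_split_evenly(self, small_params):
        pop = make_population(small_params,
                              [{"is_fair": True}, {"is_fair": True}])
        credits = pool_phase(pop, np.array([40.0, 0.0]))
        assert list(credits) == [20.0, 20.0]
        assert np.var(credits) == 0.0

    def test_selfish_adults_keep_own_gains(self, small_params):
        pop = make_population(small_params, [
            {"is_fair": True, "group": 0}, {"is_fair": True, "group": 0},
            {"is_fair": False, "group": 0},
        ])
        credits = pool_phase(pop, np.array([10.0, 0.0, 30.0]))
        assert list(credits) == [5.0, 5.0, 30.0]

    def test_pools_are_per_group(self, small_params):
        pop = make_population(small_params, [
            {"is_fair": True, "group": 0}, {"is_fair": True, "group": 1},
        ])
        credits = pool_phase(pop, np.array([12.0, 0.0]))
        assert list(credits) == [12.0, 0.0]

    def test_conservation(self, small_params, rng):
        pop = make_population(small_params, [
            {"is_fair": bool(i % 2), "group": i % 3} for i in range(30)
        ])
        gains = rng.uniform(0, 50, 30)
        credits = pool_phase(pop, gains)
        assert credits.sum() == pytest.approx(gains.sum(), rel=1e-12)


class TestReproducePhase:
    def test_below_threshold_no_offspring(self, small_params, rng):
        pop = make_population(small_params.replace(T=100.0),
                              [{"resources": 99.9}])
        assert reproduce_phase(pop, rng) == (0, 0)

    def test_at_threshold_one_offspring_parent_keeps_half(self, rng):
        params = ModelParams(T=100.0, P=0.5, d=15, r=0.0)
        pop = make_population(params, [{"resources": 100.0, "gene": True}])
        pop.step_index = 20
        births, on = reproduce_phase(pop, rng)
        assert (births, on) == (1, 1)
        assert pop.resources[0] == pytest.approx(50.0)

    def test_surplus_still_yields_single_offspring(self, small_params, rng):
        pop = make_population(small_params.replace(T=20.0),
                              [{"resources": 250.0}])
        births, _ = reproduce_phase(pop, rng)
        assert births == 1 and pop.size == 2

    def test_delay_gates_reproduction(self, small_params, rng):
        params = small_params.replace(T=20.0, d=10)
        pop = make_population(params, [{"resources": 100.0, "last_repro": 5}])
        pop.step_index = 14   # only 9 steps since last event
        assert reproduce_phase(pop, rng) == (0, 0)
        pop.step_index = 15   # exactly d steps: allowed
        births, _ = reproduce_phase(pop, rng)
        assert births == 1


class TestAgeAndFission:
    def test_agent_dies_exactly_at_lifespan(self, small_params):
        pop = make_population(small_params,
                              [{"age": 28, "lifespan": 30}])
        assert age_phase(pop) == (0, 0)   # age 29: survives
        assert age_phase(pop) == (1, 0)   # age 30 = lifespan: dies
        assert pop.size == 0

    def test_dying_adult_takes_juveniles(self, small_params):
        pop = make_population(small_params, [
            {"age": 29, "lifespan": 30},
            {"adult": False, "age": 1, "lifespan": 30, "parent_uid": 0},
        ])
        lifespan_deaths, parent_deaths = age_phase(pop)
        assert (lifespan_deaths, parent_deaths) == (1, 1)
        assert pop.size == 0

    def test_fission_splits_group_at_f(self, small_params, rng):
        # f=12, g=6: a 12-adult group splits into 6 + 6
        pop = make_population(small_params,
                              [{"group": 0} for _ in range(12)])
        assert fission_phase(pop, rng) == 1
        counts = np.bincount(pop.group, minlength=pop.next_group_id)
        assert sorted(counts[counts > 0]) == [6, 6]

    def test_no_fission_below_f(self, small_params, rng):
        pop = make_population(small_params,
                              [{"group": 0} for _ in range(11)])
        assert fission_phase(pop, rng) == 0

    def test_no_fission_at_group_cap(self, small_params, rng):
        # G = 6 groups already exist: the 12-adult group may not split
        agents = [{"group": 0} for _ in range(12)]
        agents += [{"group": i} for i in range(1, 6)]
        pop = make_population(small_params, agents)
        assert pop.n_groups == 6
        assert fission_phase(pop, rng) == 0

    def test_movers_take_dependent_juveniles(self, small_params, rng):
        agents = [{"group": 0} for _ in range(12)]
        agents += [{"adult": False, "age": 1, "parent_uid": u, "group": 0}
                   for u in range(12)]
        pop = make_population(small_params, agents)
        fission_phase(pop, rng)
        for i in np.flatnonzero(~pop.adult):
            parent = np.flatnonzero(pop.uid == pop.parent_uid[i])[0]
            assert pop.group[i] == pop.group[parent]


class TestRunSimulation:
    def test_gene_never_arises_without_mutation_or_founders(self, small_params):
        params = small_params.replace(r=0.0, F0=0.0)
        result = run_simulation(params, 5)
        assert result.gene_birth_frequency == 0.0

    def test_determinism_bit_for_bit(self, small_params):
        a = run_simulation(small_params, 99, record_trajectory=True)
        b = run_simulation(small_params, 99, record_trajectory=True)
        assert a.summary_dict() == b.summary_dict()
        assert a.trajectory.equals(b.trajectory)

    def test_different_seeds_differ(self, small_params):
        a = run_simulation(small_params, 1, record_trajectory=True)
        b = run_simulation(small_params, 2, record_trajectory=True)
        assert not a.trajectory.equals(b.trajectory)

    def test_caps_hold_every_step(self, small_params):
        result = run_simulation(small_params, 3, record_trajectory=True)
        assert (result.trajectory["adult_count"] <= small_params.K).all()

    def test_extinction_flagged_and_frequency_undefined(self):
        # No reproduction possible: threshold unreachable before lifespans end
        params = ModelParams(
            K=20, G=2, f=10, g=5, j=5, alpha=2, l=10, sd_l=0.0,
            T=1e6, d=0, p=0.0, R=1.0, c=0.0, F0=0.5,
            n_init_groups=2, n_init_per_group=5,
            init_age_range=(5, 8), tau=100, burn_in=50,
        )
        result = run_simulation(params, 0)
        assert result.extinct
        assert result.extinction_step < 10
        assert not result.frequency_defined
        assert np.isnan(result.gene_birth_frequency)

    def test_trajectory_schema(self, small_params):
        result = run_simulation(small_params, 8, record_trajectory=True)
        assert list(result.trajectory.columns) == [
            "step", "births", "play_bouts", "play_deaths", "matured",
            "cap_deaths", "lifespan_deaths", "fissions", "adult_count",
            "living_gene_frequency",
        ]
        assert len(result.trajectory) == small_params.tau
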