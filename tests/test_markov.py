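"""Cohort engine: transition structure, rewards, discounting, invariants."""

import dataclasses

import numpy as np
import pytest

from netcea import (
    HealthState,
    LifeTable,
    discount_factor,
    expected_strategy_result,
    run_cohort,
    transition_matrix,
)
from netcea.markov import N_STATES, reward_vectors


@pytest.fixture(scope="module")
def zero_mortality_table():
    return LifeTable(ages=np.arange(0, 101), qx=np.zeros(101))


def _no_death_config(config):
    """All death risks off, all utilities 1, no discounting."""
    return config.replace(
        discount_rate=0.0,
        transitions=dataclasses.replace(
            config.transitions,
            p_death_timely=0.0,
            p_death_delayed=0.0,
            p_death_untreated=0.0,
            p_death_competing=0.0,
            relative_risk_other_death=0.0,
        ),
        utilities=dataclasses.replace(
            config.utilities,
            no_burden=1.0,
            no_clinically_relevant_burden=1.0,
            clinically_relevant_treated=1.0,
            progression_untreated=1.0,
        ),
    )


class TestTransitionMatrix:
    def test_rows_sum_to_one_at_every_model_age(self, config, life_table):
        for age in range(config.start_age, config.horizon_age):
            P = transition_matrix(config, age, life_table)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0.0)

    def test_untreated_competing_risk_combination(self, config, zero_mortality_table):
        P = transition_matrix(config, 40, zero_mortality_table)
        row = P[HealthState.CLIN_REL_UNTREATED]
        expected_death = 1.0 - (1.0 - 0.1212) * (1.0 - 0.025)
        assert row[HealthState.DEATH] == pytest.approx(0.14317, abs=5e-6)
        assert row[HealthState.DEATH] == pytest.approx(expected_death, rel=1e-12)
        # survivors are all picked up and treated on the delayed track
        assert row[HealthState.CLIN_REL_TREATED_DELAYED] == pytest.approx(
            1.0 - expected_death, rel=1e-12
        )

    def test_death_is_absorbing(self, config, life_table):
        P = transition_matrix(config, 50, life_table)
        expected = np.zeros(N_STATES)
        expected[HealthState.DEATH] = 1.0
        assert np.array_equal(P[HealthState.DEATH], expected)

    def test_treated_survivors_reach_remission(self, config, zero_mortality_table):
        P = transition_matrix(config, 40, zero_mortality_table)
        for state, p_die in [
            (HealthState.CLIN_REL_TREATED_TIMELY, 0.04),
            (HealthState.CLIN_REL_TREATED_DELAYED, 0.045),
        ]:
            die = 1.0 - (1.0 - p_die) * (1.0 - 0.025)
            assert P[state, HealthState.DEATH] == pytest.approx(die, rel=1e-12)
            assert P[state, HealthState.NO_BURDEN_POST_TREATMENT] == pytest.approx(
                1.0 - die, rel=1e-12
            )

    def test_disease_free_progression(self, config, zero_mortality_table):
        P = transition_matrix(config, 40, zero_mortality_table)
        for state in (HealthState.NO_RELEVANT_BURDEN, HealthState.NO_BURDEN_POST_TREATMENT):
            die = 1.0 - (1.0 - 0.025)
            assert P[state, HealthState.CLIN_REL_TREATED_TIMELY] == pytest.approx(
                (1.0 - die) * 0.088, rel=1e-12
            )


class TestRewards:
    def test_state_rewards(self, config):
        costs, utils = reward_vectors(config)
        assert costs[HealthState.CLIN_REL_TREATED_TIMELY] == 61_375.0
        assert costs[HealthState.CLIN_REL_UNTREATED] == 61_375.0
        assert costs[HealthState.NO_BURDEN_POST_TREATMENT] == 2107.0
        assert costs[HealthState.NO_RELEVANT_BURDEN] == 0.0
        assert utils[HealthState.CLIN_REL_TREATED_TIMELY] == 0.768
        assert utils[HealthState.CLIN_REL_UNTREATED] == 0.612
        assert utils[HealthState.NO_RELEVANT_BURDEN] == 1.0
        assert utils[HealthState.DEATH] == 0.0
        assert costs[HealthState.DEATH] == 0.0

    def test_post_workup_track_only_changes_disease_free_utility(self, config):
        base_c, base_u = reward_vectors(config)
        track_c, track_u = reward_vectors(config, post_workup_cycle=True)
        assert np.array_equal(base_c, track_c)
        assert track_u[HealthState.NO_RELEVANT_BURDEN] == 0.779
        assert np.array_equal(np.delete(base_u, 0), np.delete(track_u, 0))

    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [(0.03, 1, 1.0), (0.03, 2, 1.0 / 1.03), (0.0, 7, 1.0)],
    )
    def test_discount_factor(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)


class TestCohortRun:
    def test_first_cycle_treatment_path_identities(self, config, life_table):
        tp = run_cohort(
            config, life_table, HealthState.CLIN_REL_TREATED_TIMELY, acute_cost=85_068.0
        )
        assert tp.frame["cum_cost_disc"].iloc[0] == pytest.approx(146_443.00, abs=1e-9)
        assert tp.frame["cum_qaly_disc"].iloc[0] == pytest.approx(0.768, abs=1e-12)
        fn = run_cohort(
            config, life_table, HealthState.CLIN_REL_UNTREATED, acute_cost=127_602.0
        )
        assert fn.frame["cum_cost_disc"].iloc[0] == pytest.approx(188_977.00, abs=1e-9)
        assert fn.frame["cum_qaly_disc"].iloc[0] == pytest.approx(0.612, abs=1e-12)

    def test_death_start_accrues_nothing(self, config, life_table):
        trace = run_cohort(config, life_table, HealthState.DEATH)
        assert trace.total_discounted_cost == 0.0
        assert trace.total_discounted_qaly == 0.0
        assert np.all(trace.frame["death"] == 1.0)

    def test_occupancy_conserved_and_death_monotone(self, config, life_table):
        trace = run_cohort(config, life_table, HealthState.NO_RELEVANT_BURDEN)
        occ = trace.occupancy()
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(occ >= -1e-15)
        assert np.all(np.diff(trace.frame["death"]) >= -1e-15)
        assert np.all(np.diff(trace.frame["cum_cost_disc"]) >= -1e-9)
        assert np.all(np.diff(trace.frame["cum_qaly_disc"]) >= -1e-12)

    def test_zero_death_unit_utility_gives_qalys_equal_cycles(self, config, life_table):
        cfg = _no_death_config(config)
        trace = run_cohort(cfg, life_table, HealthState.NO_RELEVANT_BURDEN)
        assert trace.total_discounted_qaly == pytest.approx(cfg.n_cycles, rel=1e-12)

    def test_life_table_must_cover_horizon(self, config):
        short = LifeTable(ages=np.arange(0, 60), qx=np.zeros(60))
        with pytest.raises(ValueError):
            run_cohort(config, short, HealthState.NO_RELEVANT_BURDEN)


class TestExpectedStrategyResult:
    def test_one_cycle_model_matches_hand_computation(self, config, life_table):
        cfg = config.replace(horizon_age=31)
        s = cfg.strategy("PET/CT")
        got = expected_strategy_result(cfg, s, life_table)
        p_tp, p_fn = 0.05 * 0.91, 0.05 * 0.09
        p_tn, p_fp = 0.95 * 0.92, 0.95 * 0.08
        cost = (
            p_tp * (1375 + 1375 + 85_068 + 61_375)
            + p_fn * (1375 + 127_602 + 61_375)
            + p_tn * 1375
            + p_fp * (1375 + 1375)
        )
        qaly = p_tp * 0.768 + p_fn * 0.612 + p_tn * 1.0 + p_fp * 0.779
        assert got.cost == pytest.approx(cost, rel=1e-12)
        assert got.qaly == pytest.approx(qaly, rel=1e-12)

    def test_perfect_test_has_no_error_branches(self, config, life_table):
        import dataclasses as dc

        s = config.strategy("PET/CT")
        perfect = dc.replace(s, performance=dc.replace(s.performance, sensitivity=1.0, specificity=1.0))
        cfg = config.replace(
            strategies=tuple(perfect if x.name == s.name else x for x in config.strategies)
        )
        got = expected_strategy_result(cfg, perfect, life_table)
        # cost decomposes exactly into the TP and TN branches
        tp_trace = run_cohort(
            cfg, life_table, HealthState.CLIN_REL_TREATED_TIMELY,
            acute_cost=1375 + 1375 + 85_068,
        )
        tn_trace = run_cohort(
            cfg, life_table, HealthState.NO_RELEVANT_BURDEN, acute_cost=1375
        )
        assert got.cost == pytest.approx(
            0.05 * tp_trace.total_discounted_cost + 0.95 * tn_trace.total_discounted_cost,
            rel=1e-12,
        )

    def test_qalys_weakly_increase_in_any_state_utility(self, config, life_table):
        base = {
            s.name: expected_strategy_result(config, s, life_table).qaly
            for s in config.strategies
        }
        for fld in (
            "no_clinically_relevant_burden",
            "clinically_relevant_treated",
            "progression_untreated",
        ):
            bumped = config.replace(
                utilities=dataclasses.replace(
                    config.utilities, **{fld: min(1.0, getattr(config.utilities, fld) + 0.05)}
                )
            )
            for s in bumped.strategies:
                assert (
                    expected_strategy_result(bumped, s, life_table).qaly
                    >= base[s.name] - 1e-12
                )
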