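"""Cohort engine: schedules, traces, conservation, absorption, effectiveness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftcea.inputs import ValidationError
from graftcea.markov import (
    CycleProbabilities,
    HealthState,
    TransitionSchedule,
    build_schedule,
    graft_survival_years,
    pooled_post_year4,
    run_cohort,
)

ZERO = CycleProbabilities(0, 0, 0, 0, 0)


def constant_schedule(cp, horizon, arm="no_induction"):
    return TransitionSchedule(arm=arm, cycles=[cp] * horizon)


unit = st.floats(min_value=0.0, max_value=1.0)


@st.composite
def random_schedules(draw, max_horizon=8):
    horizon = draw(st.integers(min_value=1, max_value=max_horizon))
    cycles = []
    for c in range(horizon):
        cycles.append(
            CycleProbabilities(
                death_functioning=draw(unit),
                graft_loss_no_ar=draw(unit),
                graft_loss_ar=draw(unit),
                death_after_graft_loss=draw(unit),
                retransplant=draw(unit),
                cmv=draw(unit) if c == 0 else 0.0,
                acute_rejection=draw(unit) if c == 0 else 0.0,
            )
        )
    return TransitionSchedule(arm="no_induction", cycles=cycles)


class TestBuildSchedule:
    def test_year1_event_probabilities_from_counts(self, events, config):
        sched = build_schedule(events, "no_induction", config, horizon=10)
        cp = sched.cycles[0]
        assert cp.acute_rejection == pytest.approx(236 / 466)
        assert cp.cmv == pytest.approx(127 / 466)
        assert cp.graft_loss_no_ar == pytest.approx(21 / 466)
        assert cp.death_functioning == pytest.approx(7 / 466)
        assert cp.death_after_graft_loss == pytest.approx(4 / 21)

    def test_r_atg_cycle2_retransplant_probability_is_zero(self, events, config):
        sched = build_schedule(events, "r_atg", config, horizon=4)
        assert sched.cycles[1].retransplant == 0.0
        assert sched.cycles[1].death_after_graft_loss == pytest.approx(1 / 13)

    def test_cycle4_uses_arm_specific_recurring_row(self, events, config):
        sched = build_schedule(events, "no_induction", config, horizon=10)
        assert sched.cycles[3].death_functioning == pytest.approx(4 / 466)
        assert sched.cycles[3].retransplant == pytest.approx(2 / 21)

    def test_cycles_past_observed_window_are_pooled_and_arm_independent(
        self, events, config
    ):
        ni = build_schedule(events, "no_induction", config, horizon=10)
        tx = build_schedule(events, "r_atg", config, horizon=10)
        pooled = pooled_post_year4(events)
        for c in range(4, 10):
            assert ni.cycles[c] == tx.cycles[c]
            assert ni.cycles[c].death_functioning == pytest.approx(
                pooled["death_functioning"]
            )
        assert pooled["death_functioning"] == pytest.approx(7 / 932)
        assert pooled["retransplant"] == pytest.approx(2 / 34)

    def test_config_override_replaces_pooled_probabilities(self, events, config):
        import dataclasses

        override = dataclasses.replace(
            config,
            post_year4_probabilities={
                "death_functioning": 0.02,
                "graft_loss_prior_ar": 0.01,
                "graft_loss_no_prior_ar": 0.01,
                "death_after_graft_loss": 0.1,
                "retransplant": 0.05,
            },
        )
        sched = build_schedule(events, "r_atg", override, horizon=10)
        assert sched.cycles[9].death_functioning == 0.02

    def test_all_zero_counts_give_valid_identity_schedule(self, config):
        from graftcea.inputs import ArmYearEvents

        rows = [
            ArmYearEvents(arm="no_induction", year=1, n_at_risk=100),
            ArmYearEvents(
                arm="no_induction", year=2, n_at_risk=100, recurring=True
            ),
        ]
        sched = build_schedule(rows, "no_induction", config, horizon=5)
        trace = run_cohort(sched, horizon=5)
        assert trace.occupancy[5, HealthState.FUNCTIONING_NO_AR_HISTORY] == 1.0


class TestRunCohort:
    def test_zero_event_schedule_stays_fully_functioning(self):
        trace = run_cohort(constant_schedule(ZERO, 10))
        assert np.all(
            trace.occupancy[:, HealthState.FUNCTIONING_NO_AR_HISTORY] == 1.0
        )

    def test_certain_death_first_cycle(self):
        cp = CycleProbabilities(1.0, 0, 0, 0, 0)
        trace = run_cohort(constant_schedule(cp, 3))
        assert trace.occupancy[1, HealthState.DEAD] == 1.0
        assert graft_survival_years(trace, 0.0) == 0.0

    def test_transition_matrix_rows_are_stochastic(self, events, config):
        for arm in ("no_induction", "r_atg"):
            sched = build_schedule(events, arm, config, horizon=10)
            for c in range(1, 11):
                assert np.allclose(sched.matrix(c).sum(axis=1), 1.0)

    @given(random_schedules())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_mass_conservation_and_absorption_for_arbitrary_schedules(self, sched):
        trace = run_cohort(sched)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, HealthState.DEAD]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_death_floor_drives_absorption(self):
        cp = CycleProbabilities(0.3, 0.1, 0.2, 0.4, 0.1, 0.0, 0.5)
        trace = run_cohort(constant_schedule(cp, 60))
        assert trace.occupancy[-1, HealthState.DEAD] > 0.999

    def test_invalid_probability_is_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            run_cohort(constant_schedule(CycleProbabilities(1.5, 0, 0, 0, 0), 2))

    def test_trace_export_roundtrip(self, events, config, tmp_path):
        sched = build_schedule(events, "r_atg", config, horizon=4)
        trace = run_cohort(sched)
        trace.to_csv(tmp_path / "trace.csv")
        trace.to_json(tmp_path / "trace.json")
        frame = trace.to_frame()
        assert len(frame) == 5 * 5  # (horizon+1) cycles x 5 states
        assert frame["occupancy"].between(0, 1).all()


class TestGraftSurvivalYears:
    def test_zero_event_horizon1_rate0(self):
        trace = run_cohort(constant_schedule(ZERO, 1))
        assert graft_survival_years(trace, 0.0) == 1.0

    def test_geometric_series_at_5_percent(self):
        trace = run_cohort(constant_schedule(ZERO, 10))
        expected = sum(1 / 1.05 ** (c - 1) for c in range(1, 11))
        assert graft_survival_years(trace, 0.05) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(8.1078, abs=1e-4)

    def test_discounted_at_rate_zero_equals_undiscounted(self, events, config):
        sched = build_schedule(events, "no_induction", config, horizon=10)
        trace = run_cohort(sched)
        undiscounted = trace.functioning()[1:].sum()
        assert graft_survival_years(trace, 0.0) == pytest.approx(
            undiscounted, abs=1e-12
        )

    def test_zero_event_effectiveness_equals_horizon(self):
        for horizon in (1, 4, 10):
            trace = run_cohort(constant_schedule(ZERO, horizon))
            assert graft_survival_years(trace, 0.0) == float(horizon)


class TestMicrosimOracle:
    """The cohort trace must equal the patient-level expectation."""

    def test_study_schedules_within_3se_of_100k_patient_simulation(
        self, events, config
    ):
        from graftcea.microsim import SimulationRecipe, simulate_cohort

        n = 100_000
        recipe = SimulationRecipe.from_events(
            events, config, horizon=10, n_per_arm=n, seed=20140617
        )
        sim = simulate_cohort(recipe)
        for arm in ("no_induction", "r_atg"):
            sched = build_schedule(events, arm, config, horizon=10)
            trace = run_cohort(sched)
            observed = sim.occupancy(arm)
            se = np.sqrt(trace.occupancy * (1 - trace.occupancy) / n)
            assert np.all(
                np.abs(observed - trace.occupancy) <= 3 * se + 1e-12
            ), f"occupancy outside 3 SE for arm {arm}"

    @pytest.mark.parametrize("seed", range(5))
    def test_random_schedules_agree_with_microsimulation(self, seed):
        from graftcea.microsim import SimulationRecipe, simulate_cohort

        rng = np.random.default_rng(seed)
        horizon = 6
        cycles = [
            CycleProbabilities(
                death_functioning=rng.uniform(0, 0.3),
                graft_loss_no_ar=rng.uniform(0, 0.3),
                graft_loss_ar=rng.uniform(0, 0.4),
                death_after_graft_loss=rng.uniform(0, 0.3),
                retransplant=rng.uniform(0, 0.3),
                cmv=rng.uniform(0, 0.5) if c == 0 else 0.0,
                acute_rejection=rng.uniform(0, 0.6) if c == 0 else 0.0,
            )
            for c in range(horizon)
        ]
        sched = TransitionSchedule(arm="no_induction", cycles=cycles)
        n = 50_000
        recipe = SimulationRecipe(
            schedules={"no_induction": sched},
            n_per_arm={"no_induction": n},
            horizon=horizon,
            seed=1000 + seed,
        )
        sim = simulate_cohort(recipe)
        trace = run_cohort(sched)
        observed = sim.occupancy("no_induction")
        se = np.sqrt(trace.occupancy * (1 - trace.occupancy) / n)
        # ~175 correlated occupancy cells checked family-wise across the
        # five schedules, so allow 4.5 SE rather than a per-cell 3 SE
        assert np.all(np.abs(observed - trace.occupancy) <= 4.5 * se + 1e-12)
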