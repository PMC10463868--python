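import numpy as np
import pytest

from hnc_cea.exceptions import (
    ConfigurationError,
    InvalidInputError,
    MatrixValidationError,
    ModelError,
)
from hnc_cea.markov import (
    CohortTrace,
    HealthState,
    ModelSpec,
    StatePayoffs,
    TransitionMatrix,
    expected_outcomes,
    expected_time_in_states,
    run_cohort,
    validate_matrix,
)

from .conftest import random_stochastic_matrix


def two_state_spec(**kw):
    defaults = dict(
        states=(HealthState("Alive"), HealthState("Death", absorbing=True)),
        cycle_length_years=1.0,
        n_cycles=10,
        discount_rate_annual=0.0,
        initial_distribution=(1.0, 0.0),
    )
    defaults.update(kw)
    return ModelSpec(**defaults)


def six_state_spec(**kw):
    states = tuple(
        [HealthState(n) for n in ("LXLD", "LXHD", "HXLD", "HXHD")]
        + [HealthState("LTF", lost_to_follow_up=True), HealthState("Death", absorbing=True)]
    )
    init = np.array([0.25, 0.25, 0.25, 0.25, 0.0, 0.0])
    defaults = dict(states=states, cycle_length_years=0.25, n_cycles=20,
                    discount_rate_annual=0.0, initial_distribution=init)
    defaults.update(kw)
    return ModelSpec(**defaults)


def ltf_matrix(death=0.03, ltf_death=None):
    """Six-state matrix where every alive row sends `death` to Death."""
    if ltf_death is None:
        ltf_death = death
    P = np.zeros((6, 6))
    for i in range(4):
        P[i, 5] = death
        P[i, 4] = 0.05
        P[i, i] = 1.0 - death - 0.05
    P[4, 5] = ltf_death
    P[4, 4] = 1.0 - ltf_death
    P[5, 5] = 1.0
    return TransitionMatrix("s", P)


class TestValidation:
    def test_identity_matrix_is_valid(self):
        spec = two_state_spec()
        validate_matrix(TransitionMatrix("s", np.eye(2)), spec)

    def test_row_sum_violation_names_the_row(self):
        spec = two_state_spec()
        with pytest.raises(MatrixValidationError, match="Alive"):
            validate_matrix(TransitionMatrix("s", np.array([[0.5, 0.48], [0.0, 1.0]])), spec)

    def test_negative_entry_rejected(self):
        spec = two_state_spec()
        with pytest.raises(MatrixValidationError, match="negative"):
            validate_matrix(TransitionMatrix("s", np.array([[1.1, -0.1], [0.0, 1.0]])), spec)

    def test_death_must_be_absorbing(self):
        spec = two_state_spec()
        with pytest.raises(MatrixValidationError, match="absorbing"):
            validate_matrix(TransitionMatrix("s", np.array([[1.0, 0.0], [0.1, 0.9]])), spec)

    def test_ltf_death_rate_equality(self):
        spec = six_state_spec()
        validate_matrix(ltf_matrix(0.03), spec)
        with pytest.raises(MatrixValidationError, match="LTF"):
            validate_matrix(ltf_matrix(0.03, ltf_death=0.05), spec)

    def test_ltf_rate_checked_against_configured_value(self):
        spec = six_state_spec(cohort_death_prob=0.03)
        validate_matrix(ltf_matrix(0.03), spec)
        spec2 = six_state_spec(cohort_death_prob=0.02)
        with pytest.raises(MatrixValidationError, match="LTF"):
            validate_matrix(ltf_matrix(0.03), spec2)

    def test_ambiguous_cohort_rate_is_configuration_error(self):
        P = ltf_matrix(0.03).entries.copy()
        P[0, 5] = 0.05  # one alive row deviates
        P[0, 0] = 1.0 - 0.05 - 0.05
        with pytest.raises(ConfigurationError, match="ambiguous"):
            validate_matrix(TransitionMatrix("s", P), six_state_spec())

    def test_spec_structural_invariants(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(states=(HealthState("Alive"),))  # no Death
        with pytest.raises(InvalidInputError):
            two_state_spec(initial_distribution=(0.6, 0.3))


class TestCohortTrace:
    def test_identity_matrix_is_a_fixed_point(self):
        spec = two_state_spec(initial_distribution=(0.7, 0.3))
        trace = run_cohort(spec, TransitionMatrix("s", np.eye(2)))
        assert np.allclose(trace.occupancy, [0.7, 0.3])

    def test_geometric_decay(self):
        spec = two_state_spec(n_cycles=3)
        m = TransitionMatrix("s", np.array([[0.5, 0.5], [0.0, 1.0]]))
        trace = run_cohort(spec, m)
        assert trace.occupancy[:, 0] == pytest.approx([1.0, 0.5, 0.25, 0.125])

    def test_matches_naive_step_by_step_oracle(self):
        """Engine trace equals an explicit per-state hand multiplication."""
        rng = np.random.default_rng(42)
        states = tuple([HealthState(f"S{i}") for i in range(3)] + [HealthState("Death", absorbing=True)])
        init = rng.dirichlet(np.ones(4))
        spec = ModelSpec(states=states, cycle_length_years=1.0, n_cycles=10,
                         discount_rate_annual=0.0, initial_distribution=init)
        P = random_stochastic_matrix(rng, 4)
        trace = run_cohort(spec, TransitionMatrix("s", P))

        occ = list(init)
        for t in range(1, 11):
            nxt = [sum(occ[i] * P[i, j] for i in range(4)) for j in range(4)]
            occ = nxt
            assert trace.occupancy[t] == pytest.approx(occ, abs=1e-12)

    def test_rows_conserve_mass_and_death_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            states = tuple([HealthState(f"S{i}") for i in range(5)] + [HealthState("Death", absorbing=True)])
            spec = ModelSpec(states=states, cycle_length_years=0.5, n_cycles=30,
                             initial_distribution=rng.dirichlet(np.ones(6)))
            P = random_stochastic_matrix(rng, 6)
            trace = run_cohort(spec, TransitionMatrix("s", P))
            assert np.max(np.abs(trace.occupancy.sum(axis=1) - 1.0)) < 1e-9
            death = trace.occupancy[:, -1]
            assert np.all(np.diff(death) >= -1e-12)


class TestExpectedTime:
    def test_geometric_survival(self):
        spec = two_state_spec()
        m = TransitionMatrix("s", np.array([[0.5, 0.5], [0.0, 1.0]]))
        assert expected_time_in_states(m, spec)["Alive"] == pytest.approx(2.0)

    def test_deterministic_chain(self):
        states = (HealthState("A"), HealthState("B"), HealthState("Death", absorbing=True))
        spec = ModelSpec(states=states, cycle_length_years=1.0, n_cycles=5,
                         initial_distribution=(1.0, 0.0, 0.0))
        P = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        times = expected_time_in_states(TransitionMatrix("s", P), spec)
        assert times["A"] == pytest.approx(1.0) and times["B"] == pytest.approx(1.0)

    def test_agrees_with_long_horizon_occupancy_sums(self):
        rng = np.random.default_rng(11)
        states = tuple([HealthState(f"S{i}") for i in range(3)] + [HealthState("Death", absorbing=True)])
        init = np.array([0.5, 0.3, 0.2, 0.0])
        spec = ModelSpec(states=states, cycle_length_years=1.0, n_cycles=10_000,
                         initial_distribution=init)
        P = random_stochastic_matrix(rng, 4)
        m = TransitionMatrix("s", P)
        trace = run_cohort(spec, m)
        sums = trace.occupancy.sum(axis=0)  # start-of-cycle occupancy incl. cycle 0
        times = expected_time_in_states(m, spec)
        for k, name in enumerate(("S0", "S1", "S2")):
            assert times[name] == pytest.approx(sums[k], abs=1e-6)

    def test_no_absorption_is_a_model_error(self):
        spec = two_state_spec()
        with pytest.raises(ModelError):
            expected_time_in_states(TransitionMatrix("s", np.eye(2)), spec)


class TestOutcomes:
    def test_full_health_full_horizon(self):
        spec = two_state_spec()
        trace = run_cohort(spec, TransitionMatrix("s", np.eye(2)))
        payoffs = StatePayoffs(utility_per_year={"Alive": 1.0})
        cost, qaly = expected_outcomes(trace, payoffs, spec)
        assert (cost, qaly) == (0.0, pytest.approx(10.0))

    def test_geometric_series_closed_form(self):
        s, u, n = 0.8, 0.9, 12
        spec = two_state_spec(n_cycles=n)
        m = TransitionMatrix("s", np.array([[s, 1 - s], [0.0, 1.0]]))
        trace = run_cohort(spec, m)
        _, qaly = expected_outcomes(trace, StatePayoffs(utility_per_year={"Alive": u}), spec)
        closed = u * sum(s**t for t in range(1, n + 1))
        assert qaly == pytest.approx(closed, abs=1e-12)

    def test_calibrated_single_state_reproduces_base_case(self, calibrated):
        res = calibrated.model.evaluate()
        assert res["3D-CRT"].cost == pytest.approx(9209.76, abs=1e-9)
        assert res["3D-CRT"].qaly == pytest.approx(3.63, abs=1e-9)
        assert res["IMRT"].cost == pytest.approx(12562.90, abs=1e-9)
        assert res["IMRT"].qaly == pytest.approx(3.17, abs=1e-9)

    def test_discounted_totals_never_exceed_undiscounted(self):
        rng = np.random.default_rng(5)
        P = random_stochastic_matrix(rng, 4)
        states = tuple([HealthState(f"S{i}") for i in range(3)] + [HealthState("Death", absorbing=True)])
        payoffs = StatePayoffs(
            utility_per_year={f"S{i}": 0.2 * (i + 1) for i in range(3)},
            cost_per_cycle={f"S{i}": 100.0 * (i + 1) for i in range(3)},
        )
        base = dict(states=states, cycle_length_years=0.5, n_cycles=20,
                    initial_distribution=(1.0, 0.0, 0.0, 0.0))
        m = TransitionMatrix("s", P)
        spec0 = ModelSpec(**base, discount_rate_annual=0.0)
        spec3 = ModelSpec(**base, discount_rate_annual=0.03)
        trace = run_cohort(spec0, m)
        c0, q0 = expected_outcomes(trace, payoffs, spec0)
        c3, q3 = expected_outcomes(trace, payoffs, spec3)
        assert c3 < c0 and q3 < q0

    def test_half_cycle_lies_between_conventions(self):
        rng = np.random.default_rng(9)
        P = random_stochastic_matrix(rng, 4)
        states = tuple([HealthState(f"S{i}") for i in range(3)] + [HealthState("Death", absorbing=True)])
        payoffs = StatePayoffs(utility_per_year={"S0": 0.8, "S1": 0.6, "S2": 0.4},
                               cost_per_cycle={"S0": 500.0, "S1": 800.0, "S2": 1200.0})
        spec = ModelSpec(states=states, cycle_length_years=0.25, n_cycles=40,
                         discount_rate_annual=0.03, initial_distribution=(1.0, 0.0, 0.0, 0.0))
        trace = run_cohort(spec, TransitionMatrix("s", P))
        c_end, q_end = expected_outcomes(trace, payoffs, spec, convention="end")
        c_start, q_start = expected_outcomes(trace, payoffs, spec, convention="start")
        c_half, q_half = expected_outcomes(trace, payoffs, spec, convention="half")
        assert min(c_end, c_start) <= c_half <= max(c_end, c_start)
        assert min(q_end, q_start) <= q_half <= max(q_end, q_start)
        assert c_half == pytest.approx(0.5 * (c_end + c_start), abs=1e-9)

    def test_fundamental_matrix_oracle_for_undiscounted_qalys(self):
        """Start-of-cycle QALYs at utility 1 equal cycle_length x expected time."""
        rng = np.random.default_rng(13)
        P = random_stochastic_matrix(rng, 5)
        states = tuple([HealthState(f"S{i}") for i in range(4)] + [HealthState("Death", absorbing=True)])
        spec = ModelSpec(states=states, cycle_length_years=0.5, n_cycles=4000,
                         discount_rate_annual=0.0, initial_distribution=(0.4, 0.3, 0.2, 0.1, 0.0))
        m = TransitionMatrix("s", P)
        trace = run_cohort(spec, m)
        payoffs = StatePayoffs(utility_per_year={f"S{i}": 1.0 for i in range(4)})
        _, qaly = expected_outcomes(trace, payoffs, spec, convention="start")
        times = expected_time_in_states(m, spec)
        assert qaly == pytest.approx(0.5 * sum(times.values()), abs=1e-6)

    def test_death_payoffs_must_be_zero(self):
        with pytest.raises(InvalidInputError):
            StatePayoffs(utility_per_year={"Death": 0.1})
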