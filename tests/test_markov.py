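"""Markov cohort engine, decision metrics, and the probabilistic sensitivity analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afscreen.markov import (
    AFModelParams,
    DistributionSpec,
    EconomicParams,
    HealthStateSpace,
    ModelValidationError,
    PSAConfig,
    ScreeningStrategy,
    TransitionModel,
    build_economic_params,
    build_transition_model,
    ceac,
    default_strategies,
    discount,
    evaluate_strategy,
    icer,
    inb,
    load_model_file,
    national_projection,
    run_cohort,
    run_psa,
    save_model_file,
    strategy_outcomes,
)

TWO_STATES = HealthStateSpace(states=("alive", "dead"))


def two_state_model(p_death: float, n_cycles: int) -> tuple[TransitionModel, EconomicParams]:
    tm = TransitionModel(
        space=TWO_STATES,
        matrix=np.array([[1 - p_death, p_death], [0.0, 1.0]]),
        n_cycles=n_cycles,
    )
    econ = EconomicParams(
        space=TWO_STATES,
        state_costs={"alive": 0.0, "dead": 0.0},
        state_utilities={"alive": 1.0, "dead": 0.0},
        discount_rate_costs=0.0,
        discount_rate_qalys=0.0,
    )
    return tm, econ


class TestValidation:
    def test_row_sum_violation_rejected_before_running(self):
        with pytest.raises(ModelValidationError, match="sums to"):
            TransitionModel(TWO_STATES, np.array([[0.5, 0.4], [0.0, 1.0]]))

    def test_dead_must_be_absorbing(self):
        with pytest.raises(ModelValidationError, match="absorbing"):
            TransitionModel(TWO_STATES, np.array([[0.9, 0.1], [0.1, 0.9]]))

    def test_utilities_outside_unit_interval_rejected(self):
        with pytest.raises(ModelValidationError):
            EconomicParams(TWO_STATES, {"alive": 0, "dead": 0}, {"alive": 1.2, "dead": 0})

    def test_bad_initial_distribution(self):
        tm, econ = two_state_model(0.1, 5)
        with pytest.raises(ModelValidationError):
            run_cohort(tm, econ, [0.7, 0.7])


class TestRunCohort:
    def test_identity_matrix_constant_occupancy(self):
        tm = TransitionModel(TWO_STATES, np.eye(2), n_cycles=8)
        _, econ = two_state_model(0.0, 8)
        trace = run_cohort(tm, econ, [0.6, 0.4])
        assert np.allclose(trace.occupancy, [0.6, 0.4])

    @pytest.mark.parametrize("p,T", [(0.1, 10), (0.35, 7), (0.0, 5)])
    def test_two_state_geometric_closed_form(self, p, T):
        """Undiscounted QALYs equal the geometric series sum over survival."""
        tm, econ = two_state_model(p, T)
        trace = run_cohort(tm, econ, [1.0, 0.0])
        expected = sum((1 - p) ** t for t in range(T))
        assert trace.discounted_qalys == pytest.approx(expected)

    def test_absorbing_occupancy_monotone(self):
        params = AFModelParams()
        tm = build_transition_model(params)
        econ = build_economic_params(params)
        trace = run_cohort(tm, econ, [0.013, 0, 0, 0.987, 0, 0])
        dead = trace.occupancy[:, tm.space.index("dead")]
        assert (np.diff(dead) >= -1e-12).all()
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_half_cycle_correction_between_bounds(self):
        tm, econ = two_state_model(0.2, 10)
        plain = run_cohort(tm, econ, [1.0, 0.0]).discounted_qalys
        half = run_cohort(tm, econ, [1.0, 0.0], half_cycle=True).discounted_qalys
        assert half < plain  # start-of-cycle accrual overstates time alive


class TestDiscount:
    def test_basic_values(self):
        assert discount(100, 0.035, 1) == pytest.approx(96.618357, abs=1e-5)
        assert discount(100, 0.0, 7) == 100
        assert discount(100, 0.05, 0) == 100

    @given(rate=st.floats(0.0, 0.2), rate2=st.floats(0.0, 0.2))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_discounted_totals_monotone_in_rate(self, rate, rate2):
        lo, hi = sorted((rate, rate2))
        tm, econ = two_state_model(0.1, 15)
        e_lo = dataclasses.replace(econ, discount_rate_qalys=lo)
        e_hi = dataclasses.replace(econ, discount_rate_qalys=hi)
        q_lo = run_cohort(tm, e_lo, [1.0, 0.0]).discounted_qalys
        q_hi = run_cohort(tm, e_hi, [1.0, 0.0]).discounted_qalys
        assert q_hi <= q_lo + 1e-12


class TestDecisionMetrics:
    def test_icer_at_threshold(self):
        assert icer(1000, 0.05).value == pytest.approx(20_000)

    def test_dominance_flags(self):
        assert icer(-10, 0.01).classification == "dominant"
        assert icer(10, -0.01).classification == "dominated"
        assert icer(10, 0).classification == "undefined"

    def test_inb_values(self):
        assert inb(0, 0, 20_000) == 0
        assert inb(1000, 0.1, 20_000) == pytest.approx(1000)

    @given(dc=st.floats(-5000, 5000), dq=st.floats(0.001, 1.0), lam=st.floats(0, 100_000))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_inb_positive_iff_icer_below_threshold(self, dc, dq, lam):
        res = icer(dc, dq)
        net = inb(dc, dq, lam)
        if res.classification == "dominant":
            assert net >= 0
        elif res.classification == "ratio":
            assert (net > 0) == (res.value < lam)

    def test_national_projection_linearity(self):
        assert national_projection(1000, 1e6, 0.5, 0.01) == pytest.approx(5_000_000)
        assert national_projection(1000, 1e6, 0.0) == 0
        assert national_projection(1000, 2e6, 0.5) == 2 * national_projection(1000, 1e6, 0.5)


class TestEvaluateStrategy:
    def test_inert_test_costs_screening_only(self):
        params = AFModelParams()
        none = ScreeningStrategy("none", 0.0, 1.0, uptake=0.0)
        inert = ScreeningStrategy("inert", 0.0, 1.0, uptake=1.0, screening_cost=5.0)
        c0, q0 = evaluate_strategy(none, params)
        c1, q1 = evaluate_strategy(inert, params)
        assert q1 == pytest.approx(q0)
        assert c1 - c0 == pytest.approx(5.0)

    def test_zero_uptake_identical_to_no_screening(self):
        params = AFModelParams()
        a = evaluate_strategy(ScreeningStrategy("a", 0.9, 0.95, uptake=0.0), params)
        b = evaluate_strategy(ScreeningStrategy("no_screening", 0.0, 1.0, uptake=0.0), params)
        assert a == b

    def test_perfect_free_test_gains_qalys(self):
        params = AFModelParams()
        perfect = ScreeningStrategy("perfect", 1.0, 1.0, confirmation_pathway_cost=0.0)
        none = ScreeningStrategy("none", 0.0, 1.0, uptake=0.0)
        _, q_perfect = evaluate_strategy(perfect, params)
        _, q_none = evaluate_strategy(none, params)
        assert q_perfect > q_none

    def test_forward_and_backward_evaluations_agree(self):
        params = AFModelParams()
        tm = build_transition_model(params)
        econ = build_economic_params(params)
        trace = run_cohort(tm, econ, [params.prevalence_undetected_af, 0, 0,
                                      1 - params.prevalence_undetected_af, 0, 0])
        c, q = evaluate_strategy(ScreeningStrategy("none", 0.0, 1.0, uptake=0.0), params)
        assert c == pytest.approx(trace.discounted_cost)
        assert q == pytest.approx(trace.discounted_qalys)


class TestPSA:
    def test_degenerate_psa_equals_deterministic_run(self):
        params = AFModelParams()
        strategies = default_strategies()
        samples = run_psa(params, strategies, PSAConfig(n_draws=3, seed=0,
                                                        parameter_spec={}, strategy_spec={}))
        for j, s in enumerate(strategies):
            c, q = evaluate_strategy(s, params)
            assert (samples.costs[:, j] == c).all()
            assert (samples.qalys[:, j] == q).all()

    def test_same_seed_reproducible(self):
        params = AFModelParams()
        a = run_psa(params, psa=PSAConfig(n_draws=500, seed=42))
        b = run_psa(params, psa=PSAConfig(n_draws=500, seed=42))
        assert (a.costs == b.costs).all() and (a.qalys == b.qalys).all()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ModelValidationError, match="not_a_param"):
            run_psa(psa=PSAConfig(n_draws=10, parameter_spec={"not_a_param": DistributionSpec("point", 1)}))

    def test_ceac_matches_brute_force_recount(self):
        samples = run_psa(psa=PSAConfig(n_draws=2000, seed=7))
        grid, prob = ceac(samples, "slecg_device", wtp_grid=[0, 10_000, 20_000, 40_000])
        dc, dq = samples.deltas("slecg_device", "no_screening")
        for lam, p in zip(grid, prob):
            count = sum(1 for i in range(samples.n_draws) if lam * dq[i] - dc[i] > 0)
            assert p == count / samples.n_draws

    def test_ceac_at_zero_threshold_is_cost_saving_fraction(self):
        samples = run_psa(psa=PSAConfig(n_draws=2000, seed=8))
        _, prob = ceac(samples, "pulse_palpation", wtp_grid=[0.0])
        dc, _ = samples.deltas("pulse_palpation", "no_screening")
        assert prob[0] == (dc < 0).mean()

    def test_small_and_large_psa_agree_within_monte_carlo_error(self):
        params = AFModelParams()
        small = run_psa(params, psa=PSAConfig(n_draws=1000, seed=3))
        large = run_psa(params, psa=PSAConfig(n_draws=20_000, seed=4))
        p_small = strategy_outcomes(small)["slecg_device"].prob_cost_effective
        p_large = strategy_outcomes(large)["slecg_device"].prob_cost_effective
        se = np.sqrt(max(p_large * (1 - p_large), 1e-4) / 1000)
        assert abs(p_small - p_large) <= 4 * se + 0.01

    def test_outcomes_consistency(self):
        samples = run_psa(psa=PSAConfig(n_draws=1000, seed=5))
        out = strategy_outcomes(samples, wtp=20_000)
        for o in out.values():
            assert o.inb == pytest.approx(20_000 * o.delta_qaly - o.delta_cost)
            assert 0.0 <= o.prob_cost_effective <= 1.0


class TestModelFile:
    def test_round_trip(self, tmp_path):
        params = AFModelParams(p_stroke_af=0.05, cost_oac_year=300.0)
        path = tmp_path / "model.yaml"
        save_model_file(path, params)
        loaded, strategies = load_model_file(path)
        assert loaded == params
        assert {s.name for s in strategies} == {"no_screening", "pulse_palpation", "slecg_device"}

    def test_invalid_file_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("af_model:\n  not_a_field: 1\n")
        with pytest.raises(ModelValidationError):
            load_model_file(path)
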