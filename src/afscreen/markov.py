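"""Markov cohort cost-utility model for AF screening strategies.

A discrete-time cohort model moves a population of over-65s through six
health states (undetected AF, detected AF on anticoagulation, detected AF
declining anticoagulation, no AF, post-stroke, dead) in one-year cycles to
a lifetime horizon.  Screening strategies differ in their one-off costs and
in the fraction of undetected AF they move onto anticoagulation at cycle 0,
via the strategy's sensitivity; false positives incur a confirmatory
12-lead ECG cost.  Costs and QALYs are discounted at the NICE reference
rate and compared at a willingness-to-pay threshold (default
20,000 GBP/QALY) through ICERs, incremental net benefit and
cost-effectiveness acceptability curves under Monte-Carlo probabilistic
sensitivity analysis with common random numbers across strategies.

The default parameter set is a reconstruction assembled from UK AF
costing and screening-evaluation literature; every value is overridable
from a YAML model file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "HealthStateSpace",
    "TransitionModel",
    "EconomicParams",
    "ScreeningStrategy",
    "AFModelParams",
    "PSAConfig",
    "PSASamples",
    "StrategyOutcome",
    "discount",
    "run_cohort",
    "build_transition_model",
    "build_economic_params",
    "evaluate_strategy",
    "default_strategies",
    "icer",
    "inb",
    "run_psa",
    "ceac",
    "strategy_outcomes",
    "national_projection",
    "save_model_file",
    "load_model_file",
]

DEFAULT_STATES = (
    "af_undetected",
    "af_detected_on_oac",
    "af_detected_no_oac",
    "no_af",
    "post_stroke",
    "dead",
)


class ModelValidationError(ValueError):
    """The model failed a structural check before any cycle ran."""


@dataclass(frozen=True)
class HealthStateSpace:
    states: tuple[str, ...] = DEFAULT_STATES
    dead_state: str = "dead"

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ModelValidationError("state labels must be unique")
        if self.dead_state not in self.states:
            raise ModelValidationError(f"dead state {self.dead_state!r} not among states")

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)


@dataclass(frozen=True)
class TransitionModel:
    """Per-cycle transition matrix over a state space.

    Rows must sum to one within 1e-9 and the dead row must be the identity
    on dead (death is absorbing).
    """

    space: HealthStateSpace
    matrix: np.ndarray
    cycle_length_years: float = 1.0
    n_cycles: int = 27

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = self.space.n
        if m.shape != (n, n):
            raise ModelValidationError(f"matrix shape {m.shape} does not match {n} states")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ModelValidationError("transition probabilities must lie in [0, 1]")
        rowsum = m.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ModelValidationError(
                f"row {self.space.states[bad]!r} sums to {rowsum[bad]!r}, not 1"
            )
        d = self.space.index(self.space.dead_state)
        expected = np.zeros(n)
        expected[d] = 1.0
        if not np.allclose(m[d], expected, atol=1e-12):
            raise ModelValidationError("dead state must be absorbing")
        if self.n_cycles <= 0:
            raise ModelValidationError("n_cycles must be positive")


@dataclass(frozen=True)
class EconomicParams:
    """Per-state costs/utilities, event costs, discounting and the threshold."""

    space: HealthStateSpace
    state_costs: Mapping[str, float]
    state_utilities: Mapping[str, float]
    stroke_event_cost: float = 0.0
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    wtp_threshold: float = 20_000.0

    def __post_init__(self) -> None:
        for s in self.space.states:
            if s not in self.state_costs or s not in self.state_utilities:
                raise ModelValidationError(f"missing cost/utility for state {s!r}")
            if self.state_costs[s] < 0:
                raise ModelValidationError(f"cost for {s!r} must be non-negative")
            if not 0.0 <= self.state_utilities[s] <= 1.0:
                raise ModelValidationError(f"utility for {s!r} must lie in [0, 1]")
        for r in (self.discount_rate_costs, self.discount_rate_qalys):
            if not 0.0 <= r < 1.0:
                raise ModelValidationError("discount rates must lie in [0, 1)")
        if self.stroke_event_cost < 0:
            raise ModelValidationError("stroke event cost must be non-negative")

    def cost_vector(self) -> np.ndarray:
        return np.array([self.state_costs[s] for s in self.space.states])

    def utility_vector(self) -> np.ndarray:
        return np.array([self.state_utilities[s] for s in self.space.states])


def discount(amount: float, annual_rate: float, time_years: float) -> float:
    """Present value of ``amount`` incurred ``time_years`` from now."""
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError(f"annual_rate must lie in [0, 1), got {annual_rate}")
    return amount / (1.0 + annual_rate) ** time_years


@dataclass(frozen=True)
class CohortTrace:
    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    discounted_cost: float
    discounted_qalys: float


def run_cohort(
    transitions: TransitionModel,
    econ: EconomicParams,
    initial_distribution: Sequence[float],
    *,
    half_cycle: bool = False,
) -> CohortTrace:
    """Propagate a cohort and accumulate discounted costs and QALYs.

    Per-cycle accrual uses start-of-cycle occupancy (simple cycle sums);
    ``half_cycle`` switches to the half-cycle correction, averaging
    start- and end-of-cycle occupancy.  Stroke events are costed on flows
    into the post-stroke state.  Occupancy conservation (rows summing to 1)
    is asserted every cycle.
    """
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (transitions.space.n,):
        raise ModelValidationError("initial distribution does not match the state space")
    if (init < -1e-12).any() or abs(init.sum() - 1.0) > 1e-9:
        raise ModelValidationError("initial distribution must be a probability vector")

    p = transitions.matrix
    costs = econ.cost_vector()
    utils = econ.utility_vector()
    dt = transitions.cycle_length_years
    post = transitions.space.index("post_stroke") if "post_stroke" in transitions.space.states else None

    # per-state expected stroke-event cost this cycle (new entries into post-stroke)
    event = np.zeros(transitions.space.n)
    if post is not None and econ.stroke_event_cost:
        event = p[:, post] * econ.stroke_event_cost
        event[post] = 0.0  # remaining in post-stroke is not a new stroke

    occ = np.empty((transitions.n_cycles + 1, transitions.space.n))
    occ[0] = init
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(transitions.n_cycles):
        occ[t + 1] = occ[t] @ p
        if abs(occ[t + 1].sum() - 1.0) > 1e-9:
            raise ModelValidationError(f"occupancy not conserved at cycle {t + 1}")
        accrual = 0.5 * (occ[t] + occ[t + 1]) if half_cycle else occ[t]
        cycle_cost = accrual @ costs + occ[t] @ event
        cycle_qaly = (accrual @ utils) * dt
        total_cost += discount(cycle_cost, econ.discount_rate_costs, t * dt)
        total_qaly += discount(cycle_qaly, econ.discount_rate_qalys, t * dt)
    return CohortTrace(occ, float(total_cost), float(total_qaly))


# ---------------------------------------------------------------------------
# Parameterised AF screening model


@dataclass(frozen=True)
class AFModelParams:
    """Reconstruction of the screening cost-utility model's inputs.

    Epidemiology: annual stroke probability in untreated AF and its relative
    risk on anticoagulation; background and post-stroke mortality; routine
    (incidental) detection of undetected AF; AF incidence among the AF-free.
    Economics: annual state costs, one-off stroke event cost, screening and
    confirmation costs; utilities; NICE 3.5%/year discounting.
    """

    start_age: float = 73.0
    horizon_age: float = 100.0
    cycle_length_years: float = 1.0

    prevalence_undetected_af: float = 0.013
    p_stroke_af: float = 0.045
    rr_stroke_oac: float = 0.36
    p_stroke_no_af: float = 0.008
    stroke_fatality: float = 0.20
    p_death_background: float = 0.030
    p_death_post_stroke_excess: float = 0.080
    p_incidental_detection: float = 0.080
    p_af_incidence: float = 0.020
    oac_acceptance: float = 0.75

    cost_af_management: float = 120.0
    cost_oac_year: float = 450.0
    cost_post_stroke_year: float = 3436.0
    cost_stroke_event: float = 11_626.0
    cost_confirmation: float = 40.0

    utility_no_af: float = 0.80
    utility_af: float = 0.774
    utility_post_stroke: float = 0.39

    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    wtp_threshold: float = 20_000.0

    def __post_init__(self) -> None:
        probs = (
            "prevalence_undetected_af",
            "p_stroke_af",
            "p_stroke_no_af",
            "stroke_fatality",
            "p_death_background",
            "p_death_post_stroke_excess",
            "p_incidental_detection",
            "p_af_incidence",
            "oac_acceptance",
        )
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.rr_stroke_oac < 0:
            raise ModelValidationError("rr_stroke_oac must be non-negative")
        if self.horizon_age <= self.start_age:
            raise ModelValidationError("horizon_age must exceed start_age")

    @property
    def n_cycles(self) -> int:
        return int(np.ceil((self.horizon_age - self.start_age) / self.cycle_length_years))


def _transition_rows(p: AFModelParams) -> np.ndarray:
    """Assemble the 6x6 per-cycle matrix from the epidemiological parameters."""

    def af_row(p_stroke: float, p_move: float = 0.0, move_to: int | None = None) -> np.ndarray:
        row = np.zeros(6)
        row[5] = p_stroke * p.stroke_fatality + (1 - p_stroke) * p.p_death_background
        row[4] = p_stroke * (1 - p.stroke_fatality)
        survive = (1 - p_stroke) * (1 - p.p_death_background)
        if move_to is not None:
            row[move_to] = survive * p_move
        return row, survive * (1 - p_move)

    m = np.zeros((6, 6))
    row, stay = af_row(p.p_stroke_af, p.p_incidental_detection, move_to=1)
    m[0] = row
    m[0, 0] = stay
    row, stay = af_row(p.p_stroke_af * p.rr_stroke_oac)
    m[1] = row
    m[1, 1] = stay
    row, stay = af_row(p.p_stroke_af)
    m[2] = row
    m[2, 2] = stay
    row, stay = af_row(p.p_stroke_no_af, p.p_af_incidence, move_to=0)
    m[3] = row
    m[3, 3] = stay
    p_death_ps = min(1.0, p.p_death_background + p.p_death_post_stroke_excess)
    m[4, 5] = p_death_ps
    m[4, 4] = 1 - p_death_ps
    m[5, 5] = 1.0
    return m


def build_transition_model(params: AFModelParams, space: HealthStateSpace | None = None) -> TransitionModel:
    space = space or HealthStateSpace()
    return TransitionModel(
        space=space,
        matrix=_transition_rows(params),
        cycle_length_years=params.cycle_length_years,
        n_cycles=params.n_cycles,
    )


def build_economic_params(params: AFModelParams, space: HealthStateSpace | None = None) -> EconomicParams:
    space = space or HealthStateSpace()
    return EconomicParams(
        space=space,
        state_costs={
            "af_undetected": params.cost_af_management,
            "af_detected_on_oac": params.cost_af_management + params.cost_oac_year,
            "af_detected_no_oac": params.cost_af_management,
            "no_af": 0.0,
            "post_stroke": params.cost_post_stroke_year,
            "dead": 0.0,
        },
        state_utilities={
            "af_undetected": params.utility_af,
            "af_detected_on_oac": params.utility_af,
            "af_detected_no_oac": params.utility_af,
            "no_af": params.utility_no_af,
            "post_stroke": params.utility_post_stroke,
            "dead": 0.0,
        },
        stroke_event_cost=params.cost_stroke_event,
        discount_rate_costs=params.discount_rate_costs,
        discount_rate_qalys=params.discount_rate_qalys,
        wtp_threshold=params.wtp_threshold,
    )


@dataclass(frozen=True)
class ScreeningStrategy:
    """A screening modality's operating point and unit costs."""

    name: str
    test_sensitivity: float
    test_specificity: float
    uptake: float = 1.0
    screening_cost: float = 0.0
    confirmation_pathway_cost: float | None = None

    def __post_init__(self) -> None:
        for name in ("test_sensitivity", "test_specificity", "uptake"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.screening_cost < 0:
            raise ModelValidationError("screening_cost must be non-negative")


def default_strategies() -> tuple[ScreeningStrategy, ...]:
    """No screening, pulse palpation, and the single-lead ECG device.

    Test characteristics default to the reference study's accuracy table
    (device 92.3%/97.4%, pulse 76.9%/92.2%); unit costs cover pharmacist
    time and device consumables.
    """
    return (
        ScreeningStrategy("no_screening", 0.0, 1.0, uptake=0.0),
        ScreeningStrategy("pulse_palpation", 0.769, 0.922, screening_cost=2.50),
        ScreeningStrategy("slecg_device", 0.923, 0.974, screening_cost=9.00),
    )


# ---------------------------------------------------------------------------
# Vectorised evaluation kernel (shared by the deterministic run and the PSA)


def _vector_params(params: AFModelParams, draws: Mapping[str, np.ndarray], n: int) -> dict[str, np.ndarray]:
    """Per-draw parameter arrays: sampled values where provided, else constants."""
    out: dict[str, np.ndarray] = {}
    for f in dataclasses.fields(AFModelParams):
        base = getattr(params, f.name)
        if f.name in draws:
            out[f.name] = np.broadcast_to(np.asarray(draws[f.name], dtype=float), (n,)).copy()
        else:
            out[f.name] = np.full(n, float(base))
    return out


def _evaluate_draws(
    v: Mapping[str, np.ndarray],
    strategies: Sequence[ScreeningStrategy],
    strategy_draws: Mapping[str, Mapping[str, np.ndarray]],
    n_cycles: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Backward-induction evaluation of every strategy on shared parameter draws.

    Returns cost and QALY arrays of shape (n_draws, n_strategies).
    """
    n = len(next(iter(v.values())))
    zeros = np.zeros(n)
    ones = np.ones(n)

    def af_block(p_stroke, move, move_to, idx, m):
        m[:, idx, 5] = p_stroke * v["stroke_fatality"] + (1 - p_stroke) * v["p_death_background"]
        m[:, idx, 4] = p_stroke * (1 - v["stroke_fatality"])
        survive = (1 - p_stroke) * (1 - v["p_death_background"])
        if move_to is not None:
            m[:, idx, move_to] = survive * move
        m[:, idx, idx] = survive * (1 - move)

    m = np.zeros((n, 6, 6))
    af_block(v["p_stroke_af"], v["p_incidental_detection"], 1, 0, m)
    af_block(v["p_stroke_af"] * v["rr_stroke_oac"], zeros, None, 1, m)
    af_block(v["p_stroke_af"], zeros, None, 2, m)
    af_block(v["p_stroke_no_af"], v["p_af_incidence"], 0, 3, m)
    p_death_ps = np.minimum(1.0, v["p_death_background"] + v["p_death_post_stroke_excess"])
    m[:, 4, 5] = p_death_ps
    m[:, 4, 4] = 1 - p_death_ps
    m[:, 5, 5] = 1.0

    costs = np.stack(
        [
            v["cost_af_management"],
            v["cost_af_management"] + v["cost_oac_year"],
            v["cost_af_management"],
            zeros,
            v["cost_post_stroke_year"],
            zeros,
        ],
        axis=1,
    )
    utils = np.stack(
        [v["utility_af"], v["utility_af"], v["utility_af"], v["utility_no_af"],
         v["utility_post_stroke"], zeros],
        axis=1,
    )
    event = m[:, :, 4] * v["cost_stroke_event"][:, None]
    event[:, 4] = 0.0

    disc_c = 1.0 / (1.0 + v["discount_rate_costs"])
    disc_q = 1.0 / (1.0 + v["discount_rate_qalys"])
    dt = v["cycle_length_years"]

    # state-value backward induction: V_t = accrual + disc * P V_{t+1}
    vc = np.zeros((n, 6))
    vq = np.zeros((n, 6))
    accrual_c = costs + event
    accrual_q = utils * dt[:, None]
    for _ in range(n_cycles):
        vc = accrual_c + disc_c[:, None] ** dt[:, None] * np.einsum("nij,nj->ni", m, vc)
        vq = accrual_q + disc_q[:, None] ** dt[:, None] * np.einsum("nij,nj->ni", m, vq)

    prev = v["prevalence_undetected_af"]
    out_cost = np.empty((n, len(strategies)))
    out_qaly = np.empty((n, len(strategies)))
    for j, s in enumerate(strategies):
        sd = strategy_draws.get(s.name, {})
        sens = np.broadcast_to(np.asarray(sd.get("sensitivity", s.test_sensitivity), float), (n,))
        spec = np.broadcast_to(np.asarray(sd.get("specificity", s.test_specificity), float), (n,))
        uptake = s.uptake * ones
        p_detect = prev * uptake * sens
        p_fp = (1 - prev) * uptake * (1 - spec)
        init = np.zeros((n, 6))
        init[:, 0] = prev - p_detect
        init[:, 1] = p_detect * v["oac_acceptance"]
        init[:, 2] = p_detect * (1 - v["oac_acceptance"])
        init[:, 3] = 1 - prev
        confirm = s.confirmation_pathway_cost
        confirm_arr = v["cost_confirmation"] if confirm is None else confirm * ones
        oneoff = uptake * s.screening_cost + (p_detect + p_fp) * confirm_arr
        out_cost[:, j] = (init * vc).sum(axis=1) + oneoff
        out_qaly[:, j] = (init * vq).sum(axis=1)
    return out_cost, out_qaly


def evaluate_strategy(
    strategy: ScreeningStrategy, params: AFModelParams | None = None
) -> tuple[float, float]:
    """Expected discounted (cost, QALYs) per person offered screening."""
    params = params or AFModelParams()
    v = _vector_params(params, {}, 1)
    cost, qaly = _evaluate_draws(v, [strategy], {}, params.n_cycles)
    return float(cost[0, 0]), float(qaly[0, 0])


# ---------------------------------------------------------------------------
# Decision metrics


@dataclass(frozen=True)
class ICERResult:
    classification: str  # "ratio", "dominant", "dominated", "undefined"
    value: float | None = None


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Incremental cost-effectiveness ratio with dominance flags.

    Dominant: cheaper and more effective.  Dominated: dearer and less
    effective.  Zero QALY difference leaves the ratio undefined.
    """
    if delta_qaly == 0:
        return ICERResult("undefined")
    if delta_cost < 0 and delta_qaly > 0:
        return ICERResult("dominant")
    if delta_cost > 0 and delta_qaly < 0:
        return ICERResult("dominated")
    return ICERResult("ratio", delta_cost / delta_qaly)


def inb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net (monetary) benefit: lambda * dQALY - dCost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be non-negative")
    return wtp * delta_qaly - delta_cost


def national_projection(
    inb_per_patient: float, population: float, uptake: float, detection_fraction: float = 1.0
) -> float:
    """Scale a per-patient incremental net benefit to a national population.

    A plain product of the supplied factors; every factor is explicit so a
    report can show exactly what was multiplied.
    """
    for name, val in (("population", population), ("uptake", uptake),
                      ("detection_fraction", detection_fraction)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    return inb_per_patient * population * uptake * detection_fraction


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution: beta(alpha, beta), gamma(shape, scale),
    lognormal(mu, sigma) or a degenerate point mass."""

    family: str
    a: float = 0.0
    b: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=n)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=n)
        if self.family == "lognormal":
            return rng.lognormal(self.a, self.b, size=n)
        if self.family == "point":
            return np.full(n, self.a)
        raise ModelValidationError(f"unknown distribution family {self.family!r}")


def _beta_from_mean(mean: float, kappa: float = 50.0) -> DistributionSpec:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return DistributionSpec("beta", mean * kappa, (1 - mean) * kappa)


def _gamma_from_mean(mean: float, cv: float = 0.2) -> DistributionSpec:
    if mean <= 0:
        return DistributionSpec("point", mean)
    shape = 1.0 / cv**2
    return DistributionSpec("gamma", shape, mean / shape)


def default_psa_spec(params: AFModelParams | None = None) -> dict[str, DistributionSpec]:
    """Standard-practice sampling distributions around the base case.

    Beta for probabilities and utilities (moderate concentration), gamma for
    costs (20% coefficient of variation), log-normal for the anticoagulation
    relative risk.
    """
    p = params or AFModelParams()
    return {
        "prevalence_undetected_af": _beta_from_mean(p.prevalence_undetected_af, 600.0),
        "p_stroke_af": _beta_from_mean(p.p_stroke_af, 200.0),
        "rr_stroke_oac": DistributionSpec("lognormal", float(np.log(p.rr_stroke_oac)), 0.2),
        "p_stroke_no_af": _beta_from_mean(p.p_stroke_no_af, 400.0),
        "stroke_fatality": _beta_from_mean(p.stroke_fatality, 100.0),
        "p_incidental_detection": _beta_from_mean(p.p_incidental_detection, 100.0),
        "oac_acceptance": _beta_from_mean(p.oac_acceptance, 50.0),
        "cost_oac_year": _gamma_from_mean(p.cost_oac_year),
        "cost_post_stroke_year": _gamma_from_mean(p.cost_post_stroke_year),
        "cost_stroke_event": _gamma_from_mean(p.cost_stroke_event),
        "cost_confirmation": _gamma_from_mean(p.cost_confirmation),
        "utility_af": _beta_from_mean(p.utility_af, 300.0),
        "utility_no_af": _beta_from_mean(p.utility_no_af, 300.0),
        "utility_post_stroke": _beta_from_mean(p.utility_post_stroke, 100.0),
    }


def default_strategy_psa_spec() -> dict[str, dict[str, DistributionSpec]]:
    """Test-characteristic uncertainty from the reference study's 2x2 counts."""
    return {
        "slecg_device": {
            "sensitivity": DistributionSpec("beta", 24, 2),
            "specificity": DistributionSpec("beta", 563, 15),
        },
        "pulse_palpation": {
            "sensitivity": DistributionSpec("beta", 20, 6),
            "specificity": DistributionSpec("beta", 533, 45),
        },
    }


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 100_000
    seed: int = 0
    parameter_spec: Mapping[str, DistributionSpec] | None = None
    strategy_spec: Mapping[str, Mapping[str, DistributionSpec]] | None = None

    def __post_init__(self) -> None:
        if self.n_draws <= 0:
            raise ModelValidationError("n_draws must be positive")


@dataclass(frozen=True)
class PSASamples:
    """Per-draw discounted (cost, QALY) pairs per strategy, on common draws."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def deltas(self, strategy: str, comparator: str) -> tuple[np.ndarray, np.ndarray]:
        i, j = self.strategies.index(strategy), self.strategies.index(comparator)
        return self.costs[:, i] - self.costs[:, j], self.qalys[:, i] - self.qalys[:, j]


def run_psa(
    params: AFModelParams | None = None,
    strategies: Sequence[ScreeningStrategy] | None = None,
    psa: PSAConfig | None = None,
) -> PSASamples:
    """Monte-Carlo PSA: every strategy evaluated on the same parameter draw.

    Reproducible per seed.  A spec of all point masses reproduces the
    deterministic run draw for draw.
    """
    params = params or AFModelParams()
    strategies = tuple(strategies or default_strategies())
    psa = psa or PSAConfig()
    spec = dict(default_psa_spec(params) if psa.parameter_spec is None else psa.parameter_spec)
    sspec = default_strategy_psa_spec() if psa.strategy_spec is None else psa.strategy_spec

    valid = {f.name for f in dataclasses.fields(AFModelParams)}
    for name in spec:
        if name not in valid:
            raise ModelValidationError(f"unknown PSA parameter {name!r}")

    rng = np.random.default_rng(np.random.SeedSequence(psa.seed, spawn_key=(71,)))
    draws = {name: d.sample(rng, psa.n_draws) for name, d in sorted(spec.items())}
    strategy_draws = {
        sname: {k: d.sample(rng, psa.n_draws) for k, d in sorted(dists.items())}
        for sname, dists in sorted(sspec.items())
    }
    v = _vector_params(params, draws, psa.n_draws)
    costs, qalys = _evaluate_draws(v, strategies, strategy_draws, params.n_cycles)
    return PSASamples(tuple(s.name for s in strategies), costs, qalys, psa.seed)


def ceac(
    samples: PSASamples,
    strategy: str,
    comparator: str = "no_screening",
    wtp_grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cost-effectiveness acceptability curve vs a comparator.

    At each threshold, the fraction of draws whose incremental net benefit
    is positive.  At lambda = 0 this is the fraction of cost-saving draws.
    """
    if samples.n_draws == 0:
        raise ValueError("empty PSA sample")
    grid = np.asarray(
        wtp_grid if wtp_grid is not None else np.linspace(0, 50_000, 101), dtype=float
    )
    dc, dq = samples.deltas(strategy, comparator)
    prob = np.array([(lam * dq - dc > 0).mean() for lam in grid])
    return grid, prob


@dataclass(frozen=True)
class StrategyOutcome:
    name: str
    mean_cost: float
    mean_qaly: float
    delta_cost: float
    delta_qaly: float
    icer: ICERResult
    inb: float
    prob_cost_effective: float
    ceac_grid: np.ndarray
    ceac_prob: np.ndarray


def strategy_outcomes(
    samples: PSASamples,
    comparator: str = "no_screening",
    wtp: float = 20_000.0,
    wtp_grid: Sequence[float] | None = None,
) -> dict[str, StrategyOutcome]:
    """Mean costs/QALYs, ICER, INB at the threshold and the CEAC per strategy."""
    out: dict[str, StrategyOutcome] = {}
    j = samples.strategies.index(comparator)
    for i, name in enumerate(samples.strategies):
        if name == comparator:
            continue
        mc, mq = float(samples.costs[:, i].mean()), float(samples.qalys[:, i].mean())
        dc = mc - float(samples.costs[:, j].mean())
        dq = mq - float(samples.qalys[:, j].mean())
        grid, prob = ceac(samples, name, comparator, wtp_grid)
        dcs, dqs = samples.deltas(name, comparator)
        p_ce = float((wtp * dqs - dcs > 0).mean())
        out[name] = StrategyOutcome(
            name, mc, mq, dc, dq, icer(dc, dq), inb(dc, dq, wtp), p_ce, grid, prob
        )
    return out


# ---------------------------------------------------------------------------
# Model file I/O


def save_model_file(path, params: AFModelParams, strategies: Sequence[ScreeningStrategy] | None = None) -> None:
    payload = {
        "af_model": dataclasses.asdict(params),
        "strategies": [dataclasses.asdict(s) for s in (strategies or default_strategies())],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model_file(path) -> tuple[AFModelParams, tuple[ScreeningStrategy, ...]]:
    """Load a YAML model file: the parameterised AF structure plus strategies."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "af_model" not in payload:
        raise ModelValidationError(f"{path}: expected a mapping with an 'af_model' section")
    try:
        params = AFModelParams(**payload["af_model"])
    except TypeError as exc:
        raise ModelValidationError(f"{path}: {exc}") from exc
    strategies = tuple(
        ScreeningStrategy(**s) for s in payload.get("strategies", [])
    ) or default_strategies()
    return params, strategies
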