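"""Costing, QALYs, discounting and incremental cost-effectiveness.

Costs are taken from a societal perspective: the programme's delivery cost
(budget spread over the exposed registered population), a one-off onward
referral cost each time someone starts seeing an advocate, and the
six-monthly societal cost of living in an abuse state (scaled by the
identified-state cost multipliers). QALYs use the area-under-the-curve
approach: each cycle contributes occupancy x population-weighted utility x
0.5 years. Both streams are discounted at an annual rate (default 3.5%)
applied at half-year resolution, with the first cycle undiscounted, and
expressed per cohort member.

Conventions (documented in docs/methods.md): the first cycle holds the
initial distribution, so a 20-cycle horizon means 19 transitions with
accrual over all 20 cycle points; no half-cycle correction; the dead state
carries zero cost and zero utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DvaCeaError, MissingParameterError
from .markov import CohortTrace, build_matrix, initial_distribution, run_cohort
from .parameters import SUBGROUPS, CostSet, ParameterSet, SubgroupWeights, UtilitySet
from .states import N_STATES, STATE_INDEX, HealthState

_NO, _UN, _ADV, _NOADV, _DEAD = range(N_STATES)

#: Cost-stream component names, in reporting order.
COST_COMPONENTS = ("abuse", "intervention", "referral")


def discount_factor(cycle_index: int, annual_rate: float) -> float:
    """Discount factor for a 1-based six-month cycle index.

    The first cycle is undiscounted; cycle k is discounted by
    ``(1 + rate) ** -((k - 1) / 2)`` — half a year of discounting per
    elapsed cycle.
    """
    if cycle_index < 1:
        raise DvaCeaError("cycle_index is 1-based")
    if annual_rate < 0:
        raise DvaCeaError("annual_rate must be >= 0")
    return float((1.0 + annual_rate) ** (-(cycle_index - 1) * 0.5))


def discount_factors(n_cycles: int, annual_rate: float) -> np.ndarray:
    """Vector of discount factors for cycles 1..n_cycles."""
    k = np.arange(n_cycles, dtype=float)  # cycle_index - 1
    return (1.0 + annual_rate) ** (-k * 0.5)


def weighted_utility(
    state: HealthState | str, utilities: UtilitySet, weights: SubgroupWeights
) -> float:
    """Population-weighted utility of one (non-dead) health state."""
    key = state.value if isinstance(state, HealthState) else state
    if key == HealthState.DEAD.value:
        raise DvaCeaError("dead carries utility 0 by construction")
    w = weights.as_mapping()
    try:
        return sum(w[sub] * utilities.base(key, sub) for sub in SUBGROUPS)
    except KeyError as exc:
        raise MissingParameterError(f"utilities.{key}.{exc}") from exc


def utility_vector(utilities: UtilitySet, weights: SubgroupWeights) -> np.ndarray:
    """Weighted utilities in canonical state order (dead = 0)."""
    u = np.zeros(N_STATES)
    for state in HealthState:
        if state is not HealthState.DEAD:
            u[STATE_INDEX[state]] = weighted_utility(state, utilities, weights)
    return u


def weighted_abuse_cost(
    adult_cost: float, child_cost: float, child_share: float
) -> float:
    """Population-weighted six-month societal cost of abuse exposure."""
    if adult_cost < 0 or child_cost < 0:
        raise DvaCeaError("costs must be >= 0")
    if not (0.0 <= child_share <= 1.0):
        raise DvaCeaError("child_share must lie in [0, 1]")
    return adult_cost * (1.0 - child_share) + child_cost * child_share


def onward_referral_cost(
    hours: float, hourly_rate: float, acceptance_share: float
) -> float:
    """One-off onward-referral cost: worker hours x hourly rate x the
    share of referred patients who accept support and need referring on."""
    if min(hours, hourly_rate, acceptance_share) < 0:
        raise DvaCeaError("inputs must be >= 0")
    return hours * hourly_rate * acceptance_share


def intervention_cost_per_patient(budget: float, exposed_population: float) -> float:
    """Programme budget spread over the exposed registered population."""
    if exposed_population <= 0:
        raise DvaCeaError("exposed_population must be > 0")
    return budget / exposed_population


@dataclass
class EconResult:
    """One arm's discounted totals and per-cycle streams, per patient."""

    arm: str
    total_discounted_cost: float
    total_discounted_qalys: float
    cost_stream: np.ndarray
    qaly_stream: np.ndarray
    cost_components: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class IncrementalResult:
    """Incremental comparison of intervention vs control."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    verdict: str
    nmb: float
    wtp_lambda: float


def accumulate_costs(
    trace: CohortTrace, costs: CostSet, arm: str, annual_rate: float = 0.035
) -> tuple[float, np.ndarray, dict[str, np.ndarray]]:
    """Discounted cost per patient, with its per-cycle stream and components.

    Per cycle point: abuse-state occupants incur the weighted abuse cost
    (times the identified-state multipliers); in the intervention arm they
    also incur the per-patient programme cost; each new entrant into
    'identified, seeing advocate' triggers the one-off referral cost — as
    do the cycle-1 initial occupants of the identified states.
    """
    if np.any(trace.occupancy < -1e-9):
        raise DvaCeaError("negative occupancy")
    occ, new = trace.occupancy, trace.new_entrants
    n = trace.n_rows
    disc = discount_factors(n, annual_rate)

    wcost = costs.base("abuse_cost_weighted_per_cycle")
    m_adv = costs.base("cost_multiplier_id_advocate")
    m_noadv = costs.base("cost_multiplier_id_no_advocate")
    c_int = costs.base("intervention_cost_per_patient_per_cycle")
    c_ref = costs.base("onward_referral_cost_once")

    abuse = wcost * (
        occ[:, _UN] + m_adv * occ[:, _ADV] + m_noadv * occ[:, _NOADV]
    )
    exposed = occ[:, _UN] + occ[:, _ADV] + occ[:, _NOADV]
    programme = c_int * exposed if arm == "intervention" else np.zeros(n)
    referral = c_ref * new[:, _ADV]
    referral[0] += c_ref * (occ[0, _ADV] + occ[0, _NOADV])

    components = {
        "abuse": disc * abuse / trace.cohort_size,
        "intervention": disc * programme / trace.cohort_size,
        "referral": disc * referral / trace.cohort_size,
    }
    stream = components["abuse"] + components["intervention"] + components["referral"]
    return float(stream.sum()), stream, components


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    weights: SubgroupWeights,
    annual_rate: float = 0.035,
) -> tuple[float, np.ndarray]:
    """Discounted QALYs per patient (area under the curve, 0.5 y/cycle)."""
    u = utility_vector(utilities, weights)
    disc = discount_factors(trace.n_rows, annual_rate)
    stream = disc * 0.5 * (trace.occupancy @ u) / trace.cohort_size
    return float(stream.sum()), stream


def evaluate_arm(trace: CohortTrace, params: ParameterSet, arm: str) -> EconResult:
    """Discounted per-patient costs and QALYs for one arm's trace."""
    rate = params.run.discount_annual
    cost, cost_stream, components = accumulate_costs(
        trace, params.costs, arm, rate
    )
    qalys, qaly_stream = accumulate_qalys(
        trace, params.utilities, params.weights, rate
    )
    return EconResult(
        arm=arm,
        total_discounted_cost=cost,
        total_discounted_qalys=qalys,
        cost_stream=cost_stream,
        qaly_stream=qaly_stream,
        cost_components=components,
    )


def incremental(
    res_int: EconResult, res_ctrl: EconResult, wtp_lambda: float = 20_000.0
) -> IncrementalResult:
    """Incremental cost, QALYs, ICER/dominance verdict and net benefit."""
    dc = res_int.total_discounted_cost - res_ctrl.total_discounted_cost
    dq = res_int.total_discounted_qalys - res_ctrl.total_discounted_qalys
    nmb = wtp_lambda * dq - dc
    if dq == 0.0:
        icer = None
        verdict = "dominant" if dc < 0 else ("dominated" if dc > 0 else "equivalent")
    else:
        icer = dc / dq
        if dc < 0 and dq > 0:
            verdict = "dominant"
        elif dc > 0 and dq < 0:
            verdict = "dominated"
        elif dq > 0:
            verdict = "northeast"  # more costly, more effective
        else:
            verdict = "southwest"  # cheaper, less effective
    return IncrementalResult(
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        verdict=verdict,
        nmb=nmb,
        wtp_lambda=wtp_lambda,
    )


def simulate_arm(params: ParameterSet, arm: str) -> CohortTrace:
    """Build one arm's matrix and run the cohort over the configured horizon.

    The configured cycle count is the number of cycle points; the first
    point is the initial distribution, so ``cycles - 1`` transitions run.
    """
    probs = params.transitions.base_for_arm(arm)
    matrix = build_matrix(probs, arm)
    init = initial_distribution(
        prevalence=probs["prevalence_all_ages"],
        split={
            "id_advocate": probs["start_id_advocate"],
            "id_no_advocate": probs["start_id_no_advocate"],
        },
        cohort=params.run.cohort,
    )
    return run_cohort(matrix, init, n_cycles=params.run.cycles - 1)


@dataclass
class ScenarioResult:
    """Both arms' traces and economics plus the incremental comparison."""

    trace_intervention: CohortTrace
    trace_control: CohortTrace
    intervention: EconResult
    control: EconResult
    incremental: IncrementalResult


def run_scenario(
    params: ParameterSet, wtp_lambda: float | None = None
) -> ScenarioResult:
    """Run both arms under one parameter set and compare them."""
    lam = params.run.wtp_lambda if wtp_lambda is None else wtp_lambda
    trace_i = simulate_arm(params, "intervention")
    trace_c = simulate_arm(params, "control")
    res_i = evaluate_arm(trace_i, params, "intervention")
    res_c = evaluate_arm(trace_c, params, "control")
    return ScenarioResult(
        trace_intervention=trace_i,
        trace_control=trace_c,
        intervention=res_i,
        control=res_c,
        incremental=incremental(res_i, res_c, lam),
    )
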