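"""Discounting, weighting, cost/QALY accumulation and incremental results."""

import numpy as np
import pytest

from dva_cea import (
    accumulate_costs,
    accumulate_qalys,
    discount_factor,
    incremental,
    intervention_cost_per_patient,
    onward_referral_cost,
    run_scenario,
    weighted_abuse_cost,
    weighted_utility,
)
from dva_cea.economics import EconResult
from dva_cea.errors import DvaCeaError
from dva_cea.markov import CohortTrace
from dva_cea.parameters import SubgroupWeights


class TestDiscounting:
    def test_first_cycle_undiscounted(self):
        assert discount_factor(1, 0.035) == 1.0

    def test_cycle_three_one_full_year(self):
        assert discount_factor(3, 0.035) == pytest.approx(1 / 1.035, rel=1e-12)

    def test_zero_rate(self):
        assert all(discount_factor(k, 0.0) == 1.0 for k in range(1, 21))

    def test_cycle_index_is_one_based(self):
        with pytest.raises(DvaCeaError):
            discount_factor(0, 0.035)


class TestWeighting:
    def test_no_abuse_weighted_utility(self, params):
        # 0.2 x 0.95 (children) + 0.8 x 0.85 (adults) = 0.87
        assert weighted_utility(
            "no_abuse", params.utilities, params.weights
        ) == pytest.approx(0.87)

    def test_unidentified_weighted_utility(self, params):
        # 0.4 x 0.656 + 0.4 x 0.626 + 0.2 x 0.801 = 0.6730
        assert weighted_utility(
            "unidentified", params.utilities, params.weights
        ) == pytest.approx(0.6730)

    def test_children_only_weights(self, params):
        w = SubgroupWeights(1.0, 0.0, 0.0)
        assert weighted_utility("no_abuse", params.utilities, w) == 0.95

    def test_weighted_abuse_cost_reproduces_published(self):
        # 0.8 x 4858 + 0.2 x 1950 = 4276.4, printed as 4276
        assert weighted_abuse_cost(4858, 1950, 0.2) == pytest.approx(4276.4)
        assert round(weighted_abuse_cost(4858, 1950, 0.2)) == 4276
        # the inflated child-cost variant
        assert weighted_abuse_cost(4858, 1969, 0.2) == pytest.approx(4280.2)
        assert weighted_abuse_cost(4858, 1950, 0.0) == 4858

    def test_onward_referral_worked_example(self):
        # 57 hours x 29.60/hour x 39% acceptance = 658.008, printed 658
        assert onward_referral_cost(57, 29.60, 0.39) == pytest.approx(658.008)
        assert round(onward_referral_cost(57, 29.60, 0.39)) == 658
        assert onward_referral_cost(57, 29.60, 0.0) == 0.0
        assert onward_referral_cost(10, 10, 0.5) == 50.0

    def test_intervention_cost_worked_example(self):
        # programme budget over the exposed registered population
        assert intervention_cost_per_patient(60_253, 79_485) == pytest.approx(
            0.758, abs=5e-4
        )
        assert intervention_cost_per_patient(0, 10) == 0.0
        assert intervention_cost_per_patient(100, 4) == 25.0
        with pytest.raises(DvaCeaError):
            intervention_cost_per_patient(100, 0)


def _toy_trace(occ_rows, new_rows=None):
    occ = np.asarray(occ_rows, dtype=float)
    new = np.zeros_like(occ) if new_rows is None else np.asarray(new_rows, float)
    return CohortTrace(cohort_size=occ[0].sum(), occupancy=occ, new_entrants=new)


class TestAccumulation:
    def test_single_cycle_abuse_cost_arithmetic(self, params):
        # 100 persons unidentified, weighted abuse cost 10/cycle, no referrals
        clone = params.copy()
        from dva_cea.distributions import DistributionSpec

        fixed = lambda v: DistributionSpec("fixed", base=v, lower=v, upper=v)
        for name, _ in list(clone.costs.items()):
            clone.costs._specs[name] = fixed(0.0)
        clone.costs._specs["abuse_cost_weighted_per_cycle"] = fixed(10.0)
        clone.costs._specs["cost_multiplier_id_advocate"] = fixed(1.0)
        clone.costs._specs["cost_multiplier_id_no_advocate"] = fixed(1.0)
        trace = _toy_trace([[900, 100, 0, 0, 0]])
        total, _, _ = accumulate_costs(trace, clone.costs, "control", 0.0)
        assert total == pytest.approx(1000.0 / 1000.0)

    def test_zero_costs_give_zero(self, params, base_scenario):
        clone = params.copy()
        from dva_cea.distributions import DistributionSpec

        fixed = lambda v: DistributionSpec("fixed", base=v, lower=v, upper=v)
        for name, _ in list(clone.costs.items()):
            clone.costs._specs[name] = fixed(0.0)
        clone.costs._specs["cost_multiplier_id_advocate"] = fixed(1.0)
        clone.costs._specs["cost_multiplier_id_no_advocate"] = fixed(1.0)
        total, _, _ = accumulate_costs(
            base_scenario.trace_intervention, clone.costs, "intervention", 0.035
        )
        assert total == 0.0

    def test_full_health_no_death_undiscounted_qalys(self, params):
        """Utilities of 1 everywhere, nobody dies, no discounting:
        20 cycle points x 0.5 years = 10 QALYs exactly."""
        clone = params.copy()
        util = {
            (state, sub): 1.0
            for state in ("no_abuse", "unidentified", "id_advocate", "id_no_advocate")
            for sub in ("women", "men", "children")
        }
        utilities = clone.utilities.replace_bases(util)
        occ = np.tile([1000.0, 0, 0, 0, 0], (20, 1))
        trace = _toy_trace(occ)
        total, _ = accumulate_qalys(trace, utilities, clone.weights, 0.0)
        assert total == pytest.approx(10.0, abs=1e-12)

    def test_single_cycle_qalys(self, params):
        util = {
            (state, sub): 0.8
            for state in ("no_abuse", "unidentified", "id_advocate", "id_no_advocate")
            for sub in ("women", "men", "children")
        }
        utilities = params.utilities.replace_bases(util)
        trace = _toy_trace([[1000.0, 0, 0, 0, 0]])
        total, _ = accumulate_qalys(trace, utilities, params.weights, 0.0)
        assert total == pytest.approx(0.4)

    def test_discount_monotonicity(self, params, base_scenario):
        trace = base_scenario.trace_intervention
        costs, qalys = [], []
        for rate in (0.0, 0.015, 0.035, 0.06):
            c, _, _ = accumulate_costs(trace, params.costs, "intervention", rate)
            q, _ = accumulate_qalys(trace, params.utilities, params.weights, rate)
            costs.append(c)
            qalys.append(q)
        assert all(a > b for a, b in zip(costs, costs[1:]))
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    def test_cost_decomposition_conserved(self, base_scenario):
        for res in (base_scenario.intervention, base_scenario.control):
            recomposed = sum(res.cost_components.values())
            np.testing.assert_allclose(recomposed, res.cost_stream, rtol=1e-12)
            assert res.total_discounted_cost == pytest.approx(
                res.cost_stream.sum(), rel=1e-12
            )


def _result(cost, qalys, arm="x"):
    return EconResult(arm, cost, qalys, np.array([cost]), np.array([qalys]))


class TestIncremental:
    def test_nmb_identity(self, base_scenario):
        inc = base_scenario.incremental
        assert inc.nmb == pytest.approx(
            inc.wtp_lambda * inc.delta_qalys - inc.delta_cost, abs=1e-9
        )

    def test_identical_arms(self):
        inc = incremental(_result(100.0, 1.0), _result(100.0, 1.0))
        assert inc.delta_cost == 0.0 and inc.delta_qalys == 0.0 and inc.nmb == 0.0
        assert inc.verdict == "equivalent"

    def test_simple_icer_arithmetic(self):
        inc = incremental(_result(200.0, 1.01), _result(100.0, 1.0), 20_000.0)
        assert inc.icer == pytest.approx(10_000.0)
        assert inc.nmb == pytest.approx(100.0)
        assert inc.verdict == "northeast"

    def test_dominance_verdicts(self):
        assert incremental(_result(90, 1.1), _result(100, 1.0)).verdict == "dominant"
        assert incremental(_result(110, 0.9), _result(100, 1.0)).verdict == "dominated"
        assert incremental(_result(90, 0.9), _result(100, 1.0)).verdict == "southwest"

    def test_zero_qaly_difference(self):
        inc = incremental(_result(90, 1.0), _result(100, 1.0))
        assert inc.icer is None and inc.verdict == "dominant"


class TestBaseCase:
    """The deterministic base case against the published results table."""

    def test_costs_within_three_percent(self, base_scenario):
        assert base_scenario.intervention.total_discounted_cost == pytest.approx(
            3867, rel=0.03
        )
        assert base_scenario.control.total_discounted_cost == pytest.approx(
            3959, rel=0.03
        )

    def test_qalys_within_three_percent(self, base_scenario):
        assert base_scenario.intervention.total_discounted_qalys == pytest.approx(
            7.000, rel=0.03
        )
        assert base_scenario.control.total_discounted_qalys == pytest.approx(
            6.997, rel=0.03
        )

    def test_intervention_dominates(self, base_scenario):
        inc = base_scenario.incremental
        assert inc.delta_cost < 0
        assert inc.delta_qalys > 0
        assert inc.verdict == "dominant"
        assert inc.nmb > 0

    def test_qaly_cap(self, base_scenario, params):
        cap = params.run.cycles * 0.5 * 0.95  # highest utility in the model
        for res in (base_scenario.intervention, base_scenario.control):
            assert res.total_discounted_qalys <= cap
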