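"""Probabilistic sensitivity analysis: sampling, CEAC, intervals."""

import numpy as np
import pytest

from dva_cea import percentile_interval, run_psa, run_scenario, sample_parameter_set
from dva_cea.distributions import DistributionSpec
from dva_cea.errors import DvaCeaError
from dva_cea.psa import ceac_curve


def _point_mass_params(params):
    """Replace every distribution with a point mass at its base value."""
    clone = params.copy()
    fixed = lambda v: DistributionSpec("fixed", base=v, lower=v, upper=v)
    sh = clone.transitions.shared
    for name in list(sh):
        sh[name] = fixed(sh[name].base)
    for arm in ("intervention", "control"):
        pa = clone.transitions.per_arm[arm]
        for name in list(pa):
            pa[name] = fixed(pa[name].base)
    clone.utilities = clone.utilities.replace_bases({})
    for name, spec in list(clone.costs.items()):
        clone.costs._specs[name] = fixed(spec.base)
    return clone


class TestPercentileInterval:
    def test_hand_computed_quantiles(self):
        lo, hi = percentile_interval(np.arange(1, 101), 0.95)
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_values(self):
        assert percentile_interval([5.0, 5.0, 5.0]) == (5.0, 5.0)

    def test_preconditions(self):
        with pytest.raises(DvaCeaError):
            percentile_interval([1.0])
        with pytest.raises(DvaCeaError):
            percentile_interval([1.0, 2.0], level=1.0)


class TestSampling:
    def test_same_seed_same_draw(self, params):
        a = sample_parameter_set(params, np.random.default_rng(7))
        b = sample_parameter_set(params, np.random.default_rng(7))
        assert a.intervention == b.intervention
        assert a.control == b.control

    def test_point_masses_reproduce_base_case(self, params):
        pm = _point_mass_params(params)
        sample = sample_parameter_set(pm, np.random.default_rng(0))
        base = run_scenario(params)
        drawn = run_scenario(sample.intervention)
        assert drawn.intervention.total_discounted_cost == pytest.approx(
            base.intervention.total_discounted_cost, rel=1e-12
        )
        assert drawn.intervention.total_discounted_qalys == pytest.approx(
            base.intervention.total_discounted_qalys, rel=1e-12
        )

    def test_sampled_sets_are_valid_rows(self, params):
        for i in range(50):
            sample = sample_parameter_set(params, np.random.default_rng(i))
            for ps in (sample.intervention, sample.control):
                for arm in ("intervention", "control"):
                    probs = ps.transitions.base_for_arm(arm)
                    assert all(0 <= v <= 1 for v in probs.values())

    def test_sample_means_match_base_values(self, params):
        """Over many draws each sampled parameter averages to its base."""
        n = 4000
        keys = [
            "prevalence_all_ages",
            "no_abuse_to_unidentified",
            "unidentified_to_no_abuse",
            "id_advocate_to_no_abuse",
        ]
        sums = {k: 0.0 for k in keys}
        cost_sum = 0.0
        for i in range(n):
            s = sample_parameter_set(params, np.random.default_rng([99, i]))
            for k in keys:
                sums[k] += s.intervention.transitions.shared[k].base
            cost_sum += s.intervention.costs.base("abuse_cost_weighted_per_cycle")
        for k in keys:
            spec = params.transitions.shared[k]
            se = spec.sd / np.sqrt(n)
            assert sums[k] / n == pytest.approx(spec.base, abs=4 * se)
        cost_spec = params.costs.spec("abuse_cost_weighted_per_cycle")
        assert cost_sum / n == pytest.approx(
            cost_spec.base, abs=4 * cost_spec.sd / np.sqrt(n)
        )

    def test_shared_policy_shares_natural_history(self, params):
        s = sample_parameter_set(
            params, np.random.default_rng(3), correlation="shared"
        )
        i_sh = s.intervention.transitions.shared
        c_sh = s.control.transitions.shared
        # the incidence row is fully shared; the remission probability
        # shares its gamma variate but each arm's Dirichlet row is
        # normalized by its own total, so agreement is approximate
        assert (
            i_sh["no_abuse_to_unidentified"].base
            == c_sh["no_abuse_to_unidentified"].base
        )
        assert i_sh["unidentified_to_no_abuse"].base == pytest.approx(
            c_sh["unidentified_to_no_abuse"].base, rel=0.1
        )

    def test_independent_policy_differs_on_natural_history(self, params):
        s = sample_parameter_set(
            params, np.random.default_rng(3), correlation="independent"
        )
        assert (
            s.intervention.transitions.shared["no_abuse_to_unidentified"].base
            != s.control.transitions.shared["no_abuse_to_unidentified"].base
        )
        # mortality remains a common background parameter: the gamma
        # variates are shared, though per-arm normalization differs slightly
        assert s.intervention.transitions.shared[
            "no_abuse_to_dead"
        ].base == pytest.approx(
            s.control.transitions.shared["no_abuse_to_dead"].base, rel=0.2
        )


class TestRunPsa:
    def test_seeded_rerun_bit_identical(self, params):
        a = run_psa(params, n_draws=40, seed=11)
        b = run_psa(params, n_draws=40, seed=11)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qalys, b.delta_qalys)

    def test_draw_stream_prefix_stable(self, params):
        """Extending the number of draws leaves earlier draws unchanged."""
        short = run_psa(params, n_draws=20, seed=5)
        long = run_psa(params, n_draws=40, seed=5)
        np.testing.assert_array_equal(long.delta_cost[:20], short.delta_cost)

    def test_single_point_mass_draw_equals_base(self, params):
        pm = _point_mass_params(params)
        psa = run_psa(pm, n_draws=1, seed=1)
        base = run_scenario(params)
        assert psa.delta_cost[0] == pytest.approx(
            base.incremental.delta_cost, rel=1e-9
        )
        assert psa.delta_qalys[0] == pytest.approx(
            base.incremental.delta_qalys, rel=1e-9
        )

    def test_ceac_identities(self, params):
        psa = run_psa(params, n_draws=200, seed=2)
        assert np.all((psa.ceac >= 0) & (psa.ceac <= 1))
        # at a zero threshold, cost-effective means cost-saving
        assert psa.ceac_at(0.0) == (psa.delta_cost < 0).mean()
        # as the threshold grows, the curve approaches the share of
        # QALY-gaining draws (cost-saving zero-QALY ties aside)
        high = psa.ceac_at(1e12)
        limit = ((psa.delta_qalys > 0) | ((psa.delta_qalys == 0) & (psa.delta_cost < 0))).mean()
        assert high == pytest.approx(limit, abs=1e-12)

    def test_increments_finite(self, params):
        psa = run_psa(params, n_draws=100, seed=9)
        assert np.all(np.isfinite(psa.delta_cost))
        assert np.all(np.isfinite(psa.delta_qalys))

    def test_ceac_curve_helper(self):
        dc = np.array([-10.0, 10.0])
        dq = np.array([0.001, 0.001])
        grid = np.array([0.0, 20_000.0])
        np.testing.assert_allclose(ceac_curve(dc, dq, grid), [0.5, 1.0])


def test_psa_outputs_round_trip(tmp_path, params):
    psa = run_psa(params, n_draws=30, seed=4)
    paths = psa.write(tmp_path)
    import pandas as pd

    plane = pd.read_csv(paths[0])
    np.testing.assert_allclose(plane["delta_cost"].to_numpy(), psa.delta_cost)
    ceac = pd.read_csv(paths[1])
    np.testing.assert_allclose(ceac["probability"].to_numpy(), psa.ceac)
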