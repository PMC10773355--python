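"""Probabilistic sensitivity analysis.

Each draw samples a full coherent parameter set from the fitted
distributions, reruns both arms deterministically, and records the
incremental cost/QALY pair. Summaries follow standard practice: the
cost-effectiveness plane (the cloud of per-draw increments), the
cost-effectiveness acceptability curve CEAC(lambda) — the share of draws
with positive net monetary benefit at each willingness-to-pay value — and
95% percentile intervals.

Correlation structure across arms (the ``correlation`` policy):

* Background mortality, the recovery (advocacy-effect) rows, prevalence,
  the starting split, utilities and costs describe common biology and
  economics and are always drawn once per draw, shared by both arms.
* The arm-specific identification probabilities are always drawn
  independently per arm.
* The calibrated natural-history pair — abuse incidence
  (no abuse -> unidentified) and remission (unidentified -> no abuse) —
  is drawn independently per arm under the default
  ``correlation="independent"`` policy, and shared under
  ``correlation="shared"``. The default reflects that this pair is pinned
  down only by calibration, not by either arm's data, and that the two
  arms are distinct practice populations; it also drives most of the
  incremental uncertainty (see docs/methods.md).

Transition rows are sampled through the gamma representation of the
Dirichlet (independent Gamma(alpha_i) variates normalized to one), so
shared components reuse the same variates in both arms and every sampled
row is an exact probability vector — no redraws are ever needed.

Reproducibility: draw ``i`` under seed ``s`` uses the dedicated bit stream
``default_rng([s, i])``, so a run is bit-reproducible and extending the
number of draws leaves earlier draws unchanged. Within a draw the sampling
order is fixed: prevalence; starting split; recovery rows; utilities;
costs; death variates; then the natural-history and identification
variates (intervention arm first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, dirichlet_concentration, fit_dirichlet_row
from .economics import evaluate_arm, incremental, simulate_arm
from .errors import DvaCeaError
from .parameters import (
    ARMS,
    SUBGROUPS,
    CostSet,
    ParameterSet,
    TransitionParameters,
)

#: Default willingness-to-pay grid, GBP 0..50 000 in steps of 500.
DEFAULT_LAMBDA_GRID = np.arange(0.0, 50_001.0, 500.0)

CORRELATION_POLICIES = ("independent", "shared")


def _fixed(value: float) -> DistributionSpec:
    v = float(value)
    return DistributionSpec("fixed", base=v, lower=v, upper=v)


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed" or spec.upper == spec.lower:
        return spec.base
    return float(spec.fit().rvs(random_state=rng))


def _gamma(rng: np.random.Generator, alpha: float) -> float:
    return float(rng.gamma(alpha)) if alpha > 0 else 0.0


def _draw_shared_row(
    specs: dict[str, DistributionSpec],
    exit_names: tuple[str, ...],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Sample one Dirichlet transition row, shared by both arms."""
    exits = [specs[n] for n in exit_names]
    if all(s.family == "fixed" or s.upper == s.lower for s in exits):
        return {n: specs[n].base for n in exit_names}
    probs = [s.base for s in exits]
    probs.append(1.0 - sum(probs))  # the stay complement
    row = fit_dirichlet_row(probs, limits=[(exits[0].lower, exits[0].upper)])
    sample = row.rvs(random_state=rng)
    return {n: float(sample[i]) for i, n in enumerate(exit_names)}


@dataclass
class PsaSample:
    """One draw's parameter sets, one per arm.

    Under the shared policy both attributes reference the same object.
    """

    intervention: ParameterSet
    control: ParameterSet

    def for_arm(self, arm: str) -> ParameterSet:
        return self.intervention if arm == "intervention" else self.control


def sample_parameter_set(
    params: ParameterSet,
    rng: np.random.Generator,
    correlation: str = "independent",
) -> PsaSample:
    """Draw one coherent parameter set per arm for a PSA iteration.

    Returns a :class:`PsaSample`; each contained :class:`ParameterSet` has
    the drawn values as point masses, with run settings and weights
    unchanged. Sampled transition rows are exact probability vectors, so
    every draw is valid by construction.
    """
    if correlation not in CORRELATION_POLICIES:
        raise DvaCeaError(f"unknown correlation policy {correlation!r}")
    tr = params.transitions
    sh = tr.shared

    common: dict[str, float] = {
        "prevalence_all_ages": _draw(sh["prevalence_all_ages"], rng),
        "start_id_advocate": _draw(sh["start_id_advocate"], rng),
        "start_id_no_advocate": _draw(sh["start_id_no_advocate"], rng),
    }
    common.update(
        _draw_shared_row(sh, ("id_advocate_to_no_abuse", "id_advocate_to_dead"), rng)
    )
    common.update(
        _draw_shared_row(
            sh, ("id_no_advocate_to_no_abuse", "id_no_advocate_to_dead"), rng
        )
    )

    # utilities: the adult no-abuse population norm is one parameter applied
    # to both adult subgroups; identified-state utilities are per subgroup;
    # the unidentified utilities copy 'identified, not seeing advocate' (the
    # no-benefit-of-identification-alone assumption).
    util_new: dict[tuple[str, str], float] = {}
    u_adult = _draw(params.utilities.spec("no_abuse", "women"), rng)
    util_new[("no_abuse", "women")] = u_adult
    util_new[("no_abuse", "men")] = u_adult
    util_new[("no_abuse", "children")] = _draw(
        params.utilities.spec("no_abuse", "children"), rng
    )
    for sub in SUBGROUPS:
        util_new[("id_advocate", sub)] = _draw(
            params.utilities.spec("id_advocate", sub), rng
        )
    for sub in SUBGROUPS:
        v = _draw(params.utilities.spec("id_no_advocate", sub), rng)
        util_new[("id_no_advocate", sub)] = v
        util_new[("unidentified", sub)] = v
    utilities = params.utilities.replace_bases(util_new)

    costs_new = {}
    for name, spec in params.costs.items():
        if name in ("abuse_cost_adult_per_cycle", "abuse_cost_child_per_cycle"):
            # components of the weighted abuse cost; the model consumes the
            # weighted figure, sampled directly from its own printed limits
            costs_new[name] = _fixed(spec.base)
        else:
            costs_new[name] = _fixed(_draw(spec, rng))
    costs = CostSet(costs_new)

    # natural-history rows via the gamma representation
    inc_spec = sh["no_abuse_to_unidentified"]
    rem_spec = sh["unidentified_to_no_abuse"]
    degenerate = inc_spec.family == "fixed" or inc_spec.upper == inc_spec.lower
    if degenerate:
        per_arm_rows = {
            arm: {
                n: tr.base_for_arm(arm)[n]
                for n in (
                    "no_abuse_to_unidentified",
                    "no_abuse_to_dead",
                    "unidentified_to_no_abuse",
                    "unidentified_to_dead",
                    "unidentified_to_id_advocate",
                    "unidentified_to_id_no_advocate",
                )
            }
            for arm in ARMS
        }
    else:
        s_na = dirichlet_concentration(inc_spec)
        s_un = dirichlet_concentration(rem_spec)
        stay_na = 1.0 - inc_spec.base - sh["no_abuse_to_dead"].base
        g_dead_na = _gamma(rng, sh["no_abuse_to_dead"].base * s_na)
        g_dead_un = _gamma(rng, sh["unidentified_to_dead"].base * s_un)
        if correlation == "shared":
            g_inc_s = _gamma(rng, inc_spec.base * s_na)
            g_stay_na_s = _gamma(rng, stay_na * s_na)
            g_rem_s = _gamma(rng, rem_spec.base * s_un)
        per_arm_rows = {}
        for arm in ARMS:
            arm_specs = tr.per_arm[arm]
            p_adv = arm_specs["unidentified_to_id_advocate"].base
            p_noadv = arm_specs["unidentified_to_id_no_advocate"].base
            stay_un = (
                1.0
                - rem_spec.base
                - sh["unidentified_to_dead"].base
                - p_adv
                - p_noadv
            )
            if correlation == "shared":
                g_inc, g_stay_na_, g_rem = g_inc_s, g_stay_na_s, g_rem_s
            else:
                g_inc = _gamma(rng, inc_spec.base * s_na)
                g_stay_na_ = _gamma(rng, stay_na * s_na)
                g_rem = _gamma(rng, rem_spec.base * s_un)
            g_adv = _gamma(rng, p_adv * s_un)
            g_noadv = _gamma(rng, p_noadv * s_un)
            g_stay_un = _gamma(rng, stay_un * s_un)
            tot_na = g_inc + g_dead_na + g_stay_na_
            tot_un = g_rem + g_dead_un + g_adv + g_noadv + g_stay_un
            per_arm_rows[arm] = {
                "no_abuse_to_unidentified": g_inc / tot_na,
                "no_abuse_to_dead": g_dead_na / tot_na,
                "unidentified_to_no_abuse": g_rem / tot_un,
                "unidentified_to_dead": g_dead_un / tot_un,
                "unidentified_to_id_advocate": g_adv / tot_un,
                "unidentified_to_id_no_advocate": g_noadv / tot_un,
            }

    def build(arm: str) -> ParameterSet:
        rows = per_arm_rows[arm]
        shared_new = {name: _fixed(value) for name, value in common.items()}
        for name in (
            "no_abuse_to_unidentified",
            "no_abuse_to_dead",
            "unidentified_to_no_abuse",
            "unidentified_to_dead",
        ):
            shared_new[name] = _fixed(rows[name])
        per = {
            a: {
                "unidentified_to_id_advocate": _fixed(
                    rows["unidentified_to_id_advocate"]
                ),
                "unidentified_to_id_no_advocate": _fixed(
                    rows["unidentified_to_id_no_advocate"]
                ),
            }
            for a in ARMS
        }
        return ParameterSet(
            transitions=TransitionParameters(
                shared=shared_new,
                intervention=per["intervention"],
                control=per["control"],
            ),
            utilities=utilities,
            costs=costs,
            weights=params.weights,
            run=params.run,
        )

    sample_int = build("intervention")
    if correlation == "shared" and per_arm_rows["intervention"] == per_arm_rows[
        "control"
    ]:
        return PsaSample(intervention=sample_int, control=sample_int)
    return PsaSample(intervention=sample_int, control=build("control"))


def percentile_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation between order
    statistics) at the given coverage level."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DvaCeaError("percentile interval needs at least 2 values")
    if not (0.0 < level < 1.0):
        raise DvaCeaError("level must lie strictly between 0 and 1")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(v, [tail, 100.0 - tail])
    return float(lo), float(hi)


def ceac_curve(
    delta_cost: np.ndarray, delta_qalys: np.ndarray, lambda_grid: np.ndarray
) -> np.ndarray:
    """CEAC: share of draws with positive NMB at each threshold."""
    nmb = np.outer(lambda_grid, delta_qalys) - delta_cost[None, :]
    return (nmb > 0).mean(axis=1)


@dataclass
class PsaDraws:
    """PSA output: per-draw increments with derived summaries."""

    n_draws: int
    seed: int
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    lambda_grid: np.ndarray
    ceac: np.ndarray
    intervals: dict[str, tuple[float, float]]
    correlation: str = "independent"

    def ceac_at(self, wtp_lambda: float) -> float:
        """CEAC evaluated exactly at one threshold (not interpolated)."""
        nmb = wtp_lambda * self.delta_qalys - self.delta_cost
        return float((nmb > 0).mean())

    def write(self, outdir: str | Path) -> list[Path]:
        """Write ce_plane.csv, ceac.csv and psa_summary.json; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plane = outdir / "ce_plane.csv"
        pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        ).to_csv(plane, index=False)
        ceac = outdir / "ceac.csv"
        pd.DataFrame(
            {"lambda": self.lambda_grid, "probability": self.ceac}
        ).to_csv(ceac, index=False)
        summary = outdir / "psa_summary.json"
        summary.write_text(
            json.dumps(
                {
                    "n_draws": self.n_draws,
                    "seed": self.seed,
                    "correlation": self.correlation,
                    "ceac_at_20000": self.ceac_at(20_000.0),
                    "intervals": {k: list(v) for k, v in self.intervals.items()},
                    "mean_delta_cost": float(self.delta_cost.mean()),
                    "mean_delta_qalys": float(self.delta_qalys.mean()),
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        return [plane, ceac, summary]


def run_psa(
    params: ParameterSet,
    n_draws: int = 1000,
    seed: int = 1,
    lambda_grid: np.ndarray | None = None,
    correlation: str = "independent",
) -> PsaDraws:
    """Run the probabilistic sensitivity analysis.

    For each draw: sample a parameter set per arm, rerun both arms over
    the configured horizon, and record the incremental cost and QALYs.
    The 95% intervals cover incremental cost, incremental QALYs and the
    per-draw ICER (draws with zero QALY difference excluded from the
    ICER interval).
    """
    if n_draws < 1:
        raise DvaCeaError("n_draws must be >= 1")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        sample = sample_parameter_set(params, rng, correlation)
        results = {}
        for arm in ARMS:
            ps = sample.for_arm(arm)
            results[arm] = evaluate_arm(simulate_arm(ps, arm), ps, arm)
        inc = incremental(
            results["intervention"], results["control"], params.run.wtp_lambda
        )
        dc[i] = inc.delta_cost
        dq[i] = inc.delta_qalys
    intervals = {}
    if n_draws >= 2:
        intervals["delta_cost"] = percentile_interval(dc)
        intervals["delta_qalys"] = percentile_interval(dq)
        nonzero = dq != 0
        if nonzero.sum() >= 2:
            intervals["icer"] = percentile_interval(dc[nonzero] / dq[nonzero])
    return PsaDraws(
        n_draws=n_draws,
        seed=seed,
        delta_cost=dc,
        delta_qalys=dq,
        lambda_grid=grid,
        ceac=ceac_curve(dc, dq, grid),
        intervals=intervals,
        correlation=correlation,
    )
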