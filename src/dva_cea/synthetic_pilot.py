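"""Synthetic pilot-style data: identification counts and utility forms.

The model's primary-data inputs are (a) six-month identification/referral
counts out of registered practice populations — 99 337 patients eligible
in the intervention-arm practices (all ages and sexes) and 39 382 women
aged 16+ in the comparison practices — and (b) small samples of
preference-based utility scores from identified patients (about 30 forms
at the start of advocacy and 16 at follow-up). This module generates data
with that statistical structure from known "true" parameters and
estimates the model parameters back from them, closing the
parameter-recovery loop: identification probabilities are count/eligible
with Wilson-score intervals, baseline utility means feed the
'identified, not seeing advocate' state (copied to 'unidentified'), and
follow-up means feed 'identified and seeing advocate'.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import DvaCeaError, MissingParameterError
from .parameters import ParameterSet

#: Registered-population denominators.
DEFAULT_ELIGIBLE = {"intervention": 99_337, "control": 39_382}

#: Share of supported patients needing onward referral to another agency.
DEFAULT_ACCEPTANCE_SHARE = 0.39

#: Beta effective sample size for utility-score noise around the true mean.
DEFAULT_UTILITY_ESS = 35.0

#: Forms returned per subgroup: baseline totals 30, follow-up totals 16.
DEFAULT_FORM_COUNTS = {
    "baseline": {"women": 16, "men": 6, "children": 8},
    "follow_up": {"women": 8, "men": 3, "children": 5},
}

_TIMEPOINT_STATE = {"baseline": "id_no_advocate", "follow_up": "id_advocate"}


@dataclass
class PilotCounts:
    """Six-month identification and referral counts for one arm."""

    arm: str
    eligible_population: int
    n_identified_seeing_advocate: int
    n_identified_not_seeing: int
    n_accepting_support: int
    n_onward_referred: int

    def __post_init__(self) -> None:
        counts = (
            self.n_identified_seeing_advocate,
            self.n_identified_not_seeing,
            self.n_accepting_support,
            self.n_onward_referred,
        )
        if min(counts) < 0 or max(counts) > self.eligible_population:
            raise DvaCeaError(f"counts out of range for {self.arm}")
        identified = (
            self.n_identified_seeing_advocate + self.n_identified_not_seeing
        )
        if not (self.n_onward_referred <= self.n_accepting_support <= identified):
            raise DvaCeaError(
                f"{self.arm}: need onward <= accepting <= identified, got "
                f"{self.n_onward_referred} <= {self.n_accepting_support} "
                f"<= {identified}"
            )


@dataclass
class UtilitySample:
    """Utility scores for one subgroup at one timepoint."""

    subgroup: str
    timepoint: str  # "baseline" or "follow_up"
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise DvaCeaError("utility scores must lie in [0, 1]")
        self.values = v


@dataclass
class PilotData:
    """One synthetic pilot: per-arm counts plus utility samples."""

    counts: dict[str, PilotCounts]
    utilities: list[UtilitySample]


def generate_pilot(
    true_params: ParameterSet,
    seed: int,
    eligible: dict[str, int] | None = None,
    acceptance_share: float = DEFAULT_ACCEPTANCE_SHARE,
    utility_ess: float = DEFAULT_UTILITY_ESS,
    form_counts: dict[str, dict[str, int]] | None = None,
) -> PilotData:
    """Generate one seeded synthetic pilot dataset.

    Identification counts are Binomial(eligible, p) with p the true
    six-month identification probabilities; onward referrals are
    Binomial(accepting, acceptance_share) where the accepting pool is
    everyone seeing the advocate. Utility scores are Beta-distributed
    around the true state utilities with effective sample size
    ``utility_ess`` (so the [0, 1] support is respected).
    """
    rng = np.random.default_rng(seed)
    eligible = dict(DEFAULT_ELIGIBLE if eligible is None else eligible)
    form_counts = DEFAULT_FORM_COUNTS if form_counts is None else form_counts

    counts = {}
    for arm in ("intervention", "control"):
        probs = true_params.transitions.base_for_arm(arm)
        n = eligible[arm]
        n_adv = int(rng.binomial(n, probs["unidentified_to_id_advocate"]))
        n_noadv = int(rng.binomial(n, probs["unidentified_to_id_no_advocate"]))
        n_onward = int(rng.binomial(n_adv, acceptance_share))
        counts[arm] = PilotCounts(
            arm=arm,
            eligible_population=n,
            n_identified_seeing_advocate=n_adv,
            n_identified_not_seeing=n_noadv,
            n_accepting_support=n_adv,
            n_onward_referred=n_onward,
        )

    samples = []
    for timepoint, per_sub in form_counts.items():
        state = _TIMEPOINT_STATE[timepoint]
        for subgroup, n_forms in per_sub.items():
            mean = true_params.utilities.base(state, subgroup)
            a = mean * utility_ess
            b = (1.0 - mean) * utility_ess
            samples.append(
                UtilitySample(
                    subgroup=subgroup,
                    timepoint=timepoint,
                    values=rng.beta(a, b, size=n_forms),
                )
            )
    return PilotData(counts=counts, utilities=samples)


def estimate_identification_probability(
    count: int, eligible: int, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Six-month identification probability: count / eligible.

    Returns the point estimate with a Wilson-score interval at ``level``.
    """
    if eligible <= 0:
        raise DvaCeaError("eligible population must be > 0")
    if not (0 <= count <= eligible):
        raise DvaCeaError("count must lie in [0, eligible]")
    est = count / eligible
    lo, hi = proportion_confint(count, eligible, alpha=1 - level, method="wilson")
    return est, (max(0.0, float(lo)), min(1.0, float(hi)))


def estimate_utilities(
    samples: list[UtilitySample], level: float = 0.95
) -> dict[tuple[str, str], dict]:
    """Per-state, per-subgroup utility means with normal-approx intervals.

    Baseline means are attributed to 'identified, not seeing advocate' and
    copied to 'unidentified' (identification alone is assumed not to
    change quality of life); follow-up means go to 'identified and seeing
    advocate'.

    Raises
    ------
    MissingParameterError
        If a requested (timepoint, subgroup) cell has no observations.
    """
    from scipy import stats as sps

    z = float(sps.norm.ppf(0.5 + level / 2.0))
    pooled: dict[tuple[str, str], np.ndarray] = {}
    for s in samples:
        key = (s.timepoint, s.subgroup)
        pooled[key] = np.concatenate([pooled.get(key, np.array([])), s.values])

    out: dict[tuple[str, str], dict] = {}
    for (timepoint, subgroup), values in pooled.items():
        if values.size == 0:
            raise MissingParameterError(
                f"no utility observations for {timepoint}/{subgroup}"
            )
        mean = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
        cell = {
            "mean": mean,
            "n": int(values.size),
            "se": se,
            "interval": (mean - z * se, mean + z * se),
        }
        state = _TIMEPOINT_STATE[timepoint]
        out[(state, subgroup)] = cell
        if state == "id_no_advocate":
            out[("unidentified", subgroup)] = dict(cell)
    return out


@dataclass
class RecoveryReport:
    """Bias and interval coverage over replicated generate->estimate runs."""

    n_replicates: int
    bias: dict[str, float]
    coverage: dict[str, float]
    mean_interval_width: dict[str, float]


def recovery_study(
    true_params: ParameterSet, n_replicates: int, seed: int
) -> RecoveryReport:
    """Repeatedly generate a pilot, re-estimate, and score the estimators.

    Reports, for each arm's identification probabilities and each utility
    cell: the mean estimation error (bias), the share of replicates whose
    95% interval covers the truth, and the mean interval width.
    """
    if n_replicates < 10:
        raise DvaCeaError("recovery_study needs at least 10 replicates")
    errors: dict[str, list[float]] = {}
    covered: dict[str, list[bool]] = {}
    widths: dict[str, list[float]] = {}

    def record(name: str, est: float, truth: float, interval: tuple[float, float]):
        errors.setdefault(name, []).append(est - truth)
        covered.setdefault(name, []).append(interval[0] <= truth <= interval[1])
        widths.setdefault(name, []).append(interval[1] - interval[0])

    for rep in range(n_replicates):
        pilot = generate_pilot(true_params, seed=int(1e6) + seed * 1000 + rep)
        for arm, c in pilot.counts.items():
            probs = true_params.transitions.base_for_arm(arm)
            for label, count, pname in (
                ("id_advocate", c.n_identified_seeing_advocate,
                 "unidentified_to_id_advocate"),
                ("id_no_advocate", c.n_identified_not_seeing,
                 "unidentified_to_id_no_advocate"),
            ):
                est, ci = estimate_identification_probability(
                    count, c.eligible_population
                )
                record(f"{arm}.{label}", est, probs[pname], ci)
        estimates = estimate_utilities(pilot.utilities)
        for (state, subgroup), cell in estimates.items():
            if state == "unidentified":
                continue  # copy of id_no_advocate
            record(
                f"utility.{state}.{subgroup}",
                cell["mean"],
                true_params.utilities.base(state, subgroup),
                cell["interval"],
            )

    return RecoveryReport(
        n_replicates=n_replicates,
        bias={k: float(np.mean(v)) for k, v in errors.items()},
        coverage={k: float(np.mean(v)) for k, v in covered.items()},
        mean_interval_width={k: float(np.mean(v)) for k, v in widths.items()},
    )


def write_pilot(pilot: PilotData, outdir: str | Path) -> list[Path]:
    """Write counts.csv and utilities.csv for a synthetic pilot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / "counts.csv"
    with open(counts_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "arm",
                "eligible_population",
                "n_identified_seeing_advocate",
                "n_identified_not_seeing",
                "n_accepting_support",
                "n_onward_referred",
            ]
        )
        for arm, c in pilot.counts.items():
            w.writerow(
                [
                    arm,
                    c.eligible_population,
                    c.n_identified_seeing_advocate,
                    c.n_identified_not_seeing,
                    c.n_accepting_support,
                    c.n_onward_referred,
                ]
            )
    util_path = outdir / "utilities.csv"
    with open(util_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subgroup", "timepoint", "value"])
        for s in pilot.utilities:
            for v in s.values:
                w.writerow([s.subgroup, s.timepoint, repr(float(v))])
    return [counts_path, util_path]


def read_pilot(outdir: str | Path) -> PilotData:
    """Read a pilot written by :func:`write_pilot`."""
    outdir = Path(outdir)
    counts = {}
    with open(outdir / "counts.csv", newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            counts[rec["arm"]] = PilotCounts(
                arm=rec["arm"],
                eligible_population=int(rec["eligible_population"]),
                n_identified_seeing_advocate=int(
                    rec["n_identified_seeing_advocate"]
                ),
                n_identified_not_seeing=int(rec["n_identified_not_seeing"]),
                n_accepting_support=int(rec["n_accepting_support"]),
                n_onward_referred=int(rec["n_onward_referred"]),
            )
    groups: dict[tuple[str, str], list[float]] = {}
    with open(outdir / "utilities.csv", newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            groups.setdefault((rec["subgroup"], rec["timepoint"]), []).append(
                float(rec["value"])
            )
    samples = [
        UtilitySample(subgroup=sub, timepoint=tp, values=np.array(vals))
        for (sub, tp), vals in groups.items()
    ]
    return PilotData(counts=counts, utilities=samples)
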