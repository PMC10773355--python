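"""Model parameters: transition probabilities, utilities, costs, weights.

Every quantity carries its base value, 95% limits and distribution family
(a :class:`~dva_cea.distributions.DistributionSpec`), so the same object
drives both the deterministic base case and the probabilistic sensitivity
analysis. A configuration file shipped with the package
(``data/default_params.yaml``) holds the default base case.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

from .distributions import DistributionSpec
from .errors import MissingParameterError, ValidationError
from .states import HealthState

ARMS = ("intervention", "control")
SUBGROUPS = ("women", "men", "children")

#: Utility-bearing states, keyed as they appear in config files.
UTILITY_STATES = ("no_abuse", "unidentified", "id_advocate", "id_no_advocate")

#: Transition probabilities shared between arms.
SHARED_TRANSITIONS = (
    "prevalence_all_ages",
    "start_id_advocate",
    "start_id_no_advocate",
    "no_abuse_to_unidentified",
    "no_abuse_to_dead",
    "id_advocate_to_no_abuse",
    "id_advocate_to_dead",
    "id_no_advocate_to_no_abuse",
    "id_no_advocate_to_dead",
    "unidentified_to_no_abuse",
    "unidentified_to_dead",
)

#: Transition probabilities that differ by arm (identification rates).
ARM_TRANSITIONS = (
    "unidentified_to_id_advocate",
    "unidentified_to_id_no_advocate",
)

COST_FIELDS = (
    "intervention_cost_per_patient_per_cycle",
    "onward_referral_cost_once",
    "abuse_cost_adult_per_cycle",
    "abuse_cost_child_per_cycle",
    "abuse_cost_weighted_per_cycle",
    "cost_multiplier_id_advocate",
    "cost_multiplier_id_no_advocate",
)

#: Exit-probability names per source state (stay is always the complement).
ROW_EXITS: dict[str, tuple[str, ...]] = {
    "no_abuse": ("no_abuse_to_unidentified", "no_abuse_to_dead"),
    "unidentified": (
        "unidentified_to_no_abuse",
        "unidentified_to_id_advocate",
        "unidentified_to_id_no_advocate",
        "unidentified_to_dead",
    ),
    "id_advocate": ("id_advocate_to_no_abuse", "id_advocate_to_dead"),
    "id_no_advocate": ("id_no_advocate_to_no_abuse", "id_no_advocate_to_dead"),
}


@dataclass(frozen=True)
class SubgroupWeights:
    """Population shares of children and adult women/men.

    The UK census puts children at roughly 20% of the population; the adult
    remainder is split near-equally between women and men by default.
    """

    child_share: float = 0.20
    adult_female_share: float = 0.40
    adult_male_share: float = 0.40

    def __post_init__(self) -> None:
        total = self.child_share + self.adult_female_share + self.adult_male_share
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(
                f"subgroup weights must sum to 1, got {total!r}"
            )
        for name in ("child_share", "adult_female_share", "adult_male_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"weights.{name} out of [0,1]: {v}")

    def as_mapping(self) -> dict[str, float]:
        return {
            "children": self.child_share,
            "women": self.adult_female_share,
            "men": self.adult_male_share,
        }

    def to_dict(self) -> dict:
        return {
            "child_share": self.child_share,
            "adult_female_share": self.adult_female_share,
            "adult_male_share": self.adult_male_share,
        }


@dataclass(frozen=True)
class RunSettings:
    """Horizon and decision-rule settings.

    ``cycles`` counts six-month model cycles; the first cycle holds the
    initial distribution, so a 20-cycle run spans a 10-year horizon with 19
    transitions. Discounting is annual (UK guideline 3.5%) applied at
    half-year resolution; ``wtp_lambda`` is the willingness-to-pay
    threshold in GBP per QALY.
    """

    cycles: int = 20
    cohort: float = 10_000.0
    discount_annual: float = 0.035
    wtp_lambda: float = 20_000.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValidationError(f"run.cycles must be >= 1, got {self.cycles}")
        if self.cohort <= 0:
            raise ValidationError(f"run.cohort must be > 0, got {self.cohort}")
        if self.discount_annual < 0:
            raise ValidationError("run.discount_annual must be >= 0")

    def to_dict(self) -> dict:
        return {
            "cycles": self.cycles,
            "cohort": self.cohort,
            "discount_annual": self.discount_annual,
            "lambda": self.wtp_lambda,
        }


class UtilitySet:
    """Per-state, per-subgroup utility values with their distributions.

    The dead state carries utility zero by construction. At base case the
    'abuse unidentified' utilities equal the 'identified, not seeing
    advocate' utilities for every subgroup — identification alone, without
    advocacy, is assumed not to change quality of life.
    """

    def __init__(self, specs: dict[str, dict[str, DistributionSpec]]) -> None:
        for state in UTILITY_STATES:
            if state not in specs:
                raise MissingParameterError(f"utilities.{state} missing")
            for sub in SUBGROUPS:
                if sub not in specs[state]:
                    raise MissingParameterError(
                        f"utilities.{state}.{sub} missing"
                    )
                spec = specs[state][sub]
                if not (0.0 <= spec.base <= 1.0):
                    raise ValidationError(
                        f"utilities.{state}.{sub} base out of [0,1]: {spec.base}"
                    )
        for sub in SUBGROUPS:
            if (
                abs(
                    specs["unidentified"][sub].base
                    - specs["id_no_advocate"][sub].base
                )
                > 1e-12
            ):
                raise ValidationError(
                    f"utilities.unidentified.{sub} must equal "
                    f"utilities.id_no_advocate.{sub} at base case"
                )
        self._specs = specs

    def spec(self, state: str, subgroup: str) -> DistributionSpec:
        return self._specs[state][subgroup]

    def base(self, state: str, subgroup: str) -> float:
        return self._specs[state][subgroup].base

    def items(self) -> Iterator[tuple[str, str, DistributionSpec]]:
        for state in UTILITY_STATES:
            for sub in SUBGROUPS:
                yield state, sub, self._specs[state][sub]

    def replace_bases(self, new: dict[tuple[str, str], float]) -> "UtilitySet":
        specs = {
            state: {
                sub: DistributionSpec(
                    "fixed",
                    base=new.get((state, sub), self._specs[state][sub].base),
                    lower=new.get((state, sub), self._specs[state][sub].base),
                    upper=new.get((state, sub), self._specs[state][sub].base),
                )
                for sub in SUBGROUPS
            }
            for state in UTILITY_STATES
        }
        return UtilitySet(specs)

    def to_dict(self) -> dict:
        return {
            state: {sub: self._specs[state][sub].to_dict() for sub in SUBGROUPS}
            for state in UTILITY_STATES
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, UtilitySet) and self.to_dict() == other.to_dict()


class CostSet:
    """Societal per-cycle and one-off costs, with distributions.

    The abuse cost is the weighted societal cost of an exposed person per
    six months (health service, lost output, justice-system and personal
    costs; monetised QALY harms excluded to avoid double counting). The two
    multipliers scale it in the identified states.
    """

    def __init__(self, specs: dict[str, DistributionSpec]) -> None:
        for name in COST_FIELDS:
            if name not in specs:
                raise MissingParameterError(f"costs.{name} missing")
            if specs[name].base < 0:
                raise ValidationError(f"costs.{name} must be >= 0")
        for name in ("cost_multiplier_id_advocate", "cost_multiplier_id_no_advocate"):
            if specs[name].base <= 0:
                raise ValidationError(f"costs.{name} must be > 0")
        self._specs = specs

    def spec(self, name: str) -> DistributionSpec:
        return self._specs[name]

    def base(self, name: str) -> float:
        return self._specs[name].base

    def items(self) -> Iterator[tuple[str, DistributionSpec]]:
        for name in COST_FIELDS:
            yield name, self._specs[name]

    def to_dict(self) -> dict:
        return {name: self._specs[name].to_dict() for name in COST_FIELDS}

    def __eq__(self, other) -> bool:
        return isinstance(other, CostSet) and self.to_dict() == other.to_dict()


class TransitionParameters:
    """Named six-month transition probabilities, shared and per-arm."""

    def __init__(
        self,
        shared: dict[str, DistributionSpec],
        intervention: dict[str, DistributionSpec],
        control: dict[str, DistributionSpec],
    ) -> None:
        for name in SHARED_TRANSITIONS:
            if name not in shared:
                raise MissingParameterError(f"transitions.shared.{name} missing")
        for arm, specs in (("intervention", intervention), ("control", control)):
            for name in ARM_TRANSITIONS:
                if name not in specs:
                    raise MissingParameterError(
                        f"transitions.{arm}.{name} missing"
                    )
        self.shared = shared
        self.per_arm = {"intervention": intervention, "control": control}
        self._validate()

    def _validate(self) -> None:
        for name, spec in self.all_items():
            if not (0.0 <= spec.base <= 1.0):
                raise ValidationError(
                    f"transitions.{name} base out of [0,1]: {spec.base}"
                )
        split = self.shared["start_id_advocate"].base + self.shared[
            "start_id_no_advocate"
        ].base
        if split > 1.0:
            raise ValidationError(
                f"starting split exceeds 1: id_advocate + id_no_advocate = {split}"
            )
        for arm in ARMS:
            probs = self.base_for_arm(arm)
            for state, exits in ROW_EXITS.items():
                total = sum(probs[name] for name in exits)
                if total >= 1.0:
                    raise ValidationError(
                        f"{arm} exits from {state} sum to {total:.4f} >= 1; "
                        "no mass left for staying"
                    )

    def all_items(self) -> Iterator[tuple[str, DistributionSpec]]:
        for name in SHARED_TRANSITIONS:
            yield f"shared.{name}", self.shared[name]
        for arm in ARMS:
            for name in ARM_TRANSITIONS:
                yield f"{arm}.{name}", self.per_arm[arm][name]

    def spec_for_arm(self, arm: str) -> dict[str, DistributionSpec]:
        """Merged shared + arm-specific specs for one arm."""
        merged = dict(self.shared)
        merged.update(self.per_arm[arm])
        return merged

    def base_for_arm(self, arm: str) -> dict[str, float]:
        return {name: spec.base for name, spec in self.spec_for_arm(arm).items()}

    def to_dict(self) -> dict:
        return {
            "shared": {n: self.shared[n].to_dict() for n in SHARED_TRANSITIONS},
            "intervention": {
                n: self.per_arm["intervention"][n].to_dict()
                for n in ARM_TRANSITIONS
            },
            "control": {
                n: self.per_arm["control"][n].to_dict() for n in ARM_TRANSITIONS
            },
        }

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TransitionParameters)
            and self.to_dict() == other.to_dict()
        )


@dataclass
class ParameterSet:
    """Everything the model needs: transitions, utilities, costs, weights, run."""

    transitions: TransitionParameters
    utilities: UtilitySet
    costs: CostSet
    weights: SubgroupWeights = field(default_factory=SubgroupWeights)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        return {
            "run": self.run.to_dict(),
            "weights": self.weights.to_dict(),
            "transitions": self.transitions.to_dict(),
            "utilities": self.utilities.to_dict(),
            "costs": self.costs.to_dict(),
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.to_dict() == other.to_dict()

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )


def _specs_from(section: dict, prefix: str) -> dict[str, DistributionSpec]:
    out = {}
    for name, raw in section.items():
        if not isinstance(raw, dict):
            raise ValidationError(f"{prefix}.{name}: expected a mapping")
        out[name] = DistributionSpec.from_dict(raw, name=f"{prefix}.{name}")
    return out


def parameters_from_dict(doc: dict) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a parsed config."""
    for key in ("transitions", "utilities", "costs"):
        if key not in doc:
            raise MissingParameterError(f"config section {key!r} missing")
    tr = doc["transitions"]
    for key in ("shared", "intervention", "control"):
        if key not in tr:
            raise MissingParameterError(f"config section transitions.{key} missing")
    transitions = TransitionParameters(
        shared=_specs_from(tr["shared"], "transitions.shared"),
        intervention=_specs_from(tr["intervention"], "transitions.intervention"),
        control=_specs_from(tr["control"], "transitions.control"),
    )
    utilities = UtilitySet(
        {
            state: _specs_from(subs, f"utilities.{state}")
            for state, subs in doc["utilities"].items()
        }
    )
    costs = CostSet(_specs_from(doc["costs"], "costs"))
    w = doc.get("weights", {})
    weights = SubgroupWeights(
        child_share=float(w.get("child_share", 0.20)),
        adult_female_share=float(w.get("adult_female_share", 0.40)),
        adult_male_share=float(w.get("adult_male_share", 0.40)),
    )
    r = doc.get("run", {})
    run = RunSettings(
        cycles=int(r.get("cycles", 20)),
        cohort=float(r.get("cohort", 10_000)),
        discount_annual=float(r.get("discount_annual", 0.035)),
        wtp_lambda=float(r.get("lambda", 20_000)),
    )
    return ParameterSet(
        transitions=transitions,
        utilities=utilities,
        costs=costs,
        weights=weights,
        run=run,
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter configuration (YAML or JSON)."""
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValidationError(f"config {path} did not parse to a mapping")
    return parameters_from_dict(doc)


def default_config_path() -> Path:
    """Path of the shipped base-case configuration file."""
    return Path(resources.files("dva_cea").joinpath("data/default_params.yaml"))


def default_parameters() -> ParameterSet:
    """The shipped base case: published probabilities, utilities and costs."""
    return load_parameters(default_config_path())
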