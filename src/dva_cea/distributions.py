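"""Samplable distributions fitted from printed base values and 95% limits.

Published model-input tables in health economics typically report a point
estimate with lower/upper limits and a distribution family (Beta for
probabilities and utilities, Gamma for costs, Dirichlet for whole transition
rows, Uniform for ranges). This module turns such rows into frozen
scipy.stats distributions by moment matching:

* mean = the printed base value (the point estimate);
* standard deviation = (upper - lower) / 3.92, i.e. the limits are read as
  a symmetric 95% interval.

A zero-width interval yields a point mass, so deterministic (base-case)
analyses fall out of the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InfeasibleMomentsError, InvalidRowError, ValidationError

#: z-interval full width for a 95% normal interval, 2 * 1.96.
_Z95_WIDTH = 3.92

FAMILIES = ("beta", "gamma", "dirichlet_row", "uniform", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """One table row: distribution family, base value and 95% limits.

    Invariants (checked on construction): ``lower <= base <= upper``;
    a beta family needs all three in [0, 1]; a gamma family needs a
    non-negative base.
    """

    family: str
    base: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if not (self.lower <= self.base <= self.upper):
            raise ValidationError(
                f"limits must bracket the base value: "
                f"lower={self.lower} base={self.base} upper={self.upper}"
            )
        if self.family == "beta" and not (
            0.0 <= self.lower and self.upper <= 1.0
        ):
            raise ValidationError(
                f"beta requires base and limits in [0, 1], got "
                f"({self.lower}, {self.base}, {self.upper})"
            )
        if self.family == "gamma" and self.base < 0:
            raise ValidationError(f"gamma requires base >= 0, got {self.base}")

    @property
    def sd(self) -> float:
        """Moment-matched standard deviation from the 95% limit width."""
        return (self.upper - self.lower) / _Z95_WIDTH

    def fit(self):
        """Return the frozen samplable distribution for this spec."""
        if self.family == "fixed":
            return PointMass(self.base)
        if self.family == "beta":
            return fit_beta(self)
        if self.family == "gamma":
            return fit_gamma(self)
        if self.family == "uniform":
            if self.upper == self.lower:
                return PointMass(self.base)
            return stats.uniform(loc=self.lower, scale=self.upper - self.lower)
        raise ValidationError(
            "dirichlet_row specs are fitted jointly per transition row; "
            "use fit_dirichlet_row"
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "base": self.base,
            "lower": self.lower,
            "upper": self.upper,
        }

    @classmethod
    def from_dict(cls, d: dict, name: str = "<spec>") -> "DistributionSpec":
        try:
            return cls(
                family=str(d["family"]),
                base=float(d["base"]),
                lower=float(d.get("lower", d["base"])),
                upper=float(d.get("upper", d["base"])),
            )
        except KeyError as exc:  # pragma: no cover - exercised via load errors
            raise ValidationError(f"{name}: missing key {exc}") from exc


class PointMass:
    """Degenerate distribution concentrated at a single value.

    Mimics the small part of the frozen scipy.stats interface the package
    uses (``mean``, ``std``, ``rvs``, ``support``).
    """

    def __init__(self, value: float) -> None:
        self.value = float(value)

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0

    def support(self) -> tuple[float, float]:
        return (self.value, self.value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


def fit_beta(spec: DistributionSpec):
    """Fit a Beta distribution with mean = base, sd = limit width / 3.92.

    Raises
    ------
    InfeasibleMomentsError
        If the implied variance reaches ``mean * (1 - mean)``, which no
        Beta distribution can attain.
    """
    m = spec.base
    s = spec.sd
    if s == 0.0:
        return PointMass(m)
    v = s * s
    if v >= m * (1.0 - m):
        raise InfeasibleMomentsError(
            f"beta moment matching infeasible: variance {v:.6g} >= "
            f"mean(1-mean) = {m * (1 - m):.6g} for base {m}"
        )
    nu = m * (1.0 - m) / v - 1.0  # effective sample size minus... (a+b)
    return stats.beta(m * nu, (1.0 - m) * nu)


def fit_gamma(spec: DistributionSpec):
    """Fit a Gamma distribution with mean = base, sd = limit width / 3.92."""
    if spec.base <= 0:
        raise ValidationError(f"gamma fit requires base > 0, got {spec.base}")
    s = spec.sd
    if s == 0.0:
        return PointMass(spec.base)
    v = s * s
    shape = spec.base**2 / v
    scale = v / spec.base
    return stats.gamma(shape, scale=scale)


def dirichlet_concentration(first_entry: DistributionSpec) -> float:
    """Effective sample size for a Dirichlet row, moment-matched from the
    printed limits of the row's first non-complement entry."""
    m = first_entry.base
    v = first_entry.sd ** 2
    if v <= 0:
        raise InfeasibleMomentsError(
            "dirichlet concentration needs a non-degenerate first entry"
        )
    s = m * (1.0 - m) / v - 1.0
    if s <= 0:
        raise InfeasibleMomentsError(
            f"dirichlet concentration non-positive (s={s:.4g}); limits too wide"
        )
    return s


class DirichletRow:
    """Joint distribution over one transition row (exits plus complement).

    Draws are exact probability vectors: non-negative, summing to one.
    Components with zero base probability stay exactly zero in every draw.
    """

    def __init__(self, probs: Sequence[float], concentration: float) -> None:
        p = np.asarray(probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidRowError(
                f"row is not a probability vector: {p} (sum {p.sum():.12f})"
            )
        self.probs = p
        self.concentration = float(concentration)
        self._nonzero = np.flatnonzero(p > 0)
        self.alpha = p[self._nonzero] * self.concentration

    def mean(self) -> np.ndarray:
        return self.probs.copy()

    def rvs(self, size: int | None = None, random_state=None):
        rng = np.random.default_rng(random_state) if not isinstance(
            random_state, np.random.Generator
        ) else random_state
        n = 1 if size is None else int(size)
        out = np.zeros((n, self.probs.size))
        if self._nonzero.size == 1:
            out[:, self._nonzero[0]] = 1.0
        else:
            out[:, self._nonzero] = rng.dirichlet(self.alpha, size=n)
        return out[0] if size is None else out


def fit_dirichlet_row(
    probs: Sequence[float],
    limits: Sequence[tuple[float, float]],
) -> DirichletRow:
    """Fit a Dirichlet over one source state's full transition row.

    ``probs`` lists the exit probabilities followed by the "stay"
    complement, summing to one. The concentration (effective sample size)
    is moment-matched from the printed limits of the first non-complement
    entry: ``s = m(1-m)/v - 1`` with ``v = ((upper-lower)/3.92)^2``.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidRowError(
            f"row is not a probability vector: {p} (sum {p.sum():.12f})"
        )
    if p.size == 1 or np.count_nonzero(p) == 1:
        return DirichletRow(p, concentration=1.0)  # degenerate
    lo, hi = limits[0]
    first = DistributionSpec("beta", base=float(p[0]), lower=lo, upper=hi)
    return DirichletRow(p, concentration=dirichlet_concentration(first))
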