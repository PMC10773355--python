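"""Steady-state calibration of the abuse incidence and remission rates.

Two transition probabilities — 'no abuse -> abuse unidentified' (incidence)
and 'abuse unidentified -> no abuse' (remission) — are not observable from
routine primary-care data. They are instead pinned down by requiring that
the chain's long-run share of people in 'no abuse' matches a survey
prevalence target (94.5% for the 5.5% general-population prevalence; an
83% variant corresponds to the higher 17% prevalence reported among
GP attenders).

Because death is absorbing, the raw chain's only stationary distribution
puts everyone in 'dead'; a long-run prevalence is only meaningful on the
death-conditioned (alive) chain. Calibration therefore removes the dead
state and renormalizes each row before iterating.

With one target and two unknowns the problem is underdetermined, so one of
the pair is held fixed (by default the remission probability at its
published value 0.0500) and the other is solved by bisection. The share is
monotone in each probability, which makes bisection exact. Calibration uses
the control arm's identification probabilities: the target describes
pre-intervention natural history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationInfeasibleError, DegenerateRowError
from .markov import TransitionMatrix, build_matrix, initial_distribution
from .parameters import ParameterSet

#: Parameter names of the two calibrated probabilities.
ENTRY = "no_abuse_to_unidentified"   # incidence
EXIT = "unidentified_to_no_abuse"    # remission


@dataclass(frozen=True)
class CalibrationTarget:
    """Target long-run 'no abuse' share among the alive.

    ``fixed_side`` chooses which probability is held at its current value:
    ``"exit"`` fixes remission and solves incidence (the default),
    ``"entry"`` the reverse.
    """

    target_no_abuse_share: float = 0.945
    n_cycles: int = 3000
    fixed_side: str = "exit"
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.target_no_abuse_share < 1.0):
            raise ValueError("target share must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.fixed_side not in ("exit", "entry"):
            raise ValueError("fixed_side must be 'exit' or 'entry'")


@dataclass(frozen=True)
class CalibrationResult:
    """Solved probability pair and the share it achieves."""

    no_abuse_to_unidentified: float
    unidentified_to_no_abuse: float
    achieved_share: float
    target_share: float
    converged: bool


def alive_conditional_matrix(matrix: TransitionMatrix) -> np.ndarray:
    """Drop the dead row/column and renormalize rows to sum to one."""
    m = matrix.matrix
    sub = m[:-1, :-1]
    surv = sub.sum(axis=1)
    if np.any(surv <= 0):
        raise DegenerateRowError(
            "a state sends all its mass to death; alive-conditional chain undefined"
        )
    return sub / surv[:, None]


def steady_state_share(
    matrix: TransitionMatrix,
    init: np.ndarray | None = None,
    n_cycles: int = 3000,
    tolerance: float = 1e-6,
) -> tuple[float, bool]:
    """Long-run 'no abuse' share among the alive, by power iteration.

    Iterates the alive-conditional chain ``n_cycles`` times from ``init``
    (default: the model's standard initial distribution) and returns the
    resulting share together with a convergence flag (False when the share
    still moves by more than ``tolerance`` on the final iteration).
    """
    a = alive_conditional_matrix(matrix)
    if init is None:
        init = initial_distribution(0.055)
    v = np.asarray(init, dtype=float)[: a.shape[0]]
    v = v / v.sum()
    prev = v[0]
    for _ in range(n_cycles - 1):
        v = v @ a
    prev = v[0]
    v = v @ a
    return float(v[0]), bool(abs(v[0] - prev) <= tolerance)


def stationary_share(matrix: TransitionMatrix) -> float:
    """'No abuse' share of the alive chain's dominant left eigenvector.

    Independent closed-form check on :func:`steady_state_share`.
    """
    a = alive_conditional_matrix(matrix)
    vals, vecs = np.linalg.eig(a.T)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    v = v / v.sum()
    return float(v[0])


def _share_given(params: ParameterSet, entry: float, exit_: float) -> float:
    probs = params.transitions.base_for_arm("control")
    probs[ENTRY] = entry
    probs[EXIT] = exit_
    matrix = build_matrix(probs, arm="control")
    share, _ = steady_state_share(matrix)
    return share


def calibrate(
    params: ParameterSet, target: CalibrationTarget | None = None
) -> CalibrationResult:
    """Solve the free probability so the steady-state share hits the target.

    Bisection on [0, upper) where ``upper`` keeps the affected row
    feasible; stops when the achieved share is within ``target.tolerance``.

    Raises
    ------
    CalibrationInfeasibleError
        If no feasible value reaches the target; the message reports the
        achievable share range.
    """
    target = target or CalibrationTarget()
    base = params.transitions.base_for_arm("control")
    entry0, exit0 = base[ENTRY], base[EXIT]
    t = target.target_no_abuse_share

    if target.fixed_side == "exit":
        # share is strictly decreasing in the incidence probability
        def share(p: float) -> float:
            return _share_given(params, p, exit0)

        hi = 1.0 - base["no_abuse_to_dead"] - 1e-12
        increasing = False
    else:
        # share is strictly increasing in the remission probability
        def share(p: float) -> float:
            return _share_given(params, entry0, p)

        hi = 1.0 - (
            base["unidentified_to_dead"]
            + base["unidentified_to_id_advocate"]
            + base["unidentified_to_id_no_advocate"]
        ) - 1e-12
        increasing = True

    lo = 0.0
    s_lo, s_hi = share(lo), share(hi)
    s_min, s_max = min(s_lo, s_hi), max(s_lo, s_hi)
    if not (s_min - target.tolerance <= t <= s_max + target.tolerance):
        raise CalibrationInfeasibleError(
            f"target {t} outside achievable share range "
            f"[{s_min:.6f}, {s_max:.6f}]"
        )

    a, b = lo, hi
    p = 0.5 * (a + b)
    for _ in range(200):
        p = 0.5 * (a + b)
        s = share(p)
        if abs(s - t) < target.tolerance:
            break
        if (s > t) == increasing:
            b = p
        else:
            a = p
    achieved = share(p)
    if target.fixed_side == "exit":
        entry, exit_ = p, exit0
    else:
        entry, exit_ = entry0, p
    return CalibrationResult(
        no_abuse_to_unidentified=entry,
        unidentified_to_no_abuse=exit_,
        achieved_share=achieved,
        target_share=t,
        converged=abs(achieved - t) < target.tolerance,
    )


def apply_calibration(
    params: ParameterSet, result: CalibrationResult
) -> ParameterSet:
    """Return a copy of ``params`` with the calibrated pair substituted.

    The substituted values become point estimates; their uncertainty limits
    are kept so the probabilistic analysis still samples them.
    """
    new = params.copy()
    for name, value in (
        (ENTRY, result.no_abuse_to_unidentified),
        (EXIT, result.unidentified_to_no_abuse),
    ):
        old = new.transitions.shared[name]
        shift = value - old.base
        from .distributions import DistributionSpec

        new.transitions.shared[name] = DistributionSpec(
            family=old.family,
            base=value,
            lower=max(0.0, old.lower + shift),
            upper=min(1.0, old.upper + shift),
        )
    return new
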