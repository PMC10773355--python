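"""Transition matrices and the deterministic cohort simulation.

The model moves a closed hypothetical cohort (default 10 000 people)
between the five health states in six-month cycles. Permitted movements:

* no abuse -> abuse unidentified (new abuse), or death;
* abuse unidentified -> no abuse (abuse ends), identified seeing advocate,
  identified not seeing advocate, or death;
* either identified state -> no abuse, or death — but never between the
  two identified states (advocacy is offered once, at referral);
* death is absorbing.

The cohort simulation is deterministic: expected occupancies are carried
as exact fractional persons and only rounded at reporting time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import DvaCeaError, InfeasibleRowError, InvalidRowError
from .states import N_STATES, STATE_INDEX, STATE_ORDER, HealthState

_NO, _UN, _ADV, _NOADV, _DEAD = range(N_STATES)


@dataclass(frozen=True)
class TransitionMatrix:
    """A validated 5x5 row-stochastic per-arm transition matrix."""

    arm: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise InvalidRowError(f"expected a 5x5 matrix, got {m.shape}")
        if np.any(m < 0) or np.any(m > 1):
            raise InvalidRowError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
            raise InvalidRowError(
                f"rows must sum to 1, got {m.sum(axis=1)}"
            )
        if not np.array_equal(m[_DEAD], np.eye(N_STATES)[_DEAD]):
            raise InvalidRowError("death must be absorbing")
        for i, j in ((_ADV, _NOADV), (_NOADV, _ADV), (_NO, _ADV), (_NO, _NOADV)):
            if m[i, j] != 0.0:
                raise InvalidRowError(
                    f"forbidden transition {STATE_ORDER[i].value} -> "
                    f"{STATE_ORDER[j].value} must be zero"
                )
        object.__setattr__(self, "matrix", m)


def build_matrix(probs: Mapping[str, float], arm: str) -> TransitionMatrix:
    """Assemble one arm's transition matrix from named probabilities.

    ``probs`` maps the named six-month exit probabilities (as produced by
    :meth:`TransitionParameters.base_for_arm`) to values; each diagonal
    "stay" entry is the complement of the row's exits.

    Raises
    ------
    InfeasibleRowError
        If any row's exits exceed 1, naming the source state.
    """
    m = np.zeros((N_STATES, N_STATES))
    m[_NO, _UN] = probs["no_abuse_to_unidentified"]
    m[_NO, _DEAD] = probs["no_abuse_to_dead"]
    m[_UN, _NO] = probs["unidentified_to_no_abuse"]
    m[_UN, _ADV] = probs["unidentified_to_id_advocate"]
    m[_UN, _NOADV] = probs["unidentified_to_id_no_advocate"]
    m[_UN, _DEAD] = probs["unidentified_to_dead"]
    m[_ADV, _NO] = probs["id_advocate_to_no_abuse"]
    m[_ADV, _DEAD] = probs["id_advocate_to_dead"]
    m[_NOADV, _NO] = probs["id_no_advocate_to_no_abuse"]
    m[_NOADV, _DEAD] = probs["id_no_advocate_to_dead"]
    m[_DEAD, _DEAD] = 1.0
    for i in range(N_STATES - 1):
        stay = 1.0 - m[i].sum()
        if stay < 0:
            raise InfeasibleRowError(
                f"{arm}: exits from {STATE_ORDER[i].value} sum to "
                f"{m[i].sum():.4f} > 1"
            )
        m[i, i] = stay
    return TransitionMatrix(arm=arm, matrix=m)


def initial_distribution(
    prevalence: float,
    split: Mapping[str, float] | None = None,
    cohort: float = 10_000.0,
) -> np.ndarray:
    """Starting occupancy row for a cohort.

    A share ``prevalence`` of the cohort starts in the abuse states, split
    between 'identified seeing advocate', 'identified not seeing advocate'
    and (as the complement) 'unidentified'; everyone else starts in
    'no abuse'. The default split (0.003 / 0.033 / 0.964) puts 94.5% of a
    5.5%-prevalence cohort in 'no abuse' and 5.3% in 'abuse unidentified'.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise InvalidRowError(f"prevalence out of [0,1]: {prevalence}")
    split = split or {"id_advocate": 0.003, "id_no_advocate": 0.033}
    p_adv = split["id_advocate"]
    p_noadv = split["id_no_advocate"]
    if p_adv < 0 or p_noadv < 0 or p_adv + p_noadv > 1.0:
        raise InvalidRowError(
            f"invalid starting split: id_advocate={p_adv}, "
            f"id_no_advocate={p_noadv}"
        )
    occ = np.zeros(N_STATES)
    occ[_NO] = (1.0 - prevalence) * cohort
    occ[_ADV] = prevalence * p_adv * cohort
    occ[_NOADV] = prevalence * p_noadv * cohort
    occ[_UN] = prevalence * (1.0 - p_adv - p_noadv) * cohort
    return occ


@dataclass
class CohortTrace:
    """Cohort occupancy over cycles, plus per-cycle new entrants.

    ``occupancy`` has one row per cycle point (row 0 is the initial
    distribution) and one column per state. ``new_entrants[k, s]`` is the
    expected number of persons entering state ``s`` during the transition
    into row ``k`` from a different state (row 0 is all zeros); it drives
    one-off costing such as the onward-referral fee.
    """

    cohort_size: float
    occupancy: np.ndarray
    new_entrants: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.occupancy.shape[0]

    def validate(self) -> None:
        if np.any(self.occupancy < -1e-9):
            raise DvaCeaError("negative occupancy in trace")
        sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(sums - self.cohort_size)) > 1e-6:
            raise DvaCeaError("trace rows do not conserve the cohort")
        dead = self.occupancy[:, _DEAD]
        if np.any(np.diff(dead) < -1e-9):
            raise DvaCeaError("dead occupancy must be non-decreasing")


def run_cohort(
    matrix: TransitionMatrix, init: np.ndarray, n_cycles: int
) -> CohortTrace:
    """Run the deterministic cohort simulation for ``n_cycles`` transitions.

    Returns a trace with ``n_cycles + 1`` occupancy rows: row 0 is ``init``
    and row k is ``row[k-1] @ matrix``. Fractional persons are carried
    exactly.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (N_STATES,):
        raise DvaCeaError(f"initial occupancy must have {N_STATES} entries")
    if n_cycles < 0:
        raise DvaCeaError("n_cycles must be >= 0")
    m = matrix.matrix
    occ = np.zeros((n_cycles + 1, N_STATES))
    new = np.zeros((n_cycles + 1, N_STATES))
    occ[0] = init
    off_diag = m - np.diag(np.diag(m))
    for k in range(1, n_cycles + 1):
        occ[k] = occ[k - 1] @ m
        new[k] = occ[k - 1] @ off_diag
    trace = CohortTrace(
        cohort_size=float(init.sum()), occupancy=occ, new_entrants=new
    )
    trace.validate()
    return trace


def occupancy_at(trace: CohortTrace, state: HealthState, row: int = -1) -> float:
    """Occupancy of one state at a given trace row (default: final)."""
    return float(trace.occupancy[row, STATE_INDEX[state]])


def write_trace(trace: CohortTrace, path: str | Path, arm: str) -> None:
    """Write one arm's trace as CSV (cycle, state, occupancy, new_entrants).

    Cycle numbering is 1-based: cycle 1 is the initial distribution.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["arm", "cycle", "state", "occupancy", "new_entrants"])
        for k in range(trace.n_rows):
            for s, state in enumerate(STATE_ORDER):
                writer.writerow(
                    [
                        arm,
                        k + 1,
                        state.value,
                        repr(float(trace.occupancy[k, s])),
                        repr(float(trace.new_entrants[k, s])),
                    ]
                )


def read_trace(path: str | Path) -> tuple[str, CohortTrace]:
    """Read a trace CSV back into a :class:`CohortTrace`."""
    rows: dict[int, dict[str, tuple[float, float]]] = {}
    arm = ""
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            arm = rec["arm"]
            rows.setdefault(int(rec["cycle"]), {})[rec["state"]] = (
                float(rec["occupancy"]),
                float(rec["new_entrants"]),
            )
    n = len(rows)
    occ = np.zeros((n, N_STATES))
    new = np.zeros((n, N_STATES))
    for k in range(n):
        for s, state in enumerate(STATE_ORDER):
            occ[k, s], new[k, s] = rows[k + 1][state.value]
    return arm, CohortTrace(
        cohort_size=float(occ[0].sum()), occupancy=occ, new_entrants=new
    )
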