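"""Three-state cohort model over 21-day cycles.

States are progression-free disease (PFD), progressed disease (PD) and
death.  The whole cohort starts in PFD.  State occupancy is derived from
the progression-free and overall survival curves by partitioned-survival
assignment: at cycle time t,

    Dead(t) = 1 - S_OS(t)
    PFD(t)  = min(S_PFS(t), S_OS(t))
    PD(t)   = 1 - Dead(t) - PFD(t)

which reproduces both marginal curves exactly and needs no assumption about
the progressed-to-death transition.  When HR-powered curves cross
(S_PFS > S_OS), PFD is clamped to S_OS and the number of clamped cycles is
recorded on the trace.  A conventional forward Markov simulation using
per-cycle conditional probabilities is provided as an alternative engine;
for non-crossing curves it coincides with the partitioned assignment.

Calendar conventions: 365.25 days/year, 30.4375 days/month; a 20-year
horizon at 21-day cycles gives 348 cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "CycleGrid",
    "CohortTrace",
    "state_occupancy",
    "transition_probs",
    "simulate_markov",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

_STATE_COLUMNS = ("pfd", "pd", "dead")


@dataclass(frozen=True)
class CycleGrid:
    """Cycle timing: cycle k spans [k*L, (k+1)*L) days."""

    cycle_length_days: float = 21.0
    horizon_years: float = 20.0

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    def times_months(self) -> np.ndarray:
        """Cycle-start times in months, length n_cycles + 1."""
        return np.arange(self.n_cycles + 1) * self.cycle_length_days / DAYS_PER_MONTH


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy matrix, rows (n_cycles+1) x columns (PFD, PD, Dead)."""

    occupancy: np.ndarray
    times_months: np.ndarray
    clamp_count: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupancy must be (n_cycles+1) x 3")
        if occ.shape[0] != len(self.times_months):
            raise ValueError("occupancy and times length mismatch")
        if np.any(occ < -1e-12):
            raise ValueError("negative occupancy")
        rowsums = occ.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("trace rows must sum to 1 within 1e-9")
        if not np.allclose(occ[0], [1.0, 0.0, 0.0]):
            raise ValueError("cohort must start fully in PFD")

    @property
    def pfd(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def pd_state(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, 2]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.times_months)),
                "time_months": self.times_months,
                "pfd": self.pfd,
                "pd": self.pd_state,
                "dead": self.dead,
            }
        )


def _eval_curve(fn, t: np.ndarray, name: str) -> np.ndarray:
    s = np.asarray(fn(t), dtype=float)
    if s.shape != t.shape:
        raise ValueError(f"{name} evaluator must be vectorised over times")
    if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
        raise ValueError(f"{name} evaluator returned values outside [0, 1]")
    return np.clip(s, 0.0, 1.0)


def state_occupancy(s_pfs, s_os, grid: CycleGrid | None = None) -> CohortTrace:
    """Partitioned-survival occupancy from PFS and OS evaluators.

    Evaluators are callables S(t) on times in months, vectorised.
    """
    grid = grid or CycleGrid()
    t = grid.times_months()
    spfs = _eval_curve(s_pfs, t, "PFS")
    sos = _eval_curve(s_os, t, "OS")
    clamp = int(np.sum(spfs > sos + 1e-12))
    pfd = np.minimum(spfs, sos)
    dead = 1.0 - sos
    pd_ = np.clip(sos - pfd, 0.0, None)
    occ = np.column_stack([pfd, pd_, dead])
    occ /= occ.sum(axis=1, keepdims=True)
    return CohortTrace(occupancy=occ, times_months=t, clamp_count=clamp)


def transition_probs(s, k: int, grid: CycleGrid | None = None) -> float:
    """Conditional per-cycle event probability 1 - S(t_{k+1})/S(t_k).

    Returns 1.0 by convention when the cohort is already absorbed
    (S(t_k) == 0).
    """
    grid = grid or CycleGrid()
    t = grid.times_months()
    if not 0 <= k < grid.n_cycles:
        raise ValueError(f"cycle index {k} out of range [0, {grid.n_cycles})")
    s0 = float(s(t[k]))
    s1 = float(s(t[k + 1]))
    if s0 <= 0.0:
        return 1.0
    return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))


def simulate_markov(s_pfs, s_os, grid: CycleGrid | None = None) -> CohortTrace:
    """Forward Markov engine: PFD exits via the PFS curve, and the
    progressed-to-death probability is solved each cycle so cumulative
    deaths match the OS curve.

    Coincides with :func:`state_occupancy` when the curves do not cross.
    """
    grid = grid or CycleGrid()
    t = grid.times_months()
    spfs = _eval_curve(s_pfs, t, "PFS")
    sos = _eval_curve(s_os, t, "OS")
    n = grid.n_cycles
    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    clamp = 0
    for k in range(n):
        pfd, pd_, dead = occ[k]
        # PFD shrinks in proportion to the PFS curve
        ratio = spfs[k + 1] / spfs[k] if spfs[k] > 0 else 0.0
        pfd_next = pfd * min(ratio, 1.0)
        dead_next = 1.0 - sos[k + 1]
        if pfd_next > sos[k + 1] + 1e-12:
            clamp += 1
            pfd_next = sos[k + 1]
        pd_next = max(1.0 - pfd_next - dead_next, 0.0)
        occ[k + 1] = (pfd_next, pd_next, dead_next)
    occ /= occ.sum(axis=1, keepdims=True)
    return CohortTrace(occupancy=occ, times_months=t, clamp_count=clamp)
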