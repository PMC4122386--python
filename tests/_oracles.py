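"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: probabilities
are obtained by compounding micro-steps or by individual-level simulation.
"""

from __future__ import annotations

import numpy as np

from oacce.cohort import CohortTrace
from oacce.risk import Block, TransitionModel, WEEKS_PER_YEAR
from oacce.states import State, Therapy


def microstep_probability(rate_per_100py: float, cycle_weeks: float, n_steps: int = 10_000) -> float:
    """Per-cycle event probability by compounding 10^4 discrete sub-steps."""
    dt = (cycle_weeks / WEEKS_PER_YEAR) / n_steps
    p_step = (rate_per_100py / 100.0) * dt
    return 1.0 - (1.0 - p_step) ** n_steps


def microstep_two_event(rate_a: float, rate_d: float, cycle_weeks: float, n_steps: int = 10_000):
    """Exhaustive micro-step enumeration of one cycle with a state-change
    event (rate_a) and death (rate_d, active in every state).

    Returns (p_stay, p_in_a_alive, p_dead).
    """
    dt = (cycle_weeks / WEEKS_PER_YEAR) / n_steps
    pa = (rate_a / 100.0) * dt
    pd = (rate_d / 100.0) * dt
    stay, in_a, dead = 1.0, 0.0, 0.0
    for _ in range(n_steps):
        new_dead = dead + stay * pd + in_a * pd
        new_in_a = in_a * (1.0 - pd) + stay * (1.0 - pd) * pa
        new_stay = stay * (1.0 - pd) * (1.0 - pa)
        stay, in_a, dead = new_stay, new_in_a, new_dead
    return stay, in_a, dead


class _TinySpace:
    """Minimal state space for hand-built transition matrices."""

    def __init__(self, n: int, entry_index: int = 0, dead_index: int | None = None):
        self.states = [State("baseline", Therapy.APIXABAN) for _ in range(n - 1)] + [State("dead")]
        self.dead_index = dead_index if dead_index is not None else n - 1
        self.entry_index = entry_index

    def __len__(self):
        return len(self.states)


def make_constant_model(matrix: np.ndarray, n_cycles: int, cycle_weeks: float = 6.0) -> TransitionModel:
    """A TransitionModel applying one fixed matrix every cycle; the last
    state is `dead`."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    space = _TinySpace(n)
    key = (0, False)
    return TransitionModel(
        states=space,
        event_keys=[],
        blocks={key: Block(matrix=matrix, flows=np.zeros((0, n)))},
        block_of_cycle=[key] * n_cycles,
        cycle_length_weeks=cycle_weeks,
        arm=Therapy.APIXABAN,
        start_age=70.0,
    )


def microsimulate(matrix: np.ndarray, n_cycles: int, n_traj: int, seed: int) -> np.ndarray:
    """Individual-level Monte-Carlo of a constant transition matrix.

    Returns the count of trajectories in each state after `n_cycles` cycles,
    all started in state 0.
    """
    rng = np.random.default_rng(seed)
    cum = np.cumsum(np.asarray(matrix, dtype=float), axis=1)
    state = np.zeros(n_traj, dtype=np.int64)
    for _ in range(n_cycles):
        u = rng.random(n_traj)
        state = (cum[state] < u[:, None]).sum(axis=1)
    return np.bincount(state, minlength=matrix.shape[0])


def check_within_mc_error(counts: np.ndarray, expected: np.ndarray, n_traj: int, z: float = 3.0):
    """Assert each state count is within z Monte-Carlo standard errors of the
    cohort-model expectation."""
    p = np.clip(expected / n_traj, 0.0, 1.0)
    se = np.sqrt(n_traj * p * (1.0 - p))
    diff = np.abs(counts - expected)
    assert np.all(diff <= z * se + 1e-9), f"microsimulation deviates: diff={diff}, allowed={z * se}"
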