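"""Mixture-of-agents learning and choice: MB, SR, and TD(1) valuation.

All three agents share a single Rescorla-Wagner estimate of each boat's
reward probability, updated with an *active* learning rate on traversal
trials and a *passive* rate on non-traversal trials. They differ in how they
turn boat values into island values:

* **MB** — recursive maximization: an island is worth its better boat.
* **SR** — on-policy averaging: an island is worth the occupancy-weighted
  mean of its boats, where the occupancy matrix ``M`` is learned from the
  subject's own boat choices (Hebbian delta rule).
* **TD(1)** — a cached island value bootstrapped from the chosen boat's
  value, with no world model.

Island choice is a softmax over the weighted sum of the three agents' values
plus a perseveration bonus for the previously chosen island; boat choice is a
softmax over the island's two boat values with its own perseveration term.

State transitions here are pure (each step returns a new state); the fitting
code uses an equivalent compiled kernel, checked against these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .task import BOAT_ISLAND, TrialRecord

__all__ = [
    "AgentParams",
    "AgentState",
    "initial_state",
    "update_boat_value",
    "boat_choice_probs",
    "mb_island_values",
    "sr_update_M",
    "sr_island_values",
    "td_update",
    "island_choice_probs",
    "step_trial",
    "softmax2",
]


def softmax2(x: np.ndarray) -> np.ndarray:
    """Stable two-way softmax."""
    x = np.asarray(x, dtype=float)
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the mixture model (natural scale).

    Learning rates live in (0,1); softmax temperatures and perseveration
    weights are unconstrained reals.
    """

    alpha_A: float = 0.3
    alpha_P: float = 0.3
    alpha_M: float = 0.3
    beta_boat: float = 1.0
    beta_MB: float = 1.0
    beta_SR: float = 1.0
    beta_TD: float = 0.0
    beta_persist_boat: float = 0.0
    beta_persist_island: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_A", "alpha_P", "alpha_M"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0,1)")


@dataclass
class AgentState:
    """Learned quantities carried across trials.

    ``m_sr`` rows are occupancy distributions over each island's own boats
    (off-island entries are structurally zero and each row sums to 1).
    ``last_boat[i]`` is the most recently chosen boat at island ``i`` (-1 if
    none yet); ``last_island`` the previous traversal's island choice.
    """

    v_boat: np.ndarray
    m_sr: np.ndarray
    v_td: np.ndarray
    last_boat: np.ndarray
    last_island: int

    def copy(self) -> "AgentState":
        return AgentState(
            v_boat=self.v_boat.copy(),
            m_sr=self.m_sr.copy(),
            v_td=self.v_td.copy(),
            last_boat=self.last_boat.copy(),
            last_island=self.last_island,
        )

    def to_dict(self) -> dict:
        return {
            "v_boat": self.v_boat.tolist(),
            "m_sr": self.m_sr.tolist(),
            "v_td": self.v_td.tolist(),
            "last_boat": self.last_boat.tolist(),
            "last_island": int(self.last_island),
        }


def initial_state() -> AgentState:
    """Uninformative start: boat/TD values at the reward midpoint 0.5 and
    uniform occupancy over each island's own boats."""
    return AgentState(
        v_boat=np.full(4, 0.5),
        m_sr=np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]]),
        v_td=np.full(2, 0.5),
        last_boat=np.array([-1, -1]),
        last_island=-1,
    )


def update_boat_value(
    state: AgentState,
    boat: int,
    reward: int,
    trial_type: str,
    params: AgentParams,
) -> AgentState:
    """Delta-rule update of the sampled boat's value.

    Uses the active rate on traversal trials, the passive rate on
    non-traversal trials; only the sampled boat changes.
    """
    alpha = params.alpha_A if trial_type == "traversal" else params.alpha_P
    out = state.copy()
    out.v_boat[boat] = (1.0 - alpha) * state.v_boat[boat] + alpha * reward
    return out


def boat_choice_probs(
    state: AgentState, island: int, params: AgentParams
) -> np.ndarray:
    """Softmax over the two boats on ``island`` with perseveration bonus."""
    b0 = 2 * island
    x = params.beta_boat * state.v_boat[b0 : b0 + 2].copy()
    if state.last_boat[island] >= 0:
        x[state.last_boat[island] - b0] += params.beta_persist_boat
    return softmax2(x)


def mb_island_values(state: AgentState) -> np.ndarray:
    """Model-based island values: per-island max over boat values."""
    return np.array(
        [state.v_boat[:2].max(), state.v_boat[2:].max()]
    )


def sr_update_M(
    state: AgentState, island: int, chosen_boat: int, params: AgentParams
) -> AgentState:
    """Hebbian update of the visited island's occupancy row.

    Both of the island's boats move (indicator 1 for the chosen, 0 for the
    unchosen), so the row stays normalized; the other island is untouched.
    """
    if BOAT_ISLAND[chosen_boat] != island:
        raise ValueError(f"boat {chosen_boat} is not on island {island}")
    out = state.copy()
    b0 = 2 * island
    for b in (b0, b0 + 1):
        ind = 1.0 if b == chosen_boat else 0.0
        out.m_sr[island, b] = params.alpha_M * ind + (1.0 - params.alpha_M) * state.m_sr[island, b]
    return out


def sr_island_values(state: AgentState) -> np.ndarray:
    """SR island values V = M R with R the learned boat values."""
    return state.m_sr @ state.v_boat


def td_update(
    state: AgentState, island: int, chosen_boat: int, params: AgentParams
) -> AgentState:
    """TD(1) cache: step the chosen island's value toward the chosen boat's
    (already-updated) value with the active learning rate."""
    if BOAT_ISLAND[chosen_boat] != island:
        raise ValueError(f"boat {chosen_boat} is not on island {island}")
    out = state.copy()
    out.v_td[island] = (
        (1.0 - params.alpha_A) * state.v_td[island]
        + params.alpha_A * state.v_boat[chosen_boat]
    )
    return out


def island_choice_probs(state: AgentState, params: AgentParams) -> np.ndarray:
    """Softmax over islands combining MB, SR and TD values plus perseveration."""
    x = (
        params.beta_MB * mb_island_values(state)
        + params.beta_SR * sr_island_values(state)
        + params.beta_TD * state.v_td
    )
    if state.last_island >= 0:
        x = x.copy()
        x[state.last_island] += params.beta_persist_island
    return softmax2(x)


def step_trial(
    state: AgentState, record: TrialRecord, params: AgentParams
) -> AgentState:
    """Apply one trial's learning.

    Traversal: boat-value update (active rate) first, then the SR occupancy
    and TD updates (TD bootstraps from the just-updated boat value), then the
    last-chosen indicators. Non-traversal: passive boat-value update only —
    no island is visited, so M, TD and perseveration are untouched.
    """
    if record.trial_type == "traversal":
        island = record.island_choice
        state = update_boat_value(state, record.boat, record.reward, "traversal", params)
        state = sr_update_M(state, island, record.boat, params)
        state = td_update(state, island, record.boat, params)
        state.last_boat[island] = record.boat
        state.last_island = island
        return state
    return update_boat_value(state, record.boat, record.reward, "nontraversal", params)
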