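"""Linear RL valuation: a single computation spanning SR-like to MB-like.

Linear RL evaluates non-terminal states under a learned *default* transition
model T, but passes rewards through an exponential nonlinearity scaled by a
temporal-abstraction parameter lambda:

    v*(island) = lambda * log sum_b T[island, b] * exp(V(b) / lambda)

As lambda -> 0 this approaches the per-island max over boats (model-based
evaluation); as lambda -> infinity it approaches the T-weighted mean (the SR
value with occupancy T). The price of MB-like precision is explicit: the
intermediate quantities exp(V/lambda) grow without bound as lambda shrinks.

The general default-representation matrix M = (diag(exp(-r_N/lambda)) -
T_NN)^{-1} is implemented for arbitrary chains; in this task islands lead
only to terminal boats (T_NN = 0) and island rewards are zero, so M is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .task import BOAT_ISLAND, TrialRecord

__all__ = [
    "LRLParams",
    "LRLState",
    "initial_lrl_state",
    "compute_dr",
    "lrl_island_values",
    "update_T",
    "lrl_choice_probs",
    "step_trial_lrl",
    "value_magnitude",
]


@dataclass(frozen=True)
class LRLParams:
    """Linear-RL free parameters (natural scale).

    ``lam`` is the temporal-abstraction scale (>0). ``beta_TD`` weights an
    auxiliary TD(1) island value in the choice rule; it is fixed at 0 for the
    plain linear-RL model and freed in the blockwise variant. Boat-level
    softmax parameters are shared with the mixture model's choice rule.
    """

    lam: float = 0.5
    alpha_T: float = 0.3
    beta_lrl: float = 1.0
    beta_TD: float = 0.0
    alpha_A: float = 0.3
    alpha_P: float = 0.3
    beta_boat: float = 1.0
    beta_persist_boat: float = 0.0
    beta_persist_island: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam={self.lam} must be strictly positive")
        for name in ("alpha_T", "alpha_A", "alpha_P"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0,1)")


@dataclass
class LRLState:
    """Learned linear-RL quantities.

    ``T`` is the default island-to-boat transition model (row-stochastic,
    support restricted to each island's own boats), updated by the same
    Hebbian rule as the SR occupancy matrix. ``v_boat`` doubles as the
    terminal reward vector r_T; island rewards are fixed at zero.
    """

    T: np.ndarray
    v_boat: np.ndarray
    v_td: np.ndarray
    last_boat: np.ndarray
    last_island: int

    def copy(self) -> "LRLState":
        return LRLState(
            T=self.T.copy(),
            v_boat=self.v_boat.copy(),
            v_td=self.v_td.copy(),
            last_boat=self.last_boat.copy(),
            last_island=self.last_island,
        )


def initial_lrl_state() -> LRLState:
    return LRLState(
        T=np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]]),
        v_boat=np.full(4, 0.5),
        v_td=np.full(2, 0.5),
        last_boat=np.array([-1, -1]),
        last_island=-1,
    )


def compute_dr(T_NN: np.ndarray, r_N: np.ndarray, lam: float) -> np.ndarray:
    """Default representation M = (diag(exp(-r_N/lam)) - T_NN)^{-1}.

    Raises on a singular system rather than regularizing silently. For this
    task T_NN = 0 and r_N = 0, giving the identity.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    T_NN = np.asarray(T_NN, dtype=float)
    r_N = np.asarray(r_N, dtype=float)
    A = np.diag(np.exp(-r_N / lam)) - T_NN
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "default-representation system is singular for this T_NN/r_N/lam"
        ) from err


def lrl_island_values(state: LRLState, params: LRLParams) -> np.ndarray:
    """Island values v* = lam * log(M T exp(r_T/lam)), evaluated in log space.

    With the task's identity default representation this is a per-island
    log-sum-exp of boat values under T-weights, always computed with a
    max-shift so small lam never overflows.
    """
    lam = params.lam
    if lam <= 0:
        raise ValueError("lam must be positive")
    v = np.empty(2)
    with np.errstate(divide="ignore"):
        logT = np.log(state.T)
    for isl in range(2):
        b0 = 2 * isl
        v[isl] = lam * logsumexp(
            logT[isl, b0 : b0 + 2] + state.v_boat[b0 : b0 + 2] / lam
        )
    return v


def update_T(
    state: LRLState, island: int, chosen_boat: int, params: LRLParams
) -> LRLState:
    """Hebbian update of the default transition row; identical contract to
    the SR occupancy update (both island boats move, row stays normalized)."""
    if BOAT_ISLAND[chosen_boat] != island:
        raise ValueError(f"boat {chosen_boat} is not on island {island}")
    out = state.copy()
    b0 = 2 * island
    for b in (b0, b0 + 1):
        ind = 1.0 if b == chosen_boat else 0.0
        out.T[island, b] = params.alpha_T * ind + (1.0 - params.alpha_T) * state.T[island, b]
    return out


def lrl_choice_probs(state: LRLState, params: LRLParams) -> np.ndarray:
    """Two-way softmax over linear-RL island values plus perseveration (and
    the optional TD term used in blockwise fits)."""
    x = params.beta_lrl * lrl_island_values(state, params) + params.beta_TD * state.v_td
    if state.last_island >= 0:
        x = x.copy()
        x[state.last_island] += params.beta_persist_island
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def boat_choice_probs_lrl(state: LRLState, island: int, params: LRLParams) -> np.ndarray:
    """Boat-level softmax shared with the mixture model's choice rule."""
    b0 = 2 * island
    x = params.beta_boat * state.v_boat[b0 : b0 + 2].copy()
    if state.last_boat[island] >= 0:
        x[state.last_boat[island] - b0] += params.beta_persist_boat
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def step_trial_lrl(
    state: LRLState, record: TrialRecord, params: LRLParams
) -> LRLState:
    """One trial's learning for the linear-RL agent.

    Traversal: boat-value update (active rate), then the T row, the TD cache,
    and the last-chosen indicators. Non-traversal: passive boat-value update
    only.
    """
    out = state.copy()
    if record.trial_type == "traversal":
        island = record.island_choice
        out.v_boat[record.boat] = (
            (1.0 - params.alpha_A) * state.v_boat[record.boat]
            + params.alpha_A * record.reward
        )
        b0 = 2 * island
        for b in (b0, b0 + 1):
            ind = 1.0 if b == record.boat else 0.0
            out.T[island, b] = params.alpha_T * ind + (1.0 - params.alpha_T) * state.T[island, b]
        out.v_td[island] = (
            (1.0 - params.alpha_A) * state.v_td[island]
            + params.alpha_A * out.v_boat[record.boat]
        )
        out.last_boat[island] = record.boat
        out.last_island = island
    else:
        out.v_boat[record.boat] = (
            (1.0 - params.alpha_P) * state.v_boat[record.boat]
            + params.alpha_P * record.reward
        )
    return out


def value_magnitude(v_boat: np.ndarray, lam: float) -> float:
    """Largest intermediate value magnitude max_b |exp(V(b)/lam)|.

    The computational-precision cost of MB-like evaluation: grows without
    bound as lam -> 0 for positive boat values.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    return float(np.max(np.abs(np.exp(np.asarray(v_boat, dtype=float) / lam))))
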