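"""Two-stage sailing-task environment: state space, trial schedule, reward blocks.

The task has a home state, two islands (0 and 1), and four boats. Boats 0 and 1
sit on island 0; boats 2 and 3 on island 1. A session consists of ``n_pairs``
alternating trial pairs: a *traversal* trial (choose island, then boat, observe
reward) followed by a *non-traversal* trial (a random boat is presented at home
and its outcome observed, with no island choice).

Rewards are Bernoulli with per-boat probabilities held fixed within a block of
8-12 pairs and permuted between blocks by one of three swap operators. Within
every block each island's two boats average probability 0.5, so island choice
carries no direct reward advantage under random boat sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "RewardSchedule",
    "TrialRecord",
    "CHANGE_TYPES",
    "apply_swap",
    "make_schedule",
    "make_nontraversal_order",
    "draw_reward",
    "records_to_frame",
    "frame_to_records",
    "write_log_csv",
    "read_log_csv",
    "LOG_COLUMNS",
]

#: island membership of each boat
BOAT_ISLAND = np.array([0, 0, 1, 1])

CHANGE_TYPES = ("initial", "congruent", "incongruent_cross", "incongruent_within")
SWAP_TYPES = ("congruent", "incongruent_cross", "incongruent_within")

LOG_COLUMNS = [
    "subject_id",
    "pair_index",
    "trial_type",
    "block_index",
    "change_type",
    "island_choice",
    "boat",
    "reward",
]


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    Defaults reproduce the standard session: 200 trial pairs, 22 reward
    blocks of 8-12 pairs, and 21 block changes of which 15 are congruent,
    3 incongruent cross-island and 3 incongruent within-island.
    """

    n_pairs: int = 200
    n_blocks: int = 22
    block_len_range: tuple[int, int] = (8, 12)
    n_congruent_changes: int = 15
    n_incongruent_cross: int = 3
    n_incongruent_within: int = 3
    init_probs: tuple[float, float, float, float] = (0.15, 0.85, 0.325, 0.675)
    shuffle_boats: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        n_changes = (
            self.n_congruent_changes
            + self.n_incongruent_cross
            + self.n_incongruent_within
        )
        if n_changes != self.n_blocks - 1:
            raise ValueError(
                f"change counts sum to {n_changes}, need n_blocks-1={self.n_blocks - 1}"
            )
        lo, hi = self.block_len_range
        if not (self.n_blocks * lo <= self.n_pairs <= self.n_blocks * hi):
            raise ValueError(
                f"{self.n_blocks} blocks of {lo}-{hi} pairs cannot sum to {self.n_pairs}"
            )
        if len(self.init_probs) != 4:
            raise ValueError("init_probs must have four entries")


@dataclass
class RewardSchedule:
    """Blockwise reward structure of one session.

    ``block_bounds[b] = (first_pair, last_pair)`` (inclusive, 0-based pair
    indices); ``probs_by_block[b]`` is the 4-vector of boat reward
    probabilities; ``change_type_by_block[b]`` labels the change that started
    block ``b`` ("initial" for the first block).
    """

    block_bounds: list[tuple[int, int]]
    probs_by_block: np.ndarray  # (n_blocks, 4)
    change_type_by_block: list[str]
    seed: int | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.block_bounds)

    @property
    def n_pairs(self) -> int:
        return self.block_bounds[-1][1] + 1

    def block_of_pair(self, pair_index: int) -> int:
        """Block containing a given trial pair."""
        if not 0 <= pair_index < self.n_pairs:
            raise IndexError(f"pair_index {pair_index} out of range")
        for b, (lo, hi) in enumerate(self.block_bounds):
            if lo <= pair_index <= hi:
                return b
        raise IndexError(pair_index)  # pragma: no cover

    def pair_to_block(self) -> np.ndarray:
        """Vector mapping each pair index to its block index."""
        out = np.empty(self.n_pairs, dtype=np.int64)
        for b, (lo, hi) in enumerate(self.block_bounds):
            out[lo : hi + 1] = b
        return out

    def to_dict(self) -> dict:
        return {
            "block_bounds": [list(b) for b in self.block_bounds],
            "probs_by_block": self.probs_by_block.tolist(),
            "change_type_by_block": list(self.change_type_by_block),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RewardSchedule":
        return cls(
            block_bounds=[tuple(b) for b in d["block_bounds"]],
            probs_by_block=np.asarray(d["probs_by_block"], dtype=float),
            change_type_by_block=list(d["change_type_by_block"]),
            seed=d.get("seed"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RewardSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: the atomic unit all likelihoods consume.

    ``island_choice`` is None on non-traversal trials; ``boat`` is the chosen
    boat on traversal trials and the presented boat on non-traversal trials.
    """

    subject_id: str
    pair_index: int
    trial_type: str  # "traversal" | "nontraversal"
    block_index: int
    change_type: str
    island_choice: int | None
    boat: int
    reward: int

    def __post_init__(self) -> None:
        if self.trial_type not in ("traversal", "nontraversal"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if not 0 <= self.boat <= 3:
            raise ValueError(f"bad boat {self.boat}")
        if self.trial_type == "traversal":
            if self.island_choice not in (0, 1):
                raise ValueError("traversal trial needs island_choice in {0,1}")
            if BOAT_ISLAND[self.boat] != self.island_choice:
                raise ValueError(
                    f"boat {self.boat} not on island {self.island_choice}"
                )
        elif self.island_choice is not None:
            raise ValueError("non-traversal record must not carry island_choice")


def _decompose(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the optimal (higher) and suboptimal boat on each island."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (4,):
        raise ValueError("probs must be a 4-vector")
    opt = np.empty(2, dtype=int)
    sub = np.empty(2, dtype=int)
    for isl in range(2):
        a, b = 2 * isl, 2 * isl + 1
        if probs[a] == probs[b]:
            raise ValueError(
                f"island {isl} boats are tied ({probs[a]}); no optimal/suboptimal split"
            )
        opt[isl], sub[isl] = (a, b) if probs[a] > probs[b] else (b, a)
    if abs(probs[:2].mean() - probs[2:].mean()) > 1e-9:
        raise ValueError(
            "islands have unequal mean reward probability; vector is not a "
            "valid block assignment"
        )
    return opt, sub


def apply_swap(probs: Sequence[float], swap_type: str) -> np.ndarray:
    """Permute the four boat reward probabilities by a block-change operator.

    congruent
        The two island-wise optimal probabilities trade places, and the two
        suboptimal ones do likewise: the optimal island flips, but the better
        boat *given* an island is unchanged, so a policy tuned to the old
        rewards still ranks the islands correctly.
    incongruent_cross
        Each island's optimal probability trades with the *other* island's
        suboptimal probability, flipping the better boat on both islands and
        the optimal island.
    incongruent_within
        The two probabilities on each island trade places; the optimal island
        is preserved but the better boat on each island flips.

    All three preserve the per-island mean of 0.5 and are involutions.
    """
    probs = np.asarray(probs, dtype=float)
    opt, sub = _decompose(probs)
    out = probs.copy()
    if swap_type == "congruent":
        out[opt[0]], out[opt[1]] = probs[opt[1]], probs[opt[0]]
        out[sub[0]], out[sub[1]] = probs[sub[1]], probs[sub[0]]
    elif swap_type == "incongruent_cross":
        out[opt[0]], out[sub[1]] = probs[sub[1]], probs[opt[0]]
        out[opt[1]], out[sub[0]] = probs[sub[0]], probs[opt[1]]
    elif swap_type == "incongruent_within":
        out[opt[0]], out[sub[0]] = probs[sub[0]], probs[opt[0]]
        out[opt[1]], out[sub[1]] = probs[sub[1]], probs[opt[1]]
    else:
        raise ValueError(f"unknown swap_type {swap_type!r}")
    return out


def _sample_block_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Block pair-lengths in [lo, hi] summing exactly to n_pairs.

    Sequential constrained sampling: each length is uniform over the values
    that keep the remaining total feasible.
    """
    lo, hi = config.block_len_range
    lengths = np.empty(config.n_blocks, dtype=np.int64)
    remaining = config.n_pairs
    for i in range(config.n_blocks):
        k = config.n_blocks - i - 1  # blocks still to fill after this one
        vmin = max(lo, remaining - k * hi)
        vmax = min(hi, remaining - k * lo)
        lengths[i] = rng.integers(vmin, vmax + 1)
        remaining -= lengths[i]
    assert remaining == 0
    return lengths


def _shuffled_init_probs(
    init_probs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Randomize boat assignment while keeping one high/low pair per island.

    Mirrors the per-participant shuffling of boat identities: the island
    hosting each probability pair and the within-island order are randomized,
    which preserves the equal-island-mean invariant an arbitrary permutation
    would break.
    """
    p = np.asarray(init_probs, dtype=float)
    pairs = [p[:2].copy(), p[2:].copy()]
    if rng.random() < 0.5:
        pairs = pairs[::-1]
    for pair in pairs:
        if rng.random() < 0.5:
            pair[:] = pair[::-1]
    return np.concatenate(pairs)


def make_schedule(config: TaskConfig, rng: np.random.Generator) -> RewardSchedule:
    """Generate one session's blockwise reward schedule.

    Block lengths sum to ``config.n_pairs``; the change types following block
    0 are a random permutation of the configured multiset; each block's
    probabilities are obtained by applying the corresponding swap to the
    previous block's.
    """
    lengths = _sample_block_lengths(config, rng)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    bounds = [(int(s), int(s + l - 1)) for s, l in zip(starts, lengths)]

    changes = (
        ["congruent"] * config.n_congruent_changes
        + ["incongruent_cross"] * config.n_incongruent_cross
        + ["incongruent_within"] * config.n_incongruent_within
    )
    changes = [changes[i] for i in rng.permutation(len(changes))]
    change_types = ["initial"] + changes

    if config.shuffle_boats:
        p0 = _shuffled_init_probs(config.init_probs, rng)
    else:
        p0 = np.asarray(config.init_probs, dtype=float)
    probs = [p0]
    for ct in changes:
        probs.append(apply_swap(probs[-1], ct))
    return RewardSchedule(
        block_bounds=bounds,
        probs_by_block=np.vstack(probs),
        change_type_by_block=change_types,
        seed=config.seed,
    )


def make_nontraversal_order(
    config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Balanced random order of presented boats across non-traversal trials.

    Each boat appears exactly ``n_pairs/4`` times (50 in the default session).
    """
    if config.n_pairs % 4 != 0:
        raise ValueError("n_pairs must be divisible by 4 for a balanced order")
    order = np.repeat(np.arange(4), config.n_pairs // 4)
    return rng.permutation(order)


def draw_reward(
    boat: int,
    pair_index: int,
    schedule: RewardSchedule,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward for a boat under the block active at ``pair_index``.

    Both trials of a pair share the block's probabilities: blocks switch only
    at pair boundaries, so a pair's non-traversal trial always uses the same
    probability as its traversal trial.
    """
    block = schedule.block_of_pair(pair_index)
    p = schedule.probs_by_block[block, boat]
    return int(rng.random() < p)


# ---------------------------------------------------------------------------
# trial-log I/O


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        rows.append(d)
    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    df["island_choice"] = df["island_choice"].astype("Int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        ic = row.island_choice
        ic = None if pd.isna(ic) else int(ic)
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                pair_index=int(row.pair_index),
                trial_type=str(row.trial_type),
                block_index=int(row.block_index),
                change_type=str(row.change_type),
                island_choice=ic,
                boat=int(row.boat),
                reward=int(row.reward),
            )
        )
    return records


def write_log_csv(df: pd.DataFrame, path) -> None:
    """Write a trial log (UTF-8, comma-separated, header row, no index)."""
    df.to_csv(path, index=False)


def read_log_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    unknown = set(df.columns) - set(LOG_COLUMNS)
    if unknown:
        raise ValueError(f"trial log has unknown columns: {sorted(unknown)}")
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    df["island_choice"] = df["island_choice"].astype("Int64")
    return df
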