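"""Synthetic-data generation: parameterized agents playing the sailing task.

Every simulated session uses the same schedule machinery as the task
definition (22 blocks, 15 congruent / 6 incongruent changes, balanced
non-traversal boat order) and produces trial logs schema-identical to real
session logs, so the fitting and regression modules cannot distinguish
provenance. Ground-truth parameters are kept in a sidecar table, never in
the trial log itself.

Presets name canonical agent types used throughout the test suite:
``pure_MB``, ``pure_SR``, ``pure_TD`` (one island-valuation system at a
time), ``hybrid`` (MB+SR with a small TD contribution), and
``block_insensitive`` (a blockwise agent whose (+) and (-) parameter sets
are identical — the control for artifacts of the blockwise design itself).
Simulated agents carry no perseveration terms by default; those enter only
when fitting human-style models.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import agents, linear_rl
from .agents import AgentParams
from .fitting import MODEL_SPECS, ParamSpec, inverse_transform
from .linear_rl import LRLParams
from .task import (
    RewardSchedule,
    TaskConfig,
    TrialRecord,
    draw_reward,
    make_nontraversal_order,
    make_schedule,
    records_to_frame,
    write_log_csv,
)

__all__ = [
    "SimAgentSpec",
    "CohortSpec",
    "PRESETS",
    "preset_spec",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]

# Canonical preset parameter values (natural scale). The task's reward
# probabilities differ by at most 0.7, so island softmax temperatures near 5
# yield clearly value-driven but still stochastic choice.
_BASE = dict(alpha_A=0.3, alpha_P=0.3, alpha_M=0.3, beta_boat=5.0)

PRESETS: dict[str, dict] = {
    "pure_MB": {**_BASE, "beta_MB": 5.0, "beta_SR": 0.0, "beta_TD": 0.0},
    "pure_SR": {**_BASE, "beta_MB": 0.0, "beta_SR": 5.0, "beta_TD": 0.0},
    "pure_TD": {**_BASE, "beta_MB": 0.0, "beta_SR": 0.0, "beta_TD": 5.0},
    "hybrid": {**_BASE, "beta_MB": 2.5, "beta_SR": 2.5, "beta_TD": 0.5},
    "block_insensitive": {
        "blockwise": (
            {**_BASE, "beta_MB": 2.5, "beta_SR": 2.5, "beta_TD": 0.5},
            {**_BASE, "beta_MB": 2.5, "beta_SR": 2.5, "beta_TD": 0.5},
        )
    },
    # ground-truth arbitration: SR-leaning after congruent changes
    # (w_SR+ = 0.75), MB-leaning after incongruent ones (w_SR- = 0.25)
    "blockwise_adaptive": {
        "blockwise": (
            {**_BASE, "beta_MB": 1.25, "beta_SR": 3.75, "beta_TD": 0.5},
            {**_BASE, "beta_MB": 3.75, "beta_SR": 1.25, "beta_TD": 0.5},
        )
    },
}


@dataclass
class SimAgentSpec:
    """One simulated agent: model family plus concrete parameters.

    ``blockwise`` holds a (plus, minus) pair of parameter sets applied
    according to the change type that began the current block (plus on
    congruent/initial blocks, minus on incongruent ones). ``preset`` records
    the label the parameters were expanded from, for metadata.
    """

    model: str = "mixture"  # "mixture" | "lrl"
    params: AgentParams | LRLParams | None = None
    blockwise: tuple | None = None
    preset: str | None = None
    include_persistence: bool = False

    def __post_init__(self) -> None:
        if self.params is None and self.blockwise is None:
            raise ValueError("SimAgentSpec needs params or a blockwise pair")
        if self.blockwise is not None and len(self.blockwise) != 2:
            raise ValueError("blockwise must be a (plus, minus) pair")


def preset_spec(name: str, model: str = "mixture") -> SimAgentSpec:
    """Expand a preset label into a concrete agent spec."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    entry = PRESETS[name]
    if "blockwise" in entry:
        pair = tuple(AgentParams(**p) for p in entry["blockwise"])
        return SimAgentSpec(model="mixture", blockwise=pair, preset=name)
    return SimAgentSpec(model=model, params=AgentParams(**entry), preset=name)


@dataclass
class CohortSpec:
    """A simulated cohort: either a shared preset or a group Gaussian.

    When ``group_means``/``group_sds`` are given they are interpreted on the
    *transformed* scale of the named fitting model (logit learning rates,
    log-scale positive temperatures), exactly the scale the hierarchical
    fitter estimates — so recovered group means are directly comparable to
    the generating ones.
    """

    n_subjects: int
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0
    preset: str | None = None
    model: str = "mixture"
    group_means: dict[str, float] | None = None
    group_sds: dict[str, float] | None = None
    include_persistence: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.preset is None and self.group_means is None:
            raise ValueError("CohortSpec needs a preset or group_means")
        if self.group_means is not None:
            if self.group_sds is None:
                raise ValueError("group_means requires group_sds")
            if any(s < 0 for s in self.group_sds.values()):
                raise ValueError("group sds must be non-negative")


def _zero_persistence(d: dict) -> dict:
    out = dict(d)
    for k in ("beta_persist_boat", "beta_persist_island"):
        out[k] = 0.0
    return out


def _agent_from_natural(model: str, nat: dict, include_persistence: bool):
    """Build concrete agent parameters from a fitting-model natural dict."""
    if not include_persistence:
        nat = _zero_persistence(nat)
    if model == "mixture":
        return SimAgentSpec(model="mixture", params=AgentParams(**nat))
    if model == "mixture_w":
        w, bc = nat.pop("w_SR"), nat.pop("beta_MBSR")
        nat["beta_MB"] = (1 - w) * bc
        nat["beta_SR"] = w * bc
        return SimAgentSpec(model="mixture", params=AgentParams(**nat))
    if model == "mixture_w_blockwise":
        shared = {
            k: nat[k]
            for k in (
                "alpha_A", "alpha_P", "alpha_M", "beta_boat",
                "beta_persist_boat", "beta_persist_island",
            )
        }
        pair = []
        for s in ("plus", "minus"):
            w, bc = nat[f"w_SR_{s}"], nat[f"beta_MBSR_{s}"]
            pair.append(
                AgentParams(
                    **shared,
                    beta_MB=(1 - w) * bc,
                    beta_SR=w * bc,
                    beta_TD=nat[f"beta_TD_{s}"],
                )
            )
        return SimAgentSpec(model="mixture", blockwise=tuple(pair))
    if model == "lrl":
        return SimAgentSpec(model="lrl", params=LRLParams(**nat))
    if model == "lrl_blockwise":
        shared = {
            k: nat[k]
            for k in (
                "alpha_A", "alpha_P", "alpha_T", "beta_boat",
                "beta_persist_boat", "beta_persist_island",
            )
        }
        pair = tuple(
            LRLParams(
                **shared,
                lam=nat[f"lam_{s}"],
                beta_lrl=nat[f"beta_lrl_{s}"],
                beta_TD=nat[f"beta_TD_{s}"],
            )
            for s in ("plus", "minus")
        )
        return SimAgentSpec(model="lrl", blockwise=pair)
    raise ValueError(f"unknown model {model!r}")


def _active_params(spec: SimAgentSpec, change_type: str):
    if spec.blockwise is None:
        return spec.params
    plus, minus = spec.blockwise
    return minus if change_type.startswith("incongruent") else plus


def simulate_subject(
    spec: SimAgentSpec,
    schedule: RewardSchedule,
    rng: np.random.Generator,
    subject_id: str = "sim",
    nontraversal_order: np.ndarray | None = None,
) -> list[TrialRecord]:
    """Play one agent through one schedule; returns the full trial log.

    Each pair is a traversal trial (island and boat sampled from the model's
    choice probabilities, reward drawn from the active block) followed by a
    non-traversal trial (boat from the balanced presentation order).
    """
    n_pairs = schedule.n_pairs
    if nontraversal_order is None:
        order = np.repeat(np.arange(4), -(-n_pairs // 4))[:n_pairs]
        nontraversal_order = rng.permutation(order)
    elif len(nontraversal_order) != n_pairs:
        raise ValueError("nontraversal_order length must equal schedule n_pairs")

    mixture = spec.model == "mixture"
    state = agents.initial_state() if mixture else linear_rl.initial_lrl_state()
    pair_block = schedule.pair_to_block()
    records: list[TrialRecord] = []
    for pair in range(n_pairs):
        block = int(pair_block[pair])
        ct = schedule.change_type_by_block[block]
        params = _active_params(spec, ct)
        if mixture:
            p_isl = agents.island_choice_probs(state, params)
        else:
            p_isl = linear_rl.lrl_choice_probs(state, params)
        island = int(rng.random() < p_isl[1])
        if mixture:
            p_boat = agents.boat_choice_probs(state, island, params)
        else:
            p_boat = linear_rl.boat_choice_probs_lrl(state, island, params)
        boat = 2 * island + int(rng.random() < p_boat[1])
        reward = draw_reward(boat, pair, schedule, rng)
        rec = TrialRecord(
            subject_id=subject_id,
            pair_index=pair,
            trial_type="traversal",
            block_index=block,
            change_type=ct,
            island_choice=island,
            boat=boat,
            reward=reward,
        )
        records.append(rec)
        state = (agents.step_trial if mixture else linear_rl.step_trial_lrl)(
            state, rec, params
        )

        nt_boat = int(nontraversal_order[pair])
        nt_reward = draw_reward(nt_boat, pair, schedule, rng)
        rec = TrialRecord(
            subject_id=subject_id,
            pair_index=pair,
            trial_type="nontraversal",
            block_index=block,
            change_type=ct,
            island_choice=None,
            boat=nt_boat,
            reward=nt_reward,
        )
        records.append(rec)
        state = (agents.step_trial if mixture else linear_rl.step_trial_lrl)(
            state, rec, params
        )
    return records


def _truth_row(spec: SimAgentSpec) -> dict:
    if spec.blockwise is not None:
        plus, minus = spec.blockwise
        row = {}
        for s, p in (("plus", plus), ("minus", minus)):
            for k, v in asdict(p).items():
                row[f"{k}_{s}"] = v
        return row
    return asdict(spec.params)


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort; returns (logs, truth, metadata).

    ``logs`` is a list of per-subject trial-log DataFrames, ``truth`` a
    DataFrame of generating parameters keyed by subject_id, and ``metadata``
    a plain dict (seeds and specification) suitable for YAML.
    """
    root = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(spec.n_subjects + 1)[1:]

    fit_spec: ParamSpec | None = None
    if spec.group_means is not None:
        fit_spec = MODEL_SPECS[spec.model]
        missing = set(fit_spec.names) - set(spec.group_means)
        extra = set(spec.group_means) - set(fit_spec.names)
        if extra:
            raise ValueError(f"group_means has unknown parameters: {sorted(extra)}")
        if missing:
            raise ValueError(f"group_means missing parameters: {sorted(missing)}")

    logs: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_subjects):
        sid = f"sub{i:03d}"
        rng = np.random.default_rng(subject_seeds[i])
        if fit_spec is not None:
            mu = np.array([spec.group_means[n] for n in fit_spec.names])
            sd = np.array([spec.group_sds[n] for n in fit_spec.names])
            x = mu + sd * param_rng.normal(size=mu.size)
            nat = fit_spec.natural_dict(inverse_transform(x, fit_spec.transforms))
            agent = _agent_from_natural(spec.model, nat, spec.include_persistence)
        else:
            agent = preset_spec(spec.preset, model=spec.model)
            agent.include_persistence = spec.include_persistence
        task_cfg = spec.task
        schedule = make_schedule(task_cfg, rng)
        order = make_nontraversal_order(task_cfg, rng)
        records = simulate_subject(agent, schedule, rng, subject_id=sid,
                                   nontraversal_order=order)
        logs.append(records_to_frame(records))
        truth_rows.append({"subject_id": sid, **_truth_row(agent)})

    truth = pd.DataFrame(truth_rows)
    metadata = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "model": spec.model,
        "preset": spec.preset,
        "group_means": spec.group_means,
        "group_sds": spec.group_sds,
        "include_persistence": spec.include_persistence,
        "task": asdict(spec.task),
        "preset_values": PRESETS.get(spec.preset) if spec.preset else None,
    }
    return logs, truth, metadata


def write_cohort(logs, truth: pd.DataFrame, metadata: dict, out_dir) -> None:
    """Write per-subject CSV logs, a ground-truth table, and YAML metadata."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for df in logs:
        sid = df["subject_id"].iloc[0]
        write_log_csv(df, out / f"{sid}.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)
    meta = dict(metadata)
    meta["ground_truth"] = "ground_truth.csv"
    meta["config_hash"] = hashlib.sha256(
        yaml.safe_dump(metadata, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
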