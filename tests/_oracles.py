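"""Independent reference evaluators used only by the tests.

These deliberately re-derive likelihoods from the pure step functions
(`sailrl.agents` / `sailrl.linear_rl`) with naive Python loops, so they share
no code with the compiled kernels they are checked against.
"""

import numpy as np

from sailrl import agents, linear_rl


def naive_mixture_nll(params_by_sign, records):
    """Brute-force mixture NLL; params_by_sign maps 'plus'/'minus' to
    AgentParams (pass the same object twice for a non-blockwise model)."""
    st = agents.initial_state()
    nll = 0.0
    for r in records:
        sign = "minus" if r.change_type.startswith("incongruent") else "plus"
        p = params_by_sign[sign]
        if r.trial_type == "traversal":
            p_isl = agents.island_choice_probs(st, p)
            nll -= np.log(p_isl[r.island_choice])
            p_boat = agents.boat_choice_probs(st, r.island_choice, p)
            nll -= np.log(p_boat[r.boat - 2 * r.island_choice])
        st = agents.step_trial(st, r, p)
    return nll


def naive_lrl_nll(params_by_sign, records):
    """Brute-force linear-RL NLL from the pure step functions."""
    st = linear_rl.initial_lrl_state()
    nll = 0.0
    for r in records:
        sign = "minus" if r.change_type.startswith("incongruent") else "plus"
        p = params_by_sign[sign]
        if r.trial_type == "traversal":
            p_isl = linear_rl.lrl_choice_probs(st, p)
            nll -= np.log(p_isl[r.island_choice])
            p_boat = linear_rl.boat_choice_probs_lrl(st, r.island_choice, p)
            nll -= np.log(p_boat[r.boat - 2 * r.island_choice])
        st = linear_rl.step_trial_lrl(st, r, p)
    return nll


def random_agent_params(rng):
    return agents.AgentParams(
        alpha_A=rng.uniform(0.05, 0.95),
        alpha_P=rng.uniform(0.05, 0.95),
        alpha_M=rng.uniform(0.05, 0.95),
        beta_boat=rng.normal(0, 2),
        beta_MB=rng.normal(0, 2),
        beta_SR=rng.normal(0, 2),
        beta_TD=rng.normal(0, 2),
        beta_persist_boat=rng.normal(0, 1),
        beta_persist_island=rng.normal(0, 1),
    )


def random_lrl_params(rng):
    return linear_rl.LRLParams(
        lam=rng.uniform(0.05, 3.0),
        alpha_T=rng.uniform(0.05, 0.95),
        beta_lrl=rng.normal(0, 2),
        beta_TD=rng.normal(0, 1),
        alpha_A=rng.uniform(0.05, 0.95),
        alpha_P=rng.uniform(0.05, 0.95),
        beta_boat=rng.normal(0, 2),
        beta_persist_boat=rng.normal(0, 1),
        beta_persist_island=rng.normal(0, 1),
    )


def params_to_dict(p, names):
    return {n: getattr(p, n) for n in names}
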