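"""Compiled trial-loop likelihood kernels used by the fitting engine.

These re-express the per-trial recursions of :mod:`sailrl.agents` and
:mod:`sailrl.linear_rl` as flat-array loops for speed inside the hierarchical
optimizer. The slow, pure-numpy step functions remain the reference
implementation; the test suite checks the two paths agree to near machine
precision.

Parameter rows are passed as a (2, 9) array: row 0 applies on blocks whose
preceding change was congruent (or on the initial block), row 1 after
incongruent changes. Non-blockwise likelihoods pass two identical rows.

Mixture row layout:   [alpha_A, alpha_P, alpha_M, beta_boat,
                       beta_MB, beta_SR, beta_TD, bpers_boat, bpers_island]
Linear-RL row layout: [alpha_A, alpha_P, alpha_T, lam, beta_boat,
                       beta_lrl, beta_TD, bpers_boat, bpers_island]
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mixture_nll_core", "lrl_nll_core", "log_arrays"]


@njit(cache=True)
def _log1pexp(x: float) -> float:
    # stable log(1 + exp(x))
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def mixture_nll_core(P, tt, island, boat, reward, bsign):
    """Negative log likelihood of one session under the mixture model.

    tt: 1 on traversal trials, 0 on non-traversal; island is -1 on
    non-traversal trials. Likelihood terms accrue on traversal trials only
    (island choice then boat choice); learning applies on every trial.
    """
    v = np.full(4, 0.5)
    m = np.zeros((2, 4))
    m[0, 0] = 0.5
    m[0, 1] = 0.5
    m[1, 2] = 0.5
    m[1, 3] = 0.5
    vtd = np.full(2, 0.5)
    last_boat = np.full(2, -1, dtype=np.int64)
    last_island = -1

    nll = 0.0
    n = tt.shape[0]
    for t in range(n):
        row = P[bsign[t]]
        b = boat[t]
        r = reward[t]
        if tt[t] == 1:
            isl = island[t]
            # island-level utilities
            x = np.empty(2)
            for i in range(2):
                b0 = 2 * i
                vmb = v[b0] if v[b0] > v[b0 + 1] else v[b0 + 1]
                vsr = m[i, b0] * v[b0] + m[i, b0 + 1] * v[b0 + 1]
                x[i] = row[4] * vmb + row[5] * vsr + row[6] * vtd[i]
            if last_island >= 0:
                x[last_island] += row[8]
            # -log softmax(x)[isl]
            nll += _log1pexp(x[1 - isl] - x[isl])
            # boat-level utilities
            b0 = 2 * isl
            y0 = row[3] * v[b0]
            y1 = row[3] * v[b0 + 1]
            if last_boat[isl] == b0:
                y0 += row[7]
            elif last_boat[isl] == b0 + 1:
                y1 += row[7]
            if b == b0:
                nll += _log1pexp(y1 - y0)
            else:
                nll += _log1pexp(y0 - y1)
            # learning: boat value (active), SR row, TD cache, perseveration
            aA = row[0]
            v[b] = (1.0 - aA) * v[b] + aA * r
            aM = row[2]
            for bb in range(b0, b0 + 2):
                ind = 1.0 if bb == b else 0.0
                m[isl, bb] = aM * ind + (1.0 - aM) * m[isl, bb]
            vtd[isl] = (1.0 - aA) * vtd[isl] + aA * v[b]
            last_boat[isl] = b
            last_island = isl
        else:
            aP = row[1]
            v[b] = (1.0 - aP) * v[b] + aP * r
    return nll


@njit(cache=True)
def lrl_nll_core(P, tt, island, boat, reward, bsign):
    """Negative log likelihood of one session under the linear-RL model."""
    v = np.full(4, 0.5)
    T = np.zeros((2, 4))
    T[0, 0] = 0.5
    T[0, 1] = 0.5
    T[1, 2] = 0.5
    T[1, 3] = 0.5
    vtd = np.full(2, 0.5)
    last_boat = np.full(2, -1, dtype=np.int64)
    last_island = -1

    nll = 0.0
    n = tt.shape[0]
    for t in range(n):
        row = P[bsign[t]]
        b = boat[t]
        r = reward[t]
        if tt[t] == 1:
            isl = island[t]
            lam = row[3]
            x = np.empty(2)
            for i in range(2):
                b0 = 2 * i
                # lam * logsumexp(log T + v/lam) over the island's two boats
                a0 = v[b0] / lam
                a1 = v[b0 + 1] / lam
                hi = a0 if a0 > a1 else a1
                s = T[i, b0] * np.exp(a0 - hi) + T[i, b0 + 1] * np.exp(a1 - hi)
                vstar = lam * (hi + np.log(s))
                x[i] = row[5] * vstar + row[6] * vtd[i]
            if last_island >= 0:
                x[last_island] += row[8]
            nll += _log1pexp(x[1 - isl] - x[isl])
            b0 = 2 * isl
            y0 = row[4] * v[b0]
            y1 = row[4] * v[b0 + 1]
            if last_boat[isl] == b0:
                y0 += row[7]
            elif last_boat[isl] == b0 + 1:
                y1 += row[7]
            if b == b0:
                nll += _log1pexp(y1 - y0)
            else:
                nll += _log1pexp(y0 - y1)
            aA = row[0]
            v[b] = (1.0 - aA) * v[b] + aA * r
            aT = row[2]
            for bb in range(b0, b0 + 2):
                ind = 1.0 if bb == b else 0.0
                T[isl, bb] = aT * ind + (1.0 - aT) * T[isl, bb]
            vtd[isl] = (1.0 - aA) * vtd[isl] + aA * v[b]
            last_boat[isl] = b
            last_island = isl
        else:
            aP = row[1]
            v[b] = (1.0 - aP) * v[b] + aP * r
    return nll


def log_arrays(df, blockwise: bool = False):
    """Flatten a single-subject trial-log DataFrame into core arrays.

    Returns (tt, island, boat, reward, bsign); bsign is all zeros unless
    ``blockwise``, in which case blocks preceded by an incongruent change map
    to 1 (the initial block counts as congruent).
    """
    tt = (df["trial_type"].to_numpy() == "traversal").astype(np.int64)
    island = df["island_choice"].fillna(-1).to_numpy(dtype=np.int64)
    boat = df["boat"].to_numpy(dtype=np.int64)
    reward = df["reward"].to_numpy(dtype=np.int64)
    if blockwise:
        ct = df["change_type"].astype(str).to_numpy()
        bsign = np.where(
            (ct == "incongruent_cross") | (ct == "incongruent_within"), 1, 0
        ).astype(np.int64)
    else:
        bsign = np.zeros(len(df), dtype=np.int64)
    return tt, island, boat, reward, bsign
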