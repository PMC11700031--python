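"""Trial-history regression signatures of MB vs. SR credit assignment.

The central question: after observing a lone boat's outcome on a
non-traversal trial, does the next island choice move toward that boat's
island, and *when*? A model-based planner maximizes over boats, so the
sampled boat's reward matters only when the neighboring boat cannot already
guarantee the island's value (neighbor recently unrewarded). An SR planner
weights boats by its own past policy, so the reward matters only when the
sampled boat is the one it expects to revisit (on-policy). These opposite
gating patterns appear as reward-by-neighbor and reward-by-policy
interactions in a logistic regression of island choice.

Designs are built per (non-traversal, following traversal) pair with the
primary regressors coded -0.5/+0.5, plus a battery of lagged history
controls (past neighbor-boat outcomes, past same-island choices, past
sampled-boat outcomes, opposite-island running value, and an island choice
kernel) coded as in the original analysis (0/1 for past events, centered
for the rest). Interactions are products of the coded columns.

The hierarchical logistic model is fit by the package's own Laplace/EM
engine: per-subject coefficients for the intercept and primary terms drawn
from a group Gaussian, lagged controls as shared fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "build_design_reward_only",
    "build_design_full",
    "PRIMARY_COLS",
    "CONTROL_COLS",
    "HierLogisticResult",
    "fit_hier_logistic",
]

logger = logging.getLogger(__name__)

PRIMARY_COLS = ["rwd", "sibNoRwd", "onPolicy", "rwd_x_sibNoRwd", "rwd_x_onPolicy"]

CONTROL_COLS = (
    [f"nbr_lag{k}" for k in range(2, 6)]
    + [f"rwd_x_nbr_lag{k}" for k in range(2, 6)]
    + [f"pol_lag{k}" for k in range(2, 6)]
    + [f"rwd_x_pol_lag{k}" for k in range(2, 6)]
    + [f"samp_lag{k}" for k in range(1, 6)]
    + [f"rwd_x_samp_lag{k}" for k in range(1, 6)]
    + [f"opp_val_lag{k}" for k in range(1, 6)]
    + [f"kernel_lag{k}" for k in range(1, 6)]
)


@dataclass(frozen=True)
class DesignConfig:
    """Row-inclusion and fill policies for the full design.

    Rows whose primary regressors are undefined (sibling never observed, no
    prior choice at the island) are dropped when ``drop_undefined_primary``;
    lagged controls beyond the available history are zero-filled.
    """

    drop_undefined_primary: bool = True
    zero_fill_lags: bool = True


def _iter_subjects(logs) -> list[pd.DataFrame]:
    if isinstance(logs, pd.DataFrame):
        return [g for _, g in logs.groupby("subject_id", sort=False)]
    return list(logs)


def _pair_tables(df: pd.DataFrame):
    """Split one subject's log into aligned traversal/non-traversal arrays."""
    df = df.sort_values(["pair_index", "trial_type"], ascending=[True, False])
    trav = df[df["trial_type"] == "traversal"].set_index("pair_index")
    nont = df[df["trial_type"] == "nontraversal"].set_index("pair_index")
    return trav, nont


def build_design_reward_only(logs) -> pd.DataFrame:
    """Design for the reward-only model: did the island choice on the next
    traversal move toward the just-sampled boat's island, as a function of
    that boat's reward (coded -0.5/+0.5)?"""
    rows = []
    for df in _iter_subjects(logs):
        sid = df["subject_id"].iloc[0]
        trav, nont = _pair_tables(df)
        for pair, nt in nont.iterrows():
            nxt = pair + 1
            if nxt not in trav.index:
                logger.debug("subject %s pair %d: no following traversal", sid, pair)
                continue
            island = nt["boat"] // 2
            rows.append(
                {
                    "subject_id": sid,
                    "pair_index": pair,
                    "y": int(trav.loc[nxt, "island_choice"] == island),
                    "rwd": nt["reward"] - 0.5,
                }
            )
    return pd.DataFrame(rows)


def build_design_full(logs, config: DesignConfig | None = None) -> pd.DataFrame:
    """Full design: primary terms, their reward interactions, and lagged
    history controls, all relative to the sampled boat and its island."""
    config = config or DesignConfig()
    rows = []
    for df in _iter_subjects(logs):
        rows.extend(_design_subject_full(df, config))
    out = pd.DataFrame(
        rows, columns=["subject_id", "pair_index", "y"] + PRIMARY_COLS + CONTROL_COLS
    )
    return out


def _design_subject_full(df: pd.DataFrame, config: DesignConfig) -> list[dict]:
    sid = df["subject_id"].iloc[0]
    trav, nont = _pair_tables(df)
    n_pairs = int(df["pair_index"].max()) + 1

    boat_outcomes: list[list[int]] = [[] for _ in range(4)]
    island_choices: list[list[int]] = [[], []]  # chosen boat per traversal, per island
    traversal_islands: list[int] = []
    # running boat-value snapshot after each completed pair (prior 0.5)
    value_snapshots: list[np.ndarray] = []
    run_sum = np.zeros(4)
    run_n = np.zeros(4)

    def boat_value() -> np.ndarray:
        v = np.full(4, 0.5)
        seen = run_n > 0
        v[seen] = run_sum[seen] / run_n[seen]
        return v

    rows = []
    for pair in range(n_pairs):
        if pair in trav.index:
            tr = trav.loc[pair]
            isl, b, r = int(tr["island_choice"]), int(tr["boat"]), int(tr["reward"])
            traversal_islands.append(isl)
            island_choices[isl].append(b)
            boat_outcomes[b].append(r)
            run_sum[b] += r
            run_n[b] += 1

        if pair in nont.index:
            nt = nont.loc[pair]
            b = int(nt["boat"])
            r = int(nt["reward"])
            isl = b // 2
            sib = b ^ 1
            row = _full_row(
                sid, pair, isl, b, sib, r,
                trav, boat_outcomes, island_choices, traversal_islands,
                value_snapshots, config,
            )
            if row is not None:
                rows.append(row)
            boat_outcomes[b].append(r)
            run_sum[b] += r
            run_n[b] += 1

        value_snapshots.append(boat_value())
    return rows


def _full_row(
    sid, pair, isl, b, sib, r,
    trav, boat_outcomes, island_choices, traversal_islands,
    value_snapshots, config,
):
    nxt = pair + 1
    if nxt not in trav.index:
        return None
    sib_hist = boat_outcomes[sib]
    pol_hist = island_choices[isl]
    if config.drop_undefined_primary and (not sib_hist or not pol_hist):
        return None

    rwd = r - 0.5
    sib_no_rwd = (0.5 - sib_hist[-1]) if sib_hist else 0.0
    on_policy = ((pol_hist[-1] == b) - 0.5) if pol_hist else 0.0
    row = {
        "subject_id": sid,
        "pair_index": pair,
        "y": int(trav.loc[nxt, "island_choice"] == isl),
        "rwd": rwd,
        "sibNoRwd": sib_no_rwd,
        "onPolicy": on_policy,
        "rwd_x_sibNoRwd": rwd * sib_no_rwd,
        "rwd_x_onPolicy": rwd * on_policy,
    }
    # neighbor-boat outcome lags 2..5 (lag 1 is sibNoRwd), coded 0/1
    for k in range(2, 6):
        v = float(sib_hist[-k]) if len(sib_hist) >= k else 0.0
        row[f"nbr_lag{k}"] = v
        row[f"rwd_x_nbr_lag{k}"] = rwd * v
    # same-island prior-choice lags 2..5 (lag 1 is onPolicy), coded 0/1
    for k in range(2, 6):
        v = float(pol_hist[-k] == b) if len(pol_hist) >= k else 0.0
        row[f"pol_lag{k}"] = v
        row[f"rwd_x_pol_lag{k}"] = rwd * v
    # sampled-boat outcome lags 1..5 (before the current outcome), coded 0/1
    samp_hist = boat_outcomes[b]
    for k in range(1, 6):
        v = float(samp_hist[-k]) if len(samp_hist) >= k else 0.0
        row[f"samp_lag{k}"] = v
        row[f"rwd_x_samp_lag{k}"] = rwd * v
    # opposite-island running mean value at the ends of the 5 previous pairs
    opp0 = 2 * (1 - isl)
    for k in range(1, 6):
        idx = pair - k
        if idx >= 0:
            snap = value_snapshots[idx]
            v = 0.5 * (snap[opp0] + snap[opp0 + 1]) - 0.5
        else:
            v = 0.0
        row[f"opp_val_lag{k}"] = v
    # island choice kernel over the last 5 traversals (including this pair's)
    for k in range(1, 6):
        if len(traversal_islands) >= k:
            v = (traversal_islands[-k] == isl) - 0.5
        else:
            v = 0.0
        row[f"kernel_lag{k}"] = v
    return row


# ---------------------------------------------------------------------------
# hierarchical logistic regression (Laplace/EM)


@dataclass
class HierLogisticResult:
    table: pd.DataFrame  # term, estimate, se, z, p, random
    mu: np.ndarray
    sigma: np.ndarray
    beta_fixed: np.ndarray
    converged: bool
    iterations: int

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _subject_map(Xr, Xf, y, beta_f, mu, prec, n_newton=30, tol=1e-9):
    """Newton MAP of one subject's random coefficients (analytic Hessian)."""
    b = mu.copy()
    off = Xf @ beta_f if Xf.shape[1] else np.zeros(len(y))
    for _ in range(n_newton):
        eta = Xr @ b + off
        p = _sigmoid(eta)
        g = Xr.T @ (p - y) + prec * (b - mu)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = (Xr * w[:, None]).T @ Xr + np.diag(prec)
        step = np.linalg.solve(H, g)
        # dampen very large steps to keep Newton stable under near-separation
        nrm = np.max(np.abs(step))
        if nrm > 5.0:
            step *= 5.0 / nrm
        b = b - step
        if np.max(np.abs(step)) < tol:
            break
    eta = Xr @ b + off
    p = _sigmoid(eta)
    w = np.clip(p * (1.0 - p), 1e-10, None)
    H_lik = (Xr * w[:, None]).T @ Xr
    H_post = H_lik + np.diag(prec)
    return b, H_post, H_lik


def fit_hier_logistic(
    design: pd.DataFrame,
    formula: str = "eq2",
    max_iter: int = 200,
    tol: float = 1e-4,
    sigma_floor: float = 1e-3,
) -> HierLogisticResult:
    """Hierarchical logistic regression of ``y`` on the design.

    ``formula='eq1'`` uses intercept + rwd (both with per-subject random
    effects); ``'eq2'`` adds the primary interaction terms (random) and the
    lagged controls (shared fixed effects). Group-level estimates are the
    Gaussian means of the random coefficients, tested with Wald z statistics
    whose SEs include the per-subject Laplace (missing-information)
    correction; fixed effects are tested from the pooled curvature.
    """
    if formula == "eq1":
        rand_cols, fixed_cols = ["rwd"], []
    elif formula == "eq2":
        rand_cols = list(PRIMARY_COLS)
        fixed_cols = [c for c in CONTROL_COLS if c in design.columns]
    else:
        raise ValueError(f"unknown formula {formula!r}")
    if design.empty:
        raise ValueError("empty design")

    subjects = design["subject_id"].unique()
    y_all, Xr_all, Xf_all = [], [], []
    for sid in subjects:
        d = design[design["subject_id"] == sid]
        y_all.append(d["y"].to_numpy(dtype=float))
        Xr = np.column_stack([np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in rand_cols])
        Xr_all.append(Xr)
        Xf_all.append(
            np.column_stack([d[c].to_numpy(dtype=float) for c in fixed_cols])
            if fixed_cols
            else np.zeros((len(d), 0))
        )

    dr = 1 + len(rand_cols)
    df_ = len(fixed_cols)
    mu = np.zeros(dr)
    sigma2 = np.ones(dr)
    beta_f = np.zeros(df_)
    maps = [mu.copy() for _ in subjects]

    converged = False
    iteration = 0
    H_liks = []
    for iteration in range(1, max_iter + 1):
        prec = 1.0 / sigma2
        H_posts, H_liks = [], []
        for i in range(len(subjects)):
            b, H_post, H_lik = _subject_map(
                Xr_all[i], Xf_all[i], y_all[i], beta_f, mu, prec
            )
            maps[i] = b
            H_posts.append(H_post)
            H_liks.append(H_lik)
        B = np.vstack(maps)
        mu_new = B.mean(axis=0)
        lap = np.vstack([np.clip(np.diag(np.linalg.inv(H)), sigma_floor**2, None)
                         for H in H_posts])
        sigma2_new = np.maximum(
            ((B - mu_new) ** 2 + lap).mean(axis=0), sigma_floor**2
        )
        # one Newton step on the shared fixed effects given subject MAPs
        if df_:
            g = np.zeros(df_)
            H = np.eye(df_) * 1e-6
            for i in range(len(subjects)):
                eta = Xr_all[i] @ maps[i] + Xf_all[i] @ beta_f
                p = _sigmoid(eta)
                w = np.clip(p * (1.0 - p), 1e-10, None)
                g += Xf_all[i].T @ (p - y_all[i])
                H += (Xf_all[i] * w[:, None]).T @ Xf_all[i]
            step = np.linalg.solve(H, g)
            nrm = np.max(np.abs(step))
            if nrm > 5.0:
                step *= 5.0 / nrm
            beta_f_new = beta_f - step
        else:
            beta_f_new = beta_f
        delta = max(
            np.max(np.abs(mu_new - mu)),
            np.max(np.abs(beta_f_new - beta_f)) if df_ else 0.0,
        )
        mu, sigma2, beta_f = mu_new, sigma2_new, beta_f_new
        if delta < tol:
            converged = True
            break

    if np.max(np.abs(mu)) > 30 or (df_ and np.max(np.abs(beta_f)) > 30):
        logger.warning("very large coefficients: possible separation in design")

    # group-mean covariance with missing-information correction
    Sigma = np.diag(sigma2)
    info = np.zeros((dr, dr))
    for H_lik in H_liks:
        Hl = 0.5 * (H_lik + H_lik.T)
        eigval, eigvec = np.linalg.eigh(Hl)
        eigval = np.clip(eigval, 1e-8, None)
        C = (eigvec / eigval) @ eigvec.T
        info += np.linalg.inv(Sigma + C)
    cov_mu = np.linalg.inv(info)
    se_mu = np.sqrt(np.diag(cov_mu))

    from scipy import stats

    terms = ["(Intercept)"] + rand_cols
    recs = []
    for j, term in enumerate(terms):
        z = mu[j] / se_mu[j] if se_mu[j] > 0 else np.inf * np.sign(mu[j])
        recs.append(
            {
                "term": term,
                "estimate": mu[j],
                "se": se_mu[j],
                "z": z,
                "p": 2 * stats.norm.sf(abs(z)),
                "random": True,
            }
        )
    if df_:
        Hf = np.eye(df_) * 1e-6
        for i in range(len(subjects)):
            eta = Xr_all[i] @ maps[i] + Xf_all[i] @ beta_f
            p = _sigmoid(eta)
            w = np.clip(p * (1.0 - p), 1e-10, None)
            Hf += (Xf_all[i] * w[:, None]).T @ Xf_all[i]
        se_f = np.sqrt(np.diag(np.linalg.inv(Hf)))
        for j, term in enumerate(fixed_cols):
            z = beta_f[j] / se_f[j] if se_f[j] > 0 else np.inf * np.sign(beta_f[j])
            recs.append(
                {
                    "term": term,
                    "estimate": beta_f[j],
                    "se": se_f[j],
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)),
                    "random": False,
                }
            )
    table = pd.DataFrame(recs)
    return HierLogisticResult(
        table=table,
        mu=mu,
        sigma=np.sqrt(sigma2),
        beta_fixed=beta_f,
        converged=converged,
        iterations=iteration,
    )
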