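"""Hierarchical (EM + Laplace) estimation of the choice models.

Subject-level free parameters are estimated on transformed scales on which
they are unbounded (logit for learning rates and the SR weight, log for the
combined MB/SR temperature and the linear-RL lambda, identity for signed
temperatures and perseveration weights), with a group-level Gaussian over
subjects. Estimation alternates:

* **E-step** — per-subject MAP under the current Gaussian prior, with the
  Hessian of the negative log posterior at the optimum (finite differences)
  giving a Laplace approximation to each subject's posterior;
* **M-step** — the group mean is the mean of the MAPs and the group variance
  the mean of squared deviations *plus* the per-subject Laplace variances
  (without which the variance would be biased toward zero).

Group-level standard errors come from an information matrix that accounts
for the E-step uncertainty ("missing information"): each subject contributes
(Sigma + C_i)^{-1}, where C_i is the Laplace covariance of that subject's
*likelihood* (posterior Hessian minus prior precision, with a pseudo-inverse
fallback when the likelihood is locally flat).

The blockwise variants estimate separate island-level parameters for blocks
that follow congruent vs. incongruent reward changes, re-parameterized as a
fractional SR weight w_SR = beta_SR / (beta_SR + beta_MB) and a combined
temperature beta_MBSR, so that congruent/incongruent shifts in SR reliance
can be tested directly as a contrast on w_SR (or, for linear RL, on lambda).
The session's first block, which no change precedes, is assigned to the
congruent set (configurable at the likelihood level via the change-type
labels in the log).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._core import lrl_nll_core, log_arrays, mixture_nll_core

__all__ = [
    "ParamSpec",
    "GroupPrior",
    "SubjectFit",
    "FitResult",
    "EMConfig",
    "get_spec",
    "MODEL_SPECS",
    "negloglik",
    "map_subject",
    "em_fit",
    "wald_test",
    "transform",
    "inverse_transform",
]

logger = logging.getLogger(__name__)

_CLIP = 30.0  # bound on log-scale transformed values before exponentiation


def transform(value: np.ndarray, kinds: Sequence[str]) -> np.ndarray:
    """Natural scale -> unconstrained scale."""
    value = np.asarray(value, dtype=float)
    out = np.empty_like(value)
    for i, k in enumerate(kinds):
        v = value[i]
        if k == "logit01":
            out[i] = np.log(v / (1.0 - v))
        elif k == "log":
            out[i] = np.log(v)
        elif k == "id":
            out[i] = v
        else:
            raise ValueError(f"unknown transform {k!r}")
    return out


def inverse_transform(x: np.ndarray, kinds: Sequence[str]) -> np.ndarray:
    """Unconstrained scale -> natural scale."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for i, k in enumerate(kinds):
        v = x[i]
        if k == "logit01":
            out[i] = 1.0 / (1.0 + np.exp(-v))
        elif k == "log":
            out[i] = np.exp(np.clip(v, -_CLIP, _CLIP))
        elif k == "id":
            out[i] = v
        else:
            raise ValueError(f"unknown transform {k!r}")
    return out


@dataclass(frozen=True)
class ParamSpec:
    """Names, transforms and core-row construction for one model variant."""

    model: str
    names: tuple[str, ...]
    transforms: tuple[str, ...]
    default_natural: tuple[float, ...]
    core: str  # "mixture" | "lrl"
    blockwise: bool

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def natural_dict(self, natural: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(natural, dtype=float)))

    def to_natural(self, x: np.ndarray) -> np.ndarray:
        return inverse_transform(x, self.transforms)

    def to_transformed(self, natural: np.ndarray) -> np.ndarray:
        return transform(natural, self.transforms)

    def default_transformed(self) -> np.ndarray:
        return self.to_transformed(np.asarray(self.default_natural))

    def core_rows(self, natural: np.ndarray) -> np.ndarray:
        """(2, 9) array of per-block-type parameter rows for the kernels."""
        p = self.natural_dict(natural)
        return _ROW_BUILDERS[self.model](p)

    def core_fn(self):
        return mixture_nll_core if self.core == "mixture" else lrl_nll_core


def _rows_mixture(p: dict) -> np.ndarray:
    row = [
        p["alpha_A"], p["alpha_P"], p["alpha_M"], p["beta_boat"],
        p["beta_MB"], p["beta_SR"], p["beta_TD"],
        p.get("beta_persist_boat", 0.0), p.get("beta_persist_island", 0.0),
    ]
    return np.array([row, row])


def _rows_mixture_w(p: dict) -> np.ndarray:
    w, bc = p["w_SR"], p["beta_MBSR"]
    row = [
        p["alpha_A"], p["alpha_P"], p["alpha_M"], p["beta_boat"],
        (1.0 - w) * bc, w * bc, p["beta_TD"],
        p.get("beta_persist_boat", 0.0), p.get("beta_persist_island", 0.0),
    ]
    return np.array([row, row])


def _rows_mixture_w_blockwise(p: dict) -> np.ndarray:
    rows = []
    for s in ("plus", "minus"):
        w, bc = p[f"w_SR_{s}"], p[f"beta_MBSR_{s}"]
        rows.append([
            p["alpha_A"], p["alpha_P"], p["alpha_M"], p["beta_boat"],
            (1.0 - w) * bc, w * bc, p[f"beta_TD_{s}"],
            p.get("beta_persist_boat", 0.0), p.get("beta_persist_island", 0.0),
        ])
    return np.array(rows)


def _rows_lrl(p: dict) -> np.ndarray:
    row = [
        p["alpha_A"], p["alpha_P"], p["alpha_T"], p["lam"], p["beta_boat"],
        p["beta_lrl"], p.get("beta_TD", 0.0),
        p.get("beta_persist_boat", 0.0), p.get("beta_persist_island", 0.0),
    ]
    return np.array([row, row])


def _rows_lrl_blockwise(p: dict) -> np.ndarray:
    rows = []
    for s in ("plus", "minus"):
        rows.append([
            p["alpha_A"], p["alpha_P"], p["alpha_T"], p[f"lam_{s}"],
            p["beta_boat"], p[f"beta_lrl_{s}"], p[f"beta_TD_{s}"],
            p.get("beta_persist_boat", 0.0), p.get("beta_persist_island", 0.0),
        ])
    return np.array(rows)


_ROW_BUILDERS = {
    "mixture": _rows_mixture,
    "mixture_w": _rows_mixture_w,
    "mixture_w_blockwise": _rows_mixture_w_blockwise,
    "lrl": _rows_lrl,
    "lrl_blockwise": _rows_lrl_blockwise,
}

MODEL_SPECS: dict[str, ParamSpec] = {
    "mixture": ParamSpec(
        model="mixture",
        names=(
            "alpha_A", "alpha_P", "alpha_M", "beta_boat",
            "beta_MB", "beta_SR", "beta_TD",
            "beta_persist_boat", "beta_persist_island",
        ),
        transforms=("logit01",) * 3 + ("id",) * 6,
        default_natural=(0.3, 0.3, 0.3, 1.0, 1.0, 1.0, 0.5, 0.0, 0.0),
        core="mixture",
        blockwise=False,
    ),
    "mixture_w": ParamSpec(
        model="mixture_w",
        names=(
            "alpha_A", "alpha_P", "alpha_M", "beta_boat",
            "w_SR", "beta_MBSR", "beta_TD",
            "beta_persist_boat", "beta_persist_island",
        ),
        transforms=("logit01",) * 3 + ("id", "logit01", "log", "id", "id", "id"),
        default_natural=(0.3, 0.3, 0.3, 1.0, 0.5, 1.5, 0.5, 0.0, 0.0),
        core="mixture",
        blockwise=False,
    ),
    "mixture_w_blockwise": ParamSpec(
        model="mixture_w_blockwise",
        names=(
            "alpha_A", "alpha_P", "alpha_M", "beta_boat",
            "w_SR_plus", "beta_MBSR_plus", "beta_TD_plus",
            "w_SR_minus", "beta_MBSR_minus", "beta_TD_minus",
            "beta_persist_boat", "beta_persist_island",
        ),
        transforms=("logit01",) * 3
        + ("id", "logit01", "log", "id", "logit01", "log", "id", "id", "id"),
        default_natural=(0.3, 0.3, 0.3, 1.0, 0.5, 1.5, 0.5, 0.5, 1.5, 0.5, 0.0, 0.0),
        core="mixture",
        blockwise=True,
    ),
    "lrl": ParamSpec(
        model="lrl",
        names=(
            "alpha_A", "alpha_P", "alpha_T", "lam", "beta_boat", "beta_lrl",
            "beta_persist_boat", "beta_persist_island",
        ),
        transforms=("logit01",) * 3 + ("log", "id", "id", "id", "id"),
        default_natural=(0.3, 0.3, 0.3, 0.5, 1.0, 1.0, 0.0, 0.0),
        core="lrl",
        blockwise=False,
    ),
    "lrl_blockwise": ParamSpec(
        model="lrl_blockwise",
        names=(
            "alpha_A", "alpha_P", "alpha_T", "beta_boat",
            "lam_plus", "beta_lrl_plus", "beta_TD_plus",
            "lam_minus", "beta_lrl_minus", "beta_TD_minus",
            "beta_persist_boat", "beta_persist_island",
        ),
        transforms=("logit01",) * 3
        + ("id", "log", "id", "id", "log", "id", "id", "id", "id"),
        default_natural=(0.3, 0.3, 0.3, 1.0, 0.5, 1.0, 0.5, 0.5, 1.0, 0.5, 0.0, 0.0),
        core="lrl",
        blockwise=True,
    ),
}


def get_spec(model: str, blockwise: bool = False) -> ParamSpec:
    """Resolve a model family + blockwise flag to its parameter spec."""
    if model in MODEL_SPECS and (blockwise == MODEL_SPECS[model].blockwise):
        return MODEL_SPECS[model]
    key = {
        ("mixture", True): "mixture_w_blockwise",
        ("mixture_w", True): "mixture_w_blockwise",
        ("lrl", True): "lrl_blockwise",
    }.get((model, blockwise))
    if key is None:
        raise ValueError(f"no model variant for {model!r}, blockwise={blockwise}")
    return MODEL_SPECS[key]


def negloglik(
    model: str,
    params: dict[str, float],
    log: pd.DataFrame,
    blockwise: bool = False,
) -> float:
    """Session negative log likelihood under a model, natural-scale params.

    Sums, over traversal trials, -log P(island choice) - log P(boat choice),
    with learning applied in trial order; non-traversal trials contribute
    learning only. In blockwise mode the (+) parameter set applies on blocks
    following a congruent change (and the initial block), the (-) set after
    incongruent changes; the log must then carry change-type labels.
    """
    if model in MODEL_SPECS and not blockwise and MODEL_SPECS[model].blockwise:
        blockwise = True
    spec = _spec_for_params(model, params, blockwise)
    for name, v in params.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite parameter {name}={v}")
    if spec.blockwise and "change_type" not in log.columns:
        raise ValueError("blockwise likelihood requires a change_type column")
    natural = np.array([params[n] for n in spec.names])
    rows = spec.core_rows(natural)
    arrays = log_arrays(log, blockwise=spec.blockwise)
    return float(spec.core_fn()(rows, *arrays))


def _spec_for_params(model: str, params: dict, blockwise: bool) -> ParamSpec:
    if model in MODEL_SPECS:
        spec = MODEL_SPECS[model]
        if spec.blockwise == blockwise and set(spec.names) <= set(params):
            return spec
    if model in ("mixture", "mixture_w"):
        if blockwise:
            return MODEL_SPECS["mixture_w_blockwise"]
        if "w_SR" in params:
            return MODEL_SPECS["mixture_w"]
        return MODEL_SPECS["mixture"]
    if model in ("lrl", "lrl_blockwise"):
        return MODEL_SPECS["lrl_blockwise" if blockwise else "lrl"]
    raise ValueError(f"unknown model {model!r}")


@dataclass
class GroupPrior:
    """Group Gaussian over transformed subject-level parameters."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("group sigma must be strictly positive")


@dataclass
class SubjectFit:
    """One subject's Laplace-approximated posterior summary."""

    map_estimate: np.ndarray  # transformed scale
    hessian: np.ndarray  # of the negative log posterior at the MAP
    log_marginal: float
    nll: float
    success: bool


@dataclass
class FitResult:
    group: GroupPrior
    subjects: list[SubjectFit]
    se_mu: np.ndarray
    cov_mu: np.ndarray
    iterations: int
    converged: bool
    log_evidence: float
    spec: ParamSpec
    n_obs: int  # island-choice observations across the cohort

    def subject_table(self) -> pd.DataFrame:
        """Per-subject MAP estimates on the natural scale."""
        rows = [self.spec.to_natural(s.map_estimate) for s in self.subjects]
        return pd.DataFrame(rows, columns=list(self.spec.names))

    def group_natural(self) -> dict[str, float]:
        """Group means mapped back to the natural scale."""
        return self.spec.natural_dict(self.spec.to_natural(self.group.mu))

    def to_dict(self) -> dict:
        return {
            "model": self.spec.model,
            "param_names": list(self.spec.names),
            "transforms": list(self.spec.transforms),
            "group_mu": self.group.mu.tolist(),
            "group_sigma": self.group.sigma.tolist(),
            "group_natural": self.group_natural(),
            "se_mu": self.se_mu.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
            "log_evidence": self.log_evidence,
            "n_obs": self.n_obs,
            "subject_map": [s.map_estimate.tolist() for s in self.subjects],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class EMConfig:
    max_iter: int = 200
    tol: float = 1e-3
    n_restarts: int = 1
    seed: int = 0
    init_sigma: float = 1.0
    sigma_floor: float = 1e-3
    optimizer_maxiter: int = 300


def _fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = x.size
    H = np.empty((d, d))
    h = eps * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _penalized_objective(spec: ParamSpec, arrays, prior: GroupPrior):
    core = spec.core_fn()

    def f(x: np.ndarray) -> float:
        natural = spec.to_natural(x)
        rows = spec.core_rows(natural)
        val = core(rows, *arrays)
        if not np.isfinite(val):
            return np.inf
        pen = 0.5 * np.sum(((x - prior.mu) / prior.sigma) ** 2)
        return val + pen

    return f


def map_subject(
    log: pd.DataFrame | tuple,
    prior: GroupPrior,
    spec: ParamSpec,
    n_restarts: int = 1,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
    optimizer_maxiter: int = 300,
) -> SubjectFit:
    """MAP estimate of one subject's transformed parameters.

    Multi-start L-BFGS from the prior mean (plus jittered restarts and an
    optional warm start); the best optimum is kept. The Hessian of the
    penalized objective at the MAP is evaluated by central finite
    differences.
    """
    arrays = log_arrays(log, blockwise=spec.blockwise) if isinstance(log, pd.DataFrame) else log
    rng = rng if rng is not None else np.random.default_rng(0)
    f = _penalized_objective(spec, arrays, prior)

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(prior.mu.copy())
    for _ in range(n_restarts):
        starts.append(prior.mu + rng.normal(0.0, 0.5, size=prior.mu.size))

    best = None
    any_success = False
    for s in starts:
        res = optimize.minimize(f, s, method="L-BFGS-B", options={"maxiter": optimizer_maxiter})
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    x = np.asarray(best.x, dtype=float)
    H = _fd_hessian(f, x)
    H = 0.5 * (H + H.T)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        # flat or indefinite curvature: fall back to the prior's own curvature
        H = H + np.diag(1.0 / prior.sigma**2)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            H = np.diag(1.0 / prior.sigma**2)
            logdet = np.sum(np.log(1.0 / prior.sigma**2))
    pen = 0.5 * np.sum(((x - prior.mu) / prior.sigma) ** 2)
    log_marg = -best.fun - np.sum(np.log(prior.sigma)) - 0.5 * logdet
    return SubjectFit(
        map_estimate=x,
        hessian=H,
        log_marginal=float(log_marg),
        nll=float(best.fun - pen),
        success=bool(any_success),
    )


def _laplace_variances(fit: SubjectFit, floor: float) -> np.ndarray:
    try:
        cov = np.linalg.inv(fit.hessian)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fit.hessian)
    v = np.diag(cov).copy()
    return np.clip(v, floor**2, None)


def em_fit(
    logs: Sequence[pd.DataFrame],
    spec: ParamSpec,
    config: EMConfig | None = None,
    init_mu: np.ndarray | None = None,
) -> FitResult:
    """Hierarchical EM fit of a cohort of single-subject trial logs.

    Alternates per-subject MAP (E-step) with moment updates of the group
    Gaussian (M-step, Laplace-corrected variance) until the group mean moves
    less than ``config.tol`` or ``config.max_iter`` is reached.
    """
    config = config or EMConfig()
    if len(logs) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    rng = np.random.default_rng(config.seed)
    arrays = [log_arrays(df, blockwise=spec.blockwise) for df in logs]
    n_obs = int(sum(a[0].sum() for a in arrays))  # traversal trials

    mu = (
        np.asarray(init_mu, dtype=float)
        if init_mu is not None
        else spec.default_transformed()
    )
    sigma = np.full(spec.n_params, float(config.init_sigma))
    warm: list[np.ndarray | None] = [None] * len(logs)

    converged = False
    fits: list[SubjectFit] = []
    iteration = 0
    for iteration in range(1, config.max_iter + 1):
        prior = GroupPrior(mu.copy(), sigma.copy())
        fits = []
        for i, arr in enumerate(arrays):
            fit = map_subject(
                arr,
                prior,
                spec,
                n_restarts=config.n_restarts,
                rng=rng,
                x0=warm[i],
                optimizer_maxiter=config.optimizer_maxiter,
            )
            if not fit.success:
                logger.warning("subject %d optimizer did not report success", i)
            fits.append(fit)
            warm[i] = fit.map_estimate
        maps = np.vstack([f.map_estimate for f in fits])
        lap_var = np.vstack([_laplace_variances(f, config.sigma_floor) for f in fits])
        mu_new = maps.mean(axis=0)
        sigma2 = ((maps - mu_new) ** 2 + lap_var).mean(axis=0)
        sigma_new = np.sqrt(np.maximum(sigma2, config.sigma_floor**2))
        delta = np.max(np.abs(mu_new - mu))
        mu, sigma = mu_new, sigma_new
        if delta < config.tol:
            converged = True
            break

    cov_mu = _group_covariance(fits, sigma, config.sigma_floor)
    se_mu = np.sqrt(np.diag(cov_mu))
    return FitResult(
        group=GroupPrior(mu, sigma),
        subjects=fits,
        se_mu=se_mu,
        cov_mu=cov_mu,
        iterations=iteration,
        converged=converged,
        log_evidence=float(sum(f.log_marginal for f in fits)),
        spec=spec,
        n_obs=n_obs,
    )


def _group_covariance(
    fits: Sequence[SubjectFit], sigma: np.ndarray, floor: float
) -> np.ndarray:
    """Missing-information-corrected covariance of the group means.

    Each subject's Laplace likelihood covariance C_i widens its contribution
    to the information about the group mean: I = sum_i (Sigma + C_i)^{-1}.
    """
    d = sigma.size
    Sigma = np.diag(sigma**2)
    prior_prec = np.diag(1.0 / sigma**2)
    info = np.zeros((d, d))
    for f in fits:
        L = f.hessian - prior_prec  # likelihood curvature
        L = 0.5 * (L + L.T)
        try:
            eigval, eigvec = np.linalg.eigh(L)
        except np.linalg.LinAlgError:  # pragma: no cover
            eigval, eigvec = np.linalg.eigh(f.hessian)
        # flat/negative directions carry no likelihood information
        eigval = np.clip(eigval, 1e-8, None)
        C = (eigvec / eigval) @ eigvec.T
        info += np.linalg.inv(Sigma + C)
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.linalg.pinv(info)


def wald_test(
    fit: FitResult,
    contrast: np.ndarray | Callable[[np.ndarray], float],
    *,
    dof: int | None = None,
) -> dict:
    """Wald test of a contrast on the group means.

    ``contrast`` is either a linear-combination vector over the transformed
    group means, or a smooth scalar function of them (tested via the delta
    method, e.g. a difference of log SR weights). Degrees of freedom follow
    the observation-count convention: total island-choice observations minus
    the number of group-level parameters.
    """
    mu, cov = fit.group.mu, fit.cov_mu
    if callable(contrast):
        est = float(contrast(mu))
        grad = optimize.approx_fprime(mu, contrast, 1e-6 * np.maximum(1.0, np.abs(mu)))
        var = float(grad @ cov @ grad)
    else:
        c = np.asarray(contrast, dtype=float)
        est = float(c @ mu)
        var = float(c @ cov @ c)
    se = float(np.sqrt(max(var, 0.0)))
    dof = dof if dof is not None else max(fit.n_obs - fit.spec.n_params, 1)
    if est == 0.0 and se == 0.0:
        t = 0.0
    elif se == 0.0:
        t = np.inf * np.sign(est)
    else:
        t = est / se
    p = float(2.0 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
    if est == 0.0:
        p = 1.0
    return {"estimate": est, "se": se, "t": float(t), "dof": int(dof), "p": p}


def log_w_contrast(spec: ParamSpec) -> Callable[[np.ndarray], float]:
    """log(w_SR+) - log(w_SR-) as a function of the transformed group means."""
    i_p = spec.index("w_SR_plus")
    i_m = spec.index("w_SR_minus")

    def fn(mu: np.ndarray) -> float:
        # w is logit-transformed: log(w) = -log(1 + exp(-x)) = -softplus(-x)
        return float(np.logaddexp(0.0, -mu[i_m]) - np.logaddexp(0.0, -mu[i_p]))

    return fn


def log_lam_contrast(spec: ParamSpec) -> np.ndarray:
    """Linear contrast log(lam+) - log(lam-) on the transformed scale."""
    c = np.zeros(spec.n_params)
    c[spec.index("lam_plus")] = 1.0
    c[spec.index("lam_minus")] = -1.0
    return c
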