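"""Maximum-likelihood / MAP fitting and model comparison for two-step agents.

Each model is fit separately per subject by maximizing the summed log
probability of the observed free-choice responses (latent state is updated on
every trial, including forced-choice trials, which carry no choice
information).  Bounded parameters are optimized on an unconstrained scale
(logit for unit-range, log for positive-range) with a quasi-Newton optimizer;
the optimization is restarted from random draws - Beta(2,2) for unit-range
parameters, Gamma(shape 2, scale 0.4) for positive-range and Normal(0, 5) for
unconstrained ones - and the best restart is kept (default 30 restarts for ML,
50 for MAP).  MAP fits add the log prior density (same families) evaluated in
the natural parameter space, so flat-likelihood data recovers the prior modes.

Model comparison uses BIC = k ln(n) - 2 ll over free-choice trials and
session-split 10-fold cross-validated log-likelihood.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kernels as K
from .agents import Agent, AgentSpec
from .task import SESSION_COLUMNS, TaskConfig, generate_session

__all__ = [
    "FitResult",
    "pack_params",
    "session_arrays",
    "session_loglik",
    "fit_ml",
    "fit_map",
    "fit_subjects",
    "bic",
    "cv_loglik",
    "simulate_from_fit",
]


@dataclass
class FitResult:
    """Best-of-restarts fit for one subject and model."""

    params: dict[str, float]
    loglik: float
    n_trials_used: int
    bic: float
    restarts: int
    converged_fraction: float
    seed: int
    cv_loglik: Optional[float] = None
    spec: Optional[AgentSpec] = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.spec is not None:
            d["spec"] = dataclasses.asdict(self.spec)
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# Packing and likelihood
# ---------------------------------------------------------------------------

def pack_params(spec: AgentSpec, params: dict[str, float]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Map named params for ``spec`` onto the fixed kernel layout."""
    full = np.zeros(K.N_PARAMS)
    full[K.FORGET_TARGET] = spec.forget_target
    alias = {
        "w_mf": K.W_MF, "alpha_mf": None, "alpha_mf_pos": K.A_MF_POS,
        "alpha_mf_neg": K.A_MF_NEG, "lam": K.LAM, "forget_mf": K.FORGET_MF,
        "w_mb": K.W_MB, "alpha_mb": None, "alpha_mb_pos": K.A_MB_POS,
        "alpha_mb_neg": K.A_MB_NEG, "forget_mb": K.FORGET_MB,
        "w_inf": K.W_INF, "p_reversal": K.P_REVERSAL, "bias": K.BIAS,
        "persev": K.PERSEV, "persev_alpha": K.PERSEV_ALPHA,
    }
    for name, value in params.items():
        if name == "alpha_mf":
            full[K.A_MF_POS] = full[K.A_MF_NEG] = value
        elif name == "alpha_mb":
            full[K.A_MB_POS] = full[K.A_MB_NEG] = value
        else:
            idx = alias[name]
            full[idx] = value
    persev_mode = {"none": 0, "single": 1, "multi": 2}[spec.perseveration]
    if spec.perseveration == "single":
        # single-trial perseveration is the multi-trial trace with rate 1
        full[K.PERSEV_ALPHA] = 1.0
    flags = np.array([
        int("mf" in spec.strategies),
        int("mb" in spec.strategies),
        int("inf" in spec.strategies),
        int(spec.asymmetric),
        persev_mode,
    ], dtype=np.int64)
    return full, flags


def session_arrays(sessions: pd.DataFrame) -> dict[str, np.ndarray]:
    """Convert a SessionTable to packed arrays for the likelihood kernel."""
    df = sessions.sort_values(["subject_id", "session_id", "trial"],
                              kind="stable")
    choices = (df["choice"].to_numpy() == "right").astype(np.int8)
    seconds = (df["second_step"].to_numpy() == "down").astype(np.int8)
    outcomes = df["outcome"].to_numpy().astype(np.int8)
    free = df["free_choice"].to_numpy().astype(np.int8)
    key = df["subject_id"].astype(str) + "\x00" + df["session_id"].astype(str)
    starts = np.flatnonzero(key.to_numpy() != np.roll(key.to_numpy(), 1))
    if len(df) > 0 and starts.size == 0:
        starts = np.array([0])
    return {"choices": choices, "seconds": seconds, "outcomes": outcomes,
            "free": free, "starts": starts.astype(np.int64)}


def session_loglik(spec: AgentSpec, params: dict[str, float],
                   sessions: pd.DataFrame) -> float:
    """Summed log P(observed choice) over free-choice trials."""
    arr = session_arrays(sessions)
    full, flags = pack_params(spec, params)
    p_up_left = 0.8 if spec.transition_type == "A" else 0.2
    probs = np.empty(arr["choices"].shape[0])
    return float(K.loglik_core(full, flags, arr["choices"], arr["seconds"],
                               arr["outcomes"], arr["free"], arr["starts"],
                               p_up_left, probs))


def predicted_choice_probs(spec: AgentSpec, params: dict[str, float],
                           sessions: pd.DataFrame) -> np.ndarray:
    """Pre-choice P(left) for every trial, in table order."""
    arr = session_arrays(sessions)
    full, flags = pack_params(spec, params)
    p_up_left = 0.8 if spec.transition_type == "A" else 0.2
    probs = np.empty(arr["choices"].shape[0])
    K.loglik_core(full, flags, arr["choices"], arr["seconds"],
                  arr["outcomes"], arr["free"], arr["starts"], p_up_left,
                  probs)
    return probs


# ---------------------------------------------------------------------------
# Transforms, initialization and priors
# ---------------------------------------------------------------------------

def _to_unconstrained(kind: str, theta: float) -> float:
    if kind == "unit":
        theta = min(max(theta, 1e-9), 1 - 1e-9)
        return math.log(theta / (1 - theta))
    if kind == "pos":
        return math.log(max(theta, 1e-12))
    return theta


def _to_natural(kind: str, x: float) -> float:
    if kind == "unit":
        return 1.0 / (1.0 + math.exp(-x))
    if kind == "pos":
        return math.exp(min(x, 50.0))
    return x


def _draw_init(kind: str, rng: np.random.Generator) -> float:
    if kind == "unit":
        return float(rng.beta(2.0, 2.0))
    if kind == "pos":
        return float(rng.gamma(2.0, 0.4))
    return float(rng.normal(0.0, 5.0))


def _log_prior(kind: str, theta: float) -> float:
    if kind == "unit":
        return float(stats.beta.logpdf(theta, 2.0, 2.0))
    if kind == "pos":
        return float(stats.gamma.logpdf(theta, 2.0, scale=0.4))
    return float(stats.norm.logpdf(theta, 0.0, 5.0))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit(spec: AgentSpec, sessions: pd.DataFrame, n_restarts: int,
         rng: np.random.Generator, use_prior: bool, seed: int) -> FitResult:
    arr = session_arrays(sessions)
    if int(arr["free"].sum()) < 1:
        raise ValueError("need at least one free-choice trial")
    names = spec.param_names
    kinds = spec.param_kinds
    p_up_left = 0.8 if spec.transition_type == "A" else 0.2
    probs = np.empty(arr["choices"].shape[0])

    if not names:  # fully constrained model: nothing to optimize
        loglik = session_loglik(spec, {}, sessions)
        n_free = int(arr["free"].sum())
        return FitResult(params={}, loglik=loglik, n_trials_used=n_free,
                         bic=bic(loglik, 0, n_free), restarts=0,
                         converged_fraction=1.0, seed=seed, spec=spec)

    def objective(x: np.ndarray) -> float:
        theta = {n: _to_natural(kinds[n], xi) for n, xi in zip(names, x)}
        full, flags = pack_params(spec, theta)
        ll = K.loglik_core(full, flags, arr["choices"], arr["seconds"],
                           arr["outcomes"], arr["free"], arr["starts"],
                           p_up_left, probs)
        if use_prior:
            ll += sum(_log_prior(kinds[n], theta[n]) for n in names)
        if not math.isfinite(ll):
            return 1e12
        return -ll

    best = None
    n_converged = 0
    statuses = []
    for _ in range(n_restarts):
        x0 = np.array([_to_unconstrained(kinds[n], _draw_init(kinds[n], rng))
                       for n in names])
        try:
            res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    options={"ftol": 1e-6, "gtol": 1e-6,
                                             "maxiter": 500})
        except Exception as exc:  # pragma: no cover - optimizer failure path
            statuses.append(str(exc))
            continue
        statuses.append(res.message)
        n_converged += int(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all restarts failed: {statuses}")

    theta = {n: _to_natural(kinds[n], xi) for n, xi in zip(names, best.x)}
    loglik = session_loglik(spec, theta, sessions)
    n_free = int(arr["free"].sum())
    return FitResult(
        params=theta, loglik=loglik, n_trials_used=n_free,
        bic=bic(loglik, len(names), n_free), restarts=n_restarts,
        converged_fraction=n_converged / max(n_restarts, 1), seed=seed,
        spec=spec,
    )


def fit_ml(spec: AgentSpec, sessions: pd.DataFrame, n_restarts: int = 30,
           rng: Optional[np.random.Generator] = None,
           seed: int = 0) -> FitResult:
    """Best-of-restarts maximum-likelihood fit for one subject's sessions."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return _fit(spec, sessions, n_restarts, rng, use_prior=False, seed=seed)


def fit_map(spec: AgentSpec, sessions: pd.DataFrame, n_restarts: int = 50,
            rng: Optional[np.random.Generator] = None,
            seed: int = 0) -> FitResult:
    """Maximum a posteriori fit (Beta/Gamma/Normal priors, mixture model)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return _fit(spec, sessions, n_restarts, rng, use_prior=True, seed=seed)


def fit_subjects(spec: AgentSpec, sessions: pd.DataFrame,
                 n_restarts: int = 30, seed: int = 0,
                 method: str = "ml") -> dict[str, FitResult]:
    """Fit each subject separately; returns subject_id -> FitResult."""
    out = {}
    fit_fn = fit_ml if method == "ml" else fit_map
    for i, (subject, df) in enumerate(sessions.groupby("subject_id")):
        out[str(subject)] = fit_fn(spec, df, n_restarts=n_restarts,
                                   seed=seed + i)
    return out


def bic(loglik: float, k: int, n: int) -> float:
    """k ln(n) - 2 loglik."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * math.log(n) - 2.0 * loglik


def cv_loglik(spec: AgentSpec, sessions: pd.DataFrame, folds: int = 10,
              rng: Optional[np.random.Generator] = None, seed: int = 0,
              n_restarts: int = 10) -> float:
    """Session-split cross-validated log-likelihood (sum over held-out sets)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    key = (sessions["subject_id"].astype(str) + "\x00"
           + sessions["session_id"].astype(str))
    ids = key.unique()
    if len(ids) < folds:
        folds = max(2, len(ids))
    perm = rng.permutation(len(ids))
    assignment = {ids[perm[i]]: i % folds for i in range(len(ids))}
    fold_of = key.map(assignment)
    total = 0.0
    for f in range(folds):
        train = sessions[fold_of != f]
        test = sessions[fold_of == f]
        if len(test) == 0:
            continue
        fit = fit_ml(spec, train, n_restarts=n_restarts, rng=rng, seed=seed)
        total += session_loglik(spec, fit.params, test)
    return total


def simulate_from_fit(fit: FitResult,
                      session_structure: dict[str, list[int]],
                      rng: np.random.Generator,
                      config: Optional[TaskConfig] = None) -> pd.DataFrame:
    """Simulate sessions from fitted parameters on a fresh task instance.

    ``session_structure`` maps subject_id -> list of per-session trial counts.
    """
    if fit.spec is None:
        raise ValueError("FitResult lacks its AgentSpec")
    if config is None:
        config = TaskConfig(transition_type=fit.spec.transition_type)
    frames = []
    for subject, trial_counts in session_structure.items():
        for s_idx, n_trials in enumerate(trial_counts):
            agent = Agent(fit.spec, fit.params)
            frames.append(generate_session(
                agent.policy(rng), config, n_trials, rng,
                subject_id=str(subject), session_id=str(s_idx)))
    if not frames:
        return pd.DataFrame(columns=SESSION_COLUMNS)
    return pd.concat(frames, ignore_index=True)
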