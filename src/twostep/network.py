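"""Cortex-basal-ganglia network model of the two-step task.

A 16-unit gated recurrent network ("PFC") learns, by predicting its next
input, to track the task's hidden reward-probability state; a feedforward
actor-critic network ("BG": 10 rectified-linear units shared by a scalar
value head and a 5-way softmax policy head) receives the current observation
and the PFC activity and learns values and actions by advantage actor-critic.

The task is presented at the time-step level: five observable states (choice
state, up-active, down-active, reward-at-up, reward-at-down; the unrewarded
outcome observation is the zero vector) and five nose-poke actions.  A trial
needs at least three steps; inactive actions leave the state unchanged.

Two variants differ only in the PFC input: the *base* variant receives the
observation and previous action as one-hot vectors; the *gated* variant
receives the observation gated by reward (zero vector on unrewarded steps),
which reproduces the asymmetric influence of rewards versus omissions.

Training: episodes of at most 100 trials or 600 steps; weights updated
between episodes (Adam; PFC learning rate 0.01 on the next-input MSE with
full-episode backpropagation through time, BG learning rate 0.05 on the
summed actor-critic loss with discount 0.9 and entropy weight 0.05).
Both backward passes are verified against finite-difference oracles in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrainConfig",
    "RunResult",
    "gate_observation",
    "discounted_returns",
    "init_weights",
    "pfc_step",
    "bg_forward",
    "bg_loss_and_grads",
    "pfc_loss_and_grads",
    "a2c_episode_update",
    "pfc_episode_update",
    "train_run",
    "run_battery",
    "pfc_pc1",
    "counterfactual_value_analysis",
    "simulated_optostim",
    "run_stay_table",
]

N_OBS = 5
N_ACT = 5
N_PFC = 16
N_BG = 10
OBS_CHOICE, OBS_UP, OBS_DOWN, OBS_REW_UP, OBS_REW_DOWN = range(5)
OBS_NO_REWARD = 5  # encoded as the zero vector


@dataclass(frozen=True)
class TrainConfig:
    pfc_lr: float = 0.01
    bg_lr: float = 0.05
    gamma: float = 0.9
    entropy_weight: float = 0.05
    max_trials: int = 100
    max_steps: int = 600
    episodes: int = 500
    n_runs: int = 12
    gated: bool = False
    seed: int = 0
    # task parameters (final-task values)
    p_common: float = 0.8
    p_high: float = 0.8
    ema_tau: float = 8.0
    threshold: float = 0.75
    post_threshold_range: tuple[int, int] = (5, 15)
    neutral_block_range: tuple[int, int] = (20, 30)
    # The network task uses the binary hidden state (up_good / down_good);
    # neutral blocks can be enabled to match the full behavioral task.
    allow_neutral: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if self.pfc_lr <= 0 or self.bg_lr <= 0:
            raise ValueError("learning rates must be positive")

    @property
    def pfc_input_dim(self) -> int:
        return N_OBS if self.gated else N_OBS + N_ACT


@dataclass
class EpisodeLog:
    """Per-step and per-trial records of one episode."""

    obs_code: np.ndarray          # step-level observation codes (0..5)
    x_pfc: np.ndarray             # PFC inputs, T x input_dim
    h: np.ndarray                 # PFC activity, T x 16
    actions: np.ndarray
    rewards: np.ndarray
    values: np.ndarray
    policies: np.ndarray          # T x 5
    trials: pd.DataFrame          # per completed trial


@dataclass
class RunResult:
    weights: dict[str, np.ndarray]
    reward_per_trial: np.ndarray  # per episode
    trials_per_episode: np.ndarray
    logs: list                    # EpisodeLog for the last `n_log` episodes
    included: bool
    seed: int
    config: TrainConfig


def gate_observation(obs: np.ndarray, reward: int) -> np.ndarray:
    """Observation if reward was received on this step, else the zero vector."""
    return obs.copy() if reward == 1 else np.zeros_like(obs)


def discounted_returns(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """R_t = r_t + gamma R_{t+1}, with R past the terminal step equal to 0."""
    out = np.empty(len(rewards))
    acc = 0.0
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def _one_hot(i: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    if 0 <= i < n:
        v[i] = 1.0
    return v


def encode_obs_code(code: int) -> np.ndarray:
    """Five-dim one-hot; the no-reward code (5) maps to the zero vector."""
    return _one_hot(code, N_OBS)


# ---------------------------------------------------------------------------
# Weights and forward passes
# ---------------------------------------------------------------------------

def init_weights(config: TrainConfig, rng: np.random.Generator
                 ) -> dict[str, np.ndarray]:
    """Glorot-uniform input kernels, orthogonal recurrent kernels (per gate
    block), and a small positive bias on the BG rectified layer to avoid
    dead units at the start of training."""
    def glorot(n_in, n_out):
        lim = math.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out))

    def orthogonal(n):
        q, _ = np.linalg.qr(rng.normal(0.0, 1.0, (n, n)))
        return q

    d = config.pfc_input_dim
    Wh = np.hstack([orthogonal(N_PFC) for _ in range(3)])
    return {
        "Wx": glorot(d, 3 * N_PFC),
        "Wh": Wh,
        "b": np.zeros(3 * N_PFC),
        "Wo": glorot(N_PFC, N_OBS),
        "bo": np.zeros(N_OBS),
        "W1": glorot(N_OBS + N_PFC, N_BG),
        "b1": np.full(N_BG, 0.1),
        "wv": glorot(N_BG, 1)[:, 0],
        "bv": np.zeros(1),
        "Wp": glorot(N_BG, N_ACT),
        "bp": np.zeros(N_ACT),
    }


def pfc_step(weights: dict, h: np.ndarray, x: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """One GRU step plus the linear prediction head.

    Gate layout in Wx/Wh/b: [update z | reset r | candidate].
    h' = (1 - z) * h + z * tanh(Wxh x + Whh (r*h) + bh).
    """
    if x.shape[0] != weights["Wx"].shape[0]:
        raise ValueError("input dimension mismatch")
    pre = x @ weights["Wx"] + weights["b"]
    pre_h = h @ weights["Wh"]
    z = _sigmoid(pre[:N_PFC] + pre_h[:N_PFC])
    r = _sigmoid(pre[N_PFC:2 * N_PFC] + pre_h[N_PFC:2 * N_PFC])
    hh = np.tanh(pre[2 * N_PFC:] + (r * h) @ weights["Wh"][:, 2 * N_PFC:])
    h_new = (1 - z) * h + z * hh
    prediction = h_new @ weights["Wo"] + weights["bo"]
    return h_new, prediction


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def bg_forward(weights: dict, obs: np.ndarray, h: np.ndarray
               ) -> tuple[float, np.ndarray, np.ndarray]:
    """Value, policy and hidden activations for one (obs, PFC) input."""
    u = np.concatenate([obs, h]) @ weights["W1"] + weights["b1"]
    a = np.maximum(u, 0.0)
    v = float(a @ weights["wv"] + weights["bv"][0])
    logits = a @ weights["Wp"] + weights["bp"]
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return v, p, a


# ---------------------------------------------------------------------------
# Losses and gradients
# ---------------------------------------------------------------------------

def bg_loss_and_grads(weights: dict, X: np.ndarray, actions: np.ndarray,
                      returns: np.ndarray, entropy_weight: float,
                      adv: Optional[np.ndarray] = None
                      ) -> tuple[float, dict[str, np.ndarray]]:
    """Summed A2C loss over an episode and its gradients.

    loss = sum_t (R_t - V_t)^2 - sum_t log pi(A_t) adv_t
           - beta sum_t H(pi_t),
    where the advantage adv_t defaults to R_t - V_t but is treated as a
    constant in the actor term (the standard semi-gradient); pass a fixed
    ``adv`` to make the returned loss an exact potential of the gradients.
    ``X`` is the stacked BG input (T x 21).
    """
    T = X.shape[0]
    U = X @ weights["W1"] + weights["b1"]
    A = np.maximum(U, 0.0)
    V = A @ weights["wv"] + weights["bv"][0]
    logits = A @ weights["Wp"] + weights["bp"]
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    P = expl / expl.sum(axis=1, keepdims=True)
    logP = np.log(np.clip(P, 1e-12, None))

    resid = returns - V
    if adv is None:
        adv = resid.copy()
    ent = -(P * logP).sum(axis=1)
    p_act = P[np.arange(T), actions]
    loss = float((resid ** 2).sum()
                 - (np.log(np.clip(p_act, 1e-12, None)) * adv).sum()
                 - entropy_weight * ent.sum())

    # critic: d/dV (R - V)^2 = -2 (R - V)
    dV = -2.0 * resid
    # actor: d/dlogits [-log pi(a) adv] = adv (pi - onehot(a))
    one = np.zeros_like(P)
    one[np.arange(T), actions] = 1.0
    dlogits = adv[:, None] * (P - one)
    # entropy: d/dlogits [-beta H] = beta * pi * (logP + H)
    dlogits += entropy_weight * P * (logP + ent[:, None])

    dA = dV[:, None] * weights["wv"][None, :] + dlogits @ weights["Wp"].T
    dU = dA * (U > 0)
    grads = {
        "W1": X.T @ dU,
        "b1": dU.sum(axis=0),
        "wv": A.T @ dV,
        "bv": np.array([dV.sum()]),
        "Wp": A.T @ dlogits,
        "bp": dlogits.sum(axis=0),
    }
    return loss, grads


def pfc_loss_and_grads(weights: dict, xs: np.ndarray, targets: np.ndarray,
                       h0: Optional[np.ndarray] = None
                       ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Full-episode BPTT for the prediction MSE.

    loss = mean over steps and output dims of (prediction_t - target_t)^2,
    where prediction_t is made from the post-step hidden state h_t.
    Returns (loss, grads, hidden states).
    """
    T = xs.shape[0]
    if h0 is None:
        h0 = np.zeros(N_PFC)
    Wx, Wh, b = weights["Wx"], weights["Wh"], weights["b"]
    Wo, bo = weights["Wo"], weights["bo"]
    H = np.empty((T, N_PFC))
    Z = np.empty((T, N_PFC))
    R = np.empty((T, N_PFC))
    HH = np.empty((T, N_PFC))
    h = h0
    for t in range(T):
        pre = xs[t] @ Wx + b
        pre_h = h @ Wh
        z = _sigmoid(pre[:N_PFC] + pre_h[:N_PFC])
        r = _sigmoid(pre[N_PFC:2 * N_PFC] + pre_h[N_PFC:2 * N_PFC])
        hh = np.tanh(pre[2 * N_PFC:] + (r * h) @ Wh[:, 2 * N_PFC:])
        h = (1 - z) * h + z * hh
        H[t], Z[t], R[t], HH[t] = h, z, r, hh
    Y = H @ Wo + bo
    err = Y - targets
    loss = float((err ** 2).mean())

    scale = 2.0 / err.size
    dY = scale * err
    gWo = H.T @ dY
    gbo = dY.sum(axis=0)
    gWx = np.zeros_like(Wx)
    gWh = np.zeros_like(Wh)
    gb = np.zeros_like(b)
    dh_next = np.zeros(N_PFC)
    for t in range(T - 1, -1, -1):
        h_prev = H[t - 1] if t > 0 else h0
        dh = dY[t] @ Wo.T + dh_next
        z, r, hh = Z[t], R[t], HH[t]
        dhh = dh * z
        da_h = dhh * (1 - hh ** 2)
        dz = dh * (hh - h_prev)
        da_z = dz * z * (1 - z)
        dr = (da_h @ Wh[:, 2 * N_PFC:].T) * h_prev
        da_r = dr * r * (1 - r)
        da = np.concatenate([da_z, da_r, da_h])
        gWx += np.outer(xs[t], da)
        gb += da
        gWh[:, :N_PFC] += np.outer(h_prev, da_z)
        gWh[:, N_PFC:2 * N_PFC] += np.outer(h_prev, da_r)
        gWh[:, 2 * N_PFC:] += np.outer(r * h_prev, da_h)
        dh_next = (dh * (1 - z)
                   + da_z @ Wh[:, :N_PFC].T
                   + da_r @ Wh[:, N_PFC:2 * N_PFC].T
                   + (da_h @ Wh[:, 2 * N_PFC:].T) * r)
    grads = {"Wx": gWx, "Wh": gWh, "b": gb, "Wo": gWo, "bo": gbo}
    return loss, grads, H


# ---------------------------------------------------------------------------
# Episode rollout (numba-accelerated with python fallback)
# ---------------------------------------------------------------------------

def _rollout_py(seed, Wx, Wh, b, W1, b1, wv, bv, Wp, bp, gated,
                max_trials, max_steps, p_common, p_high, ema_tau, threshold,
                post_lo, post_hi, neut_lo, neut_hi, allow_neutral):
    """Roll one episode; returns step logs and per-trial records.

    Observation codes: 0 choice, 1 up-active, 2 down-active, 3 reward-at-up,
    4 reward-at-down, 5 no-reward (zero vector).  Hidden states: 0 up_good,
    1 down_good, 2 neutral.  All trials are free choice.  Transition type A
    (left commonly to up).
    """
    np.random.seed(seed)
    n_pfc = Wh.shape[0]
    in_dim = Wx.shape[0]
    n_obs = 5
    Whh = np.ascontiguousarray(Wh[:, 2 * n_pfc:])

    obs_code = np.zeros(max_steps, dtype=np.int64)
    xs = np.zeros((max_steps, in_dim))
    hs = np.zeros((max_steps, n_pfc))
    actions = np.zeros(max_steps, dtype=np.int64)
    rewards = np.zeros(max_steps)
    values = np.zeros(max_steps)
    policies = np.zeros((max_steps, 5))

    tr_choice = np.zeros(max_trials, dtype=np.int64)
    tr_second = np.zeros(max_trials, dtype=np.int64)
    tr_outcome = np.zeros(max_trials, dtype=np.int64)
    tr_common = np.zeros(max_trials, dtype=np.int64)
    tr_hidden = np.zeros(max_trials, dtype=np.int64)
    tr_choice_step = np.zeros(max_trials, dtype=np.int64)
    tr_ss_entry_step = np.zeros(max_trials, dtype=np.int64)
    tr_outcome_step = np.zeros(max_trials, dtype=np.int64)

    # block state
    hidden = 0 if np.random.random() < 0.5 else 1
    ema = 0.5
    countdown = -1
    trials_in_block = 0
    block_len = -1

    obs = 0
    prev_action = -1
    h = np.zeros(n_pfc)
    n_trials = 0
    cur_choice = -1
    cur_second = -1
    cur_common = -1
    cur_choice_step = -1
    cur_ss_entry = -1
    t = 0
    while t < max_steps and n_trials < max_trials:
        # PFC input
        x = np.zeros(in_dim)
        if gated == 1:
            if obs == 3 or obs == 4:
                x[obs] = 1.0
        else:
            if obs < n_obs:
                x[obs] = 1.0
            if prev_action >= 0:
                x[n_obs + prev_action] = 1.0
        # GRU step
        pre = x @ Wx + b
        pre_h = h @ Wh
        z = 1.0 / (1.0 + np.exp(-(pre[:n_pfc] + pre_h[:n_pfc])))
        r_g = 1.0 / (1.0 + np.exp(-(pre[n_pfc:2 * n_pfc]
                                    + pre_h[n_pfc:2 * n_pfc])))
        hh = np.tanh(pre[2 * n_pfc:] + (r_g * h) @ Whh)
        h = (1.0 - z) * h + z * hh
        # BG
        bg_in = np.zeros(n_obs + n_pfc)
        if obs < n_obs:
            bg_in[obs] = 1.0
        bg_in[n_obs:] = h
        u = bg_in @ W1 + b1
        a_act = np.maximum(u, 0.0)
        v = float(a_act @ wv + bv[0])
        logits = a_act @ Wp + bp
        logits = logits - logits.max()
        p = np.exp(logits)
        p = p / p.sum()
        # sample action
        u_rand = np.random.random()
        cum = 0.0
        action = 4
        for k in range(5):
            cum += p[k]
            if u_rand < cum:
                action = k
                break

        obs_code[t] = obs
        xs[t] = x
        hs[t] = h
        actions[t] = action
        values[t] = v
        policies[t] = p

        reward = 0
        if obs == 0:
            if action == 0 or action == 1:
                cur_choice = action
                cur_choice_step = t
                common_ss = 0 if action == 0 else 1  # type A
                if np.random.random() < p_common:
                    cur_second = common_ss
                    cur_common = 1
                else:
                    cur_second = 1 - common_ss
                    cur_common = 0
                obs = 1 if cur_second == 0 else 2
                cur_ss_entry = t + 1
        elif obs == 1 or obs == 2:
            needed = 2 if obs == 1 else 3
            if action == needed:
                ss = obs - 1  # 0 up, 1 down
                if hidden == 2:
                    p_rew = 0.5
                else:
                    good = hidden  # 0 up_good -> up good
                    p_rew = p_high if ss == good else 1.0 - p_high
                reward = 1 if np.random.random() < p_rew else 0
                # record the trial at outcome
                tr_choice[n_trials] = cur_choice
                tr_second[n_trials] = cur_second
                tr_outcome[n_trials] = reward
                tr_common[n_trials] = cur_common
                tr_hidden[n_trials] = hidden
                tr_choice_step[n_trials] = cur_choice_step
                tr_ss_entry_step[n_trials] = cur_ss_entry
                tr_outcome_step[n_trials] = t + 1
                n_trials += 1
                if reward == 1:
                    obs = 3 if ss == 0 else 4
                else:
                    obs = 5
                # block bookkeeping (all trials free-choice)
                trials_in_block += 1
                if hidden == 2:
                    if trials_in_block >= block_len:
                        hidden = 0 if np.random.random() < 0.5 else 1
                        ema = 0.5
                        trials_in_block = 0
                        countdown = -1
                else:
                    good = hidden
                    correct_choice = 0 if good == 0 else 1  # type A
                    d = np.exp(-1.0 / ema_tau)
                    ema = d * ema + (1.0 - d) * (
                        1.0 if cur_choice == correct_choice else 0.0)
                    if countdown < 0 and ema > threshold:
                        countdown = post_lo + int(
                            np.random.random() * (post_hi - post_lo + 1))
                    if countdown >= 0:
                        countdown -= 1
                        if countdown < 0:
                            if allow_neutral == 1:
                                pick = np.random.random()
                                if pick < 0.5:
                                    hidden = 1 - hidden
                                else:
                                    hidden = 2
                                    block_len = neut_lo + int(
                                        np.random.random()
                                        * (neut_hi - neut_lo + 1))
                            else:
                                hidden = 1 - hidden
                            ema = 0.5
                            trials_in_block = 0
                            countdown = -1
        else:
            if action == 4:
                obs = 0

        rewards[t] = reward
        prev_action = action
        t += 1

    T = t
    return (obs_code[:T], xs[:T], hs[:T], actions[:T], rewards[:T],
            values[:T], policies[:T],
            tr_choice[:n_trials], tr_second[:n_trials], tr_outcome[:n_trials],
            tr_common[:n_trials], tr_hidden[:n_trials],
            tr_choice_step[:n_trials], tr_ss_entry_step[:n_trials],
            tr_outcome_step[:n_trials])


try:  # pragma: no cover
    from numba import njit

    _rollout = njit(cache=False)(_rollout_py)
except Exception:  # pragma: no cover
    _rollout = _rollout_py


def rollout_episode(weights: dict, config: TrainConfig, seed: int
                    ) -> EpisodeLog:
    """Run one episode under the current weights."""
    out = _rollout(
        seed, weights["Wx"], weights["Wh"], weights["b"], weights["W1"],
        weights["b1"], weights["wv"], weights["bv"], weights["Wp"],
        weights["bp"], 1 if config.gated else 0, config.max_trials,
        config.max_steps, config.p_common, config.p_high, config.ema_tau,
        config.threshold, config.post_threshold_range[0],
        config.post_threshold_range[1], config.neutral_block_range[0],
        config.neutral_block_range[1], 1 if config.allow_neutral else 0)
    (obs_code, xs, hs, actions, rewards, values, policies, tr_choice,
     tr_second, tr_outcome, tr_common, tr_hidden, tr_choice_step,
     tr_ss_entry, tr_outcome_step) = out
    trials = pd.DataFrame({
        "choice": tr_choice, "second_step": tr_second,
        "outcome": tr_outcome, "common": tr_common, "hidden": tr_hidden,
        "choice_step": tr_choice_step, "ss_entry_step": tr_ss_entry,
        "outcome_step": tr_outcome_step,
    })
    return EpisodeLog(obs_code=obs_code, x_pfc=xs, h=hs, actions=actions,
                      rewards=rewards, values=values, policies=policies,
                      trials=trials)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, keys, lr):
        self.lr = lr
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            weights[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _episode_targets(log: EpisodeLog, config: TrainConfig) -> np.ndarray:
    """Next-observation targets (gated in the gated variant); T-1 rows."""
    codes = log.obs_code
    T = len(codes)
    targets = np.zeros((T - 1, N_OBS))
    for t in range(T - 1):
        nxt = codes[t + 1]
        if nxt < N_OBS:
            if config.gated and nxt not in (OBS_REW_UP, OBS_REW_DOWN):
                continue
            targets[t, nxt] = 1.0
    return targets


def pfc_episode_update(weights: dict, log: EpisodeLog, config: TrainConfig,
                       opt: Optional[_Adam] = None) -> dict[str, np.ndarray]:
    """BPTT gradient step on the next-input prediction MSE; returns grads."""
    if len(log.obs_code) < 2:
        return {}
    targets = _episode_targets(log, config)
    loss, grads, _ = pfc_loss_and_grads(weights, log.x_pfc[:-1], targets)
    if not math.isfinite(loss):
        raise FloatingPointError("non-finite PFC loss")
    if opt is not None:
        opt.step(weights, grads)
    return grads


def a2c_episode_update(weights: dict, log: EpisodeLog, config: TrainConfig,
                       opt: Optional[_Adam] = None) -> dict[str, np.ndarray]:
    """Advantage actor-critic gradient step from one episode; returns grads."""
    T = len(log.rewards)
    if T == 0:
        return {}
    returns = discounted_returns(log.rewards, config.gamma)
    obs_onehot = np.zeros((T, N_OBS))
    valid = log.obs_code < N_OBS
    obs_onehot[np.arange(T)[valid], log.obs_code[valid]] = 1.0
    X = np.hstack([obs_onehot, log.h])
    loss, grads = bg_loss_and_grads(weights, X, log.actions, returns,
                                    config.entropy_weight)
    if not math.isfinite(loss):
        raise FloatingPointError("non-finite BG loss")
    if opt is not None:
        opt.step(weights, grads)
    return grads


def train_run(config: TrainConfig, run_seed: Optional[int] = None,
              n_log: int = 10) -> RunResult:
    """Train one network for ``config.episodes`` episodes."""
    seed = config.seed if run_seed is None else run_seed
    rng = np.random.default_rng(seed)
    weights = init_weights(config, rng)
    pfc_opt = _Adam(["Wx", "Wh", "b", "Wo", "bo"], config.pfc_lr)
    bg_opt = _Adam(["W1", "b1", "wv", "bv", "Wp", "bp"], config.bg_lr)

    reward_per_trial = np.zeros(config.episodes + n_log)
    trials_per_episode = np.zeros(config.episodes + n_log, dtype=int)
    logs: list[EpisodeLog] = []
    for ep in range(config.episodes + n_log):
        ep_seed = (seed * 1000003 + ep * 7919 + 1) % (2 ** 31 - 1)
        log = rollout_episode(weights, config, ep_seed)
        n_tr = len(log.trials)
        trials_per_episode[ep] = n_tr
        reward_per_trial[ep] = (log.trials["outcome"].mean()
                                if n_tr else 0.0)
        if ep >= config.episodes:
            # evaluation episodes: weights held constant for the analyses
            logs.append(log)
            continue
        pfc_episode_update(weights, log, config, pfc_opt)
        a2c_episode_update(weights, log, config, bg_opt)

    included = bool(reward_per_trial[-n_log:].mean() > 0.55)
    return RunResult(weights=weights, reward_per_trial=reward_per_trial,
                     trials_per_episode=trials_per_episode, logs=logs,
                     included=included, seed=seed, config=config)


def run_battery(config: TrainConfig, n_runs: Optional[int] = None
                ) -> list[RunResult]:
    """Train ``n_runs`` networks with seeds config.seed .. config.seed+n-1."""
    n = n_runs or config.n_runs
    return [train_run(config, run_seed=config.seed + i) for i in range(n)]


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def pfc_pc1(run: RunResult) -> list[dict]:
    """PC1 projection of choice-state PFC activity, per logged episode.

    Returns one dict per episode with the projection, the block hidden-state
    sign (+1 up_good, -1 down_good, 0 neutral) and |corr| between the two.
    """
    from sklearn.decomposition import PCA

    out = []
    for log in run.logs:
        tr = log.trials
        if len(tr) < 3:
            continue
        acts = log.h[tr["choice_step"].to_numpy()]
        pca = PCA(n_components=1)
        proj = pca.fit_transform(acts)[:, 0]
        sign = np.where(tr["hidden"] == 0, 1.0,
                        np.where(tr["hidden"] == 1, -1.0, 0.0))
        ok = sign != 0
        if ok.sum() > 2 and proj[ok].std() > 0:
            corr = float(np.corrcoef(proj[ok], sign[ok])[0, 1])
        else:
            corr = np.nan
        out.append({"projection": proj, "block_sign": sign,
                    "abs_corr": abs(corr),
                    "explained_var": float(pca.explained_variance_ratio_[0])})
    return out


def _second_step_values(weights: dict, config: TrainConfig, log: EpisodeLog
                        ) -> np.ndarray:
    """V(up) and V(down) at each trial's second-step entry, n_trials x 2.

    The reached state's value is read from the BG at the entry step; the
    counterfactual state's value re-runs the PFC step from the same prior
    hidden state with the substituted observation (and the same preceding
    action), then reads the BG.
    """
    tr = log.trials
    n = len(tr)
    out = np.full((n, 2), np.nan)
    for i in range(n):
        t = tr["ss_entry_step"].iloc[i]
        if t >= len(log.obs_code):
            continue
        reached = int(tr["second_step"].iloc[i])       # 0 up, 1 down
        other = 1 - reached
        obs_r = encode_obs_code(OBS_UP if reached == 0 else OBS_DOWN)
        v_r, _, _ = bg_forward(weights, obs_r, log.h[t])
        # counterfactual PFC step from the same prior hidden state
        h_prev = log.h[t - 1] if t > 0 else np.zeros(N_PFC)
        obs_o_code = OBS_UP if other == 0 else OBS_DOWN
        x = np.zeros(config.pfc_input_dim)
        if config.gated:
            pass  # unrewarded-step input is the zero vector either way
        else:
            x[obs_o_code] = 1.0
            prev_action = log.actions[t - 1] if t > 0 else -1
            if prev_action >= 0:
                x[N_OBS + prev_action] = 1.0
        h_cf, _ = pfc_step(weights, h_prev, x)
        obs_o = encode_obs_code(obs_o_code)
        v_o, _, _ = bg_forward(weights, obs_o, h_cf)
        out[i, reached] = v_r
        out[i, other] = v_o
    return out


def counterfactual_value_analysis(runs: list[RunResult],
                                  included_only: bool = True) -> dict:
    """Effect of the trial outcome on same- and different-state values.

    For each trial the change in a second-step state's value from this
    trial's evaluation to the next trial's is computed; the per-run effect is
    the mean change after reward minus the mean change after omission, for
    the state where the outcome occurred (same) and the other state
    (different).  Cross-run one-sample t-tests summarize.
    """
    same_effects, diff_effects = [], []
    for run in runs:
        if included_only and not run.included:
            continue
        d_same_r, d_same_o, d_diff_r, d_diff_o = [], [], [], []
        for log in run.logs:
            tr = log.trials
            if len(tr) < 2:
                continue
            V = _second_step_values(run.weights, run.config, log)
            for i in range(len(tr) - 1):
                s = int(tr["second_step"].iloc[i])
                r = int(tr["outcome"].iloc[i])
                d_same = V[i + 1, s] - V[i, s]
                d_diff = V[i + 1, 1 - s] - V[i, 1 - s]
                if np.isnan(d_same) or np.isnan(d_diff):
                    continue
                (d_same_r if r else d_same_o).append(d_same)
                (d_diff_r if r else d_diff_o).append(d_diff)
        if d_same_r and d_same_o:
            same_effects.append(np.mean(d_same_r) - np.mean(d_same_o))
            diff_effects.append(np.mean(d_diff_r) - np.mean(d_diff_o))
    same = np.array(same_effects)
    diff = np.array(diff_effects)
    t_same, p_same = stats.ttest_1samp(same, 0.0)
    t_diff, p_diff = stats.ttest_1samp(diff, 0.0)
    return {"same_effects": same, "diff_effects": diff,
            "t_same": float(t_same), "p_same": float(p_same),
            "t_diff": float(t_diff), "p_diff": float(p_diff),
            "n_runs": len(same)}


def _single_step_bg_grads(weights: dict, obs: np.ndarray, h: np.ndarray,
                          action: int, delta: float
                          ) -> dict[str, np.ndarray]:
    """A2C weight update that a prediction error ``delta`` would induce
    at a single step: actor ascends delta * log pi(action), critic moves V
    by delta; both heads share the hidden layer."""
    x = np.concatenate([obs, h])
    u = x @ weights["W1"] + weights["b1"]
    a = np.maximum(u, 0.0)
    logits = a @ weights["Wp"] + weights["bp"]
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    one = np.zeros(N_ACT)
    one[action] = 1.0
    dlogits = delta * (p - one)       # gradient of -delta log pi(a)
    dV = -2.0 * delta                 # gradient of (V + delta - V')^2 at V'=V
    dA = dV * weights["wv"] + dlogits @ weights["Wp"].T
    dU = dA * (u > 0)
    return {"W1": np.outer(x, dU), "b1": dU, "wv": dV * a,
            "bv": np.array([dV]), "Wp": np.outer(a, dlogits), "bp": dlogits}


def simulated_optostim(run: RunResult, time: str = "choice",
                       frac: float = 0.25, delta: float = 1.0,
                       rng: Optional[np.random.Generator] = None) -> dict:
    """Simulated dopamine-stimulation analysis for one trained run.

    On a random ``frac`` of trials the BG weight update induced by a positive
    prediction error ``delta`` is applied counterfactually at the designated
    step (after the choice action or after the second-step action), the next
    trial's stay probability is evaluated under the perturbed weights, and
    the weights revert.  A linear regression models stay probability on the
    transition, outcome and stimulation codes (each +/-0.5).
    """
    if time not in ("choice", "outcome"):
        raise ValueError("time must be 'choice' or 'outcome'")
    if rng is None:
        rng = np.random.default_rng(run.seed + 997)
    import statsmodels.api as sm

    rows = []
    lr = run.config.bg_lr
    for log in run.logs:
        tr = log.trials
        for i in range(len(tr) - 1):
            stim = rng.random() < frac
            t_next = tr["choice_step"].iloc[i + 1]
            obs_choice = encode_obs_code(OBS_CHOICE)
            h_next = log.h[t_next]
            cur_choice = int(tr["choice"].iloc[i])
            _, pol_base, _ = bg_forward(run.weights, obs_choice, h_next)
            p_base = pol_base[cur_choice] / max(pol_base[0] + pol_base[1],
                                                1e-12)
            if stim:
                if time == "choice":
                    t_s = tr["choice_step"].iloc[i]
                else:
                    # after the second-step action: the step of the ss poke
                    t_s = tr["outcome_step"].iloc[i] - 1
                obs_s = encode_obs_code(int(log.obs_code[t_s]))
                grads = _single_step_bg_grads(
                    run.weights, obs_s, log.h[t_s], int(log.actions[t_s]),
                    delta)
                perturbed = {k: (run.weights[k] - lr * g if k in grads
                                 else run.weights[k])
                             for k, g in grads.items()}
                w = dict(run.weights)
                w.update(perturbed)
                _, pol, _ = bg_forward(w, obs_choice, h_next)
                p_stay = pol[cur_choice] / max(pol[0] + pol[1], 1e-12)
            else:
                p_stay = p_base
            rows.append({
                "stay": p_stay,
                "stim_delta": (p_stay - p_base) if stim else np.nan,
                "transition": 0.5 if tr["common"].iloc[i] == 1 else -0.5,
                "outcome": 0.5 if tr["outcome"].iloc[i] == 1 else -0.5,
                "stim": 0.5 if stim else -0.5,
            })
    df = pd.DataFrame(rows)
    X = sm.add_constant(df[["transition", "outcome", "stim"]])
    res = sm.OLS(df["stay"], X).fit()
    return {"coefficients": res.params.drop("const"),
            "bse": res.bse.drop("const"),
            "mean_stim_delta": float(df["stim_delta"].mean()),
            "n_trials": len(df), "stim_time": time}


def optostim_battery(runs: list[RunResult], time: str = "choice",
                     frac: float = 0.25, delta: float = 1.0,
                     seed: int = 0) -> dict:
    """Stimulation regression per included run plus cross-run t-tests."""
    coefs = []
    for i, run in enumerate(runs):
        if not run.included:
            continue
        rng = np.random.default_rng(seed + 31 * i + 1)
        out = simulated_optostim(run, time=time, frac=frac, delta=delta,
                                 rng=rng)
        coefs.append(out["coefficients"])
    table = pd.DataFrame(coefs).reset_index(drop=True)
    tt = {c: stats.ttest_1samp(table[c], 0.0) for c in table.columns}
    summary = pd.DataFrame({
        "mean": table.mean(), "sem": table.sem(),
        "t": {c: float(v.statistic) for c, v in tt.items()},
        "p": {c: float(v.pvalue) for c, v in tt.items()},
    })
    return {"per_run": table, "summary": summary, "stim_time": time,
            "n_runs": len(table)}


def run_stay_table(run: RunResult) -> pd.DataFrame:
    """Stay probability by previous transition x outcome over logged episodes."""
    rows = []
    for log in run.logs:
        tr = log.trials
        for i in range(len(tr) - 1):
            rows.append({
                "stay": float(tr["choice"].iloc[i + 1]
                              == tr["choice"].iloc[i]),
                "transition": "common" if tr["common"].iloc[i] else "rare",
                "outcome": int(tr["outcome"].iloc[i]),
            })
    df = pd.DataFrame(rows)
    return df.groupby(["transition", "outcome"])["stay"].mean().unstack()
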