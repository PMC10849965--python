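"""Compiled likelihood recursions for agent fitting.

The object API in :mod:`twostep.agents` is the reference implementation; the
kernel here runs the same recursions over packed arrays so that maximum-
likelihood fitting with many restarts stays fast.  A test asserts the two
routes agree to machine precision on random sessions.

Parameter vector layout (fixed, inactive entries ignored):

====  ==============  ====================================================
idx   name            meaning
====  ==============  ====================================================
0     w_mf            model-free strategy weight
1     alpha_mf_pos    MF learning rate, rewarded trials
2     alpha_mf_neg    MF learning rate, unrewarded trials
3     lam             eligibility trace
4     forget_mf       MF forgetting rate (toward 0.5)
5     w_mb            model-based strategy weight
6     alpha_mb_pos    MB learning rate, rewarded trials
7     alpha_mb_neg    MB learning rate, unrewarded trials
8     forget_mb       MB forgetting rate
9     forget_target   MB forgetting target (0.5 or 0.0)
10    w_inf           inference strategy weight
11    p_reversal      per-trial reversal probability
12    bias            additive value for the left action
13    persev          perseveration strength
14    persev_alpha    multi-trial perseveration EMA rate
====  ==============  ====================================================

Flags: [use_mf, use_mb, use_inf, asymmetric, persev_mode(0/1/2)].
"""

from __future__ import annotations

import numpy as np

N_PARAMS = 15
(W_MF, A_MF_POS, A_MF_NEG, LAM, FORGET_MF, W_MB, A_MB_POS, A_MB_NEG,
 FORGET_MB, FORGET_TARGET, W_INF, P_REVERSAL, BIAS, PERSEV,
 PERSEV_ALPHA) = range(N_PARAMS)

F_USE_MF, F_USE_MB, F_USE_INF, F_ASYM, F_PERSEV_MODE = range(5)


def _loglik_core(params, flags, choices, seconds, outcomes, free, starts,
                 p_up_left, probs_out):
    """Sequential choice log-likelihood; fills probs_out with P(left) per trial.

    choices/seconds: 0 = left/up, 1 = right/down.  ``starts`` marks session
    boundaries (agent state resets).  Only free-choice trials contribute to
    the returned log-likelihood; all trials drive the latent updates.
    """
    use_mf = flags[F_USE_MF] == 1
    use_mb = flags[F_USE_MB] == 1
    use_inf = flags[F_USE_INF] == 1
    asym = flags[F_ASYM] == 1
    persev_mode = flags[F_PERSEV_MODE]

    n = choices.shape[0]
    ll = 0.0
    q_mf_l = q_mf_r = 0.5
    v_mf_u = v_mf_d = 0.5
    v_mb_u = v_mb_d = 0.5
    p_good = 0.5
    trace = 0.0
    next_start = 0

    for t in range(n):
        if next_start < starts.shape[0] and t == starts[next_start]:
            q_mf_l = q_mf_r = 0.5
            v_mf_u = v_mf_d = 0.5
            v_mb_u = v_mb_d = 0.5
            p_good = 0.5
            trace = 0.0
            next_start += 1

        qn_l = 0.0
        qn_r = 0.0
        if use_mf:
            qn_l += params[W_MF] * q_mf_l
            qn_r += params[W_MF] * q_mf_r
        if use_mb:
            qn_l += params[W_MB] * (p_up_left * v_mb_u
                                    + (1.0 - p_up_left) * v_mb_d)
            qn_r += params[W_MB] * ((1.0 - p_up_left) * v_mb_u
                                    + p_up_left * v_mb_d)
        if use_inf:
            v_u = 0.8 * p_good + 0.2 * (1.0 - p_good)
            v_d = 0.2 * p_good + 0.8 * (1.0 - p_good)
            qn_l += params[W_INF] * (p_up_left * v_u
                                     + (1.0 - p_up_left) * v_d)
            qn_r += params[W_INF] * ((1.0 - p_up_left) * v_u
                                     + p_up_left * v_d)
        qn_l += params[BIAS] + params[PERSEV] * trace
        qn_r -= params[PERSEV] * trace

        d = qn_l - qn_r
        if d > 35.0:
            d = 35.0
        elif d < -35.0:
            d = -35.0
        p_left = 1.0 / (1.0 + np.exp(-d))
        probs_out[t] = p_left
        if free[t] == 1:
            p_obs = p_left if choices[t] == 0 else 1.0 - p_left
            if p_obs < 1e-300:
                p_obs = 1e-300
            ll += np.log(p_obs)

        # --- updates -----------------------------------------------------
        c = choices[t]
        s = seconds[t]
        r = outcomes[t]
        if use_mf:
            a = params[A_MF_POS] if r == 1 else params[A_MF_NEG]
            v_s = v_mf_u if s == 0 else v_mf_d
            target = (1.0 - params[LAM]) * v_s + params[LAM] * r
            if c == 0:
                q_mf_l = (1.0 - a) * q_mf_l + a * target
            else:
                q_mf_r = (1.0 - a) * q_mf_r + a * target
            if s == 0:
                v_mf_u = (1.0 - a) * v_mf_u + a * r
            else:
                v_mf_d = (1.0 - a) * v_mf_d + a * r
            fr = params[FORGET_MF]
            if fr > 0.0:
                if c == 0:
                    q_mf_r += fr * (0.5 - q_mf_r)
                else:
                    q_mf_l += fr * (0.5 - q_mf_l)
                if s == 0:
                    v_mf_d += fr * (0.5 - v_mf_d)
                else:
                    v_mf_u += fr * (0.5 - v_mf_u)
        if use_mb:
            a = params[A_MB_POS] if r == 1 else params[A_MB_NEG]
            if s == 0:
                v_mb_u = (1.0 - a) * v_mb_u + a * r
            else:
                v_mb_d = (1.0 - a) * v_mb_d + a * r
            fr = params[FORGET_MB]
            if fr > 0.0:
                tgt = params[FORGET_TARGET]
                if s == 0:
                    v_mb_d += fr * (tgt - v_mb_d)
                else:
                    v_mb_u += fr * (tgt - v_mb_u)
        if use_inf:
            if asym:
                if r == 1:
                    lik_up = 0.4 if s == 0 else 0.1
                    lik_dn = 0.1 if s == 0 else 0.4
                    num = lik_up * p_good
                    den = num + lik_dn * (1.0 - p_good)
                    if den > 0.0:
                        p_good = num / den
                # omission: shared likelihood 0.5, belief unchanged
            else:
                p_r1_up = 0.8 if s == 0 else 0.2
                lik_up = p_r1_up if r == 1 else 1.0 - p_r1_up
                lik_dn = (1.0 - p_r1_up) if r == 1 else p_r1_up
                num = lik_up * p_good
                den = num + lik_dn * (1.0 - p_good)
                if den > 0.0:
                    p_good = num / den
            pr = params[P_REVERSAL]
            p_good = (1.0 - pr) * p_good + pr * (1.0 - p_good)
        if persev_mode == 1:
            trace = 1.0 if c == 0 else -1.0
        elif persev_mode == 2:
            pa = params[PERSEV_ALPHA]
            x = 1.0 if c == 0 else -1.0
            trace = (1.0 - pa) * trace + pa * x
    return ll


loglik_core_py = _loglik_core

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    loglik_core = njit(cache=False, fastmath=False)(_loglik_core)
except Exception:  # pragma: no cover
    loglik_core = _loglik_core
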