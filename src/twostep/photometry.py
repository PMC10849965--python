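"""Synthetic dopamine photometry: generation, preprocessing and regression.

The generator produces a two-channel session (signal + motion-control
fluorophore) at 130 Hz whose signal channel carries the statistical structure
expected of a dopamine recording in this task: RPE-like biphasic loading of
inferred values (positive at state entry, negative at outcome), a transient
reward response, a tonic reward-rate component, lateralized movement
transients at choice, double-exponential bleaching, a motion artifact shared
with the control channel and white noise.  All planted amplitudes are logged
so downstream regressions can be validated by sign/amplitude recovery.

Preprocessing follows the standard fiber-photometry chain: median filter
(5 samples), 5 Hz low-pass, motion correction by regressing the band-passed
(0.001-5 Hz) signal on the band-passed control, double-exponential
detrending, and per-session z-scoring.

Trials are aligned by linearly time-warping the two behavior-determined
intervals (initiation -> choice and second-step cue -> second-step poke) to
fixed lengths; all other segments are copied sample-exact.  Per-timepoint
Lasso regression (penalty by cross-validation, standardized predictors) then
estimates coefficient time courses, tested across subjects with
Benjamini-Hochberg correction and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .agents import Agent, AgentSpec, MODEL_REGISTRY
from .task import TaskConfig

__all__ = [
    "PhotoGenParams",
    "PhotometrySession",
    "WarpedTrialMatrix",
    "PredictorSpec",
    "agent_value_traces",
    "synth_photometry",
    "preprocess",
    "timewarp_align",
    "build_predictors",
    "per_timepoint_lasso",
    "group_stats",
    "group_photometry_pipeline",
    "DEFAULT_WARP_TARGETS",
    "lagged_cue_response_regression",
]

EVENT_NAMES = ("init_illum", "init_poke", "choice_poke", "ss_cue_on",
               "ss_poke", "outcome_cue_on")


@dataclass(frozen=True)
class PhotoGenParams:
    """Ground-truth amplitudes and nuisance parameters of the generator.

    Event-locked amplitudes are in z-ish signal units; the value/action-value
    loadings implement an RPE-like code (+V at second-step cue, -V at
    outcome; +Q at choice, -Q at second-step cue).
    """

    amp_reward: float = 1.0          # + at outcome cue on rewarded trials
    amp_ss_value: float = 0.8        # +V_inf(s) at ss cue, -V_inf(s) at outcome
    amp_chosen_value: float = 0.5    # +Q_inf(c) at choice, -Q_inf(c) at ss cue
    amp_reward_rate: float = 0.5     # tonic, scaled by the reward-rate EMA
    amp_movement: float = 0.3        # +/- at choice by movement direction
    reward_rate_tau: float = 10.0
    hemisphere: str = "left"         # recording side for the movement term
    kernel_tau: float = 0.2          # s; alpha-function transient
    noise_sd: float = 0.05
    motion_sd: float = 0.3
    bleach_amp: float = 4.0
    bleach_frac_fast: float = 0.4
    bleach_tau_fast: float = 60.0    # s
    bleach_tau_slow: float = 2000.0  # s


@dataclass
class PhotometrySession:
    """Two-channel 130 Hz traces with per-trial event timestamps."""

    sample_rate: float
    signal: np.ndarray
    control: np.ndarray
    events: pd.DataFrame            # one row per trial, columns EVENT_NAMES
    session_link: pd.DataFrame      # the SessionTable rows this aligns to
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal.shape != self.control.shape:
            raise ValueError("signal/control length mismatch")
        t_max = len(self.signal) / self.sample_rate
        ev = self.events[list(EVENT_NAMES)].to_numpy()
        if len(ev) and (np.any(np.diff(ev, axis=1) < 0) or ev.min() < 0
                        or ev.max() > t_max):
            raise ValueError("event times must be increasing and in range")


@dataclass
class WarpedTrialMatrix:
    """trial x timepoint matrix with labelled segments and a validity mask."""

    values: np.ndarray
    time_axis: np.ndarray           # seconds on the warped median-trial clock
    segment_labels: np.ndarray      # segment name per column
    anchors: dict                   # event name -> column index
    mask: np.ndarray                # valid trial flags
    sample_rate: float


@dataclass
class PredictorSpec:
    """Trial design matrix for a per-timepoint regression variant."""

    variant: str
    X: pd.DataFrame                 # one row per trial in session order
    valid: np.ndarray               # rows usable (e.g. has a previous trial)


# ---------------------------------------------------------------------------
# Agent value traces
# ---------------------------------------------------------------------------

def agent_value_traces(sessions: pd.DataFrame,
                       spec: Optional[AgentSpec] = None,
                       params: Optional[dict] = None) -> pd.DataFrame:
    """Per-trial V_inf(s_t) and Q_inf(c_t) from a (default asym-Bayes) agent.

    The agent replays the session's observed trials; values are the
    pre-outcome values of the second step actually reached and the action
    actually chosen.
    """
    if spec is None:
        spec = MODEL_REGISTRY["asym_bayes"]
        params = {"w_inf": 5.0, "p_reversal": 0.1, "bias": 0.0, "persev": 0.2}
    agent = Agent(spec, params)
    rows = []
    last_key = None
    for _, tr in sessions.iterrows():
        key = (tr["subject_id"], tr["session_id"])
        if key != last_key:
            agent.reset()
            last_key = key
        from .agents import inf_values
        v, q = inf_values(agent.belief, agent.transition)
        si = 0 if tr["second_step"] == "up" else 1
        ci = 0 if tr["choice"] == "left" else 1
        rows.append({"v_inf": v[si], "q_inf": q[ci],
                     "p_up_good": agent.belief.p_up_good})
        agent.observe(tr["choice"], tr["second_step"], int(tr["outcome"]))
    return pd.DataFrame(rows, index=sessions.index)


def reward_rate_ema(outcomes: np.ndarray, tau: float) -> np.ndarray:
    """EMA of past outcomes (decay exp(-1/tau)), excluding the current trial."""
    d = np.exp(-1.0 / tau)
    out = np.empty(len(outcomes))
    ema = 0.5
    for i, r in enumerate(outcomes):
        out[i] = ema
        ema = d * ema + (1 - d) * r
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _transient_kernel(fs: float, tau: float) -> np.ndarray:
    """Alpha-function transient, unit peak, ~5 tau long."""
    t = np.arange(0, 5 * tau, 1.0 / fs)
    k = (t / tau) * np.exp(1.0 - t / tau)
    return k


def synth_photometry(sessions: pd.DataFrame,
                     values: Optional[pd.DataFrame] = None,
                     gen_params: Optional[PhotoGenParams] = None,
                     rng: Optional[np.random.Generator] = None,
                     sample_rate: float = 130.0) -> PhotometrySession:
    """Generate one synthetic photometry session for one subject's session.

    ``sessions`` must contain a single (subject_id, session_id); ``values``
    supplies per-trial ``v_inf``/``q_inf`` (defaults to the asym-Bayes replay
    of :func:`agent_value_traces`).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    gp = gen_params or PhotoGenParams()
    if sessions[["subject_id", "session_id"]].drop_duplicates().shape[0] != 1:
        raise ValueError("synth_photometry expects a single session")
    if values is None:
        values = agent_value_traces(sessions)
    n_trials = len(sessions)
    fs = sample_rate

    # event times
    t = 1.0 + rng.uniform(1.0, 2.0)
    ev = {name: np.empty(n_trials) for name in EVENT_NAMES}
    for i in range(n_trials):
        ev["init_illum"][i] = t
        t += rng.gamma(4.0, 0.1)                    # latency to initiate
        ev["init_poke"][i] = t
        t += 0.2 + rng.gamma(2.0, 0.2)              # behavior-determined
        ev["choice_poke"][i] = t
        t += 0.2                                    # fixed delay
        ev["ss_cue_on"][i] = t
        t += 1.0 + rng.gamma(2.0, 0.15)             # cue + behavior-determined
        ev["ss_poke"][i] = t
        t += 0.2
        ev["outcome_cue_on"][i] = t
        t += 0.5 + rng.uniform(2.0, 4.0)            # outcome cue + ITI
    n_samples = int(np.ceil((t + 2.0) * fs))
    time = np.arange(n_samples) / fs

    kernel = _transient_kernel(fs, gp.kernel_tau)
    sig = np.zeros(n_samples)

    def add_transient(when: float, amplitude: float) -> None:
        i0 = int(round(when * fs))
        i1 = min(i0 + len(kernel), n_samples)
        if amplitude != 0.0 and i0 < n_samples:
            sig[i0:i1] += amplitude * kernel[:i1 - i0]

    outcomes = sessions["outcome"].to_numpy()
    choices = sessions["choice"].to_numpy()
    rr = reward_rate_ema(outcomes, gp.reward_rate_tau)
    contra = "right" if gp.hemisphere == "left" else "left"
    v = values["v_inf"].to_numpy()
    q = values["q_inf"].to_numpy()

    for i in range(n_trials):
        move = 1.0 if choices[i] == contra else -1.0
        add_transient(ev["choice_poke"][i],
                      gp.amp_chosen_value * q[i] + gp.amp_movement * move)
        add_transient(ev["ss_cue_on"][i],
                      gp.amp_ss_value * v[i] - gp.amp_chosen_value * q[i])
        add_transient(ev["outcome_cue_on"][i],
                      gp.amp_reward * outcomes[i] - gp.amp_ss_value * v[i])
        # tonic reward-rate loading across the trial
        i0 = int(round((ev["init_illum"][i] - 1.0) * fs))
        i1 = int(round((ev["outcome_cue_on"][i] + 1.0) * fs))
        sig[max(i0, 0):min(i1, n_samples)] += gp.amp_reward_rate * rr[i]

    bleach = gp.bleach_amp * (
        gp.bleach_frac_fast * np.exp(-time / gp.bleach_tau_fast)
        + (1 - gp.bleach_frac_fast) * np.exp(-time / gp.bleach_tau_slow))
    motion = np.zeros(n_samples)
    if gp.motion_sd > 0:
        # movement artifacts are transient: band-limited 0.3-3 Hz
        white = rng.normal(0.0, 1.0, n_samples)
        b, a = signal.butter(2, [0.3 / (fs / 2), 3.0 / (fs / 2)],
                             btype="band")
        motion = signal.filtfilt(b, a, white)
        motion *= gp.motion_sd / motion.std()

    signal_ch = sig + bleach + motion + rng.normal(0, gp.noise_sd, n_samples)
    control_ch = (0.5 * gp.bleach_amp
                  * np.exp(-time / (1.2 * gp.bleach_tau_slow))
                  + motion + rng.normal(0, gp.noise_sd, n_samples))

    events = pd.DataFrame(ev)
    return PhotometrySession(
        sample_rate=fs, signal=signal_ch, control=control_ch, events=events,
        session_link=sessions.reset_index(drop=True),
        meta={"gen_params": gp, "ground_truth_values": values.reset_index(drop=True)},
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _double_exp(t, a, tau1, b, tau2, c):
    return a * np.exp(-t / tau1) + b * np.exp(-t / tau2) + c


def preprocess(raw: PhotometrySession) -> PhotometrySession:
    """Median filter, low-pass, motion correction, detrend, z-score."""
    fs = raw.sample_rate
    sig = signal.medfilt(raw.signal, kernel_size=5)
    ctl = signal.medfilt(raw.control, kernel_size=5)
    b, a = signal.butter(2, 5.0 / (fs / 2), btype="low")
    sig = signal.filtfilt(b, a, sig)
    ctl = signal.filtfilt(b, a, ctl)

    # motion estimate from band-passed channels
    bb, ab = signal.butter(2, [0.001 / (fs / 2), 5.0 / (fs / 2)],
                           btype="band")
    sig_bp = signal.filtfilt(bb, ab, sig)
    ctl_bp = signal.filtfilt(bb, ab, ctl)
    slope = (np.dot(ctl_bp, sig_bp) / np.dot(ctl_bp, ctl_bp)
             if np.dot(ctl_bp, ctl_bp) > 0 else 0.0)
    sig = sig - slope * ctl_bp

    # double-exponential detrend (single-exponential fallback)
    t = np.arange(len(sig)) / fs
    span = max(t[-1], 1.0)
    try:
        p0 = (sig.max() - sig.min(), span / 20, sig.max() - sig.min(),
              span, np.median(sig))
        popt, _ = optimize.curve_fit(
            _double_exp, t, sig, p0=p0,
            bounds=([0, 1e-3, 0, 1e-3, -np.inf],
                    [np.inf, 10 * span, np.inf, 100 * span, np.inf]),
            maxfev=20000)
        trend = _double_exp(t, *popt)
    except Exception:
        coef = np.polyfit(t, np.log(np.clip(sig - sig.min() + 1e-6, 1e-6,
                                            None)), 1)
        trend = np.exp(np.polyval(coef, t)) + sig.min() - 1e-6
    sig = sig - trend
    sig = (sig - sig.mean()) / sig.std()

    return PhotometrySession(sample_rate=fs, signal=sig, control=ctl,
                             events=raw.events,
                             session_link=raw.session_link,
                             meta={**raw.meta, "preprocessed": True})


# ---------------------------------------------------------------------------
# Time warping
# ---------------------------------------------------------------------------

def timewarp_align(session: PhotometrySession,
                   target_lengths: Optional[dict] = None,
                   pre_init: float = 1.0,
                   post_outcome: float = 1.5) -> WarpedTrialMatrix:
    """Warp the two behavior-determined intervals; copy the rest sample-exact.

    Segments: ``pre_init`` (fixed window before init poke), ``init_choice``
    (warped), ``choice_cue`` (fixed 200 ms), ``cue_poke`` (warped),
    ``outcome`` (fixed window from second-step poke through the outcome cue
    to ``post_outcome`` s after it).  Default warp targets are the session
    median interval durations.
    """
    fs = session.sample_rate
    ev = session.events
    d_init_choice = (ev["choice_poke"] - ev["init_poke"]).to_numpy()
    d_cue_poke = (ev["ss_poke"] - ev["ss_cue_on"]).to_numpy()
    if target_lengths is None:
        target_lengths = {"init_choice": float(np.median(d_init_choice)),
                          "cue_poke": float(np.median(d_cue_poke))}
    n1 = max(int(round(target_lengths["init_choice"] * fs)), 2)
    n2 = max(int(round(target_lengths["cue_poke"] * fs)), 2)
    n_pre = int(round(pre_init * fs))
    n_cc = int(round((ev["ss_cue_on"] - ev["choice_poke"]).median() * fs))
    n_out = int(round(((ev["outcome_cue_on"] - ev["ss_poke"]).median()
                       + post_outcome) * fs))

    seg_sizes = [("pre_init", n_pre), ("init_choice", n1),
                 ("choice_cue", n_cc), ("cue_poke", n2), ("outcome", n_out)]
    n_cols = sum(n for _, n in seg_sizes)
    labels = np.concatenate([[name] * n for name, n in seg_sizes])
    anchors = {"init_poke": n_pre, "choice_poke": n_pre + n1,
               "ss_cue_on": n_pre + n1 + n_cc,
               "ss_poke": n_pre + n1 + n_cc + n2}

    n_trials = len(ev)
    values = np.full((n_trials, n_cols), np.nan)
    mask = np.zeros(n_trials, dtype=bool)
    sig = session.signal
    n_samp = len(sig)

    for i in range(n_trials):
        col = 0
        ok = True
        # pre-init: fixed copy ending at init_poke
        i_init = int(round(ev["init_poke"].iloc[i] * fs))
        i_choice = int(round(ev["choice_poke"].iloc[i] * fs))
        i_cue = i_choice + n_cc
        i_poke = int(round(ev["ss_poke"].iloc[i] * fs))
        if i_init - n_pre < 0 or i_poke + n_out > n_samp:
            continue
        values[i, col:col + n_pre] = sig[i_init - n_pre:i_init]
        col += n_pre
        # warped interval 1: [init_poke, choice_poke); an interval already at
        # the target length is copied sample-exact
        seg = sig[i_init:i_choice]
        if len(seg) < 2:
            continue
        src = np.linspace(0, len(seg) - 1, n1)
        values[i, col:col + n1] = np.interp(src, np.arange(len(seg)), seg)
        col += n1
        # fixed: choice -> ss cue (sample-exact copy from choice poke)
        values[i, col:col + n_cc] = sig[i_choice:i_choice + n_cc]
        col += n_cc
        # warped interval 2: [ss_cue_on, ss_poke)
        i_cue_real = int(round(ev["ss_cue_on"].iloc[i] * fs))
        seg = sig[i_cue_real:i_poke]
        if len(seg) < 2:
            continue
        src = np.linspace(0, len(seg) - 1, n2)
        values[i, col:col + n2] = np.interp(src, np.arange(len(seg)), seg)
        col += n2
        # outcome segment: sample-exact copy from ss_poke
        values[i, col:col + n_out] = sig[i_poke:i_poke + n_out]
        mask[i] = True

    time_axis = np.arange(n_cols) / fs
    return WarpedTrialMatrix(values=values, time_axis=time_axis,
                             segment_labels=labels, anchors=anchors,
                             mask=mask, sample_rate=fs)


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

def build_predictors(sessions: pd.DataFrame, variant: str = "base",
                     values: Optional[pd.DataFrame] = None,
                     reward_rate_tau: float = 10.0,
                     hemisphere: str = "left",
                     config: Optional[TaskConfig] = None) -> PredictorSpec:
    """Trial design matrix for one session, per the chosen variant.

    Variants: ``base`` (15 predictors), ``value`` (value loadings replace
    the trial-history codes) and ``outcome_split`` (same/different second
    step and inferred-update codes split by previous outcome).  All codes
    are +/-0.5 (0 where undefined) except the reward-rate EMA and the
    model-derived values.  The first trial of the session has undefined
    previous-trial codes and is flagged invalid.
    """
    if variant not in ("base", "value", "outcome_split"):
        raise ValueError(f"unknown variant {variant!r}")
    cfg = config or TaskConfig()
    df = sessions.reset_index(drop=True)
    n = len(df)
    prev = df.shift(1)
    first = prev["choice"].isna().to_numpy()

    def pm(cond):  # +/- 0.5 code
        return np.where(cond, 0.5, -0.5)

    rewarded = df["outcome"].to_numpy() == 1
    prev_rewarded = prev["outcome"].to_numpy() == 1
    neutral = (df["hidden_state"] == "neutral").to_numpy()
    prev_neutral = (prev["hidden_state"] == "neutral").to_numpy()
    good_ss = np.where(df["hidden_state"] == "up_good", "up", "down")
    prev_good_ss = np.where(prev["hidden_state"] == "up_good", "up", "down")
    same_ss = (df["second_step"] == prev["second_step"]).to_numpy()
    same_choice = (df["choice"] == prev["choice"]).to_numpy()
    common_to = df["choice"].map(cfg.common_second_step)
    # does the current choice commonly lead to the previous second step?
    common_to_prev_ss = (common_to == prev["second_step"]).to_numpy()

    X = pd.DataFrame(index=df.index)
    X["reward"] = pm(rewarded)
    X["prev_reward"] = pm(prev_rewarded)
    X["reward_rate"] = reward_rate_ema(df["outcome"].to_numpy(),
                                       reward_rate_tau)
    contra = "right" if hemisphere == "left" else "left"
    X["contralateral_choice"] = pm(df["choice"] == contra)
    X["up_second_step"] = pm(df["second_step"] == "up")
    X["common_transition"] = pm(df["transition"] == "common")
    X["forced_choice"] = pm(df["free_choice"] == 0)

    if variant in ("base", "outcome_split"):
        X["good_second_step"] = np.where(
            neutral, 0.0, pm(df["second_step"].to_numpy() == good_ss))
        X["prev_good_second_step"] = np.where(
            prev_neutral | first, 0.0,
            pm(prev["second_step"].to_numpy() == prev_good_ss))
        X["correct_choice"] = np.where(
            neutral, 0.0, pm(common_to.to_numpy() == good_ss))
        X["repeat_choice"] = pm(same_choice)
        X["direct_reinforcement"] = np.where(
            same_choice, pm(prev_rewarded), 0.0)
    if variant == "base":
        X["inferred_update"] = (np.where(common_to_prev_ss, 1.0, -1.0)
                                * pm(prev_rewarded))
        X["prev_reward_same_ss"] = np.where(same_ss, pm(prev_rewarded), 0.0)
        X["prev_reward_diff_ss"] = np.where(~same_ss, pm(prev_rewarded), 0.0)
    elif variant == "outcome_split":
        X["same_vs_diff_prev_rewarded"] = np.where(
            prev_rewarded, pm(same_ss), 0.0)
        X["same_vs_diff_prev_unrewarded"] = np.where(
            ~prev_rewarded & ~first, pm(same_ss), 0.0)
        X["inferred_update_rewarded"] = np.where(
            prev_rewarded, pm(common_to_prev_ss), 0.0)
        X["inferred_update_unrewarded"] = np.where(
            ~prev_rewarded & ~first, -pm(common_to_prev_ss), 0.0)
    elif variant == "value":
        if values is None:
            values = agent_value_traces(df)
        X["second_step_value"] = values["v_inf"].to_numpy()
        X["chosen_value"] = values["q_inf"].to_numpy()

    X[first] = np.nan  # undefined previous-trial codes
    valid = ~first
    return PredictorSpec(variant=variant, X=X, valid=valid)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def per_timepoint_lasso(matrix: WarpedTrialMatrix, design: PredictorSpec,
                        stride: int = 6, cv: int = 5,
                        alphas: Optional[Sequence[float]] = None,
                        seed: int = 0,
                        alpha_override: Optional[float] = None
                        ) -> pd.DataFrame:
    """Independent Lasso fit per (strided) timepoint.

    Predictors are standardized (mean 0, variance 1); the penalty is chosen
    per regression by k-fold cross-validation over a log-spaced grid.
    Returns a timepoint x predictor coefficient table (standardized scale),
    indexed by warped-time seconds.  ``alpha_override=0`` gives plain OLS
    (used by the OLS-oracle test).
    """
    rows = matrix.mask & design.valid.astype(bool)
    X = design.X[rows]
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        import warnings
        warnings.warn(f"dropping constant predictors: {dropped}")
    X = X[keep].to_numpy()
    mu, sd = X.mean(0), X.std(0)
    Xs = (X - mu) / sd
    if len(Xs) < 10 * Xs.shape[1]:
        import warnings
        warnings.warn("fewer than 10x trials per predictor")
    if alphas is None:
        alphas = np.logspace(-4, 1, 10)
    cols = np.arange(0, matrix.values.shape[1], stride)
    Y = matrix.values[np.asarray(rows), :][:, cols]
    betas = np.zeros((len(cols), Xs.shape[1]))
    for j in range(len(cols)):
        y = Y[:, j]
        ok = np.isfinite(y)
        if ok.sum() < Xs.shape[1] + 2:
            betas[j] = np.nan
            continue
        if alpha_override is not None:
            if alpha_override == 0:
                model = LinearRegression().fit(Xs[ok], y[ok])
            else:
                from sklearn.linear_model import Lasso
                model = Lasso(alpha=alpha_override).fit(Xs[ok], y[ok])
        else:
            model = LassoCV(alphas=alphas,
                            cv=KFold(cv, shuffle=True, random_state=seed),
                            max_iter=5000).fit(Xs[ok], y[ok])
        betas[j] = model.coef_
    out = pd.DataFrame(betas, columns=keep,
                       index=pd.Index(matrix.time_axis[cols], name="time"))
    out.attrs["segment_labels"] = matrix.segment_labels[cols]
    out.attrs["anchors"] = {k: int(np.searchsorted(cols, v))
                            for k, v in matrix.anchors.items()}
    return out


def group_stats(betas: Sequence[pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Cross-subject per-timepoint t-tests with BH correction and Cohen's d.

    ``betas`` is one coefficient table per subject (same shape).  BH runs
    over timepoints within each predictor.  Zero-variance timepoints report
    a capped d (sign * inf -> +/-1e6) with a flag column.
    """
    if len(betas) < 3:
        raise ValueError("need at least 3 subjects")
    stack = np.stack([b.to_numpy() for b in betas])   # subj x time x pred
    mean = stack.mean(0)
    sd = stack.std(0, ddof=1)
    n = stack.shape[0]
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, mean / se, np.sign(mean) * np.inf)
        d = np.where(sd > 0, mean / sd, np.sign(mean) * 1e6)
    # zero-variance, zero-mean cells (e.g. all-zero Lasso coefficients)
    degenerate = (se == 0) & (mean == 0)
    tvals = np.where(degenerate, 0.0, tvals)
    d = np.where(degenerate, 0.0, d)
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - 1)
    pvals = np.where(np.isfinite(tvals), pvals, 0.0)
    p_adj = np.empty_like(pvals)
    for k in range(pvals.shape[1]):
        p_adj[:, k] = multipletests(pvals[:, k], method="fdr_bh")[1]
    idx, cols = betas[0].index, betas[0].columns
    return {
        "mean": pd.DataFrame(mean, index=idx, columns=cols),
        "se": pd.DataFrame(se, index=idx, columns=cols),
        "t": pd.DataFrame(tvals, index=idx, columns=cols),
        "p": pd.DataFrame(pvals, index=idx, columns=cols),
        "p_adj": pd.DataFrame(p_adj, index=idx, columns=cols),
        "cohens_d": pd.DataFrame(d, index=idx, columns=cols),
        "d_capped": pd.DataFrame(sd == 0, index=idx, columns=cols),
    }


def cue_response(session: PhotometrySession,
                 window: float = 0.5) -> np.ndarray:
    """Baseline-subtracted second-step-cue response per trial.

    Mean over the last ``window`` s of the second-step cue (the 500 ms before
    the cue ends, i.e. before the port becomes responsive 1 s after cue on)
    minus the mean over the ``window`` s before the choice poke.
    """
    fs = session.sample_rate
    nw = int(round(window * fs))
    ev = session.events
    out = np.full(len(ev), np.nan)
    for i in range(len(ev)):
        i_choice = int(round(ev["choice_poke"].iloc[i] * fs))
        i_cue_end = int(round((ev["ss_cue_on"].iloc[i] + 1.0) * fs))
        if i_choice - nw < 0 or i_cue_end > len(session.signal):
            continue
        base = session.signal[i_choice - nw:i_choice].mean()
        resp = session.signal[i_cue_end - nw:i_cue_end].mean()
        out[i] = resp - base
    return out


DEFAULT_WARP_TARGETS = {"init_choice": 0.6, "cue_poke": 1.3}


def group_photometry_pipeline(sessions: pd.DataFrame, variant: str = "base",
                              gen_params: Optional[PhotoGenParams] = None,
                              seed: int = 0, stride: int = 6,
                              warp_targets: Optional[dict] = None,
                              values_by_subject: Optional[dict] = None
                              ) -> dict:
    """Synth -> preprocess -> warp -> per-timepoint Lasso -> group stats.

    One photometry session is generated per subject (all of that subject's
    trials as one recording).  A shared warp-target dict keeps the timepoint
    grid identical across subjects so coefficients can be stacked.
    """
    targets = warp_targets or dict(DEFAULT_WARP_TARGETS)
    rng = np.random.default_rng(seed)
    betas = []
    for subj, df in sessions.groupby("subject_id", sort=False):
        df = df.reset_index(drop=True)
        values = None if values_by_subject is None else values_by_subject[subj]
        ps = synth_photometry(df, values=values, gen_params=gen_params,
                              rng=rng)
        pp = preprocess(ps)
        mat = timewarp_align(pp, target_lengths=targets)
        design = build_predictors(df, variant, values=values)
        betas.append(per_timepoint_lasso(mat, design, stride=stride,
                                         seed=seed))
    return {"betas": betas, "group": group_stats(betas)}


def lagged_cue_response_regression(session: PhotometrySession,
                                   max_lag: int = 12,
                                   config: Optional[TaskConfig] = None
                                   ) -> pd.DataFrame:
    """OLS of the cue response on lagged trial-history codes (one subject).

    Lagged predictors at each lag n: previous-reward same/different second
    step, direct reinforcement and inferred update, each comparing the
    current trial with the nth previous one; plus the correction regressors
    (same-vs-different second step at lag n, and reward on trial -1).  No
    regularization.  Returns a table of coefficients with standard errors.
    """
    cfg = config or TaskConfig()
    df = session.session_link.reset_index(drop=True)
    y = cue_response(session)
    n = len(df)
    rewarded = df["outcome"].to_numpy() == 1
    ss = df["second_step"].to_numpy()
    choice = df["choice"].to_numpy()
    common_to = df["choice"].map(cfg.common_second_step).to_numpy()

    cols: dict[str, np.ndarray] = {}
    for lag in range(1, max_lag + 1):
        same = np.zeros(n)
        prev_r = np.zeros(n, dtype=bool)
        valid = np.arange(n) >= lag
        idx = np.arange(n) - lag
        same_ss = ss == np.roll(ss, lag)
        same_choice = choice == np.roll(choice, lag)
        common_prev = common_to == np.roll(ss, lag)
        prev_rew = np.roll(rewarded, lag)
        pr = np.where(prev_rew, 0.5, -0.5)
        cols[f"same_ss_rew_lag{lag}"] = np.where(valid & same_ss, pr, 0.0)
        cols[f"diff_ss_rew_lag{lag}"] = np.where(valid & ~same_ss, pr, 0.0)
        cols[f"direct_reinf_lag{lag}"] = np.where(valid & same_choice, pr, 0.0)
        cols[f"inferred_update_lag{lag}"] = np.where(
            valid, np.where(common_prev, 1.0, -1.0) * pr, 0.0)
        cols[f"same_vs_diff_ss_lag{lag}"] = np.where(
            valid, np.where(same_ss, 0.5, -0.5), 0.0)
    cols["reward_prev"] = np.where(np.roll(rewarded, 1), 0.5, -0.5)

    X = pd.DataFrame(cols)
    keep = np.isfinite(y) & (np.arange(n) >= max_lag)
    import statsmodels.api as sm
    Xc = sm.add_constant(X[keep])
    res = sm.OLS(y[keep], Xc).fit()
    return pd.DataFrame({"coef": res.params, "se": res.bse,
                         "t": res.tvalues, "p": res.pvalues}).drop("const")
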