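"""Two-step task simulator.

Trial structure: a first-step choice (left/right) leads commonly (p=0.8) to one
of two second-step states (up/down) and rarely (p=0.2) to the other; the active
second-step port delivers reward with a probability set by the current block.
In non-neutral blocks one port rewards at 0.8 and the other at 0.2; in neutral
blocks both reward at 0.5.  Blocks reverse 5-15 trials after an exponential
moving average of correct free choices crosses 0.75; neutral blocks end after a
uniform 20-30 trials.

Two views of the task are provided:

* trial level (:func:`trial_step`, :func:`update_block`,
  :func:`generate_session`) - one row per trial, used for agent fitting and
  the behavioral/photometry analyses;
* time-step level (:func:`env_step`, :class:`StepEnv`) - five observable
  states and five nose-poke actions, used by the recurrent network model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "BlockState",
    "TrialRecord",
    "trial_step",
    "update_block",
    "new_block_state",
    "generate_session",
    "OBSERVATIONS",
    "ACTIONS",
    "StepEnv",
    "env_step",
    "encode_observation",
    "SESSION_COLUMNS",
]

SESSION_COLUMNS = [
    "subject_id",
    "session_id",
    "trial",
    "free_choice",
    "choice",
    "transition",
    "second_step",
    "outcome",
    "hidden_state",
    "stim",
    "latency_ms",
]

CHOICES = ("left", "right")
SECOND_STEPS = ("up", "down")
HIDDEN_STATES = ("up_good", "down_good", "neutral")
STIM_VALUES = ("none", "choice", "outcome")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-step task.

    Defaults are the final-task values: 80/20 transitions, 0.8/0.2 reward
    probabilities in non-neutral blocks and 0.5/0.5 in neutral blocks, 75%
    free-choice trials, reversals triggered 5-15 trials after the correct-choice
    EMA (time constant 8 free-choice trials) crosses 0.75, neutral blocks
    lasting 20-30 trials.
    """

    common_prob: float = 0.8
    reward_high: float = 0.8
    reward_low: float = 0.2
    reward_neutral: float = 0.5
    free_choice_prob: float = 0.75
    correct_threshold: float = 0.75
    ema_tau_free_trials: float = 8.0
    post_threshold_range: tuple[int, int] = (5, 15)
    neutral_block_range: tuple[int, int] = (20, 30)
    transition_type: str = "A"
    stim_fraction: float = 0.0
    stim_time: str = "none"
    allow_neutral_blocks: bool = True

    def __post_init__(self) -> None:
        for name in ("common_prob", "reward_high", "reward_low",
                     "reward_neutral", "free_choice_prob", "correct_threshold",
                     "stim_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.reward_high + self.reward_low - 1.0) > 1e-12:
            raise ValueError("reward_high + reward_low must equal 1")
        for name in ("post_threshold_range", "neutral_block_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if self.transition_type not in ("A", "B"):
            raise ValueError("transition_type must be 'A' or 'B'")
        if self.stim_time not in STIM_VALUES:
            raise ValueError(f"stim_time must be one of {STIM_VALUES}")

    def common_second_step(self, choice: str) -> str:
        """Second-step state the given choice commonly leads to."""
        if choice not in CHOICES:
            raise ValueError(f"invalid choice {choice!r}")
        if self.transition_type == "A":
            return "up" if choice == "left" else "down"
        return "down" if choice == "left" else "up"

    def correct_choice(self, hidden_state: str) -> Optional[str]:
        """Choice that commonly leads to the high-reward port; None if neutral."""
        if hidden_state == "neutral":
            return None
        good = "up" if hidden_state == "up_good" else "down"
        for c in CHOICES:
            if self.common_second_step(c) == good:
                return c
        raise AssertionError("unreachable")

    def reward_prob(self, hidden_state: str, second_step: str) -> float:
        if hidden_state == "neutral":
            return self.reward_neutral
        good = "up" if hidden_state == "up_good" else "down"
        return self.reward_high if second_step == good else self.reward_low


@dataclass
class BlockState:
    """Bookkeeping for the current reward-probability block."""

    hidden_state: str = "up_good"
    correct_ema: float = 0.5
    trials_since_threshold: Optional[int] = None
    reversal_countdown: Optional[int] = None
    trials_in_block: int = 0
    block_length: Optional[int] = None  # set for neutral blocks

    def __post_init__(self) -> None:
        if self.hidden_state not in HIDDEN_STATES:
            raise ValueError(f"invalid hidden_state {self.hidden_state!r}")
        if not 0.0 <= self.correct_ema <= 1.0:
            raise ValueError("correct_ema outside [0, 1]")
        if self.trials_in_block < 0:
            raise ValueError("trials_in_block negative")


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    session_id: str
    trial_index: int
    free_choice: bool
    choice: str
    transition: str
    second_step: str
    outcome: int
    hidden_state: str
    stim: str = "none"
    latency_ms: Optional[float] = None


def trial_step(
    choice: str,
    block: BlockState,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """Sample (second_step, transition, outcome) for a first-step choice."""
    if choice not in CHOICES:
        raise ValueError(f"invalid choice {choice!r}")
    common_ss = config.common_second_step(choice)
    if rng.random() < config.common_prob:
        second_step, transition = common_ss, "common"
    else:
        second_step = "down" if common_ss == "up" else "up"
        transition = "rare"
    p_reward = config.reward_prob(block.hidden_state, second_step)
    outcome = int(rng.random() < p_reward)
    return second_step, transition, outcome


def new_block_state(
    hidden_state: str, config: TaskConfig, rng: np.random.Generator
) -> BlockState:
    """Fresh block bookkeeping for the given hidden state."""
    block_length = None
    if hidden_state == "neutral":
        lo, hi = config.neutral_block_range
        block_length = int(rng.integers(lo, hi + 1))
    return BlockState(hidden_state=hidden_state, correct_ema=0.5,
                      block_length=block_length)


def _draw_next_state(
    current: str, config: TaskConfig, rng: np.random.Generator
) -> str:
    # Never repeat the same non-neutral state; uniform over the other two.
    if not config.allow_neutral_blocks:
        return "down_good" if current == "up_good" else "up_good"
    others = [h for h in HIDDEN_STATES if h != current]
    return others[int(rng.integers(len(others)))]


def update_block(
    block: BlockState,
    last_trial: TrialRecord,
    config: TaskConfig,
    rng: np.random.Generator,
) -> BlockState:
    """Advance block bookkeeping after a trial; starts a new block when due.

    The correct-choice EMA (decay ``exp(-1/tau)``) is updated on free-choice
    trials only.  In a non-neutral block, a reversal countdown drawn uniformly
    from ``post_threshold_range`` starts once the EMA crosses the threshold;
    neutral blocks end after their pre-drawn length.
    """
    b = replace(block)
    b.trials_in_block += 1

    if b.hidden_state == "neutral":
        if b.trials_in_block >= (b.block_length or 0):
            return new_block_state(_draw_next_state(b.hidden_state, config, rng),
                                   config, rng)
        return b

    if last_trial.free_choice:
        d = math.exp(-1.0 / config.ema_tau_free_trials)
        correct = float(last_trial.choice == config.correct_choice(b.hidden_state))
        b.correct_ema = d * b.correct_ema + (1.0 - d) * correct
        if b.reversal_countdown is None and b.correct_ema > config.correct_threshold:
            lo, hi = config.post_threshold_range
            b.reversal_countdown = int(rng.integers(lo, hi + 1))
            b.trials_since_threshold = 0

    if b.reversal_countdown is not None:
        b.reversal_countdown -= 1
        b.trials_since_threshold = (b.trials_since_threshold or 0) + 1
        if b.reversal_countdown <= 0:
            return new_block_state(_draw_next_state(b.hidden_state, config, rng),
                                   config, rng)
    return b


def _schedule_stim(n_trials: int, config: TaskConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Stimulation flags honouring the lockout constraints.

    Each stimulated trial is followed by at least two non-stimulated trials
    (and the scheduler marks the next trial as forced-free).  Eligible trials
    are stimulated with probability f/(1-2f) so the realized overall fraction
    is close to the requested ``stim_fraction`` f.
    """
    stim = np.zeros(n_trials, dtype=bool)
    f = config.stim_fraction
    if f <= 0 or config.stim_time == "none":
        return stim
    if f >= 0.5:
        raise ValueError("stim_fraction must be < 1/3 for the lockout to hold")
    q = f / (1.0 - 2.0 * f)
    lockout = 0
    for i in range(n_trials - 1):  # never stimulate the final trial
        if lockout > 0:
            lockout -= 1
            continue
        if rng.random() < q:
            stim[i] = True
            lockout = 2
    return stim


def generate_session(
    agent_policy: Callable[[dict], str],
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    subject_id: str = "s0",
    session_id: str = "0",
) -> pd.DataFrame:
    """Simulate one session; returns a SessionTable DataFrame.

    ``agent_policy`` is called once per trial with a dict holding
    ``free_choice`` (bool), ``forced_action`` ("left"/"right"/None), the
    ``trial_index`` and ``prev`` (dict with the previous trial's ``choice``,
    ``second_step`` and ``outcome``, or None on the first trial, letting
    learning agents update from the last outcome before choosing); it must
    return "left" or "right" (the forced action on forced-choice trials).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rows: list[dict] = []
    if n_trials == 0:
        return pd.DataFrame(rows, columns=SESSION_COLUMNS)

    first = "up_good" if rng.random() < 0.5 else "down_good"
    block = new_block_state(first, config, rng)
    stim_flags = _schedule_stim(n_trials, config, rng)

    prev_stim = False
    prev: Optional[dict] = None
    for t in range(n_trials):
        if prev_stim:
            free = True  # the trial after stimulation is always free-choice
        else:
            free = rng.random() < config.free_choice_prob
        forced = None if free else CHOICES[int(rng.integers(2))]
        choice = agent_policy({
            "free_choice": free,
            "forced_action": forced,
            "trial_index": t,
            "prev": prev,
        })
        if choice not in CHOICES:
            raise ValueError(f"agent_policy returned invalid action {choice!r}")
        if not free and choice != forced:
            raise ValueError("agent_policy ignored the forced action")
        second_step, transition, outcome = trial_step(choice, block, config, rng)
        stim = config.stim_time if stim_flags[t] else "none"
        rec = TrialRecord(
            subject_id=subject_id, session_id=session_id, trial_index=t,
            free_choice=free, choice=choice, transition=transition,
            second_step=second_step, outcome=outcome,
            hidden_state=block.hidden_state, stim=stim,
        )
        rows.append({
            "subject_id": subject_id, "session_id": session_id, "trial": t,
            "free_choice": int(free), "choice": choice,
            "transition": transition, "second_step": second_step,
            "outcome": outcome, "hidden_state": block.hidden_state,
            "stim": stim, "latency_ms": np.nan,
        })
        block = update_block(block, rec, config, rng)
        prev_stim = stim_flags[t]
        prev = {"choice": choice, "second_step": second_step,
                "outcome": outcome}
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# Time-step level environment (network model)
# ---------------------------------------------------------------------------

OBSERVATIONS = ("choice_state", "up_active", "down_active",
                "reward_at_up", "reward_at_down")
#: symbolic outcome observation for unrewarded trials; encoded as the zero
#: vector so exactly five one-hot codes exist.
NO_REWARD = "no_reward"
ACTIONS = ("poke_left", "poke_right", "poke_up", "poke_down", "poke_center")

_OBS_INDEX = {o: i for i, o in enumerate(OBSERVATIONS)}
_ACT_INDEX = {a: i for i, a in enumerate(ACTIONS)}


def encode_observation(obs: str) -> np.ndarray:
    """One-hot encode an observation; ``no_reward`` maps to the zero vector."""
    v = np.zeros(len(OBSERVATIONS))
    if obs == NO_REWARD:
        return v
    v[_OBS_INDEX[obs]] = 1.0
    return v


def env_step(
    observation: str,
    action: str,
    block: BlockState,
    config: TaskConfig,
    rng: np.random.Generator,
    forced: Optional[str] = None,
) -> tuple[str, int, bool]:
    """One time step of the five-state environment.

    Returns ``(next_observation, reward, trial_boundary)``.  Inactive actions
    leave the observation unchanged with reward 0.  ``forced`` restricts the
    permitted choice on forced-choice trials.
    """
    if observation not in OBSERVATIONS and observation != NO_REWARD:
        raise ValueError(f"invalid observation {observation!r}")
    if action not in ACTIONS:
        raise ValueError(f"invalid action {action!r}")

    if observation == "choice_state":
        if action in ("poke_left", "poke_right"):
            choice = "left" if action == "poke_left" else "right"
            if forced is not None and choice != forced:
                return observation, 0, False  # unlit port: inactive
            second_step, _, _ = trial_step(choice, block, config, rng)
            return f"{second_step}_active", 0, False
        return observation, 0, False
    if observation == "up_active":
        if action == "poke_up":
            r = int(rng.random() < config.reward_prob(block.hidden_state, "up"))
            return ("reward_at_up" if r else NO_REWARD), r, False
        return observation, 0, False
    if observation == "down_active":
        if action == "poke_down":
            r = int(rng.random() < config.reward_prob(block.hidden_state, "down"))
            return ("reward_at_down" if r else NO_REWARD), r, False
        return observation, 0, False
    # outcome observation (reward_at_* or no_reward): poke_center starts a trial
    if action == "poke_center":
        return "choice_state", 0, True
    return observation, 0, False


class StepEnv:
    """Stateful wrapper over :func:`env_step` with block bookkeeping.

    Tracks the trial-level record implied by the step sequence so that block
    reversals follow the same EMA/threshold logic as the trial-level simulator.
    """

    def __init__(self, config: TaskConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        first = "up_good" if rng.random() < 0.5 else "down_good"
        self.block = new_block_state(first, config, rng)
        self.observation = "choice_state"
        self._begin_trial()
        self.trial_count = 0

    def _begin_trial(self) -> None:
        self.free = self.rng.random() < self.config.free_choice_prob
        self.forced = None if self.free else CHOICES[int(self.rng.integers(2))]
        self._choice: Optional[str] = None
        self._second_step: Optional[str] = None
        self._transition: Optional[str] = None

    def step(self, action: str) -> tuple[str, int, bool]:
        obs = self.observation
        forced = self.forced if obs == "choice_state" else None
        nxt, reward, boundary = env_step(obs, action, self.block, self.config,
                                         self.rng, forced=forced)
        # Record trial events as they happen.
        if obs == "choice_state" and nxt.endswith("_active"):
            self._choice = "left" if action == "poke_left" else "right"
            self._second_step = "up" if nxt == "up_active" else "down"
            common = self.config.common_second_step(self._choice)
            self._transition = "common" if common == self._second_step else "rare"
        if obs.endswith("_active") and nxt in ("reward_at_up", "reward_at_down",
                                               NO_REWARD):
            self._outcome = reward
        if boundary:
            rec = TrialRecord(
                subject_id="net", session_id="0", trial_index=self.trial_count,
                free_choice=self.free, choice=self._choice,
                transition=self._transition, second_step=self._second_step,
                outcome=self._outcome, hidden_state=self.block.hidden_state,
            )
            self.last_trial = rec
            self.block = update_block(self.block, rec, self.config, self.rng)
            self.trial_count += 1
            self._begin_trial()
        self.observation = nxt
        return nxt, reward, boundary
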