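"""Behavioral strategies for the two-step task.

Three families of strategy are implemented, each usable alone or in a
weighted mixture:

* model-free RL: direct action values ``Q_MF(c)`` updated from outcomes with
  an eligibility trace;
* model-based RL: second-step values ``V(s)`` combined with the known
  transition matrix, ``Q_MB(a) = sum_s P(s|a) V(s)``;
* Bayesian hidden-state inference: a belief ``P(up_good)`` over which port is
  currently good, updated by Bayes rule from each trial's (second step,
  outcome) observation and mixed toward 0.5 by a per-trial reversal
  probability.

Each family has an *asymmetric* variant in which rewards and omissions have
unequal influence: outcome-dependent learning rates for the RL strategies, and
for the inference strategy a generative model that treats rewarded outcomes at
the two ports as distinct observations but omissions as one shared observation
(joint table 0.4 / 0.1 rewarded, 0.5 unrewarded), which makes omissions
uninformative about the hidden state.

Net action values combine the active strategies with optional bias and
(single- or multi-trial) perseveration, and a unit-temperature softmax maps
them to choice probabilities; strategy weights absorb the inverse temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MFState",
    "MBState",
    "BayesBelief",
    "AgentSpec",
    "Agent",
    "MODEL_REGISTRY",
    "make_spec",
    "mf_update",
    "mb_update",
    "mb_values",
    "bayes_outcome_update",
    "bayes_reversal_update",
    "inf_values",
    "combine_and_choose",
    "transition_matrix",
    "STANDARD_TABLE",
    "ASYMMETRIC_JOINT_TABLE",
]

#: P(r=1 | second step s, hidden state h); rows s in (up, down),
#: cols h in (up_good, down_good).
STANDARD_TABLE = np.array([[0.8, 0.2],
                           [0.2, 0.8]])

#: P(r, s | h) for the asymmetric generative model; omission probability 0.5
#: is shared between ports, so p(r=0, s | h) is 0.5 regardless of s and h
#: (the table sums to 0.4 + 0.1 + 0.5 = 1 per hidden state).
ASYMMETRIC_JOINT_TABLE = {
    "rewarded_up": np.array([0.4, 0.1]),    # [up_good, down_good]
    "rewarded_down": np.array([0.1, 0.4]),
    "unrewarded": np.array([0.5, 0.5]),
}

_SS_INDEX = {"up": 0, "down": 1}
_CHOICE_INDEX = {"left": 0, "right": 1}


def transition_matrix(transition_type: str = "A",
                      common_prob: float = 0.8) -> np.ndarray:
    """P(s|a) with rows (left, right) and columns (up, down)."""
    if transition_type == "A":
        return np.array([[common_prob, 1 - common_prob],
                         [1 - common_prob, common_prob]])
    if transition_type == "B":
        return np.array([[1 - common_prob, common_prob],
                         [common_prob, 1 - common_prob]])
    raise ValueError("transition_type must be 'A' or 'B'")


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Model-free strategy
# ---------------------------------------------------------------------------

@dataclass
class MFState:
    """Action values Q_MF (left, right) and second-step values V (up, down)."""
    q: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    v: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))

    def copy(self) -> "MFState":
        return MFState(self.q.copy(), self.v.copy())


def mf_update(state: MFState, c: str, s: str, r: int,
              alpha_pos: float, alpha_neg: Optional[float] = None,
              lam: float = 1.0, forget_rate: float = 0.0) -> MFState:
    """Model-free update.

    Q_MF(c) <- (1-a) Q_MF(c) + a ((1-lam) V(s) + lam r);
    V(s)    <- (1-a) V(s) + a r,
    with a = alpha_pos on rewarded and alpha_neg on unrewarded trials (the
    symmetric model passes alpha_neg=None).  Forgetting then decays the
    non-chosen action and non-visited state toward the neutral value 0.5.
    """
    if alpha_neg is None:
        alpha_neg = alpha_pos
    for name, val in (("alpha_pos", alpha_pos), ("alpha_neg", alpha_neg),
                      ("lam", lam), ("forget_rate", forget_rate)):
        _check_unit(name, val)
    a = alpha_pos if r == 1 else alpha_neg
    ci, si = _CHOICE_INDEX[c], _SS_INDEX[s]
    out = state.copy()
    out.q[ci] = (1 - a) * out.q[ci] + a * ((1 - lam) * out.v[si] + lam * r)
    out.v[si] = (1 - a) * out.v[si] + a * r
    if forget_rate > 0:
        out.q[1 - ci] += forget_rate * (0.5 - out.q[1 - ci])
        out.v[1 - si] += forget_rate * (0.5 - out.v[1 - si])
    return out


# ---------------------------------------------------------------------------
# Model-based strategy
# ---------------------------------------------------------------------------

@dataclass
class MBState:
    """Second-step values V (up, down) and the known transition matrix."""
    v: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    transition: np.ndarray = field(default_factory=transition_matrix)

    def copy(self) -> "MBState":
        return MBState(self.v.copy(), self.transition)


def mb_update(state: MBState, s: str, r: int,
              alpha_pos: float, alpha_neg: Optional[float] = None,
              forget_rate: float = 0.0, forget_target: float = 0.5) -> MBState:
    """V(s) <- (1-a) V(s) + a r; non-visited state decays to forget_target."""
    if alpha_neg is None:
        alpha_neg = alpha_pos
    _check_unit("alpha_pos", alpha_pos)
    _check_unit("alpha_neg", alpha_neg)
    _check_unit("forget_rate", forget_rate)
    a = alpha_pos if r == 1 else alpha_neg
    si = _SS_INDEX[s]
    out = state.copy()
    out.v[si] = (1 - a) * out.v[si] + a * r
    if forget_rate > 0:
        out.v[1 - si] += forget_rate * (forget_target - out.v[1 - si])
    return out


def mb_values(state: MBState) -> np.ndarray:
    """Q_MB(a) = sum_s P(s|a) V(s); returns (left, right)."""
    return state.transition @ state.v


# ---------------------------------------------------------------------------
# Bayesian inference strategy
# ---------------------------------------------------------------------------

@dataclass
class BayesBelief:
    """Belief P(up_good) over the hidden state, with model variant."""
    p_up_good: float = 0.5
    model: str = "standard"  # or "asymmetric"

    def __post_init__(self) -> None:
        _check_unit("p_up_good", self.p_up_good)
        if self.model not in ("standard", "asymmetric"):
            raise ValueError(f"unknown belief model {self.model!r}")


def bayes_outcome_update(belief: BayesBelief, s: str, r: int) -> BayesBelief:
    """Posterior over the hidden state after observing (second step, outcome).

    The standard model uses the conditional table P(r|s,h) with entries
    0.8/0.2.  The asymmetric model uses the joint table P(r,s|h) with
    rewarded-at-up 0.4, rewarded-at-down 0.1 and a shared omission mass 0.5,
    so omissions leave the belief unchanged.
    """
    if r not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    si = _SS_INDEX[s]
    p = belief.p_up_good
    if belief.model == "standard":
        p_r1 = STANDARD_TABLE[si]          # P(r=1|s,h) for both h
        lik = p_r1 if r == 1 else 1.0 - p_r1
    else:
        if r == 0:
            lik = ASYMMETRIC_JOINT_TABLE["unrewarded"]
        else:
            key = "rewarded_up" if s == "up" else "rewarded_down"
            lik = ASYMMETRIC_JOINT_TABLE[key]
    num = lik[0] * p
    den = num + lik[1] * (1.0 - p)
    if den == 0.0:  # absorbing degenerate prior
        return replace(belief)
    return replace(belief, p_up_good=num / den)


def bayes_reversal_update(belief: BayesBelief, p_reversal: float) -> BayesBelief:
    """p <- (1 - P(rev)) p + P(rev) (1 - p)."""
    _check_unit("p_reversal", p_reversal)
    p = belief.p_up_good
    return replace(belief,
                   p_up_good=(1 - p_reversal) * p + p_reversal * (1 - p))


def inf_values(belief: BayesBelief,
               transition: Optional[np.ndarray] = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """(V_inf per second-step state, Q_inf per action) from the belief.

    V_inf(s) = P(r=1|s,up_good) p + P(r=1|s,down_good) (1-p), using the
    standard conditional table for both belief variants;
    Q_inf(a) = sum_s P(s|a) V_inf(s).
    """
    if transition is None:
        transition = transition_matrix()
    p = belief.p_up_good
    v = STANDARD_TABLE @ np.array([p, 1.0 - p])
    return v, transition @ v


# ---------------------------------------------------------------------------
# Combination, choice and the per-trial wrapper
# ---------------------------------------------------------------------------

def combine_and_choose(q_values: dict[str, np.ndarray],
                       weights: dict[str, float],
                       bias: float = 0.0,
                       perseveration: float = 0.0,
                       persev_trace: float = 0.0,
                       forced_action: Optional[str] = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Net action values and softmax choice probabilities.

    Q_net(a) = sum_i w_i Q_i(a) + K(a) with K adding ``bias`` to the left
    action and ``perseveration * trace`` to left / minus to right (trace in
    [-1, 1], +1 = previous choices all left).  On forced trials the returned
    probabilities concentrate on the permitted action (the likelihood skips
    these trials).
    """
    q_net = np.zeros(2)
    for name, q in q_values.items():
        w = weights[name]
        if not math.isfinite(w):
            raise ValueError(f"non-finite weight for {name}")
        q_net += w * np.asarray(q, dtype=float)
    q_net[0] += bias + perseveration * persev_trace
    q_net[1] -= perseveration * persev_trace
    if not np.all(np.isfinite(q_net)):
        raise ValueError("non-finite net action values")
    d = q_net[0] - q_net[1]
    p_left = 1.0 / (1.0 + math.exp(-d))
    probs = np.array([p_left, 1.0 - p_left])
    if forced_action is not None:
        probs = np.array([1.0, 0.0]) if forced_action == "left" else np.array([0.0, 1.0])
    return q_net, probs


@dataclass(frozen=True)
class AgentSpec:
    """Which strategies and option flags make up an agent.

    ``strategies`` is a subset of {"mf", "mb", "inf"}.  ``asymmetric``
    switches on outcome-dependent learning rates (RL strategies, paired with
    forgetting) and the joint-table observation model (inference strategy).
    ``forget_target`` applies to the model-based strategy (0.5 or 0.0).
    ``perseveration`` is "none", "single" or "multi".
    """

    strategies: tuple[str, ...]
    asymmetric: bool = False
    forget: bool = False
    forget_target: float = 0.5
    bias: bool = True
    perseveration: str = "single"
    transition_type: str = "A"

    def __post_init__(self) -> None:
        for s in self.strategies:
            if s not in ("mf", "mb", "inf"):
                raise ValueError(f"unknown strategy {s!r}")
        if len(set(self.strategies)) != len(self.strategies):
            raise ValueError("duplicate strategies")
        if self.perseveration not in ("none", "single", "multi"):
            raise ValueError("perseveration must be none/single/multi")
        if self.forget_target not in (0.5, 0.0):
            raise ValueError("forget_target must be 0.5 or 0.0")

    @property
    def param_names(self) -> list[str]:
        names: list[str] = []
        if "mf" in self.strategies:
            names.append("w_mf")
            if self.asymmetric:
                names += ["alpha_mf_pos", "alpha_mf_neg"]
            else:
                names.append("alpha_mf")
            names.append("lam")
            if self.forget:
                names.append("forget_mf")
        if "mb" in self.strategies:
            names.append("w_mb")
            if self.asymmetric:
                names += ["alpha_mb_pos", "alpha_mb_neg"]
            else:
                names.append("alpha_mb")
            if self.forget:
                names.append("forget_mb")
        if "inf" in self.strategies:
            names += ["w_inf", "p_reversal"]
        if self.bias:
            names.append("bias")
        if self.perseveration != "none":
            names.append("persev")
        if self.perseveration == "multi":
            names.append("persev_alpha")
        return names

    @property
    def param_kinds(self) -> dict[str, str]:
        """Map name -> 'unit' | 'pos' | 'unc' (init/prior family selector)."""
        kinds = {}
        for n in self.param_names:
            if n.startswith(("alpha", "lam", "forget")) or n in (
                    "p_reversal", "persev_alpha"):
                kinds[n] = "unit"
            elif n.startswith("w_"):
                kinds[n] = "pos"
            else:
                kinds[n] = "unc"
        return kinds

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def make_spec(strategies, asymmetric=False, forget=None, forget_target=0.5,
              bias=True, perseveration="single",
              transition_type="A") -> AgentSpec:
    """Factory with the convention that asymmetric RL implies forgetting."""
    strategies = tuple(strategies)
    if forget is None:
        forget = asymmetric and any(s in strategies for s in ("mf", "mb"))
    return AgentSpec(strategies=strategies, asymmetric=asymmetric,
                     forget=forget, forget_target=forget_target, bias=bias,
                     perseveration=perseveration,
                     transition_type=transition_type)


#: Commonly used members of the model zoo; the full factorial is generated
#: through :func:`make_spec`.
MODEL_REGISTRY: dict[str, AgentSpec] = {
    "mf": make_spec(("mf",)),
    "asym_mf": make_spec(("mf",), asymmetric=True),
    "mb": make_spec(("mb",)),
    "asym_mb": make_spec(("mb",), asymmetric=True),
    "asym_mb_forget0": make_spec(("mb",), asymmetric=True, forget_target=0.0),
    "bayes": make_spec(("inf",)),
    "asym_bayes": make_spec(("inf",), asymmetric=True),
    "mf_mb": make_spec(("mf", "mb")),
    "asym_mf_mb": make_spec(("mf", "mb"), asymmetric=True),
    "mixture": make_spec(("mf", "mb", "inf"), asymmetric=True,
                         perseveration="multi"),
}


class Agent:
    """Stateful per-trial wrapper sequencing the strategy updates.

    Per trial: compute Q_net and choice probabilities from the pre-trial
    state -> observe (choice, second step, outcome) -> outcome updates ->
    forgetting -> reversal mixing (inference strategy) -> perseveration trace
    update.  Forced-choice trials update all latent state but contribute no
    choice likelihood.
    """

    def __init__(self, spec: AgentSpec, params: dict[str, float]):
        missing = set(spec.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        self.spec = spec
        self.params = dict(params)
        self.transition = transition_matrix(spec.transition_type)
        self.reset()

    def reset(self) -> None:
        self.mf = MFState()
        self.mb = MBState(transition=self.transition)
        model = "asymmetric" if self.spec.asymmetric else "standard"
        self.belief = BayesBelief(model=model)
        self.persev_trace = 0.0

    # -- choice ------------------------------------------------------------
    def action_values(self) -> dict[str, np.ndarray]:
        q: dict[str, np.ndarray] = {}
        if "mf" in self.spec.strategies:
            q["mf"] = self.mf.q
        if "mb" in self.spec.strategies:
            q["mb"] = mb_values(self.mb)
        if "inf" in self.spec.strategies:
            q["inf"] = inf_values(self.belief, self.transition)[1]
        return q

    def choice_probs(self, forced_action: Optional[str] = None) -> np.ndarray:
        p = self.params
        weights = {s: p[f"w_{s}"] for s in self.spec.strategies}
        _, probs = combine_and_choose(
            self.action_values(), weights,
            bias=p.get("bias", 0.0),
            perseveration=p.get("persev", 0.0),
            persev_trace=self.persev_trace,
            forced_action=forced_action,
        )
        return probs

    # -- learning ----------------------------------------------------------
    def observe(self, choice: str, second_step: str, outcome: int) -> None:
        p = self.params
        if "mf" in self.spec.strategies:
            a_pos = p.get("alpha_mf_pos", p.get("alpha_mf"))
            a_neg = p.get("alpha_mf_neg", p.get("alpha_mf"))
            self.mf = mf_update(self.mf, choice, second_step, outcome,
                                a_pos, a_neg, lam=p["lam"],
                                forget_rate=p.get("forget_mf", 0.0))
        if "mb" in self.spec.strategies:
            a_pos = p.get("alpha_mb_pos", p.get("alpha_mb"))
            a_neg = p.get("alpha_mb_neg", p.get("alpha_mb"))
            self.mb = mb_update(self.mb, second_step, outcome, a_pos, a_neg,
                                forget_rate=p.get("forget_mb", 0.0),
                                forget_target=self.spec.forget_target)
        if "inf" in self.spec.strategies:
            self.belief = bayes_outcome_update(self.belief, second_step, outcome)
            self.belief = bayes_reversal_update(self.belief, p["p_reversal"])
        # perseveration trace (updated on all trials, incl. forced)
        if self.spec.perseveration != "none":
            x = 1.0 if choice == "left" else -1.0
            if self.spec.perseveration == "single":
                self.persev_trace = x
            else:
                pa = p["persev_alpha"]
                self.persev_trace = (1 - pa) * self.persev_trace + pa * x

    def trial(self, choice: str, second_step: str, outcome: int,
              forced_action: Optional[str] = None) -> np.ndarray:
        """Probabilities before the choice, then apply all updates."""
        probs = self.choice_probs(forced_action)
        self.observe(choice, second_step, outcome)
        return probs

    def policy(self, rng: np.random.Generator):
        """Adapter for :func:`twostep.task.generate_session`.

        The returned callable first applies the learning updates for the
        previous trial (supplied in ``info["prev"]``), then samples a choice
        from the softmax, or returns the forced action on forced trials.
        """
        agent = self

        def act(info: dict) -> str:
            prev = info.get("prev")
            if prev is not None:
                agent.observe(prev["choice"], prev["second_step"],
                              prev["outcome"])
            if not info["free_choice"]:
                return info["forced_action"]
            probs = agent.choice_probs()
            return "left" if rng.random() < probs[0] else "right"

        return act
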