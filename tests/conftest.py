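"""Shared fixtures: simulated sessions from registry agents."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twostep.agents import MODEL_REGISTRY, Agent
from twostep.task import TaskConfig, generate_session

ASYM_BAYES_PARAMS = {"w_inf": 5.0, "p_reversal": 0.1, "bias": 0.1,
                     "persev": 0.3}


def simulate_subjects(n_subjects: int, n_trials: int, seed: int = 0,
                      model: str = "asym_bayes", params: dict | None = None,
                      config: TaskConfig | None = None,
                      n_sessions: int = 1) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    cfg = config or TaskConfig()
    params = params or ASYM_BAYES_PARAMS
    frames = []
    for s in range(n_subjects):
        for k in range(n_sessions):
            agent = Agent(MODEL_REGISTRY[model], params)
            frames.append(generate_session(
                agent.policy(rng), cfg, n_trials, rng,
                subject_id=f"m{s}", session_id=str(k)))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def bayes_sessions() -> pd.DataFrame:
    """One asym-Bayes subject, 2 sessions x 500 trials."""
    return simulate_subjects(1, 500, seed=11, n_sessions=2)


@pytest.fixture(scope="session")
def group_sessions() -> pd.DataFrame:
    """Six asym-Bayes subjects, 400 trials each."""
    return simulate_subjects(6, 400, seed=23)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
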