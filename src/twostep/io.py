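"""Session-table serialization, validation and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .task import (CHOICES, HIDDEN_STATES, SECOND_STEPS, SESSION_COLUMNS,
                   STIM_VALUES, TaskConfig)

__all__ = ["read_session_csv", "write_session_csv", "validate_sessions",
           "write_manifest"]

_ENUMS = {
    "choice": set(CHOICES),
    "transition": {"common", "rare"},
    "second_step": set(SECOND_STEPS),
    "hidden_state": set(HIDDEN_STATES),
    "stim": set(STIM_VALUES),
}


def validate_sessions(df: pd.DataFrame,
                      transition_type: Optional[str] = None) -> None:
    """Raise ValueError (with row numbers) on schema or invariant violations.

    When ``transition_type`` is given, also checks that every transition
    label is consistent with (choice, second_step).
    """
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if extra:
        raise ValueError(f"unknown columns: {extra}")
    for col, allowed in _ENUMS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid {col} value {df[col].iloc[row]!r} at row {row}")
    for col in ("outcome", "free_choice"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{col} must be 0/1; bad value at row {row}")
    if transition_type is not None:
        cfg = TaskConfig(transition_type=transition_type)
        common = df["choice"].map(cfg.common_second_step)
        expected = np.where(common == df["second_step"], "common", "rare")
        bad = df["transition"].to_numpy() != expected
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"transition label inconsistent with (choice, second_step) "
                f"at row {row}")


def write_session_csv(df: pd.DataFrame, path) -> None:
    validate_sessions(df)
    df.to_csv(path, index=False, columns=SESSION_COLUMNS)


def read_session_csv(path, transition_type: Optional[str] = None
                     ) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    if len(df) == 0:
        df = df.reindex(columns=SESSION_COLUMNS)
        return df
    validate_sessions(df, transition_type=transition_type)
    return df


def write_manifest(out_dir, command: str, config: dict, seeds: dict,
                   inputs: Optional[list] = None,
                   outputs: Optional[list] = None) -> Path:
    """Write the per-invocation JSON manifest and return its path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
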