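"""Shared data containers for curves, risk tables and patient-level records.

Interval-level count data (the likelihood input) travels as a plain
:class:`pandas.DataFrame` with columns ``study``, ``treatment``,
``interval_start``, ``n_at_risk``, ``deaths``, ``censored`` — see
:func:`validate_interval_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KMCurve",
    "RiskTable",
    "PseudoIPD",
    "INTERVAL_COLUMNS",
    "validate_interval_data",
]

INTERVAL_COLUMNS = (
    "study",
    "treatment",
    "interval_start",
    "n_at_risk",
    "deaths",
    "censored",
)


@dataclass(frozen=True)
class KMCurve:
    """Digitized coordinates of a published survival curve for one arm.

    Right-continuous step function: ``survival[i]`` applies on
    ``[times[i], times[i+1])``.  The first point must be ``(0, 1)``.
    """

    times: np.ndarray
    survival: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and survival must be matching non-empty 1-d arrays")
        if t[0] != 0 or s[0] != 1:
            raise ValueError("curve must start at (time=0, survival=1)")
        if np.any(np.diff(t) < 0):
            raise ValueError("curve times must be nondecreasing")
        if np.any((s < 0) | (s > 1)) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must lie in [0, 1] and be nonincreasing")

    def __len__(self) -> int:
        return self.times.size

    def at(self, t) -> np.ndarray:
        """Step-function evaluation (right-continuous) at times ``t``."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self) - 1)]


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at scheduled reporting times for one arm."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.shape != n.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and n_at_risk must be matching non-empty 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise ValueError("at-risk counts must be nonnegative and nonincreasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PseudoIPD:
    """Patient-level observed times with death/censoring flags for one arm."""

    times: np.ndarray
    events: np.ndarray  # 1 = death, 0 = censored
    arm_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be matching 1-d arrays")
        if t.size and (np.any(~np.isfinite(t)) or np.any(t <= 0)):
            raise ValueError("observed times must be finite and positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event flags must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})


def validate_interval_data(df: pd.DataFrame) -> pd.DataFrame:
    """Check interval-count bookkeeping and return the frame sorted per arm.

    Per row: ``deaths + censored <= n_at_risk``.  Across consecutive
    intervals of one arm the at-risk count must drop by exactly the
    deaths plus censored of the previous interval.
    """
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval data missing columns: {missing}")
    df = df.sort_values(["study", "treatment", "interval_start"]).reset_index(drop=True)
    if (df["deaths"] + df["censored"] > df["n_at_risk"]).any():
        raise ValueError("deaths + censored exceed n_at_risk in some interval")
    if (df[["n_at_risk", "deaths", "censored"]] < 0).to_numpy().any():
        raise ValueError("negative counts in interval data")
    for (study, treatment), grp in df.groupby(["study", "treatment"], sort=False):
        n = grp["n_at_risk"].to_numpy()
        drop = (grp["deaths"] + grp["censored"]).to_numpy()
        if not np.array_equal(n[1:], n[:-1] - drop[:-1]):
            raise ValueError(
                f"at-risk bookkeeping violated for {study}/{treatment}: "
                "n_at_risk[j+1] != n_at_risk[j] - deaths[j] - censored[j]"
            )
    return df
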