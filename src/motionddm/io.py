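"""Light-weight containers and on-disk formats.

Trial tables are plain CSV. Continuous EEG is stored as a binary array
(.npy, channels x samples, microvolts) next to a JSON sidecar holding the
sampling rate and the event list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "block",
    "trial",
    "difficulty",
    "direction",
    "response",
    "rt_s",
    "timeout",
    "catch",
    "stim_time_s",
    "resp_time_s",
]


@dataclass
class EEGRecording:
    """Continuous EEG: data (channels x samples, microvolts), sampling rate,
    and an event list of dicts {time_s, type: 'stimulus'|'response', difficulty}."""

    data: np.ndarray
    sfreq: float
    events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def save(self, path: str | Path) -> None:
        """Write `<path>.npy` (array) and `<path>.json` (sidecar)."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {"sampling_rate_hz": self.sfreq, "events": self.events}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "EEGRecording":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(data=data, sfreq=sidecar["sampling_rate_hz"], events=sidecar["events"])


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
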