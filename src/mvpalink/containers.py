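"""Core data containers shared across the pipeline.

The common currency of the empirical stages is the :class:`EpochSet`: a
``(trial, channel, time)`` tensor of epoched multichannel recordings plus a
trial-metadata table that stays row-aligned with the tensor through every
operation. Reaction times live in :class:`RTTable` (participant x scene),
and the category classifier's per-scene signed outputs in
:class:`SceneDecisionValues`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Columns every trial-metadata table must carry.
TRIAL_COLUMNS = ("participant", "scene", "category", "task", "correct", "rt")


@dataclass
class EpochSet:
    """Epoched multichannel recordings with row-aligned trial metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Amplitudes in arbitrary units.
    times : ndarray, shape (n_times,)
        Bin-center latencies in milliseconds relative to stimulus onset at 0;
        strictly increasing and evenly spaced.
    trials : DataFrame
        One row per trial with columns ``participant, scene, category, task,
        correct, rt`` (rt in msec, NaN allowed).
    channel_names : sequence of str
    """

    data: np.ndarray
    times: np.ndarray
    trials: pd.DataFrame
    channel_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, channel, time), got "
                             f"ndim={self.data.ndim}")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must match the time axis")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be evenly spaced")
        if not isinstance(self.trials, pd.DataFrame):
            raise TypeError("trials must be a pandas DataFrame")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trials)} rows but tensor holds "
                f"{self.data.shape[0]} trials")
        rts = self.trials["rt"].to_numpy(dtype=float)
        if np.any(rts[np.isfinite(rts)] <= 0):
            raise ValueError("reaction times must be positive where present")
        if not list(self.channel_names):
            self.channel_names = [f"C{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        self.trials = self.trials.reset_index(drop=True)

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def participants(self) -> list:
        return sorted(self.trials["participant"].unique())

    @property
    def scenes(self) -> list:
        return sorted(self.trials["scene"].unique())

    def scene_categories(self) -> dict:
        """Mapping scene id -> category label (first occurrence)."""
        return (self.trials.drop_duplicates("scene")
                .set_index("scene")["category"].to_dict())

    # -- alignment-preserving selections ---------------------------------
    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return EpochSet(self.data[idx], self.times,
                        self.trials.iloc[idx].reset_index(drop=True),
                        list(self.channel_names))

    def select_channels(self, idx: Sequence[int]) -> "EpochSet":
        idx = list(idx)
        return EpochSet(self.data[:, idx, :], self.times, self.trials.copy(),
                        [self.channel_names[i] for i in idx])

    def select_times(self, idx: Sequence[int]) -> "EpochSet":
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        return EpochSet(self.data[:, :, idx], self.times[idx],
                        self.trials.copy(), list(self.channel_names))

    def iter_participants(self):
        """Yield ``(participant_id, EpochSet)`` per participant, sorted."""
        for pid in self.participants:
            yield pid, self.select_trials(
                (self.trials["participant"] == pid).to_numpy())

    def time_index(self, latency_ms: float) -> int:
        """Index of the time bin whose center is closest to ``latency_ms``."""
        return int(np.argmin(np.abs(self.times - latency_ms)))

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(),
                        self.trials.copy(), list(self.channel_names))


@dataclass
class RTTable:
    """Per participant x scene reaction times for one task.

    ``rt`` is a DataFrame indexed by participant with one column per scene
    (msec, NaN where the participant has no value for the scene).
    """

    rt: pd.DataFrame
    task: str = "categorization"

    def __post_init__(self) -> None:
        vals = self.rt.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("reaction times must be positive")

    @property
    def scenes(self) -> list:
        return list(self.rt.columns)

    @property
    def participants(self) -> list:
        return list(self.rt.index)

    @property
    def median_rt(self) -> pd.Series:
        """Scene-level median over participants (NaN-skipping)."""
        return self.rt.median(axis=0, skipna=True)

    def median_excluding(self, participant) -> pd.Series:
        """Scene-level median over all participants but one."""
        return self.rt.drop(index=participant).median(axis=0, skipna=True)


@dataclass
class DecodingTimecourse:
    """Participant x time decoding accuracy, percent correct (chance 50)."""

    accuracy: np.ndarray            # (n_participants, n_times)
    times: np.ndarray               # msec
    participants: list
    scheme: str = "identity"        # "identity" | "category"
    task: str = "categorization"

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        ok = np.isfinite(self.accuracy)
        if np.any((self.accuracy[ok] < 0) | (self.accuracy[ok] > 100)):
            raise ValueError("accuracy must lie in [0, 100]")

    @property
    def group_mean(self) -> np.ndarray:
        return np.nanmean(self.accuracy, axis=0)


@dataclass
class SceneDecisionValues:
    """Signed classifier decision values per participant x scene x time.

    The decision value is the unitless signed offset of a scene's test
    pattern from the fitted category boundary, averaged across
    cross-validation repeats; its absolute value is the "distance to the
    hyperplane".
    """

    values: np.ndarray              # (n_participants, n_scenes, n_times)
    times: np.ndarray
    participants: list
    scenes: list
    task: str = "categorization"
    n_repeats: int = 0
    #: repeat-mean of |decision value| (optional; for the mean-of-abs
    #: distance ordering)
    abs_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participants), len(self.scenes),
                                 len(self.times)):
            raise ValueError("values shape must be (participant, scene, time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("decision values must be finite")
        if self.abs_values is not None:
            self.abs_values = np.asarray(self.abs_values, dtype=float)
            if self.abs_values.shape != self.values.shape:
                raise ValueError("abs_values shape must match values")
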