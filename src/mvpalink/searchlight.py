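"""Channel-space searchlight versions of decoding and the
distance-to-hyperplane statistic.

Each channel is analyzed together with its four nearest neighbors (2-D
Euclidean distance on the provided layout coordinates), restricting the
patterns to that patch at a single latency — typically the peak of the
corresponding whole-pattern time course — and mapping the resulting metric
(accuracy % or Spearman rho) over the scalp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .containers import EpochSet, RTTable
from .decoding import decode_category, decode_identity
from .dth import dth_timecourse

METRICS = ("decode_identity", "decode_category", "dth")


@dataclass
class ChannelLayout:
    """2-D channel positions (arbitrary units) with unique names."""

    names: Sequence[str]
    coords: np.ndarray              # (n_channels, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 2):
            raise ValueError("coords must be (n_channels, 2)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        uniq = {tuple(np.round(c, 12)) for c in self.coords}
        if len(uniq) != len(self.names):
            raise ValueError("channel coordinates must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.names)


def gen_layout(n_channels: int, kind: str = "concentric") -> ChannelLayout:
    """Deterministic 2-D layout for synthetic channels.

    ``"concentric"`` distributes channels over rings of radius 1, 2, ...
    holding 8, 16, 24, ... channels; ``"ring"`` puts all channels equally
    spaced on one circle.
    """
    if n_channels < 5:
        raise ValueError("need at least 5 channels")
    names = [f"C{i:02d}" for i in range(n_channels)]
    coords = []
    if kind == "ring":
        ang = 2 * np.pi * np.arange(n_channels) / n_channels
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
    elif kind == "concentric":
        left, ring = n_channels, 1
        while left > 0:
            cap = min(8 * ring, left)
            # spread the whole remainder on the last ring to avoid a
            # nearly-empty outer ring
            if left - cap < 5 and left - cap > 0:
                cap = left
            ang = 2 * np.pi * np.arange(cap) / cap + (ring % 2) * np.pi / 8
            coords.append(np.column_stack([ring * np.cos(ang),
                                           ring * np.sin(ang)]))
            left -= cap
            ring += 1
        coords = np.concatenate(coords)[:n_channels]
    else:
        raise ValueError(f"unknown layout kind: {kind!r}")
    return ChannelLayout(names, coords)


@dataclass
class NeighborMap:
    """k nearest channels per channel (self excluded), in distance order;
    distance ties break to the lower channel index."""

    neighbors: np.ndarray           # (n_channels, k) indices
    k: int = 4
    names: Sequence[str] = field(default_factory=list)


def build_neighbor_map(layout: ChannelLayout, k: int = 4) -> NeighborMap:
    n = layout.n_channels
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_channels={n}")
    d = np.linalg.norm(layout.coords[:, None, :] - layout.coords[None, :, :],
                       axis=-1)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        order = sorted((dist, j) for j, dist in enumerate(d[i]) if j != i)
        neighbors[i] = [j for _, j in order[:k]]
    return NeighborMap(neighbors, k=k, names=list(layout.names))


@dataclass
class SearchlightMap:
    """Group-level metric per channel at one latency."""

    value: np.ndarray               # (n_channels,)
    per_participant: np.ndarray     # (n_participants, n_channels)
    latency: float                  # msec
    metric: str
    names: Sequence[str] = field(default_factory=list)


def searchlight_metric(e: EpochSet, nb: NeighborMap, latency: float,
                       metric: str, rt: Optional[RTTable] = None,
                       categories: Optional[Mapping] = None,
                       repeats: int = 10, seed: int = 0,
                       **kwargs) -> SearchlightMap:
    """Run the named analysis per channel patch at a single latency.

    For every channel the patterns are restricted to the channel plus its
    ``k`` nearest neighbors; the per-participant metric values are then
    group-averaged into a topographic map. ``metric="dth"`` requires an RT
    table.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric == "dth" and rt is None:
        raise ValueError("metric='dth' requires an RT table")
    if nb.neighbors.shape[0] != e.n_channels:
        raise ValueError("neighbor map/channel count mismatch")
    t = e.time_index(latency)
    e_t = e.select_times([t])
    n_ch = e.n_channels
    per = None
    for c in range(n_ch):
        patch = [c] + list(nb.neighbors[c])
        sub = e_t.select_channels(patch)
        if metric == "decode_identity":
            tc = decode_identity(sub, repeats=repeats, seed=seed, **kwargs)
            vals = tc.accuracy[:, 0]
        elif metric == "decode_category":
            tc, _ = decode_category(sub, repeats=repeats, seed=seed, **kwargs)
            vals = tc.accuracy[:, 0]
        else:
            _, sdv = decode_category(sub, repeats=repeats, seed=seed,
                                     **kwargs)
            d = dth_timecourse(sdv, rt, categories=categories)
            vals = d.rho[:, 0]
        if per is None:
            per = np.empty((vals.size, n_ch))
        per[:, c] = vals
    return SearchlightMap(np.nanmean(per, axis=0), per,
                          float(e.times[t]), metric,
                          names=list(e.channel_names))
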