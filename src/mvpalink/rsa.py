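"""Time-resolved representational similarity analysis with noise ceilings.

Per participant and time bin, an RDM holds the correlation distance
(1 - Pearson r, range [0, 2]) between the channel patterns of every scene
pair, computed on pseudotrials of same-scene trials and averaged over all
cross-condition pseudotrial pairings and random re-assignments. Model RDMs
come from (standardized) feature matrices of a staged network; RDMs are
compared by Spearman correlation of their strict upper triangles, and the
attainable model-data correlation is bracketed by leave-one-out /
all-participant noise ceilings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .containers import EpochSet
from .decoding import _partition_groups, equalize_trials

log = logging.getLogger(__name__)


def validate_rdm(dist: np.ndarray, atol: float = 1e-8) -> None:
    dist = np.asarray(dist)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(dist, dist.T, atol=atol):
        raise ValueError("RDM must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=atol):
        raise ValueError("RDM diagonal must be zero")
    off = dist[~np.eye(dist.shape[0], dtype=bool)]
    if np.any((off < -atol) | (off > 2 + atol)):
        raise ValueError("correlation distances must lie in [0, 2]")


@dataclass
class RDMSeries:
    """Per-participant, per-time RDMs over a fixed condition order."""

    dist: np.ndarray                # (n_participants, n_times, n_cond, n_cond)
    times: np.ndarray
    participants: list
    conditions: list

    def mean_over_participants(self) -> np.ndarray:
        return self.dist.mean(axis=0)


@dataclass
class RsaTimecourse:
    """Participant x time RDM correlations per model layer (median over the
    model's stages where it has several)."""

    rho: Dict[str, np.ndarray]      # layer -> (n_participants, n_times)
    times: np.ndarray
    participants: list
    subset: str = "all"
    aggregation: str = "median over stages"
    peak_latency: Dict[str, float] = field(default_factory=dict)


@dataclass
class NoiseCeiling:
    lower: np.ndarray               # per-time
    upper: np.ndarray
    times: np.ndarray


def _upper(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def correlate_rdms(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho of the vectorized strict upper triangles."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"RDM size mismatch: {a.shape} vs {b.shape}")
    rho = sstats.spearmanr(_upper(a), _upper(b)).statistic
    return float(rho)


def model_rdm(features: np.ndarray) -> np.ndarray:
    """Correlation-distance RDM of a scene x feature matrix.

    Features are standardized across scenes (zero mean, unit variance per
    feature); zero-variance features are dropped with a log entry.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 scenes")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features have zero variance across scenes")
    if not keep.all():
        log.info("dropping %d zero-variance feature(s)",
                 int((~keep).sum()))
    Xn = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    r = np.corrcoef(Xn)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def _pattern_corr_block(P: np.ndarray) -> np.ndarray:
    """Mean cross-pseudotrial correlation distance between all scene pairs.

    ``P`` is (scene, pseudotrial, channel); returns an (scene, scene) RDM
    averaging 1 - r over all pseudotrial cross-pairings of each pair.
    """
    S, n_pt, C = P.shape
    X = P.reshape(S * n_pt, C)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = Xc / norms
    Xn[~np.isfinite(Xn)] = 0.0      # zero-variance pattern -> r := 0
    R = Xn @ Xn.T
    D = 1.0 - R
    blocks = D.reshape(S, n_pt, S, n_pt).mean(axis=(1, 3))
    rdm = (blocks + blocks.T) / 2.0
    np.fill_diagonal(rdm, 0.0)
    return np.clip(rdm, 0.0, 2.0)


def eeg_rdm_series(e: EpochSet, group_size: int = 5, repeats: int = 100,
                   seed: int = 0) -> RDMSeries:
    """Per-participant, per-time RDMs from scene pseudotrials.

    Per repeat: trial counts are equalized across scenes, trials are
    randomly partitioned into pseudotrials of ``group_size``, and the RDM
    at each time bin averages the correlation distance over all
    cross-condition pseudotrial pairings; repeats are averaged
    arithmetically (mean of distances).
    """
    scenes = e.scenes
    if len(scenes) < 2:
        raise ValueError("need at least 2 scenes")
    participants = e.participants
    out = np.zeros((len(participants), e.n_times, len(scenes), len(scenes)))
    for pi, (pid, sub) in enumerate(e.iter_participants()):
        for r in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), 2, pi, r)))
            eq = equalize_trials(sub, rng)
            per_scene = []
            n_pt = None
            for sid in scenes:
                idx = np.flatnonzero((eq.trials["scene"] == sid).to_numpy())
                groups = _partition_groups(idx.size, group_size, rng)
                if groups.shape[0] == 0:
                    raise ValueError(
                        f"scene {sid!r} has fewer than {group_size} trials")
                per_scene.append(eq.data[idx[groups]].mean(axis=1))
                n_pt = (groups.shape[0] if n_pt is None
                        else min(n_pt, groups.shape[0]))
            P = np.stack([p[:n_pt] for p in per_scene])  # (S, n_pt, C, T)
            for t in range(e.n_times):
                out[pi, t] += _pattern_corr_block(P[:, :, :, t])
    out /= repeats
    return RDMSeries(out, e.times.copy(), participants, scenes)


def _subset_indices(conditions: Sequence, subset: str,
                    categories: Optional[Mapping]) -> np.ndarray:
    if subset == "all":
        return np.arange(len(conditions))
    if categories is None:
        raise ValueError("subset selection requires a condition->category map")
    sel = np.array([categories[c] == subset for c in conditions])
    if sel.sum() < 3:
        raise ValueError(f"subset {subset!r} keeps fewer than 3 conditions")
    return np.flatnonzero(sel)


def rsa_timecourse(series: RDMSeries,
                   model: Mapping[Tuple[str, object], np.ndarray],
                   subset: str = "all",
                   categories: Optional[Mapping] = None) -> RsaTimecourse:
    """Correlate the data RDMs with a set of model RDMs.

    ``model`` maps ``(layer, stage)`` to an RDM over the same condition
    order as ``series``. Per participant, time, layer and stage the
    sub-RDMs restricted to ``subset`` are Spearman-correlated; each layer's
    curve is the median over that layer's stages. Peak latency of the
    group-mean curve is recorded per layer.
    """
    idx = _subset_indices(series.conditions, subset, categories)
    sub_series = series.dist[:, :, idx[:, None], idx[None, :]]
    P, T = series.dist.shape[:2]
    layers = sorted({k[0] for k in model})
    rho: Dict[str, np.ndarray] = {}
    peaks: Dict[str, float] = {}
    iu = np.triu_indices(idx.size, k=1)
    for layer in layers:
        stages = sorted(k[1] for k in model if k[0] == layer)
        per_stage = np.empty((len(stages), P, T))
        for si, st in enumerate(stages):
            m = np.asarray(model[(layer, st)])
            if m.shape[0] != len(series.conditions):
                raise ValueError("model RDM condition order mismatch")
            mv = m[np.ix_(idx, idx)][iu]
            m_rank = sstats.rankdata(mv)
            for pi in range(P):
                for t in range(T):
                    dv = sub_series[pi, t][iu]
                    per_stage[si, pi, t] = _spearman_ranks(dv, m_rank)
        rho[layer] = np.median(per_stage, axis=0)
        peaks[layer] = float(series.times[int(np.argmax(
            np.nanmean(rho[layer], axis=0)))])
    return RsaTimecourse(rho, series.times.copy(), series.participants,
                         subset=subset, peak_latency=peaks)


def _spearman_ranks(x: np.ndarray, y_rank: np.ndarray) -> float:
    xr = sstats.rankdata(x)
    xc = xr - xr.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def noise_ceiling(series: RDMSeries) -> NoiseCeiling:
    """Leave-one-out lower bound and all-participant upper bound on the
    attainable RDM correlation at each time bin."""
    P, T = series.dist.shape[:2]
    if P < 2:
        raise ValueError("noise ceiling needs at least 2 participants")
    total = series.dist.sum(axis=0)
    lower = np.empty((P, T))
    upper = np.empty((P, T))
    mean_all = total / P
    for pi in range(P):
        loo = (total - series.dist[pi]) / (P - 1)
        for t in range(T):
            lower[pi, t] = correlate_rdms(series.dist[pi, t], loo[t])
            upper[pi, t] = correlate_rdms(series.dist[pi, t], mean_all[t])
    return NoiseCeiling(np.nanmean(lower, axis=0), np.nanmean(upper, axis=0),
                        series.times.copy())
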