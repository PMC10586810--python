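"""Entropy-threshold readout of staged classifier probabilities.

An anytime classifier (a recurrent network unrolled over time steps, or a
feedforward network with intermediate readouts) emits one class-probability
vector per scene and stage. Its "reaction time" for a scene is the first
stage at which the Shannon entropy of that vector falls to a confidence
threshold; if the criterion is never met the RT is S + 1. The threshold is
picked from a grid of 10 values linearly spaced over [0.01, 0.1] by
leave-one-participant-out correlation with human reaction times.

Entropy is computed in bits (log2) by default; the base is configurable and
matters because a fixed numeric threshold expresses a different confidence
level in bits than in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import RTTable

log = logging.getLogger(__name__)

SIMPLEX_ATOL = 1e-6

#: The threshold grid: 10 linearly spaced values over [0.01, 0.1].
DEFAULT_GRID = np.linspace(0.01, 0.1, 10)


@dataclass
class StageProbabilities:
    """Per-scene, per-stage class-probability simplexes."""

    p: np.ndarray                   # (n_scenes, n_stages, n_classes)
    scenes: list
    classes: Tuple[str, ...] = ("natural", "man-made")

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 3:
            raise ValueError("p must be (scene, stage, class)")
        _check_simplex(self.p)

    @property
    def n_stages(self) -> int:
        return self.p.shape[1]


def _check_simplex(p: np.ndarray) -> None:
    if np.any(p < -SIMPLEX_ATOL):
        raise ValueError("probabilities must be nonnegative")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=SIMPLEX_ATOL):
        raise ValueError("probability rows must sum to 1")


def shannon_entropy(p: np.ndarray, base: float = 2.0,
                    axis: int = -1) -> np.ndarray:
    """H = -sum p_i log p_i with 0 * log 0 := 0, in units of ``base``."""
    p = np.asarray(p, dtype=float)
    _check_simplex(np.moveaxis(p, axis, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.clip(p, 1e-300, None)), 0.0)
    return -terms.sum(axis=axis) / np.log(base)


@dataclass
class EntropyMatrix:
    """Scene x stage Shannon entropies."""

    H: np.ndarray                   # (n_scenes, n_stages)
    scenes: list
    base: float = 2.0

    @property
    def n_stages(self) -> int:
        return self.H.shape[1]


def stage_entropies(sp: StageProbabilities,
                    base: float = 2.0) -> EntropyMatrix:
    return EntropyMatrix(shannon_entropy(sp.p, base=base), list(sp.scenes),
                         base=base)


@dataclass
class NetworkRTs:
    """Integer network reaction times in 1..S+1 (S+1 = never reached)."""

    rt: np.ndarray                  # (n_scenes,), int
    scenes: list
    threshold: float
    n_stages: int


def extract_rts(H: EntropyMatrix, threshold: float) -> NetworkRTs:
    """First stage (1-based) whose entropy is <= threshold, else S + 1."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    reached = H.H <= threshold
    first = np.argmax(reached, axis=1) + 1
    never = ~reached.any(axis=1)
    rt = np.where(never, H.n_stages + 1, first)
    return NetworkRTs(rt.astype(int), list(H.scenes), float(threshold),
                      H.n_stages)


@dataclass
class CvSelection:
    """Leave-one-participant-out threshold selection and held-out fits."""

    grid: np.ndarray
    fold_participants: list
    selected: np.ndarray            # per-fold selected threshold
    heldout_r: pd.DataFrame         # fold x subset Pearson r
    mean_r: pd.Series               # per subset
    final_threshold: float
    final_rts: NetworkRTs


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(sstats.pearsonr(a, b).statistic)


def select_threshold_cv(H: EntropyMatrix, human: RTTable,
                        grid: Optional[np.ndarray] = None,
                        categories: Optional[Mapping] = None) -> CvSelection:
    """Cross-validated entropy-threshold selection against human RTs.

    Per fold, one participant is left out; for every grid threshold the
    network RTs are Pearson-correlated with the median RT over the
    remaining participants, and the best-correlating threshold is selected
    (thresholds whose network RTs are constant give undefined r and are
    excluded with a log entry). The held-out participant's own RTs are then
    correlated with the selected network RTs, for all scenes and per
    category when a scene->category map is given. The final threshold is
    the modal selection across folds (ties to the smaller value).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    participants = human.participants
    if len(participants) < 2:
        raise ValueError("need at least 2 participants")
    scenes = H.scenes
    missing = [s for s in scenes if s not in human.scenes]
    if missing:
        raise ValueError(f"human RT table lacks scenes: {missing}")

    rts_by_thr = [extract_rts(H, thr).rt.astype(float) for thr in grid]
    subsets = ["all"]
    subset_masks = {"all": np.ones(len(scenes), dtype=bool)}
    if categories is not None:
        for cat in sorted({str(categories[s]) for s in scenes}):
            subsets.append(cat)
            subset_masks[cat] = np.array(
                [categories[s] == cat for s in scenes])

    selected = np.empty(len(participants))
    heldout = np.full((len(participants), len(subsets)), np.nan)
    for fi, pid in enumerate(participants):
        median = human.median_excluding(pid).reindex(scenes).to_numpy(float)
        rs = np.array([_pearson(net, median) for net in rts_by_thr])
        if np.all(np.isnan(rs)):
            raise ValueError(
                "network RTs constant at every grid threshold; cannot select")
        if np.any(np.isnan(rs)):
            log.info("fold %s: %d threshold(s) with constant network RTs "
                     "excluded", pid, int(np.isnan(rs).sum()))
        best = int(np.nanargmax(rs))
        selected[fi] = grid[best]
        own = human.rt.loc[pid].reindex(scenes).to_numpy(float)
        for si, name in enumerate(subsets):
            m = subset_masks[name] & np.isfinite(own)
            if m.sum() >= 3:
                heldout[fi, si] = _pearson(rts_by_thr[best][m], own[m])
    heldout_df = pd.DataFrame(heldout, index=participants, columns=subsets)
    vals, counts = np.unique(selected, return_counts=True)
    final_thr = float(vals[np.argmax(counts)])
    return CvSelection(grid=grid, fold_participants=list(participants),
                       selected=selected, heldout_r=heldout_df,
                       mean_r=heldout_df.mean(axis=0),
                       final_threshold=final_thr,
                       final_rts=extract_rts(H, final_thr))


def intermediate_readout_adapter(layer_probs: np.ndarray, stride: int = 2,
                                 scenes: Optional[Sequence] = None,
                                 classes: Tuple[str, ...] = ("natural",
                                                             "man-made")
                                 ) -> StageProbabilities:
    """Map per-layer readout probabilities onto stages.

    ``layer_probs`` is (n_scenes, n_layers, n_classes); readouts after
    every ``stride``-th layer become stages 1..n_layers//stride (stride 1
    is the identity adapter). A never-reached entropy criterion downstream
    then maps to S + 1 automatically.
    """
    p = np.asarray(layer_probs, dtype=float)
    if p.ndim != 3:
        raise ValueError("layer_probs must be (scene, layer, class)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    staged = p[:, stride - 1::stride, :]
    if staged.shape[1] < 1:
        raise ValueError("stride leaves no readout layers")
    scenes = (list(scenes) if scenes is not None
              else [f"S{i:03d}" for i in range(p.shape[0])])
    return StageProbabilities(p=staged, scenes=scenes, classes=classes)
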