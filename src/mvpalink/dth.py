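"""Distance-to-hyperplane analysis: linking neural distances to behavior.

At every time bin the absolute decision value of a scene's test pattern —
its distance from the fitted natural/man-made boundary — is rank-correlated
(Spearman) with the scene-level median reaction time over participants. A
significantly negative correlation marks time points at which the neural
representations are suitably formatted for categorization decisions:
scenes far from the boundary are categorized faster.

The pairing of the data sources is explicit, so the same computation also
runs across tasks (e.g. distances from distraction-task recordings against
categorization-task reaction times).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
from scipy import stats as sstats

from .containers import RTTable, SceneDecisionValues

log = logging.getLogger(__name__)


@dataclass
class DthTimecourse:
    """Per-participant Spearman rho between scene distances and median RTs."""

    rho: np.ndarray                 # (n_participants, n_times)
    times: np.ndarray
    participants: list
    pairing: Tuple[str, str]        # (recording task, RT task)
    subset: str = "all"

    @property
    def group_mean(self) -> np.ndarray:
        """Mean over participants; NaN bins are excluded with a log entry."""
        n_nan = int(np.isnan(self.rho).sum())
        if n_nan:
            log.info("group mean excludes %d NaN participant-time cells",
                     n_nan)
        return np.nanmean(self.rho, axis=0)

    @property
    def group_sem(self) -> np.ndarray:
        n = np.sum(np.isfinite(self.rho), axis=0)
        return np.nanstd(self.rho, axis=0, ddof=1) / np.sqrt(
            np.maximum(n, 1))


def distances_from_decision_values(
        d: SceneDecisionValues, order: str = "abs_of_mean",
        signed_by_category: Optional[Mapping] = None) -> np.ndarray:
    """Distance to the hyperplane per participant x scene x time.

    The default is the absolute value of the repeat-mean decision value
    (``order="abs_of_mean"``), regardless of classification correctness.
    ``order="mean_of_abs"`` instead averages |decision value| across
    repeats (requires decision values produced by
    :func:`~mvpalink.decoding.decode_category`). When
    ``signed_by_category`` maps scenes to their true category, the
    repeat-mean decision value is instead signed positive toward each
    scene's own category side (a sensitivity-analysis variant: negative
    distances mark misclassified scenes).
    """
    if signed_by_category is not None:
        cats = sorted({signed_by_category[s] for s in d.scenes})
        if len(cats) != 2:
            raise ValueError("signed distances need exactly 2 categories")
        # positive decision value = lexicographically second category
        sign = np.array([1.0 if signed_by_category[s] == cats[1] else -1.0
                         for s in d.scenes])
        return d.values * sign[None, :, None]
    if order == "abs_of_mean":
        return np.abs(d.values)
    if order == "mean_of_abs":
        if d.abs_values is None:
            raise ValueError(
                "mean_of_abs needs repeat-resolved |decision values|")
        return d.abs_values
    raise ValueError(f"unknown distance order: {order!r}")


def _spearman_vs_fixed(dist: np.ndarray, rt_ranks: np.ndarray) -> np.ndarray:
    """Spearman rho of each (participant, time) scene vector against one
    fixed RT vector, with average ranks for ties. NaN where either side is
    constant or fewer than 3 scenes are available."""
    P, S, T = dist.shape
    if S < 3:
        raise ValueError("need at least 3 scenes for a rank correlation")
    ranks = sstats.rankdata(dist, axis=1)
    x = ranks - ranks.mean(axis=1, keepdims=True)
    y = rt_ranks - rt_ranks.mean()
    denom = (np.sqrt((x ** 2).sum(axis=1)) * np.sqrt((y ** 2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("pst,s->pt", x, y) / denom
    rho[~np.isfinite(rho)] = np.nan
    return rho


def correlate_distance_rt(dist: np.ndarray, scenes: list, rt: RTTable,
                          times: np.ndarray, participants: list,
                          subset: str = "all",
                          categories: Optional[Mapping] = None,
                          eeg_task: str = "categorization") -> DthTimecourse:
    """Spearman-correlate per-scene distances with scene-level median RTs.

    Parameters
    ----------
    dist : ndarray (n_participants, n_scenes, n_times)
        Distances from :func:`distances_from_decision_values`.
    scenes : scene ids matching ``dist``'s second axis.
    rt : RTTable whose scene inventory must cover ``scenes``.
    subset : "all" or a category label; restricting requires ``categories``.
    """
    missing = [s for s in scenes if s not in rt.scenes]
    if missing:
        raise ValueError(f"RT table lacks scenes: {missing}")
    median = rt.median_rt.reindex(scenes).to_numpy(dtype=float)
    if subset != "all":
        if categories is None:
            raise ValueError("subset selection requires a scene->category map")
        sel = np.array([categories[s] == subset for s in scenes])
        if sel.sum() < 3:
            raise ValueError(
                f"subset {subset!r} keeps {int(sel.sum())} scenes; need >= 3")
        dist = dist[:, sel, :]
        median = median[sel]
    if np.all(median == median[0]):
        log.warning("median RTs are constant; rho undefined everywhere")
    rt_ranks = sstats.rankdata(median)
    rho = _spearman_vs_fixed(dist, rt_ranks)
    return DthTimecourse(rho, np.asarray(times), list(participants),
                         pairing=(eeg_task, rt.task), subset=subset)


def dth_timecourse(d: SceneDecisionValues, rt: RTTable, subset: str = "all",
                   categories: Optional[Mapping] = None,
                   order: str = "abs_of_mean") -> DthTimecourse:
    """Convenience wrapper: distances from decision values, then the
    correlation. Handles within- and cross-task pairings alike (the RT
    table's task label is recorded in the output pairing)."""
    dist = distances_from_decision_values(d, order=order)
    return correlate_distance_rt(dist, d.scenes, rt, d.times, d.participants,
                                 subset=subset, categories=categories,
                                 eeg_task=d.task)


def cross_task_pairing(d: SceneDecisionValues, rt: RTTable,
                       subset: str = "all",
                       categories: Optional[Mapping] = None) -> DthTimecourse:
    """Distance-RT correlation with crossed sources (EEG task X, RT task Y).

    Identical computation to the within-task analysis; the scene
    inventories of the two sources must match exactly.
    """
    diff = set(d.scenes).symmetric_difference(rt.scenes)
    if diff:
        raise ValueError(f"scene inventories differ between tasks: {sorted(diff)}")
    return dth_timecourse(d, rt, subset=subset, categories=categories)
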