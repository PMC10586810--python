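"""Time-resolved multivariate decoding on pseudotrials.

Two schemes, both using a linear max-margin classifier (libsvm via
scikit-learn, ``C = 1``, no per-feature rescaling beyond upstream
whitening), run independently at every time bin:

* **Scene identity** — every pairwise combination of scenes, pseudotrials
  of ``group_size`` same-scene trials, leave-one-pseudotrial-out
  cross-validation.
* **Scene category** — binary natural vs man-made decoding where the
  training half of the trials is pooled into category pseudotrials and the
  held-out half of each scene's trials is averaged into ONE test pattern
  per scene, yielding exactly one signed decision value per scene, time
  bin and repeat. The repeat-averaged decision values feed the
  distance-to-hyperplane analysis.

Trial counts are equalized across scenes per participant and the random
trial-to-pseudotrial assignment is redrawn on every repeat; accuracies are
averaged over folds, pairs and repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import (DecodingTimecourse, EpochSet, SceneDecisionValues)

log = logging.getLogger(__name__)

#: Fixed soft-margin cost of the linear classifier.
SVM_C = 1.0


def _svm() -> SVC:
    return SVC(kernel="linear", C=SVM_C)


@dataclass
class PseudotrialSet:
    """Condition-labelled pseudotrials (trial-group means) at one or more
    time points."""

    patterns: np.ndarray        # (n_pseudotrials, n_channels[, n_times])
    labels: np.ndarray          # condition per pseudotrial
    group_size: int


def _partition_groups(n: int, group_size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Random partition of ``range(n)`` into ``n // group_size`` disjoint
    groups; remainder indices are dropped. Returns (n_groups, group_size)."""
    perm = rng.permutation(n)
    n_groups = n // group_size
    return perm[: n_groups * group_size].reshape(n_groups, group_size)


def make_pseudotrials(patterns: np.ndarray, labels: np.ndarray,
                      group_size: int,
                      rng: np.random.Generator) -> PseudotrialSet:
    """Average random disjoint groups of ``group_size`` same-condition
    trials; remainder trials are dropped.

    Raises if any condition has fewer than ``group_size`` trials.
    """
    patterns = np.asarray(patterns)
    labels = np.asarray(labels)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    out_p, out_l = [], []
    for cond in pd.unique(labels):
        idx = np.flatnonzero(labels == cond)
        if idx.size < group_size:
            raise ValueError(
                f"condition {cond!r} has {idx.size} trials, fewer than "
                f"group_size={group_size}")
        for grp in _partition_groups(idx.size, group_size, rng):
            out_p.append(patterns[idx[grp]].mean(axis=0))
            out_l.append(cond)
    return PseudotrialSet(np.stack(out_p), np.asarray(out_l), group_size)


def equalize_trials(e: EpochSet, rng: np.random.Generator) -> EpochSet:
    """Randomly downsample every scene to the participant's minimum
    per-scene trial count (applied independently per participant)."""
    keep = []
    for pid in e.participants:
        pmask = (e.trials["participant"] == pid).to_numpy()
        scenes = e.trials.loc[pmask, "scene"]
        counts = scenes.value_counts()
        m = int(counts.min())
        if m == 0:
            raise ValueError(f"participant {pid} has a scene with no trials")
        for sid in sorted(counts.index):
            idx = np.flatnonzero(pmask & (e.trials["scene"] == sid).to_numpy())
            keep.extend(rng.permutation(idx)[:m])
    return e.select_trials(np.sort(np.asarray(keep)))


def _scene_tensor(e: EpochSet, group_size: int,
                  rng: np.random.Generator) -> Tuple[np.ndarray, list]:
    """Pseudotrial tensor (scene, pseudotrial, channel, time) after
    equalization; the same trial-to-group assignment is shared by all time
    bins of a repeat."""
    scenes = e.scenes
    per_scene = []
    n_pt = None
    for sid in scenes:
        idx = np.flatnonzero((e.trials["scene"] == sid).to_numpy())
        groups = _partition_groups(idx.size, group_size, rng)
        if groups.shape[0] == 0:
            raise ValueError(
                f"scene {sid!r} has {idx.size} trials, fewer than "
                f"group_size={group_size}")
        per_scene.append(e.data[idx[groups]].mean(axis=1))
        n_pt = groups.shape[0] if n_pt is None else min(n_pt, groups.shape[0])
    return np.stack([p[:n_pt] for p in per_scene]), scenes


def decode_identity(e: EpochSet, repeats: int = 100, group_size: int = 4,
                    seed: int = 0,
                    time_indices: Optional[np.ndarray] = None
                    ) -> DecodingTimecourse:
    """Pairwise scene-identity decoding, leave-one-pseudotrial-out.

    For every pair of scenes and every time bin, a linear SVM is trained on
    all but one pseudotrial per scene and tested on the two held-out
    pseudotrials; accuracy is averaged over folds, pairs and repeats.
    """
    if len(e.scenes) < 2:
        raise ValueError("identity decoding needs at least 2 scenes")
    t_idx = (np.arange(e.n_times) if time_indices is None
             else np.atleast_1d(time_indices))
    participants = e.participants
    acc = np.zeros((len(participants), t_idx.size))
    for pi, (pid, sub) in enumerate(e.iter_participants()):
        for r in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), 0, pi, r)))
            eq = equalize_trials(sub, rng)
            P, scenes = _scene_tensor(eq, group_size, rng)
            n_s, n_pt = P.shape[:2]
            if n_pt < 2:
                raise ValueError(
                    "need at least 2 pseudotrials per scene for "
                    "leave-one-out decoding")
            hits = np.zeros(t_idx.size)
            n_tests = 0
            y = np.repeat([0, 1], n_pt - 1)
            for i in range(n_s):
                for j in range(i + 1, n_s):
                    for f in range(n_pt):
                        mask = np.arange(n_pt) != f
                        Xtr = np.concatenate([P[i, mask], P[j, mask]])
                        Xte = np.stack([P[i, f], P[j, f]])
                        for k, t in enumerate(t_idx):
                            clf = _svm().fit(Xtr[:, :, t], y)
                            pred = clf.predict(Xte[:, :, t])
                            hits[k] += (pred == [0, 1]).sum()
                        n_tests += 2
            acc[pi] += hits / n_tests
        acc[pi] *= 100.0 / repeats
    return DecodingTimecourse(acc, e.times[t_idx], participants,
                              scheme="identity",
                              task=str(e.trials["task"].iloc[0]))


def decode_category(e: EpochSet, repeats: int = 100,
                    train_group_size: int = 20, seed: int = 0,
                    time_indices: Optional[np.ndarray] = None
                    ) -> Tuple[DecodingTimecourse, SceneDecisionValues]:
    """Category decoding with scene-resolved test outputs.

    Per repeat: each scene's trials are split in half; the training halves
    are pooled within category and averaged into pseudotrials of
    ``train_group_size`` trials; the test halves stay organized by scene
    and are averaged into one pattern per scene. A linear SVM fit on the
    category pseudotrials is evaluated on every scene pattern, recording
    correctness and the signed decision value (positive sign = the
    lexicographically second category of the fitted boundary).
    """
    cats = sorted(e.trials["category"].unique())
    if len(cats) != 2:
        raise ValueError(f"category decoding needs 2 categories, got {cats}")
    t_idx = (np.arange(e.n_times) if time_indices is None
             else np.atleast_1d(time_indices))
    participants = e.participants
    scenes = e.scenes
    cat_of = e.scene_categories()
    y_true = np.array([cats.index(cat_of[s]) for s in scenes])
    acc = np.zeros((len(participants), t_idx.size))
    dvals = np.zeros((len(participants), len(scenes), t_idx.size))
    dabs = np.zeros_like(dvals)
    counts = np.zeros((len(participants), len(scenes), t_idx.size))
    for pi, (pid, sub) in enumerate(e.iter_participants()):
        for r in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), 1, pi, r)))
            eq = equalize_trials(sub, rng)
            tr_idx, te_patterns = [], []
            for s, sid in enumerate(scenes):
                idx = np.flatnonzero((eq.trials["scene"] == sid).to_numpy())
                perm = rng.permutation(idx)
                half = idx.size // 2
                tr_idx.append(perm[:half])
                te_patterns.append(eq.data[perm[half:]].mean(axis=0))
            Xte = np.stack(te_patterns)                  # (scene, chan, time)
            Xtr_parts, ytr_parts = [], []
            for ci, cat in enumerate(cats):
                pool = np.concatenate(
                    [tr_idx[s] for s in range(len(scenes))
                     if y_true[s] == ci])
                groups = _partition_groups(pool.size, train_group_size, rng)
                if groups.shape[0] == 0:
                    raise ValueError(
                        f"category {cat!r} has {pool.size} training trials, "
                        f"fewer than train_group_size={train_group_size}")
                Xtr_parts.append(eq.data[pool[groups]].mean(axis=1))
                ytr_parts.append(np.full(groups.shape[0], ci))
            Xtr = np.concatenate(Xtr_parts)
            ytr = np.concatenate(ytr_parts)
            for k, t in enumerate(t_idx):
                Xt = Xtr[:, :, t]
                if np.ptp(Xt) == 0:
                    log.warning("degenerate constant training patterns "
                                "(participant %s, t=%s)", pid, e.times[t])
                clf = _svm().fit(Xt, ytr)
                dv = clf.decision_function(Xte[:, :, t])
                pred = (dv > 0).astype(int)     # dv == 0 -> first category
                acc[pi, k] += (pred == y_true).mean()
                dvals[pi, :, k] += dv
                dabs[pi, :, k] += np.abs(dv)
                counts[pi, :, k] += 1
        acc[pi] *= 100.0 / repeats
    dvals /= np.maximum(counts, 1)
    dabs /= np.maximum(counts, 1)
    tc = DecodingTimecourse(acc, e.times[t_idx], participants,
                            scheme="category",
                            task=str(e.trials["task"].iloc[0]))
    sdv = SceneDecisionValues(dvals, e.times[t_idx], participants, scenes,
                              task=tc.task, n_repeats=repeats,
                              abs_values=dabs)
    return tc, sdv
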