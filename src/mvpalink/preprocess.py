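"""Offline preprocessing: baseline correction, bin-average downsampling,
multivariate noise normalization (whitening), and correct-trial filtering.

The whitening step controls for unequal and correlated noise levels across
channels by multiplying every time-point pattern with the inverse square
root of the channel covariance estimated from the entire epoch, pooled over
trials. The covariance is shrinkage-regularized (Ledoit-Wolf): a convex
combination of the empirical covariance with a scaled identity, with a
data-driven weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.covariance import LedoitWolf

from .containers import EpochSet

log = logging.getLogger(__name__)

#: Relative eigenvalue floor for the inverse square root.
EIG_FLOOR_REL = 1e-10


def baseline_correct(e: EpochSet, window: Tuple[float, float]) -> EpochSet:
    """Subtract, per trial and channel, the mean amplitude over ``window``.

    ``window`` is ``(start_ms, end_ms)`` inclusive of bin centers; it must
    overlap the epoch. Idempotent for a fixed window.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("baseline window must have start <= end")
    mask = (e.times >= lo) & (e.times <= hi)
    if not mask.any():
        raise ValueError(
            f"baseline window {window} contains no time bins "
            f"(epoch spans {e.times[0]}..{e.times[-1]} msec)")
    mean = e.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(e.data - mean, e.times, e.trials.copy(),
                    list(e.channel_names))


def downsample_bins(e: EpochSet, factor: int) -> EpochSet:
    """Average consecutive non-overlapping groups of ``factor`` samples.

    The trailing remainder (fewer than ``factor`` samples) is dropped; the
    new bin latency is the center (mean) of the averaged bins.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > e.n_times:
        raise ValueError(
            f"factor {factor} exceeds epoch length {e.n_times}")
    if factor == 1:
        return e.copy()
    n_out = e.n_times // factor
    n_used = n_out * factor
    data = e.data[:, :, :n_used].reshape(
        e.n_trials, e.n_channels, n_out, factor).mean(axis=3)
    times = e.times[:n_used].reshape(n_out, factor).mean(axis=1)
    return EpochSet(data, times, e.trials.copy(), list(e.channel_names))


@dataclass
class Whitener:
    """Symmetric inverse square root of the pooled channel covariance."""

    matrix: np.ndarray                  # (n_channels, n_channels)
    source_window: Tuple[float, float]  # time range of the estimate, msec
    shrinkage: float = np.nan           # weight on the scaled identity

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("whitening matrix must be symmetric")


def _inv_sqrt(cov: np.ndarray, allow_floor: bool) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    floor = EIG_FLOOR_REL * w.max()
    if np.any(w < floor) and not allow_floor:
        raise np.linalg.LinAlgError(
            "channel covariance is rank deficient; enable shrinkage "
            "regularization (shrinkage=None for Ledoit-Wolf)")
    w = np.maximum(w, floor)
    return (v / np.sqrt(w)) @ v.T


def fit_whitener(e: EpochSet, shrinkage: Optional[float] = None) -> Whitener:
    """Estimate the whitening operator from the entire epoch.

    Channel patterns from all trials and all time points are pooled into
    one sample; the covariance is estimated with Ledoit-Wolf shrinkage when
    ``shrinkage`` is None (the default), with a fixed convex weight in
    (0, 1] when given, or unregularized when 0.
    """
    X = np.moveaxis(e.data, 1, 2).reshape(-1, e.n_channels)
    if X.shape[0] <= e.n_channels:
        raise ValueError(
            f"need more pooled samples ({X.shape[0]}) than channels "
            f"({e.n_channels}) to estimate the covariance")
    if shrinkage is None:
        lw = LedoitWolf().fit(X)
        cov, a = lw.covariance_, float(lw.shrinkage_)
    else:
        a = float(shrinkage)
        if not 0.0 <= a <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        emp = np.cov(X.T, ddof=0)
        cov = (1 - a) * emp + a * (np.trace(emp) / e.n_channels) * np.eye(
            e.n_channels)
    matrix = _inv_sqrt(cov, allow_floor=a > 0)
    return Whitener(matrix=matrix,
                    source_window=(float(e.times[0]), float(e.times[-1])),
                    shrinkage=a)


def apply_whitener(e: EpochSet, w: Whitener) -> EpochSet:
    """Multiply every time-point channel pattern by the whitening matrix."""
    if w.matrix.shape != (e.n_channels, e.n_channels):
        raise ValueError("whitener/channel count mismatch")
    data = np.einsum("ij,njt->nit", w.matrix, e.data)
    return EpochSet(data, e.times, e.trials.copy(), list(e.channel_names))


def whiten_epochs(e: EpochSet,
                  shrinkage: Optional[float] = None) -> EpochSet:
    """Fit one whitener per participant (pooled over that participant's
    entire epoch and all conditions) and apply it."""
    out = e.copy()
    for pid in e.participants:
        mask = (e.trials["participant"] == pid).to_numpy()
        sub = e.select_trials(mask)
        w = fit_whitener(sub, shrinkage=shrinkage)
        out.data[mask] = np.einsum("ij,njt->nit", w.matrix, e.data[mask])
    return out


def filter_correct(e: EpochSet) -> EpochSet:
    """Retain only trials flagged correct; warn about scenes left empty."""
    correct = e.trials["correct"].astype(bool).to_numpy()
    kept = e.select_trials(correct)
    lost = sorted(set(e.trials["scene"]) - set(kept.trials["scene"]))
    if lost:
        warnings.warn(
            f"{len(lost)} scene(s) left with zero correct trials: {lost}",
            stacklevel=2)
    return kept
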