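"""Nonparametric group inference over time courses.

* Sign-permutation test: the observed statistic at each time bin is the
  group mean divided by the group standard deviation; the null flips each
  participant's whole time course by +/-1 (one flip pattern per
  permutation, shared across time, preserving temporal dependence).
* Benjamini-Hochberg step-up FDR across time bins.
* Percentile bootstrap (participants resampled with replacement) for peak
  latencies and paired peak-latency differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

log = logging.getLogger(__name__)

TAILS = ("left", "right", "two")


@dataclass
class SigTimecourse:
    """Per-time raw and FDR-adjusted p-values with the significance mask."""

    p_raw: np.ndarray
    p_adj: np.ndarray
    mask: np.ndarray
    tail: str
    alpha: float
    times: Optional[np.ndarray] = None


@dataclass
class PeakCI:
    """Peak latency of a group time course with a bootstrap 95% CI."""

    peak_latency: float             # msec, full-sample estimate
    ci: Tuple[float, float]         # percentile interval, msec
    n_boot: int


def _group_stat(x: np.ndarray) -> np.ndarray:
    """mean / sd across participants (sd with ddof=1); 0 where sd == 0."""
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / sd
    t[~np.isfinite(t)] = 0.0
    return t


def sign_permutation_test(x: np.ndarray, n_perm: int = 10000,
                          tail: str = "right",
                          rng: Optional[np.random.Generator] = None,
                          exhaustive: bool = False) -> np.ndarray:
    """Raw per-time p-values from participant-wise sign flips.

    ``x`` is (n_participants, n_times). P-values use the add-one
    convention p = (1 + #{null >= observed}) / (1 + n_perm), so p is never
    zero; the two-tailed p doubles the smaller one-sided p (capped at 1).

    With ``exhaustive=True`` all 2**n sign patterns are enumerated instead
    of sampled (n <= 20) and p is the exact rank of the observed statistic
    in the full null, p = #{null >= observed} / 2**n (the identity pattern
    keeps p positive).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, T = x.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    rng = np.random.default_rng() if rng is None else rng
    obs = _group_stat(x)
    # Under a sign flip (s_i x_i)^2 == x_i^2, so the flipped group sd is a
    # function of the flipped mean alone; the whole null can be vectorized.
    sum_sq = (x ** 2).sum(axis=0)
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration needs n <= 20")
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 2.0 * bits - 1.0
        n_perm = signs.shape[0]
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_mean = signs @ x / n                                  # (n_perm, T)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_sd = np.sqrt(np.maximum(sum_sq[None, :] - n * null_mean ** 2,
                                     0.0) / (n - 1))
        null = null_mean / null_sd
    null[~np.isfinite(null)] = 0.0
    ge = (null >= obs[None, :] - 1e-12).sum(axis=0)
    le = (null <= obs[None, :] + 1e-12).sum(axis=0)
    if exhaustive:
        p_right = ge / n_perm
        p_left = le / n_perm
    else:
        p_right = (1.0 + ge) / (1.0 + n_perm)
        p_left = (1.0 + le) / (1.0 + n_perm)
    if tail == "right":
        p = p_right
    elif tail == "left":
        p = p_left
    else:
        p = np.minimum(2.0 * np.minimum(p_left, p_right), 1.0)
    zero_sd = x.std(axis=0, ddof=1) == 0
    if zero_sd.any():
        log.info("%d time bin(s) with zero between-participant sd; p := 1",
                 int(zero_sd.sum()))
        p = np.where(zero_sd, 1.0, p)
    return p


def bh_fdr(p_raw: np.ndarray, alpha: float = 0.05
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance mask.

    Returns ``(p_adj, mask)`` with ``mask = p_adj <= alpha``; adjusted
    values are monotone and capped at 1. Empty input yields empty output.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return p_adj, p_adj <= alpha


def significance_timecourse(x: np.ndarray, tail: str, alpha: float,
                            n_perm: int = 10000,
                            rng: Optional[np.random.Generator] = None,
                            times: Optional[np.ndarray] = None
                            ) -> SigTimecourse:
    """Sign-permutation test followed by BH-FDR across time bins."""
    p_raw = sign_permutation_test(x, n_perm=n_perm, tail=tail, rng=rng)
    p_adj, mask = bh_fdr(p_raw, alpha)
    return SigTimecourse(p_raw, p_adj, mask, tail, alpha, times)


def _peak_idx(curve: np.ndarray, mode: str) -> int:
    # np.argmax/argmin return the earliest index on ties (stated rule)
    return int(np.argmax(curve) if mode == "max" else np.argmin(curve))


def bootstrap_peak_ci(x: np.ndarray, times: np.ndarray, n_boot: int = 1000,
                      mode: str = "max",
                      rng: Optional[np.random.Generator] = None) -> PeakCI:
    """Percentile bootstrap CI for the latency of the group-mean peak.

    Participants are resampled with replacement; each resample's group-mean
    time course contributes its argmax (or argmin) latency. Ties break to
    the earliest bin. The point estimate comes from the full sample.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng() if rng is None else rng
    times = np.asarray(times, dtype=float)
    full = x.mean(axis=0)
    if np.ptp(full) == 0:
        log.info("flat time course; peak tie-broken to earliest latency")
    peak = float(times[_peak_idx(full, mode)])
    idx = rng.integers(0, n, size=(n_boot, n))
    lat = np.array([times[_peak_idx(x[row].mean(axis=0), mode)]
                    for row in idx])
    lo, hi = np.percentile(lat, [2.5, 97.5])
    return PeakCI(peak, (float(lo), float(hi)), n_boot)


def bootstrap_peak_difference_ci(x1: np.ndarray, x2: np.ndarray,
                                 times: np.ndarray, n_boot: int = 1000,
                                 mode: str = "max",
                                 rng: Optional[np.random.Generator] = None
                                 ) -> PeakCI:
    """CI for the difference of two curves' peak latencies, using paired
    resamples (the same participant draw applied to both curves)."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape != x2.shape:
        raise ValueError("curves must share participants and times")
    rng = np.random.default_rng() if rng is None else rng
    times = np.asarray(times, dtype=float)
    point = (times[_peak_idx(x1.mean(axis=0), mode)]
             - times[_peak_idx(x2.mean(axis=0), mode)])
    n = x1.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    diffs = np.array([
        times[_peak_idx(x1[row].mean(axis=0), mode)]
        - times[_peak_idx(x2[row].mean(axis=0), mode)]
        for row in idx])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return PeakCI(float(point), (float(lo), float(hi)), n_boot)
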