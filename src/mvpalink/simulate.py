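"""Ground-truthed synthetic data with the statistical structure the
analyses assume.

The generator plants a binary category signal confined to a latency window:
each scene (exemplar) carries a latent signed margin ``m_s`` whose sign is
its category and whose magnitude is how far its representation sits from the
category boundary. A trial of scene ``s`` is

    ``x(c, t) = a(t) * m_s * w_c + noise(c, t)``

with ``a(t)`` a raised-cosine amplitude profile inside the effect window,
``w`` a unit-norm channel projection, and spatially correlated, temporally
band-limited Gaussian noise. Reaction times follow the linking assumption
under test downstream: scenes farther from the boundary are answered
faster, ``rt = rt_base - rt_coupling * |m_s| + noise``. Staged classifier
probabilities sharpen over stages at a rate growing with ``|m_s|``.

Everything is a pure function of the configuration (including its seed):
per-participant substreams are derived with counter-style seed keys so the
output never depends on evaluation order or parallelism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import EpochSet, RTTable

CovSpec = Union[str, Tuple[str, object]]

#: Reaction-time floor (msec): values below are clipped to stay physical.
RT_FLOOR_MS = 150.0


@dataclass
class SimConfig:
    """Simulation design. Defaults describe the standard validation design:
    20 participants x 20 scenes (half natural, half man-made), 16 channels,
    120 bins of 5 msec spanning -200..400 msec, category signal confined to
    100-200 msec post onset."""

    n_participants: int = 20
    n_scenes: int = 20
    n_channels: int = 16
    n_timepoints: int = 120
    sample_period: float = 5.0          # msec per bin
    epoch_start: float = -200.0         # msec of first bin edge
    effect_window: Tuple[float, float] = (100.0, 200.0)
    category_separation: float = 1.0    # mean margin between categories
    exemplar_spread: float = 0.25       # sd of per-scene latent margin
    noise_cov_spec: CovSpec = "identity"
    noise_scale: float = 1.0
    noise_smooth_bins: int = 3          # temporal band-limiting kernel width
    trials_per_scene: int = 24
    rt_base: float = 500.0              # msec
    rt_coupling: float = 50.0           # msec per unit |margin|, lambda >= 0
    rt_noise_sd: float = 30.0           # msec
    n_stages: int = 8
    stage_gain: float = 1.0             # evidence growth per stage per |margin|
    stage_noise_sd: float = 0.1
    task: str = "categorization"
    signal_channels: Optional[Sequence[int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scenes < 2 or self.n_scenes % 2:
            raise ValueError("n_scenes must be an even count >= 2")
        if min(self.n_participants, self.n_channels, self.n_timepoints,
               self.trials_per_scene) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.effect_window
        t0, t1 = self.times[0], self.times[-1]
        if not (t0 <= lo < hi <= t1 + self.sample_period / 2):
            raise ValueError(
                f"effect_window {self.effect_window} outside epoch "
                f"range [{t0}, {t1}]")
        if self.rt_noise_sd < 0 or self.rt_coupling < 0:
            raise ValueError("rt_noise_sd and rt_coupling must be >= 0")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")

    @property
    def times(self) -> np.ndarray:
        """Bin-center latencies in msec."""
        i = np.arange(self.n_timepoints)
        return self.epoch_start + (i + 0.5) * self.sample_period

    @property
    def categories(self) -> np.ndarray:
        """Per-scene category label; first half natural, second man-made."""
        half = self.n_scenes // 2
        return np.array(["natural"] * half + ["man-made"] * half)

    @property
    def scene_ids(self) -> list:
        return [f"S{i:03d}" for i in range(self.n_scenes)]

    @property
    def participant_ids(self) -> list:
        return [f"P{i:02d}" for i in range(self.n_participants)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_window"] = list(d["effect_window"])
        if d["signal_channels"] is not None:
            d["signal_channels"] = list(d["signal_channels"])
        return d


@dataclass
class GroundTruth:
    """Latent quantities the recovery tests check against."""

    scene_margin: np.ndarray        # (n_scenes,), signed, sign = category
    signal_profile: np.ndarray      # (n_timepoints,), a(t) in [0, 1]
    channel_weights: np.ndarray     # (n_channels,), unit norm (or zero)
    scenes: list = field(default_factory=list)
    categories: np.ndarray = field(default_factory=lambda: np.array([]))


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    """Counter-keyed substream: independent of order of use."""
    return np.random.default_rng(np.random.SeedSequence((int(cfg.seed),) + key))


def build_noise_cov(spec: CovSpec, n_channels: int) -> np.ndarray:
    """Construct the channel noise covariance from its descriptor.

    Accepted descriptors: ``"identity"``, ``("diagonal", variances)``,
    ``("exponential", rate)`` with ``cov[i, j] = exp(-rate * |i - j|)``.
    """
    if spec == "identity":
        return np.eye(n_channels)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        kind, arg = spec
        if kind == "diagonal":
            v = np.asarray(arg, dtype=float)
            if v.shape != (n_channels,) or np.any(v < 0):
                raise ValueError(
                    "diagonal spec needs one nonnegative variance per channel")
            return np.diag(v)
        if kind == "exponential":
            rate = float(arg)
            if rate < 0:
                raise ValueError("exponential decay rate must be >= 0")
            idx = np.arange(n_channels)
            return np.exp(-rate * np.abs(idx[:, None] - idx[None, :]))
    raise ValueError(f"unknown noise covariance spec: {spec!r}")


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor; rejects non-PSD matrices with an explanation."""
    if not np.allclose(cov, cov.T):
        raise ValueError("noise covariance must be symmetric")
    w, v = np.linalg.eigh(cov)
    if np.any(w < -1e-10 * max(w.max(), 1.0)):
        raise ValueError(
            "noise covariance is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g}); fix the covariance spec")
    return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def raised_cosine_profile(times: np.ndarray,
                          window: Tuple[float, float]) -> np.ndarray:
    """Raised-cosine amplitude a(t): 0 outside the window, smooth ramp to 1
    at the window center — mimics the envelope of an evoked response and
    avoids edge artifacts in time-resolved decoding."""
    lo, hi = window
    a = np.zeros_like(times, dtype=float)
    inside = (times >= lo) & (times <= hi)
    phase = (times[inside] - lo) / (hi - lo)
    a[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return a


def gen_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Draw the latent scene margins, signal profile and channel weights."""
    rng = _rng(cfg, 0)
    half = cfg.n_scenes // 2
    # magnitude ~ |N(sep/2, spread)| guarantees sign constancy per category
    mag = np.abs(rng.normal(cfg.category_separation / 2.0,
                            cfg.exemplar_spread, size=cfg.n_scenes))
    signs = np.concatenate([np.ones(half), -np.ones(half)])
    margins = signs * mag
    if cfg.signal_channels is not None:
        w = np.zeros(cfg.n_channels)
        w[list(cfg.signal_channels)] = 1.0
    else:
        w = rng.normal(size=cfg.n_channels)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    return GroundTruth(
        scene_margin=margins,
        signal_profile=raised_cosine_profile(cfg.times, cfg.effect_window),
        channel_weights=w,
        scenes=cfg.scene_ids,
        categories=cfg.categories,
    )


def _smoothed_noise(rng: np.random.Generator, shape: tuple,
                    smooth_bins: int) -> np.ndarray:
    """White noise band-limited along the last (time) axis with a unit-energy
    moving-average kernel, so the per-sample variance stays 1."""
    if smooth_bins <= 1:
        return rng.standard_normal(shape)
    k = int(smooth_bins)
    z = rng.standard_normal(shape[:-1] + (shape[-1] + k - 1,))
    cs = np.cumsum(z, axis=-1)
    zero = np.zeros(shape[:-1] + (1,))
    cs = np.concatenate([zero, cs], axis=-1)
    return (cs[..., k:] - cs[..., :-k]) / np.sqrt(k)


def gen_epochs(cfg: SimConfig,
               truth: Optional[GroundTruth] = None
               ) -> Tuple[EpochSet, GroundTruth]:
    """Generate the full epoched data set for all participants.

    Returns the epochs plus the ground truth used to plant the signal. RTs
    in the trial table come from :func:`gen_rts` with the same config and
    are therefore identical to a separate ``gen_rts`` call.
    """
    if truth is None:
        truth = gen_ground_truth(cfg)
    cov = build_noise_cov(cfg.noise_cov_spec, cfg.n_channels)
    L = _cov_factor(cov)
    rt_table = gen_rts(truth, cfg)

    signal = (truth.scene_margin[:, None, None]
              * truth.channel_weights[None, :, None]
              * truth.signal_profile[None, None, :])    # (scene, chan, time)

    n_per = cfg.n_scenes * cfg.trials_per_scene
    data = np.empty((cfg.n_participants * n_per, cfg.n_channels,
                     cfg.n_timepoints))
    rows = []
    for p, pid in enumerate(cfg.participant_ids):
        rng = _rng(cfg, 1, p)
        noise = _smoothed_noise(
            rng, (n_per, cfg.n_channels, cfg.n_timepoints),
            cfg.noise_smooth_bins)
        noise = np.einsum("ij,njt->nit", L, noise) * cfg.noise_scale
        block = slice(p * n_per, (p + 1) * n_per)
        data[block] = np.repeat(signal, cfg.trials_per_scene, axis=0) + noise
        for s, sid in enumerate(cfg.scene_ids):
            rt = rt_table.rt.loc[pid, sid]
            rows.extend(
                {"participant": pid, "scene": sid,
                 "category": cfg.categories[s], "task": cfg.task,
                 "correct": True, "rt": rt}
                for _ in range(cfg.trials_per_scene))
    trials = pd.DataFrame(rows)
    epochs = EpochSet(data, cfg.times, trials)
    return epochs, truth


def gen_rts(truth: GroundTruth, cfg: SimConfig,
            coupling: Optional[float] = None,
            task: Optional[str] = None,
            stream: int = 0) -> RTTable:
    """Reaction times negatively coupled to the latent boundary distance:

        ``rt[p, s] = rt_base - coupling * |m_s| + N(0, rt_noise_sd)``

    clipped below at the physical floor of 150 msec. ``stream`` selects an
    independent noise substream (e.g. for a second task's RTs).
    """
    lam = cfg.rt_coupling if coupling is None else float(coupling)
    if lam < 0:
        raise ValueError("rt coupling must be >= 0")
    rng = _rng(cfg, 2, stream)
    mean = cfg.rt_base - lam * np.abs(truth.scene_margin)
    rts = mean[None, :] + rng.normal(
        0.0, cfg.rt_noise_sd, size=(cfg.n_participants, len(truth.scene_margin)))
    rts = np.maximum(rts, RT_FLOOR_MS)
    df = pd.DataFrame(rts, index=cfg.participant_ids, columns=truth.scenes)
    return RTTable(rt=df, task=cfg.task if task is None else task)


def gen_stage_probs(truth: GroundTruth, cfg: SimConfig):
    """Staged two-class probability trajectories that sharpen over stages.

    Evidence for the true category after stage ``k`` is
    ``z = stage_gain * |m_s| * k * exp(eps)`` with multiplicative lognormal
    jitter (``eps ~ N(0, stage_noise_sd)``), mapped through a logistic to
    the true-class probability. A boundary scene (``m_s = 0``) stays at
    (0.5, 0.5) — maximal entropy — forever.
    """
    from .readout import StageProbabilities

    rng = _rng(cfg, 3)
    k = np.arange(1, cfg.n_stages + 1)
    base = cfg.stage_gain * np.abs(truth.scene_margin)[:, None] * k[None, :]
    if cfg.stage_noise_sd > 0:
        base = base * np.exp(rng.normal(0.0, cfg.stage_noise_sd, base.shape))
    p_true = 1.0 / (1.0 + np.exp(-base))
    # order classes (natural, man-made); put p_true on each scene's category
    p = np.empty((len(truth.scene_margin), cfg.n_stages, 2))
    is_natural = truth.categories == "natural"
    p[is_natural, :, 0] = p_true[is_natural]
    p[is_natural, :, 1] = 1.0 - p_true[is_natural]
    p[~is_natural, :, 1] = p_true[~is_natural]
    p[~is_natural, :, 0] = 1.0 - p_true[~is_natural]
    return StageProbabilities(p=p, scenes=list(truth.scenes),
                              classes=("natural", "man-made"))
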