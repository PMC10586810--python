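import numpy as np
import pandas as pd
import pytest

from mvpalink import EpochSet, SimConfig, gen_epochs, gen_rts


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact planted-effect design used across the unit tests."""
    return SimConfig(
        n_participants=4, n_scenes=8, n_channels=8, n_timepoints=30,
        epoch_start=-50.0, effect_window=(40.0, 100.0),
        trials_per_scene=16, category_separation=1.5, exemplar_spread=0.3,
        rt_noise_sd=15.0, seed=3,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    epochs, truth = gen_epochs(small_cfg)
    rt = gen_rts(truth, small_cfg)
    return epochs, truth, rt


def make_epochs(data: np.ndarray, times=None, scenes=None, categories=None,
                participant="P00", task="categorization",
                rt=400.0) -> EpochSet:
    """Hand-built EpochSet for arithmetic-level tests."""
    n, c, t = data.shape
    times = np.arange(t, dtype=float) if times is None else np.asarray(times)
    scenes = ["S0"] * n if scenes is None else scenes
    if categories is None:
        categories = ["natural"] * n
    trials = pd.DataFrame({
        "participant": participant, "scene": scenes,
        "category": categories, "task": task, "correct": True, "rt": rt,
    })
    return EpochSet(data, times, trials)
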