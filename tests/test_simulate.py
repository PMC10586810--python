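import numpy as np
import pytest
from scipy import stats as sstats

from mvpalink import SimConfig, gen_epochs, gen_rts, gen_stage_probs
from mvpalink.readout import extract_rts, stage_entropies
from mvpalink.simulate import (GroundTruth, build_noise_cov,
                               gen_ground_truth, raised_cosine_profile)


def _cfg(**kw) -> SimConfig:
    base = dict(n_participants=2, n_scenes=6, n_channels=6, n_timepoints=20,
                epoch_start=-25.0, effect_window=(20.0, 60.0),
                trials_per_scene=8, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestGenEpochs:
    def test_zero_effect_gives_zero_margins_and_pure_noise(self):
        cfg = _cfg(category_separation=0.0, exemplar_spread=0.0)
        epochs, truth = gen_epochs(cfg)
        assert np.all(truth.scene_margin == 0.0)
        cfg0 = _cfg(category_separation=0.0, exemplar_spread=0.0,
                    noise_scale=0.0)
        epochs0, _ = gen_epochs(cfg0)
        assert np.all(epochs0.data == 0.0)

    def test_noiseless_limit_reproduces_planted_signal_exactly(self):
        cfg = _cfg(noise_scale=0.0, signal_channels=[2])
        epochs, truth = gen_epochs(cfg)
        expected = (truth.scene_margin[:, None, None]
                    * truth.channel_weights[None, :, None]
                    * truth.signal_profile[None, None, :])
        for i, row in epochs.trials.iterrows():
            s = truth.scenes.index(row["scene"])
            np.testing.assert_array_equal(epochs.data[i], expected[s])

    def test_margin_sign_constant_within_category(self):
        _, truth = gen_epochs(_cfg(seed=11))
        nat = truth.scene_margin[truth.categories == "natural"]
        man = truth.scene_margin[truth.categories == "man-made"]
        assert np.all(nat >= 0) and np.all(man <= 0)

    def test_profile_zero_outside_effect_window(self):
        cfg = _cfg()
        _, truth = gen_epochs(cfg)
        t = cfg.times
        outside = (t < cfg.effect_window[0]) | (t > cfg.effect_window[1])
        assert np.all(truth.signal_profile[outside] == 0.0)
        assert truth.signal_profile.min() >= 0.0
        assert truth.signal_profile.max() <= 1.0

    def test_determinism_bit_identical(self):
        cfg = _cfg(seed=42)
        e1, t1 = gen_epochs(cfg)
        e2, t2 = gen_epochs(_cfg(seed=42))
        np.testing.assert_array_equal(e1.data, e2.data)
        np.testing.assert_array_equal(t1.scene_margin, t2.scene_margin)
        assert e1.trials.equals(e2.trials)

    def test_channel_covariance_recovered(self):
        # noise-only trials; empirical channel covariance must approach the
        # configured exponential-decay matrix
        cfg = _cfg(n_participants=1, n_scenes=2, trials_per_scene=5000,
                   n_timepoints=10, epoch_start=0.0,
                   effect_window=(5.0, 40.0),
                   category_separation=0.0, exemplar_spread=0.0,
                   noise_cov_spec=("exponential", 0.5))
        epochs, _ = gen_epochs(cfg)
        target = build_noise_cov(cfg.noise_cov_spec, cfg.n_channels)
        X = np.moveaxis(epochs.data, 1, 2).reshape(-1, cfg.n_channels)
        emp = np.cov(X.T)
        rel = (np.linalg.norm(emp - target, "fro")
               / np.linalg.norm(target, "fro"))
        assert rel < 0.05

    def test_rt_metadata_matches_gen_rts(self):
        cfg = _cfg()
        epochs, truth = gen_epochs(cfg)
        rt = gen_rts(truth, cfg)
        for (pid, sid), grp in epochs.trials.groupby(["participant",
                                                      "scene"]):
            assert np.allclose(grp["rt"], rt.rt.loc[pid, sid])


class TestNoiseCov:
    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="unknown noise covariance"):
            build_noise_cov("banana", 4)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            build_noise_cov(("diagonal", [1.0, -2.0, 1.0, 1.0]), 4)

    def test_diagonal_and_identity(self):
        np.testing.assert_array_equal(build_noise_cov("identity", 3),
                                      np.eye(3))
        np.testing.assert_array_equal(
            build_noise_cov(("diagonal", [4.0, 1.0]), 2),
            np.diag([4.0, 1.0]))


class TestGenRts:
    def _truth(self, margins):
        m = np.asarray(margins, dtype=float)
        return GroundTruth(m, np.zeros(20), np.ones(6) / np.sqrt(6),
                           scenes=[f"S{i:03d}" for i in range(m.size)],
                           categories=np.where(m >= 0, "natural", "man-made"))

    def test_no_coupling_rts_independent_of_margins(self):
        rng = np.random.default_rng(0)
        truth = self._truth(rng.normal(size=200))
        cfg = SimConfig(n_participants=2, n_scenes=200, n_channels=6,
                        n_timepoints=20, epoch_start=-25.0,
                        effect_window=(20.0, 60.0), rt_coupling=0.0, seed=9)
        rt = gen_rts(truth, cfg)
        rho = sstats.spearmanr(np.abs(truth.scene_margin),
                               rt.median_rt.to_numpy()).statistic
        assert abs(rho) < 0.2

    def test_noiseless_coupling_is_perfectly_monotone(self):
        truth = self._truth([0.1, -0.5, 0.9, -1.3, 0.7, -0.2])
        cfg = _cfg(rt_noise_sd=0.0, rt_coupling=40.0)
        rt = gen_rts(truth, cfg)
        rho = sstats.spearmanr(np.abs(truth.scene_margin),
                               rt.median_rt.to_numpy()).statistic
        assert rho == -1.0

    def test_arithmetic(self):
        truth = self._truth([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        cfg = _cfg(rt_base=500.0, rt_coupling=50.0, rt_noise_sd=0.0)
        rt = gen_rts(truth, cfg)
        assert np.all(rt.rt.to_numpy() == 450.0)

    def test_floor_clipping(self):
        truth = self._truth([10.0, -10.0, 10.0, -10.0, 10.0, -10.0])
        cfg = _cfg(rt_base=200.0, rt_coupling=50.0, rt_noise_sd=0.0)
        rt = gen_rts(truth, cfg)
        assert np.all(rt.rt.to_numpy() == 150.0)


class TestStageProbs:
    def test_saturation_large_margin(self):
        truth = GroundTruth(np.array([50.0, -50.0]), np.zeros(5), np.ones(3),
                            scenes=["S000", "S001"],
                            categories=np.array(["natural", "man-made"]))
        cfg = _cfg(n_scenes=2, stage_noise_sd=0.0)
        sp = gen_stage_probs(truth, cfg)
        H = stage_entropies(sp)
        assert np.all(H.H < 1e-6)

    def test_boundary_scene_stays_uninformative(self):
        truth = GroundTruth(np.array([0.0, 0.0]), np.zeros(5), np.ones(3),
                            scenes=["S000", "S001"],
                            categories=np.array(["natural", "man-made"]))
        sp = gen_stage_probs(truth, _cfg(n_scenes=2))
        np.testing.assert_allclose(sp.p, 0.5)

    def test_larger_margin_never_slower_at_any_threshold(self):
        truth = GroundTruth(np.array([2.0, 0.5]), np.zeros(5), np.ones(3),
                            scenes=["S000", "S001"],
                            categories=np.array(["natural", "natural"]))
        sp = gen_stage_probs(truth, _cfg(n_scenes=2, stage_noise_sd=0.0))
        H = stage_entropies(sp)
        for thr in np.linspace(0.01, 0.99, 25):
            rts = extract_rts(H, thr).rt
            assert rts[0] <= rts[1]

    def test_rows_are_simplexes(self, small_cfg):
        truth = gen_ground_truth(small_cfg)
        sp = gen_stage_probs(truth, small_cfg)
        np.testing.assert_allclose(sp.p.sum(axis=-1), 1.0)
        assert np.all(sp.p >= 0)


class TestConfigValidation:
    def test_odd_scene_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            _cfg(n_scenes=5)

    def test_effect_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="effect_window"):
            _cfg(effect_window=(500.0, 600.0))

    def test_negative_rt_noise_rejected(self):
        with pytest.raises(ValueError):
            _cfg(rt_noise_sd=-1.0)


def test_raised_cosine_peaks_at_window_center():
    t = np.linspace(0, 100, 201)
    a = raised_cosine_profile(t, (20.0, 80.0))
    assert a[np.argmin(np.abs(t - 50.0))] == pytest.approx(1.0)
    assert a[t < 20].sum() == 0 and a[t > 80].sum() == 0
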