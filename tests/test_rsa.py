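import numpy as np
import pytest

from mvpalink import (SimConfig, correlate_rdms, eeg_rdm_series, gen_epochs,
                      model_rdm, noise_ceiling, rsa_timecourse)
from mvpalink.rsa import RDMSeries, validate_rdm
from tests.conftest import make_epochs


def _epochs_from_patterns(patterns, n_rep=6):
    """Each scene's trials are exact copies of its pattern (no noise)."""
    S, C, T = patterns.shape
    data = np.repeat(patterns, n_rep, axis=0)
    scenes = sum(([f"S{i}"] * n_rep for i in range(S)), [])
    cats = ["natural" if i < S // 2 else "man-made"
            for i in range(S) for _ in range(n_rep)]
    return make_epochs(data, scenes=scenes, categories=cats)


class TestEegRdmSeries:
    def test_identical_patterns_give_zero_distance(self):
        p = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (2, 1))[:, :, None]
        e = _epochs_from_patterns(np.repeat(p, 3, axis=2))
        series = eeg_rdm_series(e, group_size=2, repeats=2)
        np.testing.assert_allclose(series.dist, 0.0, atol=1e-12)

    def test_anticorrelated_patterns_give_distance_two(self):
        v = np.array([1.0, -2.0, 3.0, -4.0])
        p = np.stack([v, -v])[:, :, None]
        e = _epochs_from_patterns(np.repeat(p, 3, axis=2))
        series = eeg_rdm_series(e, group_size=2, repeats=2)
        np.testing.assert_allclose(series.dist[:, :, 0, 1], 2.0, atol=1e-12)

    def test_affine_pattern_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(3, 6, 2))
        e1 = _epochs_from_patterns(p)
        e2 = _epochs_from_patterns(3.0 * p + 11.0)
        a = eeg_rdm_series(e1, group_size=2, repeats=2, seed=1)
        b = eeg_rdm_series(e2, group_size=2, repeats=2, seed=1)
        np.testing.assert_allclose(a.dist, b.dist, atol=1e-10)

    def test_rdms_are_valid(self, small_data):
        epochs, _, _ = small_data
        series = eeg_rdm_series(epochs, group_size=4, repeats=2, seed=0)
        for pi in range(series.dist.shape[0]):
            for t in range(0, series.dist.shape[1], 7):
                validate_rdm(series.dist[pi, t])

    def test_single_scene_rejected(self):
        e = _epochs_from_patterns(np.ones((1, 4, 2)))
        with pytest.raises(ValueError, match="2 scenes"):
            eeg_rdm_series(e, group_size=2, repeats=1)


class TestModelRdm:
    def test_duplicated_scene_rows_give_zero(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=12)
        X = np.vstack([row, row, rng.normal(size=12)])
        d = model_rdm(X)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 20))
        perm = rng.permutation(20)
        np.testing.assert_allclose(model_rdm(X), model_rdm(X[:, perm]),
                                   atol=1e-12)

    def test_hand_written_rows_match_direct_formula(self):
        X = np.array([[1.0, 0.0, 2.0],
                      [0.0, 1.0, 4.0],
                      [2.0, 2.0, 0.0]])
        d = model_rdm(X)
        # oracle: z-score columns, then 1 - Pearson r row by row
        Z = (X - X.mean(0)) / X.std(0)
        for i in range(3):
            for j in range(3):
                r = np.corrcoef(Z[i], Z[j])[0, 1]
                expect = 0.0 if i == j else np.clip(1 - r, 0, 2)
                assert d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            model_rdm(np.ones((4, 5)))


class TestCorrelateRdms:
    def _rdm(self, v):
        S = v.shape[0]
        validate_rdm(v)
        return v

    def test_identical_rdms_correlate_one(self):
        rng = np.random.default_rng(3)
        a = model_rdm(rng.normal(size=(6, 10)))
        assert correlate_rdms(a, a) == pytest.approx(1.0)

    def test_monotone_transform_preserves_rho(self):
        rng = np.random.default_rng(4)
        a = model_rdm(rng.normal(size=(6, 10)))
        b = np.sqrt(a)          # strictly increasing on [0, 2]
        assert correlate_rdms(a, b) == pytest.approx(1.0)

    def test_reversed_ranks_correlate_minus_one(self):
        rng = np.random.default_rng(5)
        a = model_rdm(rng.normal(size=(6, 10)))
        b = 2.0 - a
        np.fill_diagonal(b, 0.0)
        assert correlate_rdms(a, b) == pytest.approx(-1.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            correlate_rdms(np.zeros((3, 3)), np.zeros((4, 4)))


class TestRsaTimecourse:
    def _series_with_plant(self, target, t_plant, T=6, P=3, noise=0.0,
                           seed=0):
        rng = np.random.default_rng(seed)
        S = target.shape[0]
        dist = np.empty((P, T, S, S))
        for pi in range(P):
            for t in range(T):
                base = target if t == t_plant else model_rdm(
                    rng.normal(size=(S, 30)))
                jitter = rng.normal(scale=noise, size=(S, S))
                jitter = (jitter + jitter.T) / 2
                d = np.clip(base + jitter, 0, 2)
                np.fill_diagonal(d, 0)
                dist[pi, t] = d
        return RDMSeries(dist, np.arange(T, dtype=float) * 10,
                         [f"P{i}" for i in range(P)],
                         [f"S{i}" for i in range(S)])

    def test_planted_model_rdm_recovers_peak(self):
        rng = np.random.default_rng(6)
        target = model_rdm(rng.normal(size=(8, 30)))
        series = self._series_with_plant(target, t_plant=4)
        out = rsa_timecourse(series, {("early", 1): target})
        assert out.peak_latency["early"] == 40.0
        np.testing.assert_allclose(out.rho["early"][:, 4], 1.0, atol=1e-12)

    def test_independent_model_rdm_near_zero(self):
        rng = np.random.default_rng(7)
        target = model_rdm(rng.normal(size=(10, 30)))
        series = self._series_with_plant(
            model_rdm(rng.normal(size=(10, 30))), t_plant=0, P=6, seed=8)
        other = rsa_timecourse(series, {("late", 1): target})
        assert abs(np.nanmean(other.rho["late"])) < 0.15

    def test_subset_of_identical_rdms_still_one(self):
        rng = np.random.default_rng(9)
        target = model_rdm(rng.normal(size=(8, 30)))
        series = self._series_with_plant(target, t_plant=2)
        cats = {f"S{i}": ("natural" if i < 4 else "man-made")
                for i in range(8)}
        out = rsa_timecourse(series, {("mid", 1): target}, subset="natural",
                             categories=cats)
        np.testing.assert_allclose(out.rho["mid"][:, 2], 1.0, atol=1e-12)

    def test_median_over_stages(self):
        rng = np.random.default_rng(10)
        target = model_rdm(rng.normal(size=(6, 30)))
        series = self._series_with_plant(target, t_plant=1, P=2)
        out = rsa_timecourse(series, {("l", s): target for s in range(1, 4)})
        assert out.rho["l"].shape == (2, 6)


class TestNoiseCeiling:
    def test_shared_rdm_gives_unit_bounds(self):
        rng = np.random.default_rng(11)
        one = model_rdm(rng.normal(size=(6, 20)))
        dist = np.tile(one, (4, 3, 1, 1))
        series = RDMSeries(dist, np.arange(3, dtype=float),
                           list("abcd"), [f"S{i}" for i in range(6)])
        nc = noise_ceiling(series)
        np.testing.assert_allclose(nc.lower, 1.0, atol=1e-12)
        np.testing.assert_allclose(nc.upper, 1.0, atol=1e-12)

    def test_independent_rdms_near_zero_and_ordered(self):
        rng = np.random.default_rng(12)
        P, T, S = 10, 4, 12
        dist = np.empty((P, T, S, S))
        for pi in range(P):
            for t in range(T):
                dist[pi, t] = model_rdm(rng.normal(size=(S, 25)))
        series = RDMSeries(dist, np.arange(T, dtype=float),
                           [f"P{i}" for i in range(P)],
                           [f"S{i}" for i in range(S)])
        nc = noise_ceiling(series)
        assert np.all(nc.lower <= nc.upper + 1e-12)
        assert np.all(np.abs(nc.lower) < 0.35)

    def test_single_participant_rejected(self):
        series = RDMSeries(np.zeros((1, 2, 3, 3)), np.arange(2.0),
                           ["p"], list("xyz"))
        with pytest.raises(ValueError, match="2 participants"):
            noise_ceiling(series)
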