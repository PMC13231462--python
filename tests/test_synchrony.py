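"""Synchrony metrics against independent oracles: brute-force DTW path
enumeration, a naive all-pairs interdependence implementation, coherence
bias under independence, and hand-computed correlations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dyadaffect as da
from dyadaffect.errors import InvalidArgumentError
from dyadaffect.synchrony import SYNCHRONY_FEATURE_NAMES, _embed


# --- independent oracles ---------------------------------------------------

def brute_force_dtw(x, y):
    """Exhaustive enumeration of monotone warping paths (tiny inputs)."""
    n, m = len(x), len(y)
    results = []
    stack = [((0, 0), abs(x[0] - y[0]), 1)]
    while stack:
        (i, j), cost, length = stack.pop()
        if (i, j) == (n - 1, m - 1):
            results.append((cost, length))
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m:
                stack.append(((ii, jj), cost + abs(x[ii] - y[jj]), length + 1))
    cost, length = min(results)
    return cost / length


def naive_nli(x, y, m=3, tau=4, k=5, theiler=8):
    """O(N^2) all-pairs reference implementation."""
    ex, ey = _embed(np.asarray(x, float), m, tau), _embed(np.asarray(y, float), m, tau)
    n = len(ex)

    def neigh(emb):
        d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        idx = []
        for i in range(n):
            order = np.argsort(np.sqrt(d2[i]), kind="stable")
            idx.append([j for j in order if abs(j - i) > theiler][:k])
        return np.array(idx), d2

    ix, d2x = neigh(ex)
    iy, d2y = neigh(ey)

    def directed(d2_self, idx_self, idx_other):
        rs = np.array([d2_self[i, idx_self[i]].mean() for i in range(n)])
        rc = np.array([d2_self[i, idx_other[i]].mean() for i in range(n)])
        return np.where((rs == 0) & (rc == 0), 1.0, rs / np.maximum(rc, 1e-300)).mean()

    return 0.5 * (directed(d2x, ix, iy) + directed(d2y, iy, ix))


class TestDtw:
    def test_identity_is_zero(self):
        x = np.array([0.3, -1.2, 0.8, 2.0])
        assert da.dtw_distance(x, x) == 0.0

    def test_small_worked_example(self):
        # brute-force enumeration over all monotone paths gives 1/3:
        # the optimal path has total cost 1 over 3 steps
        assert da.dtw_distance([0, 1, 2], [0, 2, 2]) == pytest.approx(1 / 3)
        assert brute_force_dtw([0, 1, 2], [0, 2, 2]) == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 5))
            y = rng.normal(size=rng.integers(2, 5))
            assert da.dtw_distance(x, y) == pytest.approx(
                brute_force_dtw(x, y), abs=1e-9
            )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=30),
           st.lists(st.floats(-5, 5), min_size=2, max_size=30))
    def test_symmetry_and_nonnegativity(self, xs, ys):
        d_xy = da.dtw_distance(xs, ys)
        assert d_xy >= 0.0
        assert d_xy == pytest.approx(da.dtw_distance(ys, xs), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            da.dtw_distance([1.0], [1.0, 2.0])


class TestNli:
    def test_identical_trajectories_give_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        assert da.nonlinear_interdependence(x, x.copy()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_all_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.normal(size=60), rng.normal(size=60)
            assert da.nonlinear_interdependence(x, y) == pytest.approx(
                naive_nli(x, y), abs=1e-9
            )

    def test_independent_noise_low_index(self):
        rng = np.random.default_rng(4)
        vals = [
            da.nonlinear_interdependence(rng.normal(size=960), rng.normal(size=960))
            for _ in range(20)
        ]
        assert np.mean(vals) < 0.5

    def test_insufficient_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            da.nonlinear_interdependence(np.zeros(10), np.zeros(10))


class TestCoherence:
    fs = 4.0

    def test_identical_signals_unit_coherence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=960)
        c = da.band_coherence(x, x.copy(), self.fs, ((0.04, 0.15), (0.15, 0.40)))
        assert c > 0.99

    def test_independent_noise_matches_window_bias(self):
        # averaged coherence of independent series is biased ~1/L for L
        # independent windows; 960 samples at 4 Hz with 60 s windows -> small
        rng = np.random.default_rng(6)
        vals = [
            da.band_coherence(rng.normal(size=960), rng.normal(size=960),
                              self.fs, ((0.04, 0.40),))
            for _ in range(20)
        ]
        assert np.mean(vals) < 0.35

    def test_monotone_in_snr(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=960)
        noisy = x + rng.normal(size=960)  # 0 dB SNR
        bands = ((0.04, 0.40),)
        c_same = da.band_coherence(x, x.copy(), self.fs, bands)
        c_noisy = da.band_coherence(x, noisy, self.fs, bands)
        c_indep = da.band_coherence(x, rng.normal(size=960), self.fs, bands)
        assert c_indep < c_noisy < c_same

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            da.band_coherence(np.zeros(100), np.zeros(100), self.fs, ((0.1, 0.4),))


class TestCrossCorrelation:
    def test_perfect_and_inverse(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert da.cross_correlation(x, x) == pytest.approx(1.0)
        assert da.cross_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert da.cross_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert da.cross_correlation(np.ones(10), np.arange(10.0)) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert da.cross_correlation(3.0 * x + 1.0, y) == pytest.approx(
            da.cross_correlation(x, y), abs=1e-12
        )


class TestExtractSynchrony:
    def test_schema(self, featurized):
        sync = featurized["conversation1"]["synchrony"]
        assert tuple(sync.keys()) == SYNCHRONY_FEATURE_NAMES
        assert len(sync) == 16
        assert all(np.isfinite(v) for v in sync.values())
        for sig in ("hr", "resp", "eda", "temp"):
            assert sync[f"dtw_{sig}"] >= 0
            assert -1.0 <= sync[f"xcorr_{sig}"] <= 1.0
            assert 0.0 <= sync[f"coh_{sig}"] <= 1.0

    def test_participant_exchange_symmetry(self, featurized, dyad_recording):
        swapped = da.featurize_recording(dyad_recording.swapped())
        for seg in featurized:
            orig = featurized[seg]["synchrony"]
            sw = swapped[seg]["synchrony"]
            for k in orig:
                assert sw[k] == pytest.approx(orig[k], rel=1e-9), (seg, k)

    def test_coupling_raises_hr_correlation(self, effect):
        """High-coupling scenario segments show larger HR cross-correlation
        than low-coupling ones, averaged over seeds."""
        import dataclasses
        from dyadaffect.simulate import shared_modulator

        def xcorr_at(coupling, seed):
            rng = np.random.default_rng(seed)
            p = dataclasses.replace(effect.scenarios["PV-HA"], coupling=coupling)
            mod = shared_modulator(240.0, rng)
            a = da.generate_participant_signals(p, mod, 240.0, 150.0,
                                                int(rng.integers(2**31)))
            b = da.generate_participant_signals(p, mod, 240.0, 150.0,
                                                int(rng.integers(2**31)))
            return np.corrcoef(a.rate_bpm, b.rate_bpm)[0, 1]

        hi = np.mean([xcorr_at(1.0, s) for s in range(5)])
        lo = np.mean([xcorr_at(0.0, s + 100) for s in range(5)])
        assert hi > lo
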