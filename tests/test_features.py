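import math

import numpy as np
import pytest

from _oracles import freq_features_bf
from conftest import make_segment
from steerwake.features import (
    FEATURE_NAMES,
    N_FEATURES,
    FeatureMatrix,
    apply_normalizer,
    extract_features,
    extract_window_features,
    fit_normalizer,
    katz_fractal_dimension,
    sample_entropy,
    shannon_entropy,
    zero_crossing_rate,
)
from steerwake.preprocess import WindowSpec, slide_windows

FS = 60.0
W = 180

# index of each named descriptor within one channel block
IDX = {
    name: i
    for i, name in enumerate(
        ["range", "std", "energy", "zcr", "q1", "q2", "q3", "katz_fd",
         "skewness", "kurtosis", "sampen", "shen",
         "spec_var", "spec_entropy", "spec_flux", "cgf", "dom_freq", "mean_psd"]
    )
}


def _sine(freq_hz, n=W, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * math.pi * freq_hz * t + phase)


class TestScalarFeatures:
    def test_zcr_of_2hz_sine_is_4_per_second(self):
        # quarter-wave phase keeps every zero strictly between samples
        x = _sine(2.0, phase=math.pi / 4)
        assert zero_crossing_rate(x, FS) == pytest.approx(4.0)
        # cross-check against a direct crossing count
        direct = sum(1 for a, b in zip(x[:-1], x[1:]) if a * b < 0)
        assert direct / 3.0 == pytest.approx(4.0)

    def test_katz_fd_of_a_line_is_one(self):
        for slope in (0.001, 0.5, 10.0, -3.0):
            x = slope * np.arange(W)
            assert katz_fractal_dimension(x) == pytest.approx(1.0, abs=1e-6)

    def test_shannon_entropy_of_constant_window_is_zero(self):
        assert shannon_entropy(np.zeros(W)) == 0.0

    def test_shannon_entropy_bounded_by_log2_bins(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            h = shannon_entropy(rng.standard_normal(W))
            assert 0.0 <= h <= math.log2(16)

    def test_sampen_ranks_noise_above_sinusoid(self):
        # regularity ordering at matched SD, over 50 seeded windows
        rng = np.random.default_rng(7)
        sine = _sine(1.0)
        sine_en = sample_entropy(sine)
        wins = 0
        for _ in range(50):
            noise = rng.standard_normal(W)
            noise *= sine.std(ddof=1) / noise.std(ddof=1)
            if sample_entropy(noise) > sine_en:
                wins += 1
        assert wins == 50

    def test_sampen_zero_variance_returns_cap(self):
        n = W
        cap = -math.log(2.0 / ((n - 3) * (n - 2)))
        assert sample_entropy(np.zeros(n)) == pytest.approx(cap)


class TestWindowVector:
    def test_exactly_36_named_finite_features(self, short_trace):
        segs = slide_windows(short_trace, WindowSpec())
        vec = extract_window_features(segs[0], FS)
        assert vec.shape == (N_FEATURES,) == (36,)
        assert np.all(np.isfinite(vec))
        assert len(set(FEATURE_NAMES)) == 36
        assert FEATURE_NAMES[0] == "I01a" and FEATURE_NAMES[-1] == "I18v"

    def test_degenerate_constant_window(self):
        seg = make_segment(np.full(W, 3.3), np.full(W, -1.0))
        vec = extract_window_features(seg, FS)
        for name in ("range", "std", "energy", "zcr", "shen"):
            assert vec[IDX[name]] == 0.0

    def test_dominant_frequency_of_2hz_sine(self):
        x = _sine(2.0, phase=math.pi / 4)
        seg = make_segment(x, x)
        vec = extract_window_features(seg, FS)
        assert vec[IDX["dom_freq"]] == pytest.approx(2.0)
        assert vec[IDX["zcr"]] == pytest.approx(4.0)

    def test_quartiles_ordered(self, short_trace):
        segs = slide_windows(short_trace, WindowSpec())
        for seg in segs[:10]:
            vec = extract_window_features(seg, FS)
            assert vec[IDX["q1"]] <= vec[IDX["q2"]] <= vec[IDX["q3"]]

    def test_rejects_nan_input(self):
        x = np.ones(W)
        x[5] = np.nan
        with pytest.raises(ValueError):
            extract_window_features(make_segment(x), FS)

    def test_spectral_features_match_brute_force_dft(self):
        # W=16 toys against an explicit-DFT periodogram oracle
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.standard_normal(16)
            x -= x.mean()
            seg = make_segment(x, x)
            vec = extract_window_features(seg, fs=8.0)
            ref = freq_features_bf(list(x), 8.0)
            for name in ("spec_var", "spec_entropy", "cgf", "dom_freq", "mean_psd"):
                got = vec[IDX[name]]
                assert got == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

    def test_spectral_flux_chains_across_windows_and_starts_at_zero(self, short_trace):
        segs = slide_windows(short_trace, WindowSpec())
        fm, _ = extract_features(segs, FS)
        flux_col = fm.X[:, IDX["spec_flux"]]
        assert flux_col[0] == 0.0
        assert np.any(flux_col[1:] > 0.0)


class TestNormalizer:
    def test_min_max_bounds_small_example(self):
        X = np.array([[2.0], [4.0], [6.0]])
        norm = fit_normalizer(X)
        assert norm.lo[0] == 2.0 and norm.hi[0] == 6.0
        out = apply_normalizer(np.array([[2.0], [3.0], [6.0]]), norm)
        assert np.allclose(out.ravel(), [0.0, 0.25, 1.0])

    def test_constant_feature_maps_to_half(self):
        X = np.full((5, 2), 3.0)
        X[:, 1] = np.arange(5)
        norm = fit_normalizer(X)
        assert norm.constant_mask.tolist() == [True, False]
        out = apply_normalizer(X, norm)
        assert np.all(out[:, 0] == 0.5)

    def test_test_values_outside_training_bounds_are_clipped(self):
        norm = fit_normalizer(np.array([[0.0], [1.0]]))
        out = apply_normalizer(np.array([[-5.0], [0.5], [9.0]]), norm)
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_training_matrix_normalizes_into_unit_interval(self, short_trace):
        segs = slide_windows(short_trace, WindowSpec())
        fm, _ = extract_features(segs, FS)
        norm = fit_normalizer(fm.X)
        out = apply_normalizer(fm.X, norm)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestFeatureCSV:
    def test_round_trip_with_labels(self, short_trace, tmp_path):
        segs = slide_windows(short_trace, WindowSpec())
        fm, y = extract_features(segs, FS)
        fm.to_csv(tmp_path / "f.csv", labels=y)
        back, y_back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        assert back.names == FEATURE_NAMES
        assert np.allclose(back.X, fm.X, rtol=1e-9)
        assert np.array_equal(y_back, y)
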