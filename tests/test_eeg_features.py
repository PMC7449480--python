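"""EEG measures against independent brute-force oracles and closed forms."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anespk.cohort import EpochedSignal
from anespk.eeg_features import (SpectralEstimate, approximate_entropy,
                                 default_eeg_catalog, eeg_feature_matrix,
                                 estimate_spectrum, hurst_exponent,
                                 lempel_ziv_complexity, lz76_word_count,
                                 permutation_entropy, qwsmf, spectral_entropy,
                                 wsmf)

FS = 1000.0


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def apen_oracle(x, m, r):
    """Naive double-loop Pincus ApEn, self-matches included."""
    n = len(x)

    def phi(mm):
        vecs = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for v in vecs:
            c = sum(1 for w in vecs
                    if max(abs(a - b) for a, b in zip(v, w)) <= r)
            total += math.log(c / len(vecs))
        return total / len(vecs)

    return phi(m) - phi(m + 1)


def lz76_oracle(bits):
    """Word-by-word exhaustive-history parse from the definition."""
    s = "".join(str(int(b)) for b in bits)
    words, i, n = [], 0, len(s)
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[:i + k - 1]:
            k += 1
        words.append(s[i:i + min(k, n - i)])
        i += k
    return len(words)


def peen_oracle(x, order, lag):
    """Exhaustive ordinal-pattern count with stable ranking."""
    pats = []
    for i in range(len(x) - (order - 1) * lag):
        w = [x[i + j * lag] for j in range(order)]
        pats.append(tuple(sorted(range(order), key=lambda j: (w[j], j))))
    counts = Counter(pats)
    n = len(pats)
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return h / math.log(math.factorial(order))


def fgn(h_target, n, seed):
    """Fractional Gaussian noise by circulant embedding (Davies-Harte)."""
    k = np.arange(n + 1)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * h_target)
                   - 2 * np.abs(k) ** (2 * h_target)
                   + np.abs(k - 1) ** (2 * h_target))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam[lam < 0] = 0.0
    rng = np.random.default_rng(seed)
    m = len(row)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / (2 * m)) * z)
    return x.real[:n]


# ---------------------------------------------------------------------------
# spectral measures
# ---------------------------------------------------------------------------

class TestSpectrum:
    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20000)
        est = estimate_spectrum(x, FS, (0.0, FS / 2))
        df = est.frequencies[1] - est.frequencies[0]
        assert est.power.sum() * df == pytest.approx(x.var(), rel=0.1)

    def test_sine_dominant_bin(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        est = estimate_spectrum(x, FS, (0.5, 49.0), nperseg=2000)
        assert est.frequencies[np.argmax(est.power)] == pytest.approx(10.0, abs=0.5)

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            estimate_spectrum(np.zeros(1000), FS, (0.5, 600.0))


class TestWSMF:
    def test_pure_sine_median(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        est = estimate_spectrum(x, FS, (0.5, 49.0), nperseg=2000)
        assert wsmf(est) == pytest.approx(10.0, abs=0.5)

    def test_flat_spectrum_analytic_midpoint(self):
        freqs = np.linspace(0.5, 49.0, 98)
        est = SpectralEstimate(freqs, np.ones_like(freqs), (0.5, 49.0))
        # uniform density over [0.5, 49]: median at the midpoint 24.75
        assert wsmf(est) == pytest.approx(24.75, abs=0.5)

    def test_two_equal_lines_interpolation(self):
        # two equal-power lines at 5 and 15 Hz: exactly half of the
        # cumulative power is reached at the 5 Hz line, so the smallest
        # frequency attaining 50% is 5 Hz
        freqs = np.array([1.0, 5.0, 15.0])
        power = np.array([0.0, 1.0, 1.0])
        est = SpectralEstimate(freqs, power, (1.0, 15.0))
        assert wsmf(est) == pytest.approx(5.0, abs=1e-9)

    def test_weighting_changes_median(self):
        freqs = np.array([5.0, 15.0])
        est = SpectralEstimate(freqs, np.array([1.0, 1.0]), (5.0, 15.0))
        up = wsmf(est, weighting=np.array([0.1, 1.0]))
        down = wsmf(est, weighting=np.array([1.0, 0.1]))
        assert up > down

    def test_zero_power_rejected(self):
        est = SpectralEstimate(np.array([1.0, 2.0]), np.zeros(2), (1.0, 2.0))
        with pytest.raises(ValueError):
            wsmf(est)

    def test_gain_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10000)
        a = wsmf(estimate_spectrum(x, FS, (0.5, 49.0)))
        b = wsmf(estimate_spectrum(7.3 * x, FS, (0.5, 49.0)))
        assert a == pytest.approx(b, rel=1e-9)


class TestQWSMF:
    def test_identical_bands_unity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10000)
        assert qwsmf(x, FS, (0.5, 49.0), (0.5, 49.0)) == pytest.approx(1.0)

    def test_ratio_of_medians(self):
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        val = qwsmf(x, FS, (8.0, 30.0), (0.5, 49.0), nperseg=2000)
        assert val == pytest.approx(1.0, abs=0.1)    # both medians at 10 Hz

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            qwsmf(np.zeros(4096), FS, (8.0, 30.0), (0.5, 49.0))


class TestSpectralEntropy:
    def test_single_bin_zero(self):
        freqs = np.array([10.0])
        est = SpectralEstimate(freqs, np.array([3.0]), (5.0, 15.0))
        assert spectral_entropy(est) == 0.0

    def test_flat_is_one(self):
        freqs = np.linspace(1, 40, 64)
        est = SpectralEstimate(freqs, np.ones(64), (1.0, 40.0))
        assert spectral_entropy(est) == pytest.approx(1.0)

    def test_half_uniform_closed_form(self):
        n = 64
        power = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        est = SpectralEstimate(np.linspace(1, 40, n), power, (1.0, 40.0))
        assert spectral_entropy(est) == pytest.approx(
            math.log(n // 2) / math.log(n))

    def test_zero_power_rejected(self):
        est = SpectralEstimate(np.array([1.0, 2.0]), np.zeros(2), (1.0, 2.0))
        with pytest.raises(ValueError):
            spectral_entropy(est)


# ---------------------------------------------------------------------------
# nonlinear measures
# ---------------------------------------------------------------------------

class TestHurst:
    def test_white_noise_near_half(self):
        rng = np.random.default_rng(3)
        vals = [hurst_exponent(rng.standard_normal(8192)) for _ in range(5)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_fgn_parameter_recovery(self):
        vals = [hurst_exponent(fgn(0.8, 8192, seed)) for seed in range(5)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            hurst_exponent(np.ones(4096))


class TestApEn:
    def test_constant_sequence_zero(self):
        assert approximate_entropy(np.ones(100), m=2, r=0.5) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(50)
        r = 0.2 * x.std()
        assert approximate_entropy(x, 2, r) == pytest.approx(
            apen_oracle(x, 2, r), abs=1e-10)

    def test_noise_more_irregular_than_sine(self):
        rng = np.random.default_rng(4)
        n = 1000
        sine = np.sqrt(2.0) * np.sin(2 * np.pi * 8 * np.arange(n) / FS)
        noise = rng.standard_normal(n)          # equal (unit) variance
        r = 0.2
        assert approximate_entropy(noise, 2, r) > approximate_entropy(sine, 2, r)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.arange(50.0), 2, r=0.0)


class TestLZC:
    def test_constant_string_minimal(self):
        assert lz76_word_count([0] * 16) == 2     # "0" + "000000000000000"

    def test_classic_parse_example(self):
        # 0001101001000101 parses into 0|001|10|100|1000|101
        bits = [int(c) for c in "0001101001000101"]
        assert lz76_word_count(bits) == 6
        assert lz76_oracle(bits) == 6

    @pytest.mark.parametrize("n", [10, 37, 100])
    def test_word_count_matches_oracle(self, n):
        rng = np.random.default_rng(n)
        bits = (rng.random(n) > 0.5).astype(int)
        assert lz76_word_count(bits) == lz76_oracle(bits)

    def test_iid_noise_normalization_limit(self):
        rng = np.random.default_rng(5)
        val = lempel_ziv_complexity(rng.standard_normal(10000))
        assert val == pytest.approx(1.0, abs=0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        assert lempel_ziv_complexity(x) == lempel_ziv_complexity(5.0 * x + 3.0)


class TestPeEn:
    def test_monotone_ramp_zero(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_iid_noise_tends_to_one(self):
        rng = np.random.default_rng(7)
        assert permutation_entropy(rng.standard_normal(100000)) > 0.999

    @pytest.mark.parametrize("order,lag", [(3, 1), (3, 2), (4, 1)])
    def test_matches_enumeration_oracle(self, order, lag):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        assert permutation_entropy(x, order, lag) == pytest.approx(
            peen_oracle(x, order, lag), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            permutation_entropy(np.arange(3.0), order=4, lag=1)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_and_range(self, seed):
        x = np.random.default_rng(seed).standard_normal(80)
        v = permutation_entropy(x)
        assert 0.0 <= v <= 1.0
        assert permutation_entropy(2.5 * x + 1.0) == pytest.approx(v, abs=1e-12)


# ---------------------------------------------------------------------------
# catalog / feature matrix
# ---------------------------------------------------------------------------

class TestFeatureMatrix:
    def test_default_catalog_has_23_named_columns(self):
        specs = default_eeg_catalog()
        names = [s.name for s in specs]
        assert len(names) == 23 and len(set(names)) == 23

    def test_matrix_columns_and_rows(self, small_cohort):
        _, epochs, _ = small_cohort
        tab = eeg_feature_matrix(epochs[:4])
        assert list(tab.columns[:3]) == ["patient_id", "event", "state"]
        assert tab.shape == (4, 3 + 23)
        assert tab.notna().all().all()

    def test_empty_epoch_list(self):
        tab = eeg_feature_matrix([])
        assert len(tab) == 0 and len(tab.columns) == 3 + 23

    def test_duplicate_spec_names_rejected(self):
        specs = default_eeg_catalog()
        with pytest.raises(ValueError):
            eeg_feature_matrix([], specs=[specs[0], specs[0]])

    def test_artifact_epoch_row_absent(self, small_cohort):
        _, epochs, _ = small_cohort
        clean = epochs[0]
        flat = EpochedSignal(samples=np.zeros_like(clean.samples),
                             sampling_rate=clean.sampling_rate,
                             patient_id="PX", event_label="LOC1",
                             state="unconscious")
        tab = eeg_feature_matrix([clean, flat])
        assert len(tab) == 1
        assert "PX" not in set(tab["patient_id"])
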