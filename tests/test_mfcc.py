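"""MFCC extraction: Mel mapping, filterbank, framing, log powers, DCT,
beat feature assembly — each validated against independent brute-force
oracles or closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ranksums

from pcgkit import (
    BeatTemplate,
    FrameSpec,
    beat_feature_vector,
    design_filterbank,
    extract_beats,
    generate_signal,
    hz_to_mel,
    mel_to_hz,
    preprocess,
)
from pcgkit.mfcc import (
    POWER_FLOOR,
    dct2_coefficients,
    frame_dft,
    frame_segment,
    mel_log_powers,
    segment_mfcc,
)
from pcgkit.segment import resample_states


# ---------------------------------------------------------------- oracles
def dft_oracle(x, n_points):
    """Direct O(N^2) evaluation of the DFT definition, bins 0..N/2."""
    x = np.asarray(x, dtype=float)
    out = []
    for k in range(n_points // 2 + 1):
        acc = 0.0 + 0.0j
        for n, xn in enumerate(x):
            acc += xn * np.exp(-2j * np.pi * k * n / n_points)
        out.append(acc)
    return np.array(out)


def filterbank_oracle(m_filters, f_min, f_max, rate, n_points):
    """Per-bin triangular response from the Mel-design definition."""

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def inv_mel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mels = [mel(f_min) + j * (mel(f_max) - mel(f_min)) / (m_filters + 1) for j in range(m_filters + 2)]
    bins = [int(np.floor(inv_mel(m) / rate * n_points)) for m in mels]
    resp = np.zeros((m_filters, n_points // 2 + 1))
    for m in range(m_filters):
        lo, center, hi = bins[m], bins[m + 1], bins[m + 2]
        for k in range(n_points // 2 + 1):
            if k < lo or k > hi:
                resp[m, k] = 0.0
            elif k < center:
                resp[m, k] = (k - lo) / (center - lo)
            elif hi == center:
                resp[m, k] = 1.0
            else:
                resp[m, k] = (hi - k) / (hi - center)
    return np.array(bins), resp


def dct2_oracle(p):
    """Double-loop evaluation of the unnormalized DCT-II."""
    m_filters = len(p)
    out = np.zeros(m_filters)
    for k in range(m_filters):
        for m in range(m_filters):
            out[k] += p[m] * np.cos(np.pi / m_filters * (m + 0.5) * k)
    return out


# ------------------------------------------------------------- mel scale
class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert hz_to_mel(0.0) == 0.0

    def test_700_hz_closed_form(self):
        assert np.isclose(hz_to_mel(700.0), 2595.0 * np.log10(2.0))

    @pytest.mark.parametrize("freq", [50.0, 123.4, 400.0])
    def test_round_trip(self, freq):
        assert np.isclose(mel_to_hz(hz_to_mel(freq)), freq, rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)

    @given(st.floats(min_value=0.0, max_value=2000.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_and_monotone(self, freq):
        assert np.isclose(mel_to_hz(hz_to_mel(freq)), freq, rtol=1e-9, atol=1e-9)
        assert hz_to_mel(freq + 1.0) > hz_to_mel(freq)


# ------------------------------------------------------------ filterbank
class TestFilterbank:
    def test_default_edge_bins(self):
        fb = design_filterbank()
        assert fb.center_bins[0] == 0  # f_min = 0
        assert fb.center_bins[-1] == 25  # floor(400/1000 * 64)

    def test_matches_brute_force_oracle(self):
        fb = design_filterbank()
        bins, resp = filterbank_oracle(20, 0.0, 400.0, 1000.0, 64)
        np.testing.assert_array_equal(fb.center_bins, bins)
        np.testing.assert_allclose(fb.responses, resp, rtol=0, atol=1e-12)

    def test_bins_nondecreasing_and_peak_one(self):
        fb = design_filterbank()
        assert np.all(np.diff(fb.center_bins) >= 0)
        np.testing.assert_allclose(fb.responses.max(axis=1), 1.0)

    def test_triangles_zero_outside_support(self):
        fb = design_filterbank()
        for m in range(fb.n_filters):
            lo, hi = fb.center_bins[m], fb.center_bins[m + 2]
            k = np.arange(fb.responses.shape[1])
            outside = (k < lo) | (k > hi)
            np.testing.assert_array_equal(fb.responses[m, outside], 0.0)

    def test_f_max_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_filterbank(f_max=600.0, sample_rate=1000.0)


# --------------------------------------------------------------- framing
class TestFraming:
    SPEC = FrameSpec()

    def test_single_exact_frame(self):
        frames = frame_segment(np.ones(24), self.SPEC, 1000.0)
        assert frames.shape == (1, 24)

    def test_36ms_gives_three_frames(self):
        frames = frame_segment(np.ones(36), self.SPEC, 1000.0)
        assert frames.shape == (3, 24)

    def test_short_segment_single_whole_frame(self):
        frames = frame_segment(np.ones(10), self.SPEC, 1000.0)
        assert frames.shape == (1, 10)

    def test_hamming_window_applied(self):
        frames = frame_segment(np.ones(24), self.SPEC, 1000.0)
        np.testing.assert_allclose(frames[0], np.hamming(24))

    def test_frames_start_at_hop_multiples(self):
        x = np.arange(48, dtype=float)
        frames = frame_segment(x, self.SPEC, 1000.0)
        window = np.hamming(24)
        for i, frame in enumerate(frames):
            np.testing.assert_allclose(frame, x[i * 6 : i * 6 + 24] * window)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            frame_segment(np.array([]), self.SPEC, 1000.0)


# ------------------------------------------------------ DFT / log powers
class TestMelLogPowers:
    def test_dft_matches_definition_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal(24)
            np.testing.assert_allclose(
                frame_dft(x, 64), dft_oracle(x, 64), rtol=1e-9, atol=1e-9
            )

    def test_all_zero_frame_hits_power_floor(self):
        fb = design_filterbank()
        p = mel_log_powers(np.zeros(24), fb)
        np.testing.assert_allclose(p, 10.0 * np.log10(POWER_FLOOR))
        assert np.all(np.isfinite(p))

    def test_amplitude_doubling_adds_6db(self, rng):
        fb = design_filterbank()
        x = rng.standard_normal(24)
        shift = mel_log_powers(2.0 * x, fb) - mel_log_powers(x, fb)
        np.testing.assert_allclose(shift, 20.0 * np.log10(2.0), rtol=1e-9)

    def test_matches_direct_weighted_sum(self, rng):
        fb = design_filterbank()
        x = rng.standard_normal(24)
        spectrum = dft_oracle(x, 64)
        expected = [
            10.0
            * np.log10(
                max(
                    np.sum(np.abs(spectrum) ** 2 * np.abs(fb.responses[m])) / 64.0,
                    POWER_FLOOR,
                )
            )
            for m in range(20)
        ]
        np.testing.assert_allclose(mel_log_powers(x, fb), expected, rtol=1e-9)

    def test_squared_response_variant_differs(self, rng):
        fb = design_filterbank()
        x = rng.standard_normal(24)
        assert not np.allclose(
            mel_log_powers(x, fb, response_power=1),
            mel_log_powers(x, fb, response_power=2),
        )


# -------------------------------------------------------------- DCT-II
class TestDct2:
    def test_constant_input_identity(self):
        c = dct2_coefficients(np.full(20, 3.5))
        assert np.isclose(c[0], 20 * 3.5)
        np.testing.assert_allclose(c[1:], 0.0, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            p = rng.standard_normal(20)
            np.testing.assert_allclose(
                dct2_coefficients(p), dct2_oracle(p), rtol=1e-9, atol=1e-9
            )

    def test_shape_preserved(self, rng):
        assert dct2_coefficients(rng.standard_normal(20)).shape == (20,)


# ------------------------------------------------------ segment features
class TestSegmentMfcc:
    FB = design_filterbank()
    SPEC = FrameSpec()

    def test_single_frame_segment_equals_frame_coefficients(self, rng):
        seg = rng.standard_normal(24)
        direct = dct2_coefficients(
            mel_log_powers(seg * np.hamming(24), self.FB)
        )[:13]
        np.testing.assert_allclose(segment_mfcc(seg, self.SPEC, self.FB), direct)

    def test_mean_idempotent_for_identical_frames(self, rng):
        # hop-periodic segment: every frame sees the same samples, so the
        # frame-averaged descriptor equals the single-frame descriptor
        period = rng.standard_normal(6)
        seg_one = np.tile(period, 4)  # 24 samples -> 1 frame
        seg_many = np.tile(period, 8)  # 48 samples -> 5 identical frames
        np.testing.assert_allclose(
            segment_mfcc(seg_many, self.SPEC, self.FB),
            segment_mfcc(seg_one, self.SPEC, self.FB),
        )

    def test_output_length_13(self, rng):
        assert segment_mfcc(rng.standard_normal(200), self.SPEC, self.FB).shape == (13,)

    def test_invariant_to_subhop_zero_padding(self, rng):
        # last frame ends flush with the segment: padding shorter than one
        # hop cannot admit a new frame, so the descriptor is unchanged
        seg = rng.standard_normal(24 + 6 * 10)
        base = segment_mfcc(seg, self.SPEC, self.FB)
        for pad in range(1, 6):
            padded = np.concatenate([seg, np.zeros(pad)])
            np.testing.assert_allclose(segment_mfcc(padded, self.SPEC, self.FB), base)


class TestBeatFeatureVector:
    def features_for(self, template, n_beats=9, seed=0):
        sig, truth = generate_signal(template, n_beats, seed=seed, label="unknown")
        pre = preprocess(sig)
        states = resample_states(truth, sig.sample_rate, pre.sample_rate, len(pre))
        beats = extract_beats(states, n=n_beats)
        return pre, beats

    def test_52_finite_values(self, noisy_template):
        pre, beats = self.features_for(noisy_template)
        vec = beat_feature_vector(pre, beats[0])
        assert vec.values.shape == (52,)
        assert np.all(np.isfinite(vec.values))

    def test_deterministic(self, noisy_template):
        pre, beats = self.features_for(noisy_template)
        a = beat_feature_vector(pre, beats[2], beat_index=2)
        b = beat_feature_vector(pre, beats[2], beat_index=2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_out_of_bounds_beat_rejected(self, clean_template):
        pre, beats = self.features_for(clean_template)
        from pcgkit import Beat

        n = len(pre)
        bad = Beat(s1=(n - 30, n - 20), systole=(n - 20, n - 10), s2=(n - 10, n), diastole=(n, n + 100))
        with pytest.raises(ValueError):
            beat_feature_vector(pre, bad)

    def test_murmur_shifts_systole_coefficients(self):
        """Rank-sum on the systole block's first cepstral coefficient
        separates abnormal from normal beats at n=50 beats per class."""

        def systole_c0(murmur):
            template = BeatTemplate(murmur_amplitude=murmur, noise_sd=0.05)
            values = []
            for seed in range(6):  # 6 signals x 9 beats > 50 beats
                pre, beats = self.features_for(template, seed=seed)
                for i, beat in enumerate(beats):
                    values.append(beat_feature_vector(pre, beat, beat_index=i).values[13])
            return np.array(values[:50])

        stat = ranksums(systole_c0(0.5), systole_c0(0.0))
        assert stat.pvalue < 1e-6
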