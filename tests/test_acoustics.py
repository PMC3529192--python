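"""Tests for spectrogram computation, F0 estimation and segment measurement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from closecall import acoustics
from closecall.acoustics import (FEATURE_COLUMNS, SpectrogramParams,
                                 compute_spectrogram, estimate_f0,
                                 extract_features, measure_segment)
from closecall.synth import (ControlSpec, SyntheticConfig,
                             draw_individual_profile, synthesize_call,
                             _default_controls)

SR = 44100.0
PARAMS = SpectrogramParams(sample_rate=SR)


def sine(freq: float, duration: float, sr: float = SR) -> np.ndarray:
    t = np.arange(int(round(duration * sr))) / sr
    return np.sin(2 * np.pi * freq * t)


def harmonic_stack(f0: float, duration: float, n_partials: int = 5,
                   sr: float = SR) -> np.ndarray:
    t = np.arange(int(round(duration * sr))) / sr
    return sum(10 ** (-6 * (k - 1) / 20) * np.sin(2 * np.pi * k * f0 * t)
               for k in range(1, n_partials + 1))


class TestSpectrogramParams:
    def test_bin_width_43_hz(self):
        assert round(PARAMS.bin_width) == 43
        assert PARAMS.bin_width == pytest.approx(43.0664, abs=1e-3)

    def test_hop_32_samples(self):
        # round(1024 * (1 - 0.9687)) = 32
        assert PARAMS.hop == 32

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            SpectrogramParams(sample_rate=SR, fft_size=1000)

    def test_excessive_overlap_rejected(self):
        with pytest.raises(ValueError):
            SpectrogramParams(sample_rate=SR, overlap_fraction=0.9999)


class TestComputeSpectrogram:
    def test_bin_centred_tone_peaks_at_its_bin(self):
        # 430.664 Hz is exactly bin 10 of a 1,024-point FFT at 44.1 kHz
        spec = compute_spectrogram(sine(10 * PARAMS.bin_width, 0.1), PARAMS)
        assert np.all(np.argmax(spec.power, axis=1) == 10)

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(np.zeros(1000), PARAMS)

    def test_shapes_and_axes(self):
        spec = compute_spectrogram(sine(440, 0.1), PARAMS)
        assert spec.power.shape == (len(spec.times), len(spec.freqs))
        assert np.all(spec.power >= 0)
        assert np.all(np.diff(spec.times) > 0)
        assert spec.freqs[0] == 0.0
        assert spec.freqs[-1] == pytest.approx(SR / 2)


class TestEstimateF0:
    def test_pure_sine(self):
        track = estimate_f0(sine(440, 0.2), SR)
        voiced = track.f0[track.voiced]
        assert voiced.size == track.f0.size
        for point in (voiced[0], voiced[len(voiced) // 2], voiced[-1]):
            assert point == pytest.approx(440, abs=2)

    def test_harmonic_stack_no_octave_error(self):
        track = estimate_f0(harmonic_stack(350, 0.2), SR)
        assert np.nanmean(track.f0) == pytest.approx(350, abs=5)
        # no estimate near 175 (octave down) or 700 (octave up)
        assert np.all(np.abs(track.f0[track.voiced] - 350) < 20)

    def test_white_noise_unvoiced(self):
        rng = np.random.default_rng(0)
        track = estimate_f0(rng.standard_normal(int(0.2 * SR)), SR)
        assert np.mean(track.voiced) < 0.2

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="two"):
            estimate_f0(sine(440, 0.01), SR)   # < 2 periods of 100 Hz

    def test_out_of_range_flagged(self):
        track = estimate_f0(sine(50, 0.2), SR, search_range=(100.0, 1000.0))
        assert not np.all(track.voiced)


class TestMeasureSegment:
    def test_pure_tone_quartiles_and_bandwidth(self):
        feats = measure_segment(sine(440, 0.12), (0.0, 0.1), PARAMS)
        assert feats.duration == pytest.approx(0.1)
        bw = PARAMS.bin_width
        for q in (feats.q25_mean, feats.q50_mean, feats.q75_mean,
                  feats.q25_max, feats.q50_max, feats.q75_max):
            assert q == pytest.approx(440, abs=1.5 * bw)
        assert feats.bandwidth_mean < 3 * bw
        assert feats.min_freq <= feats.peak_frequency_mean <= feats.max_freq

    def test_constant_f0_zero_transitions(self):
        feats = measure_segment(sine(440, 0.2), (0.0, 0.2), PARAMS)
        assert feats.onset == pytest.approx(0, abs=3)
        assert feats.offset == pytest.approx(0, abs=3)
        assert feats.f0_mean == pytest.approx(440, abs=3)

    def test_linear_chirp_transitions(self):
        # 500 -> 300 Hz over 0.5 s: F0 at onset/middle/end ~ 500/400/300,
        # so onset ~ +100 Hz and offset ~ +100 Hz (less the half-window
        # pull-in at both ends)
        dur = 0.5
        t = np.arange(int(dur * SR)) / SR
        phase = 2 * np.pi * (500 * t - 0.5 * (200 / dur) * t**2)
        feats = measure_segment(np.sin(phase), (0.0, dur), PARAMS)
        assert feats.onset == pytest.approx(100, abs=25)
        assert feats.offset == pytest.approx(100, abs=25)

    def test_span_outside_audio_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            measure_segment(sine(440, 0.1), (0.0, 0.2), PARAMS)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            measure_segment(np.zeros(int(0.1 * SR)), (0.0, 0.1), PARAMS)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_quartile_monotonicity_property(self, seed):
        rng = np.random.default_rng(seed)
        wave = rng.standard_normal(int(0.08 * SR))
        feats = measure_segment(wave, (0.0, 0.08), PARAMS)
        assert feats.q25_mean <= feats.q50_mean <= feats.q75_mean
        assert feats.q25_max <= feats.q50_max <= feats.q75_max
        assert feats.min_freq <= feats.max_freq
        assert feats.bandwidth_mean == feats.max_freq - feats.min_freq

    def test_energy_normalization(self):
        # the cumulative energy used for quartiles reaches exactly the
        # total mean-spectrum energy at the Nyquist bin
        rng = np.random.default_rng(7)
        spec = compute_spectrogram(rng.standard_normal(int(0.1 * SR)), PARAMS)
        mean_spectrum = spec.power.mean(axis=0)
        cum = np.cumsum(mean_spectrum)
        assert cum[-1] == pytest.approx(mean_spectrum.sum(), rel=1e-12)
        (q100,) = acoustics._quartile_freqs(mean_spectrum, spec.freqs,
                                            fractions=(1.0,))
        assert q100 == pytest.approx(spec.freqs[-1])

    def test_threshold_monotone_bandwidth(self):
        rng = np.random.default_rng(11)
        spec = compute_spectrogram(rng.standard_normal(int(0.1 * SR)), PARAMS)
        mean_spectrum = spec.power.mean(axis=0)
        widths = []
        for thr in (-20.0, -15.0, -10.0, -5.0, -1.0):
            lo, hi = acoustics._band_edges(mean_spectrum, spec.freqs, thr)
            widths.append(hi - lo)
        assert all(a >= b for a, b in zip(widths, widths[1:]))


class TestGeneratorRoundTrip:
    def test_measured_harmonic_f0_tracks_drawn_f0(self):
        # generator/extractor round trip over 50 calls: measured harmonic
        # F0 within 5% of the F0 the generator drew
        cfg = SyntheticConfig(seed=31)
        profile = draw_individual_profile(cfg, "g1", "a")
        from closecall.synth import _draw_controls
        errors = []
        for k in range(50):
            rng_draw = np.random.default_rng([4, k])
            rng_call = np.random.default_rng([4, k])
            drawn = _draw_controls(profile, "moving", cfg, rng_draw)
            wave, ann = synthesize_call(profile, "moving", cfg, rng_call)
            feats = measure_segment(wave, ann.harmonic_span, PARAMS)
            errors.append(abs(feats.f0_mean - drawn["harmonic_f0"])
                          / drawn["harmonic_f0"])
        assert np.median(errors) < 0.02
        assert np.mean(np.array(errors) < 0.05) >= 0.9

    def test_zero_sd_duration_roundtrip(self):
        controls = {name: ControlSpec(spec.means, 0.0, 0.0, 0.0)
                    for name, spec in _default_controls().items()}
        cfg = SyntheticConfig(controls=controls, seed=2)
        profile = draw_individual_profile(cfg, "g1", "a")
        wave, ann = synthesize_call(profile, "moving", cfg,
                                    np.random.default_rng(0))
        feats = measure_segment(wave, ann.harmonic_span, PARAMS)
        assert feats.duration == pytest.approx(0.08, abs=1 / SR)
        assert feats.f0_mean == pytest.approx(472, rel=0.01)


class TestExtractFeatures:
    def test_row_structure(self, small_features, small_dataset):
        annotations, _ = small_dataset
        n_calls = len(annotations)
        whole = small_features[small_features["segment"] == "whole"]
        noisy = small_features[small_features["segment"] == "noisy"]
        harmonic = small_features[small_features["segment"] == "harmonic"]
        assert len(whole) == len(noisy) == n_calls
        n_harmonic_spans = annotations["harmonic_start"].notna().sum()
        assert len(harmonic) <= n_harmonic_spans
        assert list(small_features.columns) == [
            "call_id", "segment", "individual_id", "group_id", "sex",
            "context", *FEATURE_COLUMNS]

    def test_suppressed_harmonic_has_no_row(self, small_features,
                                            small_dataset):
        annotations, _ = small_dataset
        absent = annotations[annotations["harmonic_start"].isna()]["call_id"]
        harmonic = small_features[small_features["segment"] == "harmonic"]
        assert not harmonic["call_id"].isin(set(absent)).any()
        assert len(absent) > 0   # default suppression probability is 0.5

    def test_completeness_report_attached(self, small_features):
        completeness = small_features.attrs["completeness"]
        assert set(completeness.columns) == {"digging", "searching", "moving"}
        assert (completeness.to_numpy() == 5).all()

    def test_missing_file_lists_call_id(self, small_dataset, tmp_path):
        annotations, _ = small_dataset
        with pytest.raises(FileNotFoundError, match="g1i01"):
            extract_features(annotations.head(3), tmp_path)

    def test_extracted_context_ordering(self, small_features):
        harmonic = small_features[small_features["segment"] == "harmonic"]
        means = harmonic.groupby("context")["duration"].mean()
        assert means["digging"] < means["searching"] < means["moving"]

    def test_within_vs_between_individual_variance(self, small_features):
        # the noisy-segment spectral signature is individually stable:
        # between-individual variance exceeds mean within-individual variance
        noisy = small_features[small_features["segment"] == "noisy"]
        by_ind = noisy.groupby("individual_id")["q25_mean"]
        ratio = by_ind.mean().var() / by_ind.var().mean()
        assert ratio > 1.0
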