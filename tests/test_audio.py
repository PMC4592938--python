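"""Filtering, segmentation, feature extraction and classification."""

import numpy as np
import pytest

from callnet import (
    DEFAULT_ARCHETYPES,
    SegmentationParams,
    classify_kmeans,
    detect_syllables,
    extract_features,
    highpass,
    map_clusters_to_types,
    synth_recording,
    synth_syllable,
)
from callnet.audio import (
    features_to_array,
    low_frequency_power_ratio,
    rank_focal_channel,
)
from callnet.types import ConfigError

SR = 44100


def tone(freq, duration, sr=SR, amp=0.5):
    t = np.arange(int(duration * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(x**2))


class TestHighpass:
    def test_stopband_one_octave_below_cutoff(self):
        x = tone(50, 1.0)
        y = highpass(x, SR, 200.0)
        assert rms(y) < 0.1 * rms(x)

    def test_passband_within_one_db(self):
        x = tone(1000, 1.0)
        y = highpass(x, SR, 200.0)
        assert abs(20 * np.log10(rms(y) / rms(x))) < 1.0

    def test_zero_in_zero_out(self):
        x = np.zeros(1000)
        assert not highpass(x, SR).any()

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            highpass(tone(100, 0.1), SR, cutoff=SR / 2)


class TestDetectSyllables:
    def test_pure_noise_yields_nothing(self, rng):
        w = rng.standard_normal(SR) * 1e-3  # -60 dBFS noise
        assert detect_syllables(w, SR) == []

    def test_all_zero_audio_yields_nothing(self):
        assert detect_syllables(np.zeros(SR), SR) == []

    def test_audio_shorter_than_frame_rejected(self):
        with pytest.raises(ConfigError):
            detect_syllables(np.zeros(100), SR)

    def test_short_gap_merges_two_tones(self, rng):
        gap = 0.002  # below the 5 ms merge threshold
        w = np.concatenate(
            [
                rng.standard_normal(int(0.3 * SR)) * 1e-4,
                tone(2000, 0.05),
                np.zeros(int(gap * SR)),
                tone(2000, 0.05),
                rng.standard_normal(int(0.3 * SR)) * 1e-4,
            ]
        )
        assert len(detect_syllables(w, SR)) == 1

    def test_long_gap_keeps_two_detections(self, rng):
        w = np.concatenate(
            [
                rng.standard_normal(int(0.3 * SR)) * 1e-4,
                tone(2000, 0.05),
                np.zeros(int(0.2 * SR)),
                tone(2000, 0.05),
                rng.standard_normal(int(0.3 * SR)) * 1e-4,
            ]
        )
        assert len(detect_syllables(w, SR)) == 2

    def test_closed_loop_onset_accuracy(self, rng):
        import pandas as pd

        onsets = np.arange(10) * 0.5 + 0.25
        ev = pd.DataFrame(
            {
                "bird_id": "A",
                "call_type": rng.choice(list(DEFAULT_ARCHETYPES), 10),
                "onset_s": onsets,
            }
        )
        waves, truth = synth_recording(ev, noise_floor_db=-40.0, duration=6.0,
                                       rng=np.random.default_rng(8))
        detections = detect_syllables(highpass(waves["A"], SR), SR)
        assert len(detections) == 10
        for onset, _ in detections:
            err = np.min(np.abs(truth.onset_s.to_numpy() - onset))
            assert err < 0.010


class TestExtractFeatures:
    def test_stationary_tone_features(self):
        w = tone(1000, 0.1)
        f = extract_features(w, SR)
        bin_hz = SR / 512
        assert f.duration == pytest.approx(0.1, abs=1e-3)
        assert abs(f.mode_freq - 1000) <= bin_hz
        assert abs(f.first_peak - 1000) <= bin_hz
        assert abs(f.mean_freq - 1000) <= 2 * bin_hz
        assert f.mode_freq_sd == pytest.approx(0.0, abs=bin_hz)
        assert f.wiener_entropy < -5

    def test_white_noise_entropy_near_zero(self, rng):
        w = rng.standard_normal(int(0.2 * SR)) * 0.3
        f = extract_features(w, SR)
        assert f.wiener_entropy > -1.5

    def test_linear_chirp_spreads_mode_frequency(self):
        t = np.arange(int(0.2 * SR)) / SR
        from scipy.signal import chirp

        w = 0.5 * chirp(t, 2000, t[-1], 4000)
        f = extract_features(w, SR)
        assert f.mode_freq_sd > 100
        assert f.mean_freq == pytest.approx(3000, rel=0.15)

    def test_interval_selects_within_audio(self):
        w = np.concatenate([np.zeros(SR // 2), tone(3000, 0.1), np.zeros(SR // 2)])
        f = extract_features(w, SR, interval=(0.5, 0.6))
        assert abs(f.mode_freq - 3000) <= SR / 512

    def test_interval_shorter_than_two_frames_rejected(self):
        with pytest.raises(ConfigError):
            extract_features(tone(1000, 1.0), SR, interval=(0.0, 0.01))

    def test_translation_invariance(self):
        w1, _ = synth_syllable(DEFAULT_ARCHETYPES["distance"], SR, seed=5)
        pad = np.zeros(int(0.123 * SR))
        shifted = np.concatenate([pad, w1, pad])
        f1 = extract_features(w1, SR)
        f2 = extract_features(shifted, SR, interval=(0.123, 0.123 + w1.size / SR))
        bin_hz = SR / 512
        a1, a2 = f1.to_array(), f2.to_array()
        assert np.all(np.abs(a1 - a2)[1:] <= np.maximum(bin_hz, 0.1 * np.abs(a1[1:]) + 1e-6))

    def test_amplitude_scaling_invariance(self):
        w, _ = synth_syllable(DEFAULT_ARCHETYPES["cackle"], SR, seed=6)
        f1 = extract_features(w, SR)
        f2 = extract_features(0.5 * w, SR)
        assert np.allclose(f1.to_array(), f2.to_array(), rtol=1e-8, atol=1e-8)


class TestClassification:
    def test_k1_gives_single_label(self, rng):
        X = rng.standard_normal((20, 9))
        labels, centroids = classify_kmeans(X, k=1, seed=0)
        assert set(labels) == {0}
        assert centroids.shape == (1, 9)

    def test_well_separated_clouds_split_perfectly(self, rng):
        a = rng.standard_normal((30, 9))
        b = rng.standard_normal((30, 9)) + 20.0
        labels, _ = classify_kmeans(np.vstack([a, b]), k=2, seed=0)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ConfigError):
            classify_kmeans(rng.standard_normal((3, 9)), k=5)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((50, 9))
        l1, c1 = classify_kmeans(X, k=3, seed=7)
        l2, c2 = classify_kmeans(X, k=3, seed=7)
        assert np.array_equal(l1, l2)
        assert np.allclose(c1, c2)

    def test_centroids_in_original_units(self, rng):
        X = rng.standard_normal((40, 9)) * 1000 + 5000
        _, centroids = classify_kmeans(X, k=2, seed=0)
        assert centroids.min() > 1000  # not z-scored

    def test_archetype_set_clusters_cleanly(self, rng):
        feats, truth = [], []
        for name, arch in DEFAULT_ARCHETYPES.items():
            for _ in range(30):
                w, lbl = synth_syllable(arch, SR, rng=rng)
                feats.append(extract_features(w, SR))
                truth.append(lbl)
        labels, _ = classify_kmeans(features_to_array(feats), k=5, seed=0)
        mapped, _ = map_clusters_to_types(labels, truth)
        assert np.mean(mapped == np.array(truth)) >= 0.95


class TestClusterMapping:
    def test_majority_cluster_maps_to_type(self):
        labels = np.zeros(10, dtype=int)
        ref = ["tet"] * 9 + ["stack"]
        mapped, mapping = map_clusters_to_types(labels, ref)
        assert mapping[0] == "tet"
        assert (mapped == "tet").all()

    def test_sub_majority_cluster_maps_to_other(self):
        labels = np.zeros(10, dtype=int)
        ref = ["tet"] * 4 + ["stack"] * 3 + ["whine"] * 3
        _, mapping = map_clusters_to_types(labels, ref)
        assert mapping[0] == "other"

    def test_map_is_many_to_one(self):
        labels = np.array([0] * 5 + [1] * 5)
        ref = ["stack"] * 10
        _, mapping = map_clusters_to_types(labels, ref)
        assert mapping == {0: "stack", 1: "stack"}

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ConfigError):
            map_clusters_to_types(np.zeros(5, dtype=int), ["tet"] * 4)


class TestCrosstalkRanking:
    def test_focal_channel_has_higher_low_frequency_ratio(self, rng):
        call, _ = synth_syllable(DEFAULT_ARCHETYPES["tet"], SR, seed=2)
        rumble = 0.3 * np.sin(2 * np.pi * 120 * np.arange(call.size) / SR)
        focal = call + rumble  # on-bird: body noise adds low-frequency power
        distant = 0.3 * call
        assert low_frequency_power_ratio(focal, SR) > low_frequency_power_ratio(distant, SR)
        assert rank_focal_channel([distant, focal], SR) == 1
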