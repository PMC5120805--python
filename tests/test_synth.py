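"""Synthetic call generator, scene mixer, template detector, datasets."""

import numpy as np
import pytest

from flightcall.evaluation import estimate_snr
from flightcall.frontend import SpectrogramConfig, logmel_spectrogram
from flightcall.manifest import summarize_manifest
from flightcall.synth import (
    ARCHETYPES,
    BAND,
    CallArchetype,
    DatasetSpec,
    SceneSpec,
    SeasonSpec,
    build_dataset,
    build_monitoring_season,
    mix_scene,
    synth_call,
    template_detector,
)

CFG = SpectrogramConfig()


class TestSynthCall:
    def test_deterministic_per_seed(self):
        a = synth_call(ARCHETYPES["vee"], seed=9)
        b = synth_call(ARCHETYPES["vee"], seed=9)
        assert np.array_equal(a.samples, b.samples)
        c = synth_call(ARCHETYPES["vee"], seed=10)
        assert not np.array_equal(a.samples, c.samples)

    def test_duration_within_flight_call_range(self):
        for key, arch in ARCHETYPES.items():
            clip = synth_call(arch, seed=0)
            assert 50.0 <= clip.duration_ms <= 150.0, key

    def test_invalid_archetype_duration_errors(self):
        with pytest.raises(ValueError, match="duration"):
            CallArchetype("x", "down", 8000, 5000, duration_ms=300.0)

    def test_out_of_band_anchor_errors(self):
        with pytest.raises(ValueError, match="2000-11025"):
            CallArchetype("x", "down", 12000, 5000)

    def test_jittered_contour_outside_band_errors(self):
        # an archetype whose jitter inevitably exceeds the band ceiling
        arch = CallArchetype("x", "up", 5000, 11000, freq_jitter_hz=3000.0)
        with pytest.raises(ValueError, match="band"):
            for seed in range(20):
                synth_call(arch, seed=seed)

    def test_spectrogram_ridge_follows_contour(self):
        # oracle: track the mel-band ridge of the spectrogram and check
        # it matches the programmed 8->5 kHz descent within one band
        arch = CallArchetype("ridge", "down", 8000.0, 5000.0, 100.0, freq_jitter_hz=0.0,
                             duration_jitter_ms=0.0)
        clip = synth_call(arch, seed=0)
        spec = logmel_spectrogram(clip, CFG)
        from flightcall.frontend import mel_filterbank

        _, centers = mel_filterbank(CFG)
        # interior frames (envelope suppresses the edges)
        lo, hi = spec.n_frames // 4, 3 * spec.n_frames // 4
        for t in range(lo, hi):
            ridge = int(np.argmax(spec.values[:, t]))
            frac = (t * CFG.hop_length + CFG.window_length / 2) / clip.n_samples
            f_true = 8000.0 + (5000.0 - 8000.0) * frac
            expected = int(np.argmin(np.abs(centers - f_true)))
            assert abs(ridge - expected) <= 1

    def test_all_archetypes_stay_in_band(self):
        for key, arch in ARCHETYPES.items():
            for seed in range(5):
                clip = synth_call(arch, seed=seed)  # raises if out of band
                assert clip.label == key


class TestMixScene:
    def test_measured_mode_closed_loop_across_range(self):
        call = synth_call(ARCHETYPES["mtail"], seed=1)
        for target in (1.0, 3.0, 10.0, 18.0, 30.0):
            for bg in ("quiet", "wind", "insect"):
                scene = mix_scene(call, SceneSpec(background=bg, snr_db=target, seed=2))
                measured = estimate_snr(scene).snr_db
                assert abs(measured - target) <= 0.5, (bg, target)

    def test_no_call_scene_is_reject(self):
        scene = mix_scene(None, SceneSpec(background="insect", seed=3))
        assert scene.label == "Reject"
        assert scene.duration_ms == pytest.approx(1000.0)

    def test_unreachable_measured_snr_errors(self):
        call = synth_call(ARCHETYPES["dsw"], seed=4)
        with pytest.raises(ValueError, match="unreachable"):
            mix_scene(call, SceneSpec(background="quiet", snr_db=-10.0, seed=5))

    def test_call_mode_realizes_pure_ratio(self):
        # in "call" mode the measured center-vs-rest estimate approaches
        # 10*log10(1 + ratio) for stationary background
        call = synth_call(ARCHETYPES["dsw"], seed=6)
        for target in (-10.0, 0.0, 10.0):
            scene = mix_scene(
                call, SceneSpec(background="quiet", snr_db=target, seed=7, snr_mode="call")
            )
            expected = 10 * np.log10(1 + 10 ** (target / 10))
            assert abs(estimate_snr(scene).snr_db - expected) < 1.0

    def test_buried_call_lowers_confidence(self):
        # monotonicity: a nearly inaudible call must score lower than a
        # loud one under any sensible detector; use band-power contrast
        call = synth_call(ARCHETYPES["dsw"], seed=8)
        quiet = mix_scene(call, SceneSpec("wind", snr_db=-20.0, seed=9, snr_mode="call"))
        loud = mix_scene(call, SceneSpec("wind", snr_db=20.0, seed=9, snr_mode="call"))
        assert estimate_snr(quiet).snr_db < estimate_snr(loud).snr_db - 10

    def test_call_longer_than_clip_errors(self):
        call = synth_call(ARCHETYPES["dsw"], seed=10)
        with pytest.raises(ValueError, match="longer"):
            mix_scene(call, SceneSpec(clip_ms=50.0, seed=11))

    def test_determinism(self):
        call = synth_call(ARCHETYPES["usw"], seed=12)
        a = mix_scene(call, SceneSpec("peeper", snr_db=8.0, seed=13))
        b = mix_scene(call, SceneSpec("peeper", snr_db=8.0, seed=13))
        assert np.array_equal(a.samples, b.samples)


class TestTemplateDetector:
    def _stream_with_call(self, seed=0, at_s=4.0, n_s=10.0):
        sr = 22050
        gen = np.random.default_rng(seed)
        stream = 0.003 * gen.standard_normal(int(n_s * sr))
        call = synth_call(ARCHETYPES["dsw"], seed=seed)
        start = int(at_s * sr)
        stream[start : start + call.n_samples] += call.samples
        from flightcall.frontend import AudioClip

        return AudioClip(stream, sr), call

    def test_self_match_detected_near_true_position(self):
        stream, call = self._stream_with_call()
        template = logmel_spectrogram(call, CFG)
        detections = template_detector(stream, template, threshold=0.6)
        assert len(detections) >= 1
        best = max(detections, key=lambda d: d.score)
        assert best.score > 0.8
        call_center = 4.0 + call.duration_ms / 2000.0
        assert abs(best.time_s - call_center) < 0.05
        assert best.clip.duration_ms == pytest.approx(1000.0)

    def test_noise_stream_scores_in_range_and_sparse(self):
        gen = np.random.default_rng(3)
        from flightcall.frontend import AudioClip

        stream = AudioClip(0.01 * gen.standard_normal(22050 * 8), 22050)
        template = logmel_spectrogram(synth_call(ARCHETYPES["dsw"], seed=1), CFG)
        detections = template_detector(stream, template, threshold=0.6)
        assert len(detections) <= 2
        for d in detections:
            assert 0.0 <= d.score <= 1.0

    def test_peeper_confounder_triggers_false_positives(self):
        # the sensor-side failure mode: a peeper chorus spectrally
        # overlapping the target call fires the detector without calls
        from flightcall.frontend import AudioClip
        from flightcall.synth import background_noise

        gen = np.random.default_rng(5)
        stream = AudioClip(0.1 * background_noise("peeper", 22050 * 20, gen), 22050)
        template = logmel_spectrogram(synth_call(ARCHETYPES["dsw"], seed=2), CFG)
        detections = template_detector(stream, template, threshold=0.35)
        assert len(detections) >= 1  # fires on confounders, not just calls

    def test_template_wider_than_stream_errors(self):
        from flightcall.frontend import AudioClip

        stream = AudioClip(np.random.default_rng(0).standard_normal(22050), 22050)
        long_template = logmel_spectrogram(
            AudioClip(np.random.default_rng(1).standard_normal(44100), 22050), CFG
        )
        with pytest.raises(ValueError, match="wider"):
            template_detector(stream, long_template)


class TestDatasets:
    def test_manifest_counts_and_pct_pos(self):
        # a season whose detector output matches the structure of a real
        # fall training set: 882 target calls among 4134 negatives
        spec = DatasetSpec(
            name="wtsp",
            counts={
                "train": {"Target": 882, "FlightCall": 1063, "Reject": 3071},
                "test": {"Target": 656, "FlightCall": 1569, "Reject": 9462},
            },
            target_species="dsw",
        )
        manifest, clips = build_dataset(spec, seed=0, audio=False)
        assert len(manifest) == 882 + 1063 + 3071 + 656 + 1569 + 9462
        summary = summarize_manifest(manifest)
        by_split = summary.set_index("split")
        assert by_split.loc["train", "pct_pos"] == 21.3
        assert by_split.loc["test", "pct_pos"] == 5.9
        assert by_split.loc["total", "pct_pos"] == 10.1

    def test_audio_generation_exact_counts_and_determinism(self):
        spec = DatasetSpec(
            name="tiny",
            counts={"train": {"dsw": 3, "usw": 2}},
            snr_range_db={"train": (8.0, 15.0)},
            backgrounds={"train": ("quiet",)},
            date_ranges={"train": ("2014-10-01", "2014-10-05")},
            clip_ms=400.0,
        )
        m1, c1 = build_dataset(spec, seed=5)
        m2, c2 = build_dataset(spec, seed=5)
        assert list(m1["label"]) == ["dsw"] * 3 + ["usw"] * 2
        assert m1.equals(m2)
        for k in c1:
            assert np.array_equal(c1[k].samples, c2[k].samples)

    def test_wav_export_round_trip(self, tmp_path):
        spec = DatasetSpec(
            name="disk",
            counts={"train": {"dsw": 1, "Reject": 1}},
            target_species="dsw",
            snr_range_db={"train": (10.0, 12.0)},
            backgrounds={"train": ("quiet",)},
            date_ranges={"train": ("2014-10-01", "2014-10-02")},
            clip_ms=400.0,
        )
        manifest, clips = build_dataset(spec, seed=1, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        from flightcall.frontend import load_clip

        for _, row in manifest.iterrows():
            clip = load_clip(tmp_path / row["path"])
            assert clip.sample_rate == 22050

    def test_monitoring_season_structure(self):
        spec = SeasonSpec(n_days=10, total_positives=12, negatives_per_day=2.0)
        manifest, clips, reference = build_monitoring_season(spec, seed=2)
        assert reference.sum() == 12
        assert len(reference) == 10
        n_targets = int((manifest["label"] == "Target").sum())
        assert n_targets == 12  # curve conservation: reference == positives
        assert len(manifest) == len(clips)
        # timestamps parse and fall within the season
        import pandas as pd

        ts = pd.to_datetime(manifest["timestamp"])
        assert ts.min().normalize() >= reference.index[0]

    def test_generated_calls_respect_band(self):
        # band-power outside 2-11 kHz should be negligible for clean calls
        clip = synth_call(ARCHETYPES["ivee"], seed=3)
        spec = logmel_spectrogram(clip, CFG)  # band-limited analysis works
        assert np.all(np.isfinite(spec.values))
        assert BAND == (2000.0, 11025.0)
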