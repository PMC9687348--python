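"""The synthetic generator plants a recoverable pulse, deterministically."""

import numpy as np
import pytest
from scipy import stats

from axisppg.synthetic import (GroundTruthPPG, PPGTemplate, SyntheticSpec,
                               load_clip, make_dataset, make_ppg_template,
                               save_clip, synthesize_face_video, synthesize_ppg)


class TestTemplate:
    def test_degenerate_single_bump_peaks_at_systolic_pos(self):
        p = PPGTemplate(notch_depth=0.0, diastolic_amp=1e-9, systolic_pos=0.3)
        w = make_ppg_template(p, 200)
        assert abs(int(np.argmax(w)) - round(0.3 * 200)) <= 1

    def test_default_beat_has_two_peaks_and_a_notch(self):
        w = make_ppg_template(n_points=100)
        d = np.diff(w)
        maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
        minima = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
        assert len(maxima) == 2
        between = minima[(minima > maxima[0]) & (minima < maxima[1])]
        assert len(between) == 1  # the dicrotic notch

    def test_min_is_zero_and_systolic_is_global_max(self):
        w = make_ppg_template(n_points=128)
        assert w.min() == 0.0
        assert np.argmax(w) == np.argmax(make_ppg_template(n_points=128))

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            PPGTemplate(systolic_pos=0.6, diastolic_pos=0.4)
        with pytest.raises(ValueError):
            make_ppg_template(n_points=4)


class TestSynthesizePPG:
    def test_dominant_frequency_matches_heart_rate(self):
        ppg = synthesize_ppg(72, 0.0, 20, 30, seed=0)
        x = ppg.samples - ppg.samples.mean()
        freqs = np.fft.rfftfreq(len(x), 1 / 30)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert abs(peak - 1.2) <= freqs[1]  # 72 bpm = 1.2 Hz, within one bin

    def test_seed_determinism(self):
        a = synthesize_ppg(80, 0.05, 10, 30, seed=5)
        b = synthesize_ppg(80, 0.05, 10, 30, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_jitter_gives_periodic_signal(self):
        rate, hr = 30, 72
        ppg = synthesize_ppg(hr, 0.0, 20, rate, seed=1)
        lag = round(rate * 60 / hr)
        x = ppg.samples - ppg.samples.mean()
        ac = np.array([np.dot(x, np.roll(x, k)) for k in range(1, len(x) // 2)])
        # periodic signal: the autocorrelation at the beat lag ties the max
        assert ac[lag - 1] >= ac.max() - 1e-9 * abs(ac.max())

    def test_extreme_jitter_clips_period_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="axisppg.synthetic"):
            ppg = synthesize_ppg(60, 0.9, 30, 30, seed=0)
        assert np.isfinite(ppg.samples).all()
        assert any("clipping" in r.message for r in caplog.records)


class TestFaceVideo:
    def test_static_when_all_modulation_off(self):
        spec = SyntheticSpec(pulse_amp=(0, 0, 0), noise_sd=0, motion_jitter_px=0,
                             illum_drift_amp=0, duration_s=2, fps=16,
                             height=24, width=24)
        clip, _, _ = synthesize_face_video(spec)
        assert clip.n_frames == 32
        np.testing.assert_array_equal(
            clip.frames, np.broadcast_to(clip.frames[0], clip.frames.shape))

    def test_roi_mean_trace_is_affine_in_planted_ppg(self, clean_clip):
        clip, ppg, mask = clean_clip
        trace = clip.frames[:, :, :, 1][:, mask].mean(axis=1)
        r = stats.pearsonr(trace, ppg.samples)[0]
        assert abs(r - 1.0) < 1e-6

    def test_frames_bounded_and_finite(self):
        spec = SyntheticSpec(noise_sd=0.05, motion_jitter_px=2,
                             illum_drift_amp=0.1, duration_s=2, fps=16,
                             height=24, width=24, seed=9)
        clip, ppg, mask = synthesize_face_video(spec)
        assert np.isfinite(clip.frames).all()
        assert clip.frames.min() >= 0.0 and clip.frames.max() <= 1.0
        assert mask.any() and not mask.all()

    def test_determinism_bit_identical(self):
        spec = SyntheticSpec(duration_s=2, fps=16, height=24, width=24, seed=11)
        a = synthesize_face_video(spec)
        b = synthesize_face_video(spec)
        np.testing.assert_array_equal(a[0].frames, b[0].frames)
        np.testing.assert_array_equal(a[1].samples, b[1].samples)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(hr_bpm=240, fps=5)


class TestMakeDataset:
    def test_reproducible_and_hr_within_range(self):
        kwargs = dict(duration_s=2, fps=16, height=24, width=24)
        clips, meta = make_dataset(8, {"hr_bpm": (60, 120)}, seed=2, **kwargs)
        clips2, meta2 = make_dataset(8, {"hr_bpm": (60, 120)}, seed=2, **kwargs)
        assert len(clips) == 8
        for m, m2 in zip(meta, meta2):
            assert m == m2
            assert 60 <= m["hr_bpm"] <= 120
        np.testing.assert_array_equal(clips[3][0].frames, clips2[3][0].frames)

    def test_recorded_hr_matches_spectral_peak_of_ppg(self):
        clips, meta = make_dataset(6, {"hr_bpm": (60, 120)}, seed=4,
                                   duration_s=8, fps=16, height=24, width=24,
                                   hrv_sd=0.0)
        for (clip, ppg, _), m in zip(clips, meta):
            x = ppg.samples - ppg.samples.mean()
            freqs = np.fft.rfftfreq(len(x), 1 / ppg.rate)
            peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
            assert abs(peak * 60 - m["hr_bpm"]) <= 60 * freqs[1]

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(2, {"hr_bpm": (120, 60)}, seed=0)


def test_clip_roundtrip_through_writers(tmp_path):
    spec = SyntheticSpec(duration_s=2, fps=16, height=24, width=24, seed=5)
    clip, ppg, mask = synthesize_face_video(spec)
    save_clip(tmp_path, "c0", clip, ppg, mask, meta={"hr_bpm": spec.hr_bpm})
    clip2, ppg2, mask2 = load_clip(tmp_path, "c0")
    assert clip2.fps == clip.fps and ppg2.rate == ppg.rate
    np.testing.assert_allclose(clip2.frames, clip.frames, atol=1e-6)
    np.testing.assert_allclose(ppg2.samples, ppg.samples, atol=1e-9)
    np.testing.assert_array_equal(mask2, mask)
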