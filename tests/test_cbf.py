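"""Ciliary beat frequency pipeline: motion map, segmentation, FFT recovery."""

import numpy as np
import pytest

from mucoflow import synthetic
from mucoflow.cbf import (
    analyze_cbf,
    beat_density,
    dominant_frequency,
    motion_map,
    region_mean_frequencies,
    segment_motion,
    summarize_cbf,
)
from mucoflow.core import VideoStack
from mucoflow.synthetic import CiliaPatch, CiliaSceneSpec, gen_cilia_video


def _video(frames, rate=200.0):
    return VideoStack(np.asarray(frames, dtype=float), rate, 1 / 3)


class TestMotionMap:
    def test_constant_video_gives_zero(self):
        assert np.all(motion_map(_video(np.full((16, 4, 4), 7.0))) == 0)

    def test_alternating_binary_pixel_gives_half(self):
        frames = np.zeros((10, 1, 1))
        frames[1::2] = 1.0
        assert motion_map(_video(frames))[0, 0] == pytest.approx(0.5)

    def test_sinusoid_gives_amplitude_over_sqrt2(self):
        # whole number of periods, densely sampled
        t = np.arange(400) / 200.0
        a = 13.0
        frames = (a * np.sin(2 * np.pi * 10.0 * t))[:, None, None]
        assert motion_map(_video(frames))[0, 0] == pytest.approx(a / np.sqrt(2), rel=0.01)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            motion_map(_video(np.zeros((1, 4, 4))))


class TestSegmentation:
    def test_bimodal_map_segments_patch_area(self, cilia_scene):
        spec, video, truth = cilia_scene
        mask = segment_motion(motion_map(video))
        true_mask = synthetic.patch_mask(spec, spec.patches[0])
        # segmented area within 2% of the analytic patch area
        assert abs(mask.mean() - true_mask.mean()) < 0.02
        # and essentially all motion pixels lie inside the patch
        assert (mask & true_mask).sum() / max(mask.sum(), 1) > 0.95

    def test_all_noise_map_yields_empty_mask(self):
        rng = np.random.default_rng(0)
        noisy = np.abs(rng.normal(3.0, 0.05, (64, 64)))
        with pytest.warns(UserWarning, match="floor"):
            mask = segment_motion(noisy)
        assert not mask.any()

    def test_mask_fraction_is_beat_density(self, cilia_scene):
        _, video, _ = cilia_scene
        mask = segment_motion(motion_map(video))
        assert beat_density(mask) == mask.mean()

    def test_negative_map_rejected(self):
        with pytest.raises(ValueError):
            segment_motion(np.array([[-1.0, 2.0]]))


class TestBeatDensity:
    def test_full_and_empty_masks(self):
        assert beat_density(np.ones((8, 8), bool)) == 1.0
        assert beat_density(np.zeros((8, 8), bool)) == 0.0

    def test_synthetic_patch_density_matches_analytic_area(self, cilia_scene):
        spec, video, truth = cilia_scene
        result = analyze_cbf(video)
        assert result.beat_density == pytest.approx(
            truth.extras["true_beat_density"], abs=0.02
        )

    def test_density_invariant_under_intensity_rescaling(self, cilia_scene):
        _, video, _ = cilia_scene
        scaled = VideoStack(video.frames * 2.5, video.frame_rate_hz, video.pixel_size_um)
        d1 = analyze_cbf(video).beat_density
        d2 = analyze_cbf(scaled).beat_density
        assert d1 == pytest.approx(d2, abs=0.005)


class TestDominantFrequency:
    @pytest.mark.parametrize("freq", [3.0, 8.0, 14.0, 33.0, 77.0])
    def test_recovery_within_one_fft_bin(self, freq):
        """Any synthetic frequency in (f_min, Nyquist) is recovered within
        frame_rate/n_frames."""
        spec = CiliaSceneSpec(
            field_size_px=(40, 40), n_frames=256,
            patches=[CiliaPatch((20, 20), 12, freq)], seed=2,
        )
        video, _ = gen_cilia_video(spec)
        result = analyze_cbf(video)
        df = spec.frame_rate_hz / spec.n_frames
        assert abs(result.sample_mean_cbf_hz - freq) <= df + 1e-9

    def test_two_patches_yield_per_patch_means(self):
        spec = CiliaSceneSpec(
            field_size_px=(100, 100), n_frames=512,
            patches=[CiliaPatch((25, 25), 12, 5.0), CiliaPatch((75, 75), 12, 12.0)],
            seed=3,
        )
        video, _ = gen_cilia_video(spec)
        result = analyze_cbf(video)
        df = spec.frame_rate_hz / spec.n_frames
        for patch, expected in zip(spec.patches, (5.0, 12.0)):
            m = synthetic.patch_mask(spec, patch) & result.motion_mask
            vals = result.frequency_map[m]
            vals = vals[~np.isnan(vals)]
            assert abs(vals.mean() - expected) <= df + 1e-9
        regions = sorted(region_mean_frequencies(result.frequency_map, result.motion_mask))
        assert len(regions) == 2
        assert regions[0] == pytest.approx(5.0, abs=df)
        assert regions[1] == pytest.approx(12.0, abs=df)

    def test_no_smoothing_equivalent_on_clean_signal(self):
        spec = CiliaSceneSpec(
            field_size_px=(30, 30), n_frames=256, noise_sd=0.01,
            patches=[CiliaPatch((15, 15), 10, 9.0)], seed=4,
        )
        video, _ = gen_cilia_video(spec)
        mask = segment_motion(motion_map(video))
        _, m_smooth = dominant_frequency(video, mask, smooth_frames=3)
        _, m_raw = dominant_frequency(video, mask, smooth_frames=0)
        assert m_smooth == pytest.approx(m_raw, abs=1e-9)

    def test_constant_pixel_inside_mask_is_excluded(self):
        frames = np.zeros((128, 2, 1))
        t = np.arange(128) / 200.0
        frames[:, 0, 0] = 50 * np.sin(2 * np.pi * 8 * t)
        frames[:, 1, 0] = 5.0  # constant
        video = _video(frames)
        mask = np.ones((2, 1), bool)
        fmap, mean = dominant_frequency(video, mask)
        assert np.isnan(fmap[1, 0])
        assert mean == pytest.approx(fmap[0, 0])

    def test_empty_mask_flagged_undefined(self, cilia_scene):
        _, video, _ = cilia_scene
        fmap, mean = dominant_frequency(video, np.zeros(video.shape_yx, bool))
        assert np.isnan(mean) and np.isnan(fmap).all()

    def test_f_min_at_nyquist_rejected(self, cilia_scene):
        _, video, _ = cilia_scene
        with pytest.raises(ValueError, match="Nyquist"):
            dominant_frequency(video, np.ones(video.shape_yx, bool), f_min_hz=100.0)

    def test_static_surroundings_do_not_change_sample_mean(self, cilia_scene):
        """Adding masked-out static area leaves the CBF mean unchanged."""
        spec, video, _ = cilia_scene
        result = analyze_cbf(video)
        pad = np.pad(video.frames, ((0, 0), (0, 40), (0, 40)), constant_values=100.0)
        padded = analyze_cbf(VideoStack(pad, video.frame_rate_hz, video.pixel_size_um))
        assert padded.sample_mean_cbf_hz == pytest.approx(
            result.sample_mean_cbf_hz, abs=1e-6
        )


class TestSummarize:
    def _result(self, cbf_hz, density):
        from mucoflow.cbf import CBFResult

        return CBFResult(
            motion_mask=np.ones((2, 2), bool) if density > 0 else np.zeros((2, 2), bool),
            beat_density=density,
            frequency_map=np.full((2, 2), cbf_hz),
            sample_mean_cbf_hz=cbf_hz,
            frequency_resolution_hz=0.4,
        )

    def test_mean_over_fields(self):
        s = summarize_cbf([self._result(8.0, 0.2), self._result(10.0, 0.4)])
        assert s["mean_cbf_hz"] == pytest.approx(9.0)
        assert s["mean_beat_density"] == pytest.approx(0.3)

    def test_single_field_identity(self):
        s = summarize_cbf([self._result(7.5, 0.1)])
        assert s["mean_cbf_hz"] == 7.5 and s["mean_beat_density"] == 0.1

    def test_motionless_field_counts_for_density_not_frequency(self):
        s = summarize_cbf(
            [self._result(8.0, 0.2), self._result(float("nan"), 0.0)]
        )
        assert s["mean_cbf_hz"] == pytest.approx(8.0)
        assert s["mean_beat_density"] == pytest.approx(0.1)
        assert s["n_fields_with_motion"] == 1

    def test_no_fields_rejected(self):
        with pytest.raises(ValueError):
            summarize_cbf([])
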