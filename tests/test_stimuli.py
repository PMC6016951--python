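"""Stimulus generators: gratings, photon noise, random-dot fields, blur."""

import numpy as np
import pytest

from flymotion import stimuli
from flymotion.stimuli import (
    DotSpec,
    GratingSpec,
    NoiseSpec,
    StimulusMovie,
    apply_photon_noise,
    gaussian_blur,
    make_dots,
    make_grating,
)

SMALL = (40, 40, 120)


class TestGrating:
    def test_zero_contrast_is_uniform(self):
        m = make_grating(GratingSpec(contrast=0.0), dims=SMALL)
        assert np.allclose(m.luminance, 0.5, atol=1e-6)

    def test_temporal_period_one_second(self):
        m = make_grating(GratingSpec(temporal_frequency=1.0), dims=(40, 40, 250))
        px = m.luminance[7, 3]
        # 1 Hz at dt = 10 ms: period is exactly 100 frames
        assert np.allclose(px[:100], px[100:200], atol=1e-5)

    def test_spatial_mean_is_mean_luminance(self):
        m = make_grating(GratingSpec(), dims=(200, 200, 5))
        # 200 px at 0.9 deg/px = 5 full wavelengths: sine integrates out
        means = m.luminance.mean(axis=(0, 1))
        assert np.allclose(means, 0.5, atol=1e-4)

    def test_luminance_range(self):
        m = make_grating(GratingSpec(), dims=SMALL)
        assert m.luminance.min() >= 0.0
        assert m.luminance.max() <= 1.0

    def test_motion_schedule_freezes_phase(self):
        sched = ((0.0, 0.4, 0.0), (0.4, 0.8, 1.0), (0.8, 1.2, 0.0))
        m = make_grating(GratingSpec(schedule=sched), dims=SMALL)
        lum = m.luminance
        assert np.array_equal(lum[..., 0], lum[..., 39])  # stationary epoch
        assert not np.array_equal(lum[..., 45], lum[..., 50])  # moving epoch
        assert np.array_equal(lum[..., 85], lum[..., 110])  # frozen again

    def test_determinism(self):
        a = make_grating(GratingSpec(direction=30.0), dims=SMALL)
        b = make_grating(GratingSpec(direction=30.0), dims=SMALL)
        assert np.array_equal(a.luminance, b.luminance)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GratingSpec(contrast=1.5)
        with pytest.raises(ValueError):
            GratingSpec(wavelength=-1.0)


class TestPhotonNoise:
    def test_same_seed_reproduces(self):
        m = make_grating(GratingSpec(), dims=SMALL)
        a = apply_photon_noise(m, NoiseSpec(4, seed=7))
        b = apply_photon_noise(m, NoiseSpec(4, seed=7))
        assert np.array_equal(a.luminance, b.luminance)

    def test_high_photon_count_converges_to_input(self):
        m = make_grating(GratingSpec(), dims=(40, 40, 30))
        noisy = apply_photon_noise(m, NoiseSpec(1e6, seed=0))
        rms = np.sqrt(np.mean((noisy.luminance - m.luminance) ** 2))
        assert rms < 2e-3

    def test_match_normalization_restores_moments(self):
        m = make_grating(GratingSpec(), dims=SMALL)
        noisy = apply_photon_noise(m, NoiseSpec(1, seed=3))
        assert noisy.luminance.mean() == pytest.approx(m.luminance.mean(), rel=1e-5)
        assert noisy.luminance.std() == pytest.approx(m.luminance.std(), rel=1e-5)

    def test_scale_normalization_preserves_signal_mean(self):
        m = make_grating(GratingSpec(), dims=SMALL)
        noisy = apply_photon_noise(m, NoiseSpec(8, seed=3), normalization="scale")
        assert noisy.luminance.mean() == pytest.approx(0.5, abs=0.01)

    def test_negative_luminance_rejected(self):
        bad = StimulusMovie(np.full((4, 4, 4), -1.0, dtype=np.float32))
        with pytest.raises(ValueError):
            apply_photon_noise(bad, NoiseSpec(1))


class TestDots:
    def test_dot_count_conserved_before_blur(self):
        spec = DotSpec(n_dots=200, coherence=0.5, blur_half_width=None, seed=1)
        m = make_dots(spec, dims=(100, 100, 20))
        occupied = (m.luminance > 0).sum(axis=(0, 1))
        assert np.all(occupied <= 200)
        assert np.all(occupied >= 190)  # only same-pixel collisions missing
        assert np.array_equal(m.luminance.sum(axis=(0, 1)), occupied)

    def test_full_coherence_is_rigid_translation(self):
        # speed 90 deg/s at 0.9 deg/px and 10 ms steps = exactly 1 px/frame
        spec = DotSpec(n_dots=50, coherence=1.0, speed=90.0,
                       blur_half_width=None, seed=2)
        m = make_dots(spec, dims=(60, 60, 10))
        for k in range(9):
            assert np.array_equal(
                np.roll(m.luminance[..., k], 1, axis=0), m.luminance[..., k + 1]
            )

    def test_schedule_controls_coherent_motion(self):
        sched = ((0.0, 0.5, 0.0),)  # coherent dots stand still
        spec = DotSpec(n_dots=50, coherence=1.0, speed=90.0,
                       blur_half_width=None, seed=2)
        m = make_dots(spec, dims=(60, 60, 10), motion_schedule=sched)
        assert np.array_equal(m.luminance[..., 0], m.luminance[..., 9])

    def test_same_seed_reproduces(self):
        a = make_dots(DotSpec(n_dots=100, coherence=0.3, seed=5), dims=(60, 60, 20))
        b = make_dots(DotSpec(n_dots=100, coherence=0.3, seed=5), dims=(60, 60, 20))
        assert np.array_equal(a.luminance, b.luminance)

    def test_blurred_dots_keep_unit_amplitude(self):
        spec = DotSpec(n_dots=1, coherence=1.0, speed=0.0, seed=3)
        m = make_dots(spec, dims=(60, 60, 3))
        assert m.luminance[..., 0].max() == pytest.approx(1.0, rel=1e-3)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DotSpec(coherence=1.2)
        with pytest.raises(ValueError):
            DotSpec(n_dots=0)


def test_movie_roundtrip_via_container(tmp_path):
    m = make_grating(GratingSpec(direction=45.0), dims=SMALL)
    path = tmp_path / "movie.npz"
    stimuli.save_movie(m, path)
    back = stimuli.load_movie(path)
    assert np.array_equal(back.luminance, m.luminance)
    assert back.dt == m.dt
    assert back.metadata == m.metadata


class TestGaussianBlur:
    def test_uniform_movie_unchanged(self):
        m = StimulusMovie(np.full((40, 40, 3), 0.3, dtype=np.float32))
        b = gaussian_blur(m, 4.5)
        assert np.allclose(b.luminance, 0.3, atol=1e-6)

    def test_impulse_peak_stays_at_origin(self):
        lum = np.zeros((41, 41, 1), dtype=np.float32)
        lum[20, 20, 0] = 1.0
        b = gaussian_blur(StimulusMovie(lum), 4.5)
        assert np.unravel_index(b.luminance.argmax(), b.luminance.shape) == (20, 20, 0)
        assert b.luminance.sum() == pytest.approx(1.0, rel=1e-4)

    def test_peak_normalization_preserves_amplitude(self):
        lum = np.zeros((41, 41, 1), dtype=np.float32)
        lum[20, 20, 0] = 1.0
        b = gaussian_blur(StimulusMovie(lum), 4.5, normalization="peak")
        assert b.luminance.max() == pytest.approx(1.0, rel=1e-4)

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(0)
        lum = rng.uniform(0, 1, (60, 60, 2)).astype(np.float32)
        b = gaussian_blur(StimulusMovie(lum), 4.5)
        assert b.luminance.var() < lum.var()
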