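"""Wavelet front-end: pre-emphasis, Morlet values, scale mapping, CWT, rendering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chirpnet.wavelet import (
    AudioClip,
    MorletParams,
    ScaleGrid,
    Scalogram,
    SpectrogramConfig,
    build_scale_grid,
    cwt,
    cwt_direct,
    morlet_value,
    pre_emphasize,
    read_wav,
    render_spectrogram,
    waveform_to_image,
    write_wav,
)

FS = 16000.0


class TestPreEmphasis:
    def test_constant_signal(self):
        out = pre_emphasize(AudioClip([1, 1, 1, 1], FS), 0.97)
        assert out.samples == pytest.approx([1, 0.03, 0.03, 0.03])

    def test_zero_coefficient_is_identity(self):
        x = np.sin(np.arange(32))
        out = pre_emphasize(AudioClip(x, FS), 0.0)
        assert out.samples == pytest.approx(x)

    def test_impulse_response(self):
        out = pre_emphasize(AudioClip([1, 0, 0], FS), 0.97)
        assert out.samples == pytest.approx([1, -0.97, 0])

    @pytest.mark.parametrize("k", [-0.1, 1.0, 1.5])
    def test_invalid_coefficient_rejected(self, k):
        with pytest.raises(ValueError):
            pre_emphasize(AudioClip([0.0, 1.0], FS), k)

    @given(st.integers(0, 2**31 - 1))
    def test_invertible_and_length_preserving(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 64)
        k = rng.uniform(0, 0.99)
        y = pre_emphasize(AudioClip(x, FS), k).samples
        assert y.size == x.size
        rec = np.empty_like(y)
        rec[0] = y[0]
        for t in range(1, y.size):
            rec[t] = y[t] + k * rec[t - 1]
        assert rec == pytest.approx(x, abs=1e-9)


class TestMorlet:
    def test_value_at_origin(self):
        v = morlet_value(0.0, MorletParams(fc=1.0, fb=1.0))
        assert v.real == pytest.approx(1 / np.sqrt(np.pi), abs=1e-6)
        assert v.imag == pytest.approx(0.0, abs=1e-12)

    def test_modulus_at_unit_time(self):
        v = morlet_value(1.0, MorletParams(fc=1.0, fb=1.0))
        assert abs(v) == pytest.approx(np.exp(-1) / np.sqrt(np.pi), abs=1e-6)

    def test_even_envelope(self):
        t = np.linspace(-3, 3, 31)
        assert np.abs(morlet_value(t)) == pytest.approx(np.abs(morlet_value(-t)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MorletParams(fc=0.0, fb=1.0)


class TestScaleGrid:
    def test_first_scale_forced_by_mapping(self):
        grid = build_scale_grid(200, 8000, 8, FS, MorletParams(fc=1.0))
        assert grid.scales[0] == pytest.approx(2.0)

    def test_two_point_grid_endpoints(self):
        grid = build_scale_grid(4000, 8000, 2, FS)
        assert grid.frequencies == pytest.approx([8000, 4000])

    def test_frequency_scale_round_trip(self):
        params = MorletParams(fc=1.3, fb=2.0)
        grid = build_scale_grid(150, 7000, 50, FS, params)
        back = params.fc * FS / grid.scales
        assert back == pytest.approx(grid.frequencies, rel=1e-9)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_scale_grid(100, 9000, 10, FS)

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError):
            ScaleGrid(scales=[1.0, 2.0], frequencies=[100.0, 200.0])


class TestCwt:
    def test_zero_signal_gives_zero_coefficients(self):
        grid = build_scale_grid(200, 4000, 8, FS)
        out = cwt(AudioClip(np.zeros(512), FS), grid)
        assert np.abs(out.coefficients).max() == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 400)
        grid = build_scale_grid(200, 4000, 6, FS)
        a = cwt(AudioClip(s, FS), grid).coefficients
        b = cwt(AudioClip(2 * s, FS), grid).coefficients
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_fft_path_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 2048)
        grid = build_scale_grid(200, 4000, 12, FS)
        clip = AudioClip(s, FS)
        a = cwt(clip, grid).coefficients
        b = cwt_direct(clip, grid).coefficients
        rel = np.abs(a - b).max() / np.abs(b).max()
        assert rel < 1e-6

    @pytest.mark.parametrize("f0", [500.0, 1000.0, 2000.0])
    def test_tone_localizes_to_nearest_grid_row(self, f0):
        t = np.arange(int(FS)) / FS
        clip = AudioClip(np.cos(2 * np.pi * f0 * t), FS)
        grid = build_scale_grid(150, 0.95 * FS / 2, 112, FS)
        W = cwt(clip, grid).coefficients
        peak_row = int(np.abs(W).mean(axis=1).argmax())
        true_row = int(np.abs(grid.frequencies - f0).argmin())
        assert abs(peak_row - true_row) <= 1

    def test_single_precision_close_to_double(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 1, 1024)
        grid = build_scale_grid(200, 4000, 8, FS)
        clip = AudioClip(s, FS)
        a = cwt(clip, grid, dtype=np.complex64).coefficients
        b = cwt(clip, grid).coefficients
        assert np.abs(a - b).max() / np.abs(b).max() < 1e-5


class TestRendering:
    def _tone_scalogram(self, n=512, n_scales=16):
        t = np.arange(n) / FS
        clip = AudioClip(np.cos(2 * np.pi * 1000 * t), FS)
        grid = build_scale_grid(200, 4000, n_scales, FS)
        return cwt(clip, grid)

    def test_output_shape_is_112(self):
        img = render_spectrogram(self._tone_scalogram(), 112, 112)
        assert img.pixels.shape == (112, 112, 3)

    def test_constant_scalogram_renders_uniformly(self):
        grid = build_scale_grid(200, 4000, 4, FS)
        scal = Scalogram(np.full((4, 64), 0.5 + 0.5j), grid, FS)
        img = render_spectrogram(scal, 4, 64)
        assert np.ptp(img.pixels.reshape(-1, 3), axis=0) == pytest.approx([0, 0, 0])

    def test_all_zero_scalogram_is_finite_and_uniform(self):
        grid = build_scale_grid(200, 4000, 4, FS)
        scal = Scalogram(np.zeros((4, 64), dtype=complex), grid, FS)
        img = render_spectrogram(scal, 4, 64)
        assert np.isfinite(img.pixels).all()
        assert np.ptp(img.pixels.reshape(-1, 3), axis=0) == pytest.approx([0, 0, 0])

    def test_peak_magnitude_gets_maximal_colour(self):
        import matplotlib

        scal = self._tone_scalogram(n=256, n_scales=8)
        img = render_spectrogram(scal, 8, 256)  # native size: no resampling
        i, j = np.unravel_index(np.abs(scal.coefficients).argmax(), scal.coefficients.shape)
        top_colour = np.asarray(matplotlib.colormaps["jet"](1.0)[:3])
        assert img.pixels[i, j] == pytest.approx(top_colour)

    def test_rendering_scale_invariant(self):
        scal = self._tone_scalogram()
        scaled = Scalogram(37.0 * scal.coefficients, scal.scale_grid, FS)
        a = render_spectrogram(scal, 32, 32)
        b = render_spectrogram(scaled, 32, 32)
        assert b.pixels == pytest.approx(a.pixels, abs=1e-9)


class TestIO:
    def test_wav_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        clip = AudioClip(rng.uniform(-1, 1, 800).astype(np.float32), FS)
        path = tmp_path / "x.wav"
        write_wav(path, clip)
        back = read_wav(path)
        assert back.sample_rate == FS
        assert back.samples == pytest.approx(clip.samples)

    def test_stereo_averaged_to_mono(self, tmp_path):
        from scipy.io import wavfile

        stereo = np.stack([np.ones(100), np.zeros(100)], axis=1).astype(np.float32)
        path = tmp_path / "st.wav"
        wavfile.write(path, 16000, stereo)
        clip = read_wav(path)
        assert clip.samples == pytest.approx(np.full(100, 0.5))


def test_waveform_to_image_shapes_and_range():
    t = np.arange(int(0.3 * FS)) / FS
    clip = AudioClip(np.cos(2 * np.pi * 800 * t), FS)
    img = waveform_to_image(clip, SpectrogramConfig(height=48, width=56))
    assert img.pixels.shape == (48, 56, 3)
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0


def test_cwt_cross_check_against_pywavelets():
    """Independent oracle: PyWavelets' cmor CWT magnitudes on the same grid.

    Normalizations differ (1/sqrt(alpha) here vs pywt's convention), so rows
    are compared after per-row peak normalization; the time position of each
    row's energy ridge must agree.
    """
    import pywt

    t = np.arange(1024) / FS
    s = np.cos(2 * np.pi * 1500 * t)
    params = MorletParams(fc=1.0, fb=1.5)
    grid = build_scale_grid(500, 4000, 24, FS, params)
    ours = np.abs(cwt(AudioClip(s, FS), grid, params).coefficients)
    theirs, _ = pywt.cwt(s, grid.scales, "cmor1.5-1.0", method="fft")
    theirs = np.abs(theirs)
    margin = 128  # ignore boundary effects
    prof_a = ours[:, margin:-margin].mean(axis=1)
    prof_b = theirs[:, margin:-margin].mean(axis=1)
    assert prof_a.argmax() == prof_b.argmax()
    assert np.corrcoef(prof_a / prof_a.max(), prof_b / prof_b.max())[0, 1] > 0.99
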