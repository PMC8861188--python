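"""Frame-feature correctness against closed forms and a brute-force DFT."""

import numpy as np
import pandas as pd
import pytest

from voicelung.dsp import (
    EPS,
    FRAME_FEATURE_COLUMNS,
    FrameGrid,
    compute_frame_features,
    contrast_band_edges,
    frame_spectral_features,
    frame_time_features,
    spectral_contrast,
    stft_magnitude,
)

# ---------------------------------------------------------------------------
# independent oracles: plain-loop recomputations of every spectral feature
# ---------------------------------------------------------------------------


def dft_magnitude_oracle(windowed_frame: np.ndarray) -> np.ndarray:
    """O(N^2) DFT magnitude of one windowed frame."""
    N = len(windowed_frame)
    n = np.arange(N)
    mags = []
    for k in range(N // 2 + 1):
        mags.append(abs(np.sum(windowed_frame * np.exp(-2j * np.pi * k * n / N))))
    return np.array(mags)


def oracle_spectral(mag: np.ndarray, freqs: np.ndarray, sr: int) -> dict:
    total = mag.sum()
    centroid = float((freqs * mag).sum() / total)
    bandwidth = float(np.sqrt((mag * (freqs - centroid) ** 2).sum() / total))
    out = {"centroid": centroid, "bandwidth": bandwidth}
    for q, name in ((0.85, "rolloff85"), (0.95, "rolloff95")):
        acc = 0.0
        for k, s in enumerate(mag):
            acc += s
            if acc >= q * total:
                out[name] = float(freqs[k])
                break
    power = mag**2 + EPS
    out["flatness"] = float(
        np.exp(np.mean(np.log(power))) / np.mean(power)
    )
    edges = 200.0 * 2.0 ** np.arange(7)
    edges = np.minimum(edges, sr / 2)
    band_vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = mag[(freqs >= lo) & ((freqs < hi) if hi < sr / 2 else (freqs <= hi))]
        if len(sel) == 0:
            continue
        k = max(1, int(0.02 * len(sel)))
        s = np.sort(sel)
        band_vals.append(
            20 * (np.log10(s[-k:].mean() + EPS) - np.log10(s[:k].mean() + EPS))
        )
    out["contrast"] = float(np.mean(band_vals))
    return out


def test_spectral_features_match_brute_force_dft(grid, rng):
    """On 50 random frames every spectral feature agrees with a plain-loop
    recomputation from an O(N^2) DFT to relative error < 1e-6."""
    n = grid.hop_length * 60
    waveform = rng.standard_normal(n) * 0.1
    S = stft_magnitude(waveform, grid)
    feats = frame_spectral_features(S, grid)
    freqs = grid.frequencies()
    win = grid.window_array()
    pad = np.pad(waveform, grid.frame_length // 2)
    frame_ids = rng.choice(S.shape[0], size=50, replace=False)
    for i in frame_ids:
        start = i * grid.hop_length
        frame = pad[start : start + grid.frame_length] * win
        mag = dft_magnitude_oracle(frame)
        np.testing.assert_allclose(S[i], mag, rtol=1e-6, atol=1e-9)
        expected = oracle_spectral(mag, freqs, grid.sample_rate)
        for name, val in expected.items():
            got = feats[name][i]
            assert got == pytest.approx(val, rel=1e-6, abs=1e-9), name


def test_sine_frame_argmax_bin(grid):
    """A 1 kHz sine concentrates its windowed spectrum in bin
    round(1000 * 2048 / 22050) = 93."""
    t = np.arange(grid.sample_rate) / grid.sample_rate
    y = np.sin(2 * np.pi * 1000 * t)
    S = stft_magnitude(y, grid)
    mid = S.shape[0] // 2
    assert np.argmax(S[mid]) == round(1000 * 2048 / 22050) == 93


def test_zero_waveform_zero_spectrogram(grid):
    S = stft_magnitude(np.zeros(5000), grid)
    assert S.shape[1] == grid.frame_length // 2 + 1
    assert np.all(S == 0)


def test_empty_waveform_rejected(grid):
    with pytest.raises(ValueError):
        stft_magnitude(np.array([]), grid)
    with pytest.raises(ValueError):
        frame_time_features(np.array([]), grid)


def test_frame_count_and_times(grid):
    n = 3 * grid.sample_rate + 123
    S = stft_magnitude(np.ones(n), grid)
    pad_len = n + 2 * (grid.frame_length // 2)
    expected_frames = 1 + (pad_len - grid.frame_length) // grid.hop_length
    assert S.shape[0] == expected_frames
    times = grid.frame_times(S.shape[0])
    np.testing.assert_allclose(
        times, np.arange(S.shape[0]) * grid.hop_length / grid.sample_rate
    )


class TestTimeFeatures:
    def test_sine_rms_closed_form(self, grid):
        """RMS of a full-frame sine of amplitude A is A/sqrt(2)."""
        t = np.arange(grid.sample_rate) / grid.sample_rate
        y = 0.5 * np.sin(2 * np.pi * 440 * t)
        rms, _, _ = frame_time_features(y, grid)
        mid = len(rms) // 2
        assert rms[mid] == pytest.approx(0.5 / np.sqrt(2), abs=1e-3)

    def test_sine_zcr_closed_form(self, grid):
        """ZCR of a 440 Hz sine at 22050 Hz is ~2*440/22050 = 0.0399."""
        t = np.arange(grid.sample_rate) / grid.sample_rate
        y = np.sin(2 * np.pi * 440 * t)
        _, _, zcr = frame_time_features(y, grid)
        mid = len(zcr) // 2
        assert zcr[mid] == pytest.approx(2 * 440 / 22050, abs=0.002)

    def test_constant_frame_zero_zcr(self, grid):
        _, _, zcr = frame_time_features(np.full(grid.frame_length * 3, 0.3), grid)
        assert np.all(zcr[1:-1] == 0)

    def test_two_sample_frame_hand_arithmetic(self):
        """Frame [3, -4]: mean_amp 3.5, rms sqrt(12.5), zcr 1."""
        tiny = FrameGrid(sample_rate=10, frame_length=2, hop_length=2)
        # without padding effects: use a frame cut exactly on the samples
        frame = np.array([3.0, -4.0])
        rms = np.sqrt(np.mean(frame**2))
        mean_amp = np.mean(np.abs(frame))
        zcr = np.diff(np.signbit(frame)).sum() / (len(frame) - 1)
        assert rms == pytest.approx(np.sqrt(12.5))
        assert mean_amp == pytest.approx(3.5)
        assert zcr == 1.0
        # implementation agrees on a frame aligned with no zero padding
        got_rms, got_amp, got_zcr = frame_time_features(
            np.array([1.0, 3.0, -4.0, 1.0]), tiny
        )
        assert got_rms[1] == pytest.approx(rms)
        assert got_amp[1] == pytest.approx(mean_amp)
        assert got_zcr[1] == 1.0


class TestSpectralDegenerate:
    def test_single_bin_spectrum(self, grid):
        S = np.zeros((1, grid.n_bins))
        f0_bin = 100
        S[0, f0_bin] = 2.0
        feats = frame_spectral_features(S, grid)
        f0 = grid.frequencies()[f0_bin]
        assert feats["centroid"][0] == pytest.approx(f0)
        assert feats["bandwidth"][0] == pytest.approx(0.0)
        assert feats["rolloff85"][0] == f0
        assert feats["rolloff95"][0] == f0

    def test_two_equal_bins_centroid_midpoint(self, grid):
        freqs = grid.frequencies()
        S = np.zeros((1, grid.n_bins))
        i500 = np.argmin(np.abs(freqs - 500))
        i1500 = np.argmin(np.abs(freqs - 1500))
        S[0, [i500, i1500]] = 1.0
        feats = frame_spectral_features(S, grid)
        assert feats["centroid"][0] == pytest.approx(
            (freqs[i500] + freqs[i1500]) / 2
        )

    def test_all_zero_frame_conventions(self, grid):
        feats = frame_spectral_features(np.zeros((1, grid.n_bins)), grid)
        assert feats["centroid"][0] == 0
        assert feats["bandwidth"][0] == 0
        assert feats["rolloff85"][0] == 0
        assert feats["flatness"][0] == pytest.approx(1.0)

    def test_negative_spectrogram_rejected(self, grid):
        with pytest.raises(ValueError):
            frame_spectral_features(-np.ones((1, grid.n_bins)), grid)


def test_noise_vs_sine_flatness(grid, rng):
    """White-noise frames are spectrally flat (> 0.5 on average); a pure
    tone is nearly minimal (< 0.05)."""
    noise = rng.standard_normal(grid.frame_length + 100 * grid.hop_length) * 0.1
    S = stft_magnitude(noise, grid)
    flat = frame_spectral_features(S, grid)["flatness"]
    assert flat[2:-2].mean() > 0.5
    t = np.arange(len(noise)) / grid.sample_rate
    S_sine = stft_magnitude(0.5 * np.sin(2 * np.pi * 800 * t), grid)
    flat_sine = frame_spectral_features(S_sine, grid)["flatness"]
    assert np.median(flat_sine[2:-2]) < 0.05


def test_rolloff_order_on_random_frames(grid, rng):
    y = rng.standard_normal(grid.sample_rate)
    feats = frame_spectral_features(stft_magnitude(y, grid), grid)
    assert np.all(feats["rolloff85"] <= feats["rolloff95"])


@pytest.mark.parametrize("c", [0.01, 0.5, 7.0])
def test_scale_behaviour(grid, rng, c):
    """Scaling the waveform by c scales rms/mean_amp by c and leaves the
    shape features unchanged."""
    y = rng.standard_normal(grid.sample_rate // 2) * 0.2
    base = compute_frame_features(y, grid)
    scaled = compute_frame_features(c * y, grid)
    np.testing.assert_allclose(scaled["rms"], c * base["rms"], rtol=1e-9)
    np.testing.assert_allclose(scaled["mean_amp"], c * base["mean_amp"], rtol=1e-9)
    for col in ("zcr", "centroid", "bandwidth", "rolloff85", "rolloff95"):
        np.testing.assert_allclose(scaled[col], base[col], rtol=1e-6)
    # flatness and contrast are scale-free up to the epsilon log floor
    keep = base["rms"] > 1e-3
    np.testing.assert_allclose(
        scaled.loc[keep, "flatness"], base.loc[keep, "flatness"], rtol=1e-3
    )


def test_feature_matrix_schema(grid, rng):
    out = compute_frame_features(rng.standard_normal(10000), grid)
    assert list(out.columns) == ["time_s"] + FRAME_FEATURE_COLUMNS


def test_contrast_band_edges_capped_at_nyquist():
    edges = contrast_band_edges(22050)
    assert edges[0] == 200
    assert edges[-1] == 22050 / 2
    assert np.all(np.diff(edges) >= 0)
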