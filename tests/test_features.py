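"""ERP averaging, amplitude/latency extraction and the STFT power region."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cordssep.features import (
    ErpWaveform,
    SsepEpochSet,
    StftParams,
    compute_erp,
    compute_tfa_power,
    extract_amplitude_latency,
    extract_features,
    features_frame,
    read_epochs,
    read_features_csv,
    write_epochs,
    write_features_csv,
)

FS = 2000.0


def _epochs(data, fs=FS, side="right"):
    return SsepEpochSet(data=np.asarray(data, float), sampling_rate=fs, side=side, patient_id="p")


def _erp(values, fs=FS):
    values = np.asarray(values, float)
    times = np.arange(values.size) / fs * 1000.0
    return ErpWaveform(values, times)


# --------------------------------------------------------------------------
# ERP averaging
# --------------------------------------------------------------------------

def test_erp_identity_symmetry_and_mean(rng):
    trial = rng.normal(0, 1, 64)
    erp = compute_erp(_epochs(np.tile(trial, (5, 1))))
    np.testing.assert_allclose(erp.values, trial, rtol=1e-14, atol=0)

    erp0 = compute_erp(_epochs(np.stack([trial, -trial])))
    assert np.allclose(erp0.values, 0.0)

    three = np.zeros((3, 10))
    three[:, 4] = [1.0, 2.0, 6.0]
    assert compute_erp(_epochs(three)).values[4] == pytest.approx(3.0)


def test_erp_rejects_empty_and_nan():
    with pytest.raises(ValueError):
        compute_erp(_epochs(np.empty((0, 8))))
    bad = np.zeros((2, 8))
    bad[1, 3] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        compute_erp(_epochs(bad))


def test_features_invariant_to_trial_order(rng):
    data = rng.normal(0, 1, (20, 100))
    a = extract_features(_epochs(data))
    b = extract_features(_epochs(data[rng.permutation(20)]))
    assert a.amplitude_uv == b.amplitude_uv
    assert a.latency_ms == b.latency_ms
    assert a.tfa_power == b.tfa_power


# --------------------------------------------------------------------------
# amplitude / latency
# --------------------------------------------------------------------------

def test_amplitude_latency_two_extremum_waveform():
    v = np.zeros(200)
    v[80] = 3.0   # 40 ms at 2 kHz
    v[120] = -1.0
    amp, lat = extract_amplitude_latency(_erp(v), window=(0, 100))
    assert amp == pytest.approx(4.0)
    assert lat == pytest.approx(40.0)


def test_flat_erp_tie_rule():
    amp, lat = extract_amplitude_latency(_erp(np.zeros(50)), window=(5, 20))
    assert amp == 0.0
    assert lat == pytest.approx(5.0)  # earliest sample in the window


def test_amplitude_latency_window_errors():
    with pytest.raises(ValueError):
        extract_amplitude_latency(_erp(np.zeros(10)), window=(30, 10))
    with pytest.raises(ValueError):
        extract_amplitude_latency(_erp(np.zeros(10)), window=(500, 600))


@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=120))
def test_amplitude_latency_equals_bruteforce_scan(values):
    erp = _erp(values)
    amp, lat = extract_amplitude_latency(erp, window=(erp.times_ms[0], erp.times_ms[-1]))
    v = np.asarray(values)
    assert amp == pytest.approx(max(v) - min(v))
    best = max(v)
    first_idx = next(i for i, x in enumerate(v) if x == best)
    assert lat == pytest.approx(erp.times_ms[first_idx])


# --------------------------------------------------------------------------
# TFA region power
# --------------------------------------------------------------------------

def test_zero_signal_zero_power():
    _, p = compute_tfa_power(_erp(np.zeros(200)))
    assert p == 0.0


def test_sinusoid_spectral_concentration():
    # frequency discrimination at +/-10 Hz needs a window spanning the full
    # 100 ms epoch; the default quarter-epoch window trades that resolution
    # for time localisation
    t = np.arange(200) / FS
    x = np.sin(2 * np.pi * 50 * t)
    erp = _erp(x)
    params = StftParams(window="rectangular", nperseg=200, overlap_fraction=0.0, zero_pad_factor=1)
    _, total = compute_tfa_power(erp, params, region=((0, 100), (0, 1000)))
    _, inband = compute_tfa_power(erp, params, region=((0, 100), (40, 60)))
    _, outband = compute_tfa_power(erp, params, region=((0, 100), (150, 200)))
    # independent check of the band fractions via a plain DFT of the signal
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / FS)
    assert spec[(freqs >= 40) & (freqs <= 60)].sum() / spec.sum() >= 0.95
    assert inband / total >= 0.95
    assert outband / total <= 0.01


def test_power_scales_quadratically(rng):
    x = rng.normal(0, 1, 160)
    _, p1 = compute_tfa_power(_erp(x))
    _, p2 = compute_tfa_power(_erp(3.0 * x))
    assert p2 == pytest.approx(9.0 * p1, rel=1e-12)


def test_region_growth_monotone(rng):
    x = rng.normal(0, 1, 200)
    erp = _erp(x)
    small = compute_tfa_power(erp, region=((20, 60), (20, 60)))[1]
    medium = compute_tfa_power(erp, region=((10, 80), (10, 90)))[1]
    full = compute_tfa_power(erp, region=((0, 100), (0, 1000)))[1]
    assert small <= medium <= full


def test_region_disjoint_and_bad_window_errors():
    erp = _erp(np.zeros(100))
    with pytest.raises(ValueError, match="disjoint"):
        compute_tfa_power(erp, region=((900, 950), (10, 100)))
    with pytest.raises(ValueError):
        compute_tfa_power(erp, StftParams(nperseg=500))  # window longer than signal


def test_parseval_rectangular_nonoverlapping(rng):
    """With a rectangular window, hop = window and no zero padding, summed
    spectrogram power equals N_w times the framed signal energy (one-sided
    bins reweighted)."""
    x = rng.normal(0, 1, 192)
    params = StftParams(window="rectangular", nperseg=32, overlap_fraction=0.0, zero_pad_factor=1)
    sg, _ = compute_tfa_power(_erp(x), params, region=((0, 1000), (0, 10000)))
    nw = 32
    # one-sided rfft: double every bin except DC and Nyquist
    weights = np.full(sg.freqs_hz.size, 2.0)
    weights[0] = 1.0
    weights[-1] = 1.0
    total = float((sg.power * weights[:, None]).sum())
    energy = float(np.sum(x[: (192 // nw) * nw] ** 2))
    assert total == pytest.approx(nw * energy, rel=1e-9)


def test_spectrogram_matches_explicit_dft():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 64)
    params = StftParams(window="hann", nperseg=16, overlap_fraction=0.5, zero_pad_factor=2)
    sg, _ = compute_tfa_power(_erp(x), params, region=((0, 1000), (0, 10000)))
    from scipy.signal import get_window

    w = get_window("hann", 16, fftbins=True)
    nfft = 32
    frame0 = x[:16] * w
    # O(N^2) discrete Fourier sum, independently of numpy's FFT
    ks = np.arange(nfft // 2 + 1)
    ns = np.arange(nfft)
    padded = np.zeros(nfft)
    padded[:16] = frame0
    dft = np.array([np.sum(padded * np.exp(-2j * np.pi * k * ns / nfft)) for k in ks])
    assert np.allclose(sg.power[:, 0], np.abs(dft) ** 2, atol=1e-9)


# --------------------------------------------------------------------------
# on-disk round trips
# --------------------------------------------------------------------------

def test_epochs_roundtrip(tmp_path, rng):
    ep = _epochs(rng.normal(0, 1, (4, 50)).round(4), side="left")
    write_epochs(ep, tmp_path / "p_left", fmt="%.6g")
    back = read_epochs(tmp_path / "p_left")
    assert back.side == "left"
    assert back.sampling_rate == ep.sampling_rate
    assert np.allclose(back.data, ep.data, atol=1e-4)


def test_features_csv_roundtrip(tmp_path):
    from cordssep.features import SsepFeatureSet

    df = features_frame(
        [SsepFeatureSet("p1", "right", 2.1, 40.5, 12.0), SsepFeatureSet("p1", "left", 1.9, 41.0, 10.5)]
    )
    write_features_csv(df, tmp_path / "f.csv", provenance={"region": [[0, 100], [10, 100]]})
    back = read_features_csv(tmp_path / "f.csv")
    assert back.shape == df.shape
    assert back["amplitude_uV"].tolist() == df["amplitude_uV"].tolist()
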