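"""SSEP feature extraction: ERP average, amplitude/latency, TFA region power.

Three features summarise a stimulus-locked epoch set per patient and side:

* **amplitude** (µV) — peak-to-peak span (max - min) of the trial-averaged
  event-related potential (ERP) within the analysis window;
* **latency** (ms) — time of the maximal positive ERP value (earliest sample
  on ties), the P40-like peak for tibial-nerve stimulation;
* **TFA power** — summed squared-magnitude of the short-time Fourier
  transform of the ERP over a fixed time × frequency region (default
  0-100 ms × 10-100 Hz). Units are consistent but arbitrary; downstream use
  is relative (percent change against a control mean), which is invariant to
  the overall scale and to sum-vs-mean over the region.

The STFT is computed on the ERP average (configurable window/overlap/padding
via :class:`StftParams`); frames are placed fully inside the signal with no
boundary padding, so with a rectangular window, non-overlapping frames and no
zero-padding the spectrogram satisfies an exact Parseval identity against the
framed signal energy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

__all__ = [
    "SsepEpochSet",
    "ErpWaveform",
    "Spectrogram",
    "StftParams",
    "SsepFeatureSet",
    "DEFAULT_REGION",
    "compute_erp",
    "extract_amplitude_latency",
    "compute_tfa_power",
    "extract_features",
    "write_epochs",
    "read_epochs",
    "features_frame",
    "write_features_csv",
    "read_features_csv",
]

#: default fixed region: full 100 ms analysis window x 10-100 Hz
DEFAULT_REGION: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 100.0), (10.0, 100.0))


@dataclass(frozen=True)
class SsepEpochSet:
    """Raw stimulus-locked trials (µV) for one patient and side."""

    data: np.ndarray  # trials x samples
    sampling_rate: float  # samples per second
    onset_index: int = 0
    side: str = "right"
    patient_id: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("epoch data must be a trials x samples matrix")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.onset_index < data.shape[1]:
            raise ValueError("onset_index outside the sample range")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to the stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_index) / self.sampling_rate * 1000.0


@dataclass(frozen=True)
class ErpWaveform:
    """Trial-averaged waveform (µV) on a strictly increasing ms time axis."""

    values: np.ndarray
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times_ms", times)
        if values.shape != times.shape or values.ndim != 1:
            raise ValueError("values and times_ms must be 1-D of equal length")
        if values.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        if self.times_ms.size < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        return 1000.0 / float(self.times_ms[1] - self.times_ms[0])


@dataclass(frozen=True)
class StftParams:
    """Short-time Fourier transform configuration.

    ``nperseg_fraction`` sizes the window as a fraction of the epoch length
    unless an explicit ``nperseg`` is given. Defaults: Hann window of 25% of
    the epoch, 75% overlap, 4x zero-padding for finer frequency sampling.
    """

    window: str = "hann"
    nperseg: int | None = None
    nperseg_fraction: float = 0.25
    overlap_fraction: float = 0.75
    zero_pad_factor: int = 4

    def __post_init__(self) -> None:
        if self.nperseg is not None and self.nperseg < 1:
            raise ValueError("nperseg must be >= 1")
        if not 0 < self.nperseg_fraction <= 1:
            raise ValueError("nperseg_fraction must lie in (0, 1]")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be >= 1")

    def resolve(self, n_samples: int) -> tuple[np.ndarray, int, int]:
        """Return (window vector, hop, nfft) for a signal of ``n_samples``."""
        win_len = self.nperseg if self.nperseg is not None else max(1, round(self.nperseg_fraction * n_samples))
        if win_len < 1:
            raise ValueError("zero-length STFT window")
        if win_len > n_samples:
            raise ValueError(f"STFT window ({win_len}) longer than signal ({n_samples})")
        hop = max(1, round(win_len * (1.0 - self.overlap_fraction)))
        nfft = win_len * self.zero_pad_factor
        if self.window == "rectangular":
            w = np.ones(win_len)
        else:
            w = get_window(self.window, win_len, fftbins=True)
        return w, hop, nfft

    def describe(self, n_samples: int) -> dict:
        w, hop, nfft = self.resolve(n_samples)
        return {"window": self.window, "nperseg": int(w.size), "hop": int(hop), "nfft": int(nfft)}


@dataclass(frozen=True)
class Spectrogram:
    """Non-negative power matrix (frequency bins x time frames)."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    window: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "power", power)
        if power.ndim != 2:
            raise ValueError("power must be 2-D (freq x time)")
        if power.shape != (np.asarray(self.freqs_hz).size, np.asarray(self.times_ms).size):
            raise ValueError("axes do not match the power matrix shape")
        if np.any(power < 0):
            raise ValueError("spectrogram power must be non-negative")


@dataclass(frozen=True)
class SsepFeatureSet:
    """Extracted features for one patient/side."""

    patient_id: str
    side: str
    amplitude_uv: float
    latency_ms: float
    tfa_power: float

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")
        if self.tfa_power < 0:
            raise ValueError("tfa_power must be non-negative")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def compute_erp(epochs: SsepEpochSet) -> ErpWaveform:
    """Pointwise arithmetic mean over trials (the ERP average)."""
    if epochs.n_trials == 0:
        raise ValueError("cannot average zero trials")
    if np.isnan(epochs.data).any():
        raise ValueError("epoch data contains NaN samples")
    return ErpWaveform(epochs.data.mean(axis=0), epochs.times_ms)


def extract_amplitude_latency(
    erp: ErpWaveform, window: tuple[float, float] = (0.0, 100.0)
) -> tuple[float, float]:
    """Peak-to-peak amplitude and time of the maximal value within ``window``.

    Amplitude is max - min of the ERP inside the window (>= 0); latency is
    the time of the maximum, earliest sample on exact ties.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must satisfy start < end")
    mask = (erp.times_ms >= lo) & (erp.times_ms <= hi)
    if not mask.any():
        raise ValueError("window contains no samples")
    v = erp.values[mask]
    t = erp.times_ms[mask]
    amplitude = float(v.max() - v.min())
    latency = float(t[int(np.argmax(v))])  # argmax returns the first maximum
    return amplitude, latency


def compute_tfa_power(
    erp: ErpWaveform,
    stft_params: StftParams | None = None,
    region: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_REGION,
) -> tuple[Spectrogram, float]:
    """Spectrogram of the ERP and the summed power inside a fixed region.

    The spectrogram is the squared magnitude of the windowed DFT of frames
    placed fully inside the signal. ``region`` is ((t0_ms, t1_ms),
    (f0_hz, f1_hz)); a cell contributes when its time-frame centre and
    frequency-bin centre both fall inside (bounds inclusive).
    """
    stft_params = stft_params or StftParams()
    x = erp.values
    n = x.size
    w, hop, nfft = stft_params.resolve(n)
    win_len = w.size
    fs = erp.sampling_rate

    starts = np.arange(0, n - win_len + 1, hop)
    frames = np.stack([x[s : s + win_len] * w for s in starts])
    spec = np.abs(np.fft.rfft(frames, n=nfft, axis=1)) ** 2  # frames x freq
    power = spec.T  # freq x time
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    frame_times = erp.times_ms[0] + (starts + (win_len - 1) / 2.0) / fs * 1000.0

    sg = Spectrogram(power, freqs, frame_times, window=stft_params.describe(n))

    (t0, t1), (f0, f1) = region
    tmask = (frame_times >= t0) & (frame_times <= t1)
    fmask = (freqs >= f0) & (freqs <= f1)
    if not tmask.any() or not fmask.any():
        raise ValueError("region is disjoint from the spectrogram axes")
    tfa_power = float(power[np.ix_(fmask, tmask)].sum())
    return sg, tfa_power


def extract_features(
    epochs: SsepEpochSet,
    window: tuple[float, float] = (0.0, 100.0),
    stft_params: StftParams | None = None,
    region: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_REGION,
) -> SsepFeatureSet:
    """Full feature extraction for one epoch set."""
    erp = compute_erp(epochs)
    amplitude, latency = extract_amplitude_latency(erp, window)
    _, tfa = compute_tfa_power(erp, stft_params, region)
    return SsepFeatureSet(
        patient_id=epochs.patient_id or "unknown",
        side=epochs.side,
        amplitude_uv=amplitude,
        latency_ms=latency,
        tfa_power=tfa,
    )


# --------------------------------------------------------------------------
# on-disk formats: TSV trials-by-samples matrix + JSON sidecar
# --------------------------------------------------------------------------

def write_epochs(epochs: SsepEpochSet, path: str | Path, fmt: str = "%.5g") -> Path:
    """Write one epoch set as ``<path>.tsv`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    sidecar = path.with_suffix(".json")
    np.savetxt(tsv, epochs.data, fmt=fmt, delimiter="\t")
    meta = {
        "units": "uV",
        "sampling_rate": epochs.sampling_rate,
        "onset_index": epochs.onset_index,
        "side": epochs.side,
        "patient_id": epochs.patient_id,
        "n_trials": epochs.n_trials,
        "n_samples": epochs.n_samples,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return tsv


def read_epochs(path: str | Path) -> SsepEpochSet:
    """Read an epoch set written by :func:`write_epochs` (or any conforming producer)."""
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(tsv, delimiter="\t", ndmin=2)
    return SsepEpochSet(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        onset_index=int(meta.get("onset_index", 0)),
        side=meta.get("side", "right"),
        patient_id=meta.get("patient_id"),
    )


def features_frame(feature_sets: Sequence[SsepFeatureSet]) -> pd.DataFrame:
    """One row per patient/side: patient_id, side, amplitude_uV, latency_ms, tfa_power."""
    return pd.DataFrame.from_records(
        [
            {
                "patient_id": f.patient_id,
                "side": f.side,
                "amplitude_uV": f.amplitude_uv,
                "latency_ms": f.latency_ms,
                "tfa_power": f.tfa_power,
            }
            for f in feature_sets
        ]
    )


def write_features_csv(
    features: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write the features table; provenance (STFT/region config) goes in a
    leading comment line so the numbers stay machine-readable."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance, sort_keys=True) + "\n")
        features.to_csv(fh, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
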