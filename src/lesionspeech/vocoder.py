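"""Noise vocoder.

The 50-8000 Hz range is split into logarithmically spaced channels. Each
channel of the input is band-pass filtered, half-wave rectified and smoothed
with a 30 Hz low-pass filter to obtain an amplitude envelope, which is then
imposed on band-matched white noise; the modulated noise bands are summed and
the result is RMS-matched to the input.

Filters are 4th-order Butterworth applied forward-backward (zero phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "VocoderSpec",
    "channel_edges",
    "extract_envelope",
    "vocode",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class VocoderSpec:
    n_channels: int
    sample_rate: float
    f_lo: float = 50.0
    f_hi: float = 8000.0
    envelope_cutoff: float = 30.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("require 0 < f_lo < f_hi")
        if self.f_hi > self.sample_rate / 2:
            raise ValueError("f_hi exceeds the Nyquist frequency")
        if self.envelope_cutoff <= 0:
            raise ValueError("envelope_cutoff must be positive")


def channel_edges(spec: VocoderSpec) -> np.ndarray:
    """n_channels + 1 band edges forming a geometric progression f_lo..f_hi."""
    return np.geomspace(spec.f_lo, spec.f_hi, spec.n_channels + 1)


def _bandpass_sos(lo: float, hi: float, fs: float):
    nyq = fs / 2.0
    # keep the top edge strictly below Nyquist for filter stability
    hi = min(hi, nyq * 0.999)
    return butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def extract_envelope(band_signal, cutoff: float, sample_rate: float) -> np.ndarray:
    """Half-wave rectify then low-pass filter; residual ringing clipped at 0."""
    band_signal = np.asarray(band_signal, dtype=float)
    if not np.isfinite(band_signal).all():
        raise ValueError("band_signal contains non-finite values")
    if cutoff >= sample_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    rectified = np.maximum(band_signal, 0.0)
    sos = butter(4, cutoff / (sample_rate / 2.0), btype="lowpass", output="sos")
    env = sosfiltfilt(sos, rectified)
    return np.maximum(env, 0.0)


def vocode(signal, spec: VocoderSpec, seed: int = 0) -> np.ndarray:
    """Noise-vocode ``signal`` into ``spec.n_channels`` channels.

    Deterministic given ``seed`` (which seeds the noise carrier). The output
    has the same length as the input and is RMS-matched to it.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if spec.sample_rate < 2 * spec.f_hi:
        raise ValueError("sample_rate must be at least 2 * f_hi")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.size)
    edges = channel_edges(spec)
    out = np.zeros_like(signal)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = _bandpass_sos(lo, hi, spec.sample_rate)
        band = sosfiltfilt(sos, signal)
        env = extract_envelope(band, spec.envelope_cutoff, spec.sample_rate)
        carrier = sosfiltfilt(sos, noise)
        rms = np.sqrt(np.mean(carrier ** 2))
        if rms > 0:
            carrier = carrier / rms
        out += env * carrier
    in_rms = np.sqrt(np.mean(signal ** 2))
    out_rms = np.sqrt(np.mean(out ** 2))
    if in_rms > 0 and out_rms > 0:
        out *= in_rms / out_rms
    return out


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a WAV file; returns (sample_rate, float64 mono samples in [-1, 1])."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return rate, data.astype(float)


def write_wav(path, sample_rate: int, samples) -> None:
    """Write float samples as 16-bit PCM, peak-normalised only if clipping."""
    samples = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        samples = samples / peak
    wavfile.write(path, int(sample_rate), (samples * 32767).astype(np.int16))
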