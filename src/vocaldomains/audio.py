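"""Minimal mono WAV I/O and amplitude utilities.

All audio in this package is mono float64 in [-1, 1] in memory and PCM
16-bit on disk.
"""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav", "peak_normalize", "rms"]

_PCM16_FULL_SCALE = 32767.0


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file, returning (samples as float64 in [-1, 1], sample rate)."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"expected mono audio, got {data.shape[1]} channels: {path}")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / _PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 127.0
    else:  # float wav
        x = data.astype(np.float64)
    return x, int(sr)


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write float samples to PCM 16-bit mono WAV, clipping to [-1, 1]."""
    x = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), np.round(x * _PCM16_FULL_SCALE).astype(np.int16))


def peak_normalize(waveform: np.ndarray, peak: float = 1.0) -> np.ndarray:
    """Scale so that max |sample| equals `peak`; silence is returned unchanged."""
    x = np.asarray(waveform, dtype=np.float64)
    m = np.max(np.abs(x)) if x.size else 0.0
    if m == 0.0:
        return x.copy()
    return x * (peak / m)


def rms(waveform: np.ndarray) -> float:
    x = np.asarray(waveform, dtype=np.float64)
    return float(np.sqrt(np.mean(x**2))) if x.size else 0.0
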