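"""Spectro-temporal modulation spectra.

The modulation spectrum of a sound is the magnitude of the 2-D Fourier
transform of its (Gaussian-window) spectrogram: the temporal-modulation
axis (Hz) captures rhythm and amplitude modulation, the spectral-modulation
axis (cycles/kHz) captures harmonic spacing and formant structure. Two
window/step presets are provided: "corpus" (50 ms / 25 ms; temporal Nyquist
20 Hz, adequate for syllable-rate rhythm) and "roughness" (15 ms / 5 ms;
temporal Nyquist 100 Hz, required for amplitude modulation in the
perceptual roughness zone above 50 Hz). Recordings longer than 10 s are
analyzed in 10 s chunks and averaged. Category averages are interpolated to
a common grid, min-max normalized to [0, 1], and compared as log-ratio
maps; absolute log-ratio values depend on the normalization chain, so the
maps show relative prevalence, not calibrated differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import RegularGridInterpolator

from .audio import peak_normalize

__all__ = [
    "Spectrogram",
    "ModulationSpectrum",
    "LogRatioMap",
    "PRESETS",
    "spectrogram",
    "modulation_spectrum",
    "chunk_and_average",
    "common_grid",
    "aggregate_category",
    "log_ratio_map",
    "band_energy",
    "SYLLABLE_BAND_HZ",
    "ROUGHNESS_BAND_HZ",
]

#: window_ms, step_ms presets
PRESETS = {"corpus": (50.0, 25.0), "roughness": (15.0, 5.0)}

SYLLABLE_BAND_HZ = (3.0, 8.0)
ROUGHNESS_BAND_HZ = (50.0, 80.0)


@dataclass
class Spectrogram:
    magnitude: np.ndarray  # (freq bins, frames), >= 0
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window_ms: float
    step_ms: float

    @property
    def frame_rate(self) -> float:
        return 1000.0 / self.step_ms


@dataclass
class ModulationSpectrum:
    magnitude: np.ndarray  # (spectral modulation bins, temporal modulation bins)
    temporal_hz: np.ndarray  # >= 0 after folding
    spectral_cpkhz: np.ndarray  # cycles/kHz, >= 0
    provenance: dict = field(default_factory=dict)

    @property
    def temporal_nyquist(self) -> float:
        return float(self.temporal_hz[-1])


@dataclass
class LogRatioMap:
    values: np.ndarray
    temporal_hz: np.ndarray
    spectral_cpkhz: np.ndarray
    label_a: str
    label_b: str
    epsilon: float


def spectrogram(
    waveform: np.ndarray,
    sample_rate: int,
    window_ms: float = 50.0,
    step_ms: float = 25.0,
) -> Spectrogram:
    """Gaussian-window short-time Fourier magnitude.

    The input is peak-normalized to 1 first, so recordings enter the
    modulation pipeline at the same peak amplitude. Window SD = length/6.
    """
    if step_ms <= 0 or window_ms < step_ms:
        raise ValueError(f"spectrogram: need window_ms >= step_ms > 0, got {window_ms}/{step_ms}")
    x = peak_normalize(np.asarray(waveform, dtype=np.float64))
    nper = int(round(window_ms / 1000 * sample_rate))
    hop = int(round(step_ms / 1000 * sample_rate))
    if x.size < nper:
        raise ValueError(f"spectrogram: waveform ({x.size} samples) shorter than one window ({nper})")
    win = signal.windows.gaussian(nper, std=nper / 6.0)
    freqs, times, Z = signal.stft(
        x, fs=sample_rate, window=win, nperseg=nper, noverlap=nper - hop,
        boundary=None, padded=False,
    )
    return Spectrogram(
        magnitude=np.abs(Z), freqs_hz=freqs, times_s=times,
        window_ms=window_ms, step_ms=step_ms,
    )


def modulation_spectrum(spec: Spectrogram, fold: bool = True) -> ModulationSpectrum:
    """Magnitude of the 2-D FFT of the mean-subtracted spectrogram.

    The spectrogram mean (DC) is removed so the origin does not dominate.
    The spectral-modulation axis is reported in cycles/kHz; only its
    non-negative half is kept (the spectrogram is real, so the negative
    half is redundant). With ``fold=True`` the negative temporal-modulation
    half is folded onto the positive by averaging mirrored magnitudes
    (upward and downward sweeps are not distinguished); with ``fold=False``
    the full signed temporal axis is returned.
    """
    S = spec.magnitude
    n_f, n_t = S.shape
    if n_t < 8:
        raise ValueError(f"modulation_spectrum: need >= 8 frames, got {n_t}")
    M = np.abs(np.fft.fft2(S - S.mean()))
    step_s = spec.step_ms / 1000.0
    df_hz = spec.freqs_hz[1] - spec.freqs_hz[0]
    t_freqs = np.fft.fftfreq(n_t, d=step_s)
    s_freqs = np.fft.fftfreq(n_f, d=df_hz) * 1000.0  # cycles/kHz

    # order both axes; keep non-negative spectral half
    t_order = np.argsort(np.fft.fftshift(t_freqs), kind="stable")
    M = np.fft.fftshift(M, axes=(0, 1))
    tf = np.sort(np.fft.fftshift(t_freqs))
    sf = np.sort(np.fft.fftshift(s_freqs))
    keep_s = sf >= 0
    M = M[keep_s]
    sf = sf[keep_s]

    prov = {"window_ms": spec.window_ms, "step_ms": spec.step_ms, "n_chunks": 1}
    if not fold:
        return ModulationSpectrum(magnitude=M, temporal_hz=tf, spectral_cpkhz=sf, provenance=prov)

    pos = tf >= 0
    tf_pos = tf[pos]
    folded = np.empty((M.shape[0], tf_pos.size))
    for j, f in enumerate(tf_pos):
        col = M[:, np.isclose(tf, f)]
        mirror = M[:, np.isclose(tf, -f)]
        both = np.concatenate([col, mirror], axis=1)
        folded[:, j] = both.mean(axis=1)
    return ModulationSpectrum(magnitude=folded, temporal_hz=tf_pos, spectral_cpkhz=sf, provenance=prov)


def chunk_and_average(
    waveform: np.ndarray,
    sample_rate: int,
    chunk_s: float = 10.0,
    window_ms: float = 50.0,
    step_ms: float = 25.0,
    min_partial_s: float = 1.0,
) -> ModulationSpectrum:
    """Modulation spectrum averaged over consecutive ``chunk_s`` chunks.

    Recordings up to chunk_s long yield a single spectrum; longer ones are
    cut into chunks whose spectra are arithmetically averaged (a final
    partial chunk is included, interpolated to the full-chunk grid, if at
    least ``min_partial_s`` long).
    """
    x = np.asarray(waveform, dtype=np.float64)
    n_chunk = int(round(chunk_s * sample_rate))
    if x.size <= n_chunk:
        ms = modulation_spectrum(spectrogram(x, sample_rate, window_ms, step_ms))
        return ms
    pieces = [x[i : i + n_chunk] for i in range(0, x.size, n_chunk)]
    if pieces[-1].size < min_partial_s * sample_rate:
        pieces = pieces[:-1]
    spectra = [
        modulation_spectrum(spectrogram(p, sample_rate, window_ms, step_ms)) for p in pieces
    ]
    ref = spectra[0]
    mats = [ref.magnitude]
    for ms in spectra[1:]:
        if ms.magnitude.shape == ref.magnitude.shape and np.allclose(
            ms.temporal_hz, ref.temporal_hz
        ):
            mats.append(ms.magnitude)
        else:
            mats.append(_interp_to(ms, ref.temporal_hz, ref.spectral_cpkhz))
    avg = np.mean(mats, axis=0)
    prov = dict(ref.provenance)
    prov["n_chunks"] = len(mats)
    return ModulationSpectrum(
        magnitude=avg, temporal_hz=ref.temporal_hz, spectral_cpkhz=ref.spectral_cpkhz,
        provenance=prov,
    )


def _interp_to(ms: ModulationSpectrum, t_grid: np.ndarray, s_grid: np.ndarray) -> np.ndarray:
    interp = RegularGridInterpolator(
        (ms.spectral_cpkhz, ms.temporal_hz), ms.magnitude,
        bounds_error=False, fill_value=None,  # linear extrapolation at edges
    )
    T, S = np.meshgrid(t_grid, s_grid)
    return np.clip(interp(np.stack([S.ravel(), T.ravel()], axis=-1)).reshape(S.shape), 0, None)


def common_grid(
    spectra: list[ModulationSpectrum], grid_size: int | tuple[int, int] = 100
) -> tuple[np.ndarray, np.ndarray]:
    """(temporal, spectral) grid spanning the intersection of axis ranges."""
    if isinstance(grid_size, int):
        grid_size = (grid_size, grid_size)
    t_hi = min(ms.temporal_hz[-1] for ms in spectra)
    s_hi = min(ms.spectral_cpkhz[-1] for ms in spectra)
    t_lo = max(ms.temporal_hz[0] for ms in spectra)
    s_lo = max(ms.spectral_cpkhz[0] for ms in spectra)
    if t_hi <= t_lo or s_hi <= s_lo:
        bad = [
            i
            for i, ms in enumerate(spectra)
            if ms.temporal_hz[-1] == t_hi or ms.spectral_cpkhz[-1] == s_hi
        ]
        raise ValueError(f"common_grid: disjoint axis ranges (spectra {bad})")
    return np.linspace(t_lo, t_hi, grid_size[1]), np.linspace(s_lo, s_hi, grid_size[0])


def aggregate_category(
    spectra: list[ModulationSpectrum],
    grid_size: int | tuple[int, int] = 100,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModulationSpectrum:
    """Average spectra on a common grid; min-max normalize to [0, 1].

    The common grid spans the intersection of the axis ranges (bilinear
    interpolation, default 100 x 100); pass an explicit ``grid`` (temporal,
    spectral) to put several categories on one shared grid. Raises if any
    spectrum's axes do not overlap the others'.
    """
    if not spectra:
        raise ValueError("aggregate_category: need >= 1 spectrum")
    t_grid, s_grid = grid if grid is not None else common_grid(spectra, grid_size)
    acc = np.mean([_interp_to(ms, t_grid, s_grid) for ms in spectra], axis=0)
    lo, hi = acc.min(), acc.max()
    if hi > lo:
        acc = (acc - lo) / (hi - lo)
    prov = {"n_spectra": len(spectra), "normalized": True}
    return ModulationSpectrum(magnitude=acc, temporal_hz=t_grid, spectral_cpkhz=s_grid, provenance=prov)


def log_ratio_map(
    a: ModulationSpectrum,
    b: ModulationSpectrum,
    epsilon: float | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> LogRatioMap:
    """log((A + eps) / (B + eps)) on a shared grid.

    eps defaults to 1e-6 x the larger of the two matrix maxima, keeping the
    map finite. Antisymmetric: log_ratio(A, B) = -log_ratio(B, A).
    """
    if a.magnitude.shape != b.magnitude.shape or not (
        np.allclose(a.temporal_hz, b.temporal_hz) and np.allclose(a.spectral_cpkhz, b.spectral_cpkhz)
    ):
        raise ValueError("log_ratio_map: spectra are not on identical grids")
    if epsilon is None:
        epsilon = 1e-6 * max(a.magnitude.max(), b.magnitude.max())
    vals = np.log((a.magnitude + epsilon) / (b.magnitude + epsilon))
    return LogRatioMap(
        values=vals, temporal_hz=a.temporal_hz.copy(), spectral_cpkhz=a.spectral_cpkhz.copy(),
        label_a=label_a, label_b=label_b, epsilon=float(epsilon),
    )


def band_energy(ms: ModulationSpectrum, band_hz: tuple[float, float]) -> float:
    """Fraction of total modulation-spectrum magnitude in a temporal band.

    Requesting a band that extends beyond the temporal Nyquist of the
    analysis (e.g. the 50-80 Hz roughness band with a 25 ms step, Nyquist
    20 Hz) raises a configuration error rather than returning aliased
    values.
    """
    lo, hi = band_hz
    if lo >= hi:
        raise ValueError(f"band_energy: empty band {band_hz}")
    if hi > ms.temporal_nyquist + 1e-9:
        raise ValueError(
            f"band_energy: band {band_hz} Hz exceeds temporal Nyquist "
            f"{ms.temporal_nyquist:.1f} Hz of this analysis; use a shorter step "
            f"(e.g. the 'roughness' preset)"
        )
    cols = (ms.temporal_hz >= lo) & (ms.temporal_hz <= hi)
    if not np.any(cols):
        raise ValueError(f"band_energy: no temporal-modulation bins in band {band_hz}")
    total = ms.magnitude.sum()
    if total == 0:
        return 0.0
    return float(ms.magnitude[:, cols].sum() / total)
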