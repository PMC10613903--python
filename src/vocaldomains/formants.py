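"""Formant measurement, apparent vocal-tract length (VTL), normalization,
rater merging, and vowel-space density maps.

Under the quarter-wave (closed-open) uniform-tube model a tract of length L
resonates at F_i = (2i - 1) c / (4 L). Regressing measured formants on the
odd integers (2i - 1) through the origin gives a slope s, from which the
apparent VTL is L = c / (4 s) with c = 35000 cm/s. Formants are
speaker-normalized by scaling to a 17 cm reference tract:
F_norm = F * (L / 17).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.linalg import solve_toeplitz

__all__ = [
    "FormantMeasurement",
    "VTLEstimate",
    "NormalizedVowel",
    "DensityMap",
    "measure_formants",
    "estimate_vtl",
    "normalize_formants",
    "merge_raters",
    "vowel_space_density",
    "SPEED_OF_SOUND_CM_S",
    "REFERENCE_VTL_CM",
]

SPEED_OF_SOUND_CM_S = 35000.0
REFERENCE_VTL_CM = 17.0


@dataclass
class FormantMeasurement:
    region: tuple[float, float]  # (start s, end s)
    F: list[float]  # F1..Fn, Hz; ascending
    rater: str = "auto"
    low_confidence: bool = False

    def __post_init__(self):
        present = [f for f in self.F if f is not None and not np.isnan(f)]
        if any(f1 >= f2 for f1, f2 in zip(present, present[1:])):
            raise ValueError(f"FormantMeasurement: formants must ascend, got {self.F}")
        if any(f <= 0 for f in present):
            raise ValueError("FormantMeasurement: formants must be > 0")


@dataclass
class VTLEstimate:
    length_cm: float
    n_formants_used: int
    speed_of_sound: float = SPEED_OF_SOUND_CM_S


@dataclass
class NormalizedVowel:
    F1n: float
    F2n: float

    def __post_init__(self):
        if not 0 < self.F1n < self.F2n:
            raise ValueError(f"NormalizedVowel: need 0 < F1n < F2n, got {self.F1n}, {self.F2n}")


@dataclass
class DensityMap:
    f2_grid: np.ndarray  # Hz, axis 1
    f1_grid: np.ndarray  # Hz, axis 0
    density: np.ndarray  # shape (len(f1_grid), len(f2_grid)); integrates to 1
    mass_levels: dict[float, float]  # requested mass -> density threshold


# ---------------------------------------------------------------------------
# LPC formant measurement


def _lpc_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear prediction coefficients (a[0] = 1)."""
    x = x * np.hamming(x.size)
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if r[0] <= 0:
        raise ValueError("LPC: zero-energy frame")
    r = r / r[0]
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate(([1.0], a))


def measure_formants(
    waveform: np.ndarray,
    sample_rate: int,
    region: tuple[float, float] | None = None,
    n_formants: int = 4,
    max_freq: float = 5000.0,
    max_bandwidth: float = 800.0,
) -> FormantMeasurement:
    """Formant frequencies by linear-prediction root solving.

    The region is resampled to 2 x max_freq, pre-emphasized (first
    difference with a 50 Hz corner, the conventional +6 dB/oct), and
    analyzed with LPC order 2 x n_formants + 2; roots with center
    frequencies in (90 Hz, max_freq) and bandwidths below
    ``max_bandwidth`` become formant candidates, sorted ascending. If
    fewer peaks than requested are found the result is flagged
    low-confidence, with NaN for missing higher formants.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if region is None:
        region = (0.0, x.size / sample_rate)
    i0, i1 = (int(round(b * sample_rate)) for b in region)
    if not (0 <= i0 < i1 <= x.size):
        raise ValueError(f"measure_formants: region {region} outside waveform")
    seg = x[i0:i1]
    if np.max(np.abs(seg)) == 0:
        return FormantMeasurement(region=region, F=[np.nan] * n_formants, low_confidence=True)

    fs = 2 * max_freq
    from math import gcd

    g = gcd(int(fs), int(sample_rate))
    seg = signal.resample_poly(seg, int(fs) // g, int(sample_rate) // g)
    # pre-emphasis, ~50 Hz corner (+6 dB/oct)
    alpha = np.exp(-2 * np.pi * 50.0 / fs)
    seg = np.append(seg[0], seg[1:] - alpha * seg[:-1])

    order = 2 * n_formants + 2
    a = _lpc_coefficients(seg, order)
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2 * np.pi)
    bws = -np.log(np.abs(roots)) * fs / np.pi
    keep = (freqs > 90.0) & (freqs < max_freq * 0.99) & (bws < max_bandwidth)
    found = np.sort(freqs[keep])[:n_formants]
    F = list(found) + [np.nan] * (n_formants - found.size)
    return FormantMeasurement(region=region, F=F, low_confidence=found.size < n_formants)


# ---------------------------------------------------------------------------
# VTL


def estimate_vtl(F: list[float] | np.ndarray) -> VTLEstimate:
    """Apparent VTL by the regression method.

    Least squares through the origin of F_i on (2i - 1) gives slope
    s = sum(F_i (2i-1)) / sum((2i-1)^2); L = c / (4 s).
    """
    F = np.asarray([f for f in F if f is not None and not np.isnan(f)], dtype=np.float64)
    if F.size < 2:
        raise ValueError("estimate_vtl: need >= 2 formants")
    if np.any(np.diff(F) <= 0) or np.any(F <= 0):
        raise ValueError(f"estimate_vtl: formants must be positive ascending, got {F}")
    odd = 2 * np.arange(1, F.size + 1) - 1
    slope = float(np.sum(F * odd) / np.sum(odd**2))
    return VTLEstimate(length_cm=SPEED_OF_SOUND_CM_S / (4 * slope), n_formants_used=F.size)


def normalize_formants(m: FormantMeasurement, vtl: VTLEstimate) -> NormalizedVowel:
    """Scale F1/F2 to the 17 cm reference tract: Fn = F * (L / 17)."""
    if len(m.F) < 2 or np.isnan(m.F[0]) or np.isnan(m.F[1]):
        raise ValueError("normalize_formants: F1 and F2 required")
    k = vtl.length_cm / REFERENCE_VTL_CM
    return NormalizedVowel(F1n=m.F[0] * k, F2n=m.F[1] * k)


# ---------------------------------------------------------------------------
# rater merging


def merge_raters(
    measurements: list[FormantMeasurement],
    corpus_f1: np.ndarray | None = None,
    corpus_f2: np.ndarray | None = None,
    sd_limit: float = 3.0,
) -> tuple[FormantMeasurement, list[bool]]:
    """Average dual-rater measurements of one region; flag outliers.

    Consensus is the per-formant arithmetic mean (NaN-aware). Each input
    measurement is flagged if its F1 or F2 lies more than ``sd_limit``
    standard deviations from the corpus mean (corpus_f1/corpus_f2 are the
    reference samples of speaker-normalized values; no flagging without
    them). Region boundaries must agree across raters.
    """
    if not measurements:
        raise ValueError("merge_raters: need >= 1 measurement")
    r0 = measurements[0].region
    for m in measurements[1:]:
        if not np.allclose(m.region, r0, atol=1e-9):
            raise ValueError(f"merge_raters: inconsistent regions {m.region} vs {r0}")
    n = max(len(m.F) for m in measurements)
    stack = np.full((len(measurements), n), np.nan)
    for i, m in enumerate(measurements):
        stack[i, : len(m.F)] = m.F
    with np.errstate(invalid="ignore"):
        consensus = np.nanmean(stack, axis=0)
    flags = []
    for m in measurements:
        flag = False
        for val, ref in ((m.F[0], corpus_f1), (m.F[1] if len(m.F) > 1 else np.nan, corpus_f2)):
            if ref is None or val is None or np.isnan(val):
                continue
            ref = np.asarray(ref, dtype=np.float64)
            sd = ref.std()
            if sd > 0 and abs(val - ref.mean()) > sd_limit * sd:
                flag = True
        flags.append(flag)
    merged = FormantMeasurement(
        region=r0, F=list(consensus), rater="consensus",
        low_confidence=any(m.low_confidence for m in measurements),
    )
    return merged, flags


# ---------------------------------------------------------------------------
# vowel-space density


def vowel_space_density(
    points: list[NormalizedVowel],
    mass_levels: tuple[float, ...] = (0.25, 0.5, 0.75, 0.95),
    grid_size: int = 120,
    pad: float = 0.25,
) -> DensityMap:
    """Kernel density of normalized vowels on an (F2n, F1n) grid.

    Gaussian KDE with Scott's-rule bandwidth; each requested mass level p
    is mapped to the density threshold whose superlevel set contains
    fraction p of the total grid mass (thresholds found by sorting cell
    masses). Degenerate point sets fall back to an inflated diagonal
    bandwidth with a warning.
    """
    if len(points) < 20:
        raise ValueError(f"vowel_space_density: need >= 20 points, got {len(points)}")
    xy = np.array([[p.F2n, p.F1n] for p in points]).T  # rows: F2, F1
    try:
        kde = stats.gaussian_kde(xy)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("vowel_space_density: degenerate points; using diagonal bandwidth")
        jitter = 1e-3 * (np.abs(xy).mean() + 1.0)
        rng = np.random.default_rng(0)
        kde = stats.gaussian_kde(xy + rng.normal(0, jitter, xy.shape))
    span2 = xy[0].max() - xy[0].min() or 1.0
    span1 = xy[1].max() - xy[1].min() or 1.0
    f2g = np.linspace(xy[0].min() - pad * span2, xy[0].max() + pad * span2, grid_size)
    f1g = np.linspace(xy[1].min() - pad * span1, xy[1].max() + pad * span1, grid_size)
    F2, F1 = np.meshgrid(f2g, f1g)
    dens = kde(np.vstack([F2.ravel(), F1.ravel()])).reshape(F1.shape)
    cell = (f2g[1] - f2g[0]) * (f1g[1] - f1g[0])
    total = dens.sum() * cell
    dens = dens / total  # grid mass sums to 1

    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    levels = {}
    for p in mass_levels:
        if not 0 < p <= 1:
            raise ValueError(f"vowel_space_density: mass level {p} outside (0, 1]")
        k = int(np.searchsorted(cum, p))
        levels[p] = float(flat[min(k, flat.size - 1)])
    return DensityMap(f2_grid=f2g, f1_grid=f1g, density=dens, mass_levels=levels)
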