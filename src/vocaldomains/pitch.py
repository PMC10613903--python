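"""Fundamental-frequency contours: tracking, smoothing, and prosodic descriptives.

A contour is a uniformly sampled f0 track (default step 25 ms) with a
voiced mask. Descriptives are computed in log-frequency units: octaves
above C0 = 16 Hz for the median, octaves for the range, octaves/s for the
mean absolute slope, and inflections (retained direction reversals) per
second of voiced audio. Before the descriptives, contours are low-pass
smoothed in the semitone domain with Gaussian filters; the conventional
cutoff pair is 10 Hz (keeps vibrato-rate modulation) and 1 Hz (keeps only
slow intonation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PitchContour",
    "SmoothingConfig",
    "InflectionRule",
    "PitchDescriptives",
    "EmptyContourError",
    "track_f0",
    "smooth_contour",
    "pitch_descriptives",
    "descriptives_by_cutoff",
    "read_contour_csv",
    "write_contour_csv",
    "C0_HZ",
]

C0_HZ = 16.0  # reference for "octaves above C0"
_COMB_CEIL_HZ = 3000.0  # spectral ceiling for harmonic-comb candidate scores


class EmptyContourError(ValueError):
    """Raised when descriptives are requested for an all-unvoiced contour."""


@dataclass
class PitchContour:
    times: np.ndarray  # s, uniform step
    f0: np.ndarray  # Hz; meaningful only where voiced
    voiced: np.ndarray  # bool

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (self.times.shape == self.f0.shape == self.voiced.shape):
            raise ValueError("PitchContour: times, f0, voiced must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(np.abs(steps - steps[0]) > 1e-6):
                raise ValueError("PitchContour: non-uniform time step")
        if np.any(self.f0[self.voiced] <= 0):
            raise ValueError("PitchContour: f0 must be > 0 at voiced frames")

    @property
    def step(self) -> float:
        if self.times.size < 2:
            return 0.025
        return float(self.times[1] - self.times[0])

    @property
    def n_voiced(self) -> int:
        return int(np.sum(self.voiced))

    def voiced_segments(self) -> list[np.ndarray]:
        """Index arrays of maximal runs of consecutive voiced frames."""
        idx = np.flatnonzero(self.voiced)
        if idx.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(idx) > 1)
        return np.split(idx, breaks + 1)


@dataclass
class SmoothingConfig:
    """Gaussian low-pass on the semitone-domain contour.

    ``cutoff`` is the filter's half-power (-3 dB) frequency in Hz.
    """

    cutoff: float = 10.0

    DEFAULT_PAIR = (10.0, 1.0)


@dataclass
class InflectionRule:
    """Hysteresis for counting direction reversals: successive retained
    extrema must differ by at least ``min_swing_cents``."""

    min_swing_cents: float = 20.0


@dataclass
class PitchDescriptives:
    median_oct: float  # octaves above C0 (16 Hz)
    range_oct: float
    slope_abs: float  # mean |d log2 f0 / dt|, octaves/s
    inflections_per_s: float
    median_hz: float
    min_hz: float
    max_hz: float
    sd_semitones: float
    prop_voiced: float
    cutoff_hz: float | None = None  # smoothing applied before computing, if any

    def as_dict(self) -> dict[str, float]:
        return {
            "median_oct": self.median_oct,
            "range_oct": self.range_oct,
            "slope_abs": self.slope_abs,
            "inflections_per_s": self.inflections_per_s,
            "median_hz": self.median_hz,
            "min_hz": self.min_hz,
            "max_hz": self.max_hz,
            "sd_semitones": self.sd_semitones,
            "prop_voiced": self.prop_voiced,
        }


# ---------------------------------------------------------------------------
# tracking


def track_f0(
    waveform: np.ndarray,
    sample_rate: int,
    step: float = 0.025,
    f0_min: float = 75.0,
    f0_max: float = 600.0,
    voicing_threshold: float = 0.45,
    silence_threshold: float = 0.03,
) -> PitchContour:
    """Autocorrelation pitch tracker with continuity and comb-evidence repair.

    Per frame, local maxima of the normalized autocorrelation in the lag
    range become f0 candidates. A Viterbi pass picks the path through each
    voiced run, penalizing octave-scale leaps (with a deadband for
    ordinary intonation movement and a cap so one corrupted frame cannot
    lock in a gross error); consecutive runs are linked across syllable
    gaps by a softer, capped continuity cost. Frames whose tracked
    frequency shows no harmonic comb on a long-window spectrum (formant
    ringing picked up when periodicity degrades) are re-picked by the
    line-vs-floor test, and isolated octave glitches are despiked with a
    running median. A frame is voiced when its best correlation exceeds
    ``voicing_threshold`` and a short trailing RMS window clears the
    silence gate (so syllable gaps are not bridged).

    Adequate for clean synthetic audio. Genuine period doubling
    (subharmonics) is tracked at the doubled period, as in any automatic
    tracker; recordings rich in nonlinear phenomena should supply
    manually corrected contour files, which all analysis functions accept
    via ``read_contour_csv``.
    """
    if f0_min >= f0_max:
        raise ValueError("track_f0: f0_min must be < f0_max")
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("track_f0: empty waveform")

    win = int(round(sample_rate * max(0.04, 3.0 / f0_min)))
    hop = int(round(sample_rate * step))
    n_frames = max(1, int(np.floor(x.size / hop)))
    lag_min = int(np.floor(sample_rate / f0_max))
    lag_max = int(np.ceil(sample_rate / f0_min))

    n_cand = 4
    times = np.arange(n_frames) * step
    cand_f0 = np.zeros((n_frames, n_cand))
    cand_r = np.zeros((n_frames, n_cand))  # raw correlation (voicing)
    cand_s = np.zeros((n_frames, n_cand))  # path score
    frame_rms = np.zeros(n_frames)
    gate_rms = np.zeros(n_frames)  # short-window RMS for the final voicing gate

    for i in range(n_frames):
        center = i * hop
        lo = max(0, center - win // 2)
        seg = x[lo : lo + win]
        if seg.size < lag_max + 2:
            seg = np.pad(seg, (0, lag_max + 2 - seg.size))
        seg = seg - np.mean(seg)
        frame_rms[i] = np.sqrt(np.mean(seg**2))
        # trailing short window: silent for a center at a syllable onset,
        # inside the syllable for a center just before its end
        gw = max(2, int(round(0.018 * sample_rate)))
        gseg = x[max(0, center - gw) : max(1, center)]
        gate_rms[i] = np.sqrt(np.mean(gseg**2)) if gseg.size else 0.0
        if frame_rms[i] == 0:
            continue
        nfft = int(2 ** np.ceil(np.log2(2 * seg.size)))
        spec = np.fft.rfft(seg, nfft)
        mag = np.abs(spec)
        ac = np.fft.irfft(spec * np.conj(spec))[: lag_max + 2]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        window = ac[lag_min : lag_max + 1]
        peaks = np.flatnonzero((window[1:-1] > window[:-2]) & (window[1:-1] >= window[2:])) + 1
        if peaks.size == 0:
            continue
        order = peaks[np.argsort(window[peaks])[::-1][:n_cand]]
        fbin = sample_rate / nfft
        for j, p in enumerate(order):
            lag = lag_min + p
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            f = sample_rate / (lag + delta)
            cand_f0[i, j] = f
            cand_r[i, j] = y1
            cand_s[i, j] = y1

    peak_rms = np.max(frame_rms) if frame_rms.size else 0.0
    audible = frame_rms > silence_threshold * peak_rms if peak_rms > 0 else np.zeros(n_frames, bool)
    has_cand = (np.max(cand_r, axis=1) > voicing_threshold) & audible

    # Viterbi-style path within each voiced run: reward score, penalize
    # octave-scale leaps between consecutive frames
    f0_out = np.zeros(n_frames)
    jump_cost = 4.0  # score penalty per octave between consecutive frames
    gap_cost = 1.0  # per octave across unvoiced gaps (links syllables)
    voiced = has_cand.copy()
    f_prev = 0.0  # last voiced frame's f0 from the previous run
    i = 0
    while i < n_frames:
        if not voiced[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_frames and voiced[j + 1]:
            j += 1
        run_scores = np.where(cand_f0[i] > 0, cand_s[i], -np.inf)
        if f_prev > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                link = np.abs(np.log2(np.where(cand_f0[i] > 0, cand_f0[i], 1.0) / f_prev))
            # cap the link so one mistracked syllable cannot drag the rest
            run_scores = run_scores - gap_cost * np.where(
                cand_f0[i] > 0, np.minimum(link, 0.8), 0.0
            )
        choice = np.zeros((j - i + 1, n_cand), dtype=int)
        for k in range(i + 1, j + 1):
            valid = cand_f0[k] > 0
            new = np.full(n_cand, -np.inf)
            for b in range(n_cand):
                if not valid[b]:
                    continue
                costs = np.full(n_cand, -np.inf)
                for a in range(n_cand):
                    if not np.isfinite(run_scores[a]) or cand_f0[k - 1, a] <= 0:
                        continue
                    d = abs(np.log2(cand_f0[k, b] / cand_f0[k - 1, a]))
                    # deadband: ordinary intonation moves up to ~2 oct/s
                    # (0.05 oct/frame) and must not be penalized, or a
                    # constant spurious track (formant ringing) outscores
                    # the moving true one; capped so one corrupted frame
                    # cannot lock in a gross error for the rest of the run
                    costs[a] = run_scores[a] - min(jump_cost * max(0.0, d - 0.06), 2.5)
                best = int(np.argmax(costs))
                new[b] = costs[best] + cand_s[k, b]
                choice[k - i, b] = best
            run_scores = new
        b = int(np.argmax(run_scores))
        for k in range(j, i - 1, -1):
            f0_out[k] = cand_f0[k, b]
            b = choice[k - i, b]
        f_prev = f0_out[j]
        i = j + 1

    voiced &= f0_out > 0
    _repair_runs_by_line_floor(x, sample_rate, cand_f0, cand_r, f0_out, voiced, hop)
    _despike(f0_out, voiced)
    # final voicing gate: a short centered RMS window excludes frames whose
    # center falls in a syllable gap even when the long analysis window
    # still sees periodic energy from the neighboring syllables
    gate_peak = np.max(gate_rms) if gate_rms.size else 0.0
    if gate_peak > 0:
        voiced &= gate_rms > 4.0 * silence_threshold * gate_peak
    # unvoiced frames carry a placeholder 1.0 so the container invariant holds
    return PitchContour(times=times, f0=np.where(voiced, f0_out, 1.0), voiced=voiced)


def _line_floor_ratio(mag: np.ndarray, fbin: float, f: float, ceil_hz: float) -> float:
    """Mean log-magnitude excess of the first partials of f over the
    between-partial floor. Large when f's multiples are real spectral
    lines; near zero when f is a resonance frequency with no comb."""
    k = np.arange(1, min(6, int(ceil_hz / f)) + 1)
    if k.size < 2:
        return np.inf  # too few partials in band to judge; leave alone
    logmag = np.log(np.maximum(mag, 1e-12))
    i_line = np.clip(np.round(k * f / fbin).astype(int), 0, logmag.size - 1)
    i_floor = np.clip(np.round((k + 0.5) * f / fbin).astype(int), 0, logmag.size - 1)
    return float(np.mean(logmag[i_line]) - np.mean(logmag[i_floor]))


def _despike(f0_out: np.ndarray, voiced: np.ndarray, max_dev_oct: float = 0.3) -> None:
    """Replace isolated f0 outliers with the 3-point running median (in
    place, log domain, per voiced run). Octave-glitch single frames blow up
    the contour's range; genuine steps and vibrato pass through a 3-point
    median unchanged."""
    idx = np.flatnonzero(voiced)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, breaks + 1):
        if seg.size < 3:
            continue
        lf = np.log2(f0_out[seg])
        med = lf.copy()
        med[1:-1] = np.median(np.column_stack([lf[:-2], lf[1:-1], lf[2:]]), axis=1)
        bad = np.abs(lf - med) > max_dev_oct
        f0_out[seg[bad]] = 2.0 ** med[bad]


def _repair_runs_by_line_floor(
    x: np.ndarray,
    sample_rate: int,
    cand_f0: np.ndarray,
    cand_r: np.ndarray,
    f0_out: np.ndarray,
    voiced: np.ndarray,
    hop: int,
    margin: float = 1.0,
) -> None:
    """Repair voiced runs locked onto a non-harmonic frequency (in place).

    When periodicity degrades (heavy jitter, a frequency jump mid-window)
    the autocorrelation peak of formant ringing can win an entire run. The
    line-vs-floor comb score exposes this: the true f0's multiples are
    real spectral lines, a resonance frequency's are not. A run is
    repaired when, at a majority of probe frames, some other candidate's
    comb beats the tracked one by a clear margin; its frames are then
    re-picked to their best-comb candidates. Safe against octave-up
    flips (the doubled f0's "floor" samples are real odd harmonics, so
    its score never clearly beats the true f0's).
    """
    n_frames = f0_out.size
    win = int(round(0.1 * sample_rate))

    def spectrum(frame: int):
        center = frame * hop
        lo = max(0, center - win // 2)
        seg = x[lo : lo + win]
        if seg.size < win // 2:
            return None, 0.0
        seg = (seg - seg.mean()) * np.hanning(seg.size)
        nfft = int(2 ** np.ceil(np.log2(4 * seg.size)))
        return np.abs(np.fft.rfft(seg, nfft)), sample_rate / nfft

    def best_candidate(frame: int, mag, fbin):
        best_f, best_lf = 0.0, -np.inf
        for ci in range(cand_f0.shape[1]):
            fc = cand_f0[frame, ci]
            if fc <= 0 or cand_r[frame, ci] < 0.3:
                continue
            lf = _line_floor_ratio(mag, fbin, fc, _COMB_CEIL_HZ)
            if np.isfinite(lf) and lf > best_lf:
                best_f, best_lf = fc, lf
        return best_f, best_lf

    # run-edge frames are skipped: their analysis window straddles a
    # syllable boundary, smearing the comb and inviting false repairs
    interior = voiced.copy()
    idx = np.flatnonzero(voiced)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            interior[seg[0]] = False
            interior[seg[-1]] = False
    for k in range(n_frames):
        if not interior[k] or f0_out[k] <= 0:
            continue
        mag, fbin = spectrum(k)
        if mag is None:
            continue
        lf_cur = _line_floor_ratio(mag, fbin, f0_out[k], _COMB_CEIL_HZ)
        f_best, lf_best = best_candidate(k, mag, fbin)
        if f_best > 0 and np.isfinite(lf_best) and lf_best > lf_cur + margin:
            f0_out[k] = f_best


# ---------------------------------------------------------------------------
# smoothing


def smooth_contour(contour: PitchContour, cfg: SmoothingConfig) -> PitchContour:
    """Gaussian low-pass of each voiced segment in the semitone domain.

    The kernel's time-domain sigma is chosen so the filter's half-power
    (-3 dB) frequency equals ``cfg.cutoff``: sigma = sqrt(ln 2) / (2 pi fc).
    Unvoiced gaps are left untouched and never bridged. A constant contour
    is returned unchanged (DC invariance).
    """
    frame_rate = 1.0 / contour.step
    if cfg.cutoff <= 0 or cfg.cutoff >= frame_rate / 2:
        raise ValueError(
            f"SmoothingConfig.cutoff: {cfg.cutoff} Hz outside (0, {frame_rate / 2}) "
            f"for frame rate {frame_rate} Hz"
        )
    sigma_s = np.sqrt(np.log(2.0)) / (2 * np.pi * cfg.cutoff)
    sigma_frames = sigma_s * frame_rate
    f0 = contour.f0.copy()
    for seg in contour.voiced_segments():
        st = 12 * np.log2(contour.f0[seg])
        st_s = gaussian_filter1d(st, sigma_frames, mode="nearest")
        f0[seg] = 2.0 ** (st_s / 12.0)
    return PitchContour(times=contour.times.copy(), f0=f0, voiced=contour.voiced.copy())


# ---------------------------------------------------------------------------
# descriptives


def _count_inflections(semitones_segments: list[np.ndarray], min_swing_cents: float) -> int:
    """Retained direction reversals with hysteresis, summed over segments.

    Within each voiced segment, candidate extrema of the contour are
    scanned left to right; an extremum is retained only if it differs from
    the previously retained one by at least the threshold. The count of
    retained *interior* extrema (reversals) is returned.
    """
    thr = min_swing_cents / 100.0  # cents -> semitones
    total = 0
    for st in semitones_segments:
        if st.size < 3:
            continue
        d = np.diff(st)
        sign = np.sign(d)
        # compress plateaus: positions where direction actually changes
        idx_ext = []
        last_dir = 0.0
        for i, s in enumerate(sign):
            if s == 0:
                continue
            if last_dir != 0 and s != last_dir:
                idx_ext.append(i)  # st[i] is an extremum
            last_dir = s
        if not idx_ext:
            continue
        retained_val = st[0]
        count = 0
        for i in idx_ext:
            if abs(st[i] - retained_val) >= thr:
                retained_val = st[i]
                count += 1
        total += count
    return total


def pitch_descriptives(
    contour: PitchContour,
    rule: InflectionRule | None = None,
    cutoff_hz: float | None = None,
) -> PitchDescriptives:
    """Summary statistics of the voiced part of a contour.

    median_oct = log2(median f0 / 16 Hz); range_oct = log2(max/min);
    slope_abs = mean |Delta log2 f0| / Delta t over consecutive voiced
    frames within segments; inflections_per_s = retained reversals (20-cent
    hysteresis by default) divided by the total voiced duration.
    """
    rule = rule or InflectionRule()
    segs = contour.voiced_segments()
    v = contour.f0[contour.voiced]
    if v.size < 1:
        raise EmptyContourError("pitch_descriptives: contour has no voiced frames")

    step = contour.step
    med = float(np.median(v))
    fmin, fmax = float(np.min(v)), float(np.max(v))
    lf = np.log2(v)
    slopes = []
    for seg in segs:
        if seg.size >= 2:
            slopes.append(np.abs(np.diff(np.log2(contour.f0[seg]))) / step)
    slope_abs = float(np.mean(np.concatenate(slopes))) if slopes else 0.0
    voiced_dur = v.size * step
    n_infl = _count_inflections(
        [12 * np.log2(contour.f0[seg]) for seg in segs], rule.min_swing_cents
    )
    return PitchDescriptives(
        median_oct=float(np.log2(med / C0_HZ)),
        range_oct=float(np.log2(fmax / fmin)),
        slope_abs=slope_abs,
        inflections_per_s=n_infl / voiced_dur,
        median_hz=med,
        min_hz=fmin,
        max_hz=fmax,
        sd_semitones=float(np.std(12 * lf)),
        prop_voiced=float(np.mean(contour.voiced)),
        cutoff_hz=cutoff_hz,
    )


def descriptives_by_cutoff(
    contour: PitchContour,
    cutoffs: tuple[float, ...] = SmoothingConfig.DEFAULT_PAIR,
    rule: InflectionRule | None = None,
) -> dict[float, PitchDescriptives]:
    """Descriptives after Gaussian smoothing at each cutoff (10 and 1 Hz by
    default). The 10 Hz set is the conventional headline set."""
    out = {}
    for c in cutoffs:
        sm = smooth_contour(contour, SmoothingConfig(cutoff=c))
        out[c] = pitch_descriptives(sm, rule, cutoff_hz=c)
    return out


# ---------------------------------------------------------------------------
# I/O


def write_contour_csv(contour: PitchContour, path) -> None:
    pd.DataFrame(
        {
            "time_s": contour.times,
            "f0_hz": np.where(contour.voiced, contour.f0, 0.0),
            "voiced": contour.voiced.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_contour_csv(path) -> PitchContour:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"contour file is empty: {path}") from e
    for col in ("time_s", "f0_hz", "voiced"):
        if col not in df.columns:
            raise ValueError(f"contour file missing column {col!r}: {path}")
    times = df["time_s"].to_numpy(float)
    if times.size >= 2:
        steps = np.diff(times)
        if np.any(np.abs(steps - steps[0]) > 1e-6):
            raise ValueError(f"contour file has non-uniform time step: {path}")
    voiced = df["voiced"].to_numpy() > 0
    f0 = df["f0_hz"].to_numpy(float)
    f0 = np.where(voiced, f0, 0.0) + (~voiced) * 1.0
    return PitchContour(times=times, f0=f0, voiced=voiced)
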