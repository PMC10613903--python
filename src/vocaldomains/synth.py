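"""Source-filter voice synthesizer with exact ground truth.

Additive harmonic synthesis: the glottal source is a sum of harmonics whose
instantaneous frequency follows a log-linearly interpolated f0 contour
(phase-continuous by integration), with a fixed dB/octave spectral rolloff.
The vocal-tract filter is a spectral envelope assembled from a cascade of
second-order resonator magnitude responses, one per formant, applied to
each partial at its instantaneous frequency; a +6 dB/oct lip-radiation
term gives the radiated spectrum its conventional net tilt. Syllable gating, sinusoidal amplitude
modulation, subharmonics (odd multiples of f0/2), frequency jumps and a
noise-based "chaos" component are all generated with sample-accurate
bookkeeping, so the returned GroundTruth reflects exactly what was
synthesized.

The goal is controlled test material for the analysis modules, not
perceptually convincing voice quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pitch import PitchContour

__all__ = [
    "SourceSpec",
    "FilterSpec",
    "SyllableSpec",
    "AMSpec",
    "VoiceSpec",
    "GroundTruth",
    "synthesize",
    "ground_truth",
    "make_fig3_demo",
    "PHENOMENON_LABELS",
]

#: Closed vocabulary of nonlinear-phenomenon labels.
PHENOMENON_LABELS = ("subharmonics", "am", "chaos", "fry")

_CTRL_STEP = 0.005  # s; control rate for slowly varying amplitudes
_FRAME_STEP = 0.025  # s; ground-truth contour step
_VOICING_GAIN = 0.1  # syllable-envelope gain above which a frame counts as voiced


@dataclass
class SourceSpec:
    """Glottal source: f0 trajectory plus nonlinear-phenomenon controls.

    f0 between anchors is interpolated log-linearly. ``jump_events`` are
    instantaneous octave shifts applied from their onset time onward.
    Phenomenon depths apply over the matching ``*_interval`` (whole
    recording when the interval is None).
    """

    f0_anchors: list[tuple[float, float]]
    rolloff: float = -12.0  # dB/octave
    jitter_cents: float = 0.0
    subharmonic_depth: float = 0.0
    chaos_depth: float = 0.0
    jump_events: list[tuple[float, float]] = field(default_factory=list)
    subharmonic_interval: tuple[float, float] | None = None
    chaos_interval: tuple[float, float] | None = None
    fry_interval: tuple[float, float] | None = None

    def validate(self) -> None:
        if len(self.f0_anchors) == 0:
            raise ValueError("SourceSpec.f0_anchors: at least one anchor required")
        times = [t for t, _ in self.f0_anchors]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("SourceSpec.f0_anchors: times must be strictly increasing")
        if any(f <= 0 for _, f in self.f0_anchors):
            raise ValueError("SourceSpec.f0_anchors: all f0 must be > 0")
        for name in ("subharmonic_depth", "chaos_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SourceSpec.{name}: must be in [0, 1], got {v}")
        if self.jitter_cents < 0:
            raise ValueError("SourceSpec.jitter_cents: must be >= 0")


@dataclass
class FilterSpec:
    """Vocal-tract filter as (center Hz, bandwidth Hz) formants."""

    formants: list[tuple[float, float]] = field(default_factory=list)

    @staticmethod
    def from_centers(centers: list[float]) -> "FilterSpec":
        """Formants at given centers with the default bandwidth 0.06*center + 50 Hz."""
        return FilterSpec([(c, 0.06 * c + 50.0) for c in centers])

    def validate(self) -> None:
        centers = [c for c, _ in self.formants]
        if any(c1 >= c2 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("FilterSpec.formants: centers must be strictly increasing")
        if any(c <= 0 for c in centers):
            raise ValueError("FilterSpec.formants: centers must be > 0")
        if any(b <= 0 for _, b in self.formants):
            raise ValueError("FilterSpec.formants: bandwidths must be > 0")


@dataclass
class SyllableSpec:
    """Rhythmic gating: n syllables of syllable_dur separated by gap_dur."""

    n_syllables: int = 1
    syllable_dur: float = 0.5
    gap_dur: float = 0.0
    attack: float = 0.02
    decay: float = 0.02

    def validate(self) -> None:
        if self.n_syllables < 1:
            raise ValueError("SyllableSpec.n_syllables: must be >= 1")
        for name in ("syllable_dur",):
            if getattr(self, name) <= 0:
                raise ValueError(f"SyllableSpec.{name}: must be > 0")
        if self.gap_dur < 0 or self.attack < 0 or self.decay < 0:
            raise ValueError("SyllableSpec: gap_dur/attack/decay must be >= 0")
        if self.attack + self.decay > self.syllable_dur:
            raise ValueError("SyllableSpec.attack+decay: must be <= syllable_dur")

    @property
    def total_dur(self) -> float:
        return self.n_syllables * self.syllable_dur + (self.n_syllables - 1) * self.gap_dur

    def onsets(self) -> np.ndarray:
        return np.arange(self.n_syllables) * (self.syllable_dur + self.gap_dur)

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Gating gain in [0, 1] at times t (linear attack/decay ramps)."""
        period = self.syllable_dur + self.gap_dur
        env = np.zeros_like(t, dtype=np.float64)
        rel = t - period * np.minimum(np.floor(t / period), self.n_syllables - 1)
        inside = (rel >= 0) & (rel < self.syllable_dur) & (t >= 0) & (t <= self.total_dur)
        g = np.ones_like(rel)
        if self.attack > 0:
            g = np.minimum(g, rel / self.attack)
        if self.decay > 0:
            g = np.minimum(g, (self.syllable_dur - rel) / self.decay)
        env[inside] = np.clip(g[inside], 0.0, 1.0)
        return env


@dataclass
class AMSpec:
    """Sinusoidal amplitude modulation over a time interval."""

    rate: float  # Hz
    depth: float  # 0..1
    interval: tuple[float, float]

    def validate(self) -> None:
        if self.rate <= 0:
            raise ValueError("AMSpec.rate: must be > 0")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"AMSpec.depth: must be in [0, 1], got {self.depth}")
        if self.interval[0] >= self.interval[1]:
            raise ValueError("AMSpec.interval: start must be < end")


@dataclass
class VoiceSpec:
    source: SourceSpec
    filter: FilterSpec = field(default_factory=FilterSpec)
    syllables: SyllableSpec = field(default_factory=SyllableSpec)
    am: AMSpec | None = None
    sample_rate: int = 44100
    seed: int = 0

    def validate(self) -> None:
        self.source.validate()
        self.filter.validate()
        self.syllables.validate()
        if self.am is not None:
            self.am.validate()
        if self.filter.formants:
            top = self.filter.formants[-1][0]
            if self.sample_rate < 2 * top:
                raise ValueError(
                    f"VoiceSpec.sample_rate: {self.sample_rate} Hz < 2 x highest "
                    f"formant center ({top} Hz)"
                )


@dataclass
class GroundTruth:
    """What was actually synthesized, in the analysis modules' terms."""

    f0_contour: PitchContour
    formant_centers: list[float]
    phenomenon_proportions: dict[str, float]
    jump_count: int
    segments: dict[str, list[tuple[float, float]]]
    jump_times: list[float]
    category: str = ""
    subcategory: str = ""
    sex: str = ""
    speaker_id: str = ""


def _formant_envelope_fn(filt: FilterSpec):
    """Return a vectorized spectral-envelope gain function over frequency (Hz).

    Cascade (product) of second-order resonator magnitude responses, each
    normalized to unit gain at its own center — the all-pole vocal-tract
    model, so linear-prediction analysis sees a matched spectral shape.
    """
    if not filt.formants:
        return lambda f: np.ones_like(np.asarray(f, dtype=np.float64))
    params = [(fc, bw / 2.0) for fc, bw in filt.formants]

    def gain(f):
        f = np.asarray(f, dtype=np.float64)
        total = np.ones_like(f)
        for fc, hb in params:
            mag = 1.0 / (np.sqrt((f - fc) ** 2 + hb**2) * np.sqrt((f + fc) ** 2 + hb**2))
            peak = 1.0 / (hb * np.sqrt(4 * fc**2 + hb**2))
            total *= mag / peak
        return total

    return gain


def _interval_mask(t: np.ndarray, interval: tuple[float, float] | None) -> np.ndarray:
    if interval is None:
        return np.ones_like(t, dtype=bool)
    return (t >= interval[0]) & (t < interval[1])


def _log2_f0(spec: VoiceSpec, t: np.ndarray) -> np.ndarray:
    """log2 f0 at times t: anchor interpolation plus jump steps, no jitter."""
    at = np.array([a for a, _ in spec.source.f0_anchors])
    af = np.log2([f for _, f in spec.source.f0_anchors])
    lf = np.interp(t, at, af)
    for tj, shift in spec.source.jump_events:
        lf[t >= tj] += shift
    return lf


def _harmonic_stack(phase: np.ndarray, freqs_ctrl: np.ndarray, amps_ctrl: np.ndarray,
                    t: np.ndarray, t_ctrl: np.ndarray, mult: np.ndarray) -> np.ndarray:
    """Sum of partials mult[k]*f0 with control-rate amplitudes upsampled to t."""
    out = np.zeros_like(t)
    for k, m in enumerate(mult):
        a = amps_ctrl[k]
        if not np.any(a > 0):
            continue
        out += np.interp(t, t_ctrl, a) * np.sin(m * phase)
    return out


def synthesize(spec: VoiceSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a VoiceSpec to audio plus its exact ground truth.

    Returns (waveform float64 peak-normalized to 0.9, GroundTruth). The
    ground-truth contour is sampled every 25 ms; a frame is voiced iff the
    syllable-envelope gain at its center exceeds 0.1. The truth f0 excludes
    random jitter (which is noise, not melody) but includes jump events.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    dur = spec.syllables.total_dur
    n = int(round(dur * sr))
    t = np.arange(n) / sr
    t_ctrl = np.arange(0.0, dur + _CTRL_STEP, _CTRL_STEP)

    lf0 = _log2_f0(spec, t)

    # jitter: control-rate Gaussian perturbation in cents, interpolated
    jit_cents = np.zeros_like(t_ctrl)
    if spec.source.jitter_cents > 0:
        jit_cents += spec.source.jitter_cents * rng.standard_normal(t_ctrl.size)
    chaos_mask_ctrl = _interval_mask(t_ctrl, spec.source.chaos_interval)
    if spec.source.chaos_depth > 0:
        jit_cents += np.where(
            chaos_mask_ctrl, 30.0 * spec.source.chaos_depth * rng.standard_normal(t_ctrl.size), 0.0
        )
    if spec.source.fry_interval is not None:
        # mild extra irregularity; fry is chiefly *labeled* ground truth
        fry_mask = _interval_mask(t_ctrl, spec.source.fry_interval)
        jit_cents += np.where(fry_mask, 15.0 * rng.standard_normal(t_ctrl.size), 0.0)
    lf0_jit = lf0 + np.interp(t, t_ctrl, jit_cents) / 1200.0

    f0_inst = 2.0**lf0_jit
    phase = 2 * np.pi * np.cumsum(f0_inst) / sr

    env_res = _formant_envelope_fn(spec.filter)

    def env_fn(f):
        # resonator cascade times the +6 dB/oct lip-radiation characteristic
        f = np.asarray(f, dtype=np.float64)
        return env_res(f) * (f / 500.0)

    f0_ctrl = 2.0 ** np.interp(t_ctrl, t, lf0)
    nyq = 0.98 * sr / 2.0
    n_harm = max(1, int(np.floor(nyq / np.min(f0_ctrl))))

    def rolloff_gain(harmonic_number: np.ndarray | float) -> np.ndarray:
        return 10.0 ** (spec.source.rolloff * np.log2(harmonic_number) / 20.0)

    # harmonics k*f0
    mult = np.arange(1, n_harm + 1, dtype=np.float64)
    freqs = mult[:, None] * f0_ctrl[None, :]
    amps = rolloff_gain(mult)[:, None] * env_fn(freqs)
    amps[freqs > nyq] = 0.0
    voice = _harmonic_stack(phase, f0_ctrl, amps, t, t_ctrl, mult)

    # subharmonics: odd multiples of f0/2, gated to their interval
    if spec.source.subharmonic_depth > 0:
        sub_mask_ctrl = _interval_mask(t_ctrl, spec.source.subharmonic_interval).astype(float)
        mult_s = np.arange(1, 2 * n_harm, 2, dtype=np.float64) / 2.0  # 0.5, 1.5, 2.5 ...
        freqs_s = mult_s[:, None] * f0_ctrl[None, :]
        amps_s = (
            spec.source.subharmonic_depth
            * rolloff_gain(np.maximum(mult_s, 0.5))[:, None]
            * env_fn(freqs_s)
            * sub_mask_ctrl[None, :]
        )
        amps_s[freqs_s > nyq] = 0.0
        voice = voice + _harmonic_stack(phase, f0_ctrl, amps_s, t, t_ctrl, mult_s)

    # chaos: amplitude wobble on the voiced sum plus formant-shaped noise
    if spec.source.chaos_depth > 0:
        wob = 1.0 + 0.4 * spec.source.chaos_depth * rng.standard_normal(t_ctrl.size)
        wob = np.where(chaos_mask_ctrl, np.clip(wob, 0.2, 2.0), 1.0)
        voice = voice * np.interp(t, t_ctrl, wob)
        noise = rng.standard_normal(n)
        spec_n = np.fft.rfft(noise)
        freqs_n = np.fft.rfftfreq(n, 1 / sr)
        noise = np.fft.irfft(spec_n * env_fn(freqs_n), n)
        mask_t = _interval_mask(t, spec.source.chaos_interval)
        v_rms = np.sqrt(np.mean(voice[mask_t] ** 2)) if np.any(mask_t) else 0.0
        n_rms = np.sqrt(np.mean(noise[mask_t] ** 2)) if np.any(mask_t) else 1.0
        if n_rms > 0 and v_rms > 0:
            noise *= spec.source.chaos_depth * v_rms / n_rms
        voice = voice + np.where(mask_t, noise, 0.0)

    # amplitude modulation inside its interval only
    if spec.am is not None:
        a0, a1 = spec.am.interval
        in_am = (t >= a0) & (t < a1)
        gain = 1.0 - spec.am.depth * (0.5 - 0.5 * np.cos(2 * np.pi * spec.am.rate * (t - a0)))
        voice = np.where(in_am, voice * gain, voice)

    voice *= spec.syllables.envelope(t)
    peak = np.max(np.abs(voice))
    if peak > 0:
        voice *= 0.9 / peak

    truth = _ground_truth(spec, dur)
    return voice, truth


def _ground_truth(spec: VoiceSpec, dur: float) -> GroundTruth:
    times = np.arange(0.0, dur + 1e-9, _FRAME_STEP)
    env = spec.syllables.envelope(times)
    voiced = env > _VOICING_GAIN
    f0 = 2.0 ** _log2_f0(spec, times)

    intervals: dict[str, list[tuple[float, float]]] = {lab: [] for lab in PHENOMENON_LABELS}
    whole = (0.0, dur)
    if spec.source.subharmonic_depth > 0:
        intervals["subharmonics"].append(spec.source.subharmonic_interval or whole)
    if spec.source.chaos_depth > 0:
        intervals["chaos"].append(spec.source.chaos_interval or whole)
    if spec.source.fry_interval is not None:
        intervals["fry"].append(spec.source.fry_interval)
    if spec.am is not None:
        intervals["am"].append(spec.am.interval)

    n_voiced = int(np.sum(voiced))
    props = {}
    for lab in PHENOMENON_LABELS:
        if n_voiced == 0:
            props[lab] = 0.0
            continue
        covered = np.zeros_like(voiced)
        for s, e in intervals[lab]:
            covered |= (times >= s) & (times < e)
        props[lab] = float(np.sum(covered & voiced) / n_voiced)

    jump_times = [tj for tj, _ in spec.source.jump_events]
    jump_count = int(
        sum(1 for tj in jump_times if spec.syllables.envelope(np.array([tj]))[0] > _VOICING_GAIN)
    )

    contour = PitchContour(times=times, f0=f0, voiced=voiced)
    return GroundTruth(
        f0_contour=contour,
        formant_centers=[c for c, _ in spec.filter.formants],
        phenomenon_proportions=props,
        jump_count=jump_count,
        segments={k: v for k, v in intervals.items() if v},
        jump_times=jump_times,
    )


def ground_truth(spec: VoiceSpec) -> GroundTruth:
    """Ground truth of a VoiceSpec without rendering audio (cheap)."""
    spec.validate()
    return _ground_truth(spec, spec.syllables.total_dur)


def make_fig3_demo(seed: int = 0, sample_rate: int = 16000) -> tuple[np.ndarray, GroundTruth]:
    """Laugh-like demonstration sound: six syllables with rising 100-300 Hz
    f0 in each, static equidistant formants at 500, 1500, 2500 ... Hz, and
    40 Hz sinusoidal amplitude modulation on the last two syllables.

    The per-syllable contour holds 100 Hz briefly, rises log-linearly, then
    holds 300 Hz until the syllable ends, so both endpoints are realized at
    25 ms frame centers.
    """
    syl = SyllableSpec(n_syllables=6, syllable_dur=0.25, gap_dur=0.1, attack=0.02, decay=0.03)
    anchors: list[tuple[float, float]] = []
    for onset in syl.onsets():
        anchors += [
            (onset, 100.0),
            (onset + 0.15 * syl.syllable_dur, 100.0),
            (onset + 0.80 * syl.syllable_dur, 300.0),
            (onset + syl.syllable_dur, 300.0),
        ]
    am_start = syl.onsets()[4]
    spec = VoiceSpec(
        source=SourceSpec(f0_anchors=anchors, rolloff=-12.0, jitter_cents=3.0),
        filter=FilterSpec.from_centers([500.0, 1500.0, 2500.0, 3500.0, 4500.0]),
        syllables=syl,
        am=AMSpec(rate=40.0, depth=0.7, interval=(am_start, syl.total_dur)),
        sample_rate=sample_rate,
        seed=seed,
    )
    return synthesize(spec)
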