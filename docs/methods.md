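# Methods

This note documents the models behind each module, the parameter choices
that matter, what the synthetic corpus does and does not emulate, and the
numerical conventions needed to reproduce results exactly.

## Source–filter synthesizer

The synthesizer is additive: the glottal source is a sum of harmonics of a
time-varying f₀, each rendered as sin(k·φ(t)) with the phase
φ(t) = 2π ∫ f₀ dt integrated at the sample rate, so frequency is exact and
phase is continuous through arbitrary contours. f₀ between anchor points
is interpolated log-linearly (musical intervals, not Hz, are linear in
perception); jump events add a step in log₂ f₀ from their onset time.

Harmonic k has amplitude `10^(rolloff·log2(k)/20)` (default −12 dB/oct,
a typical glottal spectrum) multiplied by the vocal-tract gain at its
instantaneous frequency and by a +6 dB/oct lip-radiation term. The tract
gain is a **cascade (product) of second-order resonator magnitude
responses**, one per formant, each normalized to unit gain at its center;
default bandwidth 0.06·center + 50 Hz. The cascade form is the all-pole
model that linear-prediction analysis assumes, so formant measurement is
unbiased on this material (a parallel sum of resonators, by contrast,
shifts close formants by up to ~10%).

Nonlinear phenomena:

- **Subharmonics**: an added series at odd multiples of f₀/2 with relative
  amplitude `subharmonic_depth`, gated to an interval — true period
  doubling.
- **Chaos**: multiplicative amplitude wobble, extra jitter, and
  formant-shaped noise mixed at `chaos_depth` relative RMS. This is
  *labeled* ground truth for proportion bookkeeping, not a physically
  chaotic oscillator.
- **Amplitude modulation**: a raised-cosine gain 1 − d(½ − ½cos 2πrt)
  inside its interval.
- **Fry**: a mild (15-cent) extra jitter over its interval; chiefly a
  label, like chaos.
- **Jitter**: Gaussian perturbation of log f₀ at a 5 ms control rate.

Syllable gating multiplies the sum by a linear attack/decay envelope;
gaps are exactly zero. Ground truth is sampled every 25 ms: a frame is
voiced iff the envelope gain at its center exceeds 0.1; the truth f₀
includes jumps but excludes jitter (noise is not melody). Amplitudes vary
at a 5 ms control rate and are linearly interpolated to the sample rate.

The demonstration sound is six 0.25 s syllables with 0.1 s gaps; inside
each syllable f₀ holds 100 Hz for 15% of its length, rises log-linearly,
and holds 300 Hz for the final 20%, so both endpoints are realized at
25 ms frame centers. Formants sit at 500, 1500, 2500, 3500, 4500 Hz and a
40 Hz, depth-0.7 sinusoidal AM covers the last two syllables. Any
syllable layout with at least four syllables would satisfy the same
description; this one keeps the sound short (2 s) while giving the
modulated portion enough frames for ~1.7 Hz temporal-modulation
resolution.

## Synthetic corpus: what it emulates

Four categories × two sexes, with per-recording parameters drawn from
category distributions (all defaults in `corpus.default_categories`):

| category | median f₀ m/f (Hz) | rhythm | phenomena (mean frame share) | jumps/min |
|---|---|---|---|---|
| Neutral speech | 129 / 215 | 0.13–0.15 s syllables, 0.08 s gaps | subharmonics 1.3%, fry 2.1% | 0.18 |
| Non-neutral speech | 202 / 323 | same | subharmonics 4.2%, am 1%, chaos 1% | 0.18 |
| Singing | 258 / 430 | 0.5–0.9 s notes, 5–6 Hz vibrato ±1 st | subharmonics 1% | 0.06 |
| Nonverbal | 258 / 430 | single 0.6–1.5 s vocalizations | am 11.5% (50–70 Hz), chaos 10.9%, subharmonics 5% | 3.0 |

Per-recording medians scatter log-normally around the category target
(σ = 0.15 oct, a realistic between-speaker spread); speech contours are
smoothed random walks scaled by their standard deviation (center-heavy —
a min–max rescale piles probability mass at the extremes and makes the
per-recording median statistically unstable); singing draws Gaussian note
pitches (σ = range/4) held per note under the vibrato. Phenomenon
intervals cover a contiguous block of voiced frames whose length is drawn
so that the mean affected fraction across recordings equals the target
(presence probability q, conditional fraction Beta with mean target/q,
precision 4). Speakers recur every two recordings within a cell, giving
the cluster bootstrap real structure.

Not emulated: articulation dynamics (formant transitions), consonants,
reverberation and channel noise, real vocal-fold biomechanics, and
perceptual voice quality. Passing tests therefore demonstrate that the
*analysis chain* is correct and that the category structure the generator
encodes is recoverable — not that any particular real-world corpus would
yield the same numbers.

## Pitch

Contours are tracked at a 25 ms step by normalized autocorrelation with
up to four candidates per frame and a Viterbi path per voiced run. Three
conventions matter:

- transition cost 4 per octave between consecutive frames, with a
  **0.06 oct/frame deadband** (ordinary intonation moves at up to
  ~2 oct/s and must not be penalized, or a constant spurious track such
  as formant ringing outscores the moving true one) and a cap of 2.5 per
  transition; runs are linked across syllable gaps at cost 1 per octave,
  capped at 0.8;
- frames whose tracked frequency shows no harmonic comb on a 100 ms
  spectrum (mean log-magnitude at its first ≤6 multiples not clearly
  above the level halfway between them) are re-picked to the candidate
  with the best comb; run-edge frames are exempt because their window
  straddles a syllable boundary;
- isolated octave glitches are replaced by a 3-point running median in
  log f₀.

Voicing requires best correlation > 0.45 and a trailing 18 ms RMS window
above 12% of its maximum (the trailing window is silent for a frame
centered at a syllable onset, so gaps are not bridged). On clean
synthetic audio the tracker is accurate to well under 1%; under genuine
period doubling it reports the doubled period (an octave low), as any
automatic tracker does — phenomena-rich recordings should use corrected
contour files (`read_contour_csv`), which is how the analysis functions
are designed to be fed and how such material is handled in practice.

Smoothing: each maximal voiced segment is filtered in the semitone domain
with a Gaussian kernel whose **half-power (−3 dB) frequency** equals the
cutoff (σ_t = √(ln 2)/(2π f_c)); gaps are untouched. The "central
frequency" of a Gaussian smoother is not uniquely defined; the −3 dB
convention is this package's documented choice. Descriptives are computed
at both 10 Hz and 1 Hz cutoffs; the 10 Hz set is the headline set.
Inflections: scan the direction reversals of the smoothed semitone
contour left to right and retain one only if it differs from the last
retained extremum by ≥ 20 cents; divide by total voiced duration.
"Per second" always uses voiced duration, since recordings differ in
silence content.

## Nonlinear phenomena and the ZOIB model

A voiced frame is affected by a phenomenon iff its center lies in an
annotated segment of that label (half-open [start, end), so splitting a
segment changes nothing). Jump rate = 60 × jumps within half a frame of a
voiced center ÷ voiced seconds; normalizing by voiced rather than total
duration is a documented choice.

The ZOIB likelihood factorizes over (zoi, coi) and (μ, φ): the inflation
MLEs are the closed-form frequencies zoi* = #{y∈{0,1}}/n and
coi* = #{y=1}/#{y∈{0,1}}, and (μ, φ) are fit to the continuous values by
multistart Nelder–Mead on (logit μ, log φ). coi is reported as NaN when
no inflated values are observed rather than invented. Group fits plus the
speaker-cluster bootstrap replace a Bayesian mixed model: the reported
summary (median and 95% interval per category × sex) is preserved without
an MCMC engine.

## Formants and vocal-tract length

Measurement: the region is resampled to twice the 5 kHz ceiling,
pre-emphasized (+6 dB/oct, 50 Hz corner), Hamming-windowed, and analyzed
by autocorrelation LPC of order 2·n_formants + 2; roots with center
frequencies in (90 Hz, ceiling) and bandwidths < 800 Hz become formants.
Missing higher formants are NaN with a low-confidence flag.

VTL: least squares **through the origin** of F_i on (2i−1) — the literal
quarter-wave tube model — gives slope s and L = c/(4s) with
c = 35 000 cm/s; normalization multiplies formants by L/17. The estimator
is exactly scale-equivariant and recovers any ideal tube length exactly.

Density maps use a Gaussian KDE (Scott's rule); a mass level p maps to
the density threshold whose superlevel set holds fraction p of total grid
mass, found by sorting cell masses.

## Modulation spectra

Spectrogram: Gaussian window (SD = length/6), peak-normalized input. Two
presets: **corpus** (50 ms / 25 ms; temporal Nyquist 20 Hz, fine for
syllable rhythm and economical for long recordings) and **roughness**
(15 ms / 5 ms; Nyquist 100 Hz, required for the 50–80 Hz roughness band —
asking for that band from the corpus preset raises an error instead of
returning aliased values). The 2-D FFT is taken on the linear-magnitude,
mean-subtracted matrix (no log compression; DC removed so the origin does
not dominate); the negative temporal half is folded onto the positive by
averaging mirrored magnitudes, i.e. upward and downward sweeps are not
distinguished. Per-recording spectra are not individually normalized;
only category averages are min–max normalized to [0, 1], and log-ratio
maps use ε = 10⁻⁶ × the larger matrix maximum. Because of this
normalization chain the maps have no natural zero: they show relative
prevalence, and pixel-wise significance testing is deliberately not
provided.

## Classification and bootstrap

The random forest uses sex plus the four headline pitch descriptives, 500
trees, `balanced_subsample` class weighting (each tree's bootstrap sample
is reweighted by class frequency, so rare categories carry equal weight),
and accuracy from out-of-bag votes macro-averaged across classes.
Averaged (balanced) rather than pooled accuracy is the documented
resolution of an ambiguity. The bootstrap resamples speakers (not
recordings) with replacement within category × sex and reports the
2.5/97.5 percentiles of the resampled medians.

## Problem sizes and determinism

The test suite exercises the full pipeline on a 400-recording corpus
(~50 per category × sex, 16 kHz, 1–6 s per recording) — large enough for
stable category statistics while keeping a full run under a minute of
synthesis plus a minute of analysis. All stochastic steps take explicit
seeds; a corpus, a pipeline run, and the acceptance script are bit-for-bit
reproducible given their configuration.

## Known limitations

- Under strong subharmonics the tracker reports f₀/2; only corrected
  contours recover the carrier convention.
- The per-recording f₀ *range* is sensitive to single voiced-frame
  differences at contour extremes; category-level statistics are robust,
  per-recording ranges on phenomena-rich audio are not.
- LPC formants assume an all-pole spectrum; nasalized or high-pitched
  material (sparse harmonics) degrades gracefully to flagged,
  low-confidence measurements but is not solved.
- The ZOIB fit treats recordings as exchangeable within a group;
  speaker dependence enters only through the bootstrap, not the
  likelihood.
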