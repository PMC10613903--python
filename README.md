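# vocaldomains

Acoustic characterization of the three human vocal domains — **speech**,
**singing**, and **nonverbal vocalizations** (laughs, screams, moans, roars)
— in the framework of source–filter theory, plus a source–filter voice
synthesizer that provides exact ground truth for validating every analysis
step.

The package is aimed at bioacousticians and voice researchers who want a
tested, scriptable pipeline for comparing vocal repertoires along four
axes:

1. **Voice source (pitch).** f₀ contours at a 25 ms step, Gaussian-smoothed
   in the semitone domain at 10 Hz and 1 Hz half-power cutoffs, summarized
   by median f₀ in octaves above C0 (16 Hz), f₀ range (octaves), mean
   absolute slope (oct/s), and inflections per second with a 20-cent
   hysteresis rule.
2. **Nonlinear phenomena.** Subharmonics, amplitude modulation,
   deterministic chaos and vocal fry as annotated segments; per recording,
   the proportion of voiced frames affected and frequency jumps per voiced
   minute. Across recordings these proportions pile up at 0 and 1, so they
   are modeled with a zero-one-inflated beta distribution:
   P(y=0) = zoi·(1−coi), P(y=1) = zoi·coi, and Beta(μφ, (1−μ)φ) on (0,1),
   fit by maximum likelihood per group.
3. **Vocal-tract filter (formants).** Linear-prediction formant
   measurement; apparent vocal-tract length from the quarter-wave
   regression F_i = (2i−1)c/4L (c = 35 000 cm/s); normalization to a 17 cm
   reference tract (F_norm = F·L/17); dual-rater merging with a >3 SD
   outlier flag; kernel-density vowel-space maps with mass-level contours.
4. **Spectro-temporal modulation.** The modulation spectrum — the 2-D FFT
   magnitude of a Gaussian-window spectrogram — over temporal modulation
   (Hz) × spectral modulation (cycles/kHz); 10 s chunk averaging, category
   averages on a common grid normalized to [0, 1], and log-ratio maps for
   category contrasts (syllable band 3–8 Hz vs roughness band 50–80 Hz).

A random-forest classifier predicts the vocal domain from speaker sex plus
the four pitch descriptives, with balanced out-of-bag accuracy, and a
speaker-cluster bootstrap gives category × sex summaries with 95%
intervals.

Because corpus audio is rarely redistributable, the package bundles a
**synthesizer** (`synth`, `corpus` modules): additive harmonic synthesis
through a cascade of second-order formant resonators, with syllable
gating, vibrato, subharmonics, jumps, chaos and amplitude modulation — and
it returns the exact ground truth (contour, annotations, formant centers)
of everything it renders, so the whole pipeline is testable end to end.

## Worked example

```bash
python examples/demo_sound_analysis.py
```

synthesizes a laugh-like demonstration sound — six syllables with f₀
rising 100→300 Hz in each, static formants at 500, 1500, 2500 … Hz, and
40 Hz amplitude modulation on the final two syllables — and reads the
construction parameters back from the audio:

```
tracked f0 range: 80.2 - 301.2 Hz (truth: 100 - 300 Hz)
measured formants: 499, 1501, 2504, 3498 Hz (truth: 500, 1500, 2500, 3500)
temporal-modulation peak above 20 Hz: 40.7 Hz (truth: 40 Hz)
```

The tracked maximum (301 Hz) recovers the 300 Hz contour top within 0.5%;
linear prediction finds all four formants within a few Hz; and the 40 Hz
modulation appears as the dominant temporal-modulation peak (40.7 Hz, one
1.7 Hz bin from truth) when analyzed with the short 15 ms / 5 ms preset
whose temporal Nyquist (100 Hz) covers the roughness range.

`python examples/corpus_pipeline_demo.py` runs the full pipeline on an
80-recording synthetic corpus and prints, among other things:

```
4-class balanced OOB accuracy: 87.5% (chance 25%)
3-class (speech merged):       94.2% (chance 33%)
speech-vs-nonverbal log-ratio: +0.15 in the 3-8 Hz syllable band,
                               -0.34 in the 50-80 Hz roughness band
```

i.e. sex plus four pitch descriptives separate the domains far above
chance, and the modulation contrast shows the expected structure: syllable
rhythm is a speech signature while fast amplitude modulation marks rough
nonverbal sounds. The other examples cover pitch descriptives, the
zero-one-inflated beta fit, and vocal-tract-length normalization.

## Layout

- `src/vocaldomains/synth.py`, `corpus.py` — synthesizer and corpus generator
- `src/vocaldomains/pitch.py` — tracking, smoothing, descriptives, contour CSV I/O
- `src/vocaldomains/nonlinear.py` — annotations, proportions, jump rates, ZOIB
- `src/vocaldomains/formants.py` — LPC formants, VTL, normalization, density maps
- `src/vocaldomains/modspec.py` — spectrograms, modulation spectra, log-ratios
- `src/vocaldomains/stats.py`, `pipeline.py` — feature tables, classifier,
  bootstrap, end-to-end orchestration
- `docs/methods.md` — models, parameter choices, and known limitations
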