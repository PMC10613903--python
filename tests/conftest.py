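import numpy as np
import pytest

import vocaldomains as vd

SR = 16000


@pytest.fixture(scope="session")
def fig3():
    """The laugh-like demonstration sound and its ground truth."""
    wave, truth = vd.make_fig3_demo(seed=1)
    return wave, truth, SR


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 40-recording synthetic corpus on disk (5 per category x sex)."""
    out = tmp_path_factory.mktemp("corpus40")
    cfg = vd.SynthCorpusConfig(n_recordings=40, seed=7)
    meta, truths = vd.generate_corpus(cfg, out)
    return out, meta, truths, cfg


def flat_tone_spec(f0=200.0, dur=1.0, formants=(), seed=0, **source_kw):
    return vd.VoiceSpec(
        source=vd.SourceSpec(f0_anchors=[(0.0, f0), (dur, f0)], **source_kw),
        filter=vd.FilterSpec.from_centers(list(formants)),
        syllables=vd.SyllableSpec(n_syllables=1, syllable_dur=dur),
        sample_rate=SR,
        seed=seed,
    )


def spectrum_peaks(wave, sr, prominence_rel=0.05):
    """Frequencies of prominent magnitude-spectrum peaks (test oracle)."""
    from scipy.signal import find_peaks

    mag = np.abs(np.fft.rfft(wave * np.hanning(wave.size)))
    freqs = np.fft.rfftfreq(wave.size, 1 / sr)
    peaks, _ = find_peaks(mag, height=prominence_rel * mag.max())
    return freqs[peaks], mag[peaks]
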