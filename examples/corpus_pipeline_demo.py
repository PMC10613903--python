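"""Generate a small synthetic corpus and run the full analysis pipeline.

Builds 80 recordings (neutral speech, non-neutral speech, singing,
nonverbal vocalizations; both sexes), tracks pitch, summarizes nonlinear
phenomena, measures formants, computes category modulation spectra, and
classifies the domain of each recording from sex + four pitch descriptives
with out-of-bag random-forest accuracy.

Writes all tables under ./scratch/example_pipeline (about 30 s).
"""

import vocaldomains as vd

cfg = vd.PipelineConfig(
    out_dir="scratch/example_pipeline",
    corpus=vd.SynthCorpusConfig(n_recordings=80, seed=0),
    n_trees=300,
    n_boot=200,
    seed=0,
)
res = vd.run_pipeline(cfg)

rep4 = res["classifier_reports"][4]
rep3 = res["classifier_reports"][3]
print(f"4-class balanced OOB accuracy: {rep4.averaged_accuracy:.1%}"
      f" (chance {rep4.chance_level:.0%})")
print(f"3-class (speech merged):       {rep3.averaged_accuracy:.1%}"
      f" (chance {rep3.chance_level:.0%})")
print("\nconfusion (4-class):")
print(rep4.confusion)

lr = res["logratio"]
syl = (lr.temporal_hz >= 3) & (lr.temporal_hz <= 8)
rough = (lr.temporal_hz >= 50) & (lr.temporal_hz <= 80)
print(f"\nspeech-vs-nonverbal log-ratio: {lr.values[:, syl].mean():+.2f} in the"
      f" 3-8 Hz syllable band, {lr.values[:, rough].mean():+.2f} in the"
      f" 50-80 Hz roughness band")
print("(positive = more prevalent in speech; syllable rhythm is a speech"
      "\nsignature, fast amplitude modulation marks rough nonverbal sounds)")
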