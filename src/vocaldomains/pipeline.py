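"""End-to-end orchestration: synthesize (or load) a corpus, then run the
pitch, nonlinear-phenomena, formant, modulation-spectrum and classification
stages, writing all tables and a settings log to an output directory.

Stages run in order; a failure aborts with the stage name while retaining
partial outputs. All seeds are recorded in the settings log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formants as fmod
from . import modspec as mmod
from .audio import read_wav
from .corpus import MERGED_CATEGORY, SynthCorpusConfig, generate_corpus
from .nonlinear import fit_zoib, phenomenon_proportions, read_annotation_csv
from .pitch import InflectionRule, descriptives_by_cutoff, read_contour_csv, track_f0
from .stats import bootstrap_summary, build_feature_table, classify_domains

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str | Path = "pipeline_out"
    corpus: SynthCorpusConfig = field(default_factory=SynthCorpusConfig)
    corpus_dir: str | Path | None = None  # reuse an existing corpus instead of generating
    use_truth_contours: bool = False  # analysis from ground-truth contours vs the tracker
    smoothing_cutoffs: tuple[float, float] = (10.0, 1.0)
    f0_min: float = 60.0
    f0_max: float = 1200.0
    modspec_preset: str = "roughness"
    run_formants: bool = True
    n_trees: int = 500
    n_boot: int = 500
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        corpus_kwargs = raw.pop("corpus", {})
        cfg = PipelineConfig(**raw)
        if corpus_kwargs:
            cfg.corpus = SynthCorpusConfig(**corpus_kwargs)
        return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - report the failing stage
                raise PipelineStageError(name, e) from e

        return wrapped

    return deco


@_stage("corpus")
def _stage_corpus(cfg: PipelineConfig, out: Path):
    if cfg.corpus_dir is not None:
        cdir = Path(cfg.corpus_dir)
        meta = pd.read_csv(cdir / "metadata.csv")
        return cdir, meta
    cdir = out / "corpus"
    meta, _ = generate_corpus(cfg.corpus, cdir)
    return cdir, meta


@_stage("pitch")
def _stage_pitch(cfg: PipelineConfig, out: Path, cdir: Path, meta: pd.DataFrame):
    rows = []
    for _, rec in meta.iterrows():
        stem = rec["file"].rsplit(".", 1)[0]
        if cfg.use_truth_contours:
            contour = read_contour_csv(cdir / f"{stem}_contour.csv")
        else:
            wave, sr = read_wav(cdir / rec["file"])
            contour = track_f0(wave, sr, f0_min=cfg.f0_min, f0_max=cfg.f0_max)
        by_cut = descriptives_by_cutoff(contour, cfg.smoothing_cutoffs, InflectionRule())
        row = {"file": rec["file"]}
        headline = cfg.smoothing_cutoffs[0]
        for cut, desc in by_cut.items():
            suffix = "" if cut == headline else f"_{cut:g}hz"
            row.update({k + suffix: v for k, v in desc.as_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "pitch_descriptives.csv", index=False)
    return df


@_stage("nonlinear")
def _stage_nonlinear(cfg: PipelineConfig, out: Path, cdir: Path, meta: pd.DataFrame):
    rows = []
    for _, rec in meta.iterrows():
        stem = rec["file"].rsplit(".", 1)[0]
        ann = read_annotation_csv(cdir / f"{stem}_annotation.csv")
        contour = read_contour_csv(cdir / f"{stem}_contour.csv")
        summ = phenomenon_proportions(ann, contour)
        rows.append({"file": rec["file"], **summ.as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "nonlinear_summaries.csv", index=False)

    joined = meta.merge(df, on="file")
    fits = []
    for lab in ("am", "chaos", "subharmonics", "fry"):
        col = f"prop_{lab}"
        for cat, grp in joined.groupby("category"):
            vals = grp[col].to_numpy()
            if vals.size < 10:
                continue
            (params, ll, conv) = fit_zoib(vals, seed=cfg.seed)[0]
            fits.append(
                {
                    "phenomenon": lab, "category": cat, "zoi": params.zoi,
                    "coi": params.coi, "mu": params.mu, "phi": params.phi,
                    "loglik": ll, "converged": conv, "n": int(vals.size),
                }
            )
    pd.DataFrame(fits).to_csv(out / "zoib_fits.csv", index=False)
    return df


@_stage("formants")
def _stage_formants(cfg: PipelineConfig, out: Path, cdir: Path, meta: pd.DataFrame):
    # formants are not measured in singing (sparse harmonics make them
    # unreliable); vowel-like regions here are mid-syllable spans
    rows = []
    for _, rec in meta.iterrows():
        if rec["category"] == "Singing":
            continue
        wave, sr = read_wav(cdir / rec["file"])
        contour = read_contour_csv(cdir / f"{rec['file'].rsplit('.', 1)[0]}_contour.csv")
        segs = contour.voiced_segments()
        if not segs:
            continue
        seg = max(segs, key=len)
        t0, t1 = contour.times[seg[0]], contour.times[seg[-1]]
        m = fmod.measure_formants(wave, sr, region=(float(t0), float(t1)), max_freq=5000.0)
        if m.low_confidence or any(np.isnan(f) for f in m.F[:2]):
            continue
        vtl = fmod.estimate_vtl(m.F)
        nv = fmod.normalize_formants(m, vtl)
        rows.append(
            {
                "file": rec["file"], "F1": m.F[0], "F2": m.F[1],
                "F3": m.F[2], "F4": m.F[3], "vtl_cm": vtl.length_cm,
                "F1n": nv.F1n, "F2n": nv.F2n,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "normalized_vowels.csv", index=False)
    if len(df) >= 20:
        points = [fmod.NormalizedVowel(r.F1n, r.F2n) for r in df.itertuples()]
        dm = fmod.vowel_space_density(points)
        np.savetxt(out / "vowel_density.csv", dm.density, delimiter=",")
    return df


@_stage("modspec")
def _stage_modspec(cfg: PipelineConfig, out: Path, cdir: Path, meta: pd.DataFrame):
    window_ms, step_ms = mmod.PRESETS[cfg.modspec_preset]
    by_merged: dict[str, list] = {}
    for _, rec in meta.iterrows():
        wave, sr = read_wav(cdir / rec["file"])
        ms = mmod.chunk_and_average(wave, sr, window_ms=window_ms, step_ms=step_ms)
        by_merged.setdefault(MERGED_CATEGORY.get(rec["category"], rec["category"]), []).append(ms)
    grid = mmod.common_grid([ms for lst in by_merged.values() for ms in lst])
    averages = {cat: mmod.aggregate_category(lst, grid=grid) for cat, lst in by_merged.items()}
    band_rows = []
    for cat, ms in averages.items():
        np.savetxt(out / f"modspec_{cat.lower().replace(' ', '_')}.csv", ms.magnitude, delimiter=",")
        row = {"category": cat, "syllable_band": mmod.band_energy(ms, mmod.SYLLABLE_BAND_HZ)}
        if mmod.ROUGHNESS_BAND_HZ[1] <= ms.temporal_nyquist:
            row["roughness_band"] = mmod.band_energy(ms, mmod.ROUGHNESS_BAND_HZ)
        band_rows.append(row)
    pd.DataFrame(band_rows).to_csv(out / "modspec_band_energy.csv", index=False)
    lr = None
    if "Speech" in averages and "Nonverbal" in averages:
        lr = mmod.log_ratio_map(
            averages["Speech"], averages["Nonverbal"], label_a="Speech", label_b="Nonverbal"
        )
        np.savetxt(out / "logratio_speech_vs_nonverbal.csv", lr.values, delimiter=",")
    return averages, lr


@_stage("classify")
def _stage_classify(cfg: PipelineConfig, out: Path, meta, pitch_df, nl_df):
    table, dropped = build_feature_table(pitch_df, meta, nl_df)
    reports = {}
    for classes in (4, 3):
        rep = classify_domains(table, classes=classes, n_trees=cfg.n_trees, seed=cfg.seed)
        rep.confusion.to_csv(out / f"confusion_{classes}class.csv")
        reports[classes] = rep
    boots = {
        feat: bootstrap_summary(table, feat, n_boot=cfg.n_boot, seed=cfg.seed)
        for feat in ("median_oct", "range_oct", "slope_abs", "inflections_per_s")
    }
    pd.concat([b.table for b in boots.values()]).to_csv(out / "bootstrap_summaries.csv", index=False)
    return table, reports, boots, dropped


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a report bundle (dict of in-memory results).

    Artifacts written under cfg.out_dir: corpus files, pitch_descriptives.csv,
    nonlinear_summaries.csv, zoib_fits.csv, normalized_vowels.csv +
    vowel_density.csv, modspec_*.csv + logratio CSV + band energies,
    confusion matrices, bootstrap_summaries.csv, and settings.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cdir, meta = _stage_corpus(cfg, out)
    pitch_df = _stage_pitch(cfg, out, cdir, meta)
    nl_df = _stage_nonlinear(cfg, out, cdir, meta)
    vowels = _stage_formants(cfg, out, cdir, meta) if cfg.run_formants else None
    averages, logratio = _stage_modspec(cfg, out, cdir, meta)
    table, reports, boots, dropped = _stage_classify(cfg, out, meta, pitch_df, nl_df)

    settings = {
        "seed": cfg.seed,
        "corpus_seed": cfg.corpus.seed if cfg.corpus_dir is None else None,
        "n_recordings": len(meta),
        "smoothing_cutoffs": list(cfg.smoothing_cutoffs),
        "modspec_preset": cfg.modspec_preset,
        "n_trees": cfg.n_trees,
        "n_boot": cfg.n_boot,
        "use_truth_contours": cfg.use_truth_contours,
        "accuracy_4class": reports[4].averaged_accuracy,
        "accuracy_3class": reports[3].averaged_accuracy,
        "dropped_records": dropped,
    }
    with open(out / "settings.json", "w") as fh:
        json.dump(settings, fh, indent=2)
    return {
        "metadata": meta,
        "pitch": pitch_df,
        "nonlinear": nl_df,
        "vowels": vowels,
        "modspec_averages": averages,
        "logratio": logratio,
        "feature_table": table,
        "classifier_reports": reports,
        "bootstrap": boots,
        "settings": settings,
    }
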