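"""Corpus-level statistics: feature tables, random-forest domain
classification with out-of-bag accuracy, and speaker-cluster bootstrap
summaries.

The classifier predicts the vocal domain (4 categories, or 3 after merging
the two speech categories) from speaker sex and the four headline pitch
descriptives (median, range, slope, inflections per second). Accuracy is
estimated from out-of-bag votes and macro-averaged across classes, so
underrepresented categories count equally. Category x sex summaries use a
cluster bootstrap that resamples speakers, not recordings, respecting the
repeated-measures structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "BootstrapSummary",
    "CLASSIFIER_FEATURES",
    "build_feature_table",
    "classify_domains",
    "bootstrap_summary",
]

CLASSIFIER_FEATURES = ("sex", "median_oct", "range_oct", "slope_abs", "inflections_per_s")


@dataclass
class FeatureTable:
    """One row per recording; classifier columns must be complete."""

    df: pd.DataFrame

    REQUIRED = (
        "file", "category", "merged_category", "sex", "speaker_id",
        "median_oct", "range_oct", "slope_abs", "inflections_per_s",
    )

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"FeatureTable: missing columns {missing}")
        cls_cols = [c for c in CLASSIFIER_FEATURES if c != "sex"]
        if self.df[list(cls_cols)].isna().any().any():
            raise ValueError("FeatureTable: NaN in classifier columns")


@dataclass
class ClassifierReport:
    per_class_accuracy: dict[str, float]
    averaged_accuracy: float  # macro average over classes
    confusion: pd.DataFrame  # rows: true class, cols: OOB-predicted class
    chance_level: float
    n_trees: int
    seed: int


@dataclass
class BootstrapSummary:
    """Per category x sex x feature: median point estimate + 95% percentile CI."""

    table: pd.DataFrame  # columns: category, sex, feature, estimate, lo, hi, n_speakers
    n_boot: int
    seed: int


def build_feature_table(
    descriptives: pd.DataFrame,
    metadata: pd.DataFrame,
    summaries: pd.DataFrame | None = None,
    merged_category: dict[str, str] | None = None,
) -> tuple[FeatureTable, list[str]]:
    """Inner-join pitch descriptives (keyed by ``file``) with metadata and,
    optionally, nonlinearity summaries.

    Returns the table plus the list of files dropped by the join. Duplicate
    keys or a speaker appearing with two sexes are errors.
    """
    for name, df in (("descriptives", descriptives), ("metadata", metadata)):
        if df["file"].duplicated().any():
            dups = df.loc[df["file"].duplicated(), "file"].tolist()
            raise ValueError(f"build_feature_table: duplicate keys in {name}: {dups}")
    sex_counts = metadata.groupby("speaker_id")["sex"].nunique()
    bad = sex_counts[sex_counts > 1].index.tolist()
    if bad:
        raise ValueError(f"build_feature_table: conflicting sexes for speakers {bad}")

    merged = metadata.merge(descriptives, on="file", how="inner")
    if summaries is not None:
        merged = merged.merge(summaries, on="file", how="inner")
    all_files = set(metadata["file"]) | set(descriptives["file"])
    dropped = sorted(all_files - set(merged["file"]))
    if merged_category is None:
        from .corpus import MERGED_CATEGORY as merged_category  # default taxonomy
    merged["merged_category"] = merged["category"].map(merged_category)
    return FeatureTable(merged), dropped


def classify_domains(
    table: FeatureTable,
    classes: int = 4,
    n_trees: int = 500,
    seed: int = 0,
    min_per_class: int = 10,
) -> ClassifierReport:
    """Random-forest domain classification from sex + pitch descriptives.

    Per-tree bootstrap samples are reweighted by class frequency
    (balanced-subsample stratification) so rare categories carry equal
    weight; accuracy comes from out-of-bag votes and is macro-averaged
    across classes. Deterministic given seed.
    """
    if classes not in (3, 4):
        raise ValueError("classify_domains: classes must be 3 or 4")
    df = table.df
    y = df["merged_category" if classes == 3 else "category"].to_numpy()
    counts = pd.Series(y).value_counts()
    small = counts[counts < min_per_class]
    if len(small):
        raise ValueError(
            f"classify_domains: classes below {min_per_class} rows: {small.to_dict()}"
        )
    X = np.column_stack(
        [
            (df["sex"].astype("category").cat.codes if col == "sex" else df[col]).to_numpy(float)
            for col in CLASSIFIER_FEATURES
        ]
    )
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    votes = rf.oob_decision_function_
    pred = rf.classes_[np.argmax(votes, axis=1)]

    labels = list(rf.classes_)
    conf = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=labels, columns=labels, fill_value=0)
    per_class = {
        lab: float(conf.loc[lab, lab] / conf.loc[lab].sum()) for lab in labels
    }
    return ClassifierReport(
        per_class_accuracy=per_class,
        averaged_accuracy=float(np.mean(list(per_class.values()))),
        confusion=conf,
        chance_level=1.0 / len(labels),
        n_trees=n_trees,
        seed=seed,
    )


def bootstrap_summary(
    table: FeatureTable,
    feature: str,
    n_boot: int = 1000,
    seed: int = 0,
    min_per_cell: int = 5,
) -> BootstrapSummary:
    """Speaker-cluster bootstrap of a feature's median per category x sex.

    Within each cell, speakers are resampled with replacement and all their
    recordings enter the resample; the 2.5/97.5 percentiles of the
    resampled medians form the interval. Cells with fewer than
    ``min_per_cell`` recordings are omitted with a warning.
    """
    import warnings

    df = table.df
    if feature not in df.columns:
        raise ValueError(f"bootstrap_summary: unknown feature {feature!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for (cat, sex), cell in df.groupby(["category", "sex"], sort=True):
        if len(cell) < min_per_cell:
            warnings.warn(
                f"bootstrap_summary: cell ({cat}, {sex}) has {len(cell)} < "
                f"{min_per_cell} recordings; omitted"
            )
            continue
        speakers = cell["speaker_id"].unique()
        by_spk = {s: cell.loc[cell["speaker_id"] == s, feature].to_numpy() for s in speakers}
        meds = np.empty(n_boot)
        for b in range(n_boot):
            draw = rng.choice(speakers, size=speakers.size, replace=True)
            vals = np.concatenate([by_spk[s] for s in draw])
            meds[b] = np.median(vals)
        rows.append(
            {
                "category": cat,
                "sex": sex,
                "feature": feature,
                "estimate": float(np.median(cell[feature])),
                "lo": float(np.percentile(meds, 2.5)),
                "hi": float(np.percentile(meds, 97.5)),
                "n_speakers": int(speakers.size),
            }
        )
    return BootstrapSummary(table=pd.DataFrame(rows), n_boot=n_boot, seed=seed)
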