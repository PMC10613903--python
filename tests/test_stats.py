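"""Feature tables, random-forest domain classification, cluster bootstrap,
and pipeline orchestration."""

import numpy as np
import pandas as pd
import pytest

import vocaldomains as vd
from vocaldomains.stats import (
    FeatureTable,
    bootstrap_summary,
    build_feature_table,
    classify_domains,
)


def synthetic_table(n_per_class=30, n_classes=4, seed=0, sep=1.0):
    """Feature table with class-dependent Gaussian features."""
    rng = np.random.default_rng(seed)
    cats = ["Neutral speech", "Non-neutral speech", "Singing", "Nonverbal"][:n_classes]
    rows = []
    for ci, cat in enumerate(cats):
        for i in range(n_per_class):
            sex = "m" if i % 2 == 0 else "f"
            rows.append(
                {
                    "file": f"{cat}_{i}.wav",
                    "category": cat,
                    "merged_category": vd.MERGED_CATEGORY[cat],
                    "sex": sex,
                    "speaker_id": f"{cat}_{sex}_{i // 2}",
                    "median_oct": ci * sep + rng.normal(0, 0.3) + (0.7 if sex == "f" else 0),
                    "range_oct": 1.0 + 0.2 * ci + rng.normal(0, 0.2),
                    "slope_abs": 2.0 - 0.3 * ci + rng.normal(0, 0.3),
                    "inflections_per_s": 2.0 + ci + rng.normal(0, 0.5),
                }
            )
    return FeatureTable(pd.DataFrame(rows))


class TestBuildFeatureTable:
    @staticmethod
    def pieces(n=6):
        meta = pd.DataFrame(
            {
                "file": [f"r{i}.wav" for i in range(n)],
                "category": ["Neutral speech", "Singing"] * (n // 2),
                "sex": ["m", "f"] * (n // 2),
                "speaker_id": [f"s{i}" for i in range(n)],
            }
        )
        desc = pd.DataFrame(
            {
                "file": [f"r{i}.wav" for i in range(n)],
                "median_oct": np.linspace(3, 4, n),
                "range_oct": np.ones(n),
                "slope_abs": np.ones(n),
                "inflections_per_s": np.ones(n),
            }
        )
        return meta, desc

    def test_full_match(self):
        meta, desc = self.pieces()
        table, dropped = build_feature_table(desc, meta)
        assert len(table.df) == 6 and dropped == []
        assert set(table.df["merged_category"]) == {"Speech", "Singing"}

    def test_missing_descriptives_dropped_with_report(self):
        meta, desc = self.pieces()
        table, dropped = build_feature_table(desc.iloc[:-1], meta)
        assert len(table.df) == 5
        assert dropped == ["r5.wav"]

    def test_duplicate_keys_rejected(self):
        meta, desc = self.pieces()
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(pd.concat([desc, desc.iloc[:1]]), meta)

    def test_conflicting_speaker_sex_rejected(self):
        meta, desc = self.pieces()
        meta.loc[1, "speaker_id"] = "s0"  # s0 appears as both m and f
        with pytest.raises(ValueError, match="sex"):
            build_feature_table(desc, meta)


class TestClassifier:
    def test_separable_classes_high_accuracy(self):
        rep = classify_domains(synthetic_table(sep=2.0), classes=4, n_trees=300, seed=0)
        assert rep.averaged_accuracy >= 0.9
        assert rep.chance_level == 0.25
        assert rep.confusion.to_numpy().sum() == 120

    def test_permuted_labels_near_chance(self):
        table = synthetic_table(n_per_class=50, sep=2.0, seed=1)
        rng = np.random.default_rng(1)
        df = table.df.copy()
        df["category"] = rng.permutation(df["category"].to_numpy())
        df["merged_category"] = df["category"].map(vd.MERGED_CATEGORY)
        rep = classify_domains(FeatureTable(df), classes=4, n_trees=300, seed=0)
        assert abs(rep.averaged_accuracy - 0.25) <= 0.08

    def test_perfectly_separating_feature_ceiling(self):
        table = synthetic_table(sep=0.0, seed=2)
        df = table.df.copy()
        df["median_oct"] = df["category"].astype("category").cat.codes.astype(float)
        rep = classify_domains(FeatureTable(df), classes=4, n_trees=200, seed=0)
        assert rep.averaged_accuracy >= 0.99

    def test_row_order_invariance(self):
        table = synthetic_table(seed=3)
        rep1 = classify_domains(table, n_trees=200, seed=5)
        shuffled = FeatureTable(
            table.df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        )
        rep2 = classify_domains(shuffled, n_trees=200, seed=5)
        assert abs(rep1.averaged_accuracy - rep2.averaged_accuracy) < 0.05

    def test_monotone_transform_invariance(self):
        table = synthetic_table(seed=4)
        rep1 = classify_domains(table, n_trees=200, seed=5)
        df = table.df.copy()
        df["range_oct"] = np.exp(df["range_oct"])  # strictly monotone
        rep2 = classify_domains(FeatureTable(df), n_trees=200, seed=5)
        assert rep1.averaged_accuracy == pytest.approx(rep2.averaged_accuracy, abs=1e-9)

    def test_three_class_merge(self):
        rep = classify_domains(synthetic_table(sep=2.0), classes=3, n_trees=200, seed=0)
        assert rep.chance_level == pytest.approx(1 / 3)
        assert set(rep.confusion.index) == {"Speech", "Singing", "Nonverbal"}

    def test_class_below_minimum_named(self):
        table = synthetic_table(n_per_class=8)
        with pytest.raises(ValueError, match="below"):
            classify_domains(table, classes=4)


class TestBootstrap:
    def test_constant_feature_zero_width(self):
        table = synthetic_table()
        df = table.df.copy()
        df["range_oct"] = 1.5
        bs = bootstrap_summary(FeatureTable(df), "range_oct", n_boot=50, seed=0)
        assert (bs.table["lo"] == 1.5).all() and (bs.table["hi"] == 1.5).all()

    def test_single_resample_degenerate_interval(self):
        bs = bootstrap_summary(synthetic_table(), "median_oct", n_boot=1, seed=0)
        assert np.allclose(bs.table["lo"], bs.table["hi"])

    def test_interval_orders(self):
        bs = bootstrap_summary(synthetic_table(seed=6), "median_oct", n_boot=200, seed=0)
        assert (bs.table["lo"] <= bs.table["hi"]).all()

    def test_coverage_of_population_median(self):
        """Percentile intervals from the speaker bootstrap cover the true
        median in roughly 95% of replications."""
        mu, n_speakers, reps = 3.0, 50, 100
        hits = 0
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            df = pd.DataFrame(
                {
                    "file": [f"r{i}" for i in range(n_speakers)],
                    "category": "Singing",
                    "merged_category": "Singing",
                    "sex": "f",
                    "speaker_id": [f"s{i}" for i in range(n_speakers)],
                    "median_oct": rng.normal(mu, 1.0, n_speakers),
                    "range_oct": 1.0,
                    "slope_abs": 1.0,
                    "inflections_per_s": 1.0,
                }
            )
            bs = bootstrap_summary(FeatureTable(df), "median_oct", n_boot=200, seed=rep)
            row = bs.table.iloc[0]
            hits += row["lo"] <= mu <= row["hi"]
        assert 0.85 <= hits / reps <= 1.0

    def test_width_shrinks_with_speakers(self):
        widths = {}
        for n in (25, 100):
            rng = np.random.default_rng(42)
            df = pd.DataFrame(
                {
                    "file": [f"r{i}" for i in range(n)],
                    "category": "Singing",
                    "merged_category": "Singing",
                    "sex": "f",
                    "speaker_id": [f"s{i}" for i in range(n)],
                    "median_oct": rng.normal(3.0, 1.0, n),
                    "range_oct": 1.0,
                    "slope_abs": 1.0,
                    "inflections_per_s": 1.0,
                }
            )
            bs = bootstrap_summary(FeatureTable(df), "median_oct", n_boot=400, seed=1)
            widths[n] = float(bs.table["hi"].iloc[0] - bs.table["lo"].iloc[0])
        assert widths[100] < 0.75 * widths[25]

    def test_small_cell_omitted_with_warning(self):
        table = synthetic_table(n_per_class=4)
        with pytest.warns(UserWarning, match="omitted"):
            bs = bootstrap_summary(table, "median_oct", n_boot=20, seed=0)
        assert len(bs.table) == 0


class TestPipeline:
    def test_end_to_end_artifacts_and_determinism(self, tmp_path):
        cfg = vd.PipelineConfig(
            out_dir=tmp_path / "run1",
            corpus=vd.SynthCorpusConfig(n_recordings=48, seed=5),
            n_trees=100,
            n_boot=50,
            seed=2,
        )
        res = vd.run_pipeline(cfg)
        for name in (
            "pitch_descriptives.csv",
            "nonlinear_summaries.csv",
            "zoib_fits.csv",
            "normalized_vowels.csv",
            "modspec_band_energy.csv",
            "logratio_speech_vs_nonverbal.csv",
            "confusion_4class.csv",
            "confusion_3class.csv",
            "bootstrap_summaries.csv",
            "settings.json",
        ):
            assert (tmp_path / "run1" / name).exists(), name
        cfg2 = vd.PipelineConfig(
            out_dir=tmp_path / "run2",
            corpus=vd.SynthCorpusConfig(n_recordings=48, seed=5),
            n_trees=100,
            n_boot=50,
            seed=2,
        )
        res2 = vd.run_pipeline(cfg2)
        assert res["settings"]["accuracy_4class"] == res2["settings"]["accuracy_4class"]
        p1 = pd.read_csv(tmp_path / "run1" / "pitch_descriptives.csv")
        p2 = pd.read_csv(tmp_path / "run2" / "pitch_descriptives.csv")
        pd.testing.assert_frame_equal(p1, p2)

    def test_formant_stage_can_be_skipped(self, tmp_path):
        cfg = vd.PipelineConfig(
            out_dir=tmp_path / "nofmt",
            corpus=vd.SynthCorpusConfig(n_recordings=48, seed=5),
            run_formants=False,
            n_trees=50,
            n_boot=20,
            seed=2,
        )
        res = vd.run_pipeline(cfg)
        assert res["vowels"] is None
        assert not (tmp_path / "nofmt" / "normalized_vowels.csv").exists()

    def test_stage_failure_names_stage(self, tmp_path):
        cfg = vd.PipelineConfig(out_dir=tmp_path / "bad", corpus_dir=tmp_path / "nonexistent")
        with pytest.raises(vd.PipelineStageError, match="corpus"):
            vd.run_pipeline(cfg)
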