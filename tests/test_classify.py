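"""Undersampling, LOPO cross-validation, experiment runner, attribution."""

import numpy as np
import pandas as pd
import pytest

import speechmark as sm
from speechmark.classify import (
    forest_path_attributions,
    make_model,
    permutation_null_accuracies,
    representative_index,
)


def synthetic_table(n_per_group=10, n_features=5, separation=0.0, seed=0, groups=("A", "B")):
    """Participant-level table with Gaussian features; ``separation`` shifts
    the first feature's mean between the groups."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(groups):
        for i in range(n_per_group):
            feats = {f"f{j}": rng.normal() for j in range(n_features)}
            feats["f0"] += gi * separation
            rows.append({"participant_id": f"{g}{i:03d}", "group": g,
                         "dataset": "synthetic", "weight": 100.0, **feats})
    data = pd.DataFrame(rows)
    return sm.FeatureTable(
        data=data,
        feature_names=[f"f{j}" for j in range(n_features)],
        contrast=tuple(groups),
    )


class TestUndersample:
    def test_37_27_reduces_to_27_27(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"group": ["A"] * 37 + ["B"] * 27})
        out = sm.undersample(df, rng)
        assert out["group"].value_counts().to_dict() == {"A": 27, "B": 27}

    def test_balanced_is_noop(self):
        df = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5, "x": range(10)})
        out = sm.undersample(df, np.random.default_rng(0))
        assert out.equals(df)

    def test_ternary_min_size_rule(self):
        df = pd.DataFrame({"group": ["A"] * 34 + ["B"] * 34 + ["C"] * 40})
        out = sm.undersample(df, np.random.default_rng(1))
        assert out["group"].value_counts().to_dict() == {"A": 34, "B": 34, "C": 34}

    def test_group_below_target_rejected(self):
        df = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 5})
        with pytest.raises(ValueError):
            sm.undersample(df, np.random.default_rng(0), target_size=4)


class TestLopoCV:
    def test_one_fold_per_participant(self):
        table = synthetic_table(n_per_group=10)
        preds, _ = sm.lopo_cv(table, lambda: make_model("nb", 0))
        assert len(preds) == 20
        assert preds["participant_id"].is_unique

    def test_perfect_separation_gives_accuracy_1(self):
        table = synthetic_table(n_per_group=8, separation=50.0, seed=1)
        for model in ("rf", "nb"):
            preds, _ = sm.lopo_cv(table, lambda: make_model(model, 0))
            assert (preds["true"] == preds["predicted"]).all()

    def test_singleton_class_rejected(self):
        table = synthetic_table(n_per_group=1)
        with pytest.raises(ValueError, match="singleton"):
            sm.lopo_cv(table, lambda: make_model("nb", 0))

    def test_no_leakage_from_held_out_participant(self):
        """Poisoning a held-out participant's features never moves the
        training-fold imputation medians for their own fold."""
        from speechmark.classify import training_fold_medians

        table = synthetic_table(n_per_group=6, seed=2)
        pid = table.data.loc[0, "participant_id"]
        baseline = training_fold_medians(table, pid)
        poisoned_data = table.data.copy()
        poisoned_data.loc[0, [f"f{j}" for j in range(5)]] = 1e9
        poisoned = sm.FeatureTable(data=poisoned_data,
                                   feature_names=table.feature_names,
                                   contrast=table.contrast)
        assert training_fold_medians(poisoned, pid).equals(baseline)

    def test_label_permutation_is_chance_level(self):
        """Mean LOPO accuracy over label permutations sits at chance, within
        three binomial standard errors of a single run's accuracy."""
        table = synthetic_table(n_per_group=25, n_features=3, seed=3)
        accs = permutation_null_accuracies(table, "nb", n_permutations=100, seed=5)
        mean_acc = float(np.mean(accs))
        se = np.sqrt(0.25 / len(table.data))
        assert abs(mean_acc - 0.5) <= 3 * se


class TestRunExperiment:
    def test_default_spec_yields_15_runs(self):
        table = synthetic_table(n_per_group=7, separation=3.0, seed=4)
        spec = sm.ExperimentSpec(contrast=("A", "B"), model="nb", base_seed=0)
        result = sm.run_experiment(spec, table)
        assert len(result.run_accuracies) == 15
        assert result.mean_accuracy == pytest.approx(np.mean(result.run_accuracies))
        assert result.accuracy_sd == pytest.approx(np.std(result.run_accuracies))
        assert result.chance_level == 0.5

    def test_deterministic_backend_balanced_data_zero_sd(self):
        table = synthetic_table(n_per_group=6, separation=3.0, seed=5)
        spec = sm.ExperimentSpec(contrast=("A", "B"), model="nb",
                                 n_undersample_runs=1, n_cv_repeats=4, base_seed=1)
        result = sm.run_experiment(spec, table)
        assert result.accuracy_sd == 0.0

    def test_ternary_identical_groups_near_chance(self):
        table = synthetic_table(n_per_group=20, groups=("A", "B", "C"), seed=6)
        spec = sm.ExperimentSpec(contrast=("A", "B", "C"), model="nb",
                                 n_undersample_runs=1, n_cv_repeats=1, base_seed=2)
        result = sm.run_experiment(spec, table)
        n = len(table.data)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(result.mean_accuracy - 1 / 3) <= 3 * se + 0.05

    def test_confusion_row_sums_are_class_counts(self):
        table = synthetic_table(n_per_group=8, separation=1.0, seed=7)
        spec = sm.ExperimentSpec(contrast=("A", "B"), model="rf",
                                 n_undersample_runs=1, n_cv_repeats=2, base_seed=3)
        result = sm.run_experiment(spec, table)
        conf = result.confusion()
        assert conf.sum(axis=1).tolist() == [8, 8]
        metrics = result.per_class_metrics()
        assert set(metrics["class"]) == {"A", "B"}

    def test_same_seed_reproduces(self):
        table = synthetic_table(n_per_group=8, separation=1.0, seed=8)
        spec = sm.ExperimentSpec(contrast=("A", "B"), model="rf",
                                 n_undersample_runs=2, n_cv_repeats=2, base_seed=9)
        r1 = sm.run_experiment(spec, table)
        r2 = sm.run_experiment(spec, table)
        assert r1.run_accuracies == r2.run_accuracies


class TestRepresentativeRun:
    def test_closest_to_mean_selected(self):
        assert representative_index([0.8, 0.9, 1.0]) == 1

    def test_single_run(self):
        assert representative_index([0.7]) == 0

    def test_tie_takes_lowest_index(self):
        assert representative_index([0.8, 1.0]) == 0


class TestAttribution:
    def test_local_accuracy_of_tree_path_attributions(self):
        table = synthetic_table(n_per_group=10, separation=2.0, seed=10)
        model = make_model("rf", 0)
        X = table.X.to_numpy()
        model.fit(X, table.y)
        contribs, base = forest_path_attributions(model, X)
        recon = base + contribs.sum(axis=1)
        proba = model.predict_proba(X)
        assert np.abs(recon - proba).max() < 1e-6

    def test_constant_feature_gets_zero_attribution(self):
        table = synthetic_table(n_per_group=10, separation=3.0, seed=11)
        data = table.data.copy()
        data["f4"] = 7.0
        table = sm.FeatureTable(data=data, feature_names=table.feature_names,
                                contrast=table.contrast)
        model = make_model("rf", 0)
        model.fit(table.X.to_numpy(), table.y)
        contribs, _ = forest_path_attributions(model, table.X.to_numpy())
        assert np.abs(contribs[:, 4, :]).max() == 0.0

    def test_separating_feature_ranks_first(self):
        table = synthetic_table(n_per_group=12, n_features=10, separation=12.0, seed=12)
        spec = sm.ExperimentSpec(contrast=("A", "B"), model="rf",
                                 n_undersample_runs=1, n_cv_repeats=1, base_seed=4)
        result = sm.run_experiment(spec, table)
        report = result.attribution_report(top_k=10)
        assert report.top_features[0] == "f0"
        assert report.method == "tree_path"

    def test_report_keyed_by_name_not_position(self):
        """Reordering feature columns reorders nothing in the report: scores
        stay keyed by feature name and the separating feature stays on top."""
        table = synthetic_table(n_per_group=10, n_features=4, separation=12.0, seed=13)
        spec = sm.ExperimentSpec(contrast=("A", "B"), model="rf",
                                 n_undersample_runs=1, n_cv_repeats=1, base_seed=5)
        r1 = sm.run_experiment(spec, table)
        shuffled = sm.FeatureTable(
            data=table.data, feature_names=["f2", "f0", "f3", "f1"],
            contrast=table.contrast,
        )
        r2 = sm.run_experiment(spec, shuffled)
        s1 = r1.attribution_report().scores
        s2 = r2.attribution_report().scores
        assert set(s1) == set(s2) == {"f0", "f1", "f2", "f3"}
        assert r1.attribution_report().top_features[0] == "f0"
        assert r2.attribution_report().top_features[0] == "f0"
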