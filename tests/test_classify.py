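import numpy as np
import pandas as pd
import pytest

from microspect.classify import (
    FeatureTable,
    assemble_features,
    compare_models,
    evaluate_model,
    null_model_suite,
    relieff_rank,
)

BANDS = ("broadband", "delta", "theta", "alpha", "beta")
MAPS = tuple("ABCDE")


def make_tidy(n_per_group=10, effect=0.0, seed=0):
    """Tidy measures table; optional group effect on alpha-E mean duration."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(2 * n_per_group):
        group = 1 if s < n_per_group else 2
        for band in BANDS:
            for map_ in MAPS:
                dur = rng.normal(80, 10)
                if group == 2 and band == "alpha" and map_ == "E":
                    dur -= effect
                rows.append(
                    {
                        "subject_id": f"s{s:03d}",
                        "group": group,
                        "band": band,
                        "map": map_,
                        "occurrence_hz": rng.normal(2, 0.3),
                        "mean_duration_ms": dur,
                        "coverage": rng.uniform(0.1, 0.3),
                    }
                )
    return pd.DataFrame(rows)


def gaussian_table(n_per_group=60, delta=5.0, n_features=10, seed=0, name="toy"):
    rng = np.random.default_rng(seed)
    X1 = rng.normal(0, 1, size=(n_per_group, n_features))
    X2 = rng.normal(0, 1, size=(n_per_group, n_features))
    X2[:, 0] += delta  # only the first feature is informative
    X = pd.DataFrame(
        np.vstack([X1, X2]), columns=[f"f{j}" for j in range(n_features)]
    )
    y = np.array([1] * n_per_group + [2] * n_per_group)
    return FeatureTable(X=X, y=y, name=name)


class TestAssembleFeatures:
    def test_frequency_specific_has_15_columns(self):
        table = assemble_features(make_tidy(), "frequency_specific", "alpha")
        assert table.X.shape == (20, 15)
        assert all("|alpha|" in c for c in table.X.columns)

    def test_aggregate_has_75_columns(self):
        table = assemble_features(make_tidy(), "aggregate")
        assert table.X.shape[1] == 75

    def test_map_specific_columns_are_measure_by_band(self):
        table = assemble_features(make_tidy(), "map_specific", "E")
        expected = [
            f"{m}|{b}|E"
            for m in ("occurrence_hz", "mean_duration_ms", "coverage")
            for b in BANDS
        ]
        assert list(table.X.columns) == expected

    def test_missing_cell_raises(self):
        tidy = make_tidy()
        broken = tidy[~((tidy["subject_id"] == "s003") & (tidy["band"] == "alpha"))]
        with pytest.raises(ValueError, match="missing cell"):
            assemble_features(broken, "frequency_specific", "alpha")

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="unknown band"):
            assemble_features(make_tidy(), "frequency_specific", "gamma")


class TestReliefF:
    @staticmethod
    def naive_relieff(X, y, n_neighbors):
        """Straight-loop reference implementation of the ReliefF formula."""
        n, p = X.shape
        rng_range = X.max(axis=0) - X.min(axis=0)
        rng_range[rng_range == 0] = 1.0
        w = np.zeros(p)
        for i in range(n):
            d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
            hits = [j for j in np.argsort(d, kind="stable") if j != i and y[j] == y[i]]
            misses = [j for j in np.argsort(d, kind="stable") if y[j] != y[i]]
            hits = hits[:n_neighbors]
            misses = misses[:n_neighbors]
            for f in range(p):
                w[f] += np.mean(
                    [abs(X[j, f] - X[i, f]) / rng_range[f] for j in misses]
                ) - np.mean([abs(X[j, f] - X[i, f]) / rng_range[f] for j in hits])
        return w / n

    def test_matches_naive_formula_on_toy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(14, 4))
        y = np.array([1] * 7 + [2] * 7)
        X[y == 2, 1] += 2.0
        _, w = relieff_rank(X, y, n_neighbors=3)
        expected = self.naive_relieff(X, y, 3)
        assert np.allclose(w, expected)

    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8))
        y = np.array([1] * 20 + [2] * 20)
        X[y == 2, 5] += 10.0
        ranking, w = relieff_rank(X, y, n_neighbors=15)
        assert ranking[0] == 5
        assert w[5] > max(np.delete(w, 5))

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        X[:, 2] = 4.2
        y = np.array([1] * 10 + [2] * 10)
        _, w = relieff_rank(X, y)
        assert w[2] == 0.0

    def test_duplicated_feature_gets_equal_weight(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 0]
        y = np.array([1] * 15 + [2] * 15)
        X[y == 2, 0] += 1.0
        X[y == 2, 2] += 1.0
        _, w = relieff_rank(X, y)
        assert w[0] == pytest.approx(w[2])


class TestEvaluateModel:
    def test_separated_classes_high_accuracy(self):
        table = gaussian_table(delta=5.0, seed=5)
        ev = evaluate_model(table, k_range=(1, 3, 10), seed=0)
        assert (ev.metrics["accuracy"] >= 0.95).all()
        assert ev.top_feature == "f0"

    def test_null_labels_chance_accuracy(self):
        rng = np.random.default_rng(6)
        table = gaussian_table(delta=0.0, seed=6)
        shuffled = FeatureTable(X=table.X, y=rng.permutation(table.y), name="null")
        ev = evaluate_model(shuffled, k_range=(1, 5), seed=1)
        for k in (1, 5):
            assert abs(ev.metric_at(k, "accuracy") - 0.5) <= 0.08

    def test_seeded_reproducibility(self):
        table = gaussian_table(delta=1.0, seed=7, n_per_group=30)
        ev1 = evaluate_model(table, k_range=(1, 2), seed=3)
        ev2 = evaluate_model(table, k_range=(1, 2), seed=3)
        pd.testing.assert_frame_equal(ev1.metrics, ev2.metrics)
        assert np.array_equal(ev1.fold_auc, ev2.fold_auc, equal_nan=True)

    def test_full_selection_equals_no_selection(self):
        # selecting all features is a no-op: k = p model == selection-free model
        table = gaussian_table(delta=1.0, n_features=6, seed=8, n_per_group=25)
        ev_sel = evaluate_model(table, k_range=(6,), seed=4)
        ev_none = evaluate_model(table, k_range=(6,), seed=4, selection="none")
        assert ev_sel.metric_at(6, "accuracy") == pytest.approx(
            ev_none.metric_at(6, "accuracy")
        )
        assert ev_sel.metric_at(6, "auc") == pytest.approx(ev_none.metric_at(6, "auc"))

    def test_sensitivity_specificity_definition(self):
        # patients (group 2) are the positive class
        table = gaussian_table(delta=5.0, seed=9, n_per_group=30)
        ev = evaluate_model(table, k_range=(1,), seed=5)
        assert ev.metric_at(1, "sensitivity") > 0.9
        assert ev.metric_at(1, "specificity") > 0.9


class TestCompareModels:
    def test_model_vs_itself(self):
        table = gaussian_table(delta=1.0, seed=10, n_per_group=25)
        ev = evaluate_model(table, k_range=(1,), seed=6)
        dauc, p = compare_models(ev, ev, at_k=1, seed=0)
        assert dauc == 0.0
        assert p == 1.0

    def test_informative_beats_noise(self):
        info = gaussian_table(delta=3.0, seed=11)
        noise_X = info.X.copy()
        rng = np.random.default_rng(12)
        noise = FeatureTable(
            X=pd.DataFrame(
                rng.normal(size=noise_X.shape), columns=noise_X.columns
            ),
            y=info.y,
            name="noise",
        )
        ev_a = evaluate_model(info, k_range=(1,), seed=7)
        ev_b = evaluate_model(noise, k_range=(1,), seed=7)
        dauc, p = compare_models(ev_a, ev_b, at_k=1, seed=1)
        assert dauc > 0
        assert p < 0.05

    def test_swapping_negates_delta_same_p(self):
        a = gaussian_table(delta=1.0, seed=13, n_per_group=25, name="a")
        b = gaussian_table(delta=0.5, seed=14, n_per_group=25, name="b")
        ev_a = evaluate_model(a, k_range=(1,), seed=8)
        ev_b = evaluate_model(b, k_range=(1,), seed=8)
        d1, p1 = compare_models(ev_a, ev_b, at_k=1, seed=2)
        d2, p2 = compare_models(ev_b, ev_a, at_k=1, seed=2)
        assert d1 == pytest.approx(-d2)
        assert p1 == p2

    def test_mismatched_design_rejected(self):
        table = gaussian_table(delta=1.0, seed=15, n_per_group=25)
        ev_a = evaluate_model(table, k_range=(1,), seed=9)
        ev_b = evaluate_model(table, k_range=(1,), seed=10)
        with pytest.raises(ValueError, match="paired"):
            compare_models(ev_a, ev_b, at_k=1)


class TestNullSuite:
    def test_null_accuracy_near_chance(self):
        table = gaussian_table(delta=2.0, seed=16, n_per_group=30)
        nulls = null_model_suite(table, n_null=3, seed=0, k_range=(1, 5), n_runs=2)
        mean_acc = nulls["mean_accuracy"].mean()
        assert abs(mean_acc - 0.5) < 0.1

    def test_real_model_beats_null_distribution(self):
        table = gaussian_table(delta=2.5, seed=17, n_per_group=30)
        ev = evaluate_model(table, k_range=(1,), seed=11, n_runs=2)
        nulls = null_model_suite(table, n_null=5, seed=1, k_range=(1,), n_runs=2)
        assert ev.metric_at(1, "accuracy") > nulls["accuracy_k1"].quantile(0.95)

    def test_zero_reps_rejected(self):
        table = gaussian_table(seed=18)
        with pytest.raises(ValueError):
            null_model_suite(table, n_null=0)
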