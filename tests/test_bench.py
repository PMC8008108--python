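import numpy as np
import pandas as pd
import pytest

from mviradiomics.bench import (
    CVResult,
    ModelConfig,
    aggregate_phase_region,
    chronological_split,
    enumerate_configs,
    rank_models,
    select_features,
    tenfold_cv,
    top_feature_census,
    top_k,
)
from mviradiomics.features.extract import PhaseCombo
from mviradiomics.selectors import SELECTOR_REGISTRY


class TestEnumerateConfigs:
    def test_full_grid_size(self):
        configs = enumerate_configs()
        assert len(configs) == 33_750
        ids = {c.config_id for c in configs}
        assert len(ids) == 33_750  # every config appears exactly once

    def test_selector_classifier_grid(self):
        combos = [PhaseCombo(("PVP",))]
        configs = enumerate_configs(phase_combos=combos, regions=["core"])
        assert len(configs) == 150

    def test_single_distance_grid(self):
        regions = ["core", "ring:12", "combined:12"]
        configs = enumerate_configs(regions=regions)
        assert len(configs) == 15 * 150 * 3 == 6_750

    def test_stable_ordering(self):
        assert [c.config_id for c in enumerate_configs(regions=["core"])] == [
            c.config_id for c in enumerate_configs(regions=["core"])
        ]


class TestChronologicalSplit:
    def _cohort(self, n=111):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "f": rng.normal(size=n),
                "mvi_label": rng.integers(0, 2, n),
                "chronological_index": np.arange(n),
            },
            index=[f"case{i}" for i in range(n)],
        )

    def test_study_sized_split(self):
        train, test = chronological_split(self._cohort(111), n_train=88)
        assert len(train) == 88 and len(test) == 23

    def test_partition_and_order_stability(self):
        df = self._cohort(30)
        t1, s1 = chronological_split(df, 20)
        t2, s2 = chronological_split(df.sample(frac=1, random_state=1), 20)
        assert not set(t1.index) & set(s1.index)
        assert list(t1.index) == list(t2.index)  # insensitive to row order
        assert t1["chronological_index"].is_monotonic_increasing

    def test_bad_n_train_rejected(self):
        with pytest.raises(ValueError):
            chronological_split(self._cohort(10), 10)


def planted_matrix(n=40, n_noise=12, shift=3.0, seed=0):
    """One strongly class-separated feature among pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] += shift * y
    cols = ["signal"] + [f"noise{i:02d}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestSelectFeatures:
    @pytest.mark.parametrize("selector", sorted(SELECTOR_REGISTRY))
    def test_planted_feature_found(self, selector):
        X, y = planted_matrix()
        chosen = select_features(X, y, selector, k=3)
        assert "signal" in chosen, selector

    def test_t_score_ranks_planted_first(self):
        X, y = planted_matrix()
        assert select_features(X, y, "t_score", k=1) == ["signal"]
        # brute-force Welch statistic agrees with the ranking
        g0, g1 = X[y == 0], X[y == 1]
        t = np.abs(g0.mean() - g1.mean()) / np.sqrt(
            g0.var(ddof=1) / len(g0) + g1.var(ddof=1) / len(g1)
        )
        want = t.sort_values(ascending=False).index[:3].tolist()
        assert select_features(X, y, "t_score", k=3) == want

    def test_zero_t_score_for_identical_class_distributions(self):
        X = pd.DataFrame({"f": np.r_[np.arange(10.0), np.arange(10.0)]})
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        g0, g1 = X["f"][:10], X["f"][10:]
        t = abs(g0.mean() - g1.mean())
        assert t == pytest.approx(0.0)
        assert select_features(X, y, "t_score", k=1) == ["f"]  # tie-break only

    @pytest.mark.parametrize("selector", sorted(SELECTOR_REGISTRY))
    def test_column_order_invariance(self, selector):
        X, y = planted_matrix(seed=3)
        shuffled = X[list(reversed(X.columns))]
        assert select_features(X, y, selector, k=4) == select_features(
            shuffled, y, selector, k=4
        )

    def test_single_class_rejected(self):
        X, _ = planted_matrix()
        with pytest.raises(ValueError):
            select_features(X, np.zeros(len(X), int), "t_score", 2)


class TestTenfoldCV:
    CONFIG = ModelConfig("t_score", "logistic", PhaseCombo(("PVP",)), "core", 4)

    def test_every_case_validated_once(self):
        X, y = planted_matrix()
        res = tenfold_cv(X, y, self.CONFIG, seed=0)
        assert len(res.oof_scores) == len(y)  # all out-of-fold slots filled
        assert len(res.fold_metrics) == 10
        assert len(res.selected_features) == 10

    def test_selection_refit_per_fold(self):
        X, y = planted_matrix(shift=0.5, seed=5)
        res = tenfold_cv(X, y, self.CONFIG, seed=0)
        assert len({tuple(f) for f in res.selected_features}) > 1

    def test_metrics_bounded_and_deterministic(self):
        X, y = planted_matrix()
        a = tenfold_cv(X, y, self.CONFIG, seed=1)
        b = tenfold_cv(X, y, self.CONFIG, seed=1)
        assert a.fold_metrics.equals(b.fold_metrics)
        assert ((a.fold_metrics >= 0) & (a.fold_metrics <= 1)).all().all()
        assert a.mean_auc > 0.9  # planted effect is easily found

    def test_permutation_null_auc_near_half(self):
        """Mean CV AUC over label permutations sits at chance level."""
        X, y = planted_matrix(shift=0.0, seed=2)
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            aucs.append(tenfold_cv(X, yp, self.CONFIG, seed=seed).pooled_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)


def fake_result(auc, acc, config_id_suffix, features=None):
    cfg = ModelConfig("t_score", config_id_suffix, PhaseCombo(("PVP",)), "core")
    folds = pd.DataFrame(
        {"AUC": [auc] * 10, "ACC": [acc] * 10, "SEN": [acc] * 10, "SPE": [acc] * 10}
    )
    feats = features or [["a", "b"]] * 10
    rng = np.random.default_rng(0)
    scores = rng.random(20)
    labels = np.array([0, 1] * 10)
    return CVResult(cfg, folds, feats, scores, labels)


class TestRanking:
    def test_study_auc_ordering_preserved(self):
        results = [
            fake_result(0.776, 0.684, "b"),
            fake_result(0.788, 0.704, "a"),
            fake_result(0.775, 0.70, "c"),
        ]
        ranked = rank_models(results)
        assert [r.mean_auc for r in ranked] == pytest.approx([0.788, 0.776, 0.775])

    def test_tie_broken_by_accuracy_then_id(self):
        results = [
            fake_result(0.8, 0.60, "z"),
            fake_result(0.8, 0.70, "m"),
            fake_result(0.8, 0.70, "a"),
        ]
        ranked = rank_models(results)
        assert ranked[0].mean_acc == 0.70
        assert ranked[0].config.classifier == "a"  # lexicographic config id

    def test_top_k_returns_exactly_three(self):
        results = [fake_result(0.5 + i / 100, 0.5, f"c{i}") for i in range(6)]
        assert len(top_k(results, 3)) == 3


class TestCensus:
    def test_single_qualifying_model_equal_shares(self):
        res = fake_result(0.9, 0.8, "a", features=[["f1", "f2"]])
        res.selected_features = [["f1", "f2"]]
        census = top_feature_census([res], auc_min=0.7, top_n=2)
        assert census["percentage"].tolist() == [50.0, 50.0]

    def test_percentages_sum_to_100_and_match_recount(self):
        rng = np.random.default_rng(4)
        feats = [f"f{i}" for i in range(8)]
        results = []
        for i in range(5):
            per_fold = [list(rng.choice(feats, 3, replace=False)) for _ in range(10)]
            results.append(fake_result(0.6 + 0.1 * (i % 3), 0.6, f"c{i}", per_fold))
        census = top_feature_census(results, auc_min=0.65, top_n=3)
        assert census["percentage"].sum() == pytest.approx(100.0)
        # independent recount from the raw logs
        counts = {}
        for r in results:
            if r.mean_auc <= 0.65:
                continue
            for fold in r.selected_features:
                for f in fold[:3]:
                    counts[f] = counts.get(f, 0) + 1
        for _, row in census.iterrows():
            assert counts[row["feature"]] == row["count"]

    def test_no_qualifying_models_warns(self):
        res = fake_result(0.5, 0.5, "a")
        with pytest.warns(UserWarning):
            census = top_feature_census([res], auc_min=0.9)
        assert census.empty


class TestAggregation:
    def _table(self):
        rows = []
        for combo in ("Fpha1", "Fpha3"):
            for region in ("core", "ring:2", "ring:12", "combined:2", "combined:12"):
                for clf in ("a", "b"):
                    auc = 0.6
                    if combo == "Fpha3":
                        auc += 0.1
                        if region == "combined:12":
                            auc += 0.15
                    rows.append(
                        {
                            "phase_combo": combo,
                            "region": region,
                            "selector": "t",
                            "classifier": clf,
                            "mean_auc": auc,
                            "pooled_auc": auc,
                        }
                    )
        return pd.DataFrame(rows)

    def test_uniform_mean_and_argmax(self):
        agg = aggregate_phase_region(self._table())
        tbl = agg["phase_region_table"]
        assert tbl.loc["Fpha1", "core"] == pytest.approx(0.6)
        # combined class for Fpha3 averages the 0.85 and 0.7 cells
        assert tbl.loc["Fpha3", "combined"] == pytest.approx((0.85 + 0.7) / 2)
        assert agg["best_phase_combo"] == "Fpha3"
        assert agg["best_distance"] == 12.0
        assert list(agg["distance_trend"].index) == [2.0, 12.0]
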