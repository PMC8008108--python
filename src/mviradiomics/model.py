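"""MDT-like fusion model: a statsmodels-style facade over the pipeline.

``MDTFusion`` is constructed from data (a per-phase, per-region feature
store plus labels, or directly from a cohort of cases) and ``fit()`` runs
the whole estimation procedure: the combinatorial cross-validated benchmark,
the phase/region aggregation, top-3 model ranking, plurality-vote and
weighted fusion, test-set evaluation and the NRI comparison.  The returned
``MDTFusionResults`` carries the estimates and diagnostics and renders a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bench import (
    CVResult,
    DEFAULT_N_SELECTED,
    _make_classifier,
    _predict_proba,
    aggregate_phase_region,
    chronological_split,
    enumerate_configs,
    rank_models,
    results_table,
    select_features,
    tenfold_cv,
    top_feature_census,
)
from .features.extract import (
    PHASES,
    PhaseCombo,
    all_phase_combos,
    extract_features,
)
from .fusion import (
    EnsembleSpec,
    classification_metrics,
    feature_group_test,
    nri_matrix,
)
from .synthetic import PhantomCase
from .voi import DEFAULT_DISTANCES_MM, RegionSet, build_region_set, vessel_caliber_filter

from sklearn.preprocessing import StandardScaler


class MDTFusion:
    """Benchmark-and-fuse model for binary MVI prediction.

    Parameters
    ----------
    feature_store : nested mapping ``phase -> region_id -> DataFrame``;
        each frame holds the 94 unprefixed features, indexed by case id.
    labels : Series of binary MVI labels indexed by case id.
    chronological_index : Series defining the chronological order used for
        the train/test split (defaults to label order).
    """

    def __init__(
        self,
        feature_store: dict[str, dict[str, pd.DataFrame]],
        labels: pd.Series,
        chronological_index: pd.Series | None = None,
    ):
        self.feature_store = feature_store
        self.labels = labels.astype(int)
        if chronological_index is None:
            chronological_index = pd.Series(
                np.arange(len(labels)), index=labels.index
            )
        self.chronological_index = chronological_index
        self.phases = list(feature_store)
        first = next(iter(feature_store.values()))
        self.regions = list(first)
        for phase, by_region in feature_store.items():
            if list(by_region) != self.regions:
                raise ValueError(f"phase {phase}: inconsistent region set")
            for region, df in by_region.items():
                if not df.index.equals(labels.index):
                    raise ValueError(
                        f"case ids of ({phase}, {region}) differ from labels"
                    )
        self._matrix_cache: dict[tuple[str, str], pd.DataFrame] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_cohort(
        cls,
        cases: list[PhantomCase],
        distances_mm: tuple[float, ...] = DEFAULT_DISTANCES_MM,
        bin_width: float = 25.0,
        phases: tuple[str, ...] = PHASES,
        min_vessel_caliber_mm: float = 2.0,
        region_ids: list[str] | None = None,
    ) -> "MDTFusion":
        """Build the model directly from cases: region construction followed
        by 94-feature extraction for every (phase, region)."""
        if region_ids is None:
            region_ids = RegionSet.region_ids(distances_mm)
        store: dict[str, dict[str, dict[str, dict[str, float]]]] = {
            p: {r: {} for r in region_ids} for p in phases
        }
        labels, chrono = {}, {}
        for case in cases:
            barrier = vessel_caliber_filter(
                case.vessel_mask, case.spacing_mm, min_vessel_caliber_mm
            ) | case.bileduct_mask
            regions = build_region_set(
                case.tumor_mask,
                case.liver_mask,
                barrier,
                case.spacing_mm,
                distances_mm,
            )
            labels[case.case_id] = case.mvi_label
            chrono[case.case_id] = case.chronological_index
            for phase in phases:
                vol = case.phase_volumes[phase]
                for region in region_ids:
                    store[phase][region][case.case_id] = extract_features(
                        vol, regions.get(region), case.spacing_mm, bin_width
                    )
        feature_store = {
            p: {r: pd.DataFrame(v).T.sort_index() for r, v in by_r.items()}
            for p, by_r in store.items()
        }
        ids = sorted(labels)
        return cls(
            feature_store,
            pd.Series(labels).loc[ids],
            pd.Series(chrono).loc[ids],
        )

    # -- matrices ----------------------------------------------------------

    def matrix(self, combo: PhaseCombo, region: str) -> pd.DataFrame:
        """Phase-prefixed cohort matrix for one (phase combo, region)."""
        key = (combo.label, region)
        if key not in self._matrix_cache:
            parts = []
            for p in combo:
                df = self.feature_store[p][region]
                parts.append(df.add_prefix(f"{p}_"))
            self._matrix_cache[key] = pd.concat(parts, axis=1)
        return self._matrix_cache[key]

    # -- estimation --------------------------------------------------------

    def fit(
        self,
        selectors: tuple[str, ...] | None = None,
        classifiers: tuple[str, ...] | None = None,
        phase_combos: list[PhaseCombo] | None = None,
        regions: list[str] | None = None,
        n_selected_features: int = DEFAULT_N_SELECTED,
        n_train: int | None = None,
        seed: int = 0,
        top_l: int = 3,
        n_splits: int = 10,
        aggregation_metric: str = "pooled_auc",
    ) -> "MDTFusionResults":
        """Run the benchmark, pick the best setting, fuse the top models.

        ``n_train`` defaults to ~80% of the cohort (the study design uses 88
        of 111).  The seed drives fold shuffling and stochastic classifiers.
        """
        if phase_combos is None:
            phase_combos = [c for c in all_phase_combos()
                            if set(c.phases) <= set(self.phases)]
        if regions is None:
            regions = self.regions
        if n_train is None:
            n_train = int(round(0.8 * len(self.labels)))
        configs = enumerate_configs(
            selectors, classifiers, phase_combos, regions, n_selected_features
        )

        meta = pd.DataFrame(
            {
                "mvi_label": self.labels,
                "chronological_index": self.chronological_index,
            }
        )
        train_meta, test_meta = chronological_split(meta, n_train)
        train_ids, test_ids = train_meta.index, test_meta.index
        y_train = train_meta["mvi_label"].to_numpy()
        y_test = test_meta["mvi_label"].to_numpy()

        results: list[CVResult] = []
        for config in configs:
            X = self.matrix(config.phase_combo, config.region).loc[train_ids]
            results.append(tenfold_cv(X, y_train, config, seed, n_splits=n_splits))
        table = results_table(results)
        agg = aggregate_phase_region(table, metric=aggregation_metric)

        # best setting: best phase combo with its best combined-region distance
        best_combo_label = agg["best_phase_combo"]
        best_region = (
            f"combined:{agg['best_distance']:g}"
            if not np.isnan(agg["best_distance"])
            else agg["best_region_class"]
        )
        candidates = [
            r
            for r in results
            if r.config.phase_combo.label == best_combo_label
            and r.config.region == best_region
        ]
        if len(candidates) < top_l:
            candidates = results
        top = rank_models(candidates)[:top_l]

        # refit the top models on the full training set, score the test set
        def _safe_metrics(scores, truth):
            # a degenerate (single-class) test split leaves AUC undefined
            try:
                return classification_metrics(scores, truth)
            except ValueError:
                return {k: float("nan") for k in ("AUC", "ACC", "SEN", "SPE")}

        member_probs = {}
        member_metrics = {}
        for r in top:
            c = r.config
            X_tr = self.matrix(c.phase_combo, c.region).loc[train_ids]
            X_te = self.matrix(c.phase_combo, c.region).loc[test_ids]
            feats = select_features(X_tr, y_train, c.selector, c.n_selected_features)
            scaler = StandardScaler().fit(X_tr[feats])
            clf = _make_classifier(c.classifier, seed)
            clf.fit(scaler.transform(X_tr[feats]), y_train)
            probs = _predict_proba(clf, scaler.transform(X_te[feats]))
            member_probs[c.config_id] = probs
            member_metrics[c.config_id] = _safe_metrics(probs, y_test)

        accs = [r.validation_accuracy for r in top]
        names = [r.config.config_id for r in top]
        prob_matrix = np.vstack([member_probs[n] for n in names])
        ensembles, fused_metrics, fused_labels = {}, {}, {}
        for mode in ("PV", "WF"):
            spec = EnsembleSpec(members=names, validation_accuracies=accs, mode=mode)
            scores, labels_hat = spec.fuse(prob_matrix)
            ensembles[mode] = spec
            fused_metrics[mode] = _safe_metrics(
                scores if mode == "WF" else labels_hat.astype(float), y_test
            )
            fused_labels[mode] = labels_hat

        test_label_preds = {
            n: (member_probs[n] >= 0.5).astype(int) for n in names
        }
        test_label_preds.update(fused_labels)
        try:
            nri = nri_matrix(test_label_preds, y_test)
        except ValueError:  # single-class test split
            nri = pd.DataFrame()

        census = top_feature_census(results, auc_min=0.7, top_n=n_selected_features)
        groups = {
            combo: g[aggregation_metric].to_numpy()
            for combo, g in table.groupby("phase_combo")
            if len(g) >= 2
        }
        group_test = feature_group_test(groups) if len(groups) >= 2 else None

        return MDTFusionResults(
            model=self,
            results=results,
            table=table,
            aggregation=agg,
            top_models=top,
            ensembles=ensembles,
            member_test_metrics=member_metrics,
            fused_test_metrics=fused_metrics,
            nri_matrix=nri,
            census=census,
            group_test=group_test,
            train_ids=list(train_ids),
            test_ids=list(test_ids),
            seed=seed,
        )


@dataclass
class MDTFusionResults:
    """Fitted benchmark + fusion results."""

    model: MDTFusion
    results: list[CVResult]
    table: pd.DataFrame
    aggregation: dict
    top_models: list[CVResult]
    ensembles: dict[str, EnsembleSpec]
    member_test_metrics: dict[str, dict[str, float]]
    fused_test_metrics: dict[str, dict[str, float]]
    nri_matrix: pd.DataFrame
    census: pd.DataFrame
    group_test: dict | None
    train_ids: list
    test_ids: list
    seed: int

    @property
    def best_setting(self) -> tuple[str, str]:
        return (
            self.aggregation["best_phase_combo"],
            self.top_models[0].config.region,
        )

    def performance_table(self) -> pd.DataFrame:
        """Top-model and fusion metrics, one row per model/ensemble."""
        rows = []
        for r in self.top_models:
            cid = r.config.config_id
            row = {
                "model": cid,
                "cv_mean_auc": r.mean_auc,
                "cv_mean_acc": r.mean_acc,
            }
            row.update({f"test_{k}": v for k, v in self.member_test_metrics[cid].items()})
            rows.append(row)
        for mode, metrics in self.fused_test_metrics.items():
            row = {"model": mode, "cv_mean_auc": np.nan, "cv_mean_acc": np.nan}
            row.update({f"test_{k}": v for k, v in metrics.items()})
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        agg = self.aggregation
        lines = [
            "MDT-like radiomics fusion results",
            "=" * 64,
            f"cohort: {len(self.train_ids)} train / {len(self.test_ids)} test "
            f"(chronological split), seed={self.seed}",
            f"benchmarked configurations: {len(self.results)}",
            f"best phase combination: {agg['best_phase_combo']} "
            f"({agg['metric']}, region class {agg['best_region_class']})",
            f"best peritumoral distance: {agg['best_distance']:g} mm",
            "",
            "top models (CV on training/validation set):",
        ]
        for i, r in enumerate(self.top_models, 1):
            lines.append(
                f"  {i}. {r.config.config_id}  "
                f"AUC={r.mean_auc:.3f} ACC={r.mean_acc:.3f}"
            )
        lines.append("")
        lines.append("independent test set:")
        perf = self.performance_table()
        for name, row in perf.iterrows():
            lines.append(
                f"  {name}: AUC={row['test_AUC']:.3f} ACC={row['test_ACC']:.3f} "
                f"SEN={row['test_SEN']:.3f} SPE={row['test_SPE']:.3f}"
            )
        if self.group_test is not None:
            lines.append("")
            lines.append(
                "phase-group Kruskal-Wallis omnibus p = "
                f"{self.group_test['omnibus_p']:.3g}"
            )
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_distance_trend(self, ax=None):
        """AUC versus peritumoral distance for the best phase combination."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trend = self.aggregation["distance_trend"]
        ax.plot(trend.index, trend.values, marker="o")
        ax.set_xlabel("peritumoral distance (mm)")
        ax.set_ylabel(f"mean {self.aggregation['metric']}")
        ax.set_title(f"distance trend ({self.aggregation['best_phase_combo']})")
        return ax

    def plot_nri_matrix(self, ax=None):
        """Heatmap of the pairwise NRI comparisons on the test set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.nri_matrix
        im = ax.imshow(m.values, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(m.columns)), m.columns, rotation=90)
        ax.set_yticks(range(len(m.index)), m.index)
        for i in range(len(m.index)):
            for j in range(len(m.columns)):
                ax.text(j, i, f"{m.iloc[i, j]:.2f}", ha="center", va="center",
                        fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="NRI")
        return ax
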