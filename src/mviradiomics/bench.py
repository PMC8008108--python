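"""Combinatorial model benchmarking.

The full analysis grid crosses 15 phase combinations x 15 region options
(tumor core, 7 peritumoral shells, 7 combined regions) x 15 feature
selectors x 10 classifiers = 33,750 configurations, each evaluated by
stratified ten-fold cross-validation on the chronologically earlier
training/validation split, with feature selection refit inside every fold
(no leakage).  Models are ranked by mean validation AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features.extract import PhaseCombo, all_phase_combos
from .fusion import auc_mann_whitney, classification_metrics
from .selectors import SELECTOR_REGISTRY
from .voi import DEFAULT_DISTANCES_MM, RegionSet

DEFAULT_N_SELECTED = 10
DEFAULT_N_TRAIN = 88


def _make_classifier(name: str, seed: int):
    factories = {
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "logistic": lambda: LogisticRegression(max_iter=2000),
        "svm_linear": lambda: SVC(kernel="linear", random_state=seed),
        "svm_rbf": lambda: SVC(kernel="rbf", random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(n_estimators=50, random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "lda": lambda: LinearDiscriminantAnalysis(),
    }
    if name not in factories:
        raise KeyError(f"unknown classifier {name!r}")
    return factories[name]()


CLASSIFIER_REGISTRY: tuple[str, ...] = (
    "random_forest",
    "knn",
    "logistic",
    "svm_linear",
    "svm_rbf",
    "naive_bayes",
    "decision_tree",
    "adaboost",
    "gradient_boosting",
    "lda",
)

assert len(CLASSIFIER_REGISTRY) == 10


def _predict_proba(est, X: np.ndarray) -> np.ndarray:
    """Positive-class probability in [0, 1] for any registry classifier."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    z = est.decision_function(X)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class ModelConfig:
    """One point of the benchmark grid."""

    selector: str
    classifier: str
    phase_combo: PhaseCombo
    region: str
    n_selected_features: int = DEFAULT_N_SELECTED

    @property
    def config_id(self) -> str:
        return (
            f"{self.phase_combo.label}|{self.region}|"
            f"{self.selector}|{self.classifier}"
        )


def enumerate_configs(
    selectors: tuple[str, ...] | None = None,
    classifiers: tuple[str, ...] | None = None,
    phase_combos: list[PhaseCombo] | None = None,
    regions: list[str] | None = None,
    n_selected_features: int = DEFAULT_N_SELECTED,
) -> list[ModelConfig]:
    """Exhaustive, stably ordered configuration grid (33,750 by default)."""
    selectors = tuple(SELECTOR_REGISTRY) if selectors is None else tuple(selectors)
    classifiers = CLASSIFIER_REGISTRY if classifiers is None else tuple(classifiers)
    phase_combos = all_phase_combos() if phase_combos is None else phase_combos
    regions = (
        RegionSet.region_ids(DEFAULT_DISTANCES_MM) if regions is None else list(regions)
    )
    return [
        ModelConfig(sel, clf, combo, region, n_selected_features)
        for combo in phase_combos
        for region in regions
        for sel in selectors
        for clf in classifiers
    ]


def chronological_split(
    matrix: pd.DataFrame, n_train: int = DEFAULT_N_TRAIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First ``n_train`` cases (by chronological index) vs the rest; no shuffle."""
    if "chronological_index" not in matrix.columns:
        raise ValueError("matrix lacks a chronological_index column")
    if n_train < 1 or n_train >= len(matrix):
        raise ValueError(
            f"n_train={n_train} must be in [1, {len(matrix) - 1}] for a "
            f"{len(matrix)}-case cohort"
        )
    ordered = matrix.sort_values("chronological_index")
    return ordered.iloc[:n_train], ordered.iloc[n_train:]


def select_features(
    matrix: pd.DataFrame, labels: np.ndarray, selector_id: str, k: int
) -> list[str]:
    """Top-k feature names by the given selector; column-order invariant.

    Columns are processed in sorted-name order so that equal scores break
    ties deterministically by feature name.
    """
    if selector_id not in SELECTOR_REGISTRY:
        raise KeyError(f"unknown selector {selector_id!r}")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection requires both classes present")
    cols = sorted(matrix.columns)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds feature count {len(cols)}")
    X = matrix[cols].to_numpy(dtype=float)
    idx = SELECTOR_REGISTRY[selector_id](X, y, k)
    return [cols[i] for i in idx]


@dataclass
class CVResult:
    """Ten-fold cross-validation outcome of one configuration."""

    config: ModelConfig
    fold_metrics: pd.DataFrame  # one row per non-degenerate fold
    selected_features: list[list[str]]  # per fold
    oof_scores: np.ndarray  # pooled out-of-fold probabilities, case order
    oof_labels: np.ndarray
    n_degenerate_folds: int = 0

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics["AUC"].mean())

    @property
    def mean_acc(self) -> float:
        return float(self.fold_metrics["ACC"].mean())

    @property
    def mean_sen(self) -> float:
        return float(self.fold_metrics["SEN"].mean())

    @property
    def mean_spe(self) -> float:
        return float(self.fold_metrics["SPE"].mean())

    @property
    def pooled_auc(self) -> float:
        """AUC of the pooled out-of-fold scores (stable for small cohorts)."""
        return auc_mann_whitney(self.oof_scores, self.oof_labels)

    @property
    def validation_accuracy(self) -> float:
        """Fold-mean validation accuracy; the fusion weight source."""
        return self.mean_acc


def tenfold_cv(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: ModelConfig,
    seed: int,
    n_splits: int = 10,
) -> CVResult:
    """Stratified ten-fold CV with per-fold feature selection (leakage-free)."""
    y = np.asarray(labels).astype(int)
    if len(matrix) != len(y):
        raise ValueError("matrix and labels lengths differ")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    X_df = matrix
    oof = np.full(len(y), np.nan)
    rows = []
    selected_per_fold: list[list[str]] = []
    n_degenerate = 0
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        y_tr, y_va = y[tr], y[va]
        if len(np.unique(y_tr)) < 2:
            n_degenerate += 1
            warnings.warn(
                f"fold {fold}: single-class training portion, fold excluded"
            )
            continue
        feats = select_features(
            X_df.iloc[tr], y_tr, config.selector, config.n_selected_features
        )
        selected_per_fold.append(feats)
        scaler = StandardScaler().fit(X_df.iloc[tr][feats])
        clf = _make_classifier(config.classifier, seed)
        clf.fit(scaler.transform(X_df.iloc[tr][feats]), y_tr)
        probs = _predict_proba(clf, scaler.transform(X_df.iloc[va][feats]))
        oof[va] = probs
        row = {"fold": fold}
        if len(np.unique(y_va)) < 2:
            # AUC undefined on a single-class validation fold
            n_degenerate += 1
            warnings.warn(
                f"fold {fold}: single-class validation portion, AUC skipped"
            )
            continue
        row.update(classification_metrics(probs, y_va))
        rows.append(row)
    if not rows:
        raise ValueError("all folds degenerate; cannot cross-validate")
    valid = ~np.isnan(oof)
    return CVResult(
        config=config,
        fold_metrics=pd.DataFrame(rows).set_index("fold"),
        selected_features=selected_per_fold,
        oof_scores=oof[valid],
        oof_labels=y[valid],
        n_degenerate_folds=n_degenerate,
    )


def results_table(results: list[CVResult]) -> pd.DataFrame:
    """Tidy one-row-per-config summary of CV results."""
    rows = []
    for r in results:
        c = r.config
        rows.append(
            {
                "config_id": c.config_id,
                "phase_combo": c.phase_combo.label,
                "region": c.region,
                "selector": c.selector,
                "classifier": c.classifier,
                "mean_auc": r.mean_auc,
                "pooled_auc": r.pooled_auc,
                "mean_acc": r.mean_acc,
                "mean_sen": r.mean_sen,
                "mean_spe": r.mean_spe,
                "n_degenerate_folds": r.n_degenerate_folds,
            }
        )
    return pd.DataFrame(rows)


def rank_models(results: list[CVResult]) -> list[CVResult]:
    """Descending mean validation AUC; ties broken by pooled AUC, then mean
    ACC, then config id (deterministic)."""
    if len(results) < 3:
        raise ValueError("ranking needs at least 3 results")
    return sorted(
        results,
        key=lambda r: (-r.mean_auc, -r.pooled_auc, -r.mean_acc, r.config.config_id),
    )


def top_k(results: list[CVResult], k: int = 3) -> list[CVResult]:
    return rank_models(results)[:k]


def region_class(region_id: str) -> str:
    """Map a region id to its class: core / ring / combined."""
    return region_id.split(":")[0]


def aggregate_phase_region(
    table: pd.DataFrame, metric: str = "pooled_auc"
) -> dict:
    """Aggregate the benchmark the way the headline comparisons are drawn.

    Produces (a) the phase-combination x region-class table of mean AUC
    (averaged uniformly over all selectors, classifiers and peritumoral
    distances within each cell) with its argmax, and (b) the distance trend
    of the combined region for the best phase combination.
    """
    t = table.copy()
    t["region_class"] = t["region"].map(region_class)
    phase_region = (
        t.groupby(["phase_combo", "region_class"])[metric].mean().unstack()
    )
    stacked = phase_region.stack()
    best_combo, best_class = stacked.idxmax()

    best_phase_by_mean = phase_region.mean(axis=1).idxmax()
    combined = t[(t["region_class"] == "combined") & (t["phase_combo"] == best_combo)]
    if combined.empty:
        combined = t[t["region_class"] == "combined"]
    trend = (
        combined.assign(distance=lambda d: d["region"].str.split(":").str[1].astype(float))
        .groupby("distance")[metric]
        .mean()
        .sort_index()
    )
    return {
        "phase_region_table": phase_region,
        "best_phase_combo": best_combo,
        "best_region_class": best_class,
        "best_phase_by_mean": best_phase_by_mean,
        "distance_trend": trend,
        "best_distance": float(trend.idxmax()) if len(trend) else float("nan"),
        "metric": metric,
    }


def top_feature_census(
    results: list[CVResult], auc_min: float = 0.7, top_n: int = 10
) -> pd.DataFrame:
    """Selection-frequency census over all qualifying models.

    A model qualifies when its mean CV AUC exceeds ``auc_min``; each of its
    folds contributes its first ``top_n`` selected features.  Percentages
    are shares of all qualifying fold-selections and sum to 100.
    """
    counts: dict[str, int] = {}
    total = 0
    for r in results:
        if r.mean_auc <= auc_min:
            continue
        for feats in r.selected_features:
            for f in feats[:top_n]:
                counts[f] = counts.get(f, 0) + 1
                total += 1
    if total == 0:
        warnings.warn(f"no models with mean AUC > {auc_min}; census is empty")
        return pd.DataFrame(columns=["feature", "count", "percentage"])
    df = pd.DataFrame(
        {"feature": list(counts), "count": list(counts.values())}
    )
    df["percentage"] = 100.0 * df["count"] / total
    return df.sort_values(
        ["percentage", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
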