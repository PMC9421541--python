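"""Microstate-feature classifiers: ReliefF ranking, linear SVM, repeated CV.

Feature tables are assembled from the tidy measures table either within one
frequency band across all maps (frequency-specific, 15 features), within one
map across all bands (map-specific, 15 features), or over everything
(aggregate, 75 features). Models are linear SVMs (L2 penalty, squared hinge,
C = 1) evaluated with 10 x 10 stratified repeated cross-validation; inside
each training fold the features are standardized and ranked with ReliefF
(k-nearest-neighbours = 15), and the top-k subsets for k = 1..15 are scored
on the held-out fold.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import BAND_ORDER, derive_seed
from .stats import MEASURE_COLUMNS

__all__ = [
    "FeatureTable",
    "ModelEvaluation",
    "assemble_features",
    "relieff_rank",
    "evaluate_model",
    "compare_models",
    "null_model_suite",
]

logger = logging.getLogger(__name__)

MAP_ORDER = ("A", "B", "C", "D", "E")


@dataclass
class FeatureTable:
    """Subjects x features matrix with (measure, band, map) column names."""

    X: pd.DataFrame
    y: np.ndarray  # group labels, 1 = control, 2 = patient
    name: str

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.X) != self.y.size:
            raise ValueError("one label per subject required")


@dataclass
class ModelEvaluation:
    """Per-feature-count CV metrics for one model."""

    name: str
    k_range: tuple[int, ...]
    metrics: pd.DataFrame  # rows per k: accuracy, sensitivity, specificity, auc
    fold_auc: np.ndarray  # (len(k_range), n_runs * n_folds)
    fold_accuracy: np.ndarray
    rankings: list[list[str]]  # per-fold full feature ranking
    top_feature: str
    n_runs: int
    n_folds: int
    seed: int

    def metric_at(self, k: int, metric: str) -> float:
        return float(self.metrics.loc[self.metrics["k"] == k, metric].iloc[0])


def _band_order(bands: list[str]) -> list[str]:
    known = [b for b in BAND_ORDER if b in bands]
    return known + [b for b in bands if b not in known]


def _map_order(maps: list[str]) -> list[str]:
    known = [m for m in MAP_ORDER if m in maps]
    return known + [m for m in maps if m not in known]


def assemble_features(measures: pd.DataFrame, scheme: str, value: str | None = None) -> FeatureTable:
    """Build a model's feature table from the tidy measures table.

    scheme: ``frequency_specific`` (15 features: 3 measures x 5 maps within
    band ``value``), ``map_specific`` (3 measures x 5 bands within map
    ``value``), or ``aggregate`` (all 75). Column order is deterministic:
    measures major, maps/bands minor.
    """
    bands = _band_order(list(dict.fromkeys(measures["band"])))
    maps = _map_order(list(dict.fromkeys(measures["map"])))
    if scheme == "frequency_specific":
        if value not in bands:
            raise ValueError(f"unknown band {value!r}")
        cells = [(m, value, mp) for m in MEASURE_COLUMNS for mp in maps]
        name = f"frequency_specific[{value}]"
    elif scheme == "map_specific":
        if value not in maps:
            raise ValueError(f"unknown map {value!r}")
        cells = [(m, b, value) for m in MEASURE_COLUMNS for b in bands]
        name = f"map_specific[{value}]"
    elif scheme == "aggregate":
        cells = [(m, b, mp) for m in MEASURE_COLUMNS for b in bands for mp in maps]
        name = "aggregate"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    subjects = list(dict.fromkeys(measures["subject_id"]))
    wide = measures.set_index(["subject_id", "band", "map"])
    cols = {}
    for measure, band, mp in cells:
        col = f"{measure}|{band}|{mp}"
        try:
            cols[col] = [wide.loc[(s, band, mp), measure] for s in subjects]
        except KeyError as e:
            raise ValueError(f"missing cell for subject: {e}") from e
    X = pd.DataFrame(cols, index=subjects)
    groups = measures.drop_duplicates("subject_id").set_index("subject_id")["group"]
    y = groups.loc[subjects].to_numpy()
    return FeatureTable(X=X, y=y, name=name)


def relieff_rank(
    X: np.ndarray, y: np.ndarray, n_neighbors: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Classical ReliefF feature weights for a two-class problem.

    For every instance, the ``n_neighbors`` nearest hits (same class,
    excluding the instance) and misses (other class) are found by Euclidean
    distance; each feature's weight accumulates mean |difference to misses|
    minus mean |difference to hits|, normalized by the feature's value range
    and the number of instances. Returns (ranking, weights); ties in the
    weights resolve to the earlier column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    rng_range = X.max(axis=0) - X.min(axis=0)
    safe_range = np.where(rng_range == 0, 1.0, rng_range)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("relieff_rank supports exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("each class needs at least 2 members")
    D = np.sqrt(np.maximum(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), 0.0))
    w = np.zeros(p)
    warned = False
    for i in range(n):
        hits_pool = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        miss_pool = np.flatnonzero(y != y[i])
        n_hit = min(n_neighbors, hits_pool.size)
        n_miss = min(n_neighbors, miss_pool.size)
        if (n_hit < n_neighbors or n_miss < n_neighbors) and not warned:
            # warnings module deduplicates across repeated CV folds
            warnings.warn(
                f"fewer than {n_neighbors} neighbours available; using all",
                stacklevel=2,
            )
            warned = True
        hits = hits_pool[np.argsort(D[i, hits_pool], kind="stable")[:n_hit]]
        misses = miss_pool[np.argsort(D[i, miss_pool], kind="stable")[:n_miss]]
        diff_hit = np.abs(X[hits] - X[i]) / safe_range
        diff_miss = np.abs(X[misses] - X[i]) / safe_range
        w += diff_miss.mean(axis=0) - diff_hit.mean(axis=0)
    w /= n
    w[rng_range == 0] = 0.0
    ranking = np.argsort(-w, kind="stable")
    return ranking, w


def _fit_score(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    yte: np.ndarray,
    C: float,
) -> tuple[float, float, float, float]:
    """Fit a linear SVM and return accuracy, sensitivity, specificity, AUC.

    Positive class = patients (group 2).
    """
    clf = LinearSVC(C=C, penalty="l2", loss="squared_hinge", dual=False)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    scores = clf.decision_function(Xte)
    acc = float(np.mean(pred == yte))
    pos, neg = yte == 2, yte == 1
    sens = float(np.mean(pred[pos] == 2)) if pos.any() else np.nan
    spec = float(np.mean(pred[neg] == 1)) if neg.any() else np.nan
    auc = float(roc_auc_score((yte == 2).astype(int), scores)) if pos.any() and neg.any() else np.nan
    return acc, sens, spec, auc


def evaluate_model(
    table: FeatureTable,
    n_runs: int = 10,
    n_folds: int = 10,
    k_range: tuple[int, ...] | None = None,
    seed: int = 0,
    C: float = 1.0,
    n_neighbors: int = 15,
    selection: str = "within_fold",
) -> ModelEvaluation:
    """10 x 10 repeated stratified CV over candidate feature counts.

    Standardization and ReliefF ranking are fitted on the training folds only
    (``selection='within_fold'``, leakage-safe default). With
    ``selection='whole_data'`` the ranking is computed once on the full
    standardized table before CV (the optimistic variant); with
    ``selection='none'`` all features are used at every k.
    """
    if selection not in ("within_fold", "whole_data", "none"):
        raise ValueError(f"unknown selection mode {selection!r}")
    X = table.X.to_numpy(dtype=float)
    y = table.y
    min_class = min(np.count_nonzero(y == c) for c in np.unique(y))
    if min_class < n_folds:
        raise ValueError(
            f"smallest class has {min_class} subjects; cannot run {n_folds}-fold "
            "stratified CV (reduce n_folds)"
        )
    names = list(table.X.columns)
    k_range = tuple(k_range) if k_range is not None else tuple(range(1, X.shape[1] + 1))
    if max(k_range) > X.shape[1]:
        raise ValueError("k_range exceeds number of features")

    global_rank = None
    if selection == "whole_data":
        Xz = StandardScaler().fit_transform(X)
        global_rank, _ = relieff_rank(Xz, y, n_neighbors=n_neighbors)

    n_cells = n_runs * n_folds
    accs = np.full((len(k_range), n_cells), np.nan)
    sens = np.full_like(accs, np.nan)
    specs = np.full_like(accs, np.nan)
    aucs = np.full_like(accs, np.nan)
    rankings: list[list[str]] = []

    cell = 0
    for run in range(n_runs):
        run_seed = derive_seed(seed, "cv_run", run)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=run_seed % (2**31))
        for tr_idx, te_idx in skf.split(X, y):
            scaler = StandardScaler().fit(X[tr_idx])
            Xtr, Xte = scaler.transform(X[tr_idx]), scaler.transform(X[te_idx])
            if selection == "none":
                rank = np.arange(X.shape[1])
            elif selection == "whole_data":
                rank = global_rank
            else:
                rank, _ = relieff_rank(Xtr, y[tr_idx], n_neighbors=n_neighbors)
            rankings.append([names[j] for j in rank])
            for ki, k in enumerate(k_range):
                cols = rank[:k] if selection != "none" else rank
                a, se, sp, au = _fit_score(Xtr[:, cols], y[tr_idx], Xte[:, cols], y[te_idx], C)
                accs[ki, cell], sens[ki, cell] = a, se
                specs[ki, cell], aucs[ki, cell] = sp, au
            cell += 1

    metrics = pd.DataFrame(
        {
            "k": k_range,
            "accuracy": np.nanmean(accs, axis=1),
            "sensitivity": np.nanmean(sens, axis=1),
            "specificity": np.nanmean(specs, axis=1),
            "auc": np.nanmean(aucs, axis=1),
        }
    )
    top_feature = Counter(r[0] for r in rankings).most_common(1)[0][0]
    return ModelEvaluation(
        name=table.name,
        k_range=k_range,
        metrics=metrics,
        fold_auc=aucs,
        fold_accuracy=accs,
        rankings=rankings,
        top_feature=top_feature,
        n_runs=n_runs,
        n_folds=n_folds,
        seed=seed,
    )


def compare_models(
    a: ModelEvaluation, b: ModelEvaluation, at_k: int, n_perm: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Paired fold-wise AUC comparison via a sign-flip permutation test.

    Both evaluations must share the CV design and seed so folds pair up.
    Returns (mean AUC difference a - b, two-sided p).
    """
    if (a.n_runs, a.n_folds, a.seed) != (b.n_runs, b.n_folds, b.seed):
        raise ValueError("models were not evaluated with a paired CV design")
    if at_k not in a.k_range or at_k not in b.k_range:
        raise ValueError(f"k={at_k} not evaluated in both models")
    da = a.fold_auc[a.k_range.index(at_k)]
    db = b.fold_auc[b.k_range.index(at_k)]
    diff = da - db
    diff = diff[np.isfinite(diff)]
    obs = float(diff.mean())
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
    stats = (flips * diff).mean(axis=1)
    hits = int(np.count_nonzero(np.abs(stats) >= abs(obs) - 1e-12))
    return obs, (1 + hits) / (n_perm + 1)


def null_model_suite(
    table: FeatureTable,
    n_null: int = 10,
    seed: int = 0,
    **eval_kwargs,
) -> pd.DataFrame:
    """Chance-level reference: re-evaluate the model under permuted labels.

    Returns one row per null repetition with the mean accuracy per k.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rows = []
    for j in range(n_null):
        rng = np.random.default_rng(derive_seed(seed, "null", j))
        y_perm = rng.permutation(table.y)
        shuffled = FeatureTable(X=table.X, y=y_perm, name=f"{table.name}-null{j}")
        ev = evaluate_model(shuffled, seed=derive_seed(seed, "null_eval", j), **eval_kwargs)
        row = {"null_rep": j}
        for k in ev.k_range:
            row[f"accuracy_k{k}"] = ev.metric_at(k, "accuracy")
        row["mean_accuracy"] = float(ev.metrics["accuracy"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
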