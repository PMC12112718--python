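"""Supervised ranking of hotspots as cryptic sites.

Five classifier families (RBF-kernel SVM, random forest, two
gradient-boosted-tree variants, and AdaBoost over shallow decision trees)
are trained on standardized hotspot feature tables and evaluated with
leave-one-out cross-validation (LOOCV): with n labeled hotspots, each model
is fitted on n−1 rows (feature standardization refitted inside every fold,
so no test information leaks into the scaling) and scores the held-out row.
Pooled out-of-fold probabilities yield accuracy, precision, recall, F1,
specificity, ROC AUC (trapezoidal) and PR AUC (step-wise
average-precision). Probabilities double as a per-protein ranking score;
ties share the minimum rank, and a top-N report counts proteins whose best
cryptic hotspot ranks within N.

The AdaBoost defaults are the tuned operating point of the reference
configuration: a depth-4 base tree with min_samples_leaf=2 and
min_samples_split=15, learning_rate=0.0112 and 190 estimators.

A thin statsmodels-style surface (`HotspotRankingModel` /
`HotspotRankingResults` with ``summary()``) wraps these operations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Dataset", "ModelSpec", "MetricsReport", "TopNReport", "FittedModel",
    "ALGORITHMS", "standardize", "train", "loocv", "compute_metrics",
    "tune", "repeated_kfold", "consensus", "rank_hotspots", "topn_report",
    "HotspotRankingModel", "HotspotRankingResults",
]

ALGORITHMS = ("svm_rbf", "random_forest", "xgboost", "lightgbm", "adaboost")
_ALIASES = {
    "gradient_boosting_xgb_style": "xgboost",
    "gradient_boosting_lgb_style": "lightgbm",
    "svm": "svm_rbf",
}

#: Reference AdaBoost operating point (base tree + boosting schedule).
ADABOOST_DEFAULTS = {
    "max_depth": 4,
    "min_samples_leaf": 2,
    "min_samples_split": 15,
    "learning_rate": 0.0112,
    "n_estimators": 190,
}


@dataclass
class Dataset:
    """Labeled hotspot feature table ready for training."""

    X: pd.DataFrame                    # numeric features only
    y: np.ndarray                      # 1 = cryptic, 0 = non-cryptic
    protein_ids: np.ndarray
    hotspot_ids: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, int)
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.hotspot_ids = np.asarray(self.hotspot_ids, dtype=object)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        pairs = list(zip(self.protein_ids, self.hotspot_ids))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (protein_id, hotspot_id) rows")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int((1 - self.y).sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label",
                   positive: object = "cryptic") -> "Dataset":
        meta = [c for c in ("hotspot_id", "protein_id", label_col) if c in df.columns]
        X = df.drop(columns=meta).select_dtypes(include=[np.number])
        y = (df[label_col] == positive).astype(int).to_numpy() \
            if df[label_col].dtype == object else df[label_col].to_numpy(int)
        prot = df["protein_id"].to_numpy() if "protein_id" in df else \
            np.array(["P0"] * len(df))
        hid = df["hotspot_id"].to_numpy() if "hotspot_id" in df else \
            np.array([f"H{i}" for i in range(len(df))])
        return cls(X=X.reset_index(drop=True), y=y, protein_ids=prot,
                   hotspot_ids=hid)


@dataclass
class ModelSpec:
    """Algorithm choice, hyperparameters, operating threshold and seed."""

    algorithm: str = "adaboost"
    hyperparams: dict = field(default_factory=dict)
    classification_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithm = _ALIASES.get(self.algorithm, self.algorithm)
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    roc_auc: float
    pr_auc: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TopNReport:
    """Per-N count and percentage of proteins with a top-N cryptic hotspot."""

    n_proteins: int
    hits: dict[int, int]
    percentages: dict[int, int]        # integer percent, as reported

    def __post_init__(self) -> None:
        ns = sorted(self.hits)
        for a, b in zip(ns, ns[1:]):
            if self.hits[a] > self.hits[b]:
                raise ValueError("top-N hits must be non-decreasing in N")


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparams)
    seed = spec.seed
    if spec.algorithm == "adaboost":
        merged = {**ADABOOST_DEFAULTS, **hp}
        base = DecisionTreeClassifier(
            max_depth=merged["max_depth"],
            min_samples_leaf=merged["min_samples_leaf"],
            min_samples_split=merged["min_samples_split"],
            random_state=seed)
        return AdaBoostClassifier(
            estimator=base, n_estimators=merged["n_estimators"],
            learning_rate=merged["learning_rate"], random_state=seed)
    if spec.algorithm == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 300)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "xgboost":
        from xgboost import XGBClassifier
        hp.setdefault("n_estimators", 200)
        hp.setdefault("max_depth", 4)
        hp.setdefault("learning_rate", 0.1)
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **hp)
    if spec.algorithm == "lightgbm":
        from lightgbm import LGBMClassifier
        hp.setdefault("n_estimators", 200)
        hp.setdefault("min_child_samples", 5)
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **hp)
    raise AssertionError(spec.algorithm)


def standardize(train_X: np.ndarray | pd.DataFrame,
                apply_X: np.ndarray | pd.DataFrame | None = None
                ) -> tuple[np.ndarray, np.ndarray | None, tuple[np.ndarray, np.ndarray]]:
    """Zero-mean/unit-variance scaling fitted on the training rows only.

    Returns (train_scaled, apply_scaled, (mean, scale)); zero-variance
    columns get scale 1 with a warning. Population standard deviation.
    """
    Xt = np.asarray(train_X, float)
    mean = Xt.mean(axis=0)
    scale = Xt.std(axis=0, ddof=0)
    zero = scale == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s); scale set to 1",
                      stacklevel=2)
        scale = np.where(zero, 1.0, scale)
    train_s = (Xt - mean) / scale
    apply_s = None
    if apply_X is not None:
        apply_s = (np.asarray(apply_X, float) - mean) / scale
    return train_s, apply_s, (mean, scale)


@dataclass
class FittedModel:
    """A trained classifier with its fold-free standardization statistics."""

    estimator: object
    mean: np.ndarray
    scale: np.ndarray
    spec: ModelSpec
    feature_names: tuple[str, ...]

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.mean) / self.scale
        return self.estimator.predict_proba(Xs)[:, 1]

    @property
    def feature_importances(self) -> np.ndarray | None:
        return getattr(self.estimator, "feature_importances_", None)


def train(ds: Dataset, spec: ModelSpec) -> FittedModel:
    """Fit one classifier on the full dataset (standardized)."""
    if ds.n_positive == 0 or ds.n_negative == 0:
        raise ValueError("training requires both classes")
    Xs, _, (mean, scale) = standardize(ds.X)
    est = _make_estimator(spec)
    est.fit(Xs, ds.y)
    return FittedModel(est, mean, scale, spec, tuple(ds.X.columns))


def compute_metrics(labels: np.ndarray, probabilities: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion metrics at the threshold plus ROC AUC and PR AUC."""
    y = np.asarray(labels, int)
    p = np.asarray(probabilities, float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUCs undefined for single-class labels")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(
        accuracy=(tp + tn) / len(y),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        roc_auc=float(roc_auc_score(y, p)),
        pr_auc=float(average_precision_score(y, p)),
    )


def loocv(ds: Dataset, spec: ModelSpec,
          return_fold_stats: bool = False):
    """Leave-one-out CV: per-row out-of-fold probabilities and pooled metrics.

    Standardization is refitted inside each fold on the n−1 training rows.
    With ``return_fold_stats`` the per-fold (mean, scale) pairs are also
    returned, which makes the no-leakage property directly assertable.
    """
    n = len(ds)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 rows")
    X = ds.X.to_numpy(float)
    probs = np.empty(n)
    stats = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xs, Xi, (mean, scale) = standardize(X[mask], X[[i]])
        est = _make_estimator(spec)
        est.fit(Xs, ds.y[mask])
        probs[i] = est.predict_proba(Xi)[0, 1]
        if return_fold_stats:
            stats.append((mean, scale))
    metrics = compute_metrics(ds.y, probs, spec.classification_threshold)
    if return_fold_stats:
        return metrics, probs, stats
    return metrics, probs


_TUNE_SPACES: dict[str, dict[str, list]] = {
    "adaboost": {
        "n_estimators": [50, 100, 190, 300],
        "learning_rate": [0.005, 0.0112, 0.05, 0.1, 0.5, 1.0],
        "max_depth": [1, 2, 3, 4, 5],
        "min_samples_leaf": [1, 2, 5],
        "min_samples_split": [2, 5, 15],
    },
    "svm_rbf": {"C": [0.01, 0.1, 1.0, 10.0, 100.0],
                "gamma": ["scale", 0.001, 0.01, 0.1, 1.0]},
    "random_forest": {"n_estimators": [100, 300, 500],
                      "max_depth": [None, 4, 8],
                      "min_samples_leaf": [1, 2, 5]},
    "xgboost": {"n_estimators": [100, 200, 400],
                "max_depth": [2, 4, 6],
                "learning_rate": [0.01, 0.1, 0.3],
                "subsample": [0.7, 1.0]},
    "lightgbm": {"n_estimators": [100, 200, 400],
                 "learning_rate": [0.01, 0.1, 0.3],
                 "num_leaves": [7, 15, 31],
                 "min_child_samples": [2, 5, 10]},
}


def _cv_auc(ds: Dataset, spec: ModelSpec, cv: str | int) -> float:
    if cv == "loocv":
        metrics, _ = loocv(ds, spec)
        return metrics.roc_auc
    k = int(cv)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    X = ds.X.to_numpy(float)
    probs = np.empty(len(ds))
    for tr, te in skf.split(X, ds.y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xs, Xt, _ = standardize(X[tr], X[te])
        est = _make_estimator(spec)
        est.fit(Xs, ds.y[tr])
        probs[te] = est.predict_proba(Xt)[:, 1]
    return float(roc_auc_score(ds.y, probs))


def tune(ds: Dataset, spec: ModelSpec, budget: int = 50,
         cv: str | int = 5, space: dict[str, list] | None = None,
         seed: int | None = None) -> tuple[dict, float]:
    """Seeded hyperparameter search maximizing cross-validated ROC AUC.

    Candidate points come from ``space`` (or a built-in per-algorithm
    space). When the budget covers the whole grid the search is exhaustive
    in deterministic order; otherwise points are sampled without
    replacement with a seeded generator. Returns (best hyperparams, AUC).
    """
    space = space or _TUNE_SPACES[spec.algorithm]
    if not space or budget < 1:
        raise ValueError("empty search space or budget")
    names = sorted(space)
    grid = list(itertools.product(*(space[k] for k in names)))
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if budget < len(grid):
        order = rng.permutation(len(grid))[:budget]
        grid = [grid[i] for i in order]
    best_params, best_auc = None, -np.inf
    for values in grid:
        params = dict(zip(names, values))
        trial = ModelSpec(spec.algorithm, {**spec.hyperparams, **params},
                          spec.classification_threshold, spec.seed)
        auc = _cv_auc(ds, trial, cv)
        if auc > best_auc:
            best_params, best_auc = params, auc
    return best_params, float(best_auc)


def repeated_kfold(ds: Dataset, spec: ModelSpec, k: int = 10,
                   reps: int = 50, seed: int = 0
                   ) -> tuple[float, float, np.ndarray]:
    """Repeated stratified k-fold CV; returns (mean, sd, per-rep ROC AUCs)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if k > len(ds):
        raise ValueError("k exceeds dataset size")
    X = ds.X.to_numpy(float)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) % (2 ** 31 - 1) for s in ss.generate_state(reps)]
    aucs = np.empty(reps)
    for r in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seeds[r])
        probs = np.empty(len(ds))
        for tr, te in skf.split(X, ds.y):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Xs, Xt, _ = standardize(X[tr], X[te])
            est = _make_estimator(spec)
            est.fit(Xs, ds.y[tr])
            probs[te] = est.predict_proba(Xt)[:, 1]
        aucs[r] = roc_auc_score(ds.y, probs)
    return float(aucs.mean()), float(aucs.std(ddof=1)) if reps > 1 else 0.0, aucs


def consensus(base_probs: np.ndarray, labels: np.ndarray,
              mode: str = "average", seed: int = 0) -> np.ndarray:
    """Consensus probabilities from out-of-fold base-model probabilities.

    ``base_probs`` is (n_rows, n_models). ``average`` takes the arithmetic
    mean; ``stack_logistic`` evaluates a logistic-regression meta-learner
    out-of-fold (LOO) on the base probabilities, so the consensus stays an
    honest out-of-sample score.
    """
    P = np.asarray(base_probs, float)
    if P.ndim != 2:
        raise ValueError("base_probs must be (n_rows, n_models)")
    if mode == "average":
        return P.mean(axis=1)
    if mode == "stack_logistic":
        y = np.asarray(labels, int)
        if len(y) != len(P):
            raise ValueError("labels and base_probs row mismatch")
        out = np.empty(len(P))
        for i in range(len(P)):
            mask = np.ones(len(P), bool)
            mask[i] = False
            meta = LogisticRegression(max_iter=1000, random_state=seed)
            meta.fit(P[mask], y[mask])
            out[i] = meta.predict_proba(P[[i]])[0, 1]
        return out
    raise ValueError(f"unknown consensus mode {mode!r}")


def rank_hotspots(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein descending-probability ranks; ties share the minimum rank.

    Expects columns protein_id, hotspot_id, probability. Output is ordered
    by (protein_id, rank, hotspot_id) for stable reports.
    """
    def _rank(group: pd.DataFrame) -> pd.DataFrame:
        g = group.sort_values(["probability", "hotspot_id"],
                              ascending=[False, True], kind="mergesort").copy()
        p = g["probability"].to_numpy()
        ranks = np.empty(len(g), int)
        for i in range(len(g)):
            ranks[i] = 1 + int(np.sum(p > p[i]))
        g["rank"] = ranks
        return g

    parts = [_rank(g) for _, g in table.groupby("protein_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def topn_report(ranked: pd.DataFrame, ns: tuple[int, ...] = (1, 3, 5),
                label_col: str = "label", positive: object = "cryptic"
                ) -> TopNReport:
    """Count proteins whose best cryptic hotspot ranks within each N.

    Only proteins holding at least one positive hotspot enter the
    denominator; the percentage is (hits / n_proteins) × 100, reported to
    the nearest integer percent.
    """
    pos = ranked[label_col] == positive if ranked[label_col].dtype == object \
        else ranked[label_col] == 1
    with_pos = ranked[pos]
    if len(with_pos) == 0:
        raise ValueError("no positive hotspots in ranking table")
    best = with_pos.groupby("protein_id")["rank"].min()
    n_proteins = len(best)
    hits = {n: int((best <= n).sum()) for n in sorted(ns)}
    pct = {n: int(round(hits[n] / n_proteins * 100)) for n in hits}
    return TopNReport(n_proteins=n_proteins, hits=hits, percentages=pct)


# ---------------------------------------------------------------------------
# statsmodels-style surface

class HotspotRankingModel:
    """Model object built from a labeled feature table.

    Parameters
    ----------
    data : pandas.DataFrame
        Feature table with hotspot_id, protein_id, numeric features and a
        label column ('cryptic'/'non_cryptic' or 0/1).
    algorithm : str
        One of svm_rbf, random_forest, xgboost, lightgbm, adaboost.
    """

    def __init__(self, data: pd.DataFrame, algorithm: str = "adaboost",
                 hyperparams: dict | None = None, threshold: float = 0.5,
                 seed: int = 0, label_col: str = "label",
                 positive: object = "cryptic") -> None:
        self.data = data
        self.dataset = Dataset.from_frame(data, label_col=label_col,
                                          positive=positive)
        self.spec = ModelSpec(algorithm, hyperparams or {}, threshold, seed)

    @classmethod
    def from_csv(cls, path: str, **kwargs) -> "HotspotRankingModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, cross_validate: bool = True) -> "HotspotRankingResults":
        fitted = train(self.dataset, self.spec)
        metrics = oof = None
        if cross_validate:
            metrics, oof = loocv(self.dataset, self.spec)
        return HotspotRankingResults(self, fitted, metrics, oof)


class HotspotRankingResults:
    """Fitted estimates: LOOCV metrics, per-protein ranking, top-N report."""

    def __init__(self, model: HotspotRankingModel, fitted: FittedModel,
                 metrics: MetricsReport | None,
                 oof_probabilities: np.ndarray | None) -> None:
        self.model = model
        self.fitted = fitted
        self.metrics = metrics
        self.oof_probabilities = oof_probabilities

    def ranking(self) -> pd.DataFrame:
        ds = self.model.dataset
        probs = self.oof_probabilities
        if probs is None:
            probs = self.fitted.predict_proba(ds.X)
        table = pd.DataFrame({
            "protein_id": ds.protein_ids, "hotspot_id": ds.hotspot_ids,
            "probability": probs,
            "label": np.where(ds.y == 1, "cryptic", "non_cryptic"),
        })
        return rank_hotspots(table)

    def topn(self, ns: tuple[int, ...] = (1, 3, 5)) -> TopNReport:
        return topn_report(self.ranking(), ns=ns)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Hotspot ranking model",
            "=" * 46,
            f"algorithm:       {self.model.spec.algorithm}",
            f"n hotspots:      {len(ds)} ({ds.n_positive} cryptic / "
            f"{ds.n_negative} non-cryptic)",
            f"n features:      {ds.X.shape[1]}",
            f"threshold:       {self.model.spec.classification_threshold}",
        ]
        if self.metrics is not None:
            lines.append("-" * 46)
            lines.append("LOOCV metrics")
            for k, v in self.metrics.as_dict().items():
                lines.append(f"  {k:<12s} {v:0.3f}")
        imp = self.fitted.feature_importances
        if imp is not None:
            order = np.argsort(imp)[::-1][:5]
            lines.append("-" * 46)
            lines.append("top features by importance")
            for i in order:
                lines.append(f"  {self.fitted.feature_names[i]:<24s} {imp[i]:0.3f}")
        return "\n".join(lines)
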