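"""Dataset splitting, GA feature selection, LDA/RF classifiers, validation.

The modeling workflow mirrors standard multi-tasking QSAR practice:

1. stratified 80/20 split into modeling and external sets (the external
   set is untouched until final validation);
2. the modeling set is split 80/20 into train/test, randomly or by a
   Euclidean-distance rank-and-stride rule in modified-descriptor space;
3. a genetic algorithm selects a fixed-size descriptor subset, scored by
   Wilks λ of the class separation, by training MCC of a linear
   discriminant, or by a rank-sum combination of both;
4. linear discriminant analysis (pooled covariance, equal priors,
   decision threshold 0) and random forest models are fitted on the
   selected columns;
5. models are validated with the full confusion-matrix metric suite
   (accuracy, precision, sensitivity, specificity, F-measure, MCC) on
   train, stratified 10-fold CV (mean ± SD), test, external and
   external-within-AD sets.

Metrics are reported as fractions in [0, 1] (MCC in [−1, 1]); a metric
with a zero denominator is reported as None (undefined), never as 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .multitask import ConditionMeans

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "split_external",
    "split_train_test",
    "wilks_lambda",
    "GAParams",
    "GAResult",
    "ga_select",
    "exhaustive_select",
    "ClassifierModel",
    "fit_lda",
    "fit_rf",
    "metrics_from_confusion",
    "ValidationReport",
    "evaluate",
    "save_model",
    "load_model",
    "ModelBundleError",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f_measure", "mcc")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Record ids per partition; partitions are disjoint and exhaustive."""

    first: tuple  # modeling (or train) ids
    second: tuple  # external (or test) ids
    method: str
    seed: int | None

    def __post_init__(self):
        if set(self.first) & set(self.second):
            raise ValueError("split partitions overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_external(labeled_records, fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Activity-stratified modeling/external split.

    Per class, records are shuffled with ``seed`` and ``fraction``
    (rounded half-up) go to the external set.  A class with fewer than 5
    records triggers a warning and still sends at least one record
    external (when it has any).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    by_class: dict = {}
    for r in labeled_records:
        if r.class_label is None:
            raise ValueError(f"record {r.record_id} has no class label")
        by_class.setdefault(r.class_label, []).append(r.record_id)
    if len(by_class) == 1:
        warnings.warn("single-class dataset in stratified split")
    rng = np.random.default_rng(seed)
    modeling, external = [], []
    for label in sorted(by_class):
        ids = list(by_class[label])
        if 0 < len(ids) < 5:
            warnings.warn(f"class {label} has only {len(ids)} records")
        order = rng.permutation(len(ids))
        n_ext = _round_half_up(len(ids) * fraction)
        n_ext = max(n_ext, 1) if ids else 0
        chosen = set(order[:n_ext])
        for i, pos in enumerate(order):
            (external if i < n_ext else modeling).append(ids[pos])
        del chosen
    return SplitPlan(tuple(modeling), tuple(external), "stratified", seed)


def split_train_test(
    record_ids,
    method: str = "random",
    fraction: float = 0.2,
    seed: int = 0,
    matrix: pd.DataFrame | None = None,
) -> SplitPlan:
    """Train/test split of the modeling set.

    ``random``: seeded shuffle, ``fraction`` (rounded half-up) to test.
    ``euclidean``: records are ranked by Euclidean distance from the
    modeling-set centroid in modified-descriptor space and every k-th
    record (k = round(1/fraction)) by rank goes to the test set — a
    similarity-balanced division.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    ids = list(record_ids)
    if method == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        n_test = _round_half_up(len(ids) * fraction)
        test = [ids[i] for i in order[:n_test]]
        train = [ids[i] for i in order[n_test:]]
        return SplitPlan(tuple(train), tuple(test), "random", seed)
    if method == "euclidean":
        if matrix is None:
            raise ValueError("euclidean split requires a descriptor matrix")
        sub = matrix.loc[ids]
        X = sub.to_numpy(dtype=float)
        centroid = X.mean(axis=0)
        dist = np.linalg.norm(X - centroid, axis=1)
        rank = np.argsort(dist, kind="stable")
        k = int(round(1.0 / fraction))
        test, train = [], []
        for i, pos in enumerate(rank):
            (test if (i + 1) % k == 0 else train).append(ids[pos])
        return SplitPlan(tuple(train), tuple(test), "euclidean", seed)
    raise ValueError(f"unknown split method {method!r}")


# ---------------------------------------------------------------------------
# Wilks lambda
# ---------------------------------------------------------------------------

def wilks_lambda(features, labels) -> float:
    """Wilks λ = det(W) / det(T): within-group over total scatter.

    λ ∈ (0, 1]; smaller values mean better class separation.  Requires
    two classes with at least two records each; a singular total scatter
    matrix raises (prune collinear columns first).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("wilks_lambda requires exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 records")
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for c in classes:
        Xc = X[y == c]
        W += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise np.linalg.LinAlgError(
            "singular total scatter matrix; prune constant/collinear columns"
        )
    if sign_w <= 0 or not np.isfinite(logdet_w):
        return 0.0  # zero within-class scatter: perfect separation limit
    return float(min(np.exp(logdet_w - logdet_t), 1.0))


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """A fitted LDA or RF model over a fixed set of modified-descriptor columns.

    Prediction refuses matrices whose columns do not match ``columns``
    exactly.  ``condition_means`` and ``ad_reference`` ride along so a
    saved bundle can screen new compounds self-contained; ``backend``
    names the descriptor backend the model was trained on.
    """

    kind: str  # "lda" | "rf"
    columns: tuple
    params: dict = dc_field(default_factory=dict)
    estimator: object | None = None
    seed: int | None = None
    backend: str | None = None
    condition_means: ConditionMeans | None = None
    ad_reference: object | None = None
    metadata: dict = dc_field(default_factory=dict)

    def _check_columns(self, X: pd.DataFrame) -> None:
        if tuple(X.columns) != tuple(self.columns):
            raise ValueError(
                "column mismatch: model expects exactly "
                f"{list(self.columns)}, got {list(X.columns)}"
            )

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        A = X.to_numpy(dtype=float)
        if self.kind == "lda":
            return A @ np.asarray(self.params["weights"]) + self.params["intercept"]
        proba = self.estimator.predict_proba(A)[:, 1]
        return proba - 0.5

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        if self.kind == "lda":
            return (self.decision_scores(X) > 0).astype(int)
        return self.estimator.predict(X.to_numpy(dtype=float)).astype(int)


def fit_lda(matrix: pd.DataFrame, labels, ridge: float = 1e-6) -> ClassifierModel:
    """Two-class linear discriminant with pooled covariance.

    Equal priors; classification by the sign of the discriminant score at
    threshold 0.  A singular pooled covariance gets a ridge of ``ridge``
    added to its diagonal (logged), then the fit proceeds.
    """
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fit_lda requires exactly two classes")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    n = len(y)
    S = ((X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)) / max(n - 2, 1)
    S = np.atleast_2d(S)
    ridge_applied = False
    try:
        if np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(S, m1 - m0)
    except np.linalg.LinAlgError:
        ridge_applied = True
        logger.warning("singular pooled covariance; ridge %.1e applied", ridge)
        w = np.linalg.solve(S + ridge * np.eye(S.shape[0]), m1 - m0)
    intercept = float(-w @ (m0 + m1) / 2.0)
    return ClassifierModel(
        kind="lda",
        columns=tuple(matrix.columns),
        params={"weights": w, "intercept": intercept, "ridge_applied": ridge_applied},
    )


def fit_rf(
    matrix: pd.DataFrame,
    labels,
    n_trees: int = 500,
    max_depth: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
) -> ClassifierModel:
    """Bootstrap-sampled decision-tree ensemble with majority vote.

    Defaults (500 trees, unlimited depth, min leaf 1) are the package's
    documented choices; tune them against internal validation.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(matrix.to_numpy(dtype=float), np.asarray(labels).astype(int))
    return ClassifierModel(
        kind="rf",
        columns=tuple(matrix.columns),
        params={"n_trees": n_trees, "max_depth": max_depth, "min_leaf": min_leaf},
        estimator=est,
        seed=seed,
    )


def _refit(model: ClassifierModel, X: pd.DataFrame, y) -> ClassifierModel:
    if model.kind == "lda":
        return fit_lda(X, y)
    p = model.params
    return fit_rf(
        X, y, n_trees=p["n_trees"], max_depth=p["max_depth"], min_leaf=p["min_leaf"],
        seed=model.seed or 0,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Confusion-matrix metric suite; zero-denominator metrics are None."""
    total = tp + tn + fp + fn

    def ratio(num, den):
        return num / den if den > 0 else None

    accuracy = ratio(tp + tn, total)
    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f_measure": f_measure,
        "mcc": mcc,
    }


@dataclass
class ValidationReport:
    """Metrics of one evaluation set, optionally with 10-fold CV mean ± SD."""

    n_pos: int
    n_neg: int
    confusion: tuple  # (tp, tn, fp, fn)
    metrics: dict
    cv_mean: dict | None = None
    cv_sd: dict | None = None

    def to_row(self, percent: bool = True) -> dict:
        row = {"n_pos": self.n_pos, "n_neg": self.n_neg}
        for k, v in self.metrics.items():
            if v is None:
                row[k] = None
            elif percent and k in ("accuracy", "precision", "sensitivity", "specificity"):
                row[k] = 100.0 * v
            else:
                row[k] = v
        return row


def evaluate(model: ClassifierModel, matrix: pd.DataFrame, labels, folds: int | None = None) -> ValidationReport:
    """Confusion-matrix validation of a model on a labeled set.

    With ``folds`` set, a stratified K-fold cross-validation additionally
    refits the classifier (feature selection and condition means stay
    fixed) and reports per-metric mean ± SD over the folds; folds where a
    metric is undefined are excluded from that metric's mean.
    """
    y = np.asarray(labels).astype(int)
    pred = model.predict(matrix)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    report = ValidationReport(
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        confusion=(tp, tn, fp, fn),
        metrics=metrics_from_confusion(tp, tn, fp, fn),
    )
    if folds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=model.seed or 0)
        per_fold: dict = {k: [] for k in METRIC_NAMES}
        A = matrix.reset_index(drop=True)
        for train_idx, val_idx in skf.split(A, y):
            sub = _refit(model, A.iloc[train_idx], y[train_idx])
            fold = evaluate(sub, A.iloc[val_idx], y[val_idx])
            for k in METRIC_NAMES:
                per_fold[k].append(fold.metrics[k])
        report.cv_mean = {}
        report.cv_sd = {}
        for k in METRIC_NAMES:
            vals = [v for v in per_fold[k] if v is not None]
            report.cv_mean[k] = float(np.mean(vals)) if vals else None
            report.cv_sd[k] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return report


# ---------------------------------------------------------------------------
# GA feature selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAParams:
    pop_size: int = 60
    generations: int = 40
    crossover_p: float = 0.9
    mutation_p: float = 0.2
    tournament: int = 3
    elitism: int = 2
    seed: int = 0


@dataclass
class GAResult:
    columns: tuple
    fitness: float
    trace: list  # best raw fitness per generation


def _subset_scores(X: np.ndarray, y: np.ndarray, cols: tuple, frame_cols, cache: dict):
    """(wilks_fitness, mcc_fitness) of a column subset; −inf on failure."""
    if cols in cache:
        return cache[cols]
    sub = X[:, list(cols)]
    try:
        wl = -wilks_lambda(sub, y)
    except (np.linalg.LinAlgError, ValueError):
        wl = -np.inf
    try:
        frame = pd.DataFrame(sub, columns=[frame_cols[c] for c in cols])
        model = fit_lda(frame, y)
        rep = evaluate(model, frame, y)
        mcc = rep.metrics["mcc"]
        mcc = -np.inf if mcc is None else mcc
    except (np.linalg.LinAlgError, ValueError):
        mcc = -np.inf
    cache[cols] = (wl, mcc)
    return cache[cols]


def _combined_order(pop, scores):
    """Rank-sum ordering (best first) over (wilks, mcc) score pairs."""
    wl = np.array([scores[c][0] for c in pop])
    mc = np.array([scores[c][1] for c in pop])
    # rank 0 = best; argsort of descending scores
    rank_wl = np.empty(len(pop))
    rank_wl[np.argsort(-wl, kind="stable")] = np.arange(len(pop))
    rank_mc = np.empty(len(pop))
    rank_mc[np.argsort(-mc, kind="stable")] = np.arange(len(pop))
    return np.argsort(rank_wl + rank_mc, kind="stable")


def ga_select(
    matrix: pd.DataFrame,
    labels,
    n_features: int,
    ga_params: GAParams | None = None,
    fitness: str = "wilks",
) -> GAResult:
    """Genetic-algorithm selection of a fixed-size descriptor subset.

    Chromosomes are column subsets of size ``n_features``; tournament
    selection, uniform crossover repaired to fixed size, point mutation
    swapping one column, and elitism; fully determined by the seed.
    Fitness: ``wilks`` maximizes −λ, ``mcc`` maximizes training MCC of an
    LDA fit, ``combined`` minimizes the rank-sum of both.
    """
    if fitness not in ("wilks", "mcc", "combined"):
        raise ValueError(f"unknown fitness {fitness!r}")
    params = ga_params or GAParams()
    y = np.asarray(labels).astype(int)
    n_records, n_cols = matrix.shape
    if n_features > n_cols:
        raise ValueError("n_features exceeds available columns")
    if n_features >= n_records:
        raise ValueError("n_features must be smaller than the number of records (overfit guard)")
    X = matrix.to_numpy(dtype=float)
    frame_cols = list(matrix.columns)
    rng = np.random.default_rng(params.seed)
    cache: dict = {}

    def random_chromo():
        return tuple(sorted(rng.choice(n_cols, size=n_features, replace=False)))

    def scalar(cols):
        wl, mc = _subset_scores(X, y, cols, frame_cols, cache)
        return wl if fitness == "wilks" else mc

    pop = [random_chromo() for _ in range(params.pop_size)]
    trace: list = []

    def order_population(p):
        for c in p:
            _subset_scores(X, y, c, frame_cols, cache)
        if fitness == "combined":
            return [p[i] for i in _combined_order(p, cache)]
        return sorted(p, key=scalar, reverse=True)

    pop = order_population(pop)
    best = pop[0]
    trace.append(scalar(best) if fitness != "combined" else cache[best][0])

    for _ in range(params.generations):
        new_pop = list(pop[: params.elitism])
        while len(new_pop) < params.pop_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = [pop[i] for i in rng.integers(0, len(pop), params.tournament)]
                contenders = order_population(contenders)
                parents.append(contenders[0])
            p1, p2 = parents
            if rng.random() < params.crossover_p:
                pool = list(set(p1) | set(p2))
                # uniform crossover: genes drawn from the parent pool,
                # repaired to exact size by sampling without replacement
                child = tuple(sorted(rng.choice(pool, size=n_features, replace=False)))
            else:
                child = p1
            if rng.random() < params.mutation_p:
                child_l = list(child)
                pos = rng.integers(0, n_features)
                free = [c for c in range(n_cols) if c not in child_l]
                if free:
                    child_l[pos] = free[rng.integers(0, len(free))]
                child = tuple(sorted(child_l))
            new_pop.append(child)
        pop = order_population(new_pop)
        best = pop[0]
        trace.append(scalar(best) if fitness != "combined" else cache[best][0])

    wl, mc = cache[best]
    final = {"wilks": wl, "mcc": mc, "combined": wl}[fitness]
    return GAResult(tuple(frame_cols[i] for i in best), float(final), trace)


def exhaustive_select(matrix: pd.DataFrame, labels, n_features: int, fitness: str = "wilks"):
    """Brute-force best subset by the same fitness; oracle for small p."""
    y = np.asarray(labels).astype(int)
    X = matrix.to_numpy(dtype=float)
    frame_cols = list(matrix.columns)
    cache: dict = {}
    best, best_score = None, -np.inf
    for cols in combinations(range(matrix.shape[1]), n_features):
        wl, mc = _subset_scores(X, y, cols, frame_cols, cache)
        score = wl if fitness == "wilks" else mc
        if score > best_score:
            best, best_score = cols, score
    return tuple(frame_cols[i] for i in best), float(best_score)


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

class ModelBundleError(RuntimeError):
    """A model bundle is incomplete, tampered with, or mismatched."""


BUNDLE_VERSION = 1


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_model(model: ClassifierModel, path) -> None:
    """Persist a model as a directory bundle.

    The bundle embeds the selected columns, classifier parameters, the
    condition means, AD reference data and the descriptor-backend tag,
    with SHA-256 hashes over the payload and auxiliary files so loading
    can detect tampering.
    """
    if model.condition_means is None:
        raise ValueError("model has no ConditionMeans attached; bundle would not be self-contained")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    files = {}
    arrays = {}
    if model.kind == "lda":
        arrays["lda_weights"] = np.asarray(model.params["weights"], dtype=float)
    if model.ad_reference is not None:
        ref = model.ad_reference
        arrays["ad_fingerprints"] = ref.fingerprints
        arrays["ad_matrix"] = ref.X
        arrays["ad_xtx_pinv"] = ref.xtx_pinv
    if arrays:
        np.savez(path / "arrays.npz", **arrays)
        files["arrays.npz"] = None
    if model.kind == "rf":
        joblib.dump(model.estimator, path / "rf.joblib")
        files["rf.joblib"] = None

    payload = {
        "format_version": BUNDLE_VERSION,
        "kind": model.kind,
        "columns": list(model.columns),
        "backend": model.backend,
        "seed": model.seed,
        "params": {
            k: v for k, v in model.params.items() if not isinstance(v, np.ndarray)
        },
        "lda_intercept": model.params.get("intercept"),
        "condition_means": model.condition_means.to_dict(),
        "ad": None,
        "metadata": model.metadata,
    }
    if model.ad_reference is not None:
        ref = model.ad_reference
        payload["ad"] = {
            "columns": list(ref.columns),
            "n": ref.n,
            "k": ref.k,
            "leverage_enabled": ref.leverage_enabled,
            "nn_mean": ref.nn_mean,
            "nn_sd": ref.nn_sd,
            "thresholds": dict(ref.thresholds),
        }
    meta = dict(payload)
    meta["payload_sha256"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=float).encode()
    ).hexdigest()
    for fname in files:
        files[fname] = _sha256(path / fname)
    meta["files"] = files
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, default=float))


def load_model(path) -> ClassifierModel:
    """Load a bundle written by :func:`save_model`, validating all hashes."""
    from .applicability import ADReference

    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise ModelBundleError(f"no metadata.json in {path}")
    meta = json.loads(meta_path.read_text())
    payload = {k: v for k, v in meta.items() if k not in ("payload_sha256", "files")}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=float).encode()
    ).hexdigest()
    if digest != meta.get("payload_sha256"):
        raise ModelBundleError("payload hash mismatch: bundle metadata was modified")
    for fname, expected in meta.get("files", {}).items():
        fpath = path / fname
        if not fpath.exists():
            raise ModelBundleError(f"bundle file missing: {fname}")
        if _sha256(fpath) != expected:
            raise ModelBundleError(f"bundle file hash mismatch: {fname}")
    if meta.get("condition_means") is None:
        raise ModelBundleError("bundle lacks ConditionMeans")

    arrays = {}
    if "arrays.npz" in meta.get("files", {}):
        with np.load(path / "arrays.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}

    params = dict(meta.get("params") or {})
    estimator = None
    if meta["kind"] == "lda":
        params["weights"] = arrays["lda_weights"]
        params["intercept"] = meta["lda_intercept"]
    else:
        estimator = joblib.load(path / "rf.joblib")

    ad_ref = None
    if meta.get("ad") is not None:
        ad = meta["ad"]
        ad_ref = ADReference(
            fingerprints=arrays["ad_fingerprints"],
            X=arrays["ad_matrix"],
            columns=tuple(ad["columns"]),
            xtx_pinv=arrays["ad_xtx_pinv"],
            n=int(ad["n"]),
            k=int(ad["k"]),
            leverage_enabled=bool(ad["leverage_enabled"]),
            nn_mean=float(ad["nn_mean"]),
            nn_sd=float(ad["nn_sd"]),
            thresholds=dict(ad["thresholds"]),
        )
    return ClassifierModel(
        kind=meta["kind"],
        columns=tuple(meta["columns"]),
        params=params,
        estimator=estimator,
        seed=meta.get("seed"),
        backend=meta.get("backend"),
        condition_means=ConditionMeans.from_dict(meta["condition_means"]),
        ad_reference=ad_ref,
        metadata=meta.get("metadata") or {},
    )
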