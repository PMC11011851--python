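"""Storage-day discrimination and regression on image feature tables.

The discrimination pipeline follows common chemometric practice:
features are z-scored, a chosen feature subset is compacted into two
principal components (PCA1, PCA2), a classifier is trained on the 2-D
scores, and precision is estimated by leave-one-out (LOO)
cross-validation with the normalisation, PCA and classifier all refit
on the training observations of every fold — no information from the
held-out observation leaks into the fitted parameters.  An exhaustive
subset search enumerates every feature combination up to a size cap and
keeps the one with the highest LOO accuracy.

Storage-day regression uses stagewise gradient boosting with shallow
regression trees (F0 = mean(y); F_m = F_{m-1} + nu * tree_m fitted by
squared error to the residuals), evaluated by K-fold R².
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.tree import DecisionTreeRegressor

from ._cart import DecisionTreeCART

__all__ = [
    "PCAModel",
    "ClassificationResult",
    "RegressionResult",
    "zscore",
    "apply_zscore",
    "pca2",
    "register_classifier",
    "registered_classifiers",
    "make_classifier",
    "loo_evaluate",
    "loo_training_parameters",
    "feature_subset_search",
    "GBRTModel",
    "fit_gbrt",
    "gbrt_predict",
    "kfold_r2",
    "r_squared",
    "plot_scores",
]


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def zscore(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Standardise every column to zero mean and unit (population) SD.

    Returns the normalised table and the per-column (mean, SD) parameters
    for applying the same transform to held-out observations.
    """
    params: dict[str, tuple[float, float]] = {}
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=np.float64)
        mean = x.mean()
        sd = x.std()
        if sd == 0:
            raise ValueError(f"zero-variance column {col!r} cannot be z-scored")
        params[col] = (float(mean), float(sd))
        out[col] = (x - mean) / sd
    return pd.DataFrame(out, index=table.index), params


def apply_zscore(table: pd.DataFrame, params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = {}
    for col, (mean, sd) in params.items():
        out[col] = (table[col].to_numpy(dtype=np.float64) - mean) / sd
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# PCA compaction
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Two-component PCA of a z-scored feature subset."""

    features: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (d, 2), orthonormal columns
    explained_variance: tuple[float, float]

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.features)].to_numpy(dtype=np.float64)
        return ((X - self.means) / self.sds) @ self.loadings


def _pca2_loadings(Z: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Top-2 eigenvectors of the covariance of z-scored data Z (n, d)."""
    n, d = Z.shape
    if d == 1:
        return np.array([[1.0, 0.0]]), (float(Z.var()), 0.0)
    C = (Z.T @ Z) / n
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:2]
    load = v[:, order]
    ev = (float(max(w[order[0]], 0.0)), float(max(w[order[1]], 0.0)))
    # sign convention: the largest-magnitude entry of each loading is positive
    for j in range(load.shape[1]):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    return load, ev


def pca2(table: pd.DataFrame, subset: Sequence[str]) -> tuple[PCAModel, np.ndarray]:
    """Compact a feature subset into two principal components.

    The components are eigenvectors of the covariance matrix of the
    z-scored subset (equivalently, correlation PCA).  For a single
    feature the second component is identically zero.
    """
    subset = tuple(subset)
    if len(subset) < 1:
        raise ValueError("subset must contain at least one feature")
    if len(table) < 3:
        raise ValueError("need at least 3 observations for PCA")
    X = table[list(subset)].to_numpy(dtype=np.float64)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = subset[int(np.argmax(sds == 0))]
        raise ValueError(f"zero-variance column {bad!r} cannot be z-scored")
    Z = (X - means) / sds
    loadings, ev = _pca2_loadings(Z)
    model = PCAModel(features=subset, means=means, sds=sds, loadings=loadings,
                     explained_variance=ev)
    return model, Z @ loadings


# ---------------------------------------------------------------------------
# classifier registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., object]] = {}


def register_classifier(name: str, factory: Callable[..., object]) -> None:
    """Register a classifier factory: ``factory(seed=0, **params)`` must
    return an object with sklearn-style ``fit(scores, labels)`` /
    ``predict(scores)``."""
    if name in _REGISTRY:
        raise ValueError(f"classifier {name!r} already registered")
    _REGISTRY[name] = factory


def registered_classifiers() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def make_classifier(name: str, seed: int = 0, **params):
    if name not in _REGISTRY:
        raise ValueError(
            f"unknown classifier {name!r}; registered: {', '.join(registered_classifiers())}"
        )
    return _REGISTRY[name](seed=seed, **params)


register_classifier("nearest_centroid", lambda seed=0: NearestCentroid())
register_classifier(
    "k_nearest_neighbor", lambda seed=0, k=5: KNeighborsClassifier(n_neighbors=k)
)
register_classifier("linear_discriminant", lambda seed=0: LinearDiscriminantAnalysis())
register_classifier(
    "decision_tree", lambda seed=0, max_depth=None: DecisionTreeCART(max_depth=max_depth)
)


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    classifier: str
    subset: tuple[str, ...]
    accuracy: float  # percent
    per_class: dict[object, tuple[int, int]]  # class -> (correct, total)
    confusion: pd.DataFrame
    scores: np.ndarray  # full-data 2-D scores, for plotting
    predictions: np.ndarray
    labels: np.ndarray
    n_evaluated: int | None = None  # subsets enumerated, when from a search


def _fold_parameters(X: np.ndarray, mask: np.ndarray):
    """z-score and PCA parameters fitted on the masked (training) rows."""
    Xt = X[mask]
    means = Xt.mean(axis=0)
    sds = Xt.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("zero-variance feature inside a training fold")
    Z = (Xt - means) / sds
    loadings, ev = _pca2_loadings(Z)
    return means, sds, Z, loadings, ev


def loo_training_parameters(
    table: pd.DataFrame, subset: Sequence[str], held_out_index: int
) -> dict[str, np.ndarray]:
    """The normalisation/PCA parameters of one LOO fold (training side).

    Computed from the training rows only; the held-out observation's
    value cannot influence them.
    """
    X = table[list(subset)].to_numpy(dtype=np.float64)
    mask = np.ones(len(X), dtype=bool)
    mask[held_out_index] = False
    means, sds, _, loadings, ev = _fold_parameters(X, mask)
    return {"means": means, "sds": sds, "loadings": loadings,
            "explained_variance": np.asarray(ev)}


def _loo_predict(
    X: np.ndarray, y_enc: np.ndarray, clf_factory: Callable[[], object]
) -> np.ndarray:
    n = X.shape[0]
    preds = np.empty(n, dtype=y_enc.dtype)
    mask = np.ones(n, dtype=bool)
    for k in range(n):
        mask[k] = False
        means, sds, Z, loadings, _ = _fold_parameters(X, mask)
        scores = Z @ loadings
        test_score = ((X[k] - means) / sds) @ loadings
        clf = clf_factory()
        clf.fit(scores, y_enc[mask])
        preds[k] = clf.predict(test_score[None, :])[0]
        mask[k] = True
    return preds


def loo_evaluate(
    table: pd.DataFrame,
    labels: Sequence,
    classifier: str = "nearest_centroid",
    subset: Sequence[str] | None = None,
    seed: int = 0,
    **classifier_params,
) -> ClassificationResult:
    """Leak-free LOO accuracy of the zscore→PCA2→classifier pipeline.

    For every observation, normalisation parameters, PCA loadings and the
    classifier are refit on the remaining observations only.
    """
    subset = tuple(subset) if subset is not None else tuple(table.columns)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 observations")
    make = lambda: make_classifier(classifier, seed=seed, **classifier_params)
    X = table[list(subset)].to_numpy(dtype=np.float64)
    preds = _loo_predict(X, y, make)

    correct = preds == y
    per_class = {c: (int(correct[y == c].sum()), int((y == c).sum())) for c in classes}
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(preds, name="predicted"), dropna=False
    ).reindex(index=classes, columns=classes, fill_value=0)
    _, full_scores = pca2(table, subset)
    return ClassificationResult(
        classifier=classifier,
        subset=subset,
        accuracy=100.0 * float(correct.mean()),
        per_class=per_class,
        confusion=confusion,
        scores=full_scores,
        predictions=preds,
        labels=y,
    )


def feature_subset_search(
    table: pd.DataFrame,
    labels: Sequence,
    classifier: str = "decision_tree",
    max_subset_size: int = 5,
    features: Sequence[str] | None = None,
    seed: int = 0,
    **classifier_params,
) -> tuple[tuple[str, ...], ClassificationResult]:
    """Exhaustive LOO search over all feature subsets of size 1..cap.

    Ties are broken towards smaller subsets, then lexicographic feature
    order; the returned accuracy is >= that of every enumerated subset.
    """
    if max_subset_size < 1:
        raise ValueError("max_subset_size must be >= 1")
    names = sorted(features if features is not None else table.columns)
    if max_subset_size > len(names):
        raise ValueError("max_subset_size exceeds the number of features")
    y = np.asarray(labels)
    make = lambda: make_classifier(classifier, seed=seed, **classifier_params)
    X_full = table[names].to_numpy(dtype=np.float64)
    col_of = {name: i for i, name in enumerate(names)}

    best_subset: tuple[str, ...] | None = None
    best_correct = -1
    n_evaluated = 0
    for size in range(1, max_subset_size + 1):
        for combo in itertools.combinations(names, size):
            n_evaluated += 1
            X = np.ascontiguousarray(X_full[:, [col_of[c] for c in combo]])
            preds = _loo_predict(X, y, make)
            n_correct = int((preds == y).sum())
            if n_correct > best_correct:
                best_correct = n_correct
                best_subset = combo
    assert best_subset is not None
    result = loo_evaluate(table, y, classifier=classifier, subset=best_subset,
                          seed=seed, **classifier_params)
    result.n_evaluated = n_evaluated
    return best_subset, result


def plot_scores(result: ClassificationResult, path, seed: int = 0) -> None:
    """PCA1-vs-PCA2 scatter of a classification result with the decision
    surface of the named classifier refit on the full-data scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = result.scores
    clf = make_classifier(result.classifier, seed=seed)
    classes, y_enc = np.unique(result.labels, return_inverse=True)
    clf.fit(scores, y_enc)
    pad = 0.5
    x0, x1 = scores[:, 0].min() - pad, scores[:, 0].max() + pad
    y0, y1 = scores[:, 1].min() - pad, scores[:, 1].max() + pad
    xx, yy = np.meshgrid(np.linspace(x0, x1, 250), np.linspace(y0, y1, 250))
    zz = np.asarray(clf.predict(np.column_stack([xx.ravel(), yy.ravel()])),
                    dtype=float).reshape(xx.shape)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.contourf(xx, yy, zz, levels=max(len(classes) - 1, 1), alpha=0.15, cmap="coolwarm")
    for ci, cls in enumerate(classes):
        m = result.labels == cls
        ax.scatter(scores[m, 0], scores[m, 1], s=18, label=str(cls))
    miss = result.predictions != result.labels
    if miss.any():
        ax.scatter(scores[miss, 0], scores[miss, 1], marker="x", c="k", s=40,
                   label="misclassified")
    ax.set_xlabel("PCA1")
    ax.set_ylabel("PCA2")
    ax.set_title(f"{result.classifier} on {', '.join(result.subset)} "
                 f"({result.accuracy:.1f}% LOO)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# gradient-boosted regression
# ---------------------------------------------------------------------------


@dataclass
class GBRTModel:
    """Stagewise boosted regression trees: F_m = F_{m-1} + nu * tree_m."""

    init_prediction: float
    trees: list
    learning_rate: float
    hyperparameters: dict = field(default_factory=dict)


def fit_gbrt(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 300,
    learning_rate: float = 0.1,
    max_depth: int = 2,
    seed: int = 0,
) -> GBRTModel:
    """Gradient boosting for squared error.

    F0 is the training mean; each subsequent regression tree is fitted to
    the current residuals and added with shrinkage ``learning_rate``.
    Training squared error is non-increasing in the number of trees.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty target")
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    if not (0 < learning_rate <= 1):
        raise ValueError("learning_rate must be in (0, 1]")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    f0 = float(y.mean())
    F = np.full_like(y, f0)
    trees = []
    for m in range(n_trees):
        tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
        tree.fit(X, y - F)
        F = F + learning_rate * tree.predict(X)
        trees.append(tree)
    return GBRTModel(
        init_prediction=f0,
        trees=trees,
        learning_rate=learning_rate,
        hyperparameters={"n_trees": n_trees, "learning_rate": learning_rate,
                         "max_depth": max_depth, "seed": seed},
    )


def gbrt_predict(model: GBRTModel, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
    """Predict with the first ``n_trees`` stages (all by default)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    trees = model.trees if n_trees is None else model.trees[:n_trees]
    out = np.full(X.shape[0], model.init_prediction)
    for tree in trees:
        out = out + model.learning_rate * tree.predict(X)
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y")
    return 1.0 - float(np.sum((y - y_pred) ** 2)) / ss_tot


@dataclass
class RegressionResult:
    hyperparameters: dict
    fold_r2: list[float]
    mean_r2: float
    predictions: np.ndarray  # per-observation held-out predictions
    folds: list[np.ndarray]


def kfold_r2(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    n_trees: int = 300,
    learning_rate: float = 0.1,
    max_depth: int = 2,
    seed: int = 0,
) -> RegressionResult:
    """Seeded shuffled K-fold evaluation of the boosted day regressor.

    Per-fold R² is computed on the held-out fold; the folds partition the
    observations into K near-equal parts.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if not (2 <= k <= n):
        raise ValueError(f"k must be between 2 and {n}")
    if n // k < 2:
        raise ValueError("each fold needs at least 2 observations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(part) for part in np.array_split(perm, k)]
    preds = np.empty(n)
    r2s = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        model = fit_gbrt(X[train_mask], y[train_mask], n_trees=n_trees,
                         learning_rate=learning_rate, max_depth=max_depth, seed=seed)
        p = gbrt_predict(model, X[test_idx])
        preds[test_idx] = p
        r2s.append(r_squared(y[test_idx], p))
    return RegressionResult(
        hyperparameters={"n_trees": n_trees, "learning_rate": learning_rate,
                         "max_depth": max_depth, "seed": seed, "k": k},
        fold_r2=[float(v) for v in r2s],
        mean_r2=float(np.mean(r2s)),
        predictions=preds,
        folds=folds,
    )
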