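"""Comparator classifiers on the 20-peak feature table: PLS-DA with
Q2/R2/VIP scores, PCA + k-means on the first two components, and a bagged
random forest with OOB error, OOB permutation importance and proximity-based
outlier scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.tree import DecisionTreeClassifier

from .dataset import DatasetError, SpectralDataset

#: Canonical peaks-of-interest (cm^-1) representing a spectral sample.
FEATURE_WAVENUMBERS = (
    700.0, 744.0, 854.0, 898.0, 917.0, 1003.0, 1048.0, 1147.0, 1157.0, 1226.0,
    1288.0, 1309.0, 1328.0, 1343.0, 1355.0, 1451.0, 1456.0, 1494.0, 1525.0, 1606.0,
)


def extract_features(dataset: SpectralDataset, wavenumbers=FEATURE_WAVENUMBERS) -> pd.DataFrame:
    """Nearest-grid-point intensities at the canonical peak list, one row per
    spectrum, columns in canonical order plus ``class``."""
    grid = dataset.grid
    wavenumbers = tuple(sorted(float(w) for w in wavenumbers))  # canonical order
    idx = []
    for w in wavenumbers:
        if w < grid[0] or w > grid[-1]:
            raise DatasetError(f"feature wavenumber {w} outside dataset grid span")
        idx.append(int(np.argmin(np.abs(grid - w))))
    mat = dataset.intensities[:, idx]
    df = pd.DataFrame(mat, columns=[f"{w:g}" for w in wavenumbers])
    df.insert(0, "sample_id", dataset.meta["sample_id"].to_numpy())
    df["class"] = dataset.meta["class_label"].to_numpy()
    return df


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(str(v) for v in labels))
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, classes


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PlsdaModel:
    classes: list[str]
    n_components: int
    r_squared: float
    q_squared: float
    accuracy_pct: float
    vip: np.ndarray
    feature_names: list[str]
    x_weights: np.ndarray
    component_ss: np.ndarray
    dropped_features: list[str]

    def vip_ranking(self, k: int = 5) -> list[tuple[str, float]]:
        order = np.argsort(self.vip)[::-1][:k]
        return [(self.feature_names[i], float(self.vip[i])) for i in order]


def _vip_scores(pls: PLSRegression) -> tuple[np.ndarray, np.ndarray]:
    """VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a) with
    SS_a = (t_a' t_a)(q_a' q_a), the Y-variance captured per component."""
    W = pls.x_weights_
    T = pls.x_scores_
    Q = pls.y_loadings_
    p, a = W.shape
    ss = np.array([(T[:, i] @ T[:, i]) * (Q[:, i] @ Q[:, i]) for i in range(a)])
    wnorm2 = (W**2) / np.sum(W**2, axis=0, keepdims=True)
    vip = np.sqrt(p * (wnorm2 @ ss) / ss.sum())
    return vip, ss


def plsda_fit(
    features: pd.DataFrame | np.ndarray,
    labels=None,
    n_components: int = 5,
    cv_folds: int = 5,
    seed: int = 0,
) -> PlsdaModel:
    """PLS2 (NIPALS) on autoscaled features against one-hot class labels.

    Class prediction is the argmax of the predicted indicator block; R2 on
    the fit, Q2 = 1 - PRESS/TSS via stratified k-fold CV, and VIP per feature.
    Constant features are dropped with a warning field on the model.
    """
    X, y, names = _coerce_features(features, labels)
    keep = X.std(axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] <= n_components:
        raise ValueError("need more samples than components")
    Xs, _, _ = _autoscale(X)
    Y, classes = _one_hot(y)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Y)
    Y_hat = pls.predict(Xs)
    r2 = 1.0 - np.sum((Y - Y_hat) ** 2) / np.sum((Y - Y.mean(axis=0)) ** 2)
    acc = 100.0 * float(np.mean(np.argmax(Y_hat, axis=1) == np.argmax(Y, axis=1)))
    vip, ss = _vip_scores(pls)

    # Stratified k-fold Q2 (autoscaling refit inside each fold).
    rng = np.random.default_rng(seed)
    fold = np.zeros(X.shape[0], dtype=int)
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        fold[idx] = np.arange(idx.size) % cv_folds
    press = 0.0
    for f in range(cv_folds):
        tr, te = fold != f, fold == f
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        m = PLSRegression(n_components=min(n_components, tr.sum() - 1), scale=False)
        m.fit((X[tr] - mu) / sd, Y[tr])
        press += float(np.sum((Y[te] - m.predict((X[te] - mu) / sd)) ** 2))
    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    q2 = 1.0 - press / tss

    return PlsdaModel(
        classes=classes,
        n_components=n_components,
        r_squared=float(r2),
        q_squared=float(q2),
        accuracy_pct=acc,
        vip=vip,
        feature_names=names,
        x_weights=pls.x_weights_,
        component_ss=ss,
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# PCA + k-means
# ---------------------------------------------------------------------------


@dataclass
class KmeansResult:
    assignments: np.ndarray
    centroids: np.ndarray
    scores: np.ndarray  # (n, 2) PC scores used for clustering
    inertia_path: list[float]
    contingency: pd.DataFrame | None = None


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(X.shape[0])]]
    for _ in range(1, k):
        d2 = np.min(
            np.stack([np.sum((X - c) ** 2, axis=1) for c in centers]), axis=0
        )
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(X.shape[0], 1.0 / X.shape[0])
        centers.append(X[rng.choice(X.shape[0], p=probs)])
    return np.array(centers)


def lloyd_kmeans(
    X: np.ndarray, k: int, seed: int = 0, max_iter: int = 300, tol: float = 1e-10,
    n_init: int = 10,
) -> KmeansResult:
    """Lloyd's algorithm with k-means++ initialisation, best of ``n_init``
    restarts; the within-cluster sum of squares is recorded every iteration
    of each run and asserted non-increasing."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {X.shape[0]}")
    rng = np.random.default_rng(seed)
    best: KmeansResult | None = None
    for _ in range(max(1, n_init)):
        res = _lloyd_single(X, k, rng, max_iter, tol)
        if best is None or res.inertia_path[-1] < best.inertia_path[-1]:
            best = res
    return best


def _lloyd_single(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> KmeansResult:
    centers = _kmeans_pp_init(X, k, rng)
    path: list[float] = []
    assign = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        assign = np.argmin(d2, axis=1)
        inertia = float(np.sum(d2[np.arange(X.shape[0]), assign]))
        if path and inertia > path[-1] + 1e-9:
            raise AssertionError("k-means objective increased")
        converged = path and path[-1] - inertia < tol
        path.append(inertia)
        new_centers = centers.copy()
        for j in range(k):
            members = X[assign == j]
            if members.size:
                new_centers[j] = members.mean(axis=0)
        if converged and np.allclose(new_centers, centers):
            break
        centers = new_centers
    return KmeansResult(assignments=assign, centroids=centers, scores=X, inertia_path=path)


def pca_kmeans(
    features: pd.DataFrame | np.ndarray, labels=None, k: int = 4, seed: int = 0
) -> KmeansResult:
    """PCA on autoscaled features, then Lloyd's k-means on (PC1, PC2)."""
    X, y, _ = _coerce_features(features, labels, require_labels=False)
    Xs, _, _ = _autoscale(X)
    n_comp = min(2, Xs.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(Xs)
    res = lloyd_kmeans(scores, k, seed=seed)
    if y is not None:
        res.contingency = pd.crosstab(
            pd.Series(y, name="class"), pd.Series(res.assignments, name="cluster")
        )
    return res


# ---------------------------------------------------------------------------
# Random forest with OOB machinery
# ---------------------------------------------------------------------------


@dataclass
class RfModel:
    classes: list[str]
    n_trees: int
    mtry: int
    oob_error: float  # fraction
    per_class_error: dict[str, float]
    importance: np.ndarray  # mean decrease in OOB accuracy per feature
    feature_names: list[str]
    proximity: np.ndarray
    outlier_scores: np.ndarray  # median/MAD-normalised within class
    raw_outlier: np.ndarray

    @property
    def accuracy_pct(self) -> float:
        """Overall accuracy implied by the OOB error, in percent."""
        return 100.0 - 100.0 * self.oob_error

    def importance_ranking(self, k: int = 5) -> list[tuple[str, float]]:
        order = np.argsort(self.importance)[::-1][:k]
        return [(self.feature_names[i], float(self.importance[i])) for i in order]


def rf_fit(
    features: pd.DataFrame | np.ndarray,
    labels=None,
    n_trees: int = 500,
    mtry: int = 7,
    seed: int = 0,
) -> RfModel:
    """Bagged decision trees with explicit bootstrap bookkeeping.

    OOB error comes from out-of-bag majority votes; feature importance is the
    mean decrease in OOB accuracy when that feature's column is permuted;
    proximity(i, j) is the fraction of trees placing i and j in the same
    leaf; the outlier score is n_class / sum_j prox(i, j)^2 over same-class
    samples, median/MAD-normalised within class.
    """
    X, y, names = _coerce_features(features, labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    mtry = min(mtry, p)
    rng = np.random.default_rng(seed)
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[v] for v in y])

    trees, boot_masks, leaves = [], [], np.zeros((n_trees, n), dtype=np.int32)
    oob_votes = np.zeros((n, len(classes)))
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y_idx[boot])
        trees.append(tree)
        boot_masks.append(oob)
        leaves[t] = tree.apply(X)
        if oob.any():
            pred = tree.predict(X[oob])
            oob_votes[np.flatnonzero(oob), pred] += 1

    voted = oob_votes.sum(axis=1) > 0
    oob_pred = np.argmax(oob_votes, axis=1)
    oob_correct = (oob_pred == y_idx) & voted
    oob_error = 1.0 - oob_correct[voted].sum() / voted.sum()
    per_class_error = {}
    for c in classes:
        mask = (y_idx == class_index[c]) & voted
        per_class_error[c] = float(1.0 - np.mean(oob_pred[mask] == y_idx[mask])) if mask.any() else float("nan")

    # OOB permutation importance: accuracy drop when feature j is shuffled.
    base_acc = np.zeros(n_trees)
    for t, (tree, oob) in enumerate(zip(trees, boot_masks)):
        if oob.any():
            base_acc[t] = np.mean(tree.predict(X[oob]) == y_idx[oob])
    importance = np.zeros(p)
    for j in range(p):
        perm_rng = np.random.default_rng(seed + 7919 * (j + 1))
        drops = []
        for t, (tree, oob) in enumerate(zip(trees, boot_masks)):
            if not oob.any():
                continue
            Xp = X[oob].copy()
            Xp[:, j] = perm_rng.permutation(Xp[:, j])
            drops.append(base_acc[t] - np.mean(tree.predict(Xp) == y_idx[oob]))
        importance[j] = float(np.mean(drops)) if drops else 0.0

    # Proximity: fraction of trees placing two samples in the same leaf.
    prox = np.zeros((n, n))
    for t in range(n_trees):
        lv = leaves[t]
        prox += (lv[:, None] == lv[None, :]).astype(float)
    prox /= n_trees
    np.fill_diagonal(prox, 1.0)

    raw = np.zeros(n)
    scores = np.zeros(n)
    for c in classes:
        members = np.flatnonzero(y_idx == class_index[c])
        if members.size < 2:
            raw[members] = float("nan")
            scores[members] = float("nan")
            continue
        for i in members:
            others = members[members != i]
            denom = float(np.sum(prox[i, others] ** 2))
            raw[i] = members.size / denom if denom > 0 else np.inf
        med = np.median(raw[members])
        mad = np.median(np.abs(raw[members] - med))
        scores[members] = (raw[members] - med) / (mad if mad > 0 else 1.0)

    return RfModel(
        classes=classes,
        n_trees=n_trees,
        mtry=mtry,
        oob_error=float(oob_error),
        per_class_error=per_class_error,
        importance=importance,
        feature_names=names,
        proximity=prox,
        outlier_scores=scores,
        raw_outlier=raw,
    )


# ---------------------------------------------------------------------------


def _coerce_features(features, labels, require_labels: bool = True):
    """Accept the extract_features frame (class column) or (array, labels)."""
    if isinstance(features, pd.DataFrame):
        df = features
        y = df["class"].to_numpy() if "class" in df.columns else None
        drop = [c for c in ("sample_id", "class") if c in df.columns]
        Xdf = df.drop(columns=drop)
        X = Xdf.to_numpy(dtype=float)
        names = list(Xdf.columns)
    else:
        X = np.asarray(features, dtype=float)
        y = None
        names = [str(i) for i in range(X.shape[1])]
    if labels is not None:
        y = np.asarray(labels)
    if y is not None:
        y = np.asarray([str(v) for v in y])
    if require_labels and y is None:
        raise ValueError("labels are required")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X, y, names
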