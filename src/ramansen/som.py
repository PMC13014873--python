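"""Self-organising-map classification with a per-class discriminant-index
readout.

Training is classic online Kohonen: winner-take-all with a Gaussian
neighbourhood on a hexagonal grid, learning rate and radius decaying linearly
over the run. Neurons are labelled by the majority class of the training
samples they win; prediction routes a sample to its best-matching neuron's
label. The discriminant index (SOMDI) for a class is the elementwise mean of
the unit-normalised weight vectors of that class's neurons minus the mean
over all labelled neurons, negatives clipped to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching conventional reporting of accuracies."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _nearest_rows(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Index of the nearest row of W (squared Euclidean) for each row of X."""
    d = np.sum(W**2, axis=1)[None, :] - 2.0 * (X @ W.T)
    return np.argmin(d, axis=1)


def _hex_positions(rows: int, cols: int) -> np.ndarray:
    """(rows*cols, 2) neuron coordinates on a hexagonal lattice."""
    pos = np.zeros((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2.0)
    return pos


@dataclass
class SomModel:
    grid_shape: tuple[int, int]
    weights: np.ndarray  # (n_neurons, n_features)
    neuron_labels: list[str]
    classes: list[str]
    iterations: int
    learning_rate: float
    initial_radius: float
    seed: int
    feature_grid: np.ndarray | None = None  # wavenumbers, for SOMDI readout

    @property
    def n_neurons(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def bmu(self, x: np.ndarray) -> int:
        d = np.sum((self.weights - x) ** 2, axis=1)
        return int(np.argmin(d))

    def predict(self, X: np.ndarray) -> tuple[list[str], int]:
        """Labels for each row of X; also returns the count of samples whose
        winning neuron was unlabelled (routed to the nearest labelled one)."""
        labels_arr = np.array(self.neuron_labels)
        labelled = labels_arr != UNASSIGNED
        if not labelled.any():
            raise ValueError("model has no labelled neurons")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        winners = _nearest_rows(X, self.weights)
        preds, rerouted = [], 0
        lab_idx = np.flatnonzero(labelled)
        for i, win in enumerate(winners):
            if labels_arr[win] == UNASSIGNED:
                rerouted += 1
                sub = _nearest_rows(X[i : i + 1], self.weights[labelled])[0]
                preds.append(str(labels_arr[lab_idx[sub]]))
            else:
                preds.append(str(labels_arr[win]))
        return preds, rerouted

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "grid_shape": list(self.grid_shape),
            "weights": self.weights.tolist(),
            "neuron_labels": self.neuron_labels,
            "classes": self.classes,
            "iterations": self.iterations,
            "learning_rate": self.learning_rate,
            "initial_radius": self.initial_radius,
            "seed": self.seed,
            "feature_grid": None if self.feature_grid is None else self.feature_grid.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SomModel":
        d = json.loads(Path(path).read_text())
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            weights=np.asarray(d["weights"], dtype=float),
            neuron_labels=list(d["neuron_labels"]),
            classes=list(d["classes"]),
            iterations=d["iterations"],
            learning_rate=d["learning_rate"],
            initial_radius=d["initial_radius"],
            seed=d["seed"],
            feature_grid=(
                None if d["feature_grid"] is None else np.asarray(d["feature_grid"], float)
            ),
        )


@dataclass
class SomdiProfile:
    classes: list[str]
    profiles: dict[str, np.ndarray]  # class -> non-negative weight per feature
    feature_grid: np.ndarray | None = None

    def top_features(self, class_label: str, k: int = 5) -> list[tuple[float, float]]:
        """(wavenumber-or-index, discriminant weight) for the k strongest
        features of a class, descending."""
        prof = self.profiles[class_label]
        order = np.argsort(prof)[::-1][:k]
        axis = self.feature_grid if self.feature_grid is not None else np.arange(prof.size)
        return [(float(axis[i]), float(prof[i])) for i in order]


@dataclass
class EvalReport:
    confusion: pd.DataFrame  # rows: true class, cols: predicted
    overall_accuracy: float  # percent
    per_class_accuracy: dict[str, float]  # percent; NaN when class absent
    rerouted: int = 0
    training_accuracy: tuple[float, float] | None = None  # (mean, sd) percent
    testing_accuracy: tuple[float, float] | None = None

    @staticmethod
    def overall_model_accuracy(training_pct: float, testing_pct: float) -> float:
        """Unweighted mean of training and testing accuracy, the model's
        single headline number, rounded half-up to two decimals."""
        return round_half_up((training_pct + testing_pct) / 2.0, 2)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_som(
    X: np.ndarray,
    labels,
    grid_shape: tuple[int, int] = (8, 8),
    iterations: int = 5000,
    learning_rate: float = 0.5,
    seed: int = 0,
    feature_grid: np.ndarray | None = None,
) -> SomModel:
    """Online Kohonen training with seeded determinism.

    Learning rate decays linearly ``learning_rate -> 0.01``; neighbourhood
    radius decays linearly from half the hex-grid diagonal to 1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("X must be 2-D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = sorted(set(str(v) for v in labels))
    for c in classes:
        if not np.any(labels == c):
            raise ValueError(f"class {c} has no samples")

    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    n_neurons = rows * cols
    pos = _hex_positions(rows, cols)
    grid_dist2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)

    # Initialise from randomly chosen training samples (with replacement).
    init_idx = rng.integers(0, X.shape[0], size=n_neurons)
    W = X[init_idx].astype(float).copy()

    r0 = max(float(np.sqrt(grid_dist2.max())) / 2.0, 1.0)
    lr_end = 0.01
    sample_idx = rng.integers(0, X.shape[0], size=iterations)
    w2 = np.einsum("ij,ij->i", W, W)
    for t in range(iterations):
        frac = t / max(iterations - 1, 1)
        lr = learning_rate + (lr_end - learning_rate) * frac
        radius = r0 + (1.0 - r0) * frac
        x = X[sample_idx[t]]
        # argmin ||w - x||^2 = argmin ||w||^2 - 2 w.x (the x term is constant)
        bmu = int(np.argmin(w2 - 2.0 * (W @ x)))
        # Gaussian neighbourhood truncated at 3 sigma for speed.
        sub = np.flatnonzero(grid_dist2[bmu] <= 9.0 * radius * radius)
        h = np.exp(-grid_dist2[bmu][sub] / (2.0 * radius * radius))
        W[sub] += (lr * h)[:, None] * (x - W[sub])
        w2[sub] = np.einsum("ij,ij->i", W[sub], W[sub])

    # Majority-class neuron labelling.
    winners = _nearest_rows(X, W)
    neuron_labels: list[str] = []
    lab_arr = np.asarray([str(v) for v in labels])
    for i in range(n_neurons):
        mapped = lab_arr[winners == i]
        if mapped.size == 0:
            neuron_labels.append(UNASSIGNED)
        else:
            vals, counts = np.unique(mapped, return_counts=True)
            neuron_labels.append(str(vals[np.argmax(counts)]))
    # Unmapped neurons whose weights coincide (to rounding) with a labelled
    # neuron inherit its label — degenerate duplicated-sample datasets
    # collapse every neuron onto the same point and all share the class.
    labelled_idx = [i for i, l in enumerate(neuron_labels) if l != UNASSIGNED]
    if labelled_idx:
        for i, l in enumerate(neuron_labels):
            if l != UNASSIGNED:
                continue
            d2 = np.sum((W[labelled_idx] - W[i]) ** 2, axis=1)
            j = int(np.argmin(d2))
            tol = 1e-18 * (1.0 + float(np.sum(W[i] ** 2)))
            if d2[j] <= tol:
                neuron_labels[i] = neuron_labels[labelled_idx[j]]

    return SomModel(
        grid_shape=grid_shape,
        weights=W,
        neuron_labels=neuron_labels,
        classes=classes,
        iterations=iterations,
        learning_rate=learning_rate,
        initial_radius=r0,
        seed=seed,
        feature_grid=None if feature_grid is None else np.asarray(feature_grid, float),
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(model: SomModel, X: np.ndarray, labels) -> EvalReport:
    """Confusion matrix and accuracies; accuracy = 100 * trace / total."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = [str(v) for v in np.asarray(labels)]
    if X.shape[1] != model.weights.shape[1]:
        raise ValueError("feature length does not match model")
    preds, rerouted = model.predict(X)
    all_classes = sorted(set(model.classes) | set(labels))
    conf = pd.DataFrame(0, index=all_classes, columns=all_classes, dtype=int)
    for t, p in zip(labels, preds):
        conf.loc[t, p] += 1
    total = conf.to_numpy().sum()
    overall = 100.0 * np.trace(conf.to_numpy()) / total
    per_class = {}
    for c in all_classes:
        row = conf.loc[c].to_numpy().sum()
        per_class[c] = 100.0 * conf.loc[c, c] / row if row > 0 else float("nan")
    return EvalReport(
        confusion=conf,
        overall_accuracy=float(overall),
        per_class_accuracy=per_class,
        rerouted=rerouted,
    )


def _stratified_split(labels: np.ndarray, train_fraction: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else idx.size
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator):
    assignment = np.zeros(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        if idx.size < folds:
            raise ValueError(f"class {c} has {idx.size} samples; fewer than {folds} folds")
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def split_and_cv(
    X: np.ndarray,
    labels,
    train_fraction: float = 0.8,
    folds: int = 10,
    repeats: int = 10,
    grid_shape: tuple[int, int] = (8, 8),
    iterations: int = 5000,
    seed: int = 0,
    feature_grid: np.ndarray | None = None,
) -> EvalReport:
    """Stratified 80/20 split with k-fold CV on the training portion, repeated
    in independent runs.

    Training accuracy is the mean cross-validation accuracy over folds;
    testing accuracy comes from the model trained on the full training
    portion applied to the held-out 20 %. The overall model accuracy is the
    unweighted mean of the two.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray([str(v) for v in np.asarray(labels)])
    rng = np.random.default_rng(seed)
    train_accs, test_accs = [], []
    per_class_acc: dict[str, list[float]] = {}
    conf_sum = None
    last_report = None
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        tr, te = _stratified_split(labels, train_fraction, rep_rng)
        fold_assign = _stratified_folds(labels[tr], folds, rep_rng)
        fold_accs = []
        for f in range(folds):
            fit = tr[fold_assign != f]
            val = tr[fold_assign == f]
            m = train_som(
                X[fit], labels[fit], grid_shape, iterations, seed=rep_seed + f + 1,
                feature_grid=feature_grid,
            )
            fold_accs.append(evaluate(m, X[val], labels[val]).overall_accuracy)
        model = train_som(
            X[tr], labels[tr], grid_shape, iterations, seed=rep_seed, feature_grid=feature_grid
        )
        last_report = evaluate(model, X[te], labels[te])
        train_accs.append(float(np.mean(fold_accs)))
        test_accs.append(last_report.overall_accuracy)
        conf_sum = (
            last_report.confusion if conf_sum is None else conf_sum + last_report.confusion
        )
        for c, v in last_report.per_class_accuracy.items():
            if np.isfinite(v):
                per_class_acc.setdefault(c, []).append(v)
    tr_mean, tr_sd = float(np.mean(train_accs)), float(np.std(train_accs, ddof=1)) if repeats > 1 else 0.0
    te_mean, te_sd = float(np.mean(test_accs)), float(np.std(test_accs, ddof=1)) if repeats > 1 else 0.0
    report = EvalReport(
        confusion=conf_sum,
        overall_accuracy=EvalReport.overall_model_accuracy(tr_mean, te_mean),
        per_class_accuracy={
            c: float(np.mean(v)) for c, v in per_class_acc.items()
        },
        rerouted=last_report.rerouted,
        training_accuracy=(tr_mean, tr_sd),
        testing_accuracy=(te_mean, te_sd),
    )
    return report


# ---------------------------------------------------------------------------
# Discriminant index
# ---------------------------------------------------------------------------


def somdi(model: SomModel) -> SomdiProfile:
    """Per-class discriminant profile from unit-normalised neuron weights."""
    labels = np.array(model.neuron_labels)
    labelled = labels != UNASSIGNED
    W = model.weights[labelled]
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = W / norms
    grand = U.mean(axis=0)
    profiles = {}
    for c in model.classes:
        mask = labels[labelled] == c
        if not mask.any():
            profiles[c] = np.zeros(model.weights.shape[1])
            continue
        profiles[c] = np.clip(U[mask].mean(axis=0) - grand, 0.0, None)
    return SomdiProfile(classes=list(model.classes), profiles=profiles,
                        feature_grid=model.feature_grid)


def subset_refit(
    X: np.ndarray,
    labels,
    excluded: list[str],
    **train_kwargs,
) -> tuple[SomModel, SomdiProfile]:
    """Drop the excluded classes, retrain and return (model, SOMDI)."""
    labels = np.asarray([str(v) for v in np.asarray(labels)])
    mask = ~np.isin(labels, list(excluded))
    remaining = set(labels[mask])
    if len(remaining) < 2:
        raise ValueError(f"only {len(remaining)} class(es) remain after exclusion")
    model = train_som(np.asarray(X, float)[mask], labels[mask], **train_kwargs)
    return model, somdi(model)
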