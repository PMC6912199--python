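"""Deep-forest classifier: multi-grained scanning plus a cascade forest.

The pair feature vector is first scanned with a sliding window (stride 1):
every window slice is classified by small "scan" forests and the resulting
class-probability vectors are concatenated into a transformed
representation, analogous to a convolutional layer.  A cascade of forest
layers follows: each layer holds four forests (two random forests and two
completely-random forests) whose class-probability outputs, produced
leak-free by internal cross-validation on the training set, augment the
input of the next layer.  Cascade growth stops when the internal
validation accuracy stops improving or the layer budget is reached.  The
final score is the mean positive-class probability of the last layer's
four forests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["DeepForestConfig", "CascadeModel", "multi_grained_scan_slices", "fit_cascade", "predict_scores"]


@dataclass(frozen=True)
class DeepForestConfig:
    window: int = 100
    n_classes: int = 2
    forests_per_layer: int = 4
    trees_per_forest: int = 100
    scan_trees: int = 30
    max_layers: int = 5
    early_stop_rounds: int = 1
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("binary classification only (n_classes = 2)")
        if self.window < 1 or self.trees_per_forest < 1 or self.max_layers < 1:
            raise ValueError("window, trees_per_forest and max_layers must be >= 1")


def multi_grained_scan_slices(X: np.ndarray, window: int) -> np.ndarray:
    """Stride-1 sliding-window slices: (n, L) -> (n, L - window + 1, window)."""
    X = np.asarray(X, dtype=float)
    L = X.shape[1]
    if L < window:
        raise ValueError(f"feature length {L} is shorter than scan window {window}")
    return np.lib.stride_tricks.sliding_window_view(X, window, axis=1).copy()


def _n_splits(y: np.ndarray, requested: int) -> int:
    """Cap the CV fold count by the minority-class size (floor of 2)."""
    smallest = int(np.bincount(y).min())
    return max(2, min(requested, smallest))


def _layer_forests(cfg: DeepForestConfig, n_trees: int, seed: int) -> list:
    """Two random forests + two completely-random forests (seeded)."""
    make_rf = lambda s: RandomForestClassifier(
        n_estimators=n_trees, random_state=s, n_jobs=1
    )
    make_crf = lambda s: ExtraTreesClassifier(
        n_estimators=n_trees, max_features=1, random_state=s, n_jobs=1
    )
    return [make_rf(seed), make_rf(seed + 1), make_crf(seed + 2), make_crf(seed + 3)]


class _Scanner:
    """Sliding-window feature transformer backed by two small forests."""

    def __init__(self, cfg: DeepForestConfig):
        self.cfg = cfg
        self.forests = [
            RandomForestClassifier(
                n_estimators=cfg.scan_trees, random_state=cfg.seed + 101, n_jobs=1
            ),
            ExtraTreesClassifier(
                n_estimators=cfg.scan_trees,
                max_features=1,
                random_state=cfg.seed + 102,
                n_jobs=1,
            ),
        ]

    def _instances(self, X: np.ndarray) -> tuple[np.ndarray, int]:
        slices = multi_grained_scan_slices(X, self.cfg.window)
        n, p, w = slices.shape
        return slices.reshape(n * p, w), p

    def fit_transform(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Fit scan forests; training output uses sample-level CV splits so
        a sample's own windows never train the forests that score it."""
        inst, p = self._instances(X)
        n = X.shape[0]
        y_inst = np.repeat(y, p)
        out = np.zeros((n, p * len(self.forests) * 2))
        skf = StratifiedKFold(
            n_splits=_n_splits(y, self.cfg.cv_folds),
            shuffle=True,
            random_state=self.cfg.seed,
        )
        for train_idx, test_idx in skf.split(X, y):
            tr_rows = (train_idx[:, None] * p + np.arange(p)).ravel()
            te_rows = (test_idx[:, None] * p + np.arange(p)).ravel()
            for fi, forest in enumerate(self.forests):
                f = clone(forest).fit(inst[tr_rows], y_inst[tr_rows])
                proba = f.predict_proba(inst[te_rows])
                block = proba.reshape(len(test_idx), p * 2)
                out[test_idx, fi * p * 2 : (fi + 1) * p * 2] = block
        for forest in self.forests:
            forest.fit(inst, y_inst)
        return out

    def transform(self, X: np.ndarray) -> np.ndarray:
        inst, p = self._instances(X)
        n = X.shape[0]
        blocks = [
            forest.predict_proba(inst).reshape(n, p * 2) for forest in self.forests
        ]
        return np.hstack(blocks)


@dataclass
class CascadeModel:
    scanner: _Scanner
    layers: list[list]  # fitted 4-forest layers
    cfg: DeepForestConfig
    n_features_in: int
    val_accuracies: list[float]

    @property
    def n_layers_used(self) -> int:
        return len(self.layers)


def _cv_proba(forest, X: np.ndarray, y: np.ndarray, cfg: DeepForestConfig, seed: int) -> np.ndarray:
    """Out-of-fold positive/negative probability matrix for the training set."""
    out = np.zeros((len(y), 2))
    skf = StratifiedKFold(n_splits=_n_splits(y, cfg.cv_folds), shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        f = clone(forest).fit(X[tr], y[tr])
        out[te] = f.predict_proba(X[te])
    return out


def fit_cascade(X: np.ndarray, y: np.ndarray, cfg: DeepForestConfig) -> CascadeModel:
    """Fit scanning + cascade layers with early stopping on internal CV accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0] or X.shape[0] < 10:
        raise ValueError("need matching X/y with at least 10 samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    scanner = _Scanner(cfg)
    scan_train = scanner.fit_transform(X, y)

    layers: list[list] = []
    val_accs: list[float] = []
    best_acc, best_len, stall = -np.inf, 0, 0
    aug = np.empty((X.shape[0], 0))
    for depth in range(cfg.max_layers):
        layer_in = np.hstack([scan_train, aug])
        forests = _layer_forests(cfg, cfg.trees_per_forest, cfg.seed + 10 * depth)
        probas = [
            _cv_proba(f, layer_in, y, cfg, cfg.seed + 10 * depth + fi)
            for fi, f in enumerate(forests)
        ]
        for f in forests:
            f.fit(layer_in, y)
        layers.append(forests)
        mean_proba = np.mean(probas, axis=0)
        acc = float(np.mean(mean_proba.argmax(axis=1) == y))
        val_accs.append(acc)
        if acc > best_acc + 1e-12:
            best_acc, best_len, stall = acc, depth + 1, 0
        else:
            stall += 1
            if stall >= cfg.early_stop_rounds:
                break
        aug = np.hstack(probas)
    layers = layers[:best_len]
    val_accs = val_accs[:best_len]
    return CascadeModel(scanner, layers, cfg, X.shape[1], val_accs)


def predict_scores(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability: mean over the last layer's four forests."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"feature width {X.shape[1]} != training width {model.n_features_in}"
        )
    scan = model.scanner.transform(X)
    aug = np.empty((X.shape[0], 0))
    probas: list[np.ndarray] = []
    for forests in model.layers:
        layer_in = np.hstack([scan, aug])
        probas = [f.predict_proba(layer_in) for f in forests]
        aug = np.hstack(probas)
    return np.mean(probas, axis=0)[:, 1]
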