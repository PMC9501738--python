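"""The three discriminant models behind one train/predict contract.

* PLS-DA: partial least squares regression onto one-hot class indicators,
  argmax decision, with leave-one-out selection of the component count.
* RBF-SVM: Gaussian-kernel support vector machine; penalty c and kernel
  width g chosen by exhaustive grid search scored with stratified inner
  cross-validation.
* 1D CNN: a five-block VGG-style network over the spectrum (conv pairs of
  16/32/64/128/128 filters, kernel 3, batch norm, ELU, max-pool 2; a dense
  + dropout head), trained with Adam under an inverse-time learning-rate
  decay eta0/(1 + k*t).

All models standardize per band with statistics learned from the training
rows only, and predict integer class labels in [0, K).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import nn
from .nn import elu, softmax, cross_entropy_loss, lr_schedule

__all__ = [
    "SplitIndices",
    "Standardizer",
    "CnnSpec",
    "TrainedClassifier",
    "TrainingDivergenceError",
    "stratified_split",
    "standardize_fit",
    "standardize_apply",
    "train_plsda",
    "loo_cv",
    "train_svm_rbf",
    "build_cnn",
    "train_cnn",
    "fit_cnn",
    "elu",
    "softmax",
    "cross_entropy_loss",
    "lr_schedule",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the CNN loss becomes non-finite; carries the epoch."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss diverged (NaN/inf) at epoch {epoch}")
        self.epoch = epoch


# ---------------------------------------------------------------------------
# splitting and standardization

@dataclass
class SplitIndices:
    train_rows: np.ndarray
    test_rows: np.ndarray
    seed: int


def stratified_split(labels, ratio: tuple[int, int] = (4, 1), seed: int = 0) -> SplitIndices:
    """Per-class random train/test partition at ``ratio`` (default 4:1).

    When a class size is divisible by the ratio total the split is exact;
    otherwise the test share is rounded, keeping at least one row on each
    side. Deterministic in ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    tr_part, te_part = ratio
    total = tr_part + te_part
    rng = np.random.default_rng(seed)
    train, test = [], []
    for k in np.unique(labels):
        rows = np.flatnonzero(labels == k)
        n = len(rows)
        if n < total:
            raise ValueError(
                f"class {k} has {n} samples, fewer than the {tr_part}:{te_part} "
                f"ratio requires ({total})"
            )
        n_test = int(round(n * te_part / total))
        n_test = min(max(n_test, 1), n - 1)
        perm = rng.permutation(rows)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return SplitIndices(
        train_rows=np.sort(np.concatenate(train)),
        test_rows=np.sort(np.concatenate(test)),
        seed=seed,
    )


@dataclass
class Standardizer:
    """Per-band mean/sd learned from training rows; constant bands get sd 1."""

    mean: np.ndarray
    sd: np.ndarray
    constant_bands: list[int] = field(default_factory=list)


def standardize_fit(X_train: np.ndarray) -> Standardizer:
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    constant = np.flatnonzero(sd == 0).tolist()
    sd = np.where(sd == 0, 1.0, sd)
    return Standardizer(mean=mean, sd=sd, constant_bands=constant)


def standardize_apply(std: Standardizer, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - std.mean) / std.sd


# ---------------------------------------------------------------------------
# the uniform trained-model contract

@dataclass
class TrainedClassifier:
    kind: str                     # plsda | svm_rbf | cnn
    model: object
    standardizer: Standardizer | None
    n_classes: int
    hyperparams: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return standardize_apply(self.standardizer, X) if self.standardizer else X

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._prepare(X)
        if self.kind == "plsda":
            return np.argmax(self.model.predict(Xs), axis=1)
        if self.kind == "svm_rbf":
            return self.model.predict(Xs)
        if self.kind == "cnn":
            logits = self.model.forward(Xs[:, None, :], train=False)
            return np.argmax(logits, axis=1)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.kind != "cnn":
            raise NotImplementedError(f"{self.kind} does not expose probabilities")
        Xs = self._prepare(X)
        logits = self.model.forward(Xs[:, None, :], train=False)
        return softmax(logits, axis=1)


# ---------------------------------------------------------------------------
# PLS-DA

def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int, n_classes: int):
    Y = np.eye(n_classes)[y]
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    return pls


def loo_cv(train_fn, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy: ``train_fn(X_rest, y_rest)`` must return an
    object with ``predict``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 rows")
    correct = 0
    for i in range(n):
        keep = np.arange(n) != i
        model = train_fn(X[keep], y[keep])
        correct += int(model.predict(X[i:i + 1])[0] == y[i])
    return correct / n


def train_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "auto",
    max_components: int = 15,
    standardize: bool = True,
) -> TrainedClassifier:
    """PLS regression onto one-hot responses; class = argmax of prediction.

    ``n_components="auto"`` picks the count maximizing leave-one-out
    accuracy over 1..max grid, smallest on ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    K = int(classes.max()) + 1

    std = standardize_fit(X) if standardize else None
    Xs = standardize_apply(std, X) if std else X

    cap = min(X.shape[0] - 1, X.shape[1])
    history: dict = {}
    if n_components == "auto":
        grid = range(1, min(max_components, cap) + 1)
        accs = {}
        for m in grid:
            def fit_m(Xi, yi, m=m):
                pls = _fit_pls(Xi, yi, m, K)
                return _PlsPredictor(pls)
            accs[m] = loo_cv(fit_m, Xs, y)
        best = max(accs, key=lambda m: (accs[m], -m))  # smallest on ties
        n_components = best
        history["loo_accuracy"] = accs
    else:
        n_components = int(n_components)
        if not 1 <= n_components <= cap:
            raise ValueError(f"n_components must be in [1, {cap}]")

    pls = _fit_pls(Xs, y, n_components, K)
    return TrainedClassifier(
        kind="plsda", model=pls, standardizer=std, n_classes=K,
        hyperparams={"n_components": n_components}, history=history,
    )


class _PlsPredictor:
    def __init__(self, pls):
        self.pls = pls

    def predict(self, X):
        return np.argmax(self.pls.predict(X), axis=1)


# ---------------------------------------------------------------------------
# RBF-SVM

DEFAULT_C_GRID = tuple(float(c) for c in np.logspace(-1, 3, 5))
DEFAULT_G_GRID = tuple(float(g) for g in np.logspace(-4, 0, 5))


def train_svm_rbf(
    X: np.ndarray,
    y: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_G_GRID,
    inner_cv_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> TrainedClassifier:
    """Exhaustive (c, g) grid search scored by stratified inner CV on the
    training rows; ties resolved toward the smallest c, then smallest g."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    c_grid = sorted(float(c) for c in c_grid)
    g_grid = sorted(float(g) for g in g_grid)
    if not c_grid or not g_grid or min(c_grid) <= 0 or min(g_grid) <= 0:
        raise ValueError("grids must be nonempty and positive")
    if X.shape[0] < inner_cv_folds:
        raise ValueError(
            f"{X.shape[0]} rows is fewer than {inner_cv_folds} inner CV folds"
        )

    std = standardize_fit(X) if standardize else None
    Xs = standardize_apply(std, X) if std else X

    min_class = np.bincount(y).min() if len(np.unique(y)) else 0
    folds = min(inner_cv_folds, int(min_class)) if min_class >= 2 else 0
    scores: dict[tuple[float, float], float] = {}
    best_pair, best_score = None, -np.inf
    for c, g in itertools.product(c_grid, g_grid):
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            accs = []
            for tr, va in cv.split(Xs, y):
                clf = SVC(kernel="rbf", C=c, gamma=g).fit(Xs[tr], y[tr])
                accs.append(np.mean(clf.predict(Xs[va]) == y[va]))
            score = float(np.mean(accs))
        else:  # degenerate tiny data: resubstitution score
            clf = SVC(kernel="rbf", C=c, gamma=g).fit(Xs, y)
            score = float(np.mean(clf.predict(Xs) == y))
        scores[(c, g)] = score
        if score > best_score:  # strict: earlier (smaller c, g) wins ties
            best_score, best_pair = score, (c, g)

    c, g = best_pair
    final = SVC(kernel="rbf", C=c, gamma=g).fit(Xs, y)
    K = int(y.max()) + 1
    return TrainedClassifier(
        kind="svm_rbf", model=final, standardizer=std, n_classes=K,
        hyperparams={"c": c, "g": g},
        history={"grid_scores": scores, "cv_folds": folds},
    )


# ---------------------------------------------------------------------------
# 1D CNN

@dataclass
class CnnSpec:
    """Architecture and training recipe of the VGG-style spectral network."""

    n_blocks: int = 5
    convs_per_block: int = 2
    filters: tuple[int, ...] = (16, 32, 64, 128, 128)
    kernel: int = 3
    pool: int = 2
    alpha: float = 1.0          # ELU saturation
    fc_width: int = 256
    dropout_p: float = 0.5
    n_classes: int = 12
    epochs: int = 800
    batch_size: int = 256
    eta0: float = 0.0005
    k_decay: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if len(self.filters) != self.n_blocks:
            raise ValueError("one filter count per block required")
        if min(self.filters) <= 0 or any(np.diff(self.filters) < 0):
            raise ValueError("filters must be positive and non-decreasing")


def pooled_lengths(n_bands: int, n_blocks: int = 5, pool: int = 2) -> list[int]:
    """Spectrum length after each pooling stage (floor division chain)."""
    lengths, L = [], n_bands
    for _ in range(n_blocks):
        L //= pool
        lengths.append(L)
    return lengths


def build_cnn(spec: CnnSpec, n_bands: int) -> nn.Sequential:
    """Untrained network: five [conv-BN-ELU]x2 + max-pool blocks, then
    flatten -> dense -> ELU -> dropout -> dense(K). He-initialized from
    ``spec.seed``."""
    lengths = pooled_lengths(n_bands, spec.n_blocks, spec.pool)
    if lengths[-1] < 1:
        raise ValueError(
            f"spectrum of {n_bands} bands is too short for "
            f"{spec.n_blocks} pooling halvings"
        )
    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for f in spec.filters:
        for _ in range(spec.convs_per_block):
            layers += [
                nn.Conv1d(c_in, f, kernel=spec.kernel, pad=spec.kernel // 2, rng=rng),
                nn.BatchNorm1d(f),
                nn.Elu(spec.alpha),
            ]
            c_in = f
        layers.append(nn.MaxPool1d())
    layers += [
        nn.Flatten(),
        nn.Dense(spec.filters[-1] * lengths[-1], spec.fc_width, rng=rng),
        nn.Elu(spec.alpha),
        nn.Dropout(spec.dropout_p, rng=np.random.default_rng((spec.seed, 1))),
        nn.Dense(spec.fc_width, spec.n_classes, rng=rng),
    ]
    # zero classification head: the untrained network predicts the uniform
    # distribution, so the starting loss is ln K regardless of spectrum scale
    layers[-1].W[...] = 0.0
    return nn.Sequential(layers)


def train_cnn(
    model: nn.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    spec: CnnSpec,
    epochs: int | None = None,
    standardizer: Standardizer | None = None,
) -> TrainedClassifier:
    """Mini-batch Adam on softmax cross-entropy with the inverse-time
    learning-rate decay; ``X`` must already be standardized.

    Records per-epoch mean training loss and restores the parameters of the
    epoch with the best loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    epochs = spec.epochs if epochs is None else epochs
    K = spec.n_classes
    onehot = np.eye(K)
    n = len(y)
    rng = np.random.default_rng((spec.seed, 2))
    opt = nn.Adam(model.params())

    losses = []
    best_loss, best_state = np.inf, None
    for epoch in range(epochs):
        lr = lr_schedule(epoch, spec.eta0, spec.k_decay)
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, spec.batch_size):
            rows = order[start:start + spec.batch_size]
            logits = model.forward(X[rows][:, None, :], train=True)
            if not np.all(np.isfinite(logits)):
                raise TrainingDivergenceError(epoch)
            p = softmax(logits, axis=1)
            labels = onehot[y[rows]]
            loss = cross_entropy_loss(p, labels)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            model.backward((p - labels) / len(rows))
            opt.step(model.grads(), lr)
            batch_losses.append(loss)
        epoch_loss = float(np.mean(batch_losses))
        losses.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss, best_state = epoch_loss, model.state()
    if best_state is not None:
        model.load_state(best_state)

    return TrainedClassifier(
        kind="cnn", model=model, standardizer=standardizer, n_classes=K,
        hyperparams={"epochs": epochs, "eta0": spec.eta0, "k_decay": spec.k_decay,
                     "batch_size": spec.batch_size},
        history={"epoch_loss": losses, "best_loss": best_loss},
    )


def fit_cnn(
    X: np.ndarray,
    y: np.ndarray,
    spec: CnnSpec | None = None,
    epochs: int | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Convenience wrapper: standardize, build, train; returns the trained
    classifier carrying its standardizer."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    K = int(y.max()) + 1
    if spec is None:
        spec = CnnSpec(n_classes=K, seed=seed)
    elif spec.n_classes != K:
        spec = replace(spec, n_classes=K)
    std = standardize_fit(X)
    Xs = standardize_apply(std, X)
    model = build_cnn(spec, X.shape[1])
    return train_cnn(model, Xs, y, spec, epochs=epochs, standardizer=std)
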