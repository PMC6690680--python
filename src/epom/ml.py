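"""From-scratch multilayer-perceptron classifiers for ischemia grading.

Three networks mirror the study design:

* ``ann1`` — one multi-class network mapping the six pseudo-ECG biomarker
  magnitudes to one-hot (control, mild, severe) outputs;
* ``ann21`` — binary detector, control vs ischemic, on magnitudes;
* ``ann22`` — binary severity grader, mild vs severe, on the six ratios
  of change.

All are fully-connected perceptrons with rectified-linear hidden units and
sigmoid outputs, trained by full-batch gradient descent on binary
cross-entropy (summed over output units, averaged over examples) with an
L2 weight-decay penalty.  Model selection follows the protocol: a 75/25
train/evaluation split, 10-fold cross-validation on the training split,
selection by mean validation F1, and the best fold's weights carried to
the evaluation set.  Feature attribution uses the Garson weight-magnitude
scheme extended to deep stacks by column-normalizing each layer's absolute
weight matrix and propagating the products.

scikit-learn appears only as the regularized logistic-regression baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell_model import InvalidParameterError


class TrainingError(RuntimeError):
    """Training diverged (non-finite cost); try a smaller learning rate."""


class UndefinedMetricError(RuntimeError):
    """A class required by the metric is absent from the split."""


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Feature matrix with frozen split/fold structure and normalization.

    Normalization statistics are fitted on the training split only; the
    evaluation split never influences them.
    """

    x: np.ndarray
    y: np.ndarray  # integer class labels
    feature_names: tuple
    class_names: tuple
    train_idx: np.ndarray
    eval_idx: np.ndarray
    folds: list  # list of (train_rows, val_rows) into train_idx order
    mean: np.ndarray
    std: np.ndarray

    @property
    def xn(self) -> np.ndarray:
        return (self.x - self.mean) / self.std

    def split(self, which: str):
        idx = self.train_idx if which == "train" else self.eval_idx
        return self.xn[idx], self.y[idx]


def stratified_folds(indices, labels, n_folds: int) -> list:
    """Deal each class round-robin into folds so every validation fold
    contains every class; returns (train_rows, val_rows) index pairs."""
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    assign = np.empty(indices.size, dtype=int)
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        assign[rows] = np.arange(rows.size) % n_folds
    folds = []
    for k in range(n_folds):
        folds.append((indices[assign != k], indices[assign == k]))
    return folds


def make_dataset(x, y, *, feature_names=None, class_names=None, seed=0,
                 eval_frac=0.25, n_folds=10) -> Dataset:
    """Stratified 75/25 split plus seeded 10-fold assignment on the train set."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise InvalidParameterError("feature matrix and labels are inconsistent")
    rng = np.random.default_rng(seed)
    train_parts, eval_parts = [], []
    for c in np.unique(y):
        rows = np.flatnonzero(y == c)
        rows = rng.permutation(rows)
        n_eval = int(round(eval_frac * rows.size))
        eval_parts.append(rows[:n_eval])
        train_parts.append(rows[n_eval:])
    train_idx = rng.permutation(np.concatenate(train_parts))
    eval_idx = np.sort(np.concatenate(eval_parts))
    folds = stratified_folds(train_idx, y[train_idx], n_folds)

    mean = x[train_idx].mean(axis=0)
    std = x[train_idx].std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return Dataset(
        x=x, y=y,
        feature_names=tuple(feature_names or [f"f{i}" for i in range(x.shape[1])]),
        class_names=tuple(class_names or [str(c) for c in np.unique(y)]),
        train_idx=train_idx, eval_idx=eval_idx, folds=folds, mean=mean, std=std,
    )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPSpec:
    n_inputs: int
    hidden_layers: int
    hidden_units: int
    n_outputs: int = 1
    learning_rate: float = 0.1
    weight_decay: float = 1e-4
    epochs: int = 20000
    seed: int = 0
    plateau_rel: float = 1e-8  # early stop when the relative cost change
    plateau_window: int = 500  # over this many epochs falls below plateau_rel

    def __post_init__(self):
        if self.hidden_layers < 1 or self.hidden_units < 1:
            raise InvalidParameterError("need at least one hidden layer and unit")

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum((sizes[i] + 1) * sizes[i + 1] for i in range(len(sizes) - 1))

    @property
    def layer_sizes(self) -> tuple:
        return (self.n_inputs, *([self.hidden_units] * self.hidden_layers),
                self.n_outputs)


@dataclass
class TrainedModel:
    weights: list  # per layer, (n_in, n_out)
    biases: list  # per layer, (n_out,)
    spec: MLPSpec
    history: np.ndarray = field(default_factory=lambda: np.empty(0))
    fold: int | None = None


def init_model(spec: MLPSpec, rng=None) -> TrainedModel:
    """Random small initial weights, Glorot-scaled uniform, zero biases.

    A fixed small range such as [-0.1, 0.1] collapses the forward signal
    through four to six narrow ReLU layers (per-layer gain well below 1),
    leaving the network stuck at the class prior; fan-scaled initialization
    keeps the stack trainable at the study's depths while remaining
    "random small values".
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for i in range(len(sizes) - 1):
        r = np.sqrt(6.0 / (sizes[i] + sizes[i + 1]))
        weights.append(rng.uniform(-r, r, size=(sizes[i], sizes[i + 1])))
        biases.append(np.zeros(sizes[i + 1]))
    return TrainedModel(weights=weights, biases=biases, spec=spec)


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                    np.exp(z) / (1.0 + np.exp(z)))


def forward(model: TrainedModel, x: np.ndarray, return_hidden: bool = False):
    """Propagate examples through the network (affine + ReLU, sigmoid out)."""
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != model.weights[0].shape[0]:
        raise InvalidParameterError(
            f"feature width {a.shape[1]} does not match network input "
            f"{model.weights[0].shape[0]}"
        )
    activations = [a]
    n_layers = len(model.weights)
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        a = _sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0)
        activations.append(a)
    return activations if return_hidden else a


def cost_and_gradients(model: TrainedModel, x, y, weight_decay: float):
    """Regularized binary cross-entropy and its exact gradients.

    Cost = mean over examples of the BCE summed over output units, plus
    weight_decay * sum of squared weights (biases unpenalized).  Gradients
    by back-propagation through the ReLU stack; with the sigmoid output
    the output-layer delta is simply (p - y) / n.
    """
    acts = forward(model, x, return_hidden=True)
    p = acts[-1]
    y = np.atleast_2d(y)
    n = p.shape[0]
    eps = 1e-12
    bce = -np.sum(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)) / n
    reg = weight_decay * sum(float(np.sum(w * w)) for w in model.weights)
    cost = bce + reg

    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.weights)
    delta = (p - y) / n
    for i in range(len(model.weights) - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta + 2.0 * weight_decay * model.weights[i]
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0.0)
    return cost, grads_w, grads_b


def train(x, y, spec: MLPSpec, rng=None) -> TrainedModel:
    """Full-batch gradient descent at a fixed learning rate.

    Deterministic for a given seed; stops early when the smoothed cost
    plateaus.  Raises :class:`TrainingError` on divergence.
    """
    model = init_model(spec, rng)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.ndim == 2 and y.shape[0] == 1 and np.asarray(x).shape[0] != 1:
        y = y.T
    history = np.empty(spec.epochs)
    window_cost = None
    n_epochs = 0
    for epoch in range(spec.epochs):
        cost, gw, gb = cost_and_gradients(model, x, y, spec.weight_decay)
        if not np.isfinite(cost):
            raise TrainingError(
                f"cost diverged at epoch {epoch}; try a smaller learning rate"
            )
        history[epoch] = cost
        n_epochs = epoch + 1
        for i in range(len(model.weights)):
            model.weights[i] -= spec.learning_rate * gw[i]
            model.biases[i] -= spec.learning_rate * gb[i]
        if (epoch + 1) % spec.plateau_window == 0:
            c = history[epoch - spec.plateau_window + 1:epoch + 1].mean()
            if window_cost is not None and abs(window_cost - c) <= spec.plateau_rel * abs(window_cost):
                break
            window_cost = c
    model.history = history[:n_epochs]
    return model


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalMetrics:
    se: float  # sensitivity, %
    ppv: float  # positive predictive value, %
    f1: float  # harmonic mean of Se and PPV, %
    confusion: np.ndarray  # (true, predicted)

    def as_dict(self) -> dict:
        return {"se": self.se, "ppv": self.ppv, "f1": self.f1}


def metrics_from_counts(tp: float, fp: float, fn: float) -> tuple:
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else np.nan
    f1 = 2.0 * se * ppv / (se + ppv) if se + ppv > 0 else 0.0
    return se, ppv, f1


def evaluate_predictions(y_true, y_pred, n_classes: int) -> EvalMetrics:
    """Se/PPV/F1 from hard labels; macro-averaged over classes when
    multi-class (binary: class 1 is the positive class)."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    if n_classes == 2:
        if conf[1].sum() == 0:
            raise UndefinedMetricError("positive class absent from the split")
        se, ppv, f1 = metrics_from_counts(
            conf[1, 1], conf[0, 1], conf[1, 0]
        )
    else:
        ses, ppvs = [], []
        for c in range(n_classes):
            if conf[c].sum() == 0:
                raise UndefinedMetricError(f"class {c} absent from the split")
            tp = conf[c, c]
            se_c, ppv_c, _ = metrics_from_counts(
                tp, conf[:, c].sum() - tp, conf[c].sum() - tp
            )
            ses.append(se_c)
            ppvs.append(ppv_c)
        se, ppv = float(np.mean(ses)), float(np.mean(ppvs))
        f1 = 2.0 * se * ppv / (se + ppv) if se + ppv > 0 else 0.0
    return EvalMetrics(se=float(se), ppv=float(ppv), f1=float(f1), confusion=conf)


def predict_labels(model: TrainedModel, x) -> np.ndarray:
    p = forward(model, x)
    if p.shape[1] == 1:
        return (p.ravel() >= 0.5).astype(int)
    return np.argmax(p, axis=1)


def evaluate(model: TrainedModel, x, y_true, n_classes: int | None = None) -> EvalMetrics:
    n_classes = n_classes or max(2, model.weights[-1].shape[1])
    return evaluate_predictions(y_true, predict_labels(model, x), n_classes)


# ---------------------------------------------------------------------------
# cross-validation and selection
# ---------------------------------------------------------------------------

def _targets(y, n_outputs):
    y = np.asarray(y, dtype=int)
    if n_outputs == 1:
        return y.reshape(-1, 1).astype(float)
    return np.eye(n_outputs)[y]


def cross_validate(dataset: Dataset, spec: MLPSpec) -> dict:
    """10-fold CV of one architecture on the training split.

    Weights are re-initialized per fold (seeded by spec.seed + fold).
    Returns per-fold models and validation F1, and their mean.
    """
    xn = dataset.xn
    n_classes = len(dataset.class_names)
    fold_models, fold_f1 = [], []
    for k, (tr, va) in enumerate(dataset.folds):
        fold_spec = replace(spec, seed=spec.seed + k)
        model = train(xn[tr], _targets(dataset.y[tr], spec.n_outputs), fold_spec)
        model.fold = k
        try:
            f1 = evaluate(model, xn[va], dataset.y[va], n_classes).f1
        except UndefinedMetricError:
            # a class can be absent from a fold of a very small dataset;
            # such folds carry no validation information
            f1 = np.nan
        fold_models.append(model)
        fold_f1.append(f1)
    fold_f1 = np.array(fold_f1)
    if np.all(np.isnan(fold_f1)):
        raise UndefinedMetricError("no fold contained every class")
    return {
        "spec": spec,
        "fold_models": fold_models,
        "fold_f1": fold_f1,
        "mean_f1": float(np.nanmean(fold_f1)),
    }


def cross_validate_and_select(dataset: Dataset, spec_grid,
                              refit: str = "auto") -> dict:
    """Grid search by 10-fold CV, then carry one model to evaluation.

    Selection criterion is mean validation F1 across folds; ties break
    toward fewer parameters.  The carried weights are, by default, the
    full-training-split refit of the selected architecture — unless the
    refit fails to match the best fold's F1 on the training split, in
    which case the best fold's weights are kept (``refit="auto"``; the
    guard catches refits that diverge at the larger batch).
    ``refit="never"`` always carries the best fold; ``"always"`` always
    carries the refit.  No evaluation example influences the choice.
    """
    spec_grid = list(spec_grid)
    if not spec_grid:
        raise InvalidParameterError("empty architecture grid")
    report = [cross_validate(dataset, spec) for spec in spec_grid]
    best = max(report, key=lambda r: (r["mean_f1"], -r["spec"].n_parameters))
    best_fold = int(np.nanargmax(best["fold_f1"]))
    model = best["fold_models"][best_fold]

    n_classes = len(dataset.class_names)
    if refit in ("auto", "always"):
        x_tr, y_tr = dataset.split("train")
        refit_model = train(x_tr, _targets(y_tr, best["spec"].n_outputs),
                            best["spec"])
        if refit == "always":
            model = refit_model
        else:
            def train_f1(m):
                try:
                    return evaluate(m, x_tr, y_tr, n_classes).f1
                except UndefinedMetricError:
                    return -1.0
            if train_f1(refit_model) >= train_f1(model):
                model = refit_model
    elif refit != "never":
        raise InvalidParameterError(f"unknown refit policy {refit!r}")

    x_eval, y_eval = dataset.split("eval")
    metrics = evaluate(model, x_eval, y_eval, n_classes)
    return {"model": model, "metrics": metrics, "grid": report,
            "selected_spec": best["spec"], "selected_fold": best_fold}


def default_grid(n_inputs, n_outputs, learning_rate, *, hl_range=range(1, 7),
                 hu_range=range(2, 11), **kwargs):
    """The architecture grid: 1-6 hidden layers, 2-10 units per layer."""
    return [
        MLPSpec(n_inputs=n_inputs, hidden_layers=hl, hidden_units=hu,
                n_outputs=n_outputs, learning_rate=learning_rate, **kwargs)
        for hl in hl_range for hu in hu_range
    ]


# ---------------------------------------------------------------------------
# feature importance and baseline
# ---------------------------------------------------------------------------

def garson_importance(model: TrainedModel) -> np.ndarray:
    """Relative input importance from absolute weight magnitudes.

    Each layer's |W| is normalized per receiving neuron (columns sum to
    one), the normalized matrices are multiplied through the stack, rows
    are summed over outputs and renormalized.  For a single hidden layer
    this reduces to the classic tableau; the result is nonnegative and
    sums to one.
    """
    prod = None
    for w in model.weights:
        a = np.abs(w)
        col = a.sum(axis=0)
        col = np.where(col == 0.0, 1.0, col)
        a = a / col
        prod = a if prod is None else prod @ a
    imp = prod.sum(axis=1)
    total = imp.sum()
    if total == 0.0:
        return np.full(imp.size, 1.0 / imp.size)
    return imp / total


def logistic_baseline(dataset: Dataset, seed: int = 0) -> dict:
    """Regularized logistic regression on the same splits and scaling."""
    from sklearn.linear_model import LogisticRegression

    x_tr, y_tr = dataset.split("train")
    x_ev, y_ev = dataset.split("eval")
    clf = LogisticRegression(max_iter=5000, random_state=seed)
    clf.fit(x_tr, y_tr)
    y_hat = clf.predict(x_ev)
    metrics = evaluate_predictions(y_ev, y_hat, len(dataset.class_names))
    return {"model": clf, "metrics": metrics, "predictions": y_hat}


def cascade_predict(ann21: TrainedModel, ann22: TrainedModel,
                    x_mag, x_ratio) -> np.ndarray:
    """Two-stage prediction: detect ischemia on magnitudes, then grade
    severity on ratios.  Labels: 0 control, 1 mild, 2 severe."""
    det = predict_labels(ann21, x_mag)
    sev = predict_labels(ann22, x_ratio)
    return np.where(det == 0, 0, 1 + sev)
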