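"""CO2-free recognition of cycle types with a multilayer perceptron.

A two-hidden-layer MLP (sigmoid hidden activations, softmax output) is
trained on the 16 standardized predictors — every per-cycle parameter
except the inspired CO2 volume, which a ventilator without a capnometer
cannot measure — and evaluated by tenfold cross-validation: the table is
split at random into 10 near-equal folds; for each fold a model is fit on
the other nine (standardization fitted on the training portion only, and
30 % of the training rows held out as the early-stopping set) and scored
on the held-out fold.  ROC/AUC per class is computed by the pooling
strategy: held-out class scores are concatenated across folds and a
single empirical ROC is traced per class (one-vs-rest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, recall_score, roc_curve, auc as _sk_auc
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateDataError, InvalidParameterError

#: the predictor the classifier must never see: it is the quantity whose
#: measurement the classifier is meant to replace
FORBIDDEN_PREDICTOR = "insp_co2_volume"


@dataclass
class MlpConfig:
    """Architecture and training settings of the cycle-type MLP.

    ``hidden_layers="auto"`` sizes the two hidden layers as
    ``(min(64, 4*n_predictors), ceil(of that /2))``.  ``stop_fraction`` is
    the share of each training fold held out to define the early-stopping
    condition.
    """

    hidden_layers: tuple[int, int] | str = "auto"
    stop_fraction: float = 0.30
    max_epochs: int = 500
    patience: int = 20
    learning_rate_init: float = 1e-2
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.hidden_layers != "auto":
            if len(self.hidden_layers) != 2:
                raise InvalidParameterError("exactly two hidden layers required")
            if any(h < 1 for h in self.hidden_layers):
                raise InvalidParameterError("hidden layer sizes must be >= 1")
        if not 0 < self.stop_fraction < 1:
            raise InvalidParameterError("stop_fraction must be in (0, 1)")

    def resolve_hidden(self, n_predictors: int) -> tuple[int, int]:
        if self.hidden_layers != "auto":
            return tuple(self.hidden_layers)
        h1 = min(64, 4 * n_predictors)
        return h1, math.ceil(h1 / 2)


@dataclass
class CvResult:
    """Tenfold cross-validation metrics (fractions in [0, 1])."""

    fold_accuracy: np.ndarray
    sensitivity: dict[str, np.ndarray]   # class -> per-fold recall
    precision: dict[str, np.ndarray]     # class -> per-fold precision
    auc: dict[str, tuple[float, float, float]]  # class -> (auc, lo, hi)
    classes: list
    fold_sizes: list[int]

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    def quality_frame(self) -> pd.DataFrame:
        """Min/mean/max of accuracy, per-class sensitivity and precision, %."""
        rows = [{"measure": "accuracy",
                 "min": 100 * self.fold_accuracy.min(),
                 "mean": 100 * self.fold_accuracy.mean(),
                 "max": 100 * self.fold_accuracy.max()}]
        for kind, table in (("sensitivity", self.sensitivity),
                            ("precision", self.precision)):
            for cls in self.classes:
                v = table[cls]
                rows.append({"measure": f"{kind} for type {cls}",
                             "min": 100 * v.min(), "mean": 100 * v.mean(),
                             "max": 100 * v.max()})
        return pd.DataFrame(rows)

    def auc_frame(self) -> pd.DataFrame:
        rows = [{"type": cls, "auc": a, "ci_low": lo, "ci_high": hi}
                for cls, (a, lo, hi) in self.auc.items()]
        return pd.DataFrame(rows)


def _fit_mlp(config: MlpConfig, x_train: np.ndarray, y_train: np.ndarray,
             seed: int) -> MLPClassifier:
    """Fit the two-hidden-layer MLP with early stopping on validation loss.

    ``stop_fraction`` of the training rows (seeded random split) is held
    out; after each epoch the cross-entropy on that split is evaluated,
    and training stops once it has not improved for ``patience`` epochs.
    The weights of the best-validation-loss epoch are restored.  Stopping
    on the validation *loss* (rather than accuracy) keeps training the
    class probabilities after the 0/1 decisions have stabilized, which is
    what makes pooled ROC scores comparable across folds.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.metrics import log_loss

    rng = np.random.default_rng(seed)
    n = len(y_train)
    idx = rng.permutation(n)
    n_val = max(1, int(round(config.stop_fraction * n)))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    x_tr, y_tr = x_train[tr_idx], y_train[tr_idx]
    x_val, y_val = x_train[val_idx], y_train[val_idx]

    model = MLPClassifier(
        hidden_layer_sizes=config.resolve_hidden(x_train.shape[1]),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate_init,
        max_iter=1,
        warm_start=True,
        early_stopping=False,
        random_state=seed,
    )
    best_loss = np.inf
    best_weights = None
    stale = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(config.max_epochs):
            model.fit(x_tr, y_tr)
            loss = log_loss(y_val, model.predict_proba(x_val),
                            labels=model.classes_)
            if loss < best_loss - 1e-7:
                best_loss = loss
                best_weights = ([w.copy() for w in model.coefs_],
                                [b.copy() for b in model.intercepts_])
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_weights is not None:
        model.coefs_, model.intercepts_ = best_weights
    return model


def run_cv(table: pd.DataFrame, predictors: Sequence[str],
           config: MlpConfig | None = None, label_col: str = "cycle_type",
           n_folds: int = 10) -> CvResult:
    """Tenfold cross-validation of the MLP on a labeled feature table.

    ``predictors`` must exclude the inspired CO2 volume.  Folds are simple
    random equal splits (seeded); set ``config.stratified`` for stratified
    folds instead.  Standardization is fitted on each training portion
    only.  Per-fold accuracy, per-class sensitivity/precision and pooled
    per-class AUC (Hanley–McNeil 95 % CI) are returned.
    """
    config = config or MlpConfig()
    predictors = list(predictors)
    if FORBIDDEN_PREDICTOR in predictors:
        raise InvalidParameterError(
            f"{FORBIDDEN_PREDICTOR!r} must not be among the predictors: the "
            "classifier replaces the CO2 measurement")
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise InvalidParameterError(f"predictors not in table: {missing}")

    y_all = table[label_col].to_numpy()
    classes, counts = np.unique(y_all, return_counts=True)
    if len(classes) < 2:
        raise DegenerateDataError(
            "label table has a single class; nothing to discriminate")
    if counts.min() < 30:
        raise DegenerateDataError(
            f"every class needs >= 30 cycles, got {dict(zip(classes, counts))}")

    X_all = table[predictors].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    n = len(table)
    if config.stratified:
        folds: list[np.ndarray] = [np.empty(0, dtype=int)] * n_folds
        parts: list[list[int]] = [[] for _ in range(n_folds)]
        for cls in classes:
            idx = rng.permutation(np.flatnonzero(y_all == cls))
            for f, chunk in enumerate(np.array_split(idx, n_folds)):
                parts[f].extend(chunk)
        folds = [np.sort(np.asarray(p)) for p in parts]
    else:
        folds = np.array_split(rng.permutation(n), n_folds)

    fold_acc = []
    sens = {c: [] for c in classes}
    prec = {c: [] for c in classes}
    pooled_scores = []
    pooled_truth = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        x_train, y_train = X_all[train_mask], y_all[train_mask]
        x_test, y_test = X_all[test_idx], y_all[test_idx]

        scaler = StandardScaler().fit(x_train)
        model = _fit_mlp(config, scaler.transform(x_train), y_train,
                         seed=int(config.seed + 1000 + f))

        pred = model.predict(scaler.transform(x_test))
        fold_acc.append(float((pred == y_test).mean()))
        for c in classes:
            sens[c].append(recall_score(y_test, pred, labels=[c],
                                        average=None, zero_division=0)[0])
            prec[c].append(precision_score(y_test, pred, labels=[c],
                                           average=None, zero_division=0)[0])
        proba = model.predict_proba(scaler.transform(x_test))
        # map the model's class order onto the global one
        order = {c: i for i, c in enumerate(model.classes_)}
        proba = proba[:, [order[c] for c in classes]]
        pooled_scores.append(proba)
        pooled_truth.append(y_test)

    scores = np.vstack(pooled_scores)
    truth = np.concatenate(pooled_truth)
    aucs = pooled_roc(scores, truth, classes=list(classes))

    return CvResult(
        fold_accuracy=np.asarray(fold_acc),
        sensitivity={c: np.asarray(v) for c, v in sens.items()},
        precision={c: np.asarray(v) for c, v in prec.items()},
        auc=aucs,
        classes=list(classes),
        fold_sizes=[len(f) for f in folds],
    )


def hanley_mcneil_ci(auc_value: float, n_pos: int, n_neg: int,
                     level: float = 0.95) -> tuple[float, float]:
    """Binormal-approximation confidence interval for an empirical AUC."""
    from scipy.stats import norm

    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, a - half), min(1.0, a + half)


def pooled_roc(scores: np.ndarray, labels: np.ndarray,
               classes: list | None = None
               ) -> dict[str, tuple[float, float, float]]:
    """One-vs-rest AUC per class on pooled held-out scores.

    ``scores`` is (n, n_classes) with columns ordered like ``classes``.
    The AUC is the trapezoidal area under the empirical ROC; the 95 % CI
    uses the Hanley–McNeil variance formula.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = list(np.unique(labels))
    if len(classes) < 2:
        raise DegenerateDataError("AUC undefined for single-class labels")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise InvalidParameterError("scores must be (n, n_classes)")
    out = {}
    for j, cls in enumerate(classes):
        truth = (labels == cls).astype(int)
        n_pos, n_neg = int(truth.sum()), int((1 - truth).sum())
        if n_pos == 0 or n_neg == 0:
            raise DegenerateDataError(f"class {cls!r} absent from pooled labels")
        fpr, tpr, _ = roc_curve(truth, scores[:, j])
        a = float(_sk_auc(fpr, tpr))
        lo, hi = hanley_mcneil_ci(a, n_pos, n_neg)
        out[cls] = (a, lo, hi)
    return out
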