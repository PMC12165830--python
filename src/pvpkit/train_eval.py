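"""Training, prediction, metrics and the gamma-grid sweep.

The central objects follow the model/results idiom: ``VirionClassifier``
binds an embedding table, its labels and the architecture/loss/optimizer
configurations; ``fit()`` runs seeded mini-batch Adam on the asymmetric
loss with early stopping on a stratified validation split, and returns a
``ClassifierResults`` carrying the best-validation parameters, the
per-epoch history, and ``predict`` / ``evaluate`` / ``summary``.

Metrics are the suite used for imbalanced protein classification: accuracy,
precision, recall, F1 (binary, macro or support-weighted averaging) and the
Matthews correlation coefficient, generalized over the full confusion
matrix for more than two classes. Note that support-weighted recall equals
accuracy identically, a useful consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    matthews_corrcoef,
    precision_recall_fscore_support,
)
from sklearn.model_selection import train_test_split

from . import classifier as clf
from .asl import ASLConfig, asl_grad, asl_loss, one_hot, softmax
from .classifier import ClassifierConfig, ModelState
from .embeddings import EmbeddingTable


@dataclass(frozen=True)
class ClassPrediction:
    """One model verdict: argmax class plus the full softmax vector."""

    id: str
    class_index: int
    label: str
    confidence: np.ndarray  # per-class softmax, sums to 1

    def __post_init__(self) -> None:
        if abs(float(self.confidence.sum()) - 1.0) > 1e-6:
            raise ValueError("confidence vector must sum to 1")
        if int(np.argmax(self.confidence)) != self.class_index:
            raise ValueError("class_index must be the argmax of the confidence vector")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training parameters must be positive")
        if not 0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    averaging: str
    per_class_f1: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def compute_metrics(
    predicted: Sequence[str],
    truth: Sequence[str],
    averaging: str = "weighted",
    classes: Sequence[str] | None = None,
    positive_class: str = "PVP",
) -> MetricsReport:
    """Accuracy / precision / recall / F1 / MCC on label sequences.

    ``averaging='binary'`` treats ``positive_class`` as the positive label;
    multi-class defaults to support-weighted averaging (macro available).
    Undefined per-class precision or recall becomes 0 with a warning.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    if averaging not in ("binary", "macro", "weighted"):
        raise ValueError(f"unknown averaging {averaging!r}")
    y_true = list(truth)
    y_pred = list(predicted)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    kwargs: dict = {"zero_division": 0}
    if averaging == "binary":
        kwargs["pos_label"] = positive_class
        kwargs["labels"] = None
    else:
        kwargs["labels"] = list(classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average=averaging, **kwargs
        )
        _, _, f1_per_class, _ = precision_recall_fscore_support(
            y_true, y_pred, average=None, labels=list(classes), zero_division=0
        )
        mcc = matthews_corrcoef(y_true, y_pred)
    undefined = [c for c, f in zip(classes, f1_per_class) if c not in set(y_pred) and c in set(y_true)]
    if undefined:
        warnings.warn(f"classes never predicted (precision set to 0): {undefined}")
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        mcc=float(mcc),
        averaging=averaging,
        per_class_f1={c: float(f) for c, f in zip(classes, f1_per_class)},
    )


def _labels_to_indices(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    missing = [l for l in labels if l not in index]
    if missing:
        raise ValueError(f"labels outside the class set: {sorted(set(missing))[:5]}")
    return np.array([index[l] for l in labels], dtype=int)


class VirionClassifier:
    """Model object binding embeddings, labels and configuration.

    Parameters
    ----------
    table : EmbeddingTable
        Per-protein feature vectors (one row per labeled protein).
    labels : sequence of str
        Class label per row of ``table``, e.g. "PVP"/"nonPVP" or the seven
        functional category names.
    classes : sequence of str, optional
        Class order defining the logit index mapping; defaults to the
        sorted distinct labels.
    """

    def __init__(
        self,
        table: EmbeddingTable,
        labels: Sequence[str],
        classes: Sequence[str] | None = None,
        model_config: ClassifierConfig | None = None,
        loss_config: ASLConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        if len(labels) != len(table):
            raise ValueError("one label per embedding row required")
        self.table = table
        self.labels = list(labels)
        self.classes = tuple(classes) if classes else tuple(sorted(set(self.labels)))
        if len(self.classes) < 2:
            raise ValueError("training requires at least two classes")
        self.loss_config = loss_config or ASLConfig()
        self.train_config = train_config or TrainConfig()
        base = model_config or ClassifierConfig()
        if base.input_dim != table.dim or base.n_classes != len(self.classes):
            base = replace(base, input_dim=table.dim, n_classes=len(self.classes))
        self.model_config = base

    def fit(self) -> "ClassifierResults":
        cfg = self.train_config
        X = self.table.values
        y_idx = _labels_to_indices(self.labels, self.classes)
        if len(np.unique(y_idx)) < 2:
            raise ValueError("training data contains a single class")
        Y = one_hot(y_idx, len(self.classes))

        X_tr, X_val, Y_tr, Y_val = train_test_split(
            X, Y, test_size=cfg.val_fraction, random_state=cfg.seed, stratify=y_idx
        )
        model = clf.build_model(
            replace(self.model_config, seed=cfg.seed), classes=self.classes
        )
        optimizer_rng = np.random.default_rng(cfg.seed + 1)
        from .nn import Adam

        opt = Adam(model.network, lr=cfg.learning_rate)
        best_state = model.network.state()
        best_val = np.inf
        best_epoch = 0
        rows = []
        since_best = 0
        n = X_tr.shape[0]
        for epoch in range(1, cfg.max_epochs + 1):
            perm = optimizer_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                logits = model.forward(X_tr[idx], training=True)
                loss = asl_loss(logits, Y_tr[idx], self.loss_config)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(lr={cfg.learning_rate}, batch={len(idx)})"
                    )
                grad = asl_grad(logits, Y_tr[idx], self.loss_config)
                model.network.backward(grad.astype(logits.dtype))
                opt.step()
                epoch_loss += loss * len(idx)
            val_logits = model.forward(X_val, training=False)
            val_loss = asl_loss(val_logits, Y_val, self.loss_config)
            rows.append(
                {"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_loss}
            )
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.network.state()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        model.network.load_state(best_state)
        model.epochs_run = len(rows)
        model.best_val_loss = float(best_val)
        history = pd.DataFrame(rows)
        return ClassifierResults(self, model, history, best_epoch)


@dataclass
class ClassifierResults:
    """Fitted parameters, training history and evaluation helpers."""

    model: VirionClassifier
    state: ModelState
    history: pd.DataFrame
    best_epoch: int

    @property
    def classes(self) -> tuple[str, ...]:
        return self.model.classes

    def predict(self, table: EmbeddingTable) -> list[ClassPrediction]:
        return predict(self.state, table)

    def predict_proba(self, table: EmbeddingTable) -> np.ndarray:
        return softmax(clf.forward(self.state, table.values))

    def evaluate(
        self, table: EmbeddingTable, truth: Sequence[str], averaging: str = "weighted"
    ) -> MetricsReport:
        predicted = [p.label for p in self.predict(table)]
        return compute_metrics(predicted, truth, averaging=averaging, classes=self.classes)

    def summary(self) -> str:
        cfg = self.model.model_config
        loss = self.model.loss_config
        lines = [
            "Virion protein classifier",
            "=" * 48,
            f"classes:        {', '.join(self.classes)}",
            f"input dim:      {cfg.input_dim}",
            f"conv:           {cfg.conv_filters} filters, k={cfg.conv_kernel}, s={cfg.conv_stride}",
            f"pool:           k={cfg.pool_kernel}, s={cfg.pool_stride}",
            f"hidden units:   {cfg.hidden_units}",
            f"loss:           ASL mode={loss.mode}, gamma_pos={loss.gamma_pos}, "
            f"gamma_neg={loss.gamma_neg}",
            f"epochs run:     {self.state.epochs_run} (best epoch {self.best_epoch})",
            f"best val loss:  {self.state.best_val_loss:.6f}",
            "=" * 48,
        ]
        return "\n".join(lines)


def predict(model: ModelState, table: EmbeddingTable) -> list[ClassPrediction]:
    """Softmax confidences and argmax class per table row, order preserved."""
    probs = softmax(clf.forward(model, table.values))
    classes = model.classes or tuple(str(i) for i in range(model.config.n_classes))
    out = []
    for pid, row in zip(table.ids, probs):
        k = int(np.argmax(row))
        out.append(ClassPrediction(id=pid, class_index=k, label=classes[k], confidence=row))
    return out


def predict_labels(model: ModelState, table: EmbeddingTable) -> list[str]:
    probs = softmax(clf.forward(model, table.values))
    classes = model.classes or tuple(str(i) for i in range(model.config.n_classes))
    return [classes[int(np.argmax(row))] for row in probs]


def train(
    table: EmbeddingTable,
    labels: Sequence[str],
    classes: Sequence[str] | None = None,
    model_config: ClassifierConfig | None = None,
    loss_config: ASLConfig | None = None,
    train_config: TrainConfig | None = None,
) -> ClassifierResults:
    """Functional wrapper: build a VirionClassifier and fit it."""
    return VirionClassifier(
        table, labels, classes, model_config, loss_config, train_config
    ).fit()


def gamma_sweep(
    train_table: EmbeddingTable,
    train_labels: Sequence[str],
    test_table: EmbeddingTable,
    test_labels: Sequence[str],
    configs: Sequence[tuple[float, float]] = ((0, 1), (0, 4), (0, 6), (1, 1), (2, 0)),
    mode: str = "standard",
    classes: Sequence[str] | None = None,
    model_config: ClassifierConfig | None = None,
    train_config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train one seeded model per (gamma_pos, gamma_neg) on identical splits.

    Returns a DataFrame with one row per configuration: the summary metrics
    plus per-class F1 columns (``f1[<class>]``).
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    rows = []
    for gp, gn in configs:
        loss_cfg = ASLConfig(gamma_pos=gp, gamma_neg=gn, mode=mode)
        results = train(
            train_table, train_labels, classes=classes,
            model_config=model_config, loss_config=loss_cfg, train_config=train_config,
        )
        report = results.evaluate(test_table, test_labels)
        row = {"gamma_pos": gp, "gamma_neg": gn, **report.as_dict()}
        for cls_name, f in report.per_class_f1.items():
            row[f"f1[{cls_name}]"] = f
        rows.append(row)
    return pd.DataFrame(rows)
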