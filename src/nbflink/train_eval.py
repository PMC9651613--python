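"""Training protocol, confusion-matrix metrics and cross-validation.

Evaluation reports precision, recall, accuracy, the Matthews correlation
coefficient and AUROC.  Thresholded metrics use 0.5 on the positive-class
probability; AUROC is threshold-free (trapezoidal ROC integration).  A
metric whose denominator degenerates (e.g. precision with no predicted
positives) is reported as ``None`` — an explicit not-available marker —
rather than silently coerced to 0, and fold averages skip it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .graph import (
    DatasetSplit,
    InteractionGraph,
    LinkExample,
    kfold_split,
    message_passing_graph,
)
from .model import DPBNBFnet, PredictionPair, nll_loss


@dataclass
class TrainConfig:
    """Run configuration; the seed fixes every random draw."""

    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 32
    negatives_per_positive: int = 1
    seed: int = 0
    k_folds: int = 4
    hidden_dim: int = 32
    message: str = "distmult"
    aggregate: str = "sum"
    module_layers: tuple[int, ...] = (2, 2, 2)
    sortpool_k: int = 10
    alpha_init: float = 0.9

    def __post_init__(self):
        for name in ("epochs", "lr", "batch_size", "negatives_per_positive",
                     "k_folds", "hidden_dim", "sortpool_k"):
            if getattr(self, name) <= 0 and not (name == "lr" and self.lr == 0.0):
                raise ValueError(f"{name} must be positive")

    def make_estimator(self, graph: InteractionGraph, seed: int) -> DPBNBFnet:
        return DPBNBFnet(
            graph=graph,
            hidden_dim=self.hidden_dim,
            message=self.message,
            aggregate=self.aggregate,
            module_layers=tuple(self.module_layers),
            sortpool_k=self.sortpool_k,
            alpha_init=self.alpha_init,
            epochs=self.epochs,
            lr=self.lr,
            batch_size=self.batch_size,
            negatives_per_positive=self.negatives_per_positive,
            random_state=seed,
        )


@dataclass
class Metrics:
    """Confusion counts and the derived statistics."""

    TrP: int
    TrN: int
    FaP: int
    FaN: int
    precision: float | None
    recall: float | None
    accuracy: float | None
    mcc: float | None
    auroc: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def train(
    graph: InteractionGraph, split: DatasetSplit, config: TrainConfig
) -> DPBNBFnet:
    """Fit the model on a fold's training examples.

    Test-fold positive edges are removed from the message-passing graph so
    the model can never route messages over the links it is asked to
    predict (leakage hygiene).
    """
    if not any(e.label == 1 for e in split.train):
        raise ValueError("training fold has no positive examples")
    mp_graph = message_passing_graph(graph, split.test)
    est = config.make_estimator(mp_graph, seed=config.seed + split.fold_index)
    X = [(e.u, e.v) for e in split.train]
    y = [e.label for e in split.train]
    est.fit(X, y)
    return est


def confusion(
    predictions: list[PredictionPair], labels, threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """Tally (TrP, TrN, FaP, FaN) at a probability threshold."""
    labels = list(labels)
    if not predictions:
        raise ValueError("empty prediction list")
    if len(predictions) != len(labels):
        raise ValueError("length mismatch between predictions and labels")
    trp = trn = fap = fan = 0
    for p, l in zip(predictions, labels):
        pred = 1 if np.exp(p.log_p_pos) >= threshold else 0
        if pred == 1 and l == 1:
            trp += 1
        elif pred == 0 and l == 0:
            trn += 1
        elif pred == 1 and l == 0:
            fap += 1
        else:
            fan += 1
    return trp, trn, fap, fan


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(counts, scores, labels) -> Metrics:
    """Precision/recall/accuracy/MCC from counts plus trapezoidal AUROC."""
    trp, trn, fap, fan = counts
    total = trp + trn + fap + fan
    labels = np.asarray(list(labels), dtype=int)
    if total != len(labels):
        raise ValueError("confusion counts inconsistent with label count")
    mcc_den = (trp + fap) * (trp + fan) * (trn + fap) * (trn + fan)
    mcc = None if mcc_den == 0 else (trp * trn - fap * fan) / np.sqrt(mcc_den)
    if len(np.unique(labels)) < 2:
        auroc = None
    else:
        auroc = float(roc_auc_score(labels, np.asarray(list(scores), dtype=float)))
    return Metrics(
        TrP=trp,
        TrN=trn,
        FaP=fap,
        FaN=fan,
        precision=_safe_div(trp, trp + fap),
        recall=_safe_div(trp, trp + fan),
        accuracy=_safe_div(trp + trn, total),
        mcc=mcc,
        auroc=auroc,
    )


def evaluate(model: DPBNBFnet, examples: list[LinkExample]) -> Metrics:
    """Score held-out examples with a fitted model."""
    X = [(e.u, e.v) for e in examples]
    labels = [e.label for e in examples]
    lp = model.predict_log_proba(X)
    preds = [PredictionPair(log_p_pos=row[1], log_p_neg=row[0]) for row in lp]
    counts = confusion(preds, labels)
    scores = np.exp(lp[:, 1])
    return compute_metrics(counts, scores, labels)


def mean_metrics(folds: list[Metrics]) -> dict:
    """Fold averages; NA-marked entries are skipped per statistic."""
    out = {}
    for key in ("precision", "recall", "accuracy", "mcc", "auroc"):
        vals = [getattr(m, key) for m in folds if getattr(m, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


@dataclass
class CVResult:
    folds: list[Metrics]
    mean: dict
    loss_traces: list[list[float]] = field(default_factory=list)


def cross_validate(
    graph: InteractionGraph, examples: list[LinkExample], config: TrainConfig
) -> CVResult:
    """k-fold cross-validation: train per fold, evaluate on its test fold."""
    rng = np.random.default_rng(config.seed)
    splits = kfold_split(examples, config.k_folds, rng)
    folds, traces = [], []
    for split in splits:
        model = train(graph, split, config)
        folds.append(evaluate(model, split.test))
        traces.append(model.loss_trace_)
    return CVResult(folds=folds, mean=mean_metrics(folds), loss_traces=traces)
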