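"""Training protocol, evaluation metrics, and the ablation harness.

Training follows the benchmark protocol: Adam at batch size 64, learning
rate chosen by training-set size (1e-5 above 40k samples, else 5e-5),
early stopping when validation accuracy has not improved for 30 consecutive
epochs, k-fold (default 5) stratified cross-validation, binary
cross-entropy loss on the sigmoid output. Each fold's best-validation
checkpoint is evaluated independently on the held-out test set and the
per-fold metrics are summarized as mean +/- standard deviation.

Metrics: ACC = (TP+TN)/total, SN = TP/(TP+FN), SP = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with the
continuity convention MCC = 0 when any factor of the denominator is zero,
and AUC via the rank-statistic (Mann-Whitney) formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from .data_io import LabeledDataset, encode_sequences, kfold_split
from .network import Model, ModelConfig

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "MetricsReport",
    "TrainingLog",
    "bce_loss",
    "Adam",
    "train_fold",
    "cross_validate",
    "compute_metrics",
    "compute_auc",
    "confusion_counts",
    "evaluate_model",
    "run_ablation",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate_small: float = 5e-5
    learning_rate_large: float = 1e-5
    large_dataset_threshold: int = 40000
    patience: int = 30
    max_epochs: int = 500
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.learning_rate_small <= 0 or self.learning_rate_large <= 0:
            raise ValueError("learning rates must be positive")

    def learning_rate(self, n_train: int) -> float:
        """Size-dependent rate: large datasets get the smaller rate."""
        if n_train > self.large_dataset_threshold:
            return self.learning_rate_large
        return self.learning_rate_small


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Per-fold ACC/MCC/SN/SP/AUC plus their mean and stdev."""

    per_fold: pd.DataFrame  # columns: fold, ACC, MCC, SN, SP, AUC

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[["ACC", "MCC", "SN", "SP", "AUC"]].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold[["ACC", "MCC", "SN", "SP", "AUC"]].std(ddof=1)

    def to_tsv(self, path) -> None:
        self.per_fold.to_csv(path, sep="\t", index=False,
                             float_format="%.6f")


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with scores clipped to [1e-7, 1-1e-7]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    s = np.clip(scores, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s)))


def _bce_from_logits(logits: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    # mean(softplus(z) - y*z): numerically stable, equals bce on sigmoid(z)
    y = ad.Tensor(np.asarray(labels, dtype=logits.data.dtype))
    return (logits.softplus() - y * logits).mean()


class Adam:
    """Adam with the conventional defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, ad.Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in params.items()}
        self.v = {n: np.zeros_like(p.data) for n, p in params.items()}

    def step(self) -> None:
        from ._kernels import adam_update

        self.t += 1
        bias1 = 1 - self.beta1 ** self.t
        bias2 = 1 - self.beta2 ** self.t
        for n, p in self.params.items():
            if p.grad is None:
                continue
            adam_update(p.data.ravel(), np.ascontiguousarray(p.grad).ravel(),
                        self.m[n].ravel(), self.v[n].ravel(),
                        p.data.dtype.type(self.lr),
                        p.data.dtype.type(self.beta1),
                        p.data.dtype.type(self.beta2),
                        p.data.dtype.type(self.eps),
                        p.data.dtype.type(bias1),
                        p.data.dtype.type(bias2))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainingLog:
    """Per-epoch record: epoch, train_loss, val_accuracy, best_so_far."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0

    def to_text(self) -> str:
        lines = ["epoch\ttrain_loss\tval_accuracy\tbest_so_far"]
        for e in self.epochs:
            lines.append(f"{e['epoch']}\t{e['train_loss']:.6f}\t"
                         f"{e['val_accuracy']:.6f}\t{e['best_so_far']:.6f}")
        return "\n".join(lines) + "\n"


def _batched_scores(model: Model, indices: np.ndarray,
                    batch_size: int = 256) -> np.ndarray:
    parts = [model.predict(indices[i:i + batch_size])
             for i in range(0, len(indices), batch_size)]
    return np.concatenate(parts)


def train_fold(train_idxmat: np.ndarray, train_labels: np.ndarray,
               val_idxmat: np.ndarray, val_labels: np.ndarray,
               model_config: ModelConfig, train_config: TrainConfig,
               seed: int | None = None) -> tuple[Model, TrainingLog]:
    """Train one model on encoded data with accuracy-based early stopping.

    Adam at the size-selected learning rate; after every epoch the
    validation accuracy (threshold 0.5) is logged; the returned model holds
    the weights of the epoch with the best validation accuracy (earliest on
    ties). Training stops once the number of epochs since the last
    improvement reaches ``patience``, or at ``max_epochs``.
    """
    if len(train_idxmat) == 0 or len(val_idxmat) == 0:
        raise ValueError("train and validation splits must be nonempty")
    seed = train_config.seed if seed is None else seed
    model = Model(model_config, seed=seed)
    lr = train_config.learning_rate(len(train_idxmat))
    opt = Adam(model.params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    log = TrainingLog()
    best_state = model.state_dict()
    since_best = 0
    n = len(train_idxmat)
    bs = train_config.batch_size
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, bs):
            sel = order[lo:lo + bs]
            opt.zero_grad()
            logits = model.forward(train_idxmat[sel], train=True, rng=rng)
            loss = _bce_from_logits(logits, train_labels[sel])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_scores = _batched_scores(model, val_idxmat)
        val_acc = float(((val_scores >= 0.5).astype(int)
                         == val_labels).mean())
        if val_acc > log.best_val_accuracy:
            log.best_val_accuracy = val_acc
            log.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
        log.epochs.append({"epoch": epoch,
                           "train_loss": float(np.mean(losses)),
                           "val_accuracy": val_acc,
                           "best_so_far": log.best_val_accuracy})
        if since_best >= train_config.patience:
            break
    model.load_state_dict(best_state)
    return model, log


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """ACC/SN/SP/MCC from confusion counts.

    SN/SP are NaN when their denominator is zero; MCC is 0 when any factor
    of its denominator is zero (continuity convention).
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn > 0 else math.nan
    sp = tn / (tn + fp) if tn + fp > 0 else math.nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {"ACC": acc, "SN": sn, "SP": sp, "MCC": mcc}


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic with tie correction)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def confusion_counts(scores: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    pred = (np.asarray(scores) >= threshold).astype(int)
    labels = np.asarray(labels)
    return ConfusionCounts(
        TP=int(((pred == 1) & (labels == 1)).sum()),
        FP=int(((pred == 1) & (labels == 0)).sum()),
        TN=int(((pred == 0) & (labels == 0)).sum()),
        FN=int(((pred == 0) & (labels == 1)).sum()))


def evaluate_model(model: Model, idxmat: np.ndarray,
                   labels: np.ndarray) -> dict[str, float]:
    """Threshold-0.5 label metrics plus AUC on encoded data."""
    scores = _batched_scores(model, idxmat)
    metrics = compute_metrics(confusion_counts(scores, labels))
    metrics["AUC"] = compute_auc(scores, labels)
    return metrics


def _encode_dataset(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    return (encode_sequences([s.bases for s in dataset]), dataset.labels)


def cross_validate(dataset: LabeledDataset, test_dataset: LabeledDataset,
                   model_config: ModelConfig, train_config: TrainConfig,
                   return_models: bool = False,
                   ensemble: bool = False):
    """k-fold cross-validated training, each fold evaluated on the test set.

    Trains one model per stratified fold and scores each on the held-out
    test set; returns a :class:`MetricsReport` of per-fold ACC/MCC/SN/SP/AUC
    with mean/stdev. Training sequences are checked for absence from the
    test set. With ``ensemble`` the report also carries the metrics of the
    score-averaged fold ensemble (``report.ensemble``).
    """
    test_seqs = {s.bases for s in test_dataset}
    overlap = sum(1 for s in dataset if s.bases in test_seqs)
    if overlap:
        raise ValueError(
            f"{overlap} training sequence(s) also occur in the test set")
    idxmat, labels = _encode_dataset(dataset)
    test_idxmat, test_labels = _encode_dataset(test_dataset)
    folds = kfold_split(dataset, train_config.folds, train_config.seed)
    rows, models, logs = [], [], []
    score_sum = np.zeros(len(test_labels))
    for f, (train_idx, val_idx) in enumerate(folds):
        model, log = train_fold(
            idxmat[train_idx], labels[train_idx],
            idxmat[val_idx], labels[val_idx],
            model_config, train_config, seed=train_config.seed + f)
        scores = _batched_scores(model, test_idxmat)
        score_sum += scores
        row = compute_metrics(confusion_counts(scores, test_labels))
        row["AUC"] = compute_auc(scores, test_labels)
        rows.append({"fold": f, **row})
        models.append(model)
        logs.append(log)
    report = MetricsReport(pd.DataFrame(rows))
    if ensemble:
        mean_scores = score_sum / len(folds)
        ens = compute_metrics(confusion_counts(mean_scores, test_labels))
        ens["AUC"] = compute_auc(mean_scores, test_labels)
        report.ensemble = ens  # type: ignore[attr-defined]
    if return_models:
        return report, models, logs
    return report


# -- ablation harness ------------------------------------------------------

_ALLOWED_WINDOW_SETS = [(3,), (5,), (7,), (3, 5), (3, 7), (5, 7), (3, 5, 7)]


@dataclass(frozen=True)
class AblationVariant:
    name: str
    conv_mode: str = "position_specific"
    window_sizes: tuple[int, ...] = (3, 5, 7)


def run_ablation(dataset: LabeledDataset, test_dataset: LabeledDataset,
                 model_config: ModelConfig, train_config: TrainConfig,
                 variants: list[AblationVariant],
                 baseline: str | None = None) -> pd.DataFrame:
    """Train and evaluate each architecture variant under identical splits.

    Variants vary ``conv_mode`` (position_specific vs shared filters) and
    the window-size set. Returns a tidy table with one row per (variant,
    fold) plus summary rows carrying mean metrics and deltas against the
    named baseline variant (default: the first).
    """
    if not variants:
        raise ValueError("need at least one variant")
    for v in variants:
        if v.conv_mode not in ("position_specific", "shared"):
            raise ValueError(f"variant {v.name}: bad conv_mode")
        if tuple(sorted(v.window_sizes)) not in [
                tuple(s) for s in _ALLOWED_WINDOW_SETS]:
            raise ValueError(f"variant {v.name}: window set "
                             f"{v.window_sizes} not supported")
    baseline = baseline or variants[0].name
    rows = []
    for v in variants:
        cfg = replace(model_config, conv_mode=v.conv_mode,
                      window_sizes=tuple(v.window_sizes))
        report = cross_validate(dataset, test_dataset, cfg, train_config)
        for _, r in report.per_fold.iterrows():
            rows.append({"variant": v.name, "fold": int(r["fold"]),
                         **{m: r[m] for m in
                            ("ACC", "MCC", "SN", "SP", "AUC")}})
    table = pd.DataFrame(rows)
    means = table.groupby("variant", sort=False)[
        ["ACC", "MCC", "SN", "SP", "AUC"]].mean()
    base = means.loc[baseline]
    for m in ("ACC", "MCC", "AUC"):
        table[f"delta_{m}"] = table["variant"].map(means[m] - base[m])
    return table
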