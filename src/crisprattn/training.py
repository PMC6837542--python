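"""Training protocols: top-fraction labelling, class-balanced minibatches,
cross-validation splitters, evaluation metrics, and the fit loop.

Classification uses negative log-likelihood on log-softmax outputs with
positive oversampling per minibatch (the off-target datasets are heavily
imbalanced, ~250:1); regression uses mean squared error. Evaluation metrics
are AUC-ROC and PR-AUC for classification, Spearman/Pearson correlation and
MSE for regression — computed on unresampled held-out data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

from .errors import SamplingError, TrainingError, ValidationError
from .nn import Adam, Tensor

__all__ = [
    "FoldSplit",
    "GroupHoldout",
    "MetricsReport",
    "TrainConfig",
    "label_top_fraction",
    "balanced_batches",
    "kfold_split",
    "leave_groups_out",
    "evaluate_classifier",
    "evaluate_regressor",
    "nll_loss",
    "mse_loss",
    "train_model",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# labelling and splitting
# ---------------------------------------------------------------------------

def label_top_fraction(scores: Sequence[float], fraction: float = 0.2) -> np.ndarray:
    """Binary labels: the ``round(fraction * n)`` highest scores are positive.

    This is the top-20% activity labelling used for indel-frequency datasets.
    Ties at the cutoff are broken by stable input order (earlier rows win).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("label_top_fraction requires a nonempty score list")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    n_pos = int(round(fraction * scores.size))
    labels = np.zeros(scores.size, dtype=np.int64)
    if n_pos > 0:
        order = np.argsort(-scores, kind="stable")  # stable: earlier index first on ties
        labels[order[:n_pos]] = 1
    return labels


@dataclass
class FoldSplit:
    """k-fold partition; fold sizes differ by at most one."""

    fold_assignments: dict
    k: int
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) positions for one fold, in input order."""
        ids = list(self.fold_assignments)
        test = np.array([i for i, s in enumerate(ids) if self.fold_assignments[s] == fold])
        train = np.array([i for i, s in enumerate(ids) if self.fold_assignments[s] != fold])
        return train, test


def kfold_split(ids: Sequence, k: int, seed: int = 0) -> FoldSplit:
    ids = list(ids)
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds number of samples {len(ids)}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    chunks = np.array_split(perm, k)
    assign = {}
    for fold, chunk in enumerate(chunks):
        for i in chunk:
            assign[ids[int(i)]] = fold
    return FoldSplit(fold_assignments=assign, k=k, seed=seed)


@dataclass
class GroupHoldout:
    """Group-wise holdout: no group (sgRNA or cell line) spans train and test."""

    held_out_groups: set
    train_idx: np.ndarray
    test_idx: np.ndarray


def leave_groups_out(ids: Sequence, groups: Sequence, held_out: Sequence) -> GroupHoldout:
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(ids):
        raise ValidationError("ids and groups must align")
    held = set(held_out)
    unknown = held - set(groups.tolist())
    if unknown:
        raise ValidationError(f"held-out groups not present in data: {sorted(map(str, unknown))}")
    mask = np.isin(groups, list(held))
    test_idx = np.flatnonzero(mask)
    train_idx = np.flatnonzero(~mask)
    assert not (set(groups[train_idx]) & set(groups[test_idx]))
    return GroupHoldout(held_out_groups=held, train_idx=train_idx, test_idx=test_idx)


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------

def balanced_batches(
    labels: Sequence[int], batch_size: int, seed: int = 0
) -> Iterator[np.ndarray]:
    """Index batches with roughly equal positives and negatives.

    One epoch visits every negative exactly once; each batch draws an equal
    number of positives with replacement (minority oversampling). The final
    partial batch keeps the same balance.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise SamplingError("balanced sampling needs at least one positive and one negative")
    rng = np.random.default_rng(seed)
    neg = rng.permutation(neg)
    half = max(1, batch_size // 2)
    for start in range(0, neg.size, half):
        neg_chunk = neg[start : start + half]
        pos_chunk = rng.choice(pos, size=neg_chunk.size, replace=True)
        yield rng.permutation(np.concatenate([neg_chunk, pos_chunk]))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Evaluation summary; classification and regression fields are optional."""

    n_samples: int = 0
    auc_roc: Optional[float] = None
    pr_auc: Optional[float] = None
    spearman: Optional[float] = None
    pearson: Optional[float] = None
    mse: Optional[float] = None
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None and (k != "per_fold" or v)
        }

    @staticmethod
    def aggregate(reports: list["MetricsReport"]) -> dict:
        """mean ± s.d. across folds for every populated metric."""
        out: dict[str, tuple[float, float]] = {}
        for name in ("auc_roc", "pr_auc", "spearman", "pearson", "mse"):
            vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
            if vals:
                out[name] = (float(np.mean(vals)), float(np.std(vals)))
        return out


def evaluate_classifier(y_true: Sequence[int], y_score: Sequence[float]) -> MetricsReport:
    """AUC-ROC (trapezoid over the ROC) and PR-AUC (area under precision–recall)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValidationError("y_true and y_score must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValidationError("AUC undefined for single-class y_true")
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    return MetricsReport(
        n_samples=y_true.size,
        auc_roc=float(roc_auc_score(y_true, y_score)),
        pr_auc=float(auc(recall, precision)),
    )


def evaluate_regressor(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return MetricsReport(
        n_samples=y_true.size,
        spearman=float(stats.spearmanr(y_true, y_pred).statistic),
        pearson=float(stats.pearsonr(y_true, y_pred).statistic),
        mse=float(np.mean((y_true - y_pred) ** 2)),
    )


# ---------------------------------------------------------------------------
# losses and the fit loop
# ---------------------------------------------------------------------------

def nll_loss(log_probs: Tensor, y: np.ndarray) -> Tensor:
    """Mean negative log-likelihood given (B, C) log-probabilities."""
    y = np.asarray(y, dtype=np.int64)
    onehot = np.zeros(log_probs.shape)
    onehot[np.arange(y.size), y] = 1.0
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / y.size)


def mse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(y, dtype=np.float64))
    return (diff * diff).mean()


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 10  # early stopping on validation loss
    val_fraction: float = 0.1
    seed: int = 0
    verbose: bool = False


def _forward_loss(model, tokens, extra, y, task) -> Tensor:
    out = model(tokens, extra)
    return nll_loss(out, y) if task == "classify" else mse_loss(out, y)


def predict(model, tokens: np.ndarray, extra: Optional[np.ndarray] = None,
            batch_size: int = 256) -> np.ndarray:
    """Batched eval-mode forward pass.

    Classifiers return the positive-class probability; regressors the score.
    """
    was_training = model.training
    model.eval()
    outs = []
    for start in range(0, len(tokens), batch_size):
        sl = slice(start, start + batch_size)
        ex = None if extra is None else extra[sl]
        out = model(tokens[sl], ex).numpy()
        outs.append(np.exp(out[:, 1]) if out.ndim == 2 else out)
    if was_training:
        model.train()
    return np.concatenate(outs)


def train_model(
    model,
    tokens: np.ndarray,
    y: np.ndarray,
    extra: Optional[np.ndarray] = None,
    task: str | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[object, MetricsReport, list[float]]:
    """Fit a model; returns (model, held-out MetricsReport, per-epoch train losses).

    A ``val_fraction`` split is carved out for early stopping and the final
    report; validation data is never resampled. Classification epochs iterate
    class-balanced batches; regression epochs iterate shuffled minibatches.
    """
    cfg = cfg or TrainConfig()
    task = task or model.cfg.task
    tokens = np.asarray(tokens)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    n = len(tokens)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if cfg.val_fraction > 0 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if task == "classify" and n_val:
        # keep both classes in train; retry the carve-out if degenerate
        for _ in range(20):
            if len(np.unique(y[tr_idx])) == 2:
                break
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xt, yt = tokens[tr_idx], y[tr_idx]
    et = None if extra is None else extra[tr_idx]
    xv, yv = tokens[val_idx], y[val_idx]
    ev = None if extra is None else extra[val_idx]

    opt = Adam(model.parameters(), lr=cfg.lr)
    history: list[float] = []
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(cfg.epochs):
        model.train()
        if task == "classify":
            batches = balanced_batches(yt, cfg.batch_size, seed=cfg.seed + epoch)
        else:
            order = np.random.default_rng(cfg.seed + epoch).permutation(len(yt))
            batches = (
                order[s : s + cfg.batch_size] for s in range(0, len(yt), cfg.batch_size)
            )
        epoch_losses = []
        for idx in batches:
            opt.zero_grad()
            loss = _forward_loss(model, xt[idx], None if et is None else et[idx], yt[idx], task)
            lval = loss.item()
            if not np.isfinite(lval):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {lval} (lr={cfg.lr}, "
                    f"batch={cfg.batch_size})"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(lval)
        history.append(float(np.mean(epoch_losses)))

        if n_val:
            model.eval()
            vloss = _forward_loss(model, xv, ev, yv, task).item()
            if cfg.verbose:
                log.info("epoch %d train=%.4f val=%.4f", epoch, history[-1], vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = model.state_arrays()
                best_state = {k: v.copy() for k, v in best_state.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()

    if n_val:
        scores = predict(model, xv, ev)
        if task == "classify" and len(np.unique(yv)) == 2:
            report = evaluate_classifier(yv, scores)
        elif task == "regress" and len(yv) >= 2:
            report = evaluate_regressor(yv, scores)
        else:
            report = MetricsReport(n_samples=len(yv))
    else:
        report = MetricsReport(n_samples=0)
    return model, report, history
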