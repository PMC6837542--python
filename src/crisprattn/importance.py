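"""Input-perturbation feature importance.

For each input feature (one token position, or one named covariate such as
the NetExpress score) the feature's column is shuffled across samples and the
model's loss on the whole dataset recomputed; this is repeated ``n_repeats``
times (default 40) and the *average post-shuffle loss* is the raw importance.
Raw importances are then normalised by their sum, so they add to 1.

Note the raw score is the loss after shuffling, not the increase over the
baseline loss — a deliberate departure from conventional permutation
importance (which uses the delta); a feature the model ignores therefore
scores the baseline loss, not zero, and ranks lowest only relative to
informative features. Shuffling acts column-wise across samples, never within
a sample's sequence, and leaves the model untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .training import mse_loss, nll_loss

__all__ = ["ImportanceReport", "perturbation_importance", "plot_importance"]


@dataclass
class ImportanceReport:
    feature_names: list[str]
    raw_scores: np.ndarray
    normalized_scores: np.ndarray
    n_repeats: int
    seed: int
    baseline_loss: float

    def __post_init__(self):
        if not (
            len(self.feature_names) == len(self.raw_scores) == len(self.normalized_scores)
        ):
            raise ValidationError("feature/score lengths inconsistent")
        total = float(np.sum(self.normalized_scores))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"normalized scores sum to {total}, expected 1")

    def top(self, k: int) -> list[str]:
        order = np.argsort(-self.normalized_scores)
        return [self.feature_names[i] for i in order[:k]]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "raw_scores": self.raw_scores.tolist(),
            "normalized_scores": self.normalized_scores.tolist(),
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "baseline_loss": self.baseline_loss,
        }


def _dataset_loss(model, tokens, extra, y, task: str, batch_size: int = 512) -> float:
    n = len(tokens)
    total = 0.0
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        out = model(tokens[sl], None if extra is None else extra[sl])
        loss = nll_loss(out, y[sl]) if task == "classify" else mse_loss(out, y[sl])
        total += loss.item() * min(batch_size, n - start)
    return total / n


def perturbation_importance(
    model,
    tokens: np.ndarray,
    y: np.ndarray,
    extra: Optional[np.ndarray] = None,
    extra_names: Sequence[str] = (),
    n_repeats: int = 40,
    seed: int = 0,
    task: str | None = None,
    feature_prefix: str | None = None,
) -> ImportanceReport:
    """Shuffle-one-feature importance for a trained model (read-only).

    ``tokens`` is the (n, L) integer token matrix; token features are named
    ``dimer_k`` or ``basepair_k`` by position (``feature_prefix`` overrides
    the automatic choice), and named covariate columns of ``extra`` follow.
    """
    tokens = np.asarray(tokens)
    y = np.asarray(y)
    if tokens.ndim != 2 or len(tokens) < 1:
        raise ValidationError("tokens must be a (n_samples, L) matrix")
    task = task or model.cfg.task
    if extra is not None:
        extra = np.asarray(extra, dtype=np.float64)
        if len(extra_names) != extra.shape[1]:
            raise ValidationError("extra_names must name every extra column")
    was_training = model.training
    model.eval()

    n, length = tokens.shape
    if feature_prefix is None:
        feature_prefix = "basepair" if task == "classify" else "dimer"
    names = [f"{feature_prefix}_{k}" for k in range(length)] + list(extra_names)
    rng = np.random.default_rng(seed)
    baseline = _dataset_loss(model, tokens, extra, y, task)

    raw = np.zeros(len(names))
    for f in range(len(names)):
        losses = np.empty(n_repeats)
        for r in range(n_repeats):
            perm = rng.permutation(n)
            if f < length:
                shuffled = tokens.copy()
                shuffled[:, f] = tokens[perm, f]
                losses[r] = _dataset_loss(model, shuffled, extra, y, task)
            else:
                ex = extra.copy()
                col = f - length
                ex[:, col] = extra[perm, col]
                losses[r] = _dataset_loss(model, tokens, ex, y, task)
        raw[f] = losses.mean()
    if was_training:
        model.train()

    total = raw.sum()
    if total <= 0:
        raise ValidationError("raw importances sum to zero; cannot normalise")
    return ImportanceReport(
        feature_names=names,
        raw_scores=raw,
        normalized_scores=raw / total,
        n_repeats=n_repeats,
        seed=seed,
        baseline_loss=baseline,
    )


def plot_importance(report: ImportanceReport, path: str | Path) -> Path:
    """Bar chart of normalised importances in feature order; returns the path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.feature_names:
        raise ValidationError("cannot plot an empty importance report")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(report.feature_names)), 4))
    x = np.arange(len(report.feature_names))
    ax.bar(x, report.normalized_scores, color="steelblue")
    ax.set_xticks(x)
    ax.set_xticklabels(report.feature_names, rotation=90, fontsize=7)
    ax.set_ylabel("normalized importance")
    ax.set_title(
        f"Input-perturbation importance (n_repeats={report.n_repeats}, "
        f"sum={report.normalized_scores.sum():.6f})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
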