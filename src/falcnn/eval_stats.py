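"""Training loop and evaluation statistics for the FAL-CNN.

Covers the full protocol: SGD/cross-entropy training with a stepped
learning-rate schedule, parent-grouped five-fold cross-validation,
six-subgroup bootstrap accuracies with 95% confidence intervals, the
Wilcoxon rank-sum test, the uncertain-class filter on top-two class
probabilities, and per-class agreement tables with Wald binomial CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from . import autodiff as ad
from .model_core import Model, forward, standardize
from .synthetic_data import PatchRecord

Z95 = 1.96


# ----------------------------------------------------------------- training

@dataclass
class Hyperparams:
    """SGD settings; the learning rate decays by ``lr_decay`` every
    ``decay_every`` epochs: lr(e) = lr0 * lr_decay ** floor(e / decay_every)."""
    lr0: float = 0.0003
    momentum: float = 0.9
    epochs: int = 200
    lr_decay: float = 0.7
    decay_every: int = 30
    batch_size: int = 16


def learning_rate(hp: Hyperparams, epoch: int) -> float:
    return hp.lr0 * hp.lr_decay ** (epoch // hp.decay_every)


def _resolve_dataset(train) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(train, tuple):
        images, labels = train
        return np.asarray(images), np.asarray(labels)
    records: list[PatchRecord] = list(train)
    if not records:
        raise ValueError("empty training set")
    images = np.stack([r.load() for r in records])
    labels = np.asarray([r.class_label for r in records])
    return images, labels


def train_model(model: Model, train, hp: Hyperparams, seed: int = 0
                ) -> list[dict]:
    """Train with SGD + cross-entropy; returns per-epoch history.

    ``train`` is a list of PatchRecords or an ``(images, labels)`` tuple with
    images (N, H, W, 3) in 0..255.  Per-channel standardization statistics
    are computed from the training set and stored on the model.
    """
    images, labels = _resolve_dataset(train)
    if len(images) == 0:
        raise ValueError("empty training set")
    flat = images.reshape(-1, 3).astype(np.float64)
    model.norm_mean = flat.mean(axis=0).astype(np.float32)
    model.norm_std = np.maximum(flat.std(axis=0), 1e-3).astype(np.float32)
    x_all = standardize(images, model.norm_mean, model.norm_std)

    rng = np.random.default_rng(seed)
    opt = ad.SGD(model.params(), lr=hp.lr0, momentum=hp.momentum)
    n = len(x_all)
    history = []
    for epoch in range(hp.epochs):
        opt.lr = learning_rate(hp, epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            xb = ad.Tensor(x_all[idx])
            out = model._forward_graph(xb, model.spec.n_iterations)
            loss = ad.cross_entropy(out["logits"], labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"epoch": epoch, "lr": opt.lr,
                        "mean_loss": float(np.mean(losses))})
    return history


def predict(model: Model, images: np.ndarray, batch_size: int = 32
            ) -> np.ndarray:
    """Predicted class per image (raw uint8 images, standardized internally)."""
    if model.norm_mean is None:
        raise ValueError("model has no stored normalization statistics")
    x = standardize(images, model.norm_mean, model.norm_std)
    preds = []
    for start in range(0, len(x), batch_size):
        out = forward(model, x[start:start + batch_size])
        preds.append(out.predicted_class)
    return np.concatenate(preds)


# ------------------------------------------------------------ grouped folds

def grouped_five_fold(records: list[PatchRecord], seed: int = 0,
                      n_folds: int = 5):
    """Partition by parent id into ``n_folds`` (train, test) record splits.

    Parents are assigned whole to folds (greedy balancing by patch count on a
    seeded shuffle), so every test set draws on parents that appear in no
    other test set, and the union of the test sets covers all records.
    """
    parents: dict[str, list[PatchRecord]] = {}
    for r in records:
        parents.setdefault(r.parent_id, []).append(r)
    if len(parents) < n_folds:
        raise ValueError(
            f"need >= {n_folds} distinct parent_ids, got {len(parents)}")
    rng = np.random.default_rng(seed)
    names = sorted(parents)
    rng.shuffle(names)
    # largest-first greedy assignment to the currently lightest fold
    names.sort(key=lambda p: -len(parents[p]))
    fold_of: dict[str, int] = {}
    counts = [0] * n_folds
    for name in names:
        f = int(np.argmin(counts))
        fold_of[name] = f
        counts[f] += len(parents[name])
    splits = []
    for f in range(n_folds):
        test = [r for r in records if fold_of[r.parent_id] == f]
        train = [r for r in records if fold_of[r.parent_id] != f]
        splits.append((train, test))
    return splits


# ------------------------------------------------------ bootstrap + ranksum

def bootstrap_points(labels: np.ndarray, predictions: np.ndarray,
                     n_subgroups: int = 6, seed: int = 0) -> np.ndarray:
    """Accuracy (%) per random subgroup of a seeded partition of the records."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise ValueError("empty test set")
    if labels.size < n_subgroups:
        raise ValueError(f"{labels.size} records < {n_subgroups} subgroups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(labels.size)
    points = []
    for chunk in np.array_split(order, n_subgroups):
        points.append(100.0 * float(np.mean(labels[chunk] == predictions[chunk])))
    return np.asarray(points)


def bootstrap_accuracy(model: Model, test, n_subgroups: int = 6,
                       seed: int = 0):
    """Model accuracy over a seeded subgroup partition of a test set.

    Returns (points, mean, (ci_lo, ci_hi)).  Run once per cross-validation
    fold; five folds x six subgroups give the 30 accuracy points the overall
    mean and 95% CI are computed from.
    """
    images, labels = _resolve_dataset(test)
    preds = predict(model, images)
    points = bootstrap_points(labels, preds, n_subgroups, seed)
    mean, ci = summarize_points(points)
    return points, mean, ci


def summarize_points(points: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI (mean +/- 1.96 sd / sqrt(n))."""
    points = np.asarray(points, dtype=np.float64)
    mean = float(points.mean())
    if points.size < 2:
        return mean, (mean, mean)
    half = Z95 * float(points.std(ddof=1)) / np.sqrt(points.size)
    return mean, (mean - half, mean + half)


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum test (normal approximation) on two point samples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 points")
    res = stats.ranksums(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------- uncertain-class filter

def uncertain_filter(probs, threshold: float = 0.25) -> bool:
    """True when the top-two class probabilities are too close to call.

    With P_A the largest and P_B the second-largest class probability, a
    patch is uncertain-class when (P_A - P_B) / P_A < threshold (strict).
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.size < 2:
        raise ValueError("need at least 2 class probabilities")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("probs must be non-negative and sum to 1")
    top = np.sort(p)[::-1]
    pa, pb = top[0], top[1]
    return bool((pa - pb) / pa < threshold)


# -------------------------------------------------------- agreement tables

def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def wald_ci(k: int, n: int) -> tuple[float, float, float]:
    """Wald binomial rate and 95% CI in percent, clipped to [0, 100].

    p_hat = k/n; bounds p_hat +/- 1.96 sqrt(p_hat (1 - p_hat) / n), reported
    as percentages rounded to 2 dp (computed from the unrounded rate).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    p = k / n
    half = Z95 * np.sqrt(p * (1.0 - p) / n)
    lo = min(max(p - half, 0.0), 1.0)
    hi = min(max(p + half, 0.0), 1.0)
    return _round2(100 * p), _round2(100 * lo), _round2(100 * hi)


def agreement_table(labels, predictions, class_names: list[str]
                    ) -> pd.DataFrame:
    """Per-class agreement between expert labels and model predictions.

    Rows are grouped by the expert-assigned label; ``n_agree`` counts exact
    matches; rates carry Wald 95% CIs.  An ``all`` row aggregates every
    record (rate computed as 100 k/n).  Classes with no records report a 0%
    rate and no CI.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    k_classes = len(class_names)
    bad = set(np.unique(labels)) | set(np.unique(predictions))
    if any(c < 0 or c >= k_classes for c in bad):
        raise ValueError(f"class id outside 0..{k_classes - 1}: {sorted(bad)}")
    rows = []
    for cid, name in enumerate(class_names):
        sel = labels == cid
        n = int(sel.sum())
        agree = int((predictions[sel] == cid).sum())
        if n == 0:
            rows.append((name, 0, 0, 0.0, np.nan, np.nan))
        else:
            rate, lo, hi = wald_ci(agree, n)
            rows.append((name, n, agree, rate, lo, hi))
    n_all = int(labels.size)
    agree_all = int((labels == predictions).sum())
    rate, lo, hi = wald_ci(agree_all, n_all)
    rows.append(("all", n_all, agree_all, rate, lo, hi))
    return pd.DataFrame(rows, columns=["class", "n_patches", "n_agree",
                                       "rate_pct", "ci_lo_pct", "ci_hi_pct"]
                        ).set_index("class")
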