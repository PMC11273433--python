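"""Classification metrics, data splitting, cross-validation and the
noise-robustness protocol.

The positive class is ALL by convention (configurable): the confusion
matrix has true labels on rows and predictions on columns, with the
positive class first, so

    C = [[TP, FN],
         [FP, TN]].

``add_awgn`` injects white Gaussian noise at a requested signal-to-noise
ratio, defining signal power as the mean squared pixel value; the noisy
raster is NOT clipped, and is re-normalized before re-entering the graph
pipeline during the robustness sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .preprocess import CLASS_LABELS


@dataclass
class MetricsReport:
    """Confusion matrix plus the derived scalar metrics of one evaluation."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    kappa: float
    auc: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "kappa": self.kappa,
            "auc": self.auc,
            "n": self.n,
        }


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive: str = "ALL",
) -> np.ndarray:
    """2x2 count matrix, rows = true class, cols = predicted class, with the
    positive class indexed first."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    negative = [c for c in CLASS_LABELS if c != positive]
    if positive not in CLASS_LABELS or not negative:
        raise ValueError(f"unknown positive class {positive!r}")
    order = {positive: 0, negative[0]: 1}
    C = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in order or p not in order:
            raise ValueError(f"unknown label in inputs: {t!r}/{p!r}")
        C[order[t], order[p]] += 1
    return C


def classification_metrics(confusion: np.ndarray) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, precision from a 2x2 matrix.

    Ratios with a zero denominator are reported as None, not 0.
    """
    C = np.asarray(confusion)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp, fn = int(C[0, 0]), int(C[0, 1])
    fp, tn = int(C[1, 0]), int(C[1, 1])

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    C = np.asarray(confusion, dtype=float)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(C) / n
    p_e = float((C.sum(axis=1) * C.sum(axis=0)).sum()) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def roc_auc(
    y_true: Sequence[str],
    scores: Sequence[float],
    positive: str = "ALL",
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and AUC by the trapezoid rule.

    ``scores`` are probabilities (or any monotone score) of the positive
    class. The trapezoid AUC equals the Mann-Whitney pair-counting statistic
    with ties counted 1/2.
    """
    y = np.asarray([1 if t == positive else 0 for t in y_true])
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scores: Sequence[float] | None = None,
    positive: str = "ALL",
) -> MetricsReport:
    """Assemble the full MetricsReport for one set of predictions."""
    C = confusion_matrix(y_true, y_pred, positive)
    m = classification_metrics(C)
    auc = None
    if scores is not None:
        try:
            _, _, auc = roc_auc(y_true, scores, positive)
        except ValueError:
            auc = None
    return MetricsReport(
        confusion=C,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        precision=m["precision"],
        kappa=cohen_kappa(C),
        auc=auc,
        n=int(C.sum()),
    )


# ---------------------------------------------------------------------------
# splitting and cross-validation


def split_dataset(
    dataset: Sequence,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Random stratified train/validation/test partition.

    Items must expose a ``label`` attribute. Within each class, counts are
    apportioned by largest remainder so the split is exact and exhaustive.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for item in dataset:
        by_class.setdefault(item.label, []).append(item)
    splits: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_class):
        items = by_class[label]
        if len(items) < 3:
            raise ValueError(f"class {label!r} has fewer than 3 samples")
        idx = rng.permutation(len(items))
        n = len(items)
        raw = [f * n for f in fractions]
        counts = [int(x) for x in raw]
        rem = n - sum(counts)
        order = np.argsort([-(x - int(x)) for x in raw], kind="stable")
        for j in range(rem):
            counts[order[j]] += 1
        start = 0
        for part, cnt in zip(splits, counts):
            part.extend(items[i] for i in idx[start : start + cnt])
            start += cnt
    return splits


def kfold_cv(
    dataset: Sequence,
    k: int,
    seed: int,
    train_fn: Callable[[list], object],
    eval_fn: Callable[[object, list], MetricsReport],
) -> list[MetricsReport]:
    """Stratified k-fold cross-validation.

    Every sample lands in exactly one test fold; ``train_fn`` fits a model
    on the remaining folds and ``eval_fn`` scores it on the held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for item in dataset:
        by_class.setdefault(item.label, []).append(item)
    for label, items in by_class.items():
        if len(items) < k:
            raise ValueError(f"class {label!r} has fewer than k={k} samples")
    folds: list[list] = [[] for _ in range(k)]
    for label in sorted(by_class):
        items = by_class[label]
        idx = rng.permutation(len(items))
        for pos, i in enumerate(idx):
            folds[pos % k].append(items[i])
    reports = []
    for f in range(k):
        test = folds[f]
        train = [x for g in range(k) if g != f for x in folds[g]]
        model = train_fn(train)
        reports.append(eval_fn(model, test))
    return reports


# ---------------------------------------------------------------------------
# noise protocol


def add_awgn(
    image: np.ndarray, snr_db: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add white Gaussian noise at the requested SNR (dB).

    Noise variance is P_signal / 10^(snr_db/10) with P_signal the mean
    squared pixel value. ``snr_db = math.inf`` returns the image unchanged.
    Output is not clipped.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("raster must be finite")
    p_signal = float(np.mean(img**2))
    if p_signal == 0.0:
        raise ValueError("all-zero raster has no defined SNR")
    if math.isinf(snr_db) and snr_db > 0:
        return img.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sigma = math.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    return img + rng.normal(0.0, sigma, size=img.shape)


def noise_robustness_sweep(
    model,
    test_samples: Sequence,
    snr_list: Sequence[float],
    seed: int = 0,
    n_regions_target: int = 100,
    compactness: float = 1.0,
) -> dict[float, float]:
    """Accuracy of a trained classifier on noise-corrupted test images.

    For each SNR the clean normalized images are corrupted, re-normalized,
    re-segmented into region graphs, padded and classified. The +inf entry
    reproduces clean-test accuracy exactly (no corruption, same pipeline).
    """
    from .graphs import build_region_graph, pad_graph
    from .preprocess import minmax_normalize

    if not getattr(model, "trained", False):
        raise RuntimeError("model must be trained before the noise sweep")
    if len(snr_list) == 0:
        raise ValueError("snr_list must be non-empty")
    budget = model.config.node_budget
    out: dict[float, float] = {}
    for j, snr in enumerate(snr_list):
        rng = np.random.default_rng((seed, j))
        graphs = []
        y_true = []
        for s in test_samples:
            noisy = add_awgn(s.pixels, snr, rng)
            noisy = minmax_normalize(noisy)
            g = build_region_graph(
                noisy,
                n_regions_target=n_regions_target,
                compactness=compactness,
                label=s.label,
                source_id=s.source_id,
            )
            graphs.append(pad_graph(g, budget))
            y_true.append(s.label)
        y_pred = model.predict(graphs)
        out[float(snr)] = float(
            np.mean([t == p for t, p in zip(y_true, y_pred)])
        )
    return out
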