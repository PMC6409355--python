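"""High/low expression classification built on the regression model.

Samples — one per (gene, day) record — are split into expression groups by
the 30%-quantile rule: sorting expression values in descending order, the
top ``m = floor(fraction * n)`` form the high group and the bottom ``m`` the
low group; the smallest value of the high group is the classification
threshold, and any value >= threshold is called positive.  Model predictions
are thresholded the same way and tallied into a confusion matrix scored by
accuracy, sensitivity, specificity and Matthews correlation.

Cross-validation fits the pooled regression on the training folds only, and
also recomputes the threshold from training expressions only, so no
held-out information leaks into the classifier.  A small feedforward
network (one hidden layer of two sigmoid units, trained by full-batch
gradient descent) serves as the non-linear baseline under the identical
fold protocol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import TimeCourseRecord
from .model_core import (FitResult, ModelSpec, RankDeficientDesign,
                         design_matrix, fit_lsm)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class ClassificationMetrics:
    acc: float
    sn: float
    sp: float
    mcc: float
    degenerate: bool = False


@dataclass
class CVReport:
    fold_of_sample: np.ndarray
    fold_fits: list[FitResult | None]
    counts: ConfusionCounts
    metrics: ClassificationMetrics
    seed: int
    k: int


def min_max_normalize(
    records: Sequence[TimeCourseRecord],
) -> tuple[list[TimeCourseRecord], dict[str, tuple[float, float]]]:
    """Map each of H, D, W, Exp onto [0, 1] by (x - min)/(max - min).

    Returns the rescaled records and the per-variable (min, max) needed for
    the inverse transform.  A constant variable is fatal.
    """
    arrays = {
        "height": np.array([r.height for r in records], dtype=float),
        "distance": np.array([r.distance for r in records], dtype=float),
        "width": np.array([r.width for r in records], dtype=float),
        "expression": np.array([r.expression for r in records], dtype=float),
    }
    params: dict[str, tuple[float, float]] = {}
    scaled: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            raise ValueError(f"cannot min-max normalize constant variable {name!r}")
        params[name] = (lo, hi)
        scaled[name] = (arr - lo) / (hi - lo)
    out = [
        TimeCourseRecord(
            gene_id=r.gene_id, day=r.day,
            height=float(scaled["height"][i]),
            distance=float(scaled["distance"][i]),
            width=float(scaled["width"][i]),
            expression=float(scaled["expression"][i]),
        )
        for i, r in enumerate(records)
    ]
    return out, params


def inverse_min_max(values, lo_hi: tuple[float, float]) -> np.ndarray:
    lo, hi = lo_hi
    return np.asarray(values, dtype=float) * (hi - lo) + lo


def split_high_low(
    expressions,
    fraction: float = 0.3,
) -> tuple[float, np.ndarray, np.ndarray]:
    """30%-quantile grouping of expression values.

    Returns ``(threshold, labels, group)`` where ``labels`` is the binary
    call for every sample (value >= threshold -> positive) and ``group`` is
    +1 for the top-m high group, -1 for the bottom-m low group and 0 for the
    unlabelled middle.
    """
    values = np.asarray(expressions, dtype=float).ravel()
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not (0.0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5)")
    m = int(math.floor(fraction * n))
    if m < 1:
        raise ValueError("fraction too small: empty extreme groups")
    order = np.argsort(-values, kind="stable")
    threshold = float(values[order[m - 1]])
    labels = values >= threshold
    if int(labels.sum()) != m:
        logger.info("ties straddle the high/low boundary; the >=-threshold "
                    "rule labels %d samples positive (m=%d)", int(labels.sum()), m)
    group = np.zeros(n, dtype=int)
    group[order[:m]] = 1
    group[order[n - m:]] = -1
    return threshold, labels, group


def classify_predictions(
    predicted,
    threshold: float,
    true_labels,
) -> ConfusionCounts:
    """Threshold predictions (>= threshold -> positive) against true labels."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    true_labels = np.asarray(true_labels, dtype=bool).ravel()
    if predicted.shape != true_labels.shape:
        raise ValueError("predicted and true_labels must have equal length")
    calls = predicted >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & true_labels)),
        tn=int(np.sum(~calls & ~true_labels)),
        fp=int(np.sum(calls & ~true_labels)),
        fn=int(np.sum(~calls & true_labels)),
    )


def compute_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Acc, Sn, Sp and Matthews correlation from confusion counts.

    Sn or Sp with an empty class, and Mcc with any zero marginal, are
    degenerate: they are reported as 0 with ``degenerate=True``.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    degenerate = False
    pos, neg = c.tp + c.fn, c.tn + c.fp
    if pos > 0:
        sn = c.tp / pos
    else:
        sn, degenerate = 0.0, True
    if neg > 0:
        sp = c.tn / neg
    else:
        sp, degenerate = 0.0, True
    acc = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc, degenerate = 0.0, True
    return ClassificationMetrics(acc=acc, sn=sn, sp=sp, mcc=mcc, degenerate=degenerate)


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded shuffle into k folds whose sizes differ by at most one."""
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    return folds


def kfold_cv(
    records: Sequence[TimeCourseRecord],
    spec: ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
    fraction: float = 0.3,
    normalize: bool = True,
    eval_labels: np.ndarray | None = None,
) -> CVReport:
    """Seeded k-fold cross-validated classification via the regression model.

    Each fold: fit the pooled model on the remaining samples, derive the
    high/low threshold from *training* expressions, predict the held-out
    expressions and threshold them.  Confusion counts are pooled over folds
    before metrics are computed.

    ``eval_labels`` optionally supplies externally fixed true labels (NaN
    marks samples excluded from evaluation, e.g. the middle band in a
    strict-extremes protocol); otherwise the true label of a held-out sample
    is its observed expression against the training threshold.
    """
    spec = spec if spec is not None else ModelSpec(model_id=4)
    recs = list(records)
    n = len(recs)
    if eval_labels is not None:
        eval_labels = np.asarray(eval_labels, dtype=float).ravel()
        if eval_labels.size != n:
            raise ValueError("eval_labels length must match records")
    if normalize:
        recs, _ = min_max_normalize(recs)
    X, y = design_matrix(recs, spec)
    folds = assign_folds(n, k, seed)

    counts = ConfusionCounts()
    fold_fits: list[FitResult | None] = []
    for f in range(k):
        test = folds == f
        train = ~test
        try:
            fit = fit_lsm(X[train], y[train], term_names=spec.terms)
        except RankDeficientDesign as exc:
            logger.warning("fold %d skipped: %s", f, exc)
            fold_fits.append(None)
            continue
        fold_fits.append(fit)
        threshold, _, _ = split_high_low(y[train], fraction=fraction)
        y_hat = X[test] @ fit.beta + fit.intercept
        if eval_labels is None:
            truth = y[test] >= threshold
            mask = np.ones(truth.shape, dtype=bool)
        else:
            lab = eval_labels[test]
            mask = ~np.isnan(lab)
            truth = lab[mask] > 0.5
        counts = counts + classify_predictions(y_hat[mask], threshold, truth)

    return CVReport(
        fold_of_sample=folds,
        fold_fits=fold_fits,
        counts=counts,
        metrics=compute_metrics(counts),
        seed=seed,
        k=k,
    )


# ---------------------------------------------------------------------------
# feedforward baseline
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class _TinyNet:
    """One hidden layer of two sigmoid units, sigmoid output, MSE loss."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    @classmethod
    def init(cls, n_in: int, n_hidden: int, rng: np.random.Generator) -> "_TinyNet":
        return cls(
            w1=rng.uniform(-0.5, 0.5, size=(n_in, n_hidden)),
            b1=rng.uniform(-0.5, 0.5, size=n_hidden),
            w2=rng.uniform(-0.5, 0.5, size=n_hidden),
            b2=float(rng.uniform(-0.5, 0.5)),
        )

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = _sigmoid(X @ self.w1 + self.b1)
        out = _sigmoid(h @ self.w2 + self.b2)
        return h, out

    def train(self, X: np.ndarray, t: np.ndarray, lr: float, epochs: int) -> float:
        n = X.shape[0]
        loss = math.inf
        for _ in range(epochs):
            h, out = self.forward(X)
            err = out - t
            loss = float(np.mean(err ** 2))
            # backprop of MSE through the two sigmoid layers
            d_out = 2.0 * err * out * (1.0 - out) / n
            g_w2 = h.T @ d_out
            g_b2 = float(d_out.sum())
            d_h = np.outer(d_out, self.w2) * h * (1.0 - h)
            g_w1 = X.T @ d_h
            g_b1 = d_h.sum(axis=0)
            self.w2 -= lr * g_w2
            self.b2 -= lr * g_b2
            self.w1 -= lr * g_w1
            self.b1 -= lr * g_b1
        return loss


@dataclass(frozen=True)
class BPConfig:
    """Training regimen of the feedforward baseline (all values logged with
    every run): 2 hidden sigmoid units, full-batch gradient descent."""

    n_hidden: int = 2
    learning_rate: float = 0.1
    epochs: int = 2000
    converge_tol: float = 0.24


def _normalize_columns(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def bp_baseline(
    X: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    k: int = 10,
    config: BPConfig = BPConfig(),
    folds: np.ndarray | None = None,
) -> tuple[ClassificationMetrics, ConfusionCounts]:
    """Cross-validated metrics of the small feedforward network.

    ``X`` holds the model basis features (min-max normalised internally);
    ``labels`` the binary classes.  Uses the same seeded fold protocol as
    :func:`kfold_cv` so both classifiers see identical splits.  Final
    training loss above ``config.converge_tol`` is reported as
    non-convergence (warning), never fatal.
    """
    X = _normalize_columns(np.asarray(X, dtype=float))
    t = np.asarray(labels, dtype=float).ravel()
    n = X.shape[0]
    if t.size != n:
        raise ValueError("labels length must match X rows")
    if folds is None:
        folds = assign_folds(n, k, seed)
    rng = np.random.default_rng(seed)

    counts = ConfusionCounts()
    for f in range(int(folds.max()) + 1):
        test = folds == f
        train = ~test
        net = _TinyNet.init(X.shape[1], config.n_hidden, rng)
        loss = net.train(X[train], t[train], config.learning_rate, config.epochs)
        if loss > config.converge_tol:
            logger.warning("BP baseline fold %d did not converge (loss %.3f)", f, loss)
        _, out = net.forward(X[test])
        counts = counts + classify_predictions(out, 0.5, t[test] > 0.5)
    return compute_metrics(counts), counts
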