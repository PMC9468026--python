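"""Binary target-present vs target-free classification with bootstrapped ROC/AUC.

Given per-FOV count statistics from a 0 pM control (label 0) and a sample
with analyte (label 1), a single-feature unregularized logistic regression is
fitted on a training split and scored on held-out FOVs with a receiver
operating characteristic curve and its area (AUC). Confidence in the AUC
comes from a class-stratified out-of-bag bootstrap: each class is resampled
with replacement for training and its unsampled FOVs form the test set,
repeated (by default) 1000 times.

For a single monotone feature the ROC ranking is that of the raw statistic,
so AUC here equals the Mann-Whitney probability that a random positive FOV
out-counts a random negative one — the quantity the assay's diagnostic power
rests on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "LogisticModel",
    "RocResult",
    "fit_logistic",
    "roc_auc",
    "bootstrap_classification",
]


@dataclass(frozen=True)
class LogisticModel:
    """Single-feature logistic classifier ``P(y=1|x) = sigmoid(w*x + c)``."""

    weight: float
    intercept: float

    def scores(self, x: Sequence[float]) -> np.ndarray:
        return self.weight * np.asarray(x, dtype=float) + self.intercept

    @property
    def decision_boundary(self) -> float:
        """The x at which P(y=1|x) = 0.5, i.e. ``-c/w``."""
        return -self.intercept / self.weight


@dataclass
class RocResult:
    """ROC curve, its area, and (when bootstrapped) the AUC sample spread."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("ROC curve must be monotone non-decreasing")

    @property
    def quartiles(self) -> tuple[float, float, float]:
        """(Q1, median, Q3) of the bootstrap AUC distribution."""
        if self.auc_samples.size == 0:
            raise ValueError("no bootstrap AUC samples available")
        q = np.percentile(self.auc_samples, [25, 50, 75])
        return tuple(float(v) for v in q)

    def summary(self) -> str:
        lines = [f"AUC (full data): {self.auc:.4f}"]
        if self.auc_samples.size:
            q1, med, q3 = self.quartiles
            lines.append(
                f"bootstrap AUC over {len(self.auc_samples)} iterations: "
                f"median {med:.4f}, IQR [{q1:.4f}, {q3:.4f}]"
            )
            if self.n_redrawn:
                lines.append(f"{self.n_redrawn} degenerate iterations redrawn")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, "-", label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random guessing")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def fit_logistic(x: Sequence[float], y: Sequence[int]) -> LogisticModel:
    """Maximum-likelihood logistic fit with no regularization penalty.

    The problem is convex, so the result is deterministic given the data.
    Perfectly separated classes drive the weight toward infinity; a warning
    is issued and the returned scores remain usable for ranking.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be 0 (control) or 1 (target present)")

    clf = LogisticRegression(penalty=None, solver="lbfgs",
                             max_iter=50_000, tol=1e-12)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(x, y)
    separated = x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min()
    if separated or any(issubclass(w.category, ConvergenceWarning) for w in caught):
        warnings.warn(
            "logistic fit did not fully converge (classes may be perfectly "
            "separated); scores remain usable for ranking"
        )
    return LogisticModel(weight=float(clf.coef_[0, 0]),
                         intercept=float(clf.intercept_[0]))


def roc_auc(x: Sequence[float], y: Sequence[int], model: LogisticModel) -> RocResult:
    """ROC over all score thresholds and trapezoidal AUC on a test set."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.size == 0:
        raise ValueError("test set is empty")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined for a one-class test set")
    fpr, tpr, _ = roc_curve(y, model.scores(x))
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def bootstrap_classification(
    positive: Sequence[float],
    negative: Sequence[float],
    n_boot: int = 1000,
    rng_seed: int | np.random.Generator | None = 0,
) -> RocResult:
    """Class-stratified out-of-bag bootstrap of the logistic ROC/AUC.

    ``positive`` are per-FOV statistics from the analyte-containing sample,
    ``negative`` from the 0 pM control. Each iteration resamples each class
    with replacement for training, tests on the unsampled FOVs of both
    classes, and records the AUC; iterations whose out-of-bag set lacks a
    class are redrawn. The returned curve is the full-data fit; the samples
    carry the uncertainty.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 5 or len(neg) < 5:
        raise ValueError("each class needs at least 5 FOVs to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)

    x_all = np.concatenate([pos, neg])
    y_all = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_model = fit_logistic(x_all, y_all)
        full = roc_auc(x_all, y_all, full_model)

    samples = np.empty(n_boot)
    redrawn = 0
    i = 0
    guard = 0
    while i < n_boot:
        guard += 1
        if guard > 50 * n_boot:
            raise RuntimeError("bootstrap cannot produce two-class test sets")
        ip = rng.integers(0, len(pos), size=len(pos))
        ineg = rng.integers(0, len(neg), size=len(neg))
        oob_p = np.setdiff1d(np.arange(len(pos)), ip)
        oob_n = np.setdiff1d(np.arange(len(neg)), ineg)
        if oob_p.size == 0 or oob_n.size == 0:
            redrawn += 1
            continue
        x_tr = np.concatenate([pos[ip], neg[ineg]])
        y_tr = np.concatenate([np.ones(len(ip), int), np.zeros(len(ineg), int)])
        x_te = np.concatenate([pos[oob_p], neg[oob_n]])
        y_te = np.concatenate([np.ones(oob_p.size, int), np.zeros(oob_n.size, int)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_logistic(x_tr, y_tr)
            samples[i] = roc_auc(x_te, y_te, model).auc
        i += 1

    return RocResult(
        fpr=full.fpr, tpr=full.tpr, auc=full.auc,
        auc_samples=samples, n_redrawn=redrawn,
    )
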