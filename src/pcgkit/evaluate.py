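"""Repeated balanced cross-validated evaluation of the two strategies.

The protocol: abnormal signals are scarce, so each run draws a fresh random
balanced subsample of normals (as many as there are abnormals), pools them,
and scores the classifier by stratified 10-fold cross-validation.  Within a
fold the four metrics are computed from the confusion counts with abnormal
as the positive class:

    Acc  = (TP+TN) / (TP+FN+FP+TN)
    Se   = TP / (TP+FN)
    Sp   = TN / (FP+TN)
    MAcc = (Se+Sp) / 2

Fold metrics are averaged into run metrics, the run is repeated (50 times by
default), and the report carries the mean of each metric over runs with a
normal-approximation 95% confidence interval.  Everything is reproducible
bit-for-bit from the master seed (run r uses seed + r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .classify import PcgStrategyClassifier

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvaluationReport",
    "compute_metrics",
    "confidence_interval",
    "balanced_subsample",
    "stratified_kfold",
    "run_experiment",
    "round_half_away",
]

METRIC_NAMES = ("acc", "se", "sp", "macc")


class UndefinedMetricError(ZeroDivisionError):
    """A metric denominator is zero (a class is absent from the test set)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with abnormal (patient) as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(
        cls, y_true: Sequence[str], y_pred: Sequence[str], positive: str = "abnormal"
    ) -> "ConfusionCounts":
        t = np.asarray(y_true)
        p = np.asarray(y_pred)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred have different lengths")
        pos_t = t == positive
        pos_p = p == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity, specificity and modified accuracy (fractions)."""

    acc: float
    se: float
    sp: float
    macc: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "se": self.se, "sp": self.sp, "macc": self.macc}


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Acc/Se/Sp from confusion counts; MAcc is the Se/Sp midpoint."""
    if c.total == 0 or c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise UndefinedMetricError(
            f"metrics undefined for counts {c}: a denominator is zero"
        )
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.fp + c.tn)
    return Metrics(
        acc=(c.tp + c.tn) / c.total,
        se=se,
        sp=sp,
        macc=(se + sp) / 2.0,
    )


def confidence_interval(run_values: Sequence[float]) -> tuple[float, float]:
    """Normal-approximation 95% CI over run-level values: mean ± 1.96 sd/√n."""
    values = np.asarray(run_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 run values for a confidence interval")
    mean = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(values.size)
    return (mean - half, mean + half)


def balanced_subsample(pool: Sequence, n: int, rng: np.random.Generator) -> list:
    """Draw ``n`` distinct items uniformly without replacement."""
    pool = list(pool)
    if n > len(pool):
        raise ValueError(f"cannot draw {n} items from a pool of {len(pool)}")
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def stratified_kfold(
    labels: Sequence, k: int = 10, seed: int | None = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold train/test index splits over ``labels``.

    Folds partition the data, each item is tested exactly once, and per-fold
    class proportions are within one item of the global proportions.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} members; got {dict(zip(classes, counts))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((y.size, 1)), y))


def round_half_away(x, ndigits: int = 2) -> float:
    """Round half away from zero (report rendering; avoids banker's rounding).

    Accepts floats, Decimals, or numeric strings; strings/Decimals are
    rounded in exact decimal arithmetic.
    """
    d = x if isinstance(x, Decimal) else Decimal(str(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Aggregated metrics over repeated balanced cross-validation runs."""

    means: dict[str, float]
    cis: dict[str, tuple[float, float]]
    per_run: dict[str, list[float]]
    n_runs: int
    n_folds: int
    seed: int
    strategy: str
    family: str
    config: dict = field(default_factory=dict)

    def as_percent(self) -> dict[str, float]:
        """Metric means as percentages rounded to two decimals."""
        return {k: round_half_away(100.0 * v) for k, v in self.means.items()}

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "family": self.family,
            "n_runs": self.n_runs,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "means": self.means,
            "means_percent": self.as_percent(),
            "ci95": {k: list(v) for k, v in self.cis.items()},
            "per_run": self.per_run,
            "config": self.config,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def run_experiment(
    X_abnormal: np.ndarray,
    X_normal_pool: np.ndarray,
    classifier: PcgStrategyClassifier | None = None,
    n_runs: int = 50,
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Run the repeated balanced stratified k-fold protocol.

    ``X_abnormal`` and ``X_normal_pool`` are (n_signals, n_beats, 52) feature
    arrays.  Each run subsamples as many normals as there are abnormals,
    cross-validates a fresh clone of ``classifier`` with stratified k-fold,
    averages the four metrics over folds, and the report aggregates run
    means with 95% CIs.  Standardization happens inside the classifier on
    training folds only, so no test information leaks.
    """
    X_abn = np.asarray(X_abnormal, dtype=float)
    X_norm = np.asarray(X_normal_pool, dtype=float)
    if X_abn.ndim != 3 or X_norm.ndim != 3:
        raise ValueError("feature arrays must be (n_signals, n_beats, n_features)")
    if X_abn.shape[0] == 0 or X_norm.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    n_bal = X_abn.shape[0]
    if X_norm.shape[0] < n_bal:
        raise ValueError(
            f"normal pool ({X_norm.shape[0]}) smaller than abnormal count ({n_bal})"
        )
    clf = classifier if classifier is not None else PcgStrategyClassifier()

    per_run: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for r in range(n_runs):
        run_seed = int(seed + r)
        rng = np.random.default_rng(run_seed)
        pick = balanced_subsample(range(X_norm.shape[0]), n_bal, rng)
        X = np.concatenate([X_abn, X_norm[pick]])
        y = np.array(["abnormal"] * n_bal + ["normal"] * n_bal)
        fold_metrics = []
        for train_idx, test_idx in stratified_kfold(y, k=k, seed=run_seed % 2**31):
            model = clone(clf)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            counts = ConfusionCounts.from_labels(y[test_idx], pred)
            fold_metrics.append(compute_metrics(counts))
        for m in METRIC_NAMES:
            per_run[m].append(float(np.mean([getattr(f, m) for f in fold_metrics])))

    means = {m: float(np.mean(per_run[m])) for m in METRIC_NAMES}
    if n_runs >= 2:
        cis = {m: confidence_interval(per_run[m]) for m in METRIC_NAMES}
    else:
        cis = {m: (means[m], means[m]) for m in METRIC_NAMES}
    return EvaluationReport(
        means=means,
        cis=cis,
        per_run=per_run,
        n_runs=n_runs,
        n_folds=k,
        seed=seed,
        strategy=clf.strategy,
        family=clf.family,
        config=clf.get_params(),
    )
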