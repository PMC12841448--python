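"""Evaluation metrics for affinity regression.

Six metrics are reported: MSE, MAE, Pearson, Spearman, concordance index
(CI) and the modified squared correlation rm^2.

Conventions that matter for exact agreement with the affinity-prediction
literature:

* CI counts every ordered pair with strictly greater true affinity; a
  correctly ordered prediction scores 1, a prediction tie scores 0.5, a
  reversal 0. True-value ties are excluded from the normalizer Z. Both an
  O(n^2) reference and an O(n log n) Fenwick-tree implementation are
  provided and agree exactly.
* Spearman uses mean ranks for ties followed by the Pearson of the ranks;
  the classic 1 - 6*sum(d^2)/(n(n^2-1)) shortcut is exact only without ties.
* rm^2 follows Roy's formula  r^2 * (1 - sqrt(|r^2 - r0^2|))  where r^2 is
  the squared correlation of the with-intercept least-squares fit of y on
  y_hat and r0^2 the coefficient of determination of the through-origin
  fit of y on y_hat.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import scipy.stats

from .errors import InvalidParameterError, UndefinedMetricError

__all__ = ["MetricsReport", "mse", "mae", "pearson", "spearman",
           "concordance_index", "concordance_index_slow", "rm2", "evaluate_predictions"]


def _check(y, yhat, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise InvalidParameterError(
            f"length mismatch: {y.shape[0]} true vs {yhat.shape[0]} predicted")
    if y.size < min_n:
        raise InvalidParameterError(f"need at least {min_n} samples, got {y.size}")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise InvalidParameterError("inputs must be finite")
    return y, yhat


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    mae: float
    pearson: float
    spearman: float
    ci: float
    rm2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def mse(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def mae(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def pearson(y, yhat) -> float:
    y, yhat = _check(y, yhat, min_n=2)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedMetricError("Pearson undefined for constant input")
    return float(np.corrcoef(y, yhat)[0, 1])


def spearman(y, yhat) -> float:
    y, yhat = _check(y, yhat, min_n=2)
    ry = scipy.stats.rankdata(y)         # mean ranks for ties
    ryh = scipy.stats.rankdata(yhat)
    if np.ptp(ry) == 0 or np.ptp(ryh) == 0:
        raise UndefinedMetricError("Spearman undefined for constant input")
    return float(np.corrcoef(ry, ryh)[0, 1])


def concordance_index_slow(y, yhat) -> float:
    """O(n^2) reference CI by direct pair enumeration."""
    y, yhat = _check(y, yhat, min_n=2)
    diff_y = y[:, None] - y[None, :]
    diff_p = yhat[:, None] - yhat[None, :]
    greater = diff_y > 0
    z = int(greater.sum())
    if z == 0:
        raise UndefinedMetricError("CI undefined: all true values equal")
    credit = np.where(diff_p > 0, 1.0, np.where(diff_p == 0, 0.5, 0.0))
    return float((credit * greater).sum() / z)


class _Fenwick:
    def __init__(self, n: int):
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:
        i += 1
        while i < self.tree.size:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        """Count of inserted values with index <= i."""
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def concordance_index(y, yhat) -> float:
    """O(n log n) CI via a Fenwick tree over compressed prediction ranks.

    Items are processed in ascending true-value order, one tie-group at a
    time; for each item the counts of previously inserted predictions that
    are smaller (credit 1) or equal (credit 0.5) are read off the tree.
    """
    y, yhat = _check(y, yhat, min_n=2)
    n = y.size
    order = np.lexsort((yhat, y))
    ys, ps = y[order], yhat[order]
    _, pred_idx = np.unique(ps, return_inverse=True)
    tree = _Fenwick(int(pred_idx.max()) + 1)

    numer = 0.0
    z = 0
    inserted = 0
    i = 0
    while i < n:
        j = i
        while j < n and ys[j] == ys[i]:
            j += 1
        for t in range(i, j):  # query before inserting the tie group
            pi = int(pred_idx[t])
            less = tree.prefix(pi - 1) if pi > 0 else 0
            equal = tree.prefix(pi) - less
            numer += less + 0.5 * equal
            z += inserted
        for t in range(i, j):
            tree.add(int(pred_idx[t]))
        inserted = j
        i = j
    if z == 0:
        raise UndefinedMetricError("CI undefined: all true values equal")
    return float(numer / z)


def rm2(y, yhat) -> float:
    """Roy's external-validation metric r^2 (1 - sqrt(|r^2 - r0^2|))."""
    y, yhat = _check(y, yhat, min_n=3)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedMetricError("rm2 undefined for constant input")
    denom = float(np.sum(yhat * yhat))
    if denom == 0:
        raise UndefinedMetricError("rm2 undefined: predictions identically zero")
    r = np.corrcoef(y, yhat)[0, 1]
    r2 = r * r
    k = float(np.sum(y * yhat)) / denom          # through-origin slope of y on yhat
    ss_res0 = float(np.sum((y - k * yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r02))))


def evaluate_predictions(y, yhat) -> MetricsReport:
    """All six metrics in one report."""
    y, yhat = _check(y, yhat, min_n=2)
    return MetricsReport(
        mse=mse(y, yhat), mae=mae(y, yhat),
        pearson=pearson(y, yhat), spearman=spearman(y, yhat),
        ci=concordance_index(y, yhat), rm2=rm2(y, yhat), n=int(y.size))
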