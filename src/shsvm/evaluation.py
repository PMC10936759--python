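"""Cross-validated model selection and rank-based classifier comparison.

Two halves live here:

* :func:`kfold_cv` — stratified k-fold cross-validation with an inner grid
  search for each outer training fold.  Standardizers and the shared hidden
  space are always fitted inside training folds only, so no test-fold
  information leaks into model selection.
* :func:`friedman_ranks` / :func:`holm_test` / :func:`aggregate_report` —
  the non-parametric comparison of k classifiers over n datasets: per-dataset
  ranks (rank 1 = highest accuracy, ties averaged), the Friedman chi-square
  statistic, and the step-down Holm procedure against a reference method
  with ``z_i = |R_ref - R_i| / SE``, ``SE = sqrt(k (k+1) / (6 n))`` and
  thresholds ``alpha / i``.

:data:`BONN_BENCHMARK_ACCURACIES` holds the reported ten-fold CV accuracies
of eight classifiers on the twelve Bonn two-view scenarios (DS1-DS12); it
demonstrates the rank-comparison workflow on a fixed published matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "GridSpec",
    "CVResult",
    "AccuracyRankTable",
    "default_grids",
    "kfold_cv",
    "friedman_ranks",
    "holm_test",
    "aggregate_report",
    "BONN_BENCHMARK_ACCURACIES",
]


METHODS = ["KNN-A", "KNN-B", "SVM-A", "SVM-B", "SVM-2K", "MV-L2-SVM", "AMVMED", "Proposed"]
_DATASETS = [f"DS{i}" for i in range(1, 13)]

BONN_BENCHMARK_ACCURACIES = pd.DataFrame(
    [
        [0.9098, 0.9176, 0.9432, 0.9521, 0.9754, 0.9543, 0.9643, 0.9876],
        [0.9213, 0.9098, 0.9583, 0.9321, 0.9654, 0.9431, 0.9546, 0.9768],
        [0.9223, 0.9098, 0.9345, 0.9321, 0.9654, 0.9437, 0.9554, 0.9764],
        [0.9214, 0.9097, 0.9067, 0.9164, 0.9567, 0.9511, 0.9598, 0.9690],
        [0.9214, 0.9481, 0.9875, 0.9467, 0.9892, 0.9564, 0.9578, 0.9743],
        [0.9324, 0.9481, 0.9875, 0.9467, 0.9653, 0.9511, 0.9587, 0.9811],
        [0.9331, 0.9325, 0.9481, 0.9435, 0.9563, 0.9673, 0.9543, 0.9781],
        [0.9331, 0.9221, 0.9481, 0.9387, 0.9612, 0.9671, 0.9409, 0.9812],
        [0.9631, 0.9221, 0.9511, 0.9387, 0.9654, 0.9786, 0.9765, 0.9760],
        [0.9318, 0.9543, 0.9345, 0.9245, 0.9534, 0.9501, 0.9534, 0.9756],
        [0.9134, 0.9215, 0.9381, 0.9275, 0.9452, 0.9517, 0.9732, 0.9789],
        [0.9532, 0.9378, 0.9785, 0.9634, 0.9763, 0.9587, 0.9661, 0.9898],
    ],
    index=_DATASETS,
    columns=METHODS,
)
"""Reported mean ten-fold CV accuracies of eight classifiers on DS1-DS12."""


GridSpec = Dict[str, Sequence]
"""Mapping from parameter name to the ordered list of candidate values."""


def default_grids() -> Dict[str, GridSpec]:
    """The standard search grids per method family.

    C and sigma range over powers of two from 2^-8 to 2^8, the coupling
    lambda over {0.1, ..., 1.0}, KNN's k over 1..10 and AMVMED's gamma over
    {0.1, ..., 0.9}.
    """
    pow2 = [2.0**e for e in range(-8, 9)]
    lam = [round(0.1 * i, 1) for i in range(1, 11)]
    gamma = [round(0.1 * i, 1) for i in range(1, 10)]
    return {
        "KNN": {"k": list(range(1, 11))},
        "SVM": {"C": pow2, "sigma": pow2},
        "Proposed": {"C_A": pow2, "C_B": pow2, "sigma": pow2, "lam": lam},
        "AMVMED": {"C_A": pow2, "C_B": pow2, "gamma": gamma},
    }


@dataclass
class CVResult:
    """Outcome of one cross-validated evaluation."""

    fold_accuracies: np.ndarray
    mean: float
    sd: float
    best_params: dict
    fold_params: List[dict] = field(default_factory=list)


def _grid_iter(grid: GridSpec):
    names = list(grid.keys())
    for combo in itertools.product(*(grid[n] for n in names)):
        yield dict(zip(names, combo))


def kfold_cv(
    xa: np.ndarray,
    xb: np.ndarray,
    y: np.ndarray,
    method_factory: Callable[[dict], "object"],
    grid: GridSpec,
    k_folds: int = 10,
    seed: int = 0,
    inner_folds: int = 3,
    standardize: bool = True,
) -> CVResult:
    """Stratified k-fold CV with an inner grid search per outer fold.

    ``method_factory(params)`` must return an estimator with
    ``fit(xa, xb, y)`` and ``predict(xa, xb)``; single-view methods simply
    ignore the second view.  Per-view standardizers are fitted on each
    (inner or outer) training portion only.  Grid ties are broken by
    declaration order.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    y = np.asarray(y, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into "
            f"{k_folds} folds"
        )
    outer = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs: List[float] = []
    fold_params: List[dict] = []

    def run(params, tr_a, tr_b, tr_y, te_a, te_b, te_y) -> float:
        if standardize:
            sa = StandardScaler().fit(tr_a)
            sb = StandardScaler().fit(tr_b)
            tr_a, te_a = sa.transform(tr_a), sa.transform(te_a)
            tr_b, te_b = sb.transform(tr_b), sb.transform(te_b)
        est = method_factory(params)
        est.fit(tr_a, tr_b, tr_y)
        pred = est.predict(te_a, te_b)
        return float(np.mean(pred == te_y))

    for fold_idx, (tr, te) in enumerate(outer.split(xa, y)):
        candidates = list(_grid_iter(grid))
        if len(candidates) > 1:
            inner = StratifiedKFold(
                n_splits=inner_folds, shuffle=True, random_state=seed + 1
            )
            means = []
            for params in candidates:
                scores = [
                    run(params, xa[tr][itr], xb[tr][itr], y[tr][itr],
                        xa[tr][ite], xb[tr][ite], y[tr][ite])
                    for itr, ite in inner.split(xa[tr], y[tr])
                ]
                means.append(np.mean(scores))
            best = candidates[int(np.argmax(means))]  # argmax: first on ties
        else:
            best = candidates[0]
        fold_params.append(best)
        accs.append(run(best, xa[tr], xb[tr], y[tr], xa[te], xb[te], y[te]))

    accs_arr = np.asarray(accs)
    # report the most frequently selected configuration (first on ties)
    keys = [tuple(sorted(p.items())) for p in fold_params]
    best_key = max(dict.fromkeys(keys), key=keys.count)
    best_params = dict(best_key)
    return CVResult(
        fold_accuracies=accs_arr,
        mean=float(accs_arr.mean()),
        sd=float(accs_arr.std(ddof=1)) if len(accs_arr) > 1 else 0.0,
        best_params=best_params,
        fold_params=fold_params,
    )


def friedman_ranks(accuracy: np.ndarray) -> Tuple[np.ndarray, float]:
    """Mean within-dataset ranks (1 = best accuracy) and Friedman chi-square.

    Tied accuracies receive averaged ranks, so every row's ranks sum to
    ``k (k+1) / 2``.
    """
    acc = np.asarray(accuracy, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2 or acc.shape[1] < 2:
        raise ValueError("need an n x k accuracy matrix with n, k >= 2")
    if not np.all(np.isfinite(acc)):
        raise ValueError("accuracy matrix contains non-finite entries")
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in acc])
    mean_ranks = ranks.mean(axis=0)
    n, k = acc.shape
    chi2 = 12.0 * n / (k * (k + 1)) * (np.sum(mean_ranks**2) - k * (k + 1) ** 2 / 4.0)
    return mean_ranks, float(chi2)


@dataclass
class AccuracyRankTable:
    """Holm comparison of every method against a reference method."""

    methods: List[str]
    mean_ranks: np.ndarray
    reference: str
    se: float
    table: pd.DataFrame  # columns: i, algorithm, z, p, holm, rejected

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"Reference: {self.reference} (mean rank "
                 f"{self.mean_ranks[self.methods.index(self.reference)]:.6g}, "
                 f"SE = {self.se:.6g})"]
        lines.append(self.table.to_string(index=False))
        return "\n".join(lines)


def holm_test(
    mean_ranks: np.ndarray,
    reference_index: int,
    n_datasets: int,
    alpha: float = 0.05,
    methods: Sequence[str] | None = None,
) -> AccuracyRankTable:
    """Step-down Holm comparison of all methods against a reference.

    ``z_i = |R_ref - R_i| / SE`` with ``SE = sqrt(k (k+1) / (6 n))``;
    two-sided p-values ``2 (1 - Phi(z))``.  Methods are ordered by
    descending z, the threshold for the method with the i-th largest z is
    ``alpha / (k - i)`` counting down from ``k - 1``, and rejections stop at
    the first non-rejection.
    """
    r = np.asarray(mean_ranks, dtype=float)
    k = len(r)
    if not 0 <= reference_index < k:
        raise ValueError("reference index out of range")
    if n_datasets < 2 or k < 2:
        raise ValueError("need at least two methods and two datasets")
    if methods is None:
        methods = [f"method{i}" for i in range(k)]
    if len(methods) != k:
        raise ValueError("methods list inconsistent with rank vector")
    se = float(np.sqrt(k * (k + 1) / (6.0 * n_datasets)))
    others = [i for i in range(k) if i != reference_index]
    z = np.abs(r[others] - r[reference_index]) / se
    p = 2.0 * stats.norm.sf(z)
    order = np.argsort(-z, kind="stable")
    rows = []
    still_rejecting = True
    for rank_pos, oi in enumerate(order):
        i_label = len(others) - rank_pos  # k-1 for the largest z, down to 1
        thr = alpha / i_label
        reject = still_rejecting and p[oi] < thr
        if not reject:
            still_rejecting = False
        rows.append(
            {
                "i": i_label,
                "algorithm": methods[others[oi]],
                "z": z[oi],
                "p": p[oi],
                "holm": thr,
                "rejected": reject,
            }
        )
    table = pd.DataFrame(rows)
    return AccuracyRankTable(
        methods=list(methods),
        mean_ranks=r,
        reference=methods[reference_index],
        se=se,
        table=table,
    )


def aggregate_report(accuracy: pd.DataFrame) -> Tuple[pd.Series, str]:
    """Per-method mean accuracy (4 decimals) and a small text report."""
    if accuracy.empty:
        raise ValueError("empty accuracy table")
    means = accuracy.mean(axis=0).round(4)
    body = accuracy.round(4).to_string()
    report = f"{body}\n\nAverage\n{means.to_string()}"
    return means, report
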