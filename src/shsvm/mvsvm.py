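"""Two-view SVM trained in the expanded (original + shared hidden) space.

Each view V in {A, B} contributes a margin constraint

    y_i ( w_V' phi(x_i^V) + v_V' phi(Omega x_i^V) + b_V ) >= 1 - xi_i^V,

so the classifier of a view acts jointly on the original features and on
their shared-hidden-space projection; a coupling penalty
``lambda * || v_A - v_B ||^2`` pulls the two hidden-space weight vectors
together.  Eliminating the primal variables yields a box-constrained dual
QP over stacked multipliers ``alpha = (alpha^A, alpha^B)``:

    maximize  1' alpha - 1/2 alpha' K alpha
    s.t.      sum_i alpha_i^A y_i = 0,  sum_i alpha_i^B y_i = 0,
              0 <= alpha^A <= C_A,      0 <= alpha^B <= C_B,

where the block kernel K combines original-space Gram matrices with
hidden-space Gram matrices weighted by ``(1+2*lam)/(1+4*lam)`` on the
diagonal blocks and ``2*lam/(1+4*lam)`` off-diagonal, each multiplied
elementwise by ``y y'``.  At ``lam = 0`` the off-diagonal block vanishes and
the problem decouples into two independent extended-view SVMs.

The decision function averages the two per-view scores.  Biases are not
determined by the dual and are recovered from the KKT margin conditions:
every training point with a multiplier strictly inside its box sits exactly
on the margin of its view.

The QP is solved with an equality-constrained interior solver followed by
an active-set polishing pass that solves the reduced KKT system exactly,
which brings the KKT residuals to solver tolerance (1e-6) or better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize
from sklearn.metrics.pairwise import rbf_kernel

from .hidden_space import HiddenSpaceConfig, HiddenSpaceModel, fit_shared_space

__all__ = [
    "MVSVMConfig",
    "KernelBlocks",
    "MVSVMModel",
    "SVMModel",
    "gaussian_gram",
    "build_kernel_blocks",
    "solve_dual",
    "recover_bias",
    "decision_function",
    "fit",
    "predict",
    "svm_single_view",
    "fit_svm_precomputed",
    "kkt_residuals",
]

KKT_TOL = 1e-6


def gaussian_gram(x: np.ndarray, y_mat: Optional[np.ndarray], sigma: float) -> np.ndarray:
    """Gaussian kernel Gram matrix K(x, y) = exp(-||x-y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    return rbf_kernel(x, y_mat, gamma=1.0 / (2.0 * sigma**2))


@dataclass(frozen=True)
class MVSVMConfig:
    """Regularization and kernel settings of the two-view SVM.

    The same Gaussian width ``sigma`` is used for the original-space and
    hidden-space kernels.  ``hidden_model`` may supply a pre-trained shared
    space; otherwise ``hidden_config`` controls how one is fitted from the
    training views.
    """

    C_A: float = 1.0
    C_B: float = 1.0
    lam: float = 0.5
    sigma: float = 1.0
    hidden_model: Optional[HiddenSpaceModel] = None
    hidden_config: Optional[HiddenSpaceConfig] = None

    def __post_init__(self) -> None:
        if self.C_A <= 0 or self.C_B <= 0:
            raise ValueError("C_A and C_B must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def diag_coeff(self) -> float:
        return (1.0 + 2.0 * self.lam) / (1.0 + 4.0 * self.lam)

    @property
    def cross_coeff(self) -> float:
        return 2.0 * self.lam / (1.0 + 4.0 * self.lam)


@dataclass
class KernelBlocks:
    """Raw Gram matrices and the assembled signed dual kernel."""

    kxa: np.ndarray = field(repr=False)
    kxb: np.ndarray = field(repr=False)
    kha: np.ndarray = field(repr=False)
    khb: np.ndarray = field(repr=False)
    khab: np.ndarray = field(repr=False)  # khab[i, j] = K(h_i^A, h_j^B)
    k_a: np.ndarray = field(repr=False)
    k_b: np.ndarray = field(repr=False)
    k_ab: np.ndarray = field(repr=False)
    k_full: np.ndarray = field(repr=False)
    diag_coeff: float = 1.0
    cross_coeff: float = 0.0

    @property
    def n(self) -> int:
        return self.kxa.shape[0]


def build_kernel_blocks(
    xa: np.ndarray,
    xb: np.ndarray,
    ha: np.ndarray,
    hb: np.ndarray,
    y: np.ndarray,
    config: MVSVMConfig,
) -> KernelBlocks:
    """Assemble the 2N x 2N dual kernel from original and hidden projections.

    Diagonal blocks: ``[K(x^V, x^V) + c1 K(h^V, h^V)] o y y'`` with
    ``c1 = (1+2 lam)/(1+4 lam)``; off-diagonal: ``c2 K(h^A, h^B) o y y'``
    with ``c2 = 2 lam/(1+4 lam)`` (``o`` is the elementwise product).  The
    result is positive semidefinite by construction (Schur product of PSD
    matrices).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    for name, m in (("xa", xa), ("xb", xb), ("ha", ha), ("hb", hb)):
        if np.asarray(m).shape[0] != n:
            raise ValueError(f"{name} has inconsistent sample count")
    c1, c2 = config.diag_coeff, config.cross_coeff
    sig = config.sigma
    kxa = gaussian_gram(xa, None, sig)
    kxb = gaussian_gram(xb, None, sig)
    kha = gaussian_gram(ha, None, sig)
    khb = gaussian_gram(hb, None, sig)
    khab = gaussian_gram(ha, hb, sig)
    yy = np.outer(y, y)
    k_a = (kxa + c1 * kha) * yy
    k_b = (kxb + c1 * khb) * yy
    k_ab = c2 * khab * yy
    k_full = np.block([[k_a, k_ab], [k_ab.T, k_b]])
    if not np.all(np.isfinite(k_full)):
        raise ValueError("kernel blocks contain non-finite entries")
    return KernelBlocks(
        kxa=kxa, kxb=kxb, kha=kha, khb=khb, khab=khab,
        k_a=k_a, k_b=k_b, k_ab=k_ab, k_full=k_full,
        diag_coeff=c1, cross_coeff=c2,
    )


# ---------------------------------------------------------------------------
# box-constrained QP with per-view equality constraints
# ---------------------------------------------------------------------------


def _kkt_report(
    alpha: np.ndarray, k: np.ndarray, eq_rows: np.ndarray, upper: np.ndarray
) -> dict:
    """KKT residuals of min 1/2 a'Ka - 1'a  s.t. eq_rows @ a = 0, 0<=a<=upper."""
    g = k @ alpha - 1.0
    # estimate equality multipliers from free variables (least squares over all)
    free = (alpha > 1e-7 * upper) & (alpha < upper * (1 - 1e-7))
    if np.any(free):
        a_free = eq_rows[:, free]
        beta, *_ = np.linalg.lstsq(a_free.T, -g[free], rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(eq_rows.T, -g, rcond=None)
    lag = g + eq_rows.T @ beta
    stat = np.zeros_like(alpha)
    at_lo = alpha <= 1e-7 * upper
    at_up = alpha >= upper * (1 - 1e-7)
    interior = ~(at_lo | at_up)
    stat[interior] = np.abs(lag[interior])
    stat[at_lo] = np.maximum(0.0, -lag[at_lo])  # multiplier must be >= 0
    stat[at_up] = np.maximum(0.0, lag[at_up])
    return {
        "stationarity": float(stat.max(initial=0.0)),
        "equality": float(np.max(np.abs(eq_rows @ alpha), initial=0.0)),
        "bounds": float(
            max(np.max(-alpha, initial=0.0), np.max(alpha - upper, initial=0.0))
        ),
        "beta": beta,
    }


def kkt_residuals(alpha: np.ndarray, blocks: KernelBlocks, y: np.ndarray,
                  C_A: float, C_B: float) -> dict:
    """Stationarity / feasibility residuals of a candidate dual solution."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    eq = np.zeros((2, 2 * n))
    eq[0, :n] = y
    eq[1, n:] = y
    upper = np.concatenate([np.full(n, C_A), np.full(n, C_B)])
    return _kkt_report(np.asarray(alpha, dtype=float), blocks.k_full, eq, upper)


def _active_set_polish(
    k: np.ndarray,
    eq_rows: np.ndarray,
    upper: np.ndarray,
    alpha0: np.ndarray,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Refine a near-solution by exactly solving the reduced KKT system.

    Classifies variables as at-lower / at-upper / free from ``alpha0``, solves
    the equality-constrained QP on the free set by a direct linear solve, and
    re-classifies until the partition is consistent with the KKT sign
    conditions.  Falls back to ``alpha0`` if the sweeps fail to settle.
    """
    n = len(alpha0)
    ridge = 1e-12 * (np.trace(k) / n + 1.0)
    tol = 1e-9 * (1.0 + upper.max())
    alpha = np.clip(alpha0, 0.0, upper)
    at_lo = alpha <= 1e-6 * upper
    at_up = alpha >= upper * (1 - 1e-6)
    best = None
    for _ in range(max_sweeps):
        free = ~(at_lo | at_up)
        fixed_up = at_up & ~at_lo
        a_fix = np.where(fixed_up, upper, 0.0)
        m = eq_rows.shape[0]
        nf = int(free.sum())
        cand = a_fix.copy()
        if nf:
            kff = k[np.ix_(free, free)] + ridge * np.eye(nf)
            af = eq_rows[:, free]
            rhs = np.concatenate(
                [1.0 - k[np.ix_(free, ~free)] @ a_fix[~free], -eq_rows[:, ~free] @ a_fix[~free]]
            )
            kkt = np.block([[kff, af.T], [af, np.zeros((m, m))]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            cand[free] = sol[:nf]
        # re-classify: bound violations join the bound sets, wrong-signed
        # multipliers leave them
        viol_lo = free & (cand < -tol)
        viol_up = free & (cand > upper + tol)
        g = k @ cand - 1.0
        if nf:
            beta = sol[nf:]
        else:
            beta, *_ = np.linalg.lstsq(eq_rows.T, -g, rcond=None)
        lag = g + eq_rows.T @ beta
        rel_lo = at_lo & (lag < -tol)
        rel_up = at_up & (lag > tol)
        if not (viol_lo.any() or viol_up.any() or rel_lo.any() or rel_up.any()):
            best = np.clip(cand, 0.0, upper)
            break
        at_lo = (at_lo & ~rel_lo) | viol_lo
        at_up = (at_up & ~rel_up) | viol_up
    if best is None:
        return np.clip(alpha0, 0.0, upper)
    return best


def _solve_box_qp(
    k: np.ndarray, eq_rows: np.ndarray, upper: np.ndarray
) -> np.ndarray:
    """min 1/2 a'Ka - 1'a subject to eq_rows @ a = 0 and 0 <= a <= upper."""
    n = k.shape[0]
    x0 = np.minimum(upper, 1e-3) * 0.5

    def fun(a):
        return 0.5 * a @ k @ a - a.sum()

    def jac(a):
        return k @ a - 1.0

    res = minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda a: k,
        method="trust-constr",
        bounds=Bounds(np.zeros(n), upper),
        constraints=[LinearConstraint(eq_rows, 0.0, 0.0)],
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 3000, "verbose": 0},
    )
    return _active_set_polish(k, eq_rows, upper, res.x)


def _psd_repair(k: np.ndarray) -> np.ndarray:
    """Check PSD within tolerance; apply one ridge jitter, else fail loudly."""
    n = k.shape[0]
    scale = max(np.trace(k) / n, 1e-30)
    min_eig = float(np.linalg.eigvalsh(k)[0])
    if min_eig >= -1e-8 * scale * n:
        return k
    jittered = k + (1e-10 * np.trace(k) / n) * np.eye(n)
    if float(np.linalg.eigvalsh(jittered)[0]) < -1e-8 * scale * n:
        raise ValueError(f"dual kernel is not PSD (min eigenvalue {min_eig:.3e})")
    return jittered


def solve_dual(
    blocks: KernelBlocks, y: np.ndarray, C_A: float, C_B: float
) -> np.ndarray:
    """Solve the two-view dual QP; returns stacked multipliers (2N,).

    Enforces both per-view equality constraints and the per-view boxes;
    raises if the labels contain a single class or if the KKT residuals of
    the returned solution exceed 1e-6.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(np.sign(y))) < 2:
        raise ValueError("dual is infeasible in a useful sense: single-class labels")
    n = len(y)
    k = _psd_repair(blocks.k_full)
    eq = np.zeros((2, 2 * n))
    eq[0, :n] = y
    eq[1, n:] = y
    upper = np.concatenate([np.full(n, C_A), np.full(n, C_B)])
    alpha = _solve_box_qp(k, eq, upper)
    report = _kkt_report(alpha, k, eq, upper)
    worst = max(report["stationarity"] / (1.0 + abs(k @ alpha - 1.0).max()),
                report["equality"], report["bounds"])
    if worst > KKT_TOL:
        raise RuntimeError(
            f"QP solution failed the KKT check (residual {worst:.3e} > {KKT_TOL})"
        )
    return alpha


def _train_scores(alpha: np.ndarray, blocks: KernelBlocks, y: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-view decision scores (without bias) at the training points."""
    n = blocks.n
    wa = alpha[:n] * y
    wb = alpha[n:] * y
    c1, c2 = blocks.diag_coeff, blocks.cross_coeff
    fa = blocks.kxa @ wa + c1 * (blocks.kha @ wa) + c2 * (blocks.khab @ wb)
    fb = blocks.kxb @ wb + c1 * (blocks.khb @ wb) + c2 * (blocks.khab.T @ wa)
    return fa, fb


def recover_bias(
    alpha: np.ndarray, blocks: KernelBlocks, y: np.ndarray, C_A: float, C_B: float
) -> Tuple[float, float]:
    """Per-view bias from the KKT margin conditions.

    Margin vectors (multipliers strictly inside the box) satisfy
    ``y_i * f_V(x_i) = 1`` exactly, so ``b_V`` is averaged over them.  If a
    view has no margin vector, the bound vectors still bracket the feasible
    bias interval and its midpoint is used.
    """
    y = np.asarray(y, dtype=float)
    n = blocks.n
    fa, fb = _train_scores(np.asarray(alpha, dtype=float), blocks, y)

    def bias_for(scores: np.ndarray, a: np.ndarray, c: float) -> float:
        margin = (a > 1e-8 * c) & (a < c * (1 - 1e-8))
        if np.any(margin):
            return float(np.mean(y[margin] - scores[margin]))
        # no margin vector: the inequality constraints at the bound vectors
        # still bracket b (alpha=0 gives y*f>=1, alpha=C gives y*f<=1)
        lo, hi = -np.inf, np.inf
        for i in range(len(a)):
            bound = y[i] - scores[i]
            at_lo = a[i] <= 1e-8 * c
            if (at_lo and y[i] > 0) or (not at_lo and y[i] < 0):
                lo = max(lo, bound)
            else:
                hi = min(hi, bound)
        if np.isfinite(lo) and np.isfinite(hi):
            return float((lo + hi) / 2.0)
        if np.isfinite(lo):
            return float(lo)
        if np.isfinite(hi):
            return float(hi)
        return 0.0

    b_a = bias_for(fa, alpha[:n], C_A)
    b_b = bias_for(fb, alpha[n:], C_B)
    return b_a, b_b


@dataclass
class MVSVMModel:
    """Trained two-view SVM: dual coefficients plus stored expansions."""

    alpha: np.ndarray
    b_a: float
    b_b: float
    config: MVSVMConfig
    hidden: HiddenSpaceModel
    xa: np.ndarray = field(repr=False)
    xb: np.ndarray = field(repr=False)
    ha: np.ndarray = field(repr=False)
    hb: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def n_train(self) -> int:
        return len(self.y)


def decision_function(
    model: MVSVMModel, xa: np.ndarray, xb: np.ndarray
) -> np.ndarray:
    """Averaged two-view decision score for query points (rows).

    ``f(x) = 1/2 (f_A + f_B)`` where each per-view score expands
    ``w_V`` over original-space kernels and ``v_V`` over hidden-space
    kernels of both views' training projections.
    """
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    if xa.shape[1] != model.xa.shape[1] or xb.shape[1] != model.xb.shape[1]:
        raise ValueError("query dimension does not match the training views")
    cfg = model.config
    n = model.n_train
    wa = model.alpha[:n] * model.y
    wb = model.alpha[n:] * model.y
    c1, c2 = cfg.diag_coeff, cfg.cross_coeff
    ha_q = xa @ model.hidden.omega.T
    hb_q = xb @ model.hidden.omega.T
    sig = cfg.sigma
    fa = (
        gaussian_gram(xa, model.xa, sig) @ wa
        + c1 * (gaussian_gram(ha_q, model.ha, sig) @ wa)
        + c2 * (gaussian_gram(ha_q, model.hb, sig) @ wb)
        + model.b_a
    )
    fb = (
        gaussian_gram(xb, model.xb, sig) @ wb
        + c1 * (gaussian_gram(hb_q, model.hb, sig) @ wb)
        + c2 * (gaussian_gram(hb_q, model.ha, sig) @ wa)
        + model.b_b
    )
    return 0.5 * (fa + fb)


def _unpack(dataset) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if hasattr(dataset, "xa"):
        return (
            np.asarray(dataset.xa, dtype=float),
            np.asarray(dataset.xb, dtype=float),
            np.asarray(dataset.y, dtype=float),
        )
    xa, xb, y = dataset
    return np.asarray(xa, dtype=float), np.asarray(xb, dtype=float), np.asarray(y, dtype=float)


def fit(dataset, config: MVSVMConfig) -> MVSVMModel:
    """Train the two-view SVM (shared space, kernel blocks, dual, biases).

    ``dataset`` is a :class:`~shsvm.synthetic.TwoViewDataset` or an
    ``(xa, xb, y)`` tuple.  If the configuration does not carry a
    pre-trained hidden-space model, one is fitted on the training views.
    """
    xa, xb, y = _unpack(dataset)
    hidden = config.hidden_model
    if hidden is None:
        hcfg = config.hidden_config
        if hcfg is None:
            hcfg = HiddenSpaceConfig(r=min(xa.shape[1] - 1, 6) or 1)
        hidden = fit_shared_space(xa, xb, hcfg)
    if hidden.d != xa.shape[1]:
        raise ValueError("hidden-space dimension does not match the views")
    ha = xa @ hidden.omega.T
    hb = xb @ hidden.omega.T
    blocks = build_kernel_blocks(xa, xb, ha, hb, y, config)
    alpha = solve_dual(blocks, y, config.C_A, config.C_B)
    b_a, b_b = recover_bias(alpha, blocks, y, config.C_A, config.C_B)
    return MVSVMModel(
        alpha=alpha, b_a=b_a, b_b=b_b, config=config, hidden=hidden,
        xa=xa, xb=xb, ha=ha, hb=hb, y=y,
    )


def predict(model: MVSVMModel, dataset) -> np.ndarray:
    """Sign of the averaged decision score; exact zeros map to +1."""
    if hasattr(dataset, "xa"):
        xa, xb = dataset.xa, dataset.xb
    else:
        xa, xb = dataset
    scores = decision_function(model, xa, xb)
    return np.where(scores >= 0.0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# plain single-view SVM (internal consistency oracle / baseline)
# ---------------------------------------------------------------------------


@dataclass
class SVMModel:
    """Soft-margin Gaussian-kernel SVM solved through the same QP path."""

    alpha: np.ndarray
    b: float
    X: Optional[np.ndarray]
    y: np.ndarray
    C: float
    sigma: Optional[float]

    def decision(self, xq: np.ndarray) -> np.ndarray:
        if self.X is None or self.sigma is None:
            raise ValueError("model was fitted on a precomputed Gram matrix")
        k = gaussian_gram(np.atleast_2d(np.asarray(xq, dtype=float)), self.X, self.sigma)
        return k @ (self.alpha * self.y) + self.b

    def predict(self, xq: np.ndarray) -> np.ndarray:
        return np.where(self.decision(xq) >= 0.0, 1.0, -1.0)


def fit_svm_precomputed(gram: np.ndarray, y: np.ndarray, C: float) -> SVMModel:
    """Fit a standard SVM dual on a precomputed (raw, unsigned) Gram matrix."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(np.sign(y))) < 2:
        raise ValueError("SVM training requires both classes")
    n = len(y)
    k = _psd_repair(gram * np.outer(y, y))
    eq = y[None, :].copy()
    upper = np.full(n, float(C))
    alpha = _solve_box_qp(k, eq, upper)
    scores = gram @ (alpha * y)
    margin = (alpha > 1e-8 * C) & (alpha < C * (1 - 1e-8))
    if np.any(margin):
        b = float(np.mean(y[margin] - scores[margin]))
    else:
        lo = [y[i] - scores[i] for i in range(n)
              if (alpha[i] <= 1e-8 * C and y[i] > 0) or (alpha[i] >= C * (1 - 1e-8) and y[i] < 0)]
        hi = [y[i] - scores[i] for i in range(n)
              if (alpha[i] <= 1e-8 * C and y[i] < 0) or (alpha[i] >= C * (1 - 1e-8) and y[i] > 0)]
        lo_v = max(lo) if lo else None
        hi_v = min(hi) if hi else None
        if lo_v is not None and hi_v is not None:
            b = float((lo_v + hi_v) / 2.0)
        else:
            b = float(lo_v if lo_v is not None else (hi_v if hi_v is not None else 0.0))
    return SVMModel(alpha=alpha, b=b, X=None, y=y, C=float(C), sigma=None)


def svm_single_view(X: np.ndarray, y: np.ndarray, C: float, sigma: float) -> SVMModel:
    """Train a plain Gaussian-kernel soft-margin SVM on one view."""
    X = np.asarray(X, dtype=float)
    model = fit_svm_precomputed(gaussian_gram(X, None, sigma), y, C)
    model.X = X
    model.sigma = float(sigma)
    return model
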