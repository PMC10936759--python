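"""Independent log-barrier Newton QP solver used as a test oracle.

Solves  min 1/2 a' K a - 1' a  s.t.  eq @ a = 0,  0 <= a <= upper
with a primal interior-point method (log barrier on the box, Newton steps on
the equality-constrained barrier subproblem).  Entirely independent of the
production solver: different algorithm, no shared code.
"""

from __future__ import annotations

import numpy as np


def barrier_qp(
    k: np.ndarray, eq: np.ndarray, upper: np.ndarray, tol: float = 1e-10
) -> np.ndarray:
    n = k.shape[0]
    m = eq.shape[0]
    # feasible interior start: small mass on each side of every equality row
    a = np.zeros(n)
    for row in eq:
        pos, neg = row > 0, row < 0
        t_val = 0.25 * float(upper.min())
        if pos.sum() and neg.sum():
            a[pos] += t_val / pos.sum()
            a[neg] += t_val / neg.sum()
    a = np.clip(a, 0.05 * upper.min(), 0.95 * upper)
    for _ in range(2):  # re-project onto the equality constraints
        w = np.linalg.solve(eq @ eq.T, -(eq @ a))
        a = a + eq.T @ w
    a = np.clip(a, 1e-8 * upper, (1 - 1e-8) * upper)
    w = np.linalg.solve(eq @ eq.T, -(eq @ a))
    a = a + eq.T @ w
    if a.min() <= 0 or (upper - a).min() <= 0:
        raise RuntimeError("could not build an interior starting point")

    t = 1.0
    for _outer in range(200):
        for _inner in range(100):
            g = t * (k @ a - 1.0) - 1.0 / a + 1.0 / (upper - a)
            h_diag = 1.0 / a**2 + 1.0 / (upper - a) ** 2
            hess = t * k + np.diag(h_diag)
            kkt = np.block([[hess, eq.T], [eq, np.zeros((m, m))]])
            rhs = np.concatenate([-g, -eq @ a])
            sol = np.linalg.solve(kkt, rhs)
            da = sol[:n]
            step = 1.0
            shrink = da < 0
            if shrink.any():
                step = min(step, 0.99 * float(np.min(-a[shrink] / da[shrink])))
            grow = da > 0
            if grow.any():
                step = min(step, 0.99 * float(np.min((upper - a)[grow] / da[grow])))
            decrement = -float(g @ da)
            a = a + step * da
            if abs(decrement) * step < 1e-12 * t:
                break
        if 2 * n / t < tol:
            break
        t *= 8.0
    return a


def qp_objective(a: np.ndarray, k: np.ndarray) -> float:
    return float(0.5 * a @ k @ a - a.sum())
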