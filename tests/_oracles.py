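"""Independent reference computations used as test oracles.

These deliberately avoid the code paths they check: the SVM reference
solves the soft-margin dual QP with scipy's trust-region solver plus an
exact active-set polish, instead of libsvm.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def svm_qp_reference(X: np.ndarray, y01: np.ndarray, C: float, sigma: float):
    """Soft-margin Gaussian SVM via the dual QP.

    maximize  sum(a) - 0.5 a^T (yy^T * K) a
    s.t.      0 <= a <= C,  sum(a_i y_i) = 0

    Returns ``(alpha, y_pm, K, b)``; decision values for new points are
    ``(alpha * y_pm) @ K(X, X_new) + b``.
    """
    n = len(y01)
    ypm = 2.0 * np.asarray(y01, float) - 1.0
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * sigma**2))
    Q = np.outer(ypm, ypm) * K

    res = minimize(
        lambda a: -(a.sum() - 0.5 * a @ Q @ a),
        np.full(n, min(C, 1.0) / 2),
        jac=lambda a: -(1.0 - Q @ a),
        hess=lambda a: Q,
        bounds=[(0.0, C)] * n,
        constraints=[LinearConstraint(ypm[None, :], 0.0, 0.0)],
        method="trust-constr",
        options={"maxiter": 20000, "gtol": 1e-14, "xtol": 1e-16},
    )
    a = np.clip(res.x, 0.0, C)

    # exact KKT solve on the active set identified by the iterative solver
    eps = 1e-5 * max(1.0, C)
    lower = a <= eps
    upper = a >= C - eps
    free = ~(lower | upper)
    if free.any():
        Qff = Q[np.ix_(free, free)]
        yf = ypm[free]
        rhs = 1.0 - Q[np.ix_(free, upper)] @ np.full(int(upper.sum()), C)
        A = np.block([[Qff, yf[:, None]], [yf[None, :], np.zeros((1, 1))]])
        sol = np.linalg.solve(A, np.r_[rhs, -C * ypm[upper].sum()])
        cand = a.copy()
        cand[lower] = 0.0
        cand[upper] = C
        cand[free] = sol[:-1]
        if cand.min() >= -1e-9 and cand.max() <= C + 1e-9:
            a = np.clip(cand, 0.0, C)

    lower = a <= eps
    upper = a >= C - eps
    free = ~(lower | upper)
    f_wo_b = (a * ypm) @ K
    if free.any():
        b = float(np.mean(ypm[free] - f_wo_b[free]))
    else:  # no margin SVs: b bracketed by the KKT inequalities
        slack = ypm - f_wo_b
        lo = (lower & (ypm > 0)) | (upper & (ypm < 0))
        hi = (lower & (ypm < 0)) | (upper & (ypm > 0))
        b = float((slack[lo].min() + slack[hi].max()) / 2)
    return a, ypm, K, b


def qp_decision_values(X_train, y01, C, sigma, X_test) -> np.ndarray:
    a, ypm, _, b = svm_qp_reference(X_train, y01, C, sigma)
    d2 = ((X_train[:, None, :] - X_test[None, :, :]) ** 2).sum(-1)
    Kt = np.exp(-d2 / (2.0 * sigma**2))
    return (a * ypm) @ Kt + b
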