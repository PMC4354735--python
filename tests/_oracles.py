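"""Independent reference solvers used only by the test suite.

These deliberately avoid the package's blockwise-coordinate-descent code
path:

* :func:`fista_sgl` — accelerated proximal gradient (FISTA with adaptive
  restart and backtracking) on the same penalized multinomial likelihood,
  using the exact sparse-group-lasso proximal operator.  Run to ~1e-14
  relative objective change it serves as the high-precision convex oracle.
* :func:`golden_section` — derivative-free unimodal minimization in extended
  precision, the oracle for the inner scalar subproblem.
* :func:`sklearn_l1_logistic` — established L1-penalized logistic regression,
  the alpha = 1 endpoint oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def _nll(X, Y, beta, b):
    eta = X @ beta
    if b is not None:
        eta = eta + b
    full = np.hstack([eta, np.zeros((X.shape[0], 1))])
    return float(logsumexp(full, axis=1).sum() - (Y * full).sum())


def _grad(X, Y, beta, b):
    eta = X @ beta
    if b is not None:
        eta = eta + b
    full = np.hstack([eta, np.zeros((X.shape[0], 1))])
    full -= full.max(axis=1, keepdims=True)
    P = np.exp(full)
    P /= P.sum(axis=1, keepdims=True)
    D = P[:, :-1] - Y[:, :-1]
    return X.T @ D, D.sum(axis=0)


def sgl_prox(v, step, gamma, xi, slices, weights):
    """prox of step * (gamma * sum_J w_J ||.||_2 + xi * ||.||_1): soft
    threshold then groupwise shrinkage."""
    w = np.sign(v) * np.maximum(np.abs(v) - step * xi, 0.0)
    for wt, sl in zip(weights, slices):
        nrm = np.linalg.norm(w[sl])
        thr = step * gamma * wt
        if nrm <= thr:
            w[sl] = 0.0
        else:
            w[sl] *= 1.0 - thr / nrm
    return w


def sgl_penalty(beta, gamma, xi, slices, weights):
    return gamma * sum(w * np.linalg.norm(beta[sl])
                       for w, sl in zip(weights, slices)) \
        + xi * float(np.abs(beta).sum())


def fista_sgl(X, Y, slices, lam, alpha, weights=None, fit_intercept=True,
              max_iter=200000, tol=1e-14):
    """High-precision proximal-gradient solution of the SGL logistic problem.

    Returns ``(beta, intercept, objective)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    k = m - 1
    p = X.shape[1]
    if weights is None:
        weights = np.ones(len(slices))
    gamma, xi = lam * (1.0 - alpha), lam * alpha
    beta = np.zeros((p, k))
    b = np.zeros(k) if fit_intercept else None
    zb, zbi = beta.copy(), (b.copy() if b is not None else None)
    tk = 1.0
    # multinomial logistic smoothness: hessian <= (1/2) sigma_max(X~)^2
    Xa = np.hstack([X, np.ones((n, 1))]) if fit_intercept else X
    L = 0.5 * np.linalg.norm(Xa, 2) ** 2 * max(1, k)
    F = _nll(X, Y, beta, b) + sgl_penalty(beta, gamma, xi, slices, weights)
    stall = 0
    just_restarted = False
    for _it in range(max_iter):
        gb, gi = _grad(X, Y, zb, zbi)
        cand = sgl_prox(zb - gb / L, 1.0 / L, gamma, xi, slices, weights)
        candb = (zbi - gi / L) if b is not None else None
        F_new = _nll(X, Y, cand, candb) \
            + sgl_penalty(cand, gamma, xi, slices, weights)
        if F_new > F:  # adaptive restart on objective increase
            if just_restarted:
                # a plain prox step from the best point cannot decrease the
                # objective any further: numerical optimum reached
                break
            zb = beta.copy()
            zbi = b.copy() if b is not None else None
            tk = 1.0
            just_restarted = True
            continue
        just_restarted = False
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        zb = cand + (tk - 1.0) / tk1 * (cand - beta)
        if b is not None:
            zbi = candb + (tk - 1.0) / tk1 * (candb - b)
        step = float(np.max(np.abs(cand - beta)))
        beta, b, tk = cand, candb, tk1
        if F - F_new < tol * max(1.0, abs(F_new)) and step < 1e-11:
            stall += 1
            if stall >= 10:
                F = F_new
                break
        else:
            stall = 0
        F = F_new
    return beta, b, F


def golden_section(f, lo, hi, iters=200):
    """Golden-section minimization of a unimodal function, in extended
    precision so comparison noise near a flat minimum stays below 1e-9."""
    lo = np.longdouble(lo)
    hi = np.longdouble(hi)
    invphi = (np.sqrt(np.longdouble(5)) - 1) / 2
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = f(x1), f(x2)
    for _ in range(iters):
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = f(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = f(x2)
        if float(hi - lo) < 1e-13 * (1.0 + abs(float(lo))):
            break
    return float((lo + hi) / 2)


def omega(b, c, h, r, gamma, xi):
    """The inner scalar subproblem objective, in the argument's precision."""
    return c * b + 0.5 * h * b * b + gamma * np.sqrt(b * b + r) + xi * abs(b)


def sklearn_l1_logistic(X, y01, lam, tol=1e-12, max_iter=200000):
    """L1-penalized binary logistic fit; returns (coef, intercept) mapped to
    the package's reference-class convention (logit of the *lower* label)."""
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lam, solver="saga",
                             tol=tol, max_iter=max_iter, fit_intercept=True)
    clf.fit(X, y01)
    # sklearn's coef gives the logit of the larger class label; the package
    # uses the largest label as reference, so flip the sign
    return -clf.coef_.ravel(), -float(clf.intercept_[0])
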