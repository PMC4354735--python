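"""Three-loop estimator for the sparse-group-lasso logistic model.

The penalized maximum-likelihood problem  min_b  -l(b) + lam*Phi(b)  is solved
by nested loops:

* **outer** — coordinate gradient descent: expand the smooth loss f = -l at
  the current iterate into a quadratic model Q using the exact gradient and a
  group-block-diagonal curvature (the exact PSD Hessian block of each channel
  group; cross-group curvature zero), solve the penalized quadratic
  subproblem, and take an Armijo backtracking step on the *true* penalized
  objective along Delta = beta_hat - beta_tilde;
* **middle** — blockwise coordinate descent over channel groups: each group is
  either set exactly to zero by a subgradient test or minimized by the inner
  loop;
* **inner** — cyclic coordinate descent on the group subproblem
  omega(b) = c*b + h*b^2/2 + gamma*sqrt(b^2 + r) + xi*|b|, with closed-form
  soft-threshold updates where the group-L2 term is smooth or absent and a
  bracketed root finder otherwise.  A stalled group at zero that fails the
  zero test is pushed off zero along the soft-thresholded negative gradient
  with a line search.

The solver is fully deterministic: fixed cyclic sweep orders, no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (GroupStructure, PenaltySpec, _check_indicator,
                    class_probabilities, group_hessian_blocks,
                    intercept_hessian, log_likelihood, penalty)

__all__ = [
    "SolverSettings", "SGLFit", "fit", "solve_quadratic_subproblem",
    "group_zero_test", "inner_coordinate_update", "descent_direction_at_zero",
    "kkt_residual", "kkt_lambda_max",
]


@dataclass(frozen=True)
class SolverSettings:
    """Tolerances and iteration limits for the three loops.

    All quantities are unitless.  ``outer_tol`` is a relative change of the
    penalized objective; ``middle_tol``/``inner_tol`` are absolute coefficient
    changes; ``zero_threshold`` is the group norm below which a group counts
    as sitting at zero for the stalled-at-zero re-entry check.  When
    ``kkt_tol`` is set, the outer loop additionally iterates until the
    subgradient (KKT) residual falls below it.
    """

    outer_tol: float = 1e-6
    middle_tol: float = 1e-8
    inner_tol: float = 1e-8
    kkt_tol: float | None = None
    max_outer: int = 200
    max_middle: int = 200
    max_inner: int = 1000
    zero_threshold: float = 1e-10
    ls_contraction: float = 0.5
    ls_sufficient_decrease: float = 1e-4
    max_backtracks: int = 60
    group_weight_mode: str = "unit"

    def __post_init__(self):
        for name in ("outer_tol", "middle_tol", "inner_tol", "zero_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_outer", "max_middle", "max_inner"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")


@dataclass
class SGLFit:
    """Converged (or flagged) solution of one penalized fit."""

    beta: np.ndarray
    intercept: np.ndarray | None
    spec: PenaltySpec
    converged: bool
    n_outer: int
    objective_trace: np.ndarray
    kkt: float
    message: str = ""

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def group_zero_test(g_J: np.ndarray, spec: PenaltySpec,
                    weight: float = 1.0) -> bool:
    """Subgradient condition for a whole group being exactly zero.

    True iff ``||T(g_J, lam*alpha)||_2 <= lam*(1-alpha)*w_J`` where T is
    elementwise soft thresholding of the group gradient at the group's
    current zero point.
    """
    g = np.asarray(g_J, dtype=float)
    return float(np.linalg.norm(_soft(g, spec.lam * spec.alpha))) \
        <= spec.lam * (1.0 - spec.alpha) * weight


def _root_stationarity(c: float, h: float, r: float, gamma: float,
                       xi: float, tol: float) -> float:
    """Solve c + xi*s + h*b + gamma*b/sqrt(b^2+r) = 0, s = -sign(c).

    The left side is strictly increasing in b (h > 0), so the root is unique
    and bracketed by [-(|c|-xi)/h, 0] (for c > xi) or its mirror image; a
    safeguarded Newton iteration inside the bracket locates it.
    """
    s = -1.0 if c > 0 else 1.0
    cs = c + xi * s
    if cs > 0:
        lo, hi = -cs / h, 0.0
    else:
        lo, hi = 0.0, -cs / h
    b = 0.5 * (lo + hi)
    ftol = tol * (1.0 + abs(cs))
    for _ in range(200):
        sq = math.sqrt(b * b + r)
        f = cs + h * b + gamma * b / sq
        if -ftol < f < ftol:
            return b
        if f > 0.0:
            hi = b
        else:
            lo = b
        fp = h + gamma * r / (sq * sq * sq)
        bn = b - f / fp
        if not (lo < bn < hi):
            bn = 0.5 * (lo + hi)
        if abs(bn - b) <= 1e-16 * (1.0 + abs(b)):
            return bn
        b = bn
    return b


def inner_coordinate_update(c: float, h: float, r: float, gamma: float,
                            xi: float, tol: float = 1e-10) -> float:
    """Exact minimizer of omega(b) = c*b + h*b^2/2 + gamma*sqrt(b^2+r) + xi*|b|.

    ``c`` is the coordinate's linear term, ``h >= 0`` its curvature,
    ``r >= 0`` the squared L2 norm of the group's other coefficients,
    ``gamma = lam*(1-alpha)*w_J`` and ``xi = lam*alpha``.  Closed-form soft
    thresholding applies when ``h == 0``, ``r == 0`` or ``gamma == 0``;
    otherwise the unique stationary point is found by a bracketed root
    finder.  Zeros are returned exactly.
    """
    if h < 0 or r < 0 or gamma < 0 or xi < 0:
        raise ValueError("h, r, gamma and xi must all be nonnegative")
    if h == 0.0:
        return 0.0
    if r == 0.0 or gamma == 0.0:
        tau = xi + gamma if r == 0.0 else xi
        if c > tau:
            return (tau - c) / h
        if c < -tau:
            return (-tau - c) / h
        return 0.0
    if abs(c) <= xi:
        return 0.0
    return _root_stationarity(c, h, r, gamma, xi, tol)


def descent_direction_at_zero(g_J: np.ndarray, spec: PenaltySpec) -> np.ndarray:
    """Descent direction for a group stalled at zero that fails the zero test.

    Elementwise: zero where |g_i| <= lam*alpha, otherwise the negative
    soft-thresholded gradient -(g_i - lam*alpha*sign(g_i)).
    """
    return -_soft(np.asarray(g_J, dtype=float), spec.lam * spec.alpha)


def _group_quadratic(v: np.ndarray, g: np.ndarray,
                     H: np.ndarray) -> float:
    """Q^(J)(v) = <g, v> + 1/2 v' H_JJ v for one group."""
    quad = np.einsum("jm,jmkn,kn->", v, H, v)
    return float((g * v).sum() + 0.5 * quad)


def _group_penalty(v: np.ndarray, gamma: float, xi: float) -> float:
    return gamma * float(np.linalg.norm(v)) + xi * float(np.abs(v).sum())


def _solve_group(g: np.ndarray, H: np.ndarray, gamma: float, xi: float,
                 v0: np.ndarray, settings: SolverSettings) -> np.ndarray:
    """Inner loop: cyclic coordinate descent on one group's subproblem.

    ``g``/``v0`` have shape (d_J, K); ``H`` (d_J, K, d_J, K) is the group's
    curvature block, so every pair of coordinates may couple through the
    quadratic, and all coordinates couple through the group-L2 term via r.
    The running H v product is maintained incrementally so each coordinate
    update costs one (d_J*K)-vector operation.
    """
    d, k = g.shape
    v = np.array(v0, dtype=float)
    total_sq = float((v * v).sum())
    tol = settings.inner_tol
    for _pass in range(2):
        Hv = np.einsum("jmkn,kn->jm", H, v)
        for _sweep in range(settings.max_inner):
            max_change = 0.0
            for j in range(d):
                for m in range(k):
                    h = H[j, m, j, m]
                    old = v[j, m]
                    c = g[j, m] + Hv[j, m] - h * old
                    r = total_sq - old * old
                    if r < 0.0:
                        r = 0.0
                    new = inner_coordinate_update(c, h, r, gamma, xi, tol)
                    if new != old:
                        total_sq += new * new - old * old
                        v[j, m] = new
                        Hv += (new - old) * H[:, :, j, m]
                        change = abs(new - old)
                        if change > max_change:
                            max_change = change
            if max_change < tol:
                break
        # Algorithm-3 re-entry: cyclic descent can stall exactly at zero when
        # several moderate gradient entries jointly violate the zero test but
        # none individually exceeds the combined threshold.
        if math.sqrt(total_sq) >= settings.zero_threshold:
            break
        g0 = g  # group gradient at zero (v ~ 0 contributes nothing material)
        if np.linalg.norm(_soft(g0, xi)) <= gamma:
            v[:] = 0.0
            break
        delta = -_soft(g0, xi)
        t = 1.0
        moved = False
        for _ in range(settings.max_backtracks):
            w = t * delta
            if _group_quadratic(w, g0, H) + _group_penalty(w, gamma, xi) < 0:
                v = w
                total_sq = float((v * v).sum())
                moved = True
                break
            t *= settings.ls_contraction
        if not moved:
            v[:] = 0.0
            break
    return v


def solve_quadratic_subproblem(q: np.ndarray, blocks: list[np.ndarray],
                               beta_tilde: np.ndarray,
                               groups: GroupStructure, spec: PenaltySpec,
                               settings: SolverSettings,
                               weights: np.ndarray | None = None,
                               q0: np.ndarray | None = None,
                               H0: np.ndarray | None = None,
                               b_tilde: np.ndarray | None = None
                               ) -> tuple[np.ndarray, np.ndarray | None]:
    """Middle loop: blockwise coordinate descent over channel groups.

    Minimizes the penalized quadratic model built at ``beta_tilde`` (gradient
    ``q``, one (d_J, K, d_J, K) curvature block per group in ``blocks``).
    Groups are visited in fixed cyclic order; each is zeroed by the
    subgradient test or handed to the inner loop.  The unpenalized intercept
    block (``q0``/``H0``), if present, is minimized in closed form.
    """
    beta_tilde = np.atleast_2d(np.asarray(beta_tilde, dtype=float).T).T
    q = np.atleast_2d(np.asarray(q, dtype=float).T).T
    k = beta_tilde.shape[1]
    if weights is None:
        weights = spec.resolved_weights(groups, k, settings.group_weight_mode)
    beta_hat = beta_tilde.copy()
    xi = spec.lam * spec.alpha
    for _sweep in range(settings.max_middle):
        max_change = 0.0
        for w_J, sl, H in zip(weights, groups.slices, blocks):
            bt = beta_tilde[sl]
            # group gradient with the group's own contribution removed:
            # g^(J) = q^(J) + [H(beta-beta_tilde)]^(J) - H_JJ beta^(J)
            #       = q^(J) - H_JJ beta_tilde^(J)   (H is group-block diagonal)
            g = q[sl] - np.einsum("jmkn,kn->jm", H, bt)
            old = beta_hat[sl].copy()
            if group_zero_test(g, spec, w_J):
                beta_hat[sl] = 0.0
            else:
                gamma = spec.lam * (1.0 - spec.alpha) * w_J
                beta_hat[sl] = _solve_group(g, H, gamma, xi,
                                            beta_hat[sl], settings)
            change = float(np.max(np.abs(beta_hat[sl] - old), initial=0.0))
            if change > max_change:
                max_change = change
        if max_change < settings.middle_tol:
            break
    b_hat = None
    if q0 is not None:
        # unpenalized block: one exact minimization of the quadratic model
        H0r = np.asarray(H0, dtype=float) + 1e-10 * np.eye(k)
        b_hat = np.asarray(b_tilde, dtype=float) \
            - np.linalg.solve(H0r, np.asarray(q0, dtype=float))
    return beta_hat, b_hat


def fit(X: np.ndarray, Y: np.ndarray, groups: GroupStructure,
        spec: PenaltySpec, settings: SolverSettings | None = None,
        beta0: np.ndarray | None = None,
        intercept0: np.ndarray | None = None,
        fit_intercept: bool = True) -> SGLFit:
    """Outer loop: coordinate gradient descent with Armijo line search.

    ``X`` is assumed standardized by the caller; ``Y`` is the N x M indicator
    matrix.  Each iteration builds the quadratic model at the current point,
    solves it by the middle/inner loops, and backtracks on the true penalized
    objective along ``Delta = beta_hat - beta_tilde``.  Zeros produced by the
    thresholding survive as exact zeros because the converged step is the
    full step to the subproblem solution.
    """
    settings = settings or SolverSettings()
    X = np.asarray(X, dtype=float)
    Y = _check_indicator(Y)
    n, m = Y.shape
    if m < 2:
        raise ValueError("need at least two classes")
    k = m - 1
    p_feat = X.shape[1]
    if p_feat != groups.n_features:
        raise ValueError("group structure does not match X's column count")
    weights = spec.resolved_weights(groups, k, settings.group_weight_mode)

    beta = np.zeros((p_feat, k)) if beta0 is None \
        else np.array(np.atleast_2d(np.asarray(beta0, dtype=float).T).T)
    if fit_intercept:
        if intercept0 is None:
            # intercept-only MLE: log odds of class frequencies vs reference
            props = Y.mean(axis=0)
            props = np.clip(props, 1e-12, None)
            b = np.log(props[:k] / props[k])
        else:
            b = np.asarray(intercept0, dtype=float).copy()
    else:
        b = None

    def full_objective(bet, inter):
        return -log_likelihood(X, Y, bet, inter) \
            + penalty(bet, groups, spec, weights)

    F = full_objective(beta, b)
    trace = [F]
    converged = False
    message = ""
    n_outer = 0
    Yf = Y[:, :k]
    for n_outer in range(1, settings.max_outer + 1):
        if not np.isfinite(F):
            raise FloatingPointError("penalized objective became non-finite")
        P = class_probabilities(X, beta, b)
        D = P[:, :k] - Yf
        q = X.T @ D
        blocks = group_hessian_blocks(X, beta, groups, b)
        # floor the curvature diagonal so coordinates with vanishing observed
        # information can still move; the line search guards descent
        for H in blocks:
            dk = H.shape[0] * H.shape[1]
            flat = H.reshape(dk, dk)
            di = np.diag_indices(dk)
            flat[di] = np.maximum(flat[di], 1e-12)
        if b is not None:
            q0 = D.sum(axis=0)
            H0 = intercept_hessian(X, beta, b)
        else:
            q0 = H0 = None
        beta_hat, b_hat = solve_quadratic_subproblem(
            q, blocks, beta, groups, spec, settings, weights,
            q0=q0, H0=H0, b_tilde=b)
        dbeta = beta_hat - beta
        db = (b_hat - b) if b is not None else None
        dirderiv = float((q * dbeta).sum()) \
            + (float(q0 @ db) if db is not None else 0.0) \
            + penalty(beta_hat, groups, spec, weights) \
            - penalty(beta, groups, spec, weights)
        if dirderiv > -1e-14 * max(1.0, abs(F)):
            converged = True
            break
        eta0 = X @ beta + (b if b is not None else 0.0)
        eta_d = X @ dbeta + (db if db is not None else 0.0)
        t = 1.0
        accepted = False
        for _bt in range(settings.max_backtracks):
            if t == 1.0:
                cand_beta, cand_b = beta_hat, b_hat
            else:
                cand_beta = beta + t * dbeta
                cand_b = (b + t * db) if b is not None else None
            logits = np.hstack([eta0 + t * eta_d, np.zeros((n, 1))])
            mx = logits.max(axis=1, keepdims=True)
            ll = float((Y * logits).sum()
                       - (mx + np.log(np.exp(logits - mx)
                                      .sum(axis=1, keepdims=True))).sum())
            F_new = -ll + penalty(cand_beta, groups, spec, weights)
            if F_new <= F + settings.ls_sufficient_decrease * t * dirderiv:
                accepted = True
                break
            t *= settings.ls_contraction
        if not accepted:
            message = "line search failed to find sufficient decrease"
            break
        beta, b = (cand_beta.copy() if t < 1.0 else beta_hat), \
            (cand_b.copy() if (b is not None and t < 1.0) else cand_b)
        rel_change = (F - F_new) / max(1.0, abs(F_new))
        F = F_new
        trace.append(F)
        if t == 1.0 and rel_change <= settings.outer_tol:
            if settings.kkt_tol is not None:
                # optional optimality-based stop: keep iterating until the
                # subgradient residual is below the requested level
                if kkt_residual(X, Y, beta, groups, spec, intercept=b,
                                weights=weights) >= settings.kkt_tol:
                    continue
            converged = True
            break
    if not converged and not message:
        message = "maximum outer iterations reached without convergence"
    resid = kkt_residual(X, Y, beta, groups, spec, intercept=b,
                         weights=weights)
    return SGLFit(beta=beta, intercept=b, spec=spec, converged=converged,
                  n_outer=n_outer, objective_trace=np.asarray(trace),
                  kkt=resid, message=message)


def kkt_residual(X: np.ndarray, Y: np.ndarray, beta: np.ndarray,
                 groups: GroupStructure, spec: PenaltySpec,
                 intercept: np.ndarray | None = None,
                 weights: np.ndarray | None = None) -> float:
    """Maximum violation of the sparse-group-lasso optimality conditions.

    Zero (up to floating error) exactly at the minimizer of the penalized
    objective.  Covers three cases per group — the whole group at zero, a
    zero coordinate inside an active group, and an active coordinate — plus
    intercept stationarity when intercepts are present.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float).T).T
    k = beta.shape[1]
    if weights is None:
        weights = spec.resolved_weights(groups, k)
    Y = _check_indicator(Y)
    P = class_probabilities(X, beta, intercept)
    D = P[:, :k] - Y[:, :k]
    G = np.asarray(X).T @ D
    lam, alpha = spec.lam, spec.alpha
    worst = 0.0
    for w_J, sl in zip(weights, groups.slices):
        bJ = beta[sl]
        gJ = G[sl]
        nrm = np.linalg.norm(bJ)
        if nrm == 0.0:
            viol = np.linalg.norm(_soft(gJ, lam * alpha)) \
                - lam * (1.0 - alpha) * w_J
            worst = max(worst, viol)
            continue
        grp_sub = lam * (1.0 - alpha) * w_J * bJ / nrm
        nz = bJ != 0
        if nz.any():
            viol = np.max(np.abs(gJ[nz] + lam * alpha * np.sign(bJ[nz])
                                 + grp_sub[nz]))
            worst = max(worst, viol)
        if (~nz).any():
            viol = np.max(np.abs(gJ[~nz] + grp_sub[~nz]) - lam * alpha)
            worst = max(worst, viol)
    if intercept is not None:
        worst = max(worst, float(np.max(np.abs(D.sum(axis=0)))))
    return float(max(worst, 0.0))


def kkt_lambda_max(X: np.ndarray, Y: np.ndarray, groups: GroupStructure,
                   alpha: float, weights: np.ndarray | None = None,
                   fit_intercept: bool = True) -> float:
    """Smallest lam for which the all-zero coefficient solution is optimal.

    With intercepts enabled the gradient is taken at the intercept-only
    maximum likelihood point (class-frequency probabilities); otherwise at
    uniform probabilities.  Found per group in closed form at the alpha
    endpoints and by bisection on the monotone zero-test condition in
    between.
    """
    Y = _check_indicator(Y)
    n, m = Y.shape
    k = m - 1
    if weights is None:
        weights = np.ones(groups.n_groups)
    if fit_intercept:
        props = Y.mean(axis=0)
        Pf = np.tile(props[:k], (n, 1))
    else:
        Pf = np.full((n, k), 1.0 / m)
    G = np.asarray(X, dtype=float).T @ (Pf - Y[:, :k])
    lam_max = 0.0
    for w_J, sl in zip(weights, groups.slices):
        g = G[sl]
        if alpha >= 1.0:
            lam_J = float(np.max(np.abs(g)))
        elif alpha <= 0.0:
            lam_J = float(np.linalg.norm(g)) / max(w_J, 1e-300)
        else:
            hi = float(np.max(np.abs(g))) / alpha
            lo = 0.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                ok = np.linalg.norm(_soft(g, mid * alpha)) \
                    <= mid * (1.0 - alpha) * w_J
                if ok:
                    hi = mid
                else:
                    lo = mid
                if hi - lo <= 1e-13 * max(1.0, hi):
                    break
            lam_J = hi
        lam_max = max(lam_max, lam_J)
    return lam_max
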