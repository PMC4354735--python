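"""Penalized multinomial logistic regression with a sparse group lasso penalty.

The classifier assigns trial ``i`` with fused feature vector ``x_i`` to one of
``M`` classes through the multinomial logit model

    P(g_i = m | x_i) = exp(x_i b_m) / sum_l exp(x_i b_l),

with the last class as reference (``x_i b_M = 0``), so the free coefficients
form a ``(p*d) x (M-1)`` matrix.  Channel selection and within-channel feature
selection are induced by the sparse group lasso penalty

    lam * Phi(b) = lam*(1-alpha) * sum_J w_J ||b^(J)||_2 + lam*alpha * ||b||_1,

where group ``J`` collects all free coefficients of one channel's feature
block.  ``alpha = 0`` recovers the group lasso (channel selection only) and
``alpha = 1`` the lasso (feature selection only).

This module provides the objective pieces (probabilities, log-likelihood,
penalty, gradient, block-diagonal curvature); the estimation loops live in
:mod:`sgleeg.solver`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp


class GroupStructure:
    """Partition of feature columns into contiguous channel groups.

    Parameters
    ----------
    group_index : array of int, shape (n_features,)
        Group (channel) id per feature column.  Columns of a common group
        must be contiguous.
    """

    def __init__(self, group_index: Sequence[int]):
        gi = np.asarray(group_index)
        if gi.ndim != 1 or gi.size == 0:
            raise ValueError("group_index must be a nonempty 1-D sequence")
        ids = []
        starts = [0]
        for k in range(1, gi.size):
            if gi[k] != gi[k - 1]:
                starts.append(k)
        bounds = starts + [gi.size]
        ids = [gi[s] for s in starts]
        if len(set(map(int, ids))) != len(ids):
            raise ValueError("group blocks must be contiguous (a group id "
                             "appears in more than one block)")
        self.group_index = gi
        self.ids = np.asarray(ids)
        self.slices = [slice(bounds[k], bounds[k + 1]) for k in range(len(ids))]
        self.sizes = np.asarray([s.stop - s.start for s in self.slices])

    @classmethod
    def from_sizes(cls, n_groups: int, group_size: int) -> "GroupStructure":
        return cls(np.repeat(np.arange(n_groups), group_size))

    @property
    def n_features(self) -> int:
        return int(self.group_index.size)

    @property
    def n_groups(self) -> int:
        return len(self.slices)

    def weights(self, mode: str = "unit", n_free_classes: int = 1) -> np.ndarray:
        """Group weights w_J: all-ones, or sqrt of the coefficient count."""
        if mode == "unit":
            return np.ones(self.n_groups)
        if mode == "sqrt_size":
            return np.sqrt(self.sizes * n_free_classes).astype(float)
        raise ValueError(f"unknown group weight mode {mode!r}")


@dataclass(frozen=True)
class PenaltySpec:
    """Sparse group lasso penalty parameters.

    lam >= 0 is the overall strength; alpha in [0, 1] trades the group-L2
    term (channel sparsity) against the L1 term (feature sparsity);
    group_weights (optional, default all ones) multiply the group-L2 terms.
    """

    lam: float
    alpha: float
    group_weights: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")
        if self.group_weights is not None:
            w = np.asarray(self.group_weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("group weights must be nonnegative")
            object.__setattr__(self, "group_weights", w)

    def resolved_weights(self, groups: GroupStructure,
                         n_free_classes: int = 1,
                         mode: str = "unit") -> np.ndarray:
        if self.group_weights is not None:
            if self.group_weights.size != groups.n_groups:
                raise ValueError("group_weights length does not match the "
                                 "number of groups")
            return self.group_weights
        return groups.weights(mode, n_free_classes)


def indicator_from_labels(y: Sequence, classes: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Build the N x M one-hot indicator matrix Y from class labels.

    Classes are sorted ascending; the last one is the reference class of the
    logit parametrization.
    """
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    else:
        classes = np.asarray(classes)
        if not np.isin(y, classes).all():
            raise ValueError("labels contain values outside the class set")
    if classes.size < 2:
        raise ValueError("labels must take at least 2 distinct values")
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _check_indicator(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or not np.all((Y == 0) | (Y == 1)) \
            or not np.allclose(Y.sum(axis=1), 1.0):
        raise ValueError("Y must be a 0/1 indicator matrix with one 1 per row")
    return Y


def _full_logits(X: np.ndarray, beta: np.ndarray,
                 intercept: np.ndarray | None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 1:
        beta = beta[:, None]
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: X has {X.shape[1]} columns but "
            f"beta has {beta.shape[0]} rows")
    eta = X @ beta
    if intercept is not None:
        eta = eta + np.asarray(intercept, dtype=float)[None, :]
    return np.hstack([eta, np.zeros((X.shape[0], 1))])


def class_probabilities(X: np.ndarray, beta: np.ndarray,
                        intercept: np.ndarray | None = None) -> np.ndarray:
    """Class membership probabilities, computed with log-sum-exp stabilization.

    Returns an N x M matrix whose rows sum to one; the last column is the
    reference class.
    """
    logits = _full_logits(X, beta, intercept)
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    return expl / expl.sum(axis=1, keepdims=True)


def log_likelihood(X: np.ndarray, Y: np.ndarray, beta: np.ndarray,
                   intercept: np.ndarray | None = None) -> float:
    """Multinomial log-likelihood sum_i [x_i b_{g_i} - ln sum_l exp(x_i b_l)]."""
    Y = _check_indicator(Y)
    logits = _full_logits(X, beta, intercept)
    if Y.shape != logits.shape:
        raise ValueError("Y shape does not match the number of samples/classes")
    return float((Y * logits).sum() - logsumexp(logits, axis=1).sum())


def penalty(beta: np.ndarray, groups: GroupStructure, spec: PenaltySpec,
            weights: np.ndarray | None = None) -> float:
    """The penalty term lam * Phi(beta) of the objective."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float).T).T
    if weights is None:
        weights = spec.resolved_weights(groups, beta.shape[1])
    group_part = sum(
        w * np.linalg.norm(beta[sl]) for w, sl in zip(weights, groups.slices))
    l1_part = np.abs(beta).sum()
    return float(spec.lam * ((1.0 - spec.alpha) * group_part
                             + spec.alpha * l1_part))


def gradient(X: np.ndarray, Y: np.ndarray, beta: np.ndarray,
             intercept: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradient of the negative log-likelihood f = -l(beta).

    Returns ``(G, g0)`` where ``G = X^T (P_free - Y_free)`` is the
    (n_features x (M-1)) coefficient gradient and ``g0`` the intercept
    gradient (column sums of the same residual).  ``Y`` may be fractional
    (rows on the probability simplex); the gradient is linear in it.
    """
    Y = np.asarray(Y, dtype=float)
    P = class_probabilities(X, beta, intercept)
    if Y.shape != P.shape:
        raise ValueError("Y shape does not match the number of samples/classes")
    D = P[:, :-1] - Y[:, :-1]
    return np.asarray(X).T @ D, D.sum(axis=0)


def hessian_blocks(X: np.ndarray, beta: np.ndarray,
                   intercept: np.ndarray | None = None) -> np.ndarray:
    """Per-feature (M-1)x(M-1) curvature blocks of f = -l(beta).

    For feature j the block is sum_i x_ij^2 * (diag(p_i) - p_i p_i^T) over the
    free classes — the per-feature restriction of the full Hessian (each block
    symmetric PSD).  The estimation loops use the richer per-group restriction
    of :func:`group_hessian_blocks`; this per-feature form is the cheap
    curvature summary for diagnostics and single-feature analyses.
    """
    X = np.asarray(X, dtype=float)
    P = class_probabilities(X, beta, intercept)
    Pf = P[:, :-1]
    W = -np.einsum("im,in->imn", Pf, Pf)
    k = Pf.shape[1]
    W[:, np.arange(k), np.arange(k)] += Pf
    return np.einsum("ij,imn->jmn", X * X, W)


def group_hessian_blocks(X: np.ndarray, beta: np.ndarray,
                         groups: GroupStructure,
                         intercept: np.ndarray | None = None
                         ) -> list[np.ndarray]:
    """Exact per-group curvature blocks H_JJ of f = -l(beta).

    For group J with features j, j' and free classes m, m',

        (H_JJ)[(j,m),(j',m')] = sum_i x_ij x_ij' (diag(p_i) - p_i p_i^T)[m,m'].

    Returned as one (d_J, K, d_J, K) array per group; cross-group curvature
    is treated as zero.  These are the quadratic-model blocks the estimation
    loops minimize over — they capture the (often strong) correlation between
    fused features of the same channel, which the per-feature diagonal of
    :func:`hessian_blocks` cannot.
    """
    X = np.asarray(X, dtype=float)
    P = class_probabilities(X, beta, intercept)
    Pf = P[:, :-1]
    k = Pf.shape[1]
    out = []
    for sl in groups.slices:
        Xg = X[:, sl]
        d = Xg.shape[1]
        H = np.empty((d, k, d, k))
        for m in range(k):
            for n in range(m, k):
                w = -Pf[:, m] * Pf[:, n]
                if m == n:
                    w = w + Pf[:, m]
                block = Xg.T @ (w[:, None] * Xg)
                H[:, m, :, n] = block
                if n != m:
                    H[:, n, :, m] = block
        out.append(H)
    return out


def intercept_hessian(X: np.ndarray, beta: np.ndarray,
                      intercept: np.ndarray | None = None) -> np.ndarray:
    """Curvature of f with respect to the (unpenalized) intercepts."""
    P = class_probabilities(X, beta, intercept)
    Pf = P[:, :-1]
    W = -(Pf.T @ Pf)
    W[np.diag_indices_from(W)] += Pf.sum(axis=0)
    return W


def objective(X: np.ndarray, Y: np.ndarray, beta: np.ndarray,
              groups: GroupStructure, spec: PenaltySpec,
              intercept: np.ndarray | None = None,
              weights: np.ndarray | None = None) -> float:
    """Penalized objective -l(beta) + lam*Phi(beta); convex in beta."""
    return -log_likelihood(X, Y, beta, intercept) \
        + penalty(beta, groups, spec, weights)
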