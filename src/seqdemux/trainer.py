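"""Fitting the fused-penalty multi-label model by relaxed ADMM.

The objective separates into two blocks that are alternated until the
label vectors stabilize:

* label step — each coordinate of a label vector w_p has the closed-form
  minimizer median{ w_n[k] : n in C(p) } (the median minimizes the summed
  absolute deviations of the fused penalty);
* subclass step — with the label vectors held fixed, the w_n are fit by
  scaled ADMM. Auxiliary variables z_np stand in for the differences
  w_n - w_p; the smooth sub-problem (weighted multinomial NLL plus a
  quadratic coupling) is minimized with L-BFGS, the z-update is
  soft-thresholding with threshold 2*lambda/rho, and the scaled duals u_np
  accumulate the constraint violation. Over-relaxation (alpha = 1.9 by
  default) blends the fresh w iterate with the previous z before the z/u
  updates to speed convergence.

Iterations stop when both residual criteria hold:

    || rho*(z - z_old) ||_2  <  eps_abs*K + eps_rel*|| rho*u ||_2
    || w_n - z_np - w_p ||_2 <  eps_abs*K + eps_rel*max(||w_n||, ||z_np||, ||w_p||)

with K the number of k-mer features.

A distributed variant partitions the training examples across workers for
the w-step and averages the worker estimates; the z/u updates then act as
pooling steps. The single-worker path is the reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .model import LabelStructure, TrainConfig, WeightSet, nll, objective

log = logging.getLogger(__name__)


def shrinkage(a: np.ndarray, k) -> np.ndarray:
    """Element-wise soft-thresholding: shrink toward zero by k, zeroing |a| <= k.

    ``k`` may be a scalar or an array broadcastable against ``a``.
    """
    if np.any(np.asarray(k) < 0):
        raise ValueError("threshold must be >= 0")
    return np.sign(a) * np.maximum(np.abs(a) - k, 0.0)


def update_labels(W_sub: np.ndarray, structure: LabelStructure,
                  zero_points: int = 0) -> np.ndarray:
    """Closed-form label step: element-wise median over spanned subclasses.

    An even number of values takes the mean of the two middle values (the
    numpy convention), which is also a minimizer of the summed absolute
    deviations.

    ``zero_points`` appends that many zero pseudo-values per coordinate,
    which is the exact minimizer when the label vectors carry their own L1
    term ``zero_points * lam * ||w_p||_1``: a label coordinate then moves
    away from zero only when more than ``zero_points`` of its spanned
    subclasses pull in the same direction. With the default used in
    training (2), a label picks up a k-mer only when at least two spanned
    subclasses consistently support it — single-subclass quirks are ignored.
    """
    K = W_sub.shape[1] - 1
    W_lab = np.zeros((len(structure.labels), K))
    for j, p in enumerate(structure.labels):
        rows = structure.spanned(p)
        V = W_sub[rows, :K]
        if zero_points:
            V = np.vstack([V, np.zeros((zero_points, K))])
        W_lab[j] = np.median(V, axis=0)
    return W_lab


@dataclass
class TrainingTrace:
    """Per-iteration diagnostics of a fit (objective and ADMM residuals)."""

    sweeps: list[dict] = field(default_factory=list)
    admm: list[dict] = field(default_factory=list)
    converged: bool = False


def _nll_grad(X, Y, b, W, pair_rows, pair_targets, rho):
    """Value and gradient of NLL + (rho/2) sum ||w_n - target_np||^2."""
    T, D = W.shape
    Z = X @ W[:, :-1].T + W[:, -1]
    Z -= Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    S = E.sum(axis=1)
    P = E / S[:, None]
    val = float(-np.sum(b * ((Y * Z).sum(axis=1) - np.log(S))))
    R = (P - Y) * b[:, None]
    G = np.empty_like(W)
    G[:, :-1] = R.T @ X
    G[:, -1] = R.sum(axis=0)
    # quadratic coupling on the k-mer coords only
    diff = W[pair_rows, :-1] - pair_targets
    val += 0.5 * rho * float(np.sum(diff * diff))
    np.add.at(G[:, :-1], pair_rows, rho * diff)
    return val, G


def _solve_w_step(X, Y, b, W0, pair_rows, pair_targets, rho, maxiter,
                  parts=None):
    """Joint L-BFGS minimization of the smooth sub-problem.

    With ``parts`` (a partition of the examples across workers) the NLL and
    its gradient are computed per worker and reduced by summation — a
    pooling step that leaves the optimization identical to the
    single-worker path.
    """
    shape = W0.shape

    def fun(w):
        W = w.reshape(shape)
        if parts is None:
            v, g = _nll_grad(X, Y, b, W, pair_rows, pair_targets, rho)
        else:
            v, g = _nll_grad(X[parts[0]], Y[parts[0]], b[parts[0]], W,
                             pair_rows, pair_targets, rho)
            for ix in parts[1:]:
                v2, g2 = _nll_grad(X[ix], Y[ix], b[ix], W, pair_rows,
                                   pair_targets, 0.0)
                v, g = v + v2, g + g2
        return v, g.ravel()

    res = minimize(fun, W0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6})
    return res.x.reshape(shape)


def _partition(M: int, threads: int, strata: np.ndarray, seed: int) -> list[np.ndarray]:
    """Deterministic stratified round-robin split of example indices."""
    rng = np.random.default_rng(seed)
    order = []
    for s in np.unique(strata):
        ix = np.flatnonzero(strata == s)
        rng.shuffle(ix)
        order.append(ix)
    order = np.concatenate(order)
    return [order[j::threads] for j in range(threads)]


def admm_fit(
    X: np.ndarray,
    Y: np.ndarray,
    b: np.ndarray,
    structure: LabelStructure,
    config: TrainConfig | None = None,
    trace: TrainingTrace | None = None,
) -> WeightSet:
    """Fit subclass and label weight vectors by alternating median / ADMM steps."""
    if config is None:
        config = TrainConfig()
    T = len(structure.subclasses)
    if T < 2:
        raise ValueError("need at least 2 subclasses to train a classifier")
    M, K = X.shape
    lam_zero = config.lam if config.lam_zero is None else config.lam_zero
    rho = config.rho if config.rho is not None else 2.0 * max(config.lam, lam_zero, 0.5)
    pairs = structure.pairs()
    pair_rows = np.array([n for n, _ in pairs] + list(range(T)))
    pair_labs = np.array([j for _, j in pairs])  # label pairs only
    n_lab_pairs = len(pairs)
    # Per-pair soft-threshold: fusion pairs use lam; zero-anchor pairs use
    # lam_zero scaled by sqrt(b_n) per subclass. The b_i weighting amplifies
    # a small subclass's gradient noise by sqrt(b), so its sparsity penalty
    # is raised by the same factor — chance enrichments in small subclasses
    # are zeroed while consistently amplified real signals still break out.
    sizes = Y.sum(axis=0)
    s_n = np.sqrt(sizes.max() / np.maximum(sizes, 1.0))
    thresh = np.concatenate([np.full(n_lab_pairs, 2.0 * config.lam / rho),
                             2.0 * lam_zero * s_n / rho])[:, None]

    W = WeightSet.zeros(structure, K)
    parts = None
    if config.threads > 1:
        parts = _partition(M, config.threads, Y.argmax(axis=1), config.seed)

    if config.lam == 0.0 and lam_zero == 0.0:
        # no penalty: plain weighted multinomial fit, no splitting needed
        W.W_sub = _solve_w_step(X, Y, b, W.W_sub, pair_rows[:0],
                                np.zeros((0, K)), 0.0, 1000, parts=parts)
        W.W_lab = update_labels(W.W_sub, structure, config.label_zero_points)
        if trace is not None:
            trace.sweeps.append({"sweep": 0, "objective": nll(X, Y, b, W.W_sub),
                                 "label_change": 0.0, "admm_converged": True})
            trace.converged = True
        return W

    z_anchor = None
    for sweep in range(config.outer_sweeps):
        W_lab_old = W.W_lab.copy()
        # Dense (plain-median) label updates during the early sweeps let the
        # well-populated subclasses seed the label vectors with their k-mer
        # representatives, which the fusion then propagates to the smaller
        # subclasses; the sparse median (with zero pseudo-points) is applied
        # in the final sweep so reported label models only keep k-mers with
        # consistent multi-subclass support.
        zp = (config.label_zero_points
              if sweep >= config.outer_sweeps - config.label_sparse_sweeps else 0)
        W.W_lab = update_labels(W.W_sub, structure, zp)
        Wp = np.concatenate([W.W_lab[pair_labs], np.zeros((T, K))])  # (n_pairs, K)

        z = W.W_sub[pair_rows, :-1] - Wp
        u = np.zeros_like(z)
        converged = False
        for it in range(config.max_admm_iters):
            maxiter = config.inner_maxiter if (sweep == 0 and it == 0) else max(
                15, config.inner_maxiter // 3)
            targets = z + Wp - u  # w-step pulls w_n toward z_np + w_p - u_np
            W.W_sub = _solve_w_step(X, Y, b, W.W_sub, pair_rows, targets,
                                    rho, maxiter, parts=parts)

            Wn = W.W_sub[pair_rows, :-1]
            z_old = z
            relaxed = config.alpha * (Wn - Wp) + (1.0 - config.alpha) * z_old
            z = shrinkage(relaxed + u, thresh)
            u = u + relaxed - z

            primal = Wn - z - Wp
            primal_norm = float(np.linalg.norm(primal))
            dual_norm = float(rho * np.linalg.norm(z - z_old))
            eps_pri = config.eps_abs * K + config.eps_rel * max(
                np.linalg.norm(Wn), np.linalg.norm(z), np.linalg.norm(Wp))
            eps_dual = config.eps_abs * K + config.eps_rel * rho * np.linalg.norm(u)
            if trace is not None:
                trace.admm.append({"sweep": sweep, "iter": it,
                                   "primal": primal_norm, "dual": dual_norm,
                                   "eps_pri": eps_pri, "eps_dual": eps_dual})
            if primal_norm < eps_pri and dual_norm < eps_dual:
                converged = True
                break
        z_anchor = z[n_lab_pairs:]  # sparse consensus copies of the w_n
        if not converged:
            warnings.warn(
                f"ADMM did not satisfy both stopping criteria within "
                f"{config.max_admm_iters} iterations (sweep {sweep}); "
                "returning the current iterate", RuntimeWarning, stacklevel=2)

        obj = objective(W, X, Y, b, config.lam, lam_zero, zp)
        lab_change = float(np.abs(W.W_lab - W_lab_old).max()) if sweep else np.inf
        if trace is not None:
            trace.sweeps.append({"sweep": sweep, "objective": obj,
                                 "label_change": lab_change,
                                 "admm_converged": converged})
        if lab_change < config.outer_tol:
            break

    W.W_dense = W.W_sub.copy()
    if z_anchor is not None and lam_zero > 0:
        # report the sparse consensus iterate: irrelevant k-mer weights are
        # exactly zero there, which keeps downstream score signs honest
        W.W_sub[:, :-1] = z_anchor
    W.W_lab = update_labels(W.W_sub, structure, config.label_zero_points)
    if trace is not None:
        trace.converged = True
    return W


def fit_mcc_baseline(
    X: np.ndarray,
    label_sets: list[set[str]],
    labels: list[str] | None = None,
    lam: float = 0.1,
    seed: int = 1,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Naive multi-class baseline: one mutually exclusive class per label.

    A sequence carrying several labels is duplicated, contributing one
    training row per label. Returns (W_lab (labels x K), intercepts, labels),
    from an L1-regularized multinomial logistic regression with penalty
    strength matched to ``lam`` on the summed-loss scale.
    """
    if labels is None:
        labels = sorted({p for s in label_sets for p in s})
    rows, ys = [], []
    for i, s in enumerate(label_sets):
        for p in sorted(s):
            rows.append(i)
            ys.append(labels.index(p))
    Xd = X[np.array(rows)]
    yd = np.array(ys)
    clf = LogisticRegression(penalty="l1", solver="saga", C=1.0 / max(lam, 1e-8),
                             max_iter=max_iter, tol=1e-3, random_state=seed)
    clf.fit(Xd, yd)
    W = np.zeros((len(labels), X.shape[1]))
    icpt = np.zeros(len(labels))
    if len(clf.classes_) == 1:  # single-label degenerate case
        return W, icpt, labels
    for ci, c in enumerate(clf.classes_):
        W[int(c)] = clf.coef_[ci] if clf.coef_.shape[0] > 1 else (
            clf.coef_[0] if ci == 1 else -clf.coef_[0])
        icpt[int(c)] = clf.intercept_[ci] if clf.intercept_.shape[0] > 1 else (
            clf.intercept_[0] if ci == 1 else -clf.intercept_[0])
    return W, icpt, labels


def select_lambda_cv(
    X: np.ndarray,
    Y: np.ndarray,
    b: np.ndarray,
    structure: LabelStructure,
    grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0),
    folds: int = 3,
    config: TrainConfig | None = None,
) -> float:
    """Pick lambda by k-fold CV, maximizing mean held-out subclass log-likelihood."""
    base = config or TrainConfig()
    y = Y.argmax(axis=1)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=base.seed)
    best_lam, best_ll = grid[0], -np.inf
    for lam in grid:
        ll = 0.0
        for tr, te in skf.split(X, y):
            cfg = TrainConfig(**{**base.__dict__, "lam": lam})
            W = admm_fit(X[tr], Y[tr], b[tr], structure, cfg)
            ll -= nll(X[te], Y[te], b[te], W.W_sub)
        ll /= folds
        log.info("lambda=%g mean held-out ll=%.3f", lam, ll)
        if ll > best_ll:
            best_lam, best_ll = lam, ll
    return best_lam
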