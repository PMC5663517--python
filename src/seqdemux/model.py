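"""Label structure, model weights, and the training objective.

The classifier is a multinomial logistic regression over *subclasses* —
the distinct observed combinations of annotation labels. Each subclass n
has a k-mer weight vector w_n (plus an intercept). Each label p carries a
weight vector w_p with no intercept; label vectors are never fit to data
directly but arise through an L1 fused penalty that ties each subclass
vector to the vectors of the labels spanning it:

    J(W) = - sum_i sum_n b_i y_in log softmax_n(w_n . x_i)
           + lambda * sum_n sum_{p in Pi(n)} || w_n - w_p ||_1
           + lam_zero * sum_n sqrt(b_n) || w_n ||_1
           + label_zero_points * lambda * sum_p || w_p ||_1

b_i is an inverse-class-size weight |n_max|/|n| balancing unequal subclass
sizes. Pi(n) is the set of labels spanning subclass n and C(p) the set of
subclasses label p spans. The two plain-L1 blocks anchor the model to
zero: without them the objective is invariant to shifting one k-mer's
weight by a constant in every subclass vector, leaving score signs
meaningless (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax


@dataclass
class LabelStructure:
    """Bidirectional map between labels and subclasses (label combinations)."""

    labels: list[str]
    subclasses: list[frozenset[str]]

    def __post_init__(self) -> None:
        for n in self.subclasses:
            if not n:
                raise ValueError("empty subclass")
            if not n <= set(self.labels):
                raise ValueError(f"subclass {set(n)} has labels outside {self.labels}")
        self.subclass_names = ["+".join(sorted(n)) for n in self.subclasses]

    @classmethod
    def from_label_sets(cls, label_sets: list[set[str]]) -> "LabelStructure":
        labels = sorted({p for s in label_sets for p in s})
        combos = sorted({frozenset(s) for s in label_sets}, key=lambda n: sorted(n))
        return cls(labels=labels, subclasses=combos)

    def pi(self, n: int) -> list[str]:
        """Labels spanning subclass ``n`` (by index)."""
        return sorted(self.subclasses[n])

    def spanned(self, label: str) -> list[int]:
        """Indices of the subclasses spanned by ``label`` (C(p))."""
        out = [i for i, n in enumerate(self.subclasses) if label in n]
        if not out:
            raise ValueError(f"label {label!r} spans no subclass")
        return out

    def membership(self, label_sets: list[set[str]]) -> np.ndarray:
        """One-hot subclass membership matrix y_in (each row sums to 1)."""
        index = {n: i for i, n in enumerate(self.subclasses)}
        Y = np.zeros((len(label_sets), len(self.subclasses)))
        for i, s in enumerate(label_sets):
            Y[i, index[frozenset(s)]] = 1.0
        return Y

    def pairs(self) -> list[tuple[int, int]]:
        """All (subclass index, label index) fusion pairs, p in Pi(n)."""
        lab_ix = {p: j for j, p in enumerate(self.labels)}
        return [(i, lab_ix[p]) for i, n in enumerate(self.subclasses) for p in sorted(n)]


def instance_weights(label_sets: list[set[str]], structure: LabelStructure) -> np.ndarray:
    """Class-balancing weights b_i = |n_max|/|n| per sequence."""
    Y = structure.membership(label_sets)
    sizes = Y.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("subclass with no members")
    return (sizes.max() / sizes)[Y.argmax(axis=1)]


@dataclass
class WeightSet:
    """Trained weights: per-subclass vectors (with intercept) and per-label vectors."""

    structure: LabelStructure
    W_sub: np.ndarray  # (|T|, K_dim + 1); last column is the intercept
    W_lab: np.ndarray  # (|labels|, K_dim); no intercept
    #: dense subclass iterate from the final smooth w-step, before the sparse
    #: consensus projection; keeps small weights on motif-variant k-mers and
    #: is the better model for hill scanning (recall), while the sparse
    #: W_sub/W_lab are the reported models (precision)
    W_dense: np.ndarray | None = None

    @classmethod
    def zeros(cls, structure: LabelStructure, K_dim: int) -> "WeightSet":
        return cls(
            structure=structure,
            W_sub=np.zeros((len(structure.subclasses), K_dim + 1)),
            W_lab=np.zeros((len(structure.labels), K_dim)),
        )

    @property
    def K_dim(self) -> int:
        return self.W_sub.shape[1] - 1

    def label_vector(self, label: str) -> np.ndarray:
        return self.W_lab[self.structure.labels.index(label)]

    def subclass_vector(self, name: str) -> np.ndarray:
        return self.W_sub[self.structure.subclass_names.index(name), :-1]


@dataclass
class TrainConfig:
    """Optimizer settings for the fused-penalty fit.

    ``alpha`` is the ADMM over-relaxation parameter (default 1.9);
    ``eps_abs``/``eps_rel`` enter the stopping criteria scaled by the
    number of k-mer features. ``lam_zero`` is the coefficient of the plain
    L1 (zero-anchor) term on subclass weights; ``None`` means "equal to
    ``lam``". The zero anchor fixes the per-k-mer gauge of the softmax
    (otherwise a constant can be added to every subclass's weight for one
    k-mer without changing likelihood or fusion penalty), making the sign
    of a score interpretable and irrelevant k-mer weights exactly zero.
    """

    lam: float = 10.0
    lam_zero: float | None = 2.0
    label_zero_points: int = 2
    label_sparse_sweeps: int = 2
    rho: float | None = None  # None: 2 * max(lam, lam_zero, 0.5)
    alpha: float = 1.9
    eps_abs: float = 1e-4
    eps_rel: float = 1e-2
    max_admm_iters: int = 500
    outer_sweeps: int = 4
    outer_tol: float = 1e-4
    inner_maxiter: int = 60
    threads: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.lam_zero is not None and self.lam_zero < 0:
            raise ValueError("lam_zero must be >= 0")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must be in (0, 2]")


def _logits(X: np.ndarray, W_sub: np.ndarray) -> np.ndarray:
    return X @ W_sub[:, :-1].T + W_sub[:, -1]


def subclass_posteriors(X: np.ndarray, W_sub: np.ndarray) -> np.ndarray:
    """Softmax posteriors over subclasses, overflow-safe (max subtraction)."""
    X = np.atleast_2d(X)
    return softmax(_logits(X, W_sub), axis=1)


def nll(X: np.ndarray, Y: np.ndarray, b: np.ndarray, W_sub: np.ndarray) -> float:
    """Weighted multinomial negative log-likelihood."""
    Z = _logits(X, W_sub)
    log_post = Z - logsumexp(Z, axis=1, keepdims=True)
    return float(-np.sum(b * np.sum(Y * log_post, axis=1)))


def fused_penalty(W: WeightSet, lam: float, lam_zero: float | None = None,
                  label_zero_points: int = 0,
                  subclass_scale: np.ndarray | None = None) -> float:
    """L1 penalty block of the objective.

    lam * sum over (subclass, spanning label) pairs of ||w_n - w_p||_1,
    plus the subclass zero-anchor term lam_zero * scale_n * ||w_n||_1
    (gauge fixing / sparsity; ``subclass_scale`` is sqrt(b_n) in training,
    matching the noise amplification of the instance weighting), plus the
    label sparsity term label_zero_points * lam * sum_p ||w_p||_1.
    """
    if lam_zero is None:
        lam_zero = lam
    if subclass_scale is None:
        subclass_scale = np.ones(len(W.structure.subclasses))
    total = 0.0
    lab_ix = {p: j for j, p in enumerate(W.structure.labels)}
    for i, n in enumerate(W.structure.subclasses):
        for p in n:
            total += lam * np.abs(W.W_sub[i, :-1] - W.W_lab[lab_ix[p]]).sum()
        total += lam_zero * subclass_scale[i] * np.abs(W.W_sub[i, :-1]).sum()
    if label_zero_points:
        total += label_zero_points * lam * np.abs(W.W_lab).sum()
    return total


def subclass_penalty_scale(Y: np.ndarray) -> np.ndarray:
    """Per-subclass zero-anchor scaling sqrt(|n_max| / |n|) (= sqrt(b_n))."""
    sizes = Y.sum(axis=0)
    return np.sqrt(sizes.max() / np.maximum(sizes, 1.0))


def objective(W: WeightSet, X: np.ndarray, Y: np.ndarray, b: np.ndarray,
              lam: float, lam_zero: float | None = None,
              label_zero_points: int = 0, scaled_zero: bool = True) -> float:
    """Full training objective: weighted NLL plus the L1 penalties."""
    scale = subclass_penalty_scale(Y) if scaled_zero else None
    return nll(X, Y, b, W.W_sub) + fused_penalty(W, lam, lam_zero,
                                                 label_zero_points, scale)
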