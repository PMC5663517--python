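"""From hills to interpretable motifs: clustering, PWM discovery, scoring.

Hills called under one label model are clustered by their k-mer content
(K-means, Euclidean distance, K in 2..6 chosen by the median silhouette
index over 30 bootstrap samples; undersized clusters are merged). Each
cluster's sequences are then summarized as a PWM by a ZOOPS
(zero-or-one-occurrence-per-sequence) EM search, and every PWM is scored
against each label/subclass k-mer weight vector by summing the weights of
the k-mers belonging to the motif:

    Score_w(motif) = sum_{j in motif} w_j

A k-mer "belongs" to a motif when its best gapless alignment log-odds
against the PWM (uniform background) reaches 70% of the maximum achievable
at some offset. Positive scores mean the motif is discriminatively enriched
for that model's label; negative scores indicate depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import BASES, KmerSpace, seq_to_ints
from .hills import Hill

KMER_MIN_HILL_FRACTION = 0.05  # k-mer kept as a clustering feature if in >= 5% of hills
MERGE_FRACTION = 0.10  # clusters smaller than 10% of the largest get merged
SILHOUETTE_BOOTSTRAPS = 30
K_RANGE = (2, 3, 4, 5, 6)
MOTIF_KMER_FRAC = 0.7
MIN_HILLS_FOR_CLUSTERING = 20
LOW_COMPLEXITY_LLR = 1.0  # nats per sequence; below this a PWM is flagged
TRIM_IC_BITS = 0.25  # flank columns below this information content are trimmed
MIN_PWM_WIDTH = 7  # keep >=1 column beyond a 6-bp core so frame-shifted
                   # rediscoveries still align over >=6 columns


@dataclass
class PWM:
    """Column-stochastic position weight matrix (rows = positions, A,C,G,T)."""

    matrix: np.ndarray
    name: str = ""
    source_cluster: str = ""
    llr: float = 0.0  # ZOOPS log-likelihood ratio vs background-only
    low_complexity: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.matrix.argmax(axis=1))

    def information_content(self) -> float:
        """Mean per-column information content in bits (uniform background)."""
        M = np.clip(self.matrix, 1e-9, 1.0)
        return float(np.mean(2.0 + (M * np.log2(M)).sum(axis=1)))


# ---------------------------------------------------------------------------
# Hill clustering


def _hill_features(hills: list[Hill], space: KmerSpace,
                   min_fraction: float = KMER_MIN_HILL_FRACTION
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Raw k-mer count matrix over hills, restricted to commonly present k-mers."""
    C = space.count_matrix([h.dna for h in hills])
    present = (C > 0).mean(axis=0) >= min_fraction
    if not present.any():
        present = (C > 0).any(axis=0)
    return C[:, present], np.flatnonzero(present)


def _choose_k(F: np.ndarray, rng: np.random.Generator,
              k_range=K_RANGE, n_boot: int = SILHOUETTE_BOOTSTRAPS) -> int:
    """Pick K by the highest median silhouette over bootstrap samples.

    Bootstrap samples are capped at 300 hills: the silhouette computation
    is quadratic in the sample and its ranking over K stabilizes well
    below that size.
    """
    n = F.shape[0]
    size = min(300, n)
    best_k, best_med = k_range[0], -np.inf
    for k in k_range:
        if k >= n:
            break
        sils = []
        for _ in range(n_boot):
            ix = rng.integers(0, n, size=size)
            Fb = F[ix]
            seed = int(rng.integers(2**31 - 1))
            lab = KMeans(n_clusters=k, n_init=1, random_state=seed).fit_predict(Fb)
            if len(np.unique(lab)) < 2:
                sils.append(-1.0)
                continue
            sils.append(silhouette_score(Fb, lab))
        med = float(np.median(sils))
        if med > best_med:
            best_k, best_med = k, med
    return best_k


def cluster_hills(hills: list[Hill], space: KmerSpace, seed: int = 1,
                  max_hills: int = 1000) -> list[list[Hill]]:
    """Group hills by k-mer content into K-means clusters.

    Fewer than 20 hills (or degenerate identical features) yield a single
    cluster. At most ``max_hills`` hills (a seeded subsample) are used. After
    the final K-means fit, clusters smaller than 10% of the largest cluster
    are dissolved into their members' next-closest surviving centroid.
    """
    rng = np.random.default_rng(seed)
    if len(hills) > max_hills:
        # keep the highest-scoring hills: they carry the discriminative signal
        order = sorted(range(len(hills)), key=lambda i: -hills[i].score)
        hills = [hills[i] for i in sorted(order[:max_hills])]
    if len(hills) < MIN_HILLS_FOR_CLUSTERING:
        return [list(hills)]
    F, _ = _hill_features(hills, space)
    if np.allclose(F, F[0]):
        return [list(hills)]
    k = _choose_k(F, rng)
    km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31 - 1)))
    lab = km.fit_predict(F)
    centers = km.cluster_centers_

    sizes = np.bincount(lab, minlength=k)
    largest = sizes.max()
    keep = np.flatnonzero(sizes >= MERGE_FRACTION * largest)
    if keep.size < k:
        dist = ((F[:, None, :] - centers[None, keep, :]) ** 2).sum(axis=2)
        merged = keep[dist.argmin(axis=1)]
        lab = np.where(np.isin(lab, keep), lab, merged)
    return [[h for h, l in zip(hills, lab) if l == c] for c in np.unique(lab)]


# ---------------------------------------------------------------------------
# ZOOPS-EM PWM discovery


def _windows_int(B: np.ndarray, w: int, n_off: int | None = None) -> np.ndarray:
    """w-wide windows of each row, both strands: (n, 2*n_off, w)."""
    fwd = np.lib.stride_tricks.sliding_window_view(B, w, axis=1)
    if n_off is not None:
        fwd = fwd[:, :n_off]
    rev = 3 - fwd[:, :, ::-1]
    return np.concatenate([fwd, rev], axis=1)


def _zoops_em(W: np.ndarray, width: int, rng: np.random.Generator,
              gamma0: float = 0.5, max_iter: int = 40, tol: float = 1e-5,
              bg: np.ndarray | None = None) -> tuple[np.ndarray, float, float]:
    """One EM run. W: (n, n_cand, width) int windows. Returns (theta, gamma, llr)."""
    n, n_cand, _ = W.shape
    if bg is None:
        bg = np.bincount(W[:, : n_cand // 2, :].ravel(), minlength=4).astype(float)
        bg = np.clip(bg / bg.sum(), 1e-6, 1.0)
    # seed theta from one random window, heavily smoothed
    seed_win = W[rng.integers(n), rng.integers(n_cand)]
    theta = np.full((width, 4), 0.17)
    theta[np.arange(width), seed_win] = 0.49
    log_bg_win = np.log(bg)[W].sum(axis=2)  # (n, n_cand)
    gamma = gamma0
    prev_ll = -np.inf
    ll = prev_ll
    for _ in range(max_iter):
        log_theta = np.log(np.clip(theta, 1e-9, 1.0))
        log_ratio = log_theta.T[W, np.arange(width)].sum(axis=2) - log_bg_win
        r = np.exp(np.clip(log_ratio, -700, 700)) * (gamma / n_cand)
        denom = (1.0 - gamma) + r.sum(axis=1)
        resp = r / denom[:, None]  # (n, n_cand)
        ll = float(np.log(denom).sum())
        if abs(ll - prev_ll) < tol * n:
            break
        prev_ll = ll
        counts = np.zeros((width, 4))
        flat_resp = resp.ravel()
        flat_win = W.reshape(-1, width)
        for j in range(width):
            counts[j] = np.bincount(flat_win[:, j], weights=flat_resp, minlength=4)
        counts += 0.1
        theta = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(resp.sum() / n, 1e-3, 1.0 - 1e-3))
    return theta, gamma, ll


def discover_pwm(seqs: list[str], widths: range | tuple = range(7, 13),
                 n_restarts: int = 5, seed: int = 1, max_seqs: int = 300,
                 name: str = "", source_cluster: str = "") -> PWM:
    """Find the best PWM in a set of sequences by ZOOPS EM.

    Runs EM at each width with ``n_restarts`` random seedings and keeps the
    highest log-likelihood-ratio model. A PWM whose per-sequence LLR falls
    below a null threshold is flagged ``low_complexity``. Falls back to the
    aligned consensus frequency matrix if EM degenerates.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    if len(seqs) > max_seqs:
        ix = rng.choice(len(seqs), size=max_seqs, replace=False)
        seqs = [seqs[i] for i in ix]
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)

    best: tuple[float, np.ndarray] | None = None
    for width in widths:
        lens = [L for L in by_len if L >= width]
        if not lens:
            continue
        n_off = min(L - width + 1 for L in lens)
        groups = []
        for L in lens:
            B = np.stack([seq_to_ints(s) for s in by_len[L]])
            if (B < 0).any():
                B = np.where(B < 0, 0, B)
            groups.append(_windows_int(B, width, n_off=n_off))
        W = np.concatenate(groups, axis=0)
        for _ in range(n_restarts):
            try:
                theta, gamma, llr = _zoops_em(W, width, rng)
            except FloatingPointError:  # pragma: no cover - EM failure fallback
                continue
            if best is None or llr > best[0]:
                best = (llr, theta)
    if best is None:  # pragma: no cover - fallback: consensus frequency matrix
        L = min(len(s) for s in seqs)
        B = np.stack([seq_to_ints(s[:L]) for s in seqs])
        counts = np.stack([np.bincount(np.maximum(B[:, j], 0), minlength=4)
                           for j in range(L)]).astype(float) + 0.1
        return PWM(counts / counts.sum(axis=1, keepdims=True), name=name,
                   source_cluster=source_cluster, low_complexity=True)
    llr, theta = best
    theta = trim_flanks(theta)
    per_seq = llr / len(seqs)
    return PWM(theta, name=name, source_cluster=source_cluster, llr=llr,
               low_complexity=per_seq < LOW_COMPLEXITY_LLR)


def trim_flanks(theta: np.ndarray, ic_thresh: float = TRIM_IC_BITS,
                min_width: int = MIN_PWM_WIDTH) -> np.ndarray:
    """Strip uninformative flank columns from a PWM.

    Columns are trimmed from both ends while their information content is
    below ``ic_thresh`` bits. If that would leave fewer than ``min_width``
    columns, the ``min_width`` window with the highest total information
    content is kept instead.
    """
    M = np.clip(theta, 1e-9, 1.0)
    ic = 2.0 + (M * np.log2(M)).sum(axis=1)
    lo, hi = 0, len(ic)
    while lo < hi and ic[lo] < ic_thresh:
        lo += 1
    while hi > lo and ic[hi - 1] < ic_thresh:
        hi -= 1
    if hi - lo >= min_width:
        return theta[lo:hi]
    if len(ic) <= min_width:
        return theta
    totals = np.convolve(ic, np.ones(min_width), mode="valid")
    s = int(totals.argmax())
    return theta[s:s + min_width]


# ---------------------------------------------------------------------------
# Motif scoring against k-mer models


def motif_kmer_membership(pwm: PWM, space: KmerSpace,
                          frac: float = MOTIF_KMER_FRAC) -> np.ndarray:
    """Column ids of the canonical k-mers that belong to the motif.

    A k-mer belongs when, at some gapless offset inside the PWM, its
    log-odds against a uniform background reaches ``frac`` of the maximum
    achievable log-odds at that offset.
    """
    log_ratio = np.log(np.clip(pwm.matrix, 1e-9, 1.0) / 0.25)  # (w, 4)
    col_max = log_ratio.max(axis=1)
    member_cols: set[int] = set()
    for k in space.k_values:
        if pwm.width < k:
            continue
        digits = np.stack([(np.arange(4**k) // 4**(k - 1 - j)) % 4
                           for j in range(k)], axis=1)
        for off in range(pwm.width - k + 1):
            scores = log_ratio[off:off + k][np.arange(k), digits].sum(axis=1)
            cutoff = frac * col_max[off:off + k].sum()
            for code in np.flatnonzero(scores >= cutoff):
                member_cols.add(space._code_to_col[k][code])
    return np.array(sorted(member_cols), dtype=int)


def score_motif(pwm: PWM, w: np.ndarray, space: KmerSpace,
                frac: float = MOTIF_KMER_FRAC,
                membership: np.ndarray | None = None) -> float:
    """Sum of the model weights of the motif's member k-mers."""
    if membership is None:
        membership = motif_kmer_membership(pwm, space, frac)
    if membership.size == 0:
        warnings.warn(f"motif {pwm.name or pwm.consensus} has an empty k-mer "
                      "membership set; score is 0", stacklevel=2)
        return 0.0
    return float(w[membership].sum())


@dataclass
class MotifScoreTable:
    """Discovered PWMs with their scores against every label/subclass model."""

    motifs: list[PWM]
    model_names: list[str]  # labels then subclass names
    scores: np.ndarray = field(default=None)  # (n_motifs, n_models)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores,
                            index=[m.name or m.consensus for m in self.motifs],
                            columns=self.model_names)


def score_table(motifs: list[PWM], weights: dict[str, np.ndarray],
                space: KmerSpace, frac: float = MOTIF_KMER_FRAC) -> MotifScoreTable:
    """Score every motif against every named weight vector."""
    names = list(weights)
    S = np.zeros((len(motifs), len(names)))
    for i, m in enumerate(motifs):
        membership = motif_kmer_membership(m, space, frac)
        for j, nm in enumerate(names):
            S[i, j] = (float(weights[nm][membership].sum())
                       if membership.size else 0.0)
    return MotifScoreTable(motifs=motifs, model_names=names, scores=S)
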