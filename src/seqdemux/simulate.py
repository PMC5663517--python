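"""Synthetic labeled regulatory sequences with controlled label overlap.

The generator emulates collections of ChIP-seq-scale site sets: fixed-width
(150 bp) sequences drawn from a 2nd-order Markov background, annotated with
labels from two sets (e.g. {A, B} and {X, Y}) whose pairwise co-occurrence
rate is controlled, and carrying motif instances sampled column-wise from a
label-assigned PWM at 70% of label-bearing sites.

"Overlap" is operationalized as P(paired set-2 label | set-1 label) for the
label pairing (A<->X, B<->Y, ...); the construction is symmetric. Label
assignment and insertion both use exact counts (round(rate * n), seeded
shuffles) so the realized rates equal the requested ones up to rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import BASES

# ---------------------------------------------------------------------------
# Bundled motif PWMs (synthetic, literature-style consensi; widths 6-10).
# Column-stochastic, rows = positions, columns = A,C,G,T.

_SHARP = 0.85
_SOFT = 0.60


def _pwm_from_consensus(consensus: str, soft_positions: tuple[int, ...] = ()) -> np.ndarray:
    w = len(consensus)
    M = np.full((w, 4), 0.05)
    for i, base in enumerate(consensus):
        j = BASES.index(base)
        if i in soft_positions:
            M[i] = (1.0 - _SOFT) / 3.0
            M[i, j] = _SOFT
        else:
            M[i] = (1.0 - _SHARP) / 3.0
            M[i, j] = _SHARP
    return M / M.sum(axis=1, keepdims=True)


#: Five distinct synthetic PWMs in the style of common TF-binding motifs
#: (E-box-, RUNX-, homeodomain-, AP-1- and Sp1-like consensi). Mixed
#: AT/GC composition keeps them distinguishable from background tracts.
BUNDLED_PWMS: dict[str, np.ndarray] = {
    "ebox": _pwm_from_consensus("CACGTG"),
    "runx": _pwm_from_consensus("TGTGGTCA", soft_positions=(7,)),
    "homeo": _pwm_from_consensus("TAATTAGC", soft_positions=(7,)),
    "ap1": _pwm_from_consensus("TTGACTCAT", soft_positions=(0, 8)),
    "sp1": _pwm_from_consensus("GGGGGCGGGG", soft_positions=(0, 9)),
}


# ---------------------------------------------------------------------------
# 2nd-order Markov background


@dataclass
class MarkovBackground:
    """Order-r Markov model over A,C,G,T: P(next base | previous r bases)."""

    order: int
    trans: np.ndarray  # (4**order, 4) row-stochastic; context in base-4 code
    init: np.ndarray  # (4**order,) distribution over the first r-mer

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")

    def sample(self, n_seqs: int, length: int, rng: np.random.Generator) -> list[str]:
        """Draw sequences; vectorized across sequences, sequential in position."""
        r = self.order
        out = np.empty((n_seqs, length), dtype=np.int8)
        if r == 0:
            out[:] = _sample_rows(np.tile(self.trans[0], (n_seqs, 1)), length, rng)
            return ["".join(BASES[v] for v in row) for row in out]
        ctx = rng.choice(4**r, size=n_seqs, p=self.init)
        for j in range(r):
            shift = 4 ** (r - 1 - j)
            out[:, j] = (ctx // shift) % 4 if j < length else 0
        cum = np.cumsum(self.trans, axis=1)
        for pos in range(r, length):
            u = rng.random(n_seqs)
            nxt = (cum[ctx] < u[:, None]).sum(axis=1).astype(np.int8)
            out[:, pos] = nxt
            ctx = (ctx * 4) % (4**r) + nxt
        return ["".join(BASES[v] for v in row) for row in out]

    def to_json(self) -> str:
        return json.dumps({"order": self.order, "trans": self.trans.tolist(),
                           "init": self.init.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "MarkovBackground":
        d = json.loads(text)
        return cls(order=d["order"], trans=np.array(d["trans"]), init=np.array(d["init"]))


def _sample_rows(P: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random((P.shape[0], length))
    return (cum[:, None, :] < u[:, :, None]).sum(axis=2).astype(np.int8)


def fit_markov_background(seqs: list[str], order: int = 2) -> MarkovBackground:
    """Maximum-likelihood transition probabilities with add-one smoothing.

    Contexts never observed in training back off to the marginal base
    distribution rather than to the uniform distribution.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    counts = np.zeros((4**order, 4))
    init = np.ones(4**order)
    for s in seqs:
        b = [BASES.index(c) for c in s.upper() if c in BASES]
        if len(b) <= order:
            continue
        ctx = 0
        for v in b[:order]:
            ctx = ctx * 4 + v
        if order:
            init[ctx] += 1
        for v in b[order:]:
            counts[ctx, v] += 1
            ctx = (ctx * 4) % (4**order) + v if order else 0
    marginal = counts.sum(axis=0)
    unseen = counts.sum(axis=1) == 0
    counts[unseen] = marginal  # full-strength marginal backoff
    counts += 1.0  # add-one smoothing
    return MarkovBackground(order=order,
                            trans=counts / counts.sum(axis=1, keepdims=True),
                            init=init / init.sum())


def default_background(order: int = 2) -> MarkovBackground:
    """Synthetic vertebrate-like background built in code.

    Emulates the dominant compositional biases of mammalian genomes:
    ~59% AT, strong CpG depletion, mild TpA depletion, and a slight
    poly-A/poly-T tract enrichment (which makes the model genuinely
    2nd-order). Not fit to any real genome.
    """
    base = np.array([0.295, 0.205, 0.205, 0.295])  # A C G T
    dinuc = np.ones((4, 4))
    dinuc[1, 2] = 0.22  # CpG depletion
    dinuc[3, 0] = 0.68  # TpA depletion
    dinuc[0, 0] = 1.15  # AA / TT enrichment
    dinuc[3, 3] = 1.15
    n_ctx = 4**order
    trans = np.empty((n_ctx, 4))
    for ctx in range(n_ctx):
        prev = ctx % 4  # last base of the context
        row = base * dinuc[prev]
        if order >= 2:
            prev2 = (ctx // 4) % 4
            if prev2 == 0 and prev == 0:  # AAA tracts
                row = row * np.array([1.25, 1.0, 1.0, 1.0])
            if prev2 == 3 and prev == 3:  # TTT tracts
                row = row * np.array([1.0, 1.0, 1.0, 1.25])
        trans[ctx] = row / row.sum()
    init = np.ones(n_ctx) / n_ctx
    return MarkovBackground(order=order, trans=trans, init=init)


def trinucleotide_frequencies(seqs: list[str]) -> np.ndarray:
    """Empirical 3-mer frequency vector (64 entries, A..T lexicographic)."""
    counts = np.zeros(64)
    for s in seqs:
        b = np.array([BASES.index(c) for c in s.upper() if c in BASES])
        if b.size < 3:
            continue
        codes = b[:-2] * 16 + b[1:-1] * 4 + b[2:]
        counts += np.bincount(codes, minlength=64)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Dataset generation


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_sites: int = 6000
    seq_len: int = 150
    label_sets: tuple[tuple[str, ...], ...] = (("A", "B"), ("X", "Y"))
    overlap: float = 0.7
    insertion_freq: float = 0.7
    motif_assignment: dict[str, np.ndarray] = field(default_factory=dict)
    markov_order: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        if not 0.0 <= self.insertion_freq <= 1.0:
            raise ValueError("insertion_freq must be in [0, 1]")
        if not self.motif_assignment:
            names = list(BUNDLED_PWMS)
            self.motif_assignment = {
                lab: BUNDLED_PWMS[names[i % len(names)]]
                for i, lab in enumerate(p for s in self.label_sets for p in s)
            }


@dataclass
class GroundTruth:
    """Per-sequence truth ledger consistent with the emitted sequences."""

    labels: list[set[str]]
    insertions: list[list[dict]]  # per-seq: {label, motif, start, end, instance}
    motif_names: dict[str, str]  # label -> motif name
    skipped: int = 0  # insertions dropped after repeated placement collisions

    def to_json(self) -> str:
        return json.dumps({
            "labels": [sorted(s) for s in self.labels],
            "insertions": self.insertions,
            "motif_names": self.motif_names,
            "skipped": self.skipped,
        })


def sample_pwm_instance(pwm: np.ndarray, rng: np.random.Generator) -> str:
    """One motif instance drawn column-wise from the PWM distribution."""
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm)


def _exact_count_mask(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with exactly round(rate*n) True entries, randomly placed."""
    mask = np.zeros(n, dtype=bool)
    mask[: int(round(rate * n))] = True
    rng.shuffle(mask)
    return mask


def _assign_labels(cfg: SimConfig, rng: np.random.Generator) -> list[set[str]]:
    """Exact-count assignment with single- and double-labeled sites.

    Sites are split evenly across the set-1 labels; each set-1 label p is
    paired with one set-2 label q, and its block is divided into {p}, {q}
    and {p, q} sites so that the realized co-occurrence rate
    P(q | p) = P(p | q) equals the requested overlap up to rounding. The
    single-label sites give every label a subclass not shared with its
    partner, which is what lets the label models separate at high overlap.
    """
    set1, set2 = cfg.label_sets[0], cfg.label_sets[1]
    n = cfg.n_sites
    o = cfg.overlap
    # Block size m per set-1 label: each block holds {p,partner} at rate o,
    # {p,cross} and {p} at rate (1-o)/2 each; each set-2 label additionally
    # gets a single-label block of (1-o)m/2 sites, which makes the realized
    # co-occurrence symmetric: P(partner|p) = P(p|partner) = o. Every label
    # then spans three subclasses (its two doubles and its single), so the
    # median label update is robust to leakage from any one subclass.
    m = n / (len(set1) + len(set2) * (1.0 - o) / 2.0)
    labels: list[set[str]] = []
    for i1, p in enumerate(set1):
        partner = set2[i1 % len(set2)]
        cross = set2[(i1 + 1) % len(set2)]
        n_pair = int(round(m * o))
        n_cross = int(round(m * (1.0 - o) / 2.0))
        labels.extend([{p, partner}] * n_pair + [{p, cross}] * n_cross
                      + [{p}] * n_cross)
    for q in set2:
        n_single = int(round(m * (1.0 - o) / 2.0))
        labels.extend([{q}] * n_single)
    # exact-count rounding can drift a few sites from n; trim or pad singles
    while len(labels) > n:
        labels.pop()
    while len(labels) < n:
        labels.append({set1[len(labels) % len(set1)]})
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def _insert_motifs(seqs, labels, cfg, rng) -> tuple[list[str], list[list[dict]], int]:
    insertions: list[list[dict]] = [[] for _ in seqs]
    skipped = 0
    all_labels = [p for s in cfg.label_sets for p in s]
    carriers = {p: np.flatnonzero([p in s for s in labels]) for p in all_labels}
    chosen = {p: carriers[p][_exact_count_mask(carriers[p].size, cfg.insertion_freq, rng)]
              for p in all_labels}
    for p in all_labels:
        pwm = cfg.motif_assignment[p]
        w = pwm.shape[0]
        if w > cfg.seq_len:
            raise ValueError(f"motif for label {p} longer than seq_len")
        for i in chosen[p]:
            placed = False
            for _ in range(10):
                start = int(rng.integers(0, cfg.seq_len - w + 1))
                if all(start + w <= rec["start"] or start >= rec["end"]
                       for rec in insertions[i]):
                    placed = True
                    break
            if not placed:
                skipped += 1
                continue
            inst = sample_pwm_instance(pwm, rng)
            s = seqs[i]
            seqs[i] = s[:start] + inst + s[start + w:]
            insertions[i].append({"label": p, "motif": _motif_name(cfg, p),
                                  "start": start, "end": start + w, "instance": inst})
    return seqs, insertions, skipped


def _motif_name(cfg: SimConfig, label: str) -> str:
    pwm = cfg.motif_assignment[label]
    for name, M in BUNDLED_PWMS.items():
        if M.shape == pwm.shape and np.allclose(M, pwm):
            return name
    return f"motif_{label}"


def generate(cfg: SimConfig, background: MarkovBackground | None = None
             ) -> tuple[list[str], GroundTruth]:
    """Generate one synthetic dataset: sequences plus a ground-truth ledger."""
    rng = np.random.default_rng(cfg.seed)
    if background is None:
        background = default_background(cfg.markov_order)
    seqs = background.sample(cfg.n_sites, cfg.seq_len, rng)
    labels = _assign_labels(cfg, rng)
    seqs, insertions, skipped = _insert_motifs(seqs, labels, cfg, rng)
    truth = GroundTruth(labels=labels, insertions=insertions,
                        motif_names={p: _motif_name(cfg, p)
                                     for s in cfg.label_sets for p in s},
                        skipped=skipped)
    return seqs, truth


def fig_design_fixture(seed: int = 1, n_sites: int = 9000) -> tuple[list[str], GroundTruth, SimConfig]:
    """The five-label benchmark design: 9,000 sequences, labels {A,B,C} x {X,Y}.

    Every sequence carries one label from each set; the co-occurrence pattern
    pairs A strongly with X and C strongly with Y, with B intermediate. Each
    label gets a distinct bundled PWM, inserted at 70% of its sites.
    """
    names = list(BUNDLED_PWMS)
    cfg = SimConfig(
        n_sites=n_sites,
        label_sets=(("A", "B", "C"), ("X", "Y")),
        overlap=0.85,
        insertion_freq=0.7,
        motif_assignment={lab: BUNDLED_PWMS[names[i]]
                          for i, lab in enumerate(["A", "B", "C", "X", "Y"])},
        seed=seed,
    )
    rng = np.random.default_rng(cfg.seed)
    background = default_background(cfg.markov_order)
    seqs = background.sample(cfg.n_sites, cfg.seq_len, rng)

    # co-occurrence pattern: P(X | set-1 label); strong A<->X, C<->Y pairing
    p_x = {"A": 0.85, "B": 0.50, "C": 0.15}
    n = cfg.n_sites
    set1 = ["A", "B", "C"]
    lab1 = np.array([set1[i * 3 // n] for i in range(n)])
    rng.shuffle(lab1)
    labels: list[set[str]] = [{l} for l in lab1]
    for p in set1:
        ix = np.flatnonzero(lab1 == p)
        mask = _exact_count_mask(ix.size, p_x[p], rng)
        for j, takes_x in zip(ix, mask):
            labels[j].add("X" if takes_x else "Y")
    seqs, insertions, skipped = _insert_motifs(seqs, labels, cfg, rng)
    truth = GroundTruth(labels=labels, insertions=insertions,
                        motif_names={lab: names[i]
                                     for i, lab in enumerate(["A", "B", "C", "X", "Y"])},
                        skipped=skipped)
    return seqs, truth, cfg
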