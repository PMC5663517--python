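"""Hill-finding: locate short high-scoring subregions under a k-mer model.

A trained label (or subclass) k-mer weight vector is scanned across each
sequence: every 15 bp window is scored by summing the model weight of each
k-mer occurrence it contains (raw occurrence counts — per-window
standardization is undefined, so weights multiply plain counts). Maximal
runs of windows scoring above a threshold (0.1 by default) are merged and
each run is reported as a single 10-15 bp "hill" centered on its
best-scoring window. These hills carry the discriminative signal and feed
motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import KmerSpace

HILL_MIN = 10
HILL_MAX = 15
SCAN_WINDOW = 15
DEFAULT_THRESHOLD = 0.1


@dataclass
class Hill:
    """A focused high-scoring subregion of one input sequence."""

    seq_id: int
    start: int  # 0-based, half-open within the sequence
    end: int
    score: float
    source_model: str
    dna: str

    def __post_init__(self) -> None:
        if not HILL_MIN <= self.end - self.start <= HILL_MAX:
            raise ValueError("hill span must be 10-15 bp")


def position_weight_track(seq: str, w: np.ndarray, space: KmerSpace) -> dict[int, np.ndarray]:
    """Per-k arrays of the model weight of the k-mer starting at each offset."""
    tracks = {}
    for k in space.k_values:
        cols = space.position_columns(seq, k)
        t = np.zeros(cols.shape)
        ok = cols >= 0
        t[ok] = w[cols[ok]]
        tracks[k] = t
    return tracks


def scan(seq: str, w: np.ndarray, space: KmerSpace,
         window: int = SCAN_WINDOW) -> np.ndarray:
    """Score track over all ``window``-bp windows (length L - window + 1).

    The score of a window is the sum of model weights over every k-mer
    occurrence fully contained in it.
    """
    L = len(seq)
    if L < window:
        return np.empty(0)
    n_win = L - window + 1
    out = np.zeros(n_win)
    tracks = position_weight_track(seq, w, space)
    for k, t in tracks.items():
        span = window - k + 1  # k-mer starts per window
        if t.size < span:
            continue
        c = np.concatenate(([0.0], np.cumsum(t)))
        sums = c[span:] - c[:-span]  # sliding sums over all start positions
        out += sums[:n_win]
    return out


def call_hills(track: np.ndarray, seq: str, seq_id: int = 0,
               source_model: str = "", threshold: float = DEFAULT_THRESHOLD,
               window: int = SCAN_WINDOW) -> list[Hill]:
    """Segment a score track into hills.

    Maximal runs of windows with score > threshold become one hill each,
    centered on the run's best window. Overlapping candidates from nearby
    runs are resolved greedily by score so no two hills from the same model
    overlap on the same sequence.
    """
    if track.size == 0:
        return []
    above = track > threshold
    if not above.any():
        return []
    # run boundaries of the boolean mask
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(track.size)

    candidates = []
    for s, e in zip(starts, ends):
        m = s + int(np.argmax(track[s:e]))
        candidates.append((float(track[m]), m, m + window))
    candidates.sort(reverse=True)

    hills: list[Hill] = []
    taken: list[tuple[int, int]] = []
    for score, h_start, h_end in candidates:
        if any(h_start < e and h_end > s for s, e in taken):
            continue
        taken.append((h_start, h_end))
        hills.append(Hill(seq_id=seq_id, start=h_start, end=h_end, score=score,
                          source_model=source_model, dna=seq[h_start:h_end]))
    hills.sort(key=lambda h: h.start)
    return hills


def find_hills(seqs: list[str], seq_ids: list[int], w: np.ndarray,
               space: KmerSpace, source_model: str = "",
               threshold: float = DEFAULT_THRESHOLD) -> list[Hill]:
    """Scan a model over many sequences and collect all hills."""
    out: list[Hill] = []
    for sid, seq in zip(seq_ids, seqs):
        track = scan(seq, w, space)
        out.extend(call_hills(track, seq, seq_id=sid, source_model=source_model,
                              threshold=threshold))
    return out
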