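import numpy as np
import pytest

from seqdemux import KmerSpace, LabeledDataset, SimConfig, generate

BASES = "ACGT"


@pytest.fixture(scope="session")
def space():
    return KmerSpace()


@pytest.fixture(scope="session")
def space3():
    """Tiny 3-mer space for fast trainer tests."""
    return KmerSpace(k_values=(3,))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, p=None):
    return "".join(rng.choice(list(BASES), size=length, p=p))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset (overlap 0.6) shared across tests."""
    cfg = SimConfig(n_sites=600, overlap=0.6, seed=7)
    seqs, truth = generate(cfg)
    return LabeledDataset(sequences=seqs, label_sets=truth.labels), truth, cfg


@pytest.fixture(scope="session")
def noisy_dataset():
    """Two overlapping classes: the class motif appears in only 60% of the
    sequences and 10% of labels are flipped, so classes are not separable
    and the unpenalized maximum-likelihood fit is finite."""
    r = np.random.default_rng(4242)
    seqs, labels = [], []
    for i in range(400):
        s = list(random_seq(r, 40))
        cls = i % 2
        if r.random() < 0.5:
            motif = "GACGTC" if cls == 0 else "TTAACC"
            off = int(r.integers(0, 40 - 6))
            s[off:off + 6] = motif
        if r.random() < 0.2:
            cls = 1 - cls
        seqs.append("".join(s))
        labels.append({"a"} if cls == 0 else {"b"})
    return seqs, labels


@pytest.fixture(scope="session")
def planted_dataset():
    """Two disjoint subclasses, each defined by one planted 6-mer.

    200 sequences of length 60; subclass 'a' sequences carry GACGTC, 'b'
    sequences carry TTAACC, inserted at a random offset on a uniform
    background.
    """
    r = np.random.default_rng(99)
    seqs, labels = [], []
    for i in range(200):
        s = list(random_seq(r, 60))
        motif = "GACGTC" if i % 2 == 0 else "TTAACC"
        off = int(r.integers(0, 60 - 6))
        s[off:off + 6] = motif
        seqs.append("".join(s))
        labels.append({"a"} if i % 2 == 0 else {"b"})
    return seqs, labels
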