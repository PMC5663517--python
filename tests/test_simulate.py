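import numpy as np
import pytest

from seqdemux import (BUNDLED_PWMS, MarkovBackground, SimConfig,
                      default_background, fig_design_fixture,
                      fit_markov_background, generate,
                      trinucleotide_frequencies)
from seqdemux.simulate import sample_pwm_instance


def realized_overlap(labels, p, q):
    n_p = sum(1 for s in labels if p in s)
    n_pq = sum(1 for s in labels if p in s and q in s)
    return n_pq / n_p


class TestMarkovBackground:
    def test_training_on_homopolymer_reproduces_it(self):
        bg = fit_markov_background(["A" * 500], order=2)
        rng = np.random.default_rng(0)
        seqs = bg.sample(5, 100, rng)
        # add-one smoothing leaves a small escape probability; A dominates
        counts = "".join(seqs)
        assert counts.count("A") / len(counts) > 0.95

    def test_order_zero_reduces_to_iid_base_sampling(self):
        bg = fit_markov_background(["ACGT" * 250], order=0)
        assert bg.trans.shape == (1, 4)
        assert np.allclose(bg.trans[0], 0.25, atol=0.01)

    def test_fitted_model_reproduces_trinucleotide_spectrum(self):
        rng = np.random.default_rng(11)
        truth = default_background()
        train = truth.sample(2000, 250, rng)  # 500 kb of training sequence
        fitted = fit_markov_background(train, order=2)
        sample = fitted.sample(4000, 250, rng)  # 1 Mb generated
        dev = np.abs(trinucleotide_frequencies(sample)
                     - trinucleotide_frequencies(train)).max()
        assert dev < 0.005

    def test_default_background_depletes_cpg(self):
        rng = np.random.default_rng(3)
        seqs = default_background().sample(500, 200, rng)
        f = trinucleotide_frequencies(seqs)
        # CG-containing trinucleotides rare relative to average
        cg_codes = [i for i in range(64)
                    if "CG" in "ACGT"[i // 16] + "ACGT"[(i // 4) % 4] + "ACGT"[i % 4]]
        assert f[cg_codes].mean() < f.mean() / 2

    def test_json_round_trip(self):
        bg = default_background()
        bg2 = MarkovBackground.from_json(bg.to_json())
        assert bg2.order == bg.order
        assert np.allclose(bg2.trans, bg.trans)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            fit_markov_background(["ACGT"], order=-1)


class TestGenerate:
    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(n_sites=300, overlap=0.7, seed=5)
        s1, t1 = generate(cfg)
        s2, t2 = generate(SimConfig(n_sites=300, overlap=0.7, seed=5))
        assert s1 == s2
        assert t1.to_json() == t2.to_json()

    @pytest.mark.parametrize("overlap", [0.5, 0.7, 0.9, 0.99])
    def test_realized_overlap_tracks_request(self, overlap):
        cfg = SimConfig(n_sites=2000, overlap=overlap, seed=2)
        _, truth = generate(cfg)
        assert realized_overlap(truth.labels, "A", "X") == pytest.approx(
            overlap, abs=0.02)
        assert realized_overlap(truth.labels, "X", "A") == pytest.approx(
            overlap, abs=0.02)

    def test_high_overlap_example(self):
        _, truth = generate(SimConfig(n_sites=2000, overlap=0.99, seed=3))
        assert realized_overlap(truth.labels, "A", "X") >= 0.97

    def test_insertion_frequency_on_label_bearing_sites(self):
        _, truth = generate(SimConfig(n_sites=2000, overlap=0.7, seed=4))
        for label in ("A", "B", "X", "Y"):
            carriers = [i for i, s in enumerate(truth.labels) if label in s]
            with_instance = sum(
                1 for i in carriers
                if any(r["label"] == label for r in truth.insertions[i]))
            assert with_instance / len(carriers) == pytest.approx(0.70, abs=0.02)

    def test_zero_insertion_rate_leaves_pure_background(self):
        seqs, truth = generate(SimConfig(n_sites=100, insertion_freq=0.0, seed=6))
        assert all(not recs for recs in truth.insertions)

    def test_ledger_consistent_with_sequences(self):
        seqs, truth = generate(SimConfig(n_sites=200, seed=8))
        for i, recs in enumerate(truth.insertions):
            for r in recs:
                assert seqs[i][r["start"]:r["end"]] == r["instance"]

    def test_insertions_do_not_overlap(self):
        _, truth = generate(SimConfig(n_sites=500, overlap=0.9, seed=9))
        for recs in truth.insertions:
            spans = sorted((r["start"], r["end"]) for r in recs)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_motif_longer_than_sequence_rejected(self):
        cfg = SimConfig(n_sites=10, seq_len=8)
        with pytest.raises(ValueError):
            generate(cfg)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(overlap=1.5)
        with pytest.raises(ValueError):
            SimConfig(insertion_freq=-0.1)


class TestFigDesignFixture:
    @pytest.fixture(scope="class")
    def fixture(self):
        return fig_design_fixture(seed=1, n_sites=9000)

    def test_emits_requested_number_of_sequences(self, fixture):
        seqs, truth, cfg = fixture
        assert len(seqs) == 9000

    def test_every_sequence_is_labeled(self, fixture):
        _, truth, _ = fixture
        assert all(len(s) >= 1 for s in truth.labels)

    def test_five_labels_with_distinct_motifs(self, fixture):
        _, truth, _ = fixture
        assert sorted(truth.motif_names) == ["A", "B", "C", "X", "Y"]
        assert len(set(truth.motif_names.values())) == 5

    def test_per_label_insertion_rate(self, fixture):
        _, truth, _ = fixture
        for label in "ABCXY":
            carriers = [i for i, s in enumerate(truth.labels) if label in s]
            hit = sum(1 for i in carriers
                      if any(r["label"] == label for r in truth.insertions[i]))
            assert hit / len(carriers) == pytest.approx(0.70, abs=0.02)

    def test_a_pairs_strongly_with_x(self, fixture):
        _, truth, _ = fixture
        assert realized_overlap(truth.labels, "A", "X") > 0.8
        assert realized_overlap(truth.labels, "C", "Y") > 0.8


class TestSamplePwmInstance:
    def test_instances_follow_column_distributions(self):
        rng = np.random.default_rng(1)
        pwm = BUNDLED_PWMS["ebox"]
        hits = sum(sample_pwm_instance(pwm, rng) == "CACGTG" for _ in range(500))
        expected = np.prod(pwm.max(axis=1))
        assert hits / 500 == pytest.approx(expected, abs=0.08)
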