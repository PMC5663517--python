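import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from seqdemux import (LabelStructure, TrainConfig, admm_fit, count_and_standardize,
                      fit_mcc_baseline, instance_weights, shrinkage, update_labels)
from seqdemux.model import nll
from seqdemux.trainer import TrainingTrace


class TestShrinkage:
    @pytest.mark.parametrize("a,k,expected", [
        (1.2, 0.5, 0.7),
        (-0.2, 0.5, 0.0),
        (-1.0, 0.5, -0.5),
        (0.5, 0.5, 0.0),
        (0.0, 0.0, 0.0),
    ])
    def test_closed_form(self, a, k, expected):
        assert shrinkage(np.array([a]), k)[0] == pytest.approx(expected)

    def test_vector_thresholds_broadcast(self):
        a = np.array([[1.0, -1.0], [1.0, -1.0]])
        k = np.array([[0.25], [0.75]])
        out = shrinkage(a, k)
        assert np.allclose(out, [[0.75, -0.75], [0.25, -0.25]])

    def test_never_increases_magnitude(self, rng):
        a = rng.normal(size=100)
        out = shrinkage(a, 0.3)
        assert (np.abs(out) <= np.abs(a)).all()
        assert (out * a >= 0).all()  # never flips sign

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrinkage(np.ones(3), -0.1)


class TestMedianUpdate:
    def _structure(self):
        return LabelStructure.from_label_sets([{"A"}, {"A", "X"}, {"X"}])

    def test_median_of_three(self):
        s = self._structure()
        W_sub = np.zeros((3, 2))
        W_sub[:, 0] = [0.2, -0.1, 0.4]  # subclasses A, A+X, X all span...
        W_lab = update_labels(W_sub, s)
        # label A spans subclasses {A, A+X}: even set -> mean of middles
        a_rows = s.spanned("A")
        assert W_lab[s.labels.index("A"), 0] == pytest.approx(
            np.median(W_sub[a_rows, 0]))

    def test_even_set_takes_mean_of_middle(self):
        s = self._structure()
        W_sub = np.zeros((3, 2))
        W_sub[s.spanned("A"), 0] = [0.1, 0.3]
        W_lab = update_labels(W_sub, s)
        assert W_lab[s.labels.index("A"), 0] == pytest.approx(0.2)

    def test_label_spanning_one_subclass_copies_it(self):
        labels = [{"A"}, {"A", "X"}]  # X spans only A+X
        s = LabelStructure.from_label_sets(labels)
        W_sub = np.arange(10.0).reshape(2, 5)
        W_lab = update_labels(W_sub, s)
        i = s.subclass_names.index("A+X")
        assert np.allclose(W_lab[s.labels.index("X")], W_sub[i, :4])

    def test_zero_points_suppress_single_subclass_support(self):
        s = self._structure()
        W_sub = np.zeros((3, 2))
        W_sub[:, 0] = [0.0, 0.5, 0.0]
        W_lab = update_labels(W_sub, s, zero_points=2)
        assert (W_lab[:, 0] == 0).all()
        # but consistent support across all spanned subclasses survives
        W_sub[:, 0] = [0.4, 0.5, 0.6]
        W_lab = update_labels(W_sub, s, zero_points=2)
        assert W_lab[s.labels.index("A"), 0] > 0

    def test_unspanned_label_rejected(self):
        s = self._structure()
        with pytest.raises(ValueError):
            s.spanned("Z")


def _featurized(planted_dataset, space3):
    seqs, labels = planted_dataset
    fm = count_and_standardize(seqs, space3)
    s = LabelStructure.from_label_sets(labels)
    Y = s.membership(labels)
    b = instance_weights(labels, s)
    return fm, s, Y, b


class TestAdmmFit:
    def test_unpenalized_fit_matches_reference(self, noisy_dataset, space3):
        """lambda = 0 reduces to plain weighted multinomial logistic regression."""
        fm, s, Y, b = _featurized(noisy_dataset, space3)
        cfg = TrainConfig(lam=0.0, lam_zero=0.0, outer_sweeps=1,
                          max_admm_iters=80, inner_maxiter=300)
        W = admm_fit(fm.X, Y, b, s, cfg)
        ref = LogisticRegression(penalty=None, max_iter=2000, tol=1e-8)
        ref.fit(fm.X, Y.argmax(axis=1), sample_weight=b)
        if ref.coef_.shape[0] == 1:  # binary fit: expand to two logit rows
            W_ref = np.vstack([np.zeros(fm.X.shape[1] + 1),
                               np.hstack([ref.coef_[0], ref.intercept_])])
        else:
            W_ref = np.hstack([ref.coef_, ref.intercept_[:, None]])
        assert abs(nll(fm.X, Y, b, W.W_sub) - nll(fm.X, Y, b, W_ref)) < 1e-3

    def test_planted_kmer_gets_largest_weight(self, planted_dataset, space3):
        fm, s, Y, b = _featurized(planted_dataset, space3)
        W = admm_fit(fm.X, Y, b, s, TrainConfig(lam=1.0, lam_zero=0.5))
        for label, motif in [("a", "GACGTC"), ("b", "TTAACC")]:
            i = s.subclass_names.index(label)
            w = W.W_sub[i, :-1]
            constituent = {space3.canonical(motif[j:j + 3]) for j in range(4)}
            assert w.argmax() in constituent

    def test_pooled_threads_match_single_thread(self, planted_dataset, space3):
        fm, s, Y, b = _featurized(planted_dataset, space3)
        from seqdemux.model import objective
        outs = []
        for threads in (1, 4):
            cfg = TrainConfig(lam=0.5, lam_zero=0.25, threads=threads,
                              max_admm_iters=200, eps_abs=1e-6, eps_rel=1e-4)
            W = admm_fit(fm.X, Y, b, s, cfg)
            outs.append(objective(W, fm.X, Y, b, 0.5, 0.25,
                                  cfg.label_zero_points))
        assert outs[0] == pytest.approx(outs[1], abs=1e-4)

    def test_objective_non_increasing_over_sweeps(self, planted_dataset, space3):
        fm, s, Y, b = _featurized(planted_dataset, space3)
        trace = TrainingTrace()
        cfg = TrainConfig(lam=1.0, lam_zero=0.5, outer_sweeps=4,
                          label_sparse_sweeps=0, outer_tol=0.0)
        admm_fit(fm.X, Y, b, s, cfg, trace=trace)
        objs = [sw["objective"] for sw in trace.sweeps]
        assert all(b2 <= a2 + 1e-6 for a2, b2 in zip(objs, objs[1:]))

    def test_large_lambda_fuses_subclasses_to_labels(self, planted_dataset, space3):
        fm, s, Y, b = _featurized(planted_dataset, space3)
        cfg = TrainConfig(lam=100.0, lam_zero=0.0, label_sparse_sweeps=0,
                          eps_abs=1e-6, eps_rel=1e-5)
        W = admm_fit(fm.X, Y, b, s, cfg)
        for i, combo in enumerate(s.subclasses):
            for p in combo:
                j = s.labels.index(p)
                diff = np.abs(W.W_sub[i, :-1] - W.W_lab[j]).sum()
                assert diff < 1e-3

    def test_stopping_criteria_hold_at_convergence(self, planted_dataset, space3):
        fm, s, Y, b = _featurized(planted_dataset, space3)
        trace = TrainingTrace()
        admm_fit(fm.X, Y, b, s, TrainConfig(lam=1.0, lam_zero=0.5), trace=trace)
        for sw in trace.sweeps:
            assert sw["admm_converged"]
        last = trace.admm[-1]
        assert last["primal"] < last["eps_pri"]
        assert last["dual"] < last["eps_dual"]

    def test_single_subclass_rejected(self, space3):
        labels = [{"A"}] * 10
        s = LabelStructure.from_label_sets(labels)
        with pytest.raises(ValueError):
            admm_fit(np.zeros((10, 4)), s.membership(labels),
                     np.ones(10), s, TrainConfig())

    def test_nonconvergence_warns_and_returns(self, planted_dataset, space3):
        fm, s, Y, b = _featurized(planted_dataset, space3)
        cfg = TrainConfig(lam=1.0, max_admm_iters=1, outer_sweeps=1,
                          eps_abs=1e-12, eps_rel=1e-12)
        with pytest.warns(RuntimeWarning):
            W = admm_fit(fm.X, Y, b, s, cfg)
        assert np.isfinite(W.W_sub).all()


class TestLambdaSelection:
    def test_cv_selector_returns_grid_member(self, noisy_dataset, space3):
        from seqdemux import select_lambda_cv
        from seqdemux import LabelStructure, instance_weights, count_and_standardize
        seqs, labels = noisy_dataset
        fm = count_and_standardize(seqs[:150], space3)
        s = LabelStructure.from_label_sets(labels[:150])
        Y = s.membership(labels[:150])
        b = instance_weights(labels[:150], s)
        from seqdemux import TrainConfig
        lam = select_lambda_cv(fm.X, Y, b, s, grid=(0.5, 5.0), folds=3,
                               config=TrainConfig(outer_sweeps=2, max_admm_iters=40))
        assert lam in (0.5, 5.0)


class TestMccBaseline:
    def test_multilabel_site_contributes_one_row_per_label(self, space3, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(60)]
        labels = [{"A", "X"} if i < 20 else ({"A"} if i < 40 else {"X"})
                  for i in range(60)]
        fm = count_and_standardize(seqs, space3)
        W, icpt, labs = fit_mcc_baseline(fm.X, labels)
        assert labs == ["A", "X"]
        assert W.shape == (2, fm.X.shape[1])

    def test_single_label_data_reduces_to_multinomial(self, planted_dataset, space3):
        seqs, labels = planted_dataset
        fm = count_and_standardize(seqs, space3)
        W, icpt, labs = fit_mcc_baseline(fm.X, labels, lam=0.5, seed=1)
        ref = LogisticRegression(penalty="l1", solver="saga", C=2.0,
                                 max_iter=200, tol=1e-3, random_state=1)
        ref.fit(fm.X, [0 if "a" in s else 1 for s in labels])
        pred_ours = (fm.X @ W.T + icpt).argmax(axis=1)
        pred_ref = ref.predict(fm.X)
        assert (pred_ours == pred_ref).mean() > 0.95

    def test_planted_kmers_ranked_top_when_labels_disjoint(self, planted_dataset, space3):
        seqs, labels = planted_dataset
        fm = count_and_standardize(seqs, space3)
        W, _, labs = fit_mcc_baseline(fm.X, labels, lam=0.5)
        for lab, motif in [("a", "GACGTC"), ("b", "TTAACC")]:
            constituent = {space3.canonical(motif[j:j + 3]) for j in range(4)}
            assert W[labs.index(lab)].argmax() in constituent
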