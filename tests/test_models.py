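"""Model contract tests: decay, LR closed forms, early stopping, AUROC."""

import numpy as np
import pytest

from ehrisk.autodiff import sigmoid
from ehrisk.encoding import EncodedSequence
from ehrisk.models import (
    EvalReport,
    ModelConfig,
    evaluate,
    load_model,
    make_logistic_model,
    predict_proba,
    predict_risk,
    save_model,
    tlstm_decay,
    train,
)


def seqs_from_bags(bags, labels, rng=None):
    out = []
    for i, (bag, lab) in enumerate(zip(bags, labels)):
        idxs = frozenset(int(j) for j in np.flatnonzero(bag))
        visits = [(idxs, 0)] if idxs else []
        out.append(EncodedSequence(visits, int(lab), f"P{i}"))
    return out


def random_dataset(rng, n, v=12, signal_idx=3):
    bags = (rng.random((n, v)) < 0.3).astype(float)
    labels = bags[:, signal_idx].astype(int)
    return seqs_from_bags(bags, labels)


class TestTlstmDecay:
    def test_zero_gap_means_no_decay(self):
        assert tlstm_decay(0) == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        d = tlstm_decay(np.array([0, 1, 30, 365, 3650]))
        assert np.all(np.diff(d) < 0) and np.all(d > 0)

    def test_matches_log_closed_form(self):
        for t in (0, 7, 90):
            assert tlstm_decay(t) == pytest.approx(1.0 / np.log(np.e + t))

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            tlstm_decay(-1)


class TestLogisticPath:
    def test_prediction_is_exact_sigmoid(self, rng):
        for _ in range(20):
            coef = rng.normal(size=10)
            b = float(rng.normal())
            bag = (rng.random(10) < 0.5).astype(float)
            model = make_logistic_model(coef, b)
            (s,) = seqs_from_bags([bag], [0])
            assert predict_risk(model, s) == pytest.approx(
                float(sigmoid(coef @ bag + b)), abs=1e-12)

    def test_adding_positive_weight_code_never_decreases_risk(self, rng):
        coef = np.abs(rng.normal(size=8))
        model = make_logistic_model(coef, 0.0)
        base = EncodedSequence([(frozenset({1}), 0)], 0, "p")
        more = EncodedSequence([(frozenset({1, 2}), 0)], 0, "p")
        assert predict_risk(model, more) >= predict_risk(model, base)

    def test_duplicate_visit_leaves_presence_bag_prediction_unchanged(self):
        model = make_logistic_model(np.ones(5), -1.0)
        s1 = EncodedSequence([(frozenset({1, 3}), 0)], 0, "p")
        s2 = EncodedSequence([(frozenset({1, 3}), 0), (frozenset({1, 3}), 0)], 0, "p")
        assert predict_risk(model, s1) == predict_risk(model, s2)

    def test_empty_sequence_returns_intercept_sigmoid(self):
        model = make_logistic_model(np.ones(5), -0.7)
        s = EncodedSequence([], 0, "p")
        assert predict_risk(model, s) == pytest.approx(float(sigmoid(-0.7)))

    def test_lr_separable_fixture_reaches_high_auroc(self, rng):
        train_s = random_dataset(rng, 400)
        val_s = random_dataset(rng, 200)
        model = train("LR", train_s, val_s, ModelConfig(model_kind="LR"), 12)
        assert model.history[0] > 0.99


class TestTraining:
    def test_single_class_split_rejected(self, rng):
        samples = random_dataset(rng, 50)
        all_zero = [EncodedSequence(s.visits, 0, s.patient_id) for s in samples]
        with pytest.raises(ValueError, match="both classes"):
            train("LR", all_zero, samples, ModelConfig(model_kind="LR"), 12)

    def test_max_epochs_one_stops_at_one(self, rng):
        cfg = ModelConfig(model_kind="RNN", embedding_dim=8, hidden_dim=8,
                          n_layers=1, max_epochs=1, seed=0)
        model = train("RNN", random_dataset(rng, 80), random_dataset(rng, 40),
                      cfg, 12)
        assert model.stopped_epoch == 1

    @pytest.mark.parametrize("kind", ["RNN", "TLSTM", "RETAIN"])
    def test_early_stopping_respects_patience(self, rng, kind):
        """Training never runs more than `patience` epochs past the best
        validation AUROC."""
        cfg = ModelConfig(model_kind=kind, embedding_dim=8, hidden_dim=8,
                          n_layers=1, max_epochs=12, patience=2, seed=1)
        model = train(kind, random_dataset(rng, 120), random_dataset(rng, 60),
                      cfg, 12)
        best_epoch = int(np.argmax(model.history)) + 1
        assert model.stopped_epoch <= max(best_epoch + cfg.patience,
                                          cfg.patience + 1)

    @pytest.mark.parametrize("kind", ["RNN", "TLSTM", "RETAIN"])
    def test_sequence_models_fit_separable_signal(self, rng, kind):
        cfg = ModelConfig(model_kind=kind, embedding_dim=12, hidden_dim=12,
                          n_layers=1, max_epochs=25, patience=25,
                          weight_decay=0.0, dropout=0.0, seed=2,
                          learning_rate=3e-3)
        model = train(kind, random_dataset(rng, 500), random_dataset(rng, 200),
                      cfg, 12)
        assert max(model.history) > 0.95

    def test_training_deterministic_given_seed(self, rng):
        cfg = ModelConfig(model_kind="RNN", embedding_dim=8, hidden_dim=8,
                          n_layers=1, max_epochs=3, seed=5)
        tr, va = random_dataset(rng, 100), random_dataset(rng, 50)
        m1 = train("RNN", tr, va, cfg, 12)
        m2 = train("RNN", tr, va, cfg, 12)
        assert m1.history == m2.history

    def test_empty_neural_sequence_predicts_base_rate(self, rng):
        cfg = ModelConfig(model_kind="RNN", embedding_dim=8, hidden_dim=8,
                          n_layers=1, max_epochs=2, seed=0)
        model = train("RNN", random_dataset(rng, 80), random_dataset(rng, 40),
                      cfg, 12)
        assert predict_risk(model, EncodedSequence([], 0, "p")) == \
            pytest.approx(model.base_rate)

    def test_save_load_round_trip(self, rng, tmp_path):
        cfg = ModelConfig(model_kind="RETAIN", embedding_dim=8, hidden_dim=8,
                          n_layers=1, max_epochs=2, seed=0)
        tr, va = random_dataset(rng, 80), random_dataset(rng, 40)
        model = train("RETAIN", tr, va, cfg, 12)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(predict_proba(model, va),
                                   predict_proba(loaded, va))


def brute_force_auroc(y, p):
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pos_i > neg_j) + 0.5 * (pos_i == neg_j)
               for pos_i in pos for neg_j in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluation:
    def _model_with_scores(self, scores):
        # identity LR over one-hot bags reproduces any score vector
        logits = np.log(np.array(scores) / (1 - np.array(scores)))
        model = make_logistic_model(logits, 0.0)
        samples = [EncodedSequence([(frozenset({i}), 0)], 0, f"p{i}")
                   for i in range(len(scores))]
        return model, samples

    def test_perfect_separation_gives_auroc_and_f1_one(self):
        model, samples = self._model_with_scores([0.9, 0.8, 0.2, 0.1])
        for s, lab in zip(samples, [1, 1, 0, 0]):
            s.label = lab
        model.threshold = 0.5
        report = evaluate(model, samples)
        assert report.auroc == 1.0 and report.f1 == 1.0

    def test_all_case_scores_above_all_control_scores(self):
        model, samples = self._model_with_scores([0.9, 0.8, 0.7, 0.1])
        for s, lab in zip(samples, [1, 1, 0, 0]):
            s.label = lab
        assert evaluate(model, samples).auroc == 1.0

    def test_random_scores_near_half_auroc(self, rng):
        n = 10_000
        scores = rng.random(n)
        y = (rng.random(n) < 0.5).astype(int)
        from sklearn.metrics import roc_auc_score
        assert abs(roc_auc_score(y, scores) - 0.5) < 0.02

    def test_rank_auroc_matches_pairwise_brute_force(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(10):
            n = int(rng.integers(10, 200))
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc_score(y, p) == pytest.approx(brute_force_auroc(y, p))

    def test_single_class_test_set_rejected(self):
        model, samples = self._model_with_scores([0.9, 0.8])
        with pytest.raises(ValueError):
            evaluate(model, samples)

    def test_f1_consistent_with_precision_recall(self, rng):
        train_s = random_dataset(rng, 300)
        val_s = random_dataset(rng, 100)
        model = train("LR", train_s, val_s, ModelConfig(model_kind="LR"), 12)
        report = evaluate(model, random_dataset(rng, 100))
        if report.precision + report.recall > 0:
            assert report.f1 == pytest.approx(
                2 * report.precision * report.recall
                / (report.precision + report.recall))
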