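"""Losses, label weights, model assembly, training protocol, metrics."""

import numpy as np
import pytest

from geoprot.autodiff import Tensor
from geoprot.metrics import (compute_label_weights, evaluate, micro_aupr,
                             protein_centric_fmax, spearman_rho)
from geoprot.models import (ProteinPropertyPredictor, TrainConfig, build_model,
                            load_checkpoint, loss, save_checkpoint,
                            stratified_split)


class TestLabelWeights:
    def test_balanced_labels_give_unit_weights(self):
        labels = np.zeros((30, 3))
        labels[:10, 0] = labels[10:20, 1] = labels[20:, 2] = 1
        np.testing.assert_allclose(compute_label_weights(labels), [1.0, 1.0, 1.0])

    def test_imbalanced_labels_clamp_both_ways(self):
        # N+ = (1, 99): 100/2 = 50 -> clamp 10; 100/198 ~ 0.505 -> clamp 1
        labels = np.zeros((100, 2))
        labels[0, 0] = 1
        labels[1:, 1] = 1
        np.testing.assert_allclose(compute_label_weights(labels), [10.0, 1.0])

    def test_weights_always_in_clamp_range(self, rng):
        for _ in range(20):
            labels = (rng.random((int(rng.integers(5, 50)),
                                  int(rng.integers(1, 6)))) < 0.3).astype(float)
            if labels.sum() == 0:
                continue
            import warnings as w
            with w.catch_warnings():
                w.simplefilter("ignore")
                weights = compute_label_weights(labels)
            assert weights.min() >= 1.0 and weights.max() <= 10.0

    def test_zero_positive_label_warns_and_clamps(self):
        labels = np.zeros((10, 2))
        labels[:5, 0] = 1
        with pytest.warns(UserWarning, match="zero positives"):
            weights = compute_label_weights(labels)
        assert weights[1] == 10.0


class TestLoss:
    def test_regression_zero_at_exact_predictions(self):
        t = np.array([[1.0], [2.0], [-0.5]])
        assert loss(t.copy(), t, "regression").data == 0.0

    def test_weighted_bce_matches_hand_oracle(self):
        logits = np.array([[0.5, -1.0, 2.0], [0.0, 1.5, -0.3]])
        targets = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        w = np.array([1.0, 1.0, 1.0])
        p = 1.0 / (1.0 + np.exp(-logits))
        hand = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).mean()
        got = loss(logits, targets, "multilabel", w).data
        assert abs(got - hand) < 1e-8

    def test_loss_linear_in_weights(self):
        logits = np.array([[0.5, -1.0], [2.0, 0.1]])
        targets = np.array([[1.0, 0.0], [0.0, 1.0]])
        l1 = loss(logits, targets, "multilabel", np.array([1.0, 2.0])).data
        l2 = loss(logits, targets, "multilabel", np.array([2.0, 4.0])).data
        assert abs(l2 - 2 * l1) < 1e-10

    def test_nonfinite_predictions_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            loss(np.array([[np.nan]]), np.array([[1.0]]), "regression")


class TestBuildModel:
    def test_two_stage_and_end_to_end_have_identical_parameters(self):
        kw = dict(hidden_scalar=12, hidden_vector=2)
        a = build_model("hybrid_gvp", "two_stage", "multilabel", 3, seed=0, **kw)
        b = build_model("hybrid_gvp", "end_to_end", "multilabel", 3, seed=0, **kw)
        sa, sb = a.state_dict(), b.state_dict()
        assert len(sa) == len(sb)
        for x, y in zip(sa, sb):
            np.testing.assert_array_equal(x, y)

    def test_structure_only_consumes_27_wide_scalars(self):
        net = build_model("gvp", "end_to_end", "multilabel", 2, seed=0,
                          hidden_scalar=8, hidden_vector=2)
        assert net.input_gvp.in_dims == (27, 3)

    def test_seq_only_has_no_gnn(self):
        net = build_model("seq_only", "end_to_end", "regression", 1, seed=0)
        assert not hasattr(net, "gnn_layers")
        assert net.head.weight.data.shape == (net.lm.h, 1)

    def test_invalid_combinations_raise(self):
        with pytest.raises(ValueError):
            build_model("gvp", "two_stage", "multilabel", 1)
        with pytest.raises(ValueError):
            build_model("unknown", "end_to_end", "multilabel", 1)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rates=())

    def test_hybrid_gat_uses_lm_only_scalars(self):
        net = build_model("hybrid_gat", "two_stage", "multilabel", 2, seed=0,
                          hidden_scalar=8, hidden_vector=2)
        assert net.feature_mode == "lm_only"
        assert net.gnn_layers[0].in_width == net.lm.h


@pytest.fixture(scope="module")
def tiny_task():
    from geoprot.synthetic import make_structure_task
    return make_structure_task(24, seed=5, min_length=15, max_length=20)


class TestTrainingProtocol:

    def test_loss_decreases_on_tiny_task(self, tiny_task):
        est = ProteinPropertyPredictor(
            family="gvp", mode="end_to_end", task="multilabel",
            hidden_scalar=16, hidden_vector=4, learning_rate=1e-3,
            batch_size=8, max_epochs=6, patience=10, seed=0)
        est.fit(tiny_task.structures, tiny_task.labels)
        h = est.history_
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_lm_frozen_during_phase_one(self, tiny_task):
        est = ProteinPropertyPredictor(
            family="hybrid_gvp", mode="two_stage", task="multilabel",
            hidden_scalar=8, hidden_vector=2, learning_rate=1e-3,
            batch_size=8, max_epochs=2, patience=10, seed=0)
        from geoprot.lm import StubProteinLM
        lm = StubProteinLM(seed=0)
        before = lm.parameter_checksum()
        est.lm = lm
        est.fit(tiny_task.structures[:12], tiny_task.labels[:12])
        assert lm.parameter_checksum() == before

    def test_early_stopping_patience_one(self, tiny_task):
        """With patience 1 and a learning rate of zero the validation loss
        never improves after the first epoch, so training stops after
        exactly two validation evaluations."""
        est = ProteinPropertyPredictor(
            family="gvp", mode="end_to_end", task="multilabel",
            hidden_scalar=8, hidden_vector=2, learning_rate=0.0,
            batch_size=8, max_epochs=50, patience=1, seed=0)
        est.fit(tiny_task.structures[:12], tiny_task.labels[:12])
        assert len(est.history_["val_loss"]) == 2

    def test_two_stage_equals_end_to_end_phase_one(self, tiny_task):
        """The 2-stage schedule is exactly end-to-end with phase 2 removed:
        phase-1 histories at a fixed seed are identical."""
        kw = dict(family="hybrid_gvp", task="multilabel", hidden_scalar=8,
                  hidden_vector=2, learning_rate=1e-3, batch_size=8,
                  max_epochs=3, patience=10, seed=3)
        a = ProteinPropertyPredictor(mode="two_stage", **kw)
        a.fit(tiny_task.structures[:12], tiny_task.labels[:12])
        b = ProteinPropertyPredictor(mode="end_to_end", **kw)
        b.fit(tiny_task.structures[:12], tiny_task.labels[:12])
        n1 = a.history_["phase_boundaries"][0]
        assert a.history_["train_loss"] == b.history_["train_loss"][:n1]
        assert a.history_["val_loss"] == b.history_["val_loss"][:n1]

    def test_end_to_end_records_phase_boundary_and_reinit(self, tiny_task):
        est = ProteinPropertyPredictor(
            family="hybrid_gvp", mode="end_to_end", task="multilabel",
            hidden_scalar=8, hidden_vector=2, learning_rate=1e-3,
            batch_size=8, max_epochs=4, patience=10, seed=0)
        est.fit(tiny_task.structures[:12], tiny_task.labels[:12])
        assert est.history_["optimizer_reinitialized"]
        assert len(est.history_["phase_boundaries"]) == 2

    def test_checkpoint_roundtrip(self, tiny_task, tmp_path):
        net = build_model("gvp", "end_to_end", "multilabel", 1, seed=0,
                          hidden_scalar=8, hidden_vector=2)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, str(path), meta={"family": "gvp"})
        net2 = build_model("gvp", "end_to_end", "multilabel", 1, seed=99,
                           hidden_scalar=8, hidden_vector=2)
        manifest = load_checkpoint(net2, str(path))
        assert manifest["meta"]["family"] == "gvp"
        for x, y in zip(net.state_dict(), net2.state_dict()):
            np.testing.assert_array_equal(x, y)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([[1, 0], [0, 1], [1, 1]], dtype=float)
        m = evaluate(y.copy(), y, "multilabel")
        assert m["micro_aupr"] == 1.0
        assert m["fmax"] == 1.0

    def test_fmax_matches_threshold_sweep_oracle(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.7]])
        truth = np.array([[1.0, 0.0], [1.0, 1.0]])

        def oracle():
            best = 0.0
            for tau in np.concatenate([scores.reshape(-1), [0.0, 1.0]]):
                pred = scores >= tau
                covered = pred.sum(1) > 0
                if not covered.any():
                    continue
                tp = (pred & (truth > 0)).sum(1)
                prec = np.mean(tp[covered] / pred.sum(1)[covered])
                rec = np.mean(tp / truth.sum(1))
                if prec + rec > 0:
                    best = max(best, 2 * prec * rec / (prec + rec))
            return best

        assert abs(protein_centric_fmax(truth, scores) - oracle()) < 1e-12

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(10.0)
        assert abs(spearman_rho(x, -x) + 1.0) < 1e-12

    def test_constant_input_reported_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho = spearman_rho(np.ones(5), np.arange(5.0))
        assert np.isnan(rho)

    def test_probability_range_enforced(self):
        with pytest.raises(ValueError, match="probabilities"):
            evaluate(np.array([[1.5]]), np.array([[1.0]]), "multilabel")

    def test_micro_aupr_pools_all_decisions(self):
        y = np.array([[1, 0], [0, 0]], dtype=float)
        s = np.array([[0.9, 0.2], [0.1, 0.3]])
        # pooled ranking: 0.9(+), 0.3(-), 0.2(-), 0.1(-) -> AP = 1.0
        assert micro_aupr(y, s) == 1.0


def test_stratified_split_covers_target_range():
    rng = np.random.default_rng(0)
    targets = rng.normal(size=80)
    train_idx, test_idx = stratified_split(targets, test_fraction=0.25, seed=1)
    assert len(set(train_idx) & set(test_idx)) == 0
    assert len(train_idx) + len(test_idx) == 80
    # every quantile bin contributes to the test set
    edges = np.quantile(targets, [0.2, 0.4, 0.6, 0.8])
    bins = np.digitize(targets[test_idx], edges)
    assert set(bins) == {0, 1, 2, 3, 4}
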