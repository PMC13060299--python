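"""Losses, loss decomposition, freezing, optimisation sanity, and metrics."""

import hashlib
import math

import numpy as np
import pytest

from cytoset._autodiff import Tensor
from cytoset.core import CytometrySample, MarkerVocabulary
from cytoset.masking import (MARKER_WISE, UNIFORM_RANDOM, MaskDistributionConfig,
                             MaskedView, make_views)
from cytoset.model import CytoTransformer, ModelConfig
from cytoset.targets import PretrainTargets, compute_targets
from cytoset.train import (DownstreamConfig, PretrainConfig, PretrainLossConfig,
                           breakdown_weights, compute_metrics, cross_entropy,
                           gnll, make_splits, predict_proba, pretrain_loss,
                           run_downstream, run_pretraining)

from conftest import make_corpus

HALF_LOG_2PI = 0.5 * math.log(2 * math.pi)


class TestGNLL:
    def test_perfect_prediction_unit_variance(self):
        t = np.zeros((3, 4))
        val = gnll(t, Tensor(t.copy()), Tensor(np.ones_like(t))).data.item()
        assert val == pytest.approx(HALF_LOG_2PI, abs=1e-12)
        assert val == pytest.approx(0.9189, abs=1e-4)

    def test_unit_residual_unit_variance(self):
        t = np.zeros((2, 2))
        val = gnll(t, Tensor(np.ones_like(t)), Tensor(np.ones_like(t))).data.item()
        assert val == pytest.approx(0.5 + HALF_LOG_2PI, abs=1e-12)
        assert val == pytest.approx(1.4189, abs=1e-4)

    def test_doubling_variance_adds_half_log_two(self):
        t = np.zeros(5)
        base = gnll(t, Tensor(t.copy()), Tensor(np.ones(5))).data.item()
        double = gnll(t, Tensor(t.copy()), Tensor(2 * np.ones(5))).data.item()
        assert double - base == pytest.approx(0.5 * math.log(2), abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            gnll(np.zeros(2), Tensor(np.zeros(2)), Tensor(np.array([1.0, 0.0])))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gnll(np.zeros(2), Tensor(np.zeros(3)), Tensor(np.ones(3)))


def _manual_views(n, m, mask_uni, mask_mw, dropped=frozenset()):
    events = np.zeros((n, m))
    return {UNIFORM_RANDOM: MaskedView(events, mask_uni, UNIFORM_RANDOM, dropped),
            MARKER_WISE: MaskedView(events, mask_mw, MARKER_WISE)}


def _head_outputs(model, sample, views):
    return {p: model.pretrain_heads(model.encode(sample, per_cell_mask=v.mask))
            for p, v in views.items()}


@pytest.fixture
def loss_setup(tiny_model, vocab):
    rng = np.random.default_rng(0)
    sample = CytometrySample(rng.normal(0.5, 0.2, (6, 3)),
                             ["CD3", "CD8", "NK1.1"], "s")
    targets = compute_targets(sample.events)
    views = dict(zip((UNIFORM_RANDOM, MARKER_WISE),
                     make_views(sample.events, MaskDistributionConfig(), 3, "s", 0)))
    heads = _head_outputs(tiny_model, sample, views)
    slots = vocab.slots(sample.measured_markers)
    return sample, targets, views, heads, slots


class TestPretrainLoss:
    def test_total_equals_weighted_component_sum(self, loss_setup):
        _, targets, views, heads, slots = loss_setup
        config = PretrainLossConfig(beta_unmasked=0.3, w_x=1.5, w_p=0.5, w_d=2.0,
                                    w_uniform=0.7, w_markerwise=0.3)
        total, breakdown = pretrain_loss(targets, views, heads, config, slots)
        assert len(breakdown) == 12
        weights = breakdown_weights(config)
        recombined = sum(weights[k] * v for k, v in breakdown.items())
        assert total.data.item() == pytest.approx(recombined, abs=1e-10)

    def test_beta_zero_ignores_unmasked_predictions(self, tiny_model, loss_setup):
        sample, targets, views, heads, slots = loss_setup
        config = PretrainLossConfig(beta_unmasked=0.0)
        base, _ = pretrain_loss(targets, views, heads, config, slots)
        # perturb head means at unmasked-measured entries only
        heads2 = _head_outputs(tiny_model, sample, views)
        for pattern, view in views.items():
            _, unmasked, _ = view.entry_classes()
            rows, cols = np.nonzero(unmasked)
            heads2[pattern].expr_mean.data[rows, slots[cols]] += 100.0
        perturbed, _ = pretrain_loss(targets, views, heads2, config, slots)
        assert perturbed.data.item() == pytest.approx(base.data.item(), abs=1e-12)

    def test_unmeasured_slots_never_contribute(self, tiny_model, loss_setup):
        sample, targets, views, heads, slots = loss_setup
        config = PretrainLossConfig()
        base, _ = pretrain_loss(targets, views, heads, config, slots)
        heads2 = _head_outputs(tiny_model, sample, views)
        unmeasured = [j for j in range(tiny_model.vocabulary.size) if j not in slots]
        for h in heads2.values():
            h.expr_mean.data[:, unmeasured] = 1e6
            h.pct_mean.data[:, unmeasured] = -1e6
            h.dens_var.data[:, unmeasured] = 1e6
        perturbed, _ = pretrain_loss(targets, views, heads2, config, slots)
        assert perturbed.data.item() == pytest.approx(base.data.item(), abs=1e-12)

    def test_pattern_weight_selection(self, loss_setup):
        _, targets, views, heads, slots = loss_setup
        only_uni, bd = pretrain_loss(targets, views, heads,
                                     PretrainLossConfig(w_uniform=1.0, w_markerwise=0.0),
                                     slots)
        beta = PretrainLossConfig().beta_unmasked
        expected = sum(bd[f"{UNIFORM_RANDOM}.{t}.masked"]
                       + beta * bd[f"{UNIFORM_RANDOM}.{t}.unmasked"]
                       for t in "XPD")
        assert only_uni.data.item() == pytest.approx(expected, abs=1e-10)

    def test_scaling_pattern_weights_scales_loss(self, loss_setup):
        _, targets, views, heads, slots = loss_setup
        one, _ = pretrain_loss(targets, views, heads, PretrainLossConfig(), slots)
        tripled, _ = pretrain_loss(targets, views, heads,
                                   PretrainLossConfig(w_uniform=1.5, w_markerwise=1.5),
                                   slots)
        assert tripled.data.item() == pytest.approx(3 * one.data.item(), abs=1e-10)

    def test_all_masked_perfect_prediction_closed_form(self, vocab):
        # 2 cells x 2 markers, everything masked, exact means, unit variances:
        # each component = 0.5*log(2*pi); total = (wx+wp+wd) * that * sum(wk)
        n, m = 2, 2
        sample = CytometrySample(np.array([[0.1, 0.2], [0.3, 0.4]]),
                                 ["CD3", "CD4"], "s")
        targets = compute_targets(sample.events)
        zero_mask = np.zeros((n, m), dtype=np.int8)
        views = _manual_views(n, m, zero_mask, zero_mask.copy())
        model = CytoTransformer(vocab, ModelConfig(hidden_size=8, encoder_layers=1,
                                                   decoder_layers=1, heads=2), seed=0)
        heads = _head_outputs(model, sample, views)
        slots = vocab.slots(sample.measured_markers)
        for h in heads.values():
            for mean_attr, tgt in (("expr_mean", targets.expression),
                                   ("pct_mean", targets.percentile),
                                   ("dens_mean", targets.density)):
                getattr(h, mean_attr).data[:, slots] = tgt
            for var_attr in ("expr_var", "pct_var", "dens_var"):
                getattr(h, var_attr).data[:] = 1.0
        total, _ = pretrain_loss(targets, views, heads, PretrainLossConfig(), slots)
        assert total.data.item() == pytest.approx(3 * HALF_LOG_2PI * (0.5 + 0.5),
                                                  abs=1e-10)

    def test_empty_masked_view_warns_not_errors(self, loss_setup, caplog):
        _, targets, views, heads, slots = loss_setup
        n, m = targets.expression.shape
        views[MARKER_WISE] = MaskedView(targets.expression,
                                        np.ones((n, m), dtype=np.int8), MARKER_WISE)
        with caplog.at_level("WARNING", logger="cytoset.train"):
            total, bd = pretrain_loss(targets, views, heads, PretrainLossConfig(), slots)
        assert bd[f"{MARKER_WISE}.X.masked"] == 0.0
        assert "no masked entries" in caplog.text


def test_cross_entropy_matches_log_softmax():
    scores = Tensor(np.array([1.0, 3.0, -2.0]))
    val = cross_entropy(scores, 1).data.item()
    probs = np.exp([1.0, 3.0, -2.0])
    assert val == pytest.approx(-math.log(probs[1] / probs.sum()), abs=1e-12)


def _param_digest(params):
    h = hashlib.sha256()
    for p in params:
        h.update(p.data.tobytes())
    return h.hexdigest()


class TestPretraining:
    def test_loss_decreases_and_is_reproducible(self, vocab):
        corpus, _ = make_corpus(n_samples=6, n_cells=40, seed=3, vocab=vocab)
        config = PretrainConfig(epochs=4, lr=1e-3, cells_per_step=40,
                                validation_fraction=0.0)
        histories = []
        for _ in range(2):
            model = CytoTransformer(vocab, ModelConfig(hidden_size=16,
                                                       encoder_layers=1,
                                                       decoder_layers=1, heads=2),
                                    seed=5)
            record = run_pretraining(corpus, model, config, seed=5)
            histories.append([h["train_loss"] for h in record["history"]])
        assert histories[0] == histories[1]  # same seed, identical trajectory
        assert histories[0][-1] < histories[0][0]

    def test_learns_marker_dependency_better_than_mean_predictor(self):
        # marker B = 2*A - 0.5 + small noise; after pretraining, the masked-B
        # prediction must beat the column-mean oracle (MSE < Var(B))
        rng = np.random.default_rng(8)
        vocab = MarkerVocabulary(["A", "B"])
        corpus = []
        for i in range(6):
            a = rng.uniform(0, 1, size=150)
            b = 2 * a - 0.5 + rng.normal(0, 0.05, size=150)
            corpus.append(CytometrySample(np.column_stack([a, b]), ["A", "B"],
                                          sample_id=f"s{i}"))
        model = CytoTransformer(vocab, ModelConfig(hidden_size=16, encoder_layers=2,
                                                   decoder_layers=1, heads=2), seed=2)
        config = PretrainConfig(epochs=25, lr=3e-3, cells_per_step=150,
                                validation_fraction=0.0)
        run_pretraining(corpus, model, config, seed=2)
        errs, base = [], []
        for s in corpus:
            mask = np.ones((s.n_cells, 2), dtype=np.int8)
            mask[:, 1] = 0  # hide B
            out = model.pretrain_heads(model.encode(s, per_cell_mask=mask))
            pred_b = out.expr_mean.data[:, 1]
            errs.append(np.mean((pred_b - s.events[:, 1]) ** 2))
            base.append(np.var(s.events[:, 1]))
        assert np.mean(errs) < np.mean(base)

    def test_empty_corpus_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            run_pretraining([], tiny_model, PretrainConfig(epochs=1), seed=0)


class TestDownstream:
    def test_frozen_encoder_bitwise_unchanged(self, vocab):
        corpus, _ = make_corpus(n_samples=8, n_cells=30, seed=1, vocab=vocab)
        y = np.array([s.label for s in corpus])
        model = CytoTransformer(vocab, ModelConfig(hidden_size=16, encoder_layers=1,
                                                   decoder_layers=1, heads=2), seed=3)
        before = _param_digest(model.pretrain_parameters())
        decoder_before = _param_digest(model.decoder_parameters())
        config = DownstreamConfig(epochs=3, lr=1e-3, freeze_encoder=True,
                                  cells_per_step=30, validation_fraction=0.0,
                                  batch_size=4)
        run_downstream(corpus, y, model, config, seed=3)
        assert _param_digest(model.pretrain_parameters()) == before
        assert _param_digest(model.decoder_parameters()) != decoder_before

    def test_unfrozen_encoder_changes(self, vocab):
        corpus, _ = make_corpus(n_samples=6, n_cells=30, seed=1, vocab=vocab)
        y = np.array([s.label for s in corpus])
        model = CytoTransformer(vocab, ModelConfig(hidden_size=16, encoder_layers=1,
                                                   decoder_layers=1, heads=2), seed=3)
        before = _param_digest(model.pretrain_parameters())
        config = DownstreamConfig(epochs=2, lr=1e-3, freeze_encoder=False,
                                  cells_per_step=30, validation_fraction=0.0,
                                  batch_size=3)
        run_downstream(corpus, y, model, config, seed=3)
        assert _param_digest(model.pretrain_parameters()) != before

    def test_eval_predictions_deterministic(self, vocab):
        corpus, _ = make_corpus(n_samples=6, n_cells=30, seed=2, vocab=vocab)
        y = np.array([s.label for s in corpus])
        model = CytoTransformer(vocab, ModelConfig(hidden_size=16, encoder_layers=1,
                                                   decoder_layers=1, heads=2), seed=1)
        run_downstream(corpus, y, model,
                       DownstreamConfig(epochs=2, cells_per_step=30, batch_size=3,
                                        validation_fraction=0.0), seed=1)
        p1 = predict_proba(model, corpus[0])
        p2 = predict_proba(model, corpus[0])
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, vocab, tiny_model):
        corpus, _ = make_corpus(n_samples=4, n_cells=20, seed=0, vocab=vocab)
        with pytest.raises(ValueError, match="two classes"):
            run_downstream(corpus, np.zeros(4), tiny_model,
                           DownstreamConfig(epochs=1), seed=0)


class TestMetrics:
    def test_hand_built_confusion_table(self):
        # TP=3, FP=1, FN=1, TN=3 -> accuracy 6/8 = 0.75
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        proba = np.array([[0.1, 0.9]] * 3 + [[0.8, 0.2]]
                         + [[0.3, 0.7]] + [[0.9, 0.1]] * 3)
        m = compute_metrics(y, proba)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["confusion"] == [[3, 1], [1, 3]]

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        proba = np.eye(2)[y]
        m = compute_metrics(y, proba)
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0 and m["auc"] == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = rng.integers(0, 2, n)
        p1 = rng.uniform(size=n)
        m = compute_metrics(y, np.column_stack([1 - p1, p1]))
        assert abs(m["auc"] - 0.5) < 3.0 / math.sqrt(n)

    def test_binary_threshold_is_half_not_argmax_margin(self):
        y = np.array([0, 1])
        proba = np.array([[0.49, 0.51], [0.45, 0.55]])
        m = compute_metrics(y, proba)
        assert m["confusion"] == [[0, 1], [0, 1]]  # 0.51 >= 0.5 -> class 1

    def test_multiclass_macro_auc(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        proba = (np.eye(3)[y] * 0.8 + 0.1) / 1.1
        m = compute_metrics(y, proba)
        assert m["auc"] == 1.0


class TestSplits:
    def test_batch_grouped_no_leakage(self):
        rng = np.random.default_rng(0)
        groups = np.repeat([f"b{i}" for i in range(10)], 6)
        y = rng.integers(0, 2, 60)
        for tr, te in make_splits(y, groups, {"kind": "stratified_group_kfold", "k": 5}):
            assert set(groups[tr]) & set(groups[te]) == set()

    def test_leave_one_batch_out_fold_count(self):
        groups = np.repeat(["a", "b", "c", "d"], 3)
        y = np.tile([0, 1, 0], 4)
        folds = make_splits(y, groups, {"kind": "leave_one_batch_out"})
        assert len(folds) == 4
        for tr, te in folds:
            assert len(set(groups[te])) == 1

    def test_holdout_stratified(self):
        y = np.array([0] * 8 + [1] * 8)
        (tr, te), = make_splits(y, y.astype(str), {"kind": "holdout",
                                                   "test_fraction": 0.25}, seed=1)
        assert (y[te] == 0).sum() == 2 and (y[te] == 1).sum() == 2
        assert len(np.intersect1d(tr, te)) == 0

    def test_infeasible_grouping_warns_and_falls_back(self):
        y = np.array([0, 1] * 6)
        groups = np.array(["g0"] * 12)  # one group: grouped 3-fold impossible
        with pytest.warns(UserWarning, match="infeasible"):
            folds = make_splits(y, groups, {"kind": "stratified_group_kfold", "k": 3})
        assert len(folds) == 3
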