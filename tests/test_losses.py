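"""Discrepancy, classification and domain losses, and the four-step trainer."""

import numpy as np
import pytest

from tdsan import (
    SynthConfig,
    TrainConfig,
    adv_discrepancy_loss,
    discrepancy,
    domain_loss,
    fit,
    gen_domain_pair,
    generate,
    generator_confusion_loss,
    source_classification_loss,
    train_minibatch,
)
from tdsan.io_preprocess import EpochedRecording
from tdsan.losses_train import _cross_entropy, _binary_ce, _Optimizers
from tdsan.model import ModelConfig, TDSANModel, classify
from tdsan.nn import Tensor


def _simplex(rng, n, k=5):
    x = rng.random((n, k))
    return x / x.sum(axis=1, keepdims=True)


class TestDiscrepancy:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ((1, 0, 0, 0, 0), (1, 0, 0, 0, 0), 0.0),
            ((1, 0, 0, 0, 0), (0, 1, 0, 0, 0), 0.4),
            ((0.6, 0.4, 0, 0, 0), (0.4, 0.6, 0, 0, 0), 0.08),
        ],
    )
    def test_hand_examples(self, p1, p2, expected):
        assert discrepancy(np.array(p1, float), np.array(p2, float)).item() \
            == pytest.approx(expected, abs=1e-7)

    def test_matches_brute_force_and_invariants(self, rng):
        p1, p2 = _simplex(rng, 300), _simplex(rng, 300)
        got = discrepancy(p1, p2).item()
        brute = np.mean([
            sum(abs(a - b) for a, b in zip(r1, r2)) / 5 for r1, r2 in zip(p1, p2)
        ])
        assert got == pytest.approx(brute, abs=1e-6)
        # symmetry, non-negativity, 2/K bound
        assert discrepancy(p2, p1).item() == pytest.approx(got, abs=1e-7)
        assert 0 <= got <= 2 / 5

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            discrepancy(np.array([0.9, 0.0, 0, 0, 0]), np.array([1.0, 0, 0, 0, 0]))


class TestClosedFormLosses:
    def test_cross_entropy_uniform_is_log_k(self):
        p = Tensor(np.full((4, 5), 0.2, np.float32))
        y = np.array([0, 1, 2, 3])
        assert _cross_entropy(p, y).item() == pytest.approx(np.log(5), rel=1e-5)

    def test_cross_entropy_perfect_is_zero(self):
        p = Tensor(np.eye(5, dtype=np.float32)[[0, 3]])
        assert _cross_entropy(p, np.array([0, 3])).item() == pytest.approx(0.0, abs=1e-5)

    def test_head_aggregation_is_the_mean(self, small_model, rng):
        """Loss equals the hand-averaged per-head cross-entropies."""
        small_model.set_training(False)
        x = rng.standard_normal((4, 1, 3000)).astype(np.float32)
        y = np.array([0, 1, 2, 3])
        feat = generate(x, "source", small_model)
        per_head = [
            _cross_entropy(classify(feat, h, small_model), y).item()
            for h in ("C1", "C2")
        ]
        got = source_classification_loss(x, y, small_model).item()
        assert got == pytest.approx(np.mean(per_head), rel=1e-5)

    def test_label_out_of_range_rejected(self, small_model):
        with pytest.raises(ValueError, match="labels"):
            source_classification_loss(
                np.zeros((1, 1, 3000), np.float32), np.array([7]), small_model
            )

    def test_binary_ce_closed_forms(self):
        half = Tensor(np.full(6, 0.5, np.float32))
        assert _binary_ce(half, np.ones(6)).item() == pytest.approx(np.log(2), rel=1e-5)
        perfect = Tensor(np.array([1.0, 0.0, 1.0], np.float32))
        y = np.array([1.0, 0.0, 1.0])
        assert _binary_ce(perfect, y).item() == pytest.approx(0.0, abs=1e-4)
        # confidently wrong predictions stay finite thanks to the clamp
        wrong = Tensor(np.array([0.0, 1.0], np.float32))
        val = _binary_ce(wrong, np.array([1.0, 0.0])).item()
        assert np.isfinite(val) and val > 10


class TestDomainLosses:
    def test_domain_loss_matches_manual_bce(self, small_model, rng):
        small_model.set_training(False)
        fs = generate(rng.standard_normal((3, 1, 3000)).astype(np.float32),
                      "source", small_model)
        ft = generate(rng.standard_normal((2, 1, 3000)).astype(np.float32),
                      "target", small_model)
        from tdsan.model import discriminate

        ps = discriminate(fs, small_model).data[:, 1]
        pt = discriminate(ft, small_model).data[:, 1]
        manual = -(np.sum(np.log(ps)) + np.sum(np.log(1 - pt))) / 5
        assert domain_loss(fs, ft, small_model).item() == pytest.approx(manual, rel=1e-4)

    def test_confusion_loss_is_domain_loss_with_flipped_labels(self, small_model, rng):
        small_model.set_training(False)
        x = rng.standard_normal((3, 1, 3000)).astype(np.float32)
        fs = generate(x, "source", small_model)
        ft = generate(x, "target", small_model)
        # flipping labels == swapping which stream is called source/target
        assert generator_confusion_loss(fs, ft, small_model).item() == pytest.approx(
            domain_loss(ft, fs, small_model).item(), rel=1e-5
        )

    def test_empty_batch_rejected(self, small_model):
        f = Tensor(np.zeros((0, 2656), np.float32))
        g = Tensor(np.zeros((2, 2656), np.float32))
        with pytest.raises(ValueError, match="non-empty"):
            domain_loss(f, g, small_model)

    def test_adv_discrepancy_equals_per_sample_mean(self, small_model, rng):
        small_model.set_training(False)
        x = rng.standard_normal((4, 1, 3000)).astype(np.float32)
        feat = generate(x, "target", small_model)
        p1 = classify(feat, "C1", small_model).data
        p2 = classify(feat, "C2", small_model).data
        manual = np.mean([np.abs(a - b).sum() / 5 for a, b in zip(p1, p2)])
        assert adv_discrepancy_loss(x, small_model).item() \
            == pytest.approx(manual, rel=1e-5)


class TestTrainer:
    def test_minibatch_smoke_all_losses_finite(self, tiny_pair, tiny_train_cfg):
        src, tgt = tiny_pair
        model = TDSANModel(tiny_train_cfg.model, seed=0)
        out = train_minibatch(
            src.epochs[:16], src.labels[:16], tgt.epochs[:16], model, tiny_train_cfg
        )
        assert all(np.isfinite(v) for v in out.values())

    def test_classifier_step_raises_discrepancy_generator_step_lowers_it(
        self, tiny_pair, tiny_train_cfg
    ):
        src, tgt = tiny_pair
        cfg = tiny_train_cfg
        model = TDSANModel(cfg.model, seed=0)
        opts = _Optimizers(model, cfg)
        xs, ys = src.epochs[:32], src.labels[:32]
        xt = tgt.epochs[:32]
        # warm-up so the heads are not at their random initialization
        for _ in range(2):
            train_minibatch(xs, ys, xt, model, cfg, opts)

        from tdsan.losses_train import _step

        model.set_training(True)
        before = adv_discrepancy_loss(xt, model).item()
        fs = generate(xs, "source", model).detach()
        ft = generate(xt, "target", model).detach()
        loss_c = source_classification_loss(xs, ys, model, feat=fs) \
            - adv_discrepancy_loss(xt, model, feat=ft)
        _step(loss_c, opts, [opts.c], "C")
        after_c = adv_discrepancy_loss(xt, model).item()
        assert after_c >= before - 1e-6

        for _ in range(cfg.n_gen_steps):
            _step(adv_discrepancy_loss(xt, model), opts, [opts.g], "D")
        after_d = adv_discrepancy_loss(xt, model).item()
        assert after_d <= after_c + 1e-6

    def test_fit_telemetry_matches_epochs_and_batches(self, tiny_pair, tiny_train_cfg):
        src, tgt = tiny_pair
        cfg = tiny_train_cfg
        model, record = fit(src, tgt, cfg)
        n_train = int(round(len(src) * 0.8))
        batches_per_epoch = int(np.ceil(n_train / cfg.batch_size))
        assert len(record) == cfg.max_epochs * batches_per_epoch
        assert all(np.isfinite(v) for v in record.discrepancy)

    def test_poisoned_target_labels_train_bit_identically(self, tiny_pair, tiny_train_cfg):
        """UDA hygiene: target labels can never influence training."""
        src, tgt = tiny_pair
        cfg = tiny_train_cfg
        poisoned = EpochedRecording(
            epochs=tgt.epochs, labels=(tgt.labels + 2) % 5, rate=tgt.rate
        )
        m1, _ = fit(src, tgt, cfg)
        m2, _ = fit(src, poisoned, cfg)
        for a, b in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_identical_seeds_give_identical_models(self, tiny_pair, tiny_train_cfg):
        src, tgt = tiny_pair
        m1, _ = fit(src, tgt, tiny_train_cfg)
        m2, _ = fit(src, tgt, tiny_train_cfg)
        for a, b in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_nonpositive_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(n_gen_steps=0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


def test_checkpoint_roundtrip(tmp_path, tiny_pair, tiny_train_cfg):
    from tdsan import load_checkpoint, predict, save_checkpoint

    src, tgt = tiny_pair
    model, _ = fit(src, tgt, tiny_train_cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, tiny_train_cfg)
    back, cfg2 = load_checkpoint(path)
    assert cfg2.batch_size == tiny_train_cfg.batch_size
    x = src.epochs[:8]
    assert np.array_equal(predict(x, "source", model), predict(x, "source", back))


class TestDiscriminatorLearning:
    def test_untrained_discriminator_is_at_chance(self, tiny_pair):
        """Averaged over initializations, an untrained D is a coin flip."""
        src, tgt = tiny_pair
        from tdsan.model import discriminate

        truth = np.concatenate([np.ones(40), np.zeros(40)])
        accs = []
        for seed in range(5):
            model = TDSANModel(ModelConfig.reduced(), seed=seed)
            model.set_training(False)
            fs = generate(src.epochs[:40], "source", model)
            ft = generate(tgt.epochs[:40], "target", model)
            pred = np.concatenate([
                discriminate(fs, model).data.argmax(1),
                discriminate(ft, model).data.argmax(1),
            ])
            accs.append((pred == truth).mean())
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_discriminator_separates_shifted_domains_with_fixed_generator(self):
        from tdsan.losses_train import _Optimizers, _step
        from tdsan.model import discriminate

        # strong pure-gain shift: the domains are cleanly separable
        src, tgt = gen_domain_pair(
            SynthConfig(n_per_class=60, seed=3, shift=(6.0, 0.0, 0.0))
        )
        cfg = TrainConfig(model=ModelConfig.reduced(), batch_size=32, max_epochs=1,
                          seed=0)
        model = TDSANModel(cfg.model, seed=0)
        m = 240
        # warm up BN statistics as ordinary training would, then freeze G
        model.set_training(True)
        for _ in range(10):
            generate(src.epochs[:m], "source", model)
            generate(tgt.epochs[:m], "target", model)
        model.set_training(False)
        opts = _Optimizers(model, cfg)
        fs = generate(src.epochs[:m], "source", model).detach()
        ft = generate(tgt.epochs[:m], "target", model).detach()
        for _ in range(100):
            _step(domain_loss(fs, ft, model), opts, [opts.d], "B1")
        hs = generate(src.epochs[m:], "source", model)
        ht = generate(tgt.epochs[m:], "target", model)
        pred = np.concatenate([
            discriminate(hs, model).data.argmax(1),
            discriminate(ht, model).data.argmax(1),
        ])
        truth = np.concatenate([np.ones(60), np.zeros(60)])
        assert (pred == truth).mean() > 0.9


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=10, max_size=10))
    def test_discrepancy_properties_hold_on_arbitrary_simplex_pairs(vals):
        """Symmetry, non-negativity, the 2/K bound, and zero iff equal."""
        v = np.array(vals).reshape(2, 5)
        p1 = v[0] / v[0].sum()
        p2 = v[1] / v[1].sum()
        d12 = discrepancy(p1, p2).item()
        d21 = discrepancy(p2, p1).item()
        assert d12 == pytest.approx(d21, abs=1e-7)
        assert 0.0 <= d12 <= 2 / 5 + 1e-7
        assert discrepancy(p1, p1).item() == 0.0
        if d12 < 1e-9:
            assert np.allclose(p1, p2, atol=1e-6)
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_adaptation_experiment_reports_both_models(tiny_pair, tiny_train_cfg):
    from tdsan import adaptation_experiment

    src, tgt = tiny_pair
    out = adaptation_experiment(src, tgt, tiny_train_cfg)
    assert 0.0 <= out["tdsan"].acc <= 1.0
    assert 0.0 <= out["direct_transfer"].acc <= 1.0
    assert out["gain"] == pytest.approx(
        out["tdsan"].acc - out["direct_transfer"].acc
    )
    assert len(out["record"]) > 0
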