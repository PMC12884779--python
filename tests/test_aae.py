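import numpy as np
import pytest

from scper import aae
from scper.aae import (
    ConfounderLabels,
    TrainingConfig,
    adversary_loss,
    encode,
    embed_bulk,
    init_adversary,
    init_params,
    joint_adversarial_train,
    pretrain_adversary,
    pretrain_autoencoder,
    reconstruction_loss,
)

TINY = TrainingConfig(
    d_latent=8,
    hidden=(32,),
    ae_pretrain_epochs=30,
    adv_pretrain_epochs=60,
    joint_rounds=5,
    batch_size=32,
    mix_per_batch=4,
    mix_cells=8,
    seed=0,
)


@pytest.fixture(scope="module")
def toy_data():
    """Two latent clusters in 40-gene space, with a batch shift on 10 genes."""
    rng = np.random.default_rng(4)
    n = 200
    base = rng.normal(2.0, 0.3, size=(n, 40))
    types = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
    base[types == "b", :10] += 2.0
    batches = np.array((["x", "y"] * 100)[:n], dtype=object)
    base[batches == "y", 20:30] += 2.0
    return np.abs(base), types, batches


class TestEncode:
    def test_deterministic_and_shapes(self, toy_data):
        X, _, _ = toy_data
        params = init_params(40, TINY)
        z1, z2 = encode(params, X), encode(params, X)
        assert z1.shape == (200, 8)
        assert np.array_equal(z1, z2)
        assert encode(params, X[:1]).shape == (1, 8)

    def test_bulk_and_cells_share_the_encoder(self, toy_data):
        X, _, _ = toy_data
        params = init_params(40, TINY)
        assert np.array_equal(encode(params, X[:5]), embed_bulk(params, X[:5]))

    def test_gene_order_mismatch_rejected(self, toy_data):
        X, _, _ = toy_data
        params = init_params(40, TINY, gene_ids=[f"g{i}" for i in range(40)])
        wrong = [f"g{i}" for i in reversed(range(40))]
        with pytest.raises(ValueError):
            encode(params, X, gene_ids=wrong)
        with pytest.raises(ValueError):
            embed_bulk(params, X[:, :30])


class TestLosses:
    def test_reconstruction_zero_for_identity(self):
        params = init_params(4, TrainingConfig(d_latent=4, hidden=(), seed=0))
        # force an exact identity map
        params.encoder.W = [np.eye(4)]
        params.encoder.b = [np.zeros(4)]
        params.decoder.W = [np.eye(4)]
        params.decoder.b = [np.zeros(4)]
        X = np.random.default_rng(0).normal(size=(6, 4))
        assert reconstruction_loss(params, X) == pytest.approx(0.0)

    def test_single_coordinate_difference_squared(self):
        params = init_params(3, TrainingConfig(d_latent=3, hidden=(), seed=0))
        params.encoder.W, params.encoder.b = [np.eye(3)], [np.zeros(3)]
        params.decoder.W, params.decoder.b = [np.eye(3)], [np.array([2.0, 0, 0])]
        x = np.zeros((1, 3))
        assert reconstruction_loss(params, x) == pytest.approx(4.0)

    def test_adversary_uniform_prediction_log_k(self):
        labels = ConfounderLabels("batch", np.array(["p", "q", "r"] * 4))
        cfg = TrainingConfig(d_latent=5, adv_hidden=(), seed=1)
        adv = init_adversary(cfg, labels.classes)
        adv.net.W = [np.zeros((5, 3))]
        adv.net.b = [np.zeros(3)]
        z = np.random.default_rng(1).normal(size=(12, 5))
        assert adversary_loss(adv, z, labels) == pytest.approx(np.log(3))

    def test_adversary_perfect_prediction_near_zero(self):
        labels = ConfounderLabels("batch", np.array(["p"] * 5 + ["q"] * 5))
        cfg = TrainingConfig(d_latent=1, adv_hidden=(), seed=1)
        adv = init_adversary(cfg, labels.classes)
        adv.net.W = [np.array([[-100.0, 100.0]])]
        adv.net.b = [np.zeros(2)]
        z = np.array([[-1.0]] * 5 + [[1.0]] * 5)
        assert adversary_loss(adv, z, labels) < 1e-6

    def test_unseen_label_class_rejected(self):
        labels = ConfounderLabels("batch", np.array(["p", "q"] * 3))
        cfg = TrainingConfig(d_latent=2, seed=1)
        adv = init_adversary(cfg, labels.classes)
        other = ConfounderLabels("batch", np.array(["zz"] * 6))
        with pytest.raises(ValueError):
            adversary_loss(adv, np.zeros((6, 2)), other)


class TestTraining:
    def test_pretraining_decreases_reconstruction(self, toy_data):
        X, _, _ = toy_data
        params, hist = pretrain_autoencoder(X, TINY)
        assert hist[-1] < hist[0]

    def test_zero_epochs_returns_initial_params(self, toy_data):
        X, _, _ = toy_data
        cfg = TrainingConfig(d_latent=8, hidden=(32,), ae_pretrain_epochs=0, seed=0)
        params, hist = pretrain_autoencoder(X, cfg)
        fresh = init_params(40, cfg)
        assert hist == []
        assert all(np.array_equal(a, b) for a, b in zip(params.encoder.W, fresh.encoder.W))

    def test_same_seed_identical_loss_history(self, toy_data):
        X, _, _ = toy_data
        _, h1 = pretrain_autoencoder(X, TINY)
        _, h2 = pretrain_autoencoder(X, TINY)
        assert h1 == h2

    def test_adversary_learns_separable_batches(self, toy_data):
        X, _, batches = toy_data
        params, _ = pretrain_autoencoder(X, TINY)
        labels = ConfounderLabels("batch", batches)
        adv, hist = pretrain_adversary(params, X, labels, TINY)
        z = encode(params, X)
        assert aae.adversary_accuracy(adv, z, labels) > 0.8
        assert hist[-1] < hist[0]

    def test_single_class_labels_rejected(self, toy_data):
        X, _, _ = toy_data
        params, _ = pretrain_autoencoder(X, TINY)
        with pytest.raises(ValueError):
            pretrain_adversary(params, X, ConfounderLabels("batch", np.array(["x"] * 200)), TINY)

    def test_zero_joint_rounds_is_a_no_op(self, toy_data):
        X, _, batches = toy_data
        params, _ = pretrain_autoencoder(X, TINY)
        labels = ConfounderLabels("batch", batches)
        adv, _ = pretrain_adversary(params, X, labels, TINY)
        w_before = [w.copy() for w in params.encoder.W]
        cfg = TrainingConfig(d_latent=8, hidden=(32,), joint_rounds=0, seed=0)
        params, adv, hist = joint_adversarial_train(params, adv, X, labels, cfg)
        assert hist["reconstruction"] == []
        assert all(np.array_equal(a, b) for a, b in zip(params.encoder.W, w_before))

    def test_joint_training_confuses_adversary(self, toy_data):
        X, _, batches = toy_data
        labels = ConfounderLabels("batch", batches)
        cfg = TrainingConfig(
            d_latent=8, hidden=(32,), ae_pretrain_epochs=30, adv_pretrain_epochs=60,
            joint_rounds=300, batch_size=32, mix_per_batch=4, mix_cells=8, seed=0,
        )
        params, adv, hist = aae.train_adversarial_autoencoder(X, labels, cfg)
        z = encode(params, X)
        assert aae.adversary_accuracy(adv, z, labels) <= 0.6
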