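"""Network forward/backward contracts, training behavior, ensembles."""

import numpy as np
import pytest

from sctab import (
    LabelSpace,
    ScTabConfig,
    SimConfig,
    TrainConfig,
    class_weights,
    predict_ensemble,
    simulate,
    train,
    train_baseline,
)
from sctab.autodiff import BatchNorm, Tensor
from sctab.model import (
    FittedModel,
    LinearNetwork,
    MLPNetwork,
    ScTabNetwork,
    TrainedEnsemble,
)


TINY = dict(n_genes=12, n_classes=3, n_d=6, n_a=4, n_shared=2, n_independent=2,
            virtual_batch_size=4)


class TestClassWeights:
    def test_direct_formula(self):
        space = LabelSpace(classes=("A", "B"))
        w = class_weights(["A"] * 8 + ["B"] * 2, space)
        assert w.weights == {"A": pytest.approx(0.625), "B": pytest.approx(2.5)}

    def test_balanced_gives_unit_weights(self):
        space = LabelSpace(classes=("A", "B", "C"))
        w = class_weights(["A", "B", "C"] * 4, space)
        assert all(v == pytest.approx(1.0) for v in w.weights.values())

    def test_unobserved_class_raises(self):
        space = LabelSpace(classes=("A", "B"))
        with pytest.raises(ValueError, match="B"):
            class_weights(["A", "A"], space)


class TestForward:
    def test_shapes_and_mask_simplex(self):
        cfg = ScTabConfig(n_genes=200, n_classes=8)
        net = ScTabNetwork(cfg, seed=0)
        x = np.random.default_rng(0).uniform(0, 5, size=(4, 200))
        logits, mask = net.forward(x, training=False)
        assert logits.shape == (4, 8)
        assert mask.shape == (4, 200)
        np.testing.assert_allclose(mask.data.sum(axis=1), 1.0, atol=1e-6)
        assert mask.data.min() >= 0

    def test_eval_mode_deterministic_per_row(self):
        cfg = ScTabConfig(**TINY)
        net = ScTabNetwork(cfg, seed=0)
        x = np.random.default_rng(1).uniform(0, 3, size=(1, 12))
        stacked = np.repeat(x, 5, axis=0)
        logits, _ = net.forward(stacked, training=False)
        for i in range(1, 5):
            np.testing.assert_allclose(logits.data[i], logits.data[0], atol=1e-12)

    def test_shape_mismatch_raises(self):
        net = ScTabNetwork(ScTabConfig(**TINY), seed=0)
        with pytest.raises(ValueError, match="genes"):
            net.forward(np.zeros((2, 13)))

    def test_trained_mask_is_sparse(self, trained_sctab):
        model, sim, split = trained_sctab
        from sctab import normalize

        x = normalize(sim.dataset).values[:200]
        _, mask = model.network.forward(x, training=False)
        assert (mask.data == 0.0).any()  # entmax yields exact zeros per row


class TestSparsityLoss:
    def _entropy(self, rows):
        from sctab.autodiff import mask_entropy

        return float(mask_entropy(Tensor(np.asarray(rows))).data)

    def test_one_hot_rows_zero(self):
        assert self._entropy(np.eye(5)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_rows_log_d(self):
        d = 16
        rows = np.full((3, d), 1.0 / d)
        assert self._entropy(rows) == pytest.approx(np.log(d), abs=1e-9)

    def test_mixed_batch_is_mean(self):
        d = 8
        uniform = np.full(d, 1.0 / d)
        onehot = np.eye(d)[0]
        got = self._entropy(np.stack([uniform, onehot]))
        assert got == pytest.approx(np.log(d) / 2, abs=1e-9)


class TestGhostBatchNorm:
    def test_equals_plain_bn_when_vbs_is_batch(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2, 3, size=(32, 6))
        plain = BatchNorm(6, virtual_batch_size=None)
        ghost = BatchNorm(6, virtual_batch_size=32)
        np.testing.assert_allclose(
            plain(Tensor(x), training=True).data,
            ghost(Tensor(x), training=True).data,
            atol=1e-12,
        )

    def test_ghost_differs_for_smaller_vbs(self):
        rng = np.random.default_rng(4)
        x = rng.normal(2, 3, size=(32, 6))
        plain = BatchNorm(6)(Tensor(x), training=True).data
        ghost = BatchNorm(6, virtual_batch_size=8)(Tensor(x), training=True).data
        assert not np.allclose(plain, ghost)


class TestGradients:
    def test_sctab_loss_matches_finite_differences(self):
        cfg = ScTabConfig(**TINY)
        net = ScTabNetwork(cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 3, size=(8, 12))
        y = rng.integers(0, 3, size=8)
        w = np.array([1.0, 2.0, 0.5])
        loss, _ = net.loss(x, y, w)
        loss.backward()
        params = net.parameters()
        grads = [p.grad.copy() for p in params]
        eps = 1e-6
        for pi, p in enumerate(params):
            flat = p.data.ravel()
            for k in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                old = flat[k]
                flat[k] = old + eps
                lp = float(net.loss(x, y, w)[0].data)
                flat[k] = old - eps
                lm = float(net.loss(x, y, w)[0].data)
                flat[k] = old
                fd = (lp - lm) / (2 * eps)
                assert grads[pi].ravel()[k] == pytest.approx(fd, abs=1e-4, rel=1e-3)

    @pytest.mark.parametrize("net_cls", [LinearNetwork, MLPNetwork])
    def test_baseline_gradients(self, net_cls):
        kwargs = dict(n_genes=7, n_classes=3, seed=0)
        if net_cls is MLPNetwork:
            kwargs.update(n_hidden=2, hidden_size=5, p_dropout=0.0)
        net = net_cls(**kwargs)
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, size=(6, 7))
        y = rng.integers(0, 3, size=6)
        w = np.ones(3)
        loss, _ = net.loss(x, y, w)
        loss.backward()
        params = net.parameters()
        grads = [p.grad.copy() for p in params]
        eps = 1e-6
        for pi, p in enumerate(params):
            flat = p.data.ravel()
            k = int(rng.integers(flat.size))
            old = flat[k]
            flat[k] = old + eps
            lp = float(net.loss(x, y, w)[0].data)
            flat[k] = old - eps
            lm = float(net.loss(x, y, w)[0].data)
            flat[k] = old
            assert grads[pi].ravel()[k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


@pytest.fixture(scope="module")
def small_sim():
    return simulate(SimConfig(seed=5, n_genes=60, n_cell_types=4, n_donors=8,
                              cells_per_donor=150))


@pytest.fixture(scope="module")
def small_split(small_sim):
    from sctab import split_by_donor

    return split_by_donor(small_sim.dataset.cell_meta["donor_id"].unique().tolist(),
                          seed=5)


@pytest.fixture(scope="module")
def trained_sctab(small_sim, small_split):
    cfg = ScTabConfig(n_genes=60, n_classes=4, n_d=16, n_a=8, n_shared=2,
                      n_independent=2, virtual_batch_size=128)
    tcfg = TrainConfig(seed=5, max_epochs=3, batch_size=512, augment=False)
    model = train(small_sim.dataset, small_split, cfg=cfg, tcfg=tcfg)
    return model, small_sim, small_split


class TestTraining:
    def test_loss_decreases_early(self, trained_sctab):
        hist = trained_sctab[0].history["train_loss"]
        assert hist[-1] < hist[0]

    def test_same_seed_identical_trajectory(self, small_sim, small_split):
        cfg = ScTabConfig(n_genes=60, n_classes=4, n_d=8, n_a=4, n_shared=1,
                          n_independent=1, virtual_batch_size=128)
        tcfg = TrainConfig(seed=7, max_epochs=2, batch_size=512, augment=False)
        h1 = train(small_sim.dataset, small_split, cfg=cfg, tcfg=tcfg).history
        h2 = train(small_sim.dataset, small_split, cfg=cfg, tcfg=tcfg).history
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_macro_f1"] == h2["val_macro_f1"]

    def test_mask_on_simplex_after_training(self, trained_sctab):
        model, sim, _ = trained_sctab
        from sctab import normalize

        _, mask = model.network.forward(normalize(sim.dataset).values[:64],
                                        training=False)
        np.testing.assert_allclose(mask.data.sum(axis=1), 1.0, atol=1e-6)
        assert mask.data.min() >= 0

    def test_empty_training_split_raises(self, small_sim):
        from sctab.corpus import SplitAssignment

        donors = small_sim.dataset.cell_meta["donor_id"].unique().tolist()
        split = SplitAssignment(
            donor_to_split={d: "test" for d in donors}, fractions=(0, 0, 1)
        )
        with pytest.raises(ValueError):
            train(small_sim.dataset, split,
                  tcfg=TrainConfig(max_epochs=1, batch_size=256))


class TestBaselines:
    def test_linear_parameter_count(self):
        net = LinearNetwork(n_genes=200, n_classes=8)
        assert net.n_parameters == 200 * 8 + 8

    def test_mlp_depth_and_width(self):
        net = MLPNetwork(n_genes=50, n_classes=4)
        assert len(net.layers) == 8
        assert all(w.data.shape[1] == 128 for w, _ in net.layers[1:])

    def test_linear_separable_high_f1(self, small_sim, small_split):
        # learning rate scaled up for the small sample so SGD converges within
        # the epoch budget; the default is tuned for corpora orders of
        # magnitude larger
        tcfg = TrainConfig(learning_rate=0.05, weight_decay=0.001, augment=False,
                           seed=5, max_epochs=40, batch_size=128,
                           early_stop_patience=40, lr_gamma=0.97)
        model = train_baseline("linear", small_sim.dataset, small_split, tcfg=tcfg)
        assert max(model.history["val_macro_f1"]) >= 0.95

    def test_unknown_baseline(self, small_sim, small_split):
        with pytest.raises(ValueError):
            train_baseline("xgboost", small_sim.dataset, small_split)


class TestEnsemble:
    def _member(self, probs_fn, space):
        class FakeNet:
            def forward(self, x, training=False):
                return Tensor(np.log(probs_fn(x) + 1e-12)), None

        return FittedModel(FakeNet(), space, ["g"], 1e4)

    def test_unanimous_members_zero_uncertainty(self):
        space = LabelSpace(classes=("A", "B"))
        member = self._member(lambda x: np.tile([1.0, 0.0], (x.shape[0], 1)), space)
        ens = TrainedEnsemble(members=[member] * 5, label_space=space)
        labels, probs, unc = predict_ensemble(ens, np.zeros((3, 1)))
        assert labels == ["A"] * 3
        np.testing.assert_allclose(unc, 0.0, atol=1e-9)

    def test_uncertainty_is_one_minus_max_mean(self):
        space = LabelSpace(classes=("A", "B"))
        m1 = self._member(lambda x: np.tile([0.8, 0.2], (x.shape[0], 1)), space)
        m2 = self._member(lambda x: np.tile([0.4, 0.6], (x.shape[0], 1)), space)
        ens = TrainedEnsemble(members=[m1, m2], label_space=space)
        _, probs, unc = predict_ensemble(ens, np.zeros((2, 1)))
        np.testing.assert_allclose(probs[:, 0], 0.6, atol=1e-9)
        np.testing.assert_allclose(unc, 0.4, atol=1e-9)

    def test_uniform_members(self):
        space = LabelSpace(classes=("A", "B", "C", "D"))
        member = self._member(lambda x: np.full((x.shape[0], 4), 0.25), space)
        ens = TrainedEnsemble(members=[member] * 3, label_space=space)
        _, _, unc = predict_ensemble(ens, np.zeros((2, 1)))
        np.testing.assert_allclose(unc, 1 - 0.25, atol=1e-9)

    def test_trained_ensemble_on_small_corpus(self, small_sim, small_split):
        from sctab import train_ensemble
        from sctab.io import normalize

        cfg = ScTabConfig(n_genes=60, n_classes=4, n_d=8, n_a=4, n_shared=1,
                          n_independent=1, virtual_batch_size=128)
        tcfg = TrainConfig(seed=3, max_epochs=1, batch_size=512, augment=False)
        ens = train_ensemble(small_sim.dataset, small_split, cfg=cfg, tcfg=tcfg,
                             n_members=2)
        assert len(ens.members) == 2
        # members differ by seed, so their weights differ
        w0 = ens.members[0].network.head_w.data
        w1 = ens.members[1].network.head_w.data
        assert not np.allclose(w0, w1)
        x = normalize(small_sim.dataset).values[:50]
        labels, probs, unc = predict_ensemble(ens, x)
        assert len(labels) == 50
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert unc.min() >= 0 and unc.max() <= 1

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            TrainedEnsemble(members=[], label_space=LabelSpace(classes=("A",)))

    def test_label_space_mismatch_rejected(self):
        s1 = LabelSpace(classes=("A", "B"))
        s2 = LabelSpace(classes=("A", "C"))
        m1 = self._member(lambda x: np.tile([1, 0], (x.shape[0], 1)), s1)
        m2 = self._member(lambda x: np.tile([1, 0], (x.shape[0], 1)), s2)
        with pytest.raises(ValueError):
            TrainedEnsemble(members=[m1, m2], label_space=s1)
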