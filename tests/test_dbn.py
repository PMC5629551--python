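import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepsubtype.dbn import (DbnModel, DeepBeliefNetwork, RbmParams,
                             TrainConfig, cross_entropy, encode, finetune,
                             rbm_energy, rbm_exact_distribution,
                             rbm_exact_gradient, rbm_exact_loglik,
                             rbm_train_cd, reconstruction_error,
                             stack_pretrain, unfold)

WORKED = RbmParams(W=[[0.5, -0.2]], b=[0.1], c=[0.3, 0.0])


def brute_force_table(p: RbmParams):
    """Independent enumeration oracle: loops + scalar arithmetic only."""
    table = {}
    for v in itertools.product((0, 1), repeat=p.n_visible):
        for h in itertools.product((0, 1), repeat=p.n_hidden):
            e = 0.0
            for j in range(p.n_hidden):
                for i in range(p.n_visible):
                    e -= h[j] * p.W[j, i] * v[i]
            for i in range(p.n_visible):
                e -= p.c[i] * v[i]
            for j in range(p.n_hidden):
                e -= p.b[j] * h[j]
            table[(v, h)] = np.exp(-e)
    z = sum(table.values())
    return {k: val / z for k, val in table.items()}, z


class TestEnergy:
    def test_zero_states_zero_energy(self):
        assert rbm_energy([0, 0], [0], WORKED) == 0.0

    def test_worked_example(self):
        # -(h W v + c v + b h) = -(0.5 + 0.3 + 0.1)
        assert rbm_energy([1, 0], [1], WORKED) == pytest.approx(-0.9)

    def test_linearity_in_parameters(self):
        doubled = RbmParams(2 * WORKED.W, 2 * WORKED.b, 2 * WORKED.c)
        v, h = [1, 1], [1]
        assert rbm_energy(v, h, doubled) == pytest.approx(
            2 * rbm_energy(v, h, WORKED))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbm_energy([1, 0, 0], [1], WORKED)


class TestExactDistribution:
    def test_normalizes(self):
        rng = np.random.default_rng(0)
        p = RbmParams(rng.normal(0, 1, (3, 4)), rng.normal(0, 1, 3),
                      rng.normal(0, 1, 4))
        _, _, P = rbm_exact_distribution(p)
        assert abs(P.sum() - 1.0) < 1e-12

    def test_zero_parameters_uniform(self):
        p = RbmParams(np.zeros((2, 3)), np.zeros(2), np.zeros(3))
        _, _, P = rbm_exact_distribution(p)
        assert np.allclose(P, 1.0 / P.size)

    def test_matches_brute_force_enumeration(self):
        V, H, P = rbm_exact_distribution(WORKED)
        oracle, _ = brute_force_table(WORKED)
        for i, v in enumerate(V):
            for j, h in enumerate(H):
                key = (tuple(int(x) for x in v), tuple(int(x) for x in h))
                assert P[i, j] == pytest.approx(oracle[key], abs=1e-12)

    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 4), st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_free_energy_consistent_with_joint(self, seed, nv, nh):
        rng = np.random.default_rng(seed)
        p = RbmParams(rng.normal(0, 1, (nh, nv)), rng.normal(0, 1, nh),
                      rng.normal(0, 1, nv))
        V, _, P = rbm_exact_distribution(p)
        marg = P.sum(axis=1)
        ll = rbm_exact_loglik(V, p)
        assert ll == pytest.approx(float(np.mean(np.log(marg))), abs=1e-10)

    def test_too_large_rejected(self):
        p = RbmParams(np.zeros((15, 15)), np.zeros(15), np.zeros(15))
        with pytest.raises(ValueError, match="state space"):
            rbm_exact_distribution(p)


class TestCdTraining:
    @staticmethod
    def clustered_patterns(seed, n=16, width=4, flip=0.1):
        """Noisy two-prototype binary data, the structure CD is meant to fit."""
        rng = np.random.default_rng(seed)
        protos = rng.integers(0, 2, size=(2, width)).astype(float)
        data = protos[rng.integers(0, 2, n)]
        return np.abs(data - (rng.random(data.shape) < flip))

    def test_likelihood_improves_on_tiny_instance(self):
        data = self.clustered_patterns(1)
        cfg = TrainConfig(layer_sizes=(3,), lr_pretrain=0.1,
                          epochs_pretrain=100, batch_size=8, seed=1001)
        p0 = RbmParams(np.random.default_rng(1001).normal(0, 0.01, (3, 4)),
                       np.zeros(3), np.zeros(4))
        trained = rbm_train_cd(data, 3, cfg)
        assert rbm_exact_loglik(data, trained) > rbm_exact_loglik(data, p0)

    def test_cd_update_correlates_with_exact_gradient(self):
        """CD-1 on one datapoint points (on average) along the exact
        likelihood gradient."""
        cos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = RbmParams(rng.normal(0, 0.5, (2, 3)), rng.normal(0, 0.5, 2),
                          rng.normal(0, 0.5, 3))
            v = (rng.random(3) < 0.5).astype(float)
            gW, gb, gc = rbm_exact_gradient(v, p)
            exact = np.concatenate([gW.ravel(), gb, gc])
            # one CD-1 step of the implementation from these params (lr=1,
            # single datapoint, single epoch): parameter delta == CD update
            cfg = TrainConfig(layer_sizes=(2,), lr_pretrain=1.0,
                              epochs_pretrain=1, batch_size=1, seed=seed)
            after = rbm_train_cd(v[None, :], 2, cfg, init=p)
            cd = np.concatenate([(after.W - p.W).ravel(), after.b - p.b,
                                 after.c - p.c])
            denom = np.linalg.norm(exact) * np.linalg.norm(cd)
            if denom > 0:
                cos.append(float(exact @ cd) / denom)
        assert np.mean(cos) > 0

    def test_zero_learning_rate_leaves_parameters(self):
        rng = np.random.default_rng(0)
        data = (rng.random((10, 4)) < 0.5).astype(float)
        cfg = TrainConfig(layer_sizes=(3,), lr_pretrain=0.0,
                          epochs_pretrain=5, seed=7)
        p = rbm_train_cd(data, 3, cfg)
        p2 = rbm_train_cd(data, 3, cfg)
        # init is seeded; zero lr means output == seeded init both times
        assert np.array_equal(p.W, p2.W)
        assert np.array_equal(p.b, np.zeros(3))
        assert np.array_equal(p.c, np.zeros(4))


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(4)
    return (rng.random((30, 50)) < 0.3).astype(float)


class TestStackAndUnfold:

    def test_stack_shapes(self, data):
        cfg = TrainConfig(layer_sizes=(20, 10, 5), epochs_pretrain=2, seed=0)
        rbms = stack_pretrain(data, cfg)
        assert [(p.n_hidden, p.n_visible) for p in rbms] == \
            [(20, 50), (10, 20), (5, 10)]

    def test_single_layer_stack_equals_rbm(self, data):
        cfg = TrainConfig(layer_sizes=(8,), epochs_pretrain=3, seed=5)
        rbms = stack_pretrain(data, cfg, rng=np.random.default_rng(5))
        single = rbm_train_cd(data, 8, cfg, rng=np.random.default_rng(5))
        assert np.array_equal(rbms[0].W, single.W)

    def test_seed_reproducibility(self, data):
        cfg = TrainConfig(layer_sizes=(10, 4), epochs_pretrain=3, seed=9)
        a = stack_pretrain(data, cfg)
        b = stack_pretrain(data, cfg)
        assert all(np.array_equal(x.W, y.W) for x, y in zip(a, b))

    def test_unfold_depth_and_untied_weights(self, data):
        cfg = TrainConfig(layer_sizes=(10, 6, 3), epochs_pretrain=2, seed=0)
        model = unfold(stack_pretrain(data, cfg))
        assert len(model.encoder) == 3 and len(model.decoder) == 3
        before = model.encoder[0][0].copy()
        model.decoder[-1][0][:] += 1.0
        assert np.array_equal(model.encoder[0][0], before)

    def test_reconstruction_is_deterministic_up_down_pass(self, data):
        cfg = TrainConfig(layer_sizes=(6,), epochs_pretrain=3, seed=2)
        rbms = stack_pretrain(data, cfg)
        model = unfold(rbms)
        p = rbms[0]
        sig = lambda x: 1 / (1 + np.exp(-x))
        manual = sig(sig(data @ p.W.T + p.b) @ p.W + p.c)
        assert np.allclose(model.reconstruct(data), manual)


class TestFinetune:
    def test_overtrained_model_memorizes(self):
        rng = np.random.default_rng(0)
        data = (rng.random((5, 20)) < 0.4).astype(float)
        cfg = TrainConfig(layer_sizes=(10, 5), lr_pretrain=0.1,
                          epochs_pretrain=50, lr_finetune=0.5,
                          epochs_finetune=500, batch_size=5, seed=2,
                          momentum=0.9)
        m = finetune(unfold(stack_pretrain(data, cfg)), data, cfg)
        log = m.training_log["finetune_cross_entropy"]
        assert log[-1] < 0.05
        steps = np.diff(log)
        assert np.mean(steps <= 0) >= 0.90

    def test_reconstruction_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        data = (rng.random((8, 10)) < 0.5).astype(float)
        cfg = TrainConfig(layer_sizes=(4,), epochs_pretrain=2,
                          epochs_finetune=2, seed=1)
        m = finetune(unfold(stack_pretrain(data, cfg)), data, cfg)
        r = m.reconstruct(data)
        assert (r > 0).all() and (r < 1).all()

    def test_divergence_aborts_with_diagnostic(self):
        rng = np.random.default_rng(2)
        data = (rng.random((20, 12)) < 0.5).astype(float)
        cfg = TrainConfig(layer_sizes=(6,), epochs_pretrain=2,
                          lr_finetune=500.0, epochs_finetune=50,
                          batch_size=4, seed=3)
        with pytest.raises(RuntimeError, match="lr_finetune|diverged"):
            finetune(unfold(stack_pretrain(data, cfg)), data, cfg)

    def test_shapes_preserved(self):
        rng = np.random.default_rng(3)
        data = (rng.random((12, 15)) < 0.5).astype(float)
        cfg = TrainConfig(layer_sizes=(7, 3), epochs_pretrain=2,
                          epochs_finetune=3, seed=4)
        m0 = unfold(stack_pretrain(data, cfg))
        m1 = finetune(m0, data, cfg)
        for (a0, b0), (a1, b1) in zip(m0.encoder + m0.decoder,
                                      m1.encoder + m1.decoder):
            assert a0.shape == a1.shape and b0.shape == b1.shape


class TestErrorsAndEncode:
    def _const_half_model(self, n):
        # zero weights and offsets -> reconstruction 0.5 everywhere
        p = RbmParams(np.zeros((n, n)), np.zeros(n), np.zeros(n))
        return unfold([p])

    def test_half_probability_cross_entropy_is_ln2(self):
        rng = np.random.default_rng(0)
        data = (rng.random((4, 6)) < 0.5).astype(float)
        m = self._const_half_model(6)
        assert cross_entropy(m, data) == pytest.approx(np.log(2), abs=1e-12)
        assert reconstruction_error(m, data) == pytest.approx(0.25)

    def test_fixture_matches_hand_computation(self):
        # single layer, tiny weights: compute expected values independently
        p = RbmParams(np.array([[1.0, -1.0]]), np.array([0.5]),
                      np.array([0.2, -0.3]))
        m = unfold([p])
        data = np.array([[1.0, 0.0], [0.0, 1.0]])
        sig = lambda x: 1 / (1 + np.exp(-x))
        h = sig(data @ p.W.T + p.b)
        rec = sig(h @ p.W + p.c)
        mse = np.mean((data - rec) ** 2)
        ce = -np.mean(data * np.log(rec) + (1 - data) * np.log(1 - rec))
        assert reconstruction_error(m, data) == pytest.approx(mse, abs=1e-12)
        assert cross_entropy(m, data) == pytest.approx(ce, abs=1e-12)

    def test_encode_shape_and_determinism(self):
        rng = np.random.default_rng(5)
        data = (rng.random((30, 40)) < 0.4).astype(float)
        cfg = TrainConfig(layer_sizes=(15, 8, 4), epochs_pretrain=2,
                          epochs_finetune=2, seed=5)
        m = finetune(unfold(stack_pretrain(data, cfg)), data, cfg)
        z1, z2 = m.encode(data), m.encode(data)
        assert z1.shape == (30, 4)
        assert np.array_equal(z1, z2)

    def test_duplicated_samples_encode_identically(self):
        rng = np.random.default_rng(6)
        data = (rng.random((10, 12)) < 0.5).astype(float)
        cfg = TrainConfig(layer_sizes=(5,), epochs_pretrain=2, seed=6)
        m = unfold(stack_pretrain(data, cfg))
        dup = np.vstack([data, data[:3]])
        z = m.encode(dup)
        assert np.array_equal(z[:3], z[10:])

    def test_gene_id_mismatch_raises(self):
        df = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
        cfg = TrainConfig(layer_sizes=(2,), epochs_pretrain=1, seed=0)
        m = unfold(stack_pretrain(df.to_numpy(), cfg))
        m.gene_ids = list("abcd")
        bad = df.rename(columns={"d": "z"})
        with pytest.raises(ValueError, match="gene ids"):
            encode(m, bad)


class TestModelResultsApi:
    def test_fit_returns_results_with_summary_and_log(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame((rng.random((25, 30)) < 0.4).astype(float),
                          index=[f"s{i}" for i in range(25)],
                          columns=[f"g{i}" for i in range(30)])
        res = DeepBeliefNetwork.from_dataframe(
            df, layer_sizes=(12, 5), epochs_pretrain=3, epochs_finetune=5,
            seed=1).fit()
        z = res.encode()
        assert z.shape == (25, 5) and list(z.index) == list(df.index)
        s = res.summary()
        assert "12-5" in s and "cross-entropy" in s.lower()
        assert len(res.training_log["finetune_mse"]) == 5

    def test_serialization_round_trips_bit_exactly(self, tmp_path):
        rng = np.random.default_rng(8)
        df = pd.DataFrame((rng.random((10, 12)) < 0.4).astype(float),
                          columns=[f"g{i}" for i in range(12)])
        res = DeepBeliefNetwork.from_dataframe(
            df, layer_sizes=(6, 3), epochs_pretrain=2, epochs_finetune=2,
            seed=2).fit()
        path = tmp_path / "model.h5"
        res.save(path)
        back = DbnModel.load(path)
        for (a0, b0), (a1, b1) in zip(res.model.encoder + res.model.decoder,
                                      back.encoder + back.decoder):
            assert np.array_equal(a0, a1) and np.array_equal(b0, b1)
        assert back.gene_ids == list(df.columns)
        assert back.training_log == res.training_log

    def test_rejects_nonbinary_data(self):
        with pytest.raises(ValueError, match="binary"):
            DeepBeliefNetwork(np.array([[0.5, 1.0]]))
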