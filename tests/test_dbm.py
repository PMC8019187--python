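"""DBM pre-training, fine-tuning, mean-field inference and full-network
sampling, checked against brute-force enumeration of the layered joint."""

import numpy as np
import pytest

from boltzgen import DBM, RBM, AISConfig, LayerConfig, dbm_logproblowerbound
from boltzgen.dbm import pretrain_stack

from conftest import enumerate_dbm_joint, enumerate_visible_marginal


def zero_dbm(sizes):
    weights = [np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    return DBM.from_arrays(weights, [np.zeros(s) for s in sizes])


class TestParameters:
    def test_joint_normalizes(self, tiny_dbm):
        _, probs = enumerate_dbm_joint(tiny_dbm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_broken_dimension_chain_rejected(self):
        with pytest.raises(ValueError):
            DBM.from_arrays([np.zeros((2, 3)), np.zeros((2, 2))],
                            [np.zeros(2), np.zeros(3), np.zeros(2)])


class TestPretraining:
    def test_single_layer_identical_to_rbm_fit(self, random_dataset):
        d = random_dataset(50, 6, seed=1, p=0.3)
        stack, _ = pretrain_stack(
            d, [LayerConfig(nhidden=4, epochspretraining=5)], seed=9)
        direct = RBM(n_hidden=4, epochs=5, learning_rate=0.001, batch_size=20,
                     random_state=9).fit(d)
        assert np.array_equal(stack[0].weights_, direct.weights_)

    def test_dimensions_chain(self, snp_fixture):
        stack, _ = pretrain_stack(
            snp_fixture.data,
            [LayerConfig(50, epochspretraining=2), LayerConfig(10, epochspretraining=2)],
            seed=0)
        assert stack[0].weights_.shape == (50, 50)
        assert stack[1].weights_.shape == (50, 10)

    def test_deterministic_given_seed(self, random_dataset):
        d = random_dataset(40, 5, seed=2)
        cfgs = [LayerConfig(3, epochspretraining=3), LayerConfig(2, epochspretraining=3)]
        a, _ = pretrain_stack(d, cfgs, seed=4)
        b, _ = pretrain_stack(d, cfgs, seed=4)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.weights_, rb.weights_)

    def test_empty_layer_list_rejected(self, random_dataset):
        with pytest.raises(ValueError):
            pretrain_stack(random_dataset(10, 3), [], seed=0)


class TestFit:
    def test_zero_finetune_epochs_keeps_pretrained_stack(self, random_dataset):
        d = random_dataset(40, 6, seed=3, p=0.3)
        kw = dict(n_hiddens=(4, 2), epochs_pretraining=3, random_state=8)
        untuned = DBM(epochs=0, **kw).fit(d)
        tuned = DBM(epochs=5, **kw).fit(d)
        other = DBM(epochs=0, **kw).fit(d)
        assert np.array_equal(untuned.weights_[0], other.weights_[0])
        assert not np.array_equal(untuned.weights_[0], tuned.weights_[0])

    def test_finetuning_does_not_hurt_lower_bound_on_point_mass(self):
        from boltzgen import BinaryDataset
        d = BinaryDataset(np.ones((100, 4), dtype=np.uint8))
        kw = dict(n_hiddens=(3, 2), epochs_pretraining=15,
                  learning_rate_pretraining=0.05, learning_rate=0.05,
                  random_state=0)
        cfg = AISConfig(n_temperatures=100, n_particles=100, seed=5)
        lb0 = dbm_logproblowerbound(DBM(epochs=0, **kw).fit(d), d, cfg)
        lb1 = dbm_logproblowerbound(DBM(epochs=15, **kw).fit(d), d, cfg)
        assert lb1.value >= lb0.value - 3 * (lb0.std_error + lb1.std_error)

    def test_deterministic_given_seed(self, random_dataset):
        d = random_dataset(30, 5, seed=4)
        kw = dict(n_hiddens=(3, 2), epochs=3, epochs_pretraining=3, random_state=2)
        a, b = DBM(**kw).fit(d), DBM(**kw).fit(d)
        for wa, wb in zip(a.weights_, b.weights_):
            assert np.array_equal(wa, wb)

    def test_empty_architecture_rejected(self, random_dataset):
        with pytest.raises(ValueError):
            DBM(n_hiddens=()).fit(random_dataset(10, 3))

    def test_monitoring_off_yields_no_records(self, random_dataset):
        dbm = DBM(n_hiddens=(3,), epochs=2, epochs_pretraining=2,
                  random_state=1).fit(random_dataset(20, 4, seed=5))
        assert dbm.monitor_ == []

    def test_checkpoints_cover_grid_and_end_matches_fit(self, random_dataset):
        d = random_dataset(40, 6, seed=6, p=0.3)
        kw = dict(n_hiddens=(4, 2), epochs_pretraining=2, random_state=3)
        snaps = dict(DBM(epochs=6, **kw).fit_with_checkpoints(d, [2, 4, 6]))
        plain = DBM(epochs=6, **kw).fit(d)
        assert sorted(snaps) == [2, 4, 6]
        assert np.array_equal(snaps[6].weights_[0], plain.weights_[0])


class TestMeanField:
    def test_zero_model_means_half(self):
        mus = zero_dbm([3, 2, 2]).mean_field(np.array([[1, 0, 1.0]]))
        assert all(np.allclose(mu, 0.5) for mu in mus)

    def test_single_layer_reduces_to_rbm_conditional(self, random_dataset):
        rng = np.random.default_rng(5)
        W, a, b = rng.normal(0, 1, (4, 3)), rng.normal(0, 1, 4), rng.normal(0, 1, 3)
        dbm = DBM.from_arrays([W], [a, b])
        rbm = RBM.from_arrays(W, a, b)
        v = np.array([[1.0, 0.0, 1.0, 1.0]])
        assert np.allclose(dbm.mean_field(v)[0], rbm.hidden_conditional(v))

    def test_approximates_exact_posterior_on_weak_coupling(self):
        rng = np.random.default_rng(11)
        dbm = DBM.from_arrays(
            [rng.normal(0, 0.2, (3, 2)), rng.normal(0, 0.2, (2, 2))],
            [rng.normal(0, 0.2, 3), rng.normal(0, 0.2, 2), rng.normal(0, 0.2, 2)])
        v0 = (1, 0, 1)
        states, probs = enumerate_dbm_joint(dbm)
        post = [np.zeros(2), np.zeros(2)]
        den = 0.0
        for layers, p in zip(states, probs):
            if tuple(int(x) for x in layers[0]) == v0:
                post[0] += p * layers[1]
                post[1] += p * layers[2]
                den += p
        mus = dbm.mean_field(np.array([v0], dtype=float), max_iters=100)
        for mu, exact in zip(mus, post):
            assert np.abs(mu[0] - exact / den).max() < 0.05


class TestSampling:
    def test_zero_model_uniform(self):
        gen = zero_dbm([4, 3, 2]).sample(10_000, burnin=5, random_state=0)
        assert np.abs(gen.values.mean(axis=0) - 0.5).max() < 0.02

    def test_clamping_contract(self, tiny_dbm):
        gen = tiny_dbm.sample(300, clamped={1: 1}, random_state=1)
        assert (gen.values[:, 1] == 1).all()

    def test_matches_enumerated_marginal(self, tiny_dbm):
        gen = tiny_dbm.sample(50_000, burnin=30, random_state=2)
        marg = enumerate_visible_marginal(tiny_dbm)
        emp = {}
        for row in gen.values:
            key = tuple(int(x) for x in row)
            emp[key] = emp.get(key, 0) + 1 / gen.n_samples
        tv = 0.5 * sum(abs(marg[k] - emp.get(k, 0.0)) for k in marg)
        assert tv < 0.02


class TestTop2Latent:
    def test_zero_model_all_half(self, random_dataset):
        rep = zero_dbm([4, 3, 2]).top2_latent_dims(random_dataset(10, 4, seed=7))
        assert np.allclose(rep, 0.5)

    def test_output_in_unit_square(self, snp_fixture):
        dbm = DBM(n_hiddens=(20, 2), epochs=5, epochs_pretraining=5,
                  random_state=0).fit(snp_fixture.data)
        rep = dbm.top2_latent_dims(snp_fixture.data)
        assert rep.shape == (500, 2)
        assert (rep >= 0).all() and (rep <= 1).all()

    def test_cases_and_controls_separate(self, snp_fixture):
        dbm = DBM(n_hiddens=(20, 2), epochs=20, epochs_pretraining=20,
                  learning_rate=0.05, random_state=1).fit(snp_fixture.data)
        rep = dbm.top2_latent_dims(snp_fixture.data)
        cases = rep[snp_fixture.labels == "case"].mean(axis=0)
        controls = rep[snp_fixture.labels == "control"].mean(axis=0)
        assert np.abs(cases - controls).max() > 0.05

    def test_wrong_top_layer_size_rejected(self, tiny_dbm, random_dataset):
        with pytest.raises(ValueError, match="2-unit top"):
            zero_dbm([4, 3, 3]).top2_latent_dims(random_dataset(5, 4, seed=8))
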