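"""Partition functions and likelihoods: exact enumeration (two independent
strategies) and AIS estimates with their reported uncertainties."""

import numpy as np
import pytest

from boltzgen import (DBM, RBM, AISConfig, ais_log_partition, dbm_loglikelihood,
                      dbm_logproblowerbound, exact_log_partition,
                      exact_loglikelihood, rbm_loglikelihood)
from boltzgen.likelihood import SizeError

from conftest import (brute_force_log_partition_dbm,
                      brute_force_log_partition_rbm)


def zero_rbm(nv, nh):
    return RBM.from_arrays(np.zeros((nv, nh)), np.zeros(nv), np.zeros(nh))


class TestExactPartition:
    def test_zero_model_closed_form(self):
        assert exact_log_partition(zero_rbm(3, 2)) == pytest.approx(5 * np.log(2))

    def test_analytic_collapse_equals_full_enumeration_rbm(self, tiny_rbm):
        assert exact_log_partition(tiny_rbm) == pytest.approx(
            brute_force_log_partition_rbm(tiny_rbm), abs=1e-10)

    def test_analytic_collapse_equals_full_enumeration_dbm(self, tiny_dbm):
        assert exact_log_partition(tiny_dbm) == pytest.approx(
            brute_force_log_partition_dbm(tiny_dbm), abs=1e-10)

    def test_bias_shift_closed_form(self):
        c = 0.7
        base = zero_rbm(4, 2)
        shifted = RBM.from_arrays(np.zeros((4, 2)), np.full(4, c), np.zeros(2))
        expected = 4 * (np.logaddexp(0, c) - np.log(2))
        assert exact_log_partition(shifted) - exact_log_partition(base) == \
            pytest.approx(expected, abs=1e-10)

    def test_size_cap_enforced(self):
        with pytest.raises(SizeError, match="AIS"):
            exact_log_partition(zero_rbm(20, 20))


class TestExactLoglikelihood:
    def test_zero_model_is_uniform(self, random_dataset):
        est = exact_loglikelihood(zero_rbm(5, 3), random_dataset(10, 5, seed=1))
        assert est.value == pytest.approx(-5 * np.log(2))
        assert est.std_error == 0.0 and est.method == "exact"

    def test_invariant_to_duplicating_samples(self, tiny_rbm, random_dataset):
        d = random_dataset(6, 3, seed=2)
        doubled = np.vstack([d.values, d.values])
        assert exact_loglikelihood(tiny_rbm, d.values).value == pytest.approx(
            exact_loglikelihood(tiny_rbm, doubled).value)

    def test_matches_independent_enumeration(self, tiny_dbm):
        """Mean log p(v) from the collapsed path must match summing the
        brute-force joint over hidden states."""
        from conftest import enumerate_visible_marginal
        V = np.array([[0, 0], [1, 0], [1, 1.0]])
        marg = enumerate_visible_marginal(tiny_dbm)
        expected = np.mean([np.log(marg[tuple(int(x) for x in v)]) for v in V])
        assert exact_loglikelihood(tiny_dbm, V).value == pytest.approx(
            expected, abs=1e-10)


class TestAIS:
    def test_zero_weight_target_is_exact(self):
        rbm = RBM.from_arrays(np.zeros((4, 3)), np.linspace(-1, 1, 4),
                              np.linspace(-0.5, 0.5, 3))
        est = ais_log_partition(rbm, AISConfig(seed=0))
        assert est.value == pytest.approx(exact_log_partition(rbm), abs=1e-12)
        assert est.std_error == pytest.approx(0.0, abs=1e-12)

    def test_within_three_sigma_of_exact_rbm(self):
        rng = np.random.default_rng(1)
        rbm = RBM.from_arrays(rng.normal(0, 1, (4, 3)), rng.normal(0, 0.5, 4),
                              rng.normal(0, 0.5, 3))
        est = ais_log_partition(rbm, AISConfig(100, 100, seed=2))
        assert abs(est.value - exact_log_partition(rbm)) < 3 * est.std_error + 0.05

    def test_within_three_sigma_of_exact_dbm(self, tiny_dbm):
        est = ais_log_partition(tiny_dbm, AISConfig(100, 100, seed=3))
        assert abs(est.value - exact_log_partition(tiny_dbm)) \
            < 3 * est.std_error + 0.05

    def test_more_temperatures_do_not_hurt(self):
        rng = np.random.default_rng(4)
        rbm = RBM.from_arrays(rng.normal(0, 1, (4, 3)), rng.normal(0, 0.5, 4),
                              rng.normal(0, 0.5, 3))
        exact = exact_log_partition(rbm)
        errors = {}
        for n_temps in (10, 1000):
            errs = [abs(ais_log_partition(
                rbm, AISConfig(n_temps, 50, seed=s)).value - exact)
                for s in range(20)]
            errors[n_temps] = np.median(errs)
        assert errors[1000] <= errors[10] + 1e-9


class TestModelLoglikelihoods:
    def test_rbm_uniform_model(self, random_dataset):
        est = rbm_loglikelihood(zero_rbm(6, 2), random_dataset(8, 6, seed=5),
                                AISConfig(seed=1))
        assert est.value == pytest.approx(-6 * np.log(2), abs=1e-10)

    def test_rbm_agrees_with_exact(self, random_dataset):
        rng = np.random.default_rng(6)
        rbm = RBM.from_arrays(rng.normal(0, 1, (4, 3)), rng.normal(0, 0.5, 4),
                              rng.normal(0, 0.5, 3))
        d = random_dataset(10, 4, seed=7)
        est = rbm_loglikelihood(rbm, d, AISConfig(100, 100, seed=8))
        assert abs(est.value - exact_loglikelihood(rbm, d).value) \
            < 3 * est.std_error + 0.05

    def test_training_data_more_likely_than_noise_after_fit(self):
        from boltzgen import BinaryDataset
        train = BinaryDataset(np.ones((100, 5), dtype=np.uint8))
        noise = (np.random.default_rng(9).random((100, 5)) < 0.5).astype(float)
        rbm = RBM(n_hidden=3, epochs=30, learning_rate=0.2,
                  random_state=0).fit(train)
        assert exact_loglikelihood(rbm, train).value \
            > exact_loglikelihood(rbm, noise).value

    def test_dbm_lower_bound_uniform_model(self, random_dataset):
        dbm = DBM.from_arrays([np.zeros((5, 2)), np.zeros((2, 2))],
                              [np.zeros(5), np.zeros(2), np.zeros(2)])
        est = dbm_logproblowerbound(dbm, random_dataset(6, 5, seed=10),
                                    AISConfig(seed=2))
        assert est.value == pytest.approx(-5 * np.log(2), abs=1e-10)

    def test_lower_bound_below_exact_likelihood(self, tiny_dbm, random_dataset):
        d = random_dataset(8, 2, seed=11)
        bound = dbm_logproblowerbound(tiny_dbm, d, AISConfig(100, 200, seed=3))
        exact = exact_loglikelihood(tiny_dbm, d).value
        assert bound.value <= exact + 3 * bound.std_error

    def test_dbm_loglikelihood_uniform_model(self, random_dataset):
        dbm = DBM.from_arrays([np.zeros((4, 2)), np.zeros((2, 2))],
                              [np.zeros(4), np.zeros(2), np.zeros(2)])
        est = dbm_loglikelihood(dbm, random_dataset(5, 4, seed=12),
                                AISConfig(seed=4))
        assert est.value == pytest.approx(-4 * np.log(2), abs=1e-10)

    def test_dbm_loglikelihood_agrees_with_exact(self, tiny_dbm, random_dataset):
        d = random_dataset(6, 2, seed=13)
        est = dbm_loglikelihood(tiny_dbm, d, AISConfig(100, 100, seed=5))
        assert abs(est.value - exact_loglikelihood(tiny_dbm, d).value) \
            < 3 * est.std_error + 0.05

    def test_likelihood_at_least_lower_bound(self, tiny_dbm, random_dataset):
        d = random_dataset(6, 2, seed=14)
        cfg = AISConfig(100, 200, seed=6)
        ll = dbm_loglikelihood(tiny_dbm, d, cfg)
        lb = dbm_logproblowerbound(tiny_dbm, d, cfg)
        assert ll.value >= lb.value - 3 * (ll.std_error + lb.std_error)

    def test_deterministic_given_seed(self, tiny_dbm, random_dataset):
        d = random_dataset(4, 2, seed=15)
        cfg = AISConfig(50, 50, seed=7)
        assert dbm_logproblowerbound(tiny_dbm, d, cfg).value == \
            dbm_logproblowerbound(tiny_dbm, d, cfg).value

    def test_estimates_finite_for_extreme_parameters(self):
        rbm = RBM.from_arrays(np.full((3, 2), 20.0), np.full(3, -15.0),
                              np.full(2, 15.0))
        est = ais_log_partition(rbm, AISConfig(50, 50, seed=8))
        assert np.isfinite(est.value)
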