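"""Shared fixtures and brute-force oracles.

The oracles enumerate every joint state of a tiny Boltzmann machine
directly from the energy function, independently of the package's analytic
collapses, and are the reference for conditionals, partition functions and
marginals in the tests.
"""

import itertools

import numpy as np
import pytest

from boltzgen import RBM, DBM, BinaryDataset, simulate_snp_sets


# -- brute-force oracles ----------------------------------------------------

def enumerate_rbm_joint(rbm):
    """(states, probabilities) of the full joint over all (v, h) pairs."""
    nv, nh = rbm.weights_.shape
    states, energies = [], []
    for v in itertools.product((0, 1), repeat=nv):
        for h in itertools.product((0, 1), repeat=nh):
            states.append((np.array(v, float), np.array(h, float)))
            energies.append(rbm.energy(np.array(v, float), np.array(h, float)))
    unnorm = np.exp(-np.array(energies))
    return states, unnorm / unnorm.sum()


def brute_force_log_partition_rbm(rbm):
    """log Z by summing exp(-E) over every (v, h) state, no analytic collapse."""
    nv, nh = rbm.weights_.shape
    energies = [rbm.energy(np.array(v, float), np.array(h, float))
                for v in itertools.product((0, 1), repeat=nv)
                for h in itertools.product((0, 1), repeat=nh)]
    e = -np.array(energies)
    m = e.max()
    return float(m + np.log(np.exp(e - m).sum()))


def dbm_energy(dbm, layers):
    """Layered energy E(s) = -sum_l s_{l-1}'W_l s_l - sum_l b_l's_l."""
    e = 0.0
    for l, W in enumerate(dbm.weights_):
        e -= layers[l] @ W @ layers[l + 1]
    for l, b in enumerate(dbm.biases_):
        e -= b @ layers[l]
    return e


def enumerate_dbm_joint(dbm):
    """(layer-state tuples, probabilities) over every configuration."""
    sizes = [len(b) for b in dbm.biases_]
    states, energies = [], []
    for combo in itertools.product(*[itertools.product((0, 1), repeat=s)
                                     for s in sizes]):
        layers = [np.array(c, float) for c in combo]
        states.append(layers)
        energies.append(dbm_energy(dbm, layers))
    unnorm = np.exp(-np.array(energies))
    return states, unnorm / unnorm.sum()


def brute_force_log_partition_dbm(dbm):
    sizes = [len(b) for b in dbm.biases_]
    energies = []
    for combo in itertools.product(*[itertools.product((0, 1), repeat=s)
                                     for s in sizes]):
        energies.append(dbm_energy(dbm, [np.array(c, float) for c in combo]))
    e = -np.array(energies)
    m = e.max()
    return float(m + np.log(np.exp(e - m).sum()))


def enumerate_visible_marginal(model):
    """dict visible-tuple -> p(v), from the brute-force joint."""
    if isinstance(model, RBM):
        states, probs = enumerate_rbm_joint(model)
        keyed = [(tuple(int(x) for x in v), p) for (v, _), p in zip(states, probs)]
    else:
        states, probs = enumerate_dbm_joint(model)
        keyed = [(tuple(int(x) for x in layers[0]), p)
                 for layers, p in zip(states, probs)]
    marg = {}
    for key, p in keyed:
        marg[key] = marg.get(key, 0.0) + p
    return marg


# -- fixtures ---------------------------------------------------------------

@pytest.fixture
def tiny_rbm():
    """Random 3-visible x 2-hidden RBM with moderate weights."""
    rng = np.random.default_rng(42)
    return RBM.from_arrays(rng.normal(0, 0.7, (3, 2)),
                           rng.normal(0, 0.5, 3), rng.normal(0, 0.5, 2))


@pytest.fixture
def tiny_dbm():
    """Random 2-2-2 DBM with moderate weights."""
    rng = np.random.default_rng(7)
    return DBM.from_arrays(
        [rng.normal(0, 0.7, (2, 2)), rng.normal(0, 0.7, (2, 2))],
        [rng.normal(0, 0.5, 2), rng.normal(0, 0.5, 2), rng.normal(0, 0.5, 2)])


@pytest.fixture(scope="session")
def snp_fixture():
    """The default simulated SNP-set panel (500 x 50, 250 cases)."""
    return simulate_snp_sets(seed=20240901)


@pytest.fixture
def random_dataset():
    def make(n, k, seed=0, p=0.5):
        rng = np.random.default_rng(seed)
        return BinaryDataset((rng.random((n, k)) < p).astype(np.uint8))
    return make


def block_logor_stats(data, blocks):
    """(mean within-block, mean between-block) pairwise log OR of a dataset."""
    from boltzgen import log_odds_ratio_matrix
    lor = log_odds_ratio_matrix(data).values
    k = lor.shape[0]
    in_block = np.zeros((k, k), bool)
    for b in blocks:
        in_block[np.ix_(b, b)] = True
    iu = np.triu_indices(k, 1)
    mask = in_block[iu]
    return float(lor[iu][mask].mean()), float(lor[iu][~mask].mean())
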