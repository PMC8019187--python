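"""Likelihood machinery for Boltzmann machines.

Exact quantities (partition function, log-likelihood) are available for
tiny models by enumeration; beyond the size cap, annealed importance
sampling (AIS) estimates the partition function along a geometric path of
inverse temperatures applied to the weights, starting from the zero-weight
base model whose biases are retained (the layers are then independent, so
the base partition function is analytic).

Everything here treats an RBM as the one-hidden-layer special case of the
layered model: layers s_0 (visible), s_1, ..., s_L with energy
E(s) = - sum_l s_{l-1}' W_l s_l - sum_l b_l' s_l.  Within any such model the
odd layers are conditionally independent given the even layers, so the odd
sums collapse analytically via the product-of-(1 + e^x) identity and only
even layers are ever enumerated or carried as AIS particle states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .rbm import RBM, as_matrix

__all__ = ["AISConfig", "LikelihoodEstimate", "SizeError", "exact_log_partition",
           "exact_loglikelihood", "ais_log_partition", "rbm_loglikelihood",
           "dbm_logproblowerbound", "dbm_loglikelihood"]

UNIT_CAP = 24


class SizeError(ValueError):
    """Model too large for exact enumeration."""


@dataclass
class AISConfig:
    n_temperatures: int = 100
    n_particles: int = 100
    seed: int = None

    def __post_init__(self):
        if self.n_temperatures < 2:
            raise ValueError("need at least 2 temperatures")
        if self.n_particles < 1:
            raise ValueError("need at least 1 particle")


@dataclass
class LikelihoodEstimate:
    value: float       # log scale, nats
    std_error: float   # 0 iff method == "exact"
    method: str        # exact | ais

    def __post_init__(self):
        if (self.std_error == 0.0) != (self.method == "exact") and self.method == "exact":
            raise ValueError("exact estimates carry zero std_error")


def _layers(model):
    """(weights, biases) in layered form for an RBM or DBM."""
    if isinstance(model, RBM):
        return [model.weights_], [model.visible_bias_, model.hidden_bias_]
    return list(model.weights_), list(model.biases_)


def _check_cap(biases, what="exact enumeration"):
    total = sum(len(b) for b in biases)
    if total > UNIT_CAP:
        raise SizeError(
            f"{total} units exceed the cap of {UNIT_CAP} for {what}; "
            f"use AIS (ais_log_partition) instead")


def _enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n as rows."""
    return ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)


def _log_pstar(weights, biases, even_states, beta=1.0):
    """Log unnormalized probability of even-layer states, odd layers collapsed.

    ``even_states`` maps even layer index -> (m, n_l) state matrix; all
    matrices share the leading dimension m.  Weights enter scaled by ``beta``.
    """
    L = len(weights)
    m = next(iter(even_states.values())).shape[0]
    logp = np.zeros(m)
    for l, s in even_states.items():
        logp += s @ biases[l]
    for l in range(1, L + 1, 2):  # odd layers, collapsed
        act = np.broadcast_to(biases[l], (m, len(biases[l]))).copy()
        if l - 1 in even_states:
            act += beta * (even_states[l - 1] @ weights[l - 1])
        if l + 1 in even_states:
            act += beta * (even_states[l + 1] @ weights[l].T)
        logp += np.logaddexp(0.0, act).sum(axis=1)
    return logp


def _collapsed_log_partition(weights, biases, beta=1.0) -> float:
    """log Z by enumerating even layers with odd layers collapsed."""
    if not weights:  # single independent layer
        return float(np.logaddexp(0.0, biases[0]).sum())
    evens = list(range(0, len(weights) + 1, 2))
    tables = [_enumerate_states(len(biases[l])) for l in evens]
    sizes = [t.shape[0] for t in tables]
    total = int(np.prod(sizes))
    even_states = {}
    rep = total
    for l, t, size in zip(evens, tables, sizes):
        rep //= size
        idx = np.tile(np.repeat(np.arange(size), rep), total // (size * rep))
        even_states[l] = t[idx]
    return float(logsumexp(_log_pstar(weights, biases, even_states, beta)))


def exact_log_partition(model) -> float:
    """Exact log Z; exponential in the number of even-layer units."""
    weights, biases = _layers(model)
    _check_cap(biases)
    return _collapsed_log_partition(weights, biases)


def _log_pstar_visible(weights, biases, v) -> float:
    """log p*(v) = log sum_h exp(-E(v, h)) for one visible vector."""
    if len(weights) == 1:  # RBM: analytic
        act = biases[1] + v @ weights[0]
        return float(v @ biases[0] + np.logaddexp(0.0, act).sum())
    sub_w = weights[1:]
    sub_b = [biases[1] + v @ weights[0]] + biases[2:]
    return float(v @ biases[0]) + _collapsed_log_partition(sub_w, sub_b)


def exact_loglikelihood(model, data) -> LikelihoodEstimate:
    """Mean per-sample log-likelihood by full enumeration (tiny models only)."""
    weights, biases = _layers(model)
    _check_cap(biases)
    V = as_matrix(data)
    if V.shape[1] != len(biases[0]):
        raise ValueError(
            f"data has {V.shape[1]} variables, model {len(biases[0])}")
    log_z = _collapsed_log_partition(weights, biases)
    logp = np.array([_log_pstar_visible(weights, biases, v) for v in V])
    return LikelihoodEstimate(float(logp.mean() - log_z), 0.0, "exact")


# -- annealed importance sampling ------------------------------------------

def _base_log_partition(biases) -> float:
    return float(sum(np.logaddexp(0.0, b).sum() for b in biases))


def _ais_transition(weights, biases, even_states, beta, rng):
    """One Gibbs sweep at inverse temperature beta: odd layers given even,
    then even given odd; odd states are transient within the sweep."""
    L = len(weights)
    m = next(iter(even_states.values())).shape[0]
    odd_states = {}
    for l in range(1, L + 1, 2):
        act = np.broadcast_to(biases[l], (m, len(biases[l]))).copy()
        if l - 1 in even_states:
            act += beta * (even_states[l - 1] @ weights[l - 1])
        if l + 1 in even_states:
            act += beta * (even_states[l + 1] @ weights[l].T)
        odd_states[l] = (rng.random(act.shape) < expit(act)).astype(float)
    for l in even_states:
        act = np.broadcast_to(biases[l], (m, len(biases[l]))).copy()
        if l - 1 in odd_states:
            act += beta * (odd_states[l - 1] @ weights[l - 1])
        if l + 1 in odd_states:
            act += beta * (odd_states[l + 1] @ weights[l].T)
        even_states[l] = (rng.random(act.shape) < expit(act)).astype(float)


def _ais_layered(weights, biases, config, rng=None) -> LikelihoodEstimate:
    if not weights:
        return LikelihoodEstimate(_base_log_partition(biases), 0.0, "exact")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    P = config.n_particles
    betas = np.linspace(0.0, 1.0, config.n_temperatures)
    evens = list(range(0, len(weights) + 1, 2))
    even_states = {l: (rng.random((P, len(biases[l]))) < expit(biases[l]))
                   .astype(float) for l in evens}
    logw = np.zeros(P)
    for k in range(1, len(betas)):
        logw += (_log_pstar(weights, biases, even_states, betas[k])
                 - _log_pstar(weights, biases, even_states, betas[k - 1]))
        _ais_transition(weights, biases, even_states, betas[k], rng)
    log_z = _base_log_partition(biases) + logsumexp(logw) - np.log(P)
    # delta-method std error of log mean(w) from the particle variance
    w = np.exp(logw - logw.max())
    se = 0.0 if P == 1 else float(w.std(ddof=1) / (w.mean() * np.sqrt(P)))
    return LikelihoodEstimate(float(log_z), se, "ais")


def ais_log_partition(model, config=None) -> LikelihoodEstimate:
    """AIS estimate of log Z (geometric weight path, biases retained in the base)."""
    config = config or AISConfig()
    weights, biases = _layers(model)
    return _ais_layered(weights, biases, config)


def rbm_loglikelihood(rbm, data, config=None) -> LikelihoodEstimate:
    """Mean log-likelihood of an RBM: analytic free energies minus AIS log Z."""
    config = config or AISConfig()
    V = as_matrix(data)
    z = ais_log_partition(rbm, config)
    value = float((-rbm.free_energy(V)).mean() - z.value)
    return LikelihoodEstimate(value, z.std_error, "ais")


def dbm_logproblowerbound(dbm, data, config=None) -> LikelihoodEstimate:
    """Mean-field variational lower bound of the DBM log-likelihood.

    Per sample: E_q[-E(v, h)] + H(q) - log Z_hat, where q is the mean-field
    posterior (a product distribution, so the expected energy is bilinear in
    the means) and log Z_hat comes from AIS.
    """
    config = config or AISConfig()
    V = as_matrix(data)
    mus = [V] + dbm.mean_field(V)
    weights, biases = _layers(dbm)
    neg_energy = np.zeros(V.shape[0])
    entropy = np.zeros(V.shape[0])
    for l, W in enumerate(weights):
        neg_energy += (mus[l] @ W * mus[l + 1]).sum(axis=1)
    for l, b in enumerate(biases):
        neg_energy += mus[l] @ b
        if l > 0:
            mu = np.clip(mus[l], 1e-12, 1 - 1e-12)
            entropy += -(mu * np.log(mu) + (1 - mu) * np.log(1 - mu)).sum(axis=1)
    z = ais_log_partition(dbm, config)
    value = float((neg_energy + entropy).mean() - z.value)
    return LikelihoodEstimate(value, z.std_error, "ais")


def dbm_loglikelihood(dbm, data, config=None) -> LikelihoodEstimate:
    """Mean DBM log-likelihood with a separate clamped-visible AIS run per sample.

    With v clamped, the first hidden layer absorbs v W_1 into its bias and
    the remaining network is again a layered model, whose partition function
    (= p*(v) up to the factor e^{a'v}) is estimated by AIS.
    """
    config = config or AISConfig()
    V = as_matrix(data)
    weights, biases = _layers(dbm)
    if V.shape[1] != len(biases[0]):
        raise ValueError(
            f"data has {V.shape[1]} variables, model {len(biases[0])}")
    rng = np.random.default_rng(config.seed)
    z = _ais_layered(weights, biases, config, rng=rng)
    logps, ses = [], []
    for v in V:
        sub_w = weights[1:]
        sub_b = [biases[1] + v @ weights[0]] + biases[2:]
        est = _ais_layered(sub_w, sub_b, config, rng=rng)
        logps.append(float(v @ biases[0]) + est.value)
        ses.append(est.std_error)
    n = len(logps)
    value = float(np.mean(logps) - z.value)
    se = float(np.sqrt(np.sum(np.square(ses)) / n ** 2 + z.std_error ** 2))
    return LikelihoodEstimate(value, se, "ais")
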