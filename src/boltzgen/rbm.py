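"""Restricted Boltzmann machine trained with contrastive divergence.

A binary RBM over visible units v and hidden units h with energy

    E(v, h) = -v' W h - a' v - b' h

defines the Boltzmann distribution p(v, h) = exp(-E(v, h)) / Z.  The
bipartite graph makes both conditionals factorize into logistic units,
which gives cheap block Gibbs sampling and the CD-k gradient estimator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .dataset import BinaryDataset

__all__ = ["RBM", "MonitoringRecord", "fit_rbm", "energy", "hidden_conditional",
           "visible_conditional", "reconstruction_error", "gibbs_sample"]


@dataclass
class MonitoringRecord:
    """One monitoring evaluation collected during training."""

    epoch: int
    metric: str  # reconstruction_error | exact_loglik | ais_loglik | logproblowerbound
    value: float
    partition: str  # train | test


def as_matrix(X) -> np.ndarray:
    """Accept a BinaryDataset or array-like; return a float matrix."""
    if isinstance(X, BinaryDataset):
        return X.values.astype(float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _variable_names(X, n):
    if isinstance(X, BinaryDataset):
        return list(X.variable_names)
    return [f"var{j}" for j in range(n)]


class RBM(BaseEstimator):
    """Bernoulli-Bernoulli RBM generator fitted with CD-k.

    Parameters
    ----------
    n_hidden : int
        Number of hidden units.
    epochs : int
        Passes over the training data.
    learning_rate : float
        SGD step size (plain SGD, no momentum or weight decay).
    batch_size : int
        Minibatch size.
    cd_steps : int
        Gibbs steps for the negative phase (CD-k).
    random_state : int or None
        Seed controlling initialization, minibatch order and all sampling.

    Attributes
    ----------
    weights_ : ndarray (n_visible, n_hidden)
    visible_bias_ : ndarray (n_visible,)
    hidden_bias_ : ndarray (n_hidden,)
    monitor_ : list of MonitoringRecord
    feature_names_ : list of str
    """

    def __init__(self, n_hidden=10, epochs=20, learning_rate=0.1, batch_size=20,
                 cd_steps=1, random_state=None):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.cd_steps = cd_steps
        self.random_state = random_state

    # -- parameter plumbing -------------------------------------------------

    @classmethod
    def from_arrays(cls, weights, visible_bias, hidden_bias) -> "RBM":
        """Build a fitted RBM directly from its parameter arrays."""
        weights = np.asarray(weights, dtype=float)
        visible_bias = np.asarray(visible_bias, dtype=float)
        hidden_bias = np.asarray(hidden_bias, dtype=float)
        if weights.ndim != 2 or weights.shape != (len(visible_bias), len(hidden_bias)):
            raise ValueError(
                f"inconsistent shapes: W {weights.shape}, a {visible_bias.shape}, "
                f"b {hidden_bias.shape}"
            )
        if not (np.isfinite(weights).all() and np.isfinite(visible_bias).all()
                and np.isfinite(hidden_bias).all()):
            raise ValueError("parameters must be finite")
        rbm = cls(n_hidden=len(hidden_bias))
        rbm.weights_ = weights
        rbm.visible_bias_ = visible_bias
        rbm.hidden_bias_ = hidden_bias
        rbm.monitor_ = []
        rbm.feature_names_ = [f"var{j}" for j in range(len(visible_bias))]
        return rbm

    @property
    def n_visible_(self) -> int:
        return self.weights_.shape[0]

    def _check_v(self, v):
        v = np.asarray(v, dtype=float)
        if v.shape[-1] != self.weights_.shape[0]:
            raise ValueError(
                f"visible vector of length {v.shape[-1]}, model has "
                f"{self.weights_.shape[0]} visible units"
            )
        return v

    def _check_h(self, h):
        h = np.asarray(h, dtype=float)
        if h.shape[-1] != self.weights_.shape[1]:
            raise ValueError(
                f"hidden vector of length {h.shape[-1]}, model has "
                f"{self.weights_.shape[1]} hidden units"
            )
        return h

    # -- energy model -------------------------------------------------------

    def energy(self, v, h) -> float:
        """E(v, h) = -v'Wh - a'v - b'h for single state vectors."""
        v = self._check_v(v)
        h = self._check_h(h)
        return float(-(v @ self.weights_ @ h) - self.visible_bias_ @ v
                     - self.hidden_bias_ @ h)

    def hidden_conditional(self, v) -> np.ndarray:
        """p(h_j = 1 | v) = logistic(b_j + sum_i v_i W_ij); accepts mean activations."""
        v = self._check_v(v)
        return expit(self.hidden_bias_ + v @ self.weights_)

    def visible_conditional(self, h) -> np.ndarray:
        """p(v_i = 1 | h) = logistic(a_i + sum_j W_ij h_j)."""
        h = self._check_h(h)
        return expit(self.visible_bias_ + h @ self.weights_.T)

    def free_energy(self, v) -> np.ndarray:
        """F(v) = -a'v - sum_j log(1 + exp(b_j + (vW)_j)), vectorized over rows."""
        v = self._check_v(v)
        act = self.hidden_bias_ + v @ self.weights_
        return -(v @ self.visible_bias_) - np.logaddexp(0.0, act).sum(axis=-1)

    # -- training -----------------------------------------------------------

    def fit(self, X, y=None, monitor=None, test_data=None):
        """Train with CD-k stochastic gradient ascent.

        ``monitor`` may list metric names (currently ``reconstruction_error``)
        evaluated once per epoch on the training data and, if ``test_data``
        is given, on the test partition as well.
        """
        V = as_matrix(X)
        if V.shape[0] == 0:
            raise ValueError("cannot fit on empty data")
        self.feature_names_ = _variable_names(X, V.shape[1])
        rng = np.random.default_rng(self.random_state)
        self._init_params(V.shape[1], rng)
        self.monitor_ = []
        self._train_epochs(V, self.epochs, rng, monitor=monitor,
                           test_data=test_data, epoch_offset=0)
        return self

    def fit_with_checkpoints(self, X, epoch_grid, monitor=None):
        """Train incrementally, yielding ``(epoch, frozen_copy)`` at each
        epoch in ``epoch_grid``; the final state is left in ``self``."""
        V = as_matrix(X)
        if V.shape[0] == 0:
            raise ValueError("cannot fit on empty data")
        self.feature_names_ = _variable_names(X, V.shape[1])
        rng = np.random.default_rng(self.random_state)
        self._init_params(V.shape[1], rng)
        self.monitor_ = []
        done = 0
        for target in sorted(set(int(e) for e in epoch_grid)):
            self._train_epochs(V, target - done, rng, monitor=monitor,
                               epoch_offset=done)
            done = target
            yield target, self.copy()

    def _init_params(self, n_visible, rng):
        self.weights_ = rng.normal(0.0, 0.01, size=(n_visible, self.n_hidden))
        self.visible_bias_ = np.zeros(n_visible)
        self.hidden_bias_ = np.zeros(self.n_hidden)

    def _train_epochs(self, V, epochs, rng, monitor=None, test_data=None,
                      epoch_offset=0, up_scale=1.0, down_scale=1.0):
        """Run CD epochs in place.  The scale factors multiply the weight term
        in the conditionals; stack pre-training uses them to compensate the
        double counting of inputs in the assembled deep model."""
        n = V.shape[0]
        lr = self.learning_rate
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = V[order[start:start + self.batch_size]]
                m = batch.shape[0]
                h_pos = expit(self.hidden_bias_ + up_scale * (batch @ self.weights_))
                v_neg = batch
                h_prob = h_pos
                for _ in range(self.cd_steps):
                    h_samp = (rng.random(h_prob.shape) < h_prob).astype(float)
                    v_prob = expit(self.visible_bias_
                                   + down_scale * (h_samp @ self.weights_.T))
                    v_neg = (rng.random(v_prob.shape) < v_prob).astype(float)
                    h_prob = expit(self.hidden_bias_
                                   + up_scale * (v_neg @ self.weights_))
                self.weights_ += lr * (batch.T @ h_pos - v_neg.T @ h_prob) / m
                self.visible_bias_ += lr * (batch - v_neg).mean(axis=0)
                self.hidden_bias_ += lr * (h_pos - h_prob).mean(axis=0)
            if monitor:
                for metric in monitor:
                    self._record(metric, epoch + epoch_offset, V, "train")
                    if test_data is not None:
                        self._record(metric, epoch + epoch_offset,
                                     as_matrix(test_data), "test")

    def _record(self, metric, epoch, V, partition):
        if metric == "reconstruction_error":
            value = self.reconstruction_error(V)
        elif metric == "exact_loglik":
            from .likelihood import exact_loglikelihood
            value = exact_loglikelihood(self, V).value
        else:
            raise ValueError(f"unknown monitoring metric {metric!r}")
        self.monitor_.append(MonitoringRecord(epoch, metric, float(value), partition))

    # -- evaluation and sampling -------------------------------------------

    def reconstruction_error(self, X) -> float:
        """Mean squared Euclidean distance between data and one-step reconstruction."""
        V = as_matrix(X)
        self._check_v(V)
        recon = self.visible_conditional(self.hidden_conditional(V))
        return float(((V - recon) ** 2).sum(axis=1).mean())

    def sample(self, n_samples, burnin=50, clamped=None, random_state=None
               ) -> BinaryDataset:
        """Draw samples by block Gibbs, one independent chain per sample.

        ``clamped`` maps visible variable indices to fixed {0, 1} values; the
        clamped columns are reset after every visible update (conditional
        sampling).
        """
        if burnin < 1:
            raise ValueError("burnin must be >= 1")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        n_vis = self.n_visible_
        clamp_idx, clamp_val = _check_clamped(clamped, n_vis)
        v = (rng.random((n_samples, n_vis)) < 0.5).astype(float)
        if clamp_idx.size:
            v[:, clamp_idx] = clamp_val
        for _ in range(burnin):
            h_prob = self.hidden_conditional(v)
            h = (rng.random(h_prob.shape) < h_prob).astype(float)
            v_prob = self.visible_conditional(h)
            v = (rng.random(v_prob.shape) < v_prob).astype(float)
            if clamp_idx.size:
                v[:, clamp_idx] = clamp_val
        names = getattr(self, "feature_names_", None)
        return BinaryDataset(v.astype(np.uint8),
                             sample_ids=[f"gen{i}" for i in range(n_samples)],
                             variable_names=names)

    def copy(self) -> "RBM":
        return copy.deepcopy(self)


def _check_clamped(clamped, n_visible):
    if not clamped:
        return np.empty(0, dtype=int), np.empty(0)
    idx = np.array(sorted(clamped), dtype=int)
    if idx.min() < 0 or idx.max() >= n_visible:
        raise ValueError(
            f"clamped index out of range for {n_visible} visible variables")
    val = np.array([float(clamped[i]) for i in idx])
    if not np.isin(val, (0.0, 1.0)).all():
        raise ValueError("clamped values must be 0 or 1")
    return idx, val


# -- thin functional wrappers ----------------------------------------------

def fit_rbm(data, config=None, monitor=None, test_data=None, **params):
    """Train an RBM; returns ``(rbm, monitoring_records)``."""
    if config is not None:
        params = {**config.rbm_params(), **params}
    rbm = RBM(**params).fit(data, monitor=monitor, test_data=test_data)
    return rbm, rbm.monitor_


def energy(rbm, v, h):
    return rbm.energy(v, h)


def hidden_conditional(rbm, v):
    return rbm.hidden_conditional(v)


def visible_conditional(rbm, h):
    return rbm.visible_conditional(h)


def reconstruction_error(rbm, data):
    return rbm.reconstruction_error(data)


def gibbs_sample(rbm, n_samples, burnin=50, clamped=None, seed=None):
    return rbm.sample(n_samples, burnin=burnin, clamped=clamped, random_state=seed)
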