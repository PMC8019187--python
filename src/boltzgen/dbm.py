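"""Deep Boltzmann machine: greedy layer-wise pre-training, mean-field
fine-tuning, and full-network Gibbs sampling.

A DBM stacks layers s_0 (visible), s_1, ..., s_L with energy

    E(s) = - sum_l s_{l-1}' W_l s_l - sum_l b_l' s_l

Training first fits a stack of RBMs greedily (with doubled inputs on the
sides of each RBM that will receive input from two directions in the
assembled network, compensating the double counting), then maximises the
mean-field variational lower bound of the likelihood by stochastic gradient
ascent: the positive phase uses mean-field inference on the data, the
negative phase persistent Gibbs chains on the full network.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .dataset import BinaryDataset
from .rbm import RBM, MonitoringRecord, as_matrix, _check_clamped, _variable_names

__all__ = ["DBM", "LayerConfig", "pretrain_stack", "finetune_dbm", "fit_dbm",
           "mean_field_inference", "dbm_gibbs_sample", "top2_latent_dims"]


@dataclass
class LayerConfig:
    """Per-layer pre-training settings (one per RBM in the stack)."""

    nhidden: int
    learningratepretraining: float = 0.001
    epochspretraining: int = 30
    batchsizepretraining: int = 20

    def __post_init__(self):
        if self.nhidden < 1 or self.epochspretraining < 1 \
                or self.batchsizepretraining < 1 or self.learningratepretraining <= 0:
            raise ValueError(f"invalid layer configuration: {self}")


def _stack_scales(layer_index: int, n_layers: int):
    """(up_scale, down_scale) for the RBM at ``layer_index`` in a stack of
    ``n_layers`` destined for a DBM.  Sides facing another layer in the
    assembled network are doubled during pre-training."""
    if n_layers == 1:
        return 1.0, 1.0
    up = 2.0 if layer_index < n_layers - 1 else 1.0
    down = 2.0 if layer_index > 0 else 1.0
    return up, down


def pretrain_stack(data, layers, seed=None, cd_steps=1, monitor=None,
                   for_dbm=True):
    """Greedy layer-wise training of a stack of RBMs.

    Each RBM is trained on the hidden activation *probabilities* of the
    previous one.  Returns the list of fitted :class:`RBM` objects.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("need at least one layer")
    rng = np.random.default_rng(seed)
    V = as_matrix(data)
    stack, records = [], []
    for l, cfg in enumerate(layers):
        up, down = _stack_scales(l, len(layers)) if for_dbm else (1.0, 1.0)
        rbm = RBM(n_hidden=cfg.nhidden, epochs=cfg.epochspretraining,
                  learning_rate=cfg.learningratepretraining,
                  batch_size=cfg.batchsizepretraining, cd_steps=cd_steps)
        rbm.feature_names_ = [f"layer{l}_unit{j}" for j in range(V.shape[1])]
        rbm._init_params(V.shape[1], rng)
        rbm.monitor_ = []
        rbm._train_epochs(V, cfg.epochspretraining, rng,
                          monitor=monitor, up_scale=up, down_scale=down)
        records.extend(rbm.monitor_)
        stack.append(rbm)
        V = expit(rbm.hidden_bias_ + up * (V @ rbm.weights_))
    return stack, records


class DBM(BaseEstimator):
    """Deep Boltzmann machine generator.

    Parameters mirror the hyperparameter surface of the underlying training
    procedure: ``n_hiddens`` fixes the architecture (one entry per hidden
    layer); pre-training and fine-tuning each have their own epoch count and
    learning rate.

    Attributes
    ----------
    weights_ : list of ndarray, W_1 ... W_L
    biases_ : list of ndarray, b_0 ... b_L (b_0 is the visible bias)
    monitor_ : list of MonitoringRecord
    """

    def __init__(self, n_hiddens=(50, 10), epochs=30, learning_rate=0.1,
                 epochs_pretraining=30, learning_rate_pretraining=0.001,
                 batch_size_pretraining=20, batch_size=20, cd_steps=1,
                 n_meanfield_iters=10, meanfield_tol=1e-6,
                 n_persistent_chains=5, n_gibbs_steps=5, random_state=None):
        self.n_hiddens = n_hiddens
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.epochs_pretraining = epochs_pretraining
        self.learning_rate_pretraining = learning_rate_pretraining
        self.batch_size_pretraining = batch_size_pretraining
        self.batch_size = batch_size
        self.cd_steps = cd_steps
        self.n_meanfield_iters = n_meanfield_iters
        self.meanfield_tol = meanfield_tol
        self.n_persistent_chains = n_persistent_chains
        self.n_gibbs_steps = n_gibbs_steps
        self.random_state = random_state

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(cls, weights, biases) -> "DBM":
        """Build a fitted DBM from weight matrices W_1..W_L and biases b_0..b_L."""
        weights = [np.asarray(W, dtype=float) for W in weights]
        biases = [np.asarray(b, dtype=float) for b in biases]
        if len(biases) != len(weights) + 1 or not weights:
            raise ValueError("need L >= 1 weight matrices and L + 1 bias vectors")
        for l, W in enumerate(weights):
            if W.shape != (len(biases[l]), len(biases[l + 1])):
                raise ValueError(
                    f"W_{l + 1} has shape {W.shape}, expected "
                    f"({len(biases[l])}, {len(biases[l + 1])})")
        if not all(np.isfinite(W).all() for W in weights) or \
                not all(np.isfinite(b).all() for b in biases):
            raise ValueError("parameters must be finite")
        dbm = cls(n_hiddens=tuple(len(b) for b in biases[1:]))
        dbm.weights_ = weights
        dbm.biases_ = biases
        dbm.monitor_ = []
        dbm.feature_names_ = [f"var{j}" for j in range(len(biases[0]))]
        return dbm

    @classmethod
    def from_stack(cls, stack) -> "DBM":
        """Assemble DBM parameters from a pre-trained RBM stack.

        Weights are taken unchanged (the doubled-input pre-training already
        compensates double counting); biases of layers shared by two RBMs
        are averaged.
        """
        weights = [rbm.weights_.copy() for rbm in stack]
        for a, b in zip(stack[:-1], stack[1:]):
            if a.weights_.shape[1] != b.weights_.shape[0]:
                raise ValueError("stack dimensions do not chain")
        biases = [stack[0].visible_bias_.copy()]
        for l in range(len(stack) - 1):
            biases.append((stack[l].hidden_bias_ + stack[l + 1].visible_bias_) / 2.0)
        biases.append(stack[-1].hidden_bias_.copy())
        return cls.from_arrays(weights, biases)

    @property
    def n_layers_(self) -> int:
        """Number of hidden layers L."""
        return len(self.weights_)

    @property
    def n_visible_(self) -> int:
        return len(self.biases_[0])

    # -- inference ----------------------------------------------------------

    def _layer_input(self, states, l):
        total = np.broadcast_to(self.biases_[l], states[l].shape).copy()
        if l > 0:
            total += states[l - 1] @ self.weights_[l - 1]
        if l < self.n_layers_:
            total += states[l + 1] @ self.weights_[l].T
        return total

    def mean_field(self, X, max_iters=None, tol=None):
        """Mean-field posterior means of all hidden layers given visible data.

        Fixed-point iteration of the layer-wise logistic updates with the
        visible layer clamped to the data; returns [mu_1, ..., mu_L].
        """
        V = as_matrix(X)
        if V.shape[1] != self.n_visible_:
            raise ValueError(
                f"data has {V.shape[1]} variables, model {self.n_visible_}")
        max_iters = self.n_meanfield_iters if max_iters is None else max_iters
        tol = self.meanfield_tol if tol is None else tol
        L = self.n_layers_
        mus = [V]
        for l in range(1, L + 1):  # upward pass initialization
            mus.append(expit(self.biases_[l] + mus[-1] @ self.weights_[l - 1]))
        if L == 1:
            return mus[1:]
        for _ in range(max_iters):
            delta = 0.0
            for l in range(1, L + 1):
                new = expit(self._layer_input(mus, l))
                delta = max(delta, float(np.abs(new - mus[l]).max()))
                mus[l] = new
            if delta < tol:
                break
        return mus[1:]

    def top2_latent_dims(self, X) -> np.ndarray:
        """Two-dimensional latent representation from a 2-unit top layer."""
        if len(self.biases_[-1]) != 2:
            raise ValueError(
                f"top2_latent_dims requires a 2-unit top hidden layer; this "
                f"model's top layer has {len(self.biases_[-1])} units "
                f"(architecture {[len(b) for b in self.biases_[1:]]})")
        return self.mean_field(X)[-1]

    # -- training -----------------------------------------------------------

    def _layer_configs(self):
        if not len(self.n_hiddens):
            raise ValueError("n_hiddens must name at least one hidden layer")
        return [LayerConfig(nhidden=h,
                            learningratepretraining=self.learning_rate_pretraining,
                            epochspretraining=self.epochs_pretraining,
                            batchsizepretraining=self.batch_size_pretraining)
                for h in self.n_hiddens]

    def fit(self, X, y=None, monitor=None):
        """Pre-train the stack, assemble, then fine-tune the lower bound."""
        for _ in self.fit_with_checkpoints(X, epoch_grid=(self.epochs,),
                                           monitor=monitor):
            pass
        return self

    def fit_with_checkpoints(self, X, epoch_grid, monitor=None):
        """Train, yielding ``(epoch, frozen_copy)`` at each fine-tuning epoch
        in ``epoch_grid`` (epoch 0 = pre-trained stack only).  The final
        yielded state is also left in ``self``."""
        V = as_matrix(X)
        if V.shape[0] == 0:
            raise ValueError("cannot fit on empty data")
        names = _variable_names(X, V.shape[1])
        rng = np.random.default_rng(self.random_state)
        seed_pre, seed_fine = rng.integers(2 ** 31, size=2)
        stack, records = pretrain_stack(
            V, self._layer_configs(), seed=int(seed_pre), cd_steps=self.cd_steps,
            monitor=[m for m in (monitor or []) if m == "reconstruction_error"]
            or None)
        assembled = DBM.from_stack(stack)
        self.weights_ = assembled.weights_
        self.biases_ = assembled.biases_
        self.feature_names_ = names
        self.monitor_ = records
        grid = sorted(set(int(e) for e in epoch_grid))
        rng_fine = np.random.default_rng(int(seed_fine))
        chains = [(rng_fine.random((self.n_persistent_chains, len(b))) < 0.5)
                  .astype(float) for b in self.biases_]
        done = 0
        if grid and grid[0] == 0:
            yield 0, self._frozen()
            grid = grid[1:]
        for target in grid:
            self._finetune_epochs(V, target - done, rng_fine, chains,
                                  monitor=monitor, epoch_offset=done)
            done = target
            yield target, self._frozen()

    def _frozen(self) -> "DBM":
        return copy.deepcopy(self)

    def _finetune_epochs(self, V, epochs, rng, chains, monitor=None,
                         epoch_offset=0):
        n = V.shape[0]
        L = self.n_layers_
        lr = self.learning_rate
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = V[order[start:start + self.batch_size]]
                m = batch.shape[0]
                mus = [batch] + self.mean_field(batch)
                for _ in range(self.n_gibbs_steps):
                    self._gibbs_sweep(chains, rng)
                c = self.n_persistent_chains
                for l in range(L):
                    self.weights_[l] += lr * (
                        mus[l].T @ mus[l + 1] / m
                        - chains[l].T @ chains[l + 1] / c)
                for l in range(L + 1):
                    self.biases_[l] += lr * (mus[l].mean(axis=0)
                                             - chains[l].mean(axis=0))
            if monitor and "logproblowerbound" in monitor:
                from .likelihood import AISConfig, dbm_logproblowerbound
                est = dbm_logproblowerbound(
                    self, V, AISConfig(n_temperatures=50, n_particles=20,
                                       seed=int(rng.integers(2 ** 31))))
                self.monitor_.append(MonitoringRecord(
                    epoch + epoch_offset, "logproblowerbound", est.value, "train"))

    # -- sampling -----------------------------------------------------------

    def _gibbs_sweep(self, states, rng, clamp_idx=None, clamp_val=None):
        L = self.n_layers_
        for parity in (1, 0):  # odd layers given even, then even given odd
            for l in range(parity, L + 1, 2):
                prob = expit(self._layer_input(states, l))
                states[l] = (rng.random(prob.shape) < prob).astype(float)
                if l == 0 and clamp_idx is not None and clamp_idx.size:
                    states[0][:, clamp_idx] = clamp_val

    def sample(self, n_samples, burnin=50, clamped=None, random_state=None
               ) -> BinaryDataset:
        """Visible-layer samples from block Gibbs over the full network,
        one independent chain per sample; clamped visible variables held fixed."""
        if burnin < 1:
            raise ValueError("burnin must be >= 1")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        clamp_idx, clamp_val = _check_clamped(clamped, self.n_visible_)
        states = [(rng.random((n_samples, len(b))) < 0.5).astype(float)
                  for b in self.biases_]
        if clamp_idx.size:
            states[0][:, clamp_idx] = clamp_val
        for _ in range(burnin):
            self._gibbs_sweep(states, rng, clamp_idx, clamp_val)
        names = getattr(self, "feature_names_", None)
        return BinaryDataset(states[0].astype(np.uint8),
                             sample_ids=[f"gen{i}" for i in range(n_samples)],
                             variable_names=names)

    def copy(self) -> "DBM":
        return copy.deepcopy(self)


# -- thin functional wrappers ----------------------------------------------

def finetune_dbm(stack, data, config):
    """Assemble a pre-trained stack and fine-tune it; ``config`` is a TrainConfig."""
    dbm = DBM(**config.dbm_params())
    assembled = DBM.from_stack(stack)
    dbm.weights_ = assembled.weights_
    dbm.biases_ = assembled.biases_
    V = as_matrix(data)
    if V.shape[1] != dbm.n_visible_:
        raise ValueError("data does not match the stack's visible layer")
    dbm.feature_names_ = _variable_names(data, V.shape[1])
    dbm.monitor_ = []
    rng = np.random.default_rng(config.seed)
    chains = [(rng.random((dbm.n_persistent_chains, len(b))) < 0.5).astype(float)
              for b in dbm.biases_]
    dbm._finetune_epochs(V, config.epochs, rng, chains)
    return dbm


def fit_dbm(data, config=None, monitor=None, **params):
    """Pre-train + fine-tune a DBM; returns ``(dbm, monitoring_records)``."""
    if config is not None:
        params = {**config.dbm_params(), **params}
    dbm = DBM(**params).fit(data, monitor=monitor)
    return dbm, dbm.monitor_


def mean_field_inference(dbm, v, max_iters=10, tol=1e-6):
    mus = dbm.mean_field(np.atleast_2d(np.asarray(v, dtype=float)),
                         max_iters=max_iters, tol=tol)
    return [mu[0] for mu in mus]


def dbm_gibbs_sample(dbm, n_samples, burnin=50, clamped=None, seed=None):
    return dbm.sample(n_samples, burnin=burnin, clamped=clamped, random_state=seed)


def top2_latent_dims(dbm, data):
    return dbm.top2_latent_dims(data)
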