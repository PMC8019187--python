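"""Synthetic binary SNP data.

The flagship generator emulates a case/control panel in which "cases" carry
SNP sets: blocks of five consecutive minor alleles that co-occur, standing
in for jointly deleterious mutations in one pathway.  Background cells are
iid Bernoulli noise.  Also provided: plain iid Bernoulli panels and a
sequential-logistic process whose ground-truth parameters match the MICE
model family (for parameter-recovery tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .dataset import BinaryDataset

__all__ = ["SNPSimConfig", "LabeledDataset", "simulate_snp_sets",
           "simulate_iid_bernoulli", "simulate_logistic_chain"]


@dataclass
class SNPSimConfig:
    """Design of the simulated SNP-set panel.

    Defaults give 500 samples x 50 variables: 250 cases / 250 controls,
    Bernoulli(0.1) background noise, and five 5-SNP sets at evenly spaced
    starts (columns 0-4, 10-14, ..., 40-44).  Each case activates each set
    independently with probability ``set_activation_p`` (activation writes
    ones over the whole block).
    """

    n_samples: int = 500
    n_variables: int = 50
    noise_p: float = 0.1
    n_sets: int = 5
    set_size: int = 5
    case_fraction: float = 0.5
    set_activation_p: float = 0.5
    seed: int = None

    def __post_init__(self):
        if self.n_sets * self.set_size > self.n_variables:
            raise ValueError(
                f"{self.n_sets} sets of {self.set_size} do not fit in "
                f"{self.n_variables} variables")
        if not (0 <= self.noise_p <= 1 and 0 <= self.set_activation_p <= 1
                and 0 <= self.case_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_samples < 1 or self.set_size < 1 or self.n_sets < 1:
            raise ValueError("counts must be positive")

    def set_positions(self):
        """Column index blocks of the SNP sets (evenly spaced starts)."""
        starts = [int(i * self.n_variables / self.n_sets)
                  for i in range(self.n_sets)]
        blocks = [list(range(s, s + self.set_size)) for s in starts]
        for a, b in zip(blocks[:-1], blocks[1:]):
            if a[-1] >= b[0]:
                raise ValueError("SNP sets overlap; reduce set_size or n_sets")
        return blocks


@dataclass
class LabeledDataset:
    """A dataset with case/control labels and the planted block positions."""

    data: BinaryDataset
    labels: np.ndarray       # "case" / "control" per sample
    set_positions: list      # list of column-index blocks


def simulate_snp_sets(config: SNPSimConfig = None, **overrides) -> LabeledDataset:
    """Simulate the SNP-set case/control panel described by ``config``."""
    if config is None:
        config = SNPSimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_variables
    n_cases = int(round(config.case_fraction * n))
    values = (rng.random((n, k)) < config.noise_p).astype(np.uint8)
    blocks = config.set_positions()
    activations = rng.random((n_cases, len(blocks))) < config.set_activation_p
    for b, block in enumerate(blocks):
        rows = np.flatnonzero(activations[:, b])
        values[np.ix_(rows, block)] = 1
    labels = np.array(["case"] * n_cases + ["control"] * (n - n_cases))
    data = BinaryDataset(values,
                         sample_ids=[f"sample{i}" for i in range(n)],
                         variable_names=[f"snp{j}" for j in range(k)])
    return LabeledDataset(data=data, labels=labels, set_positions=blocks)


def simulate_iid_bernoulli(n_samples, probabilities, seed=None) -> BinaryDataset:
    """Independent Bernoulli draws per cell, column i at probabilities[i]."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must be a vector in [0, 1]")
    rng = np.random.default_rng(seed)
    values = (rng.random((n_samples, len(p))) < p).astype(np.uint8)
    return BinaryDataset(values,
                         sample_ids=[f"sample{i}" for i in range(n_samples)],
                         variable_names=[f"var{j}" for j in range(len(p))])


def simulate_logistic_chain(n_samples, intercepts, coefficients, seed=None
                            ) -> BinaryDataset:
    """Sequential logistic process: p(v_j = 1 | v_<j) = logistic(c_j + beta_j . v_<j).

    ``coefficients[j]`` must have length j (coefficients on the j preceding
    variables); the sampling semantics mirror the MICE generator exactly.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    intercepts = np.asarray(intercepts, dtype=float)
    k = len(intercepts)
    coefficients = [np.asarray(c, dtype=float) for c in coefficients]
    if len(coefficients) != k or any(len(c) != j for j, c in enumerate(coefficients)):
        raise ValueError(
            "coefficients[j] must hold exactly j entries (predecessors only)")
    rng = np.random.default_rng(seed)
    values = np.zeros((n_samples, k))
    for j in range(k):
        logit = intercepts[j] + (values[:, :j] @ coefficients[j] if j else 0.0)
        values[:, j] = rng.random(n_samples) < expit(logit)
    return BinaryDataset(values.astype(np.uint8),
                         sample_ids=[f"sample{i}" for i in range(n_samples)],
                         variable_names=[f"var{j}" for j in range(k)])
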