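"""Utility and disclosure metrics for synthetic binary data.

Utility: the RMSE d(x_gen, x_ref) between the strictly-lower-triangle
entries of the pairwise log-odds-ratio matrices of generated and reference
data (zero cells of each 2x2 table are replaced by 0.5 so every log OR is
finite).

Disclosure: the proportion of overfitting
(d(gen, val) - d(gen, train)) / d(gen, val), and a distance-based
membership attack that guesses "training member" whenever a generated
sample lies within a Hamming-distance threshold of the probe record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import BinaryDataset

__all__ = ["LogORMatrix", "AttackResult", "log_odds_ratio_matrix",
           "odds_ratio_distance", "overfitting_proportion", "membership_attack"]


@dataclass
class LogORMatrix:
    """Symmetric matrix of continuity-corrected pairwise log odds ratios.

    The diagonal is undefined and stored as NaN.
    """

    values: np.ndarray
    variable_names: list


@dataclass
class AttackResult:
    """Confusion counts of the membership attack at one distance threshold.

    ``precision`` is None when the attacker makes no positive guess (never
    reported as 0).
    """

    threshold: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self):
        pos = self.tp + self.fp
        return self.tp / pos if pos > 0 else None

    @property
    def sensitivity(self):
        return self.tp / (self.tp + self.fn)


def log_odds_ratio_matrix(data: BinaryDataset) -> LogORMatrix:
    """Pairwise log odds ratios with 0.5 substituted for zero table cells."""
    X = (data.values if isinstance(data, BinaryDataset)
         else np.asarray(data)).astype(float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if X.shape[0] < 1:
        raise ValueError("need at least 1 sample")
    n11 = X.T @ X
    n10 = X.T @ (1 - X)
    n01 = n10.T
    n00 = (1 - X).T @ (1 - X)
    tables = [np.where(t == 0, 0.5, t) for t in (n11, n10, n01, n00)]
    values = np.log(tables[0] * tables[3]) - np.log(tables[1] * tables[2])
    np.fill_diagonal(values, np.nan)
    names = (list(data.variable_names) if isinstance(data, BinaryDataset)
             else [f"var{j}" for j in range(X.shape[1])])
    return LogORMatrix(values, names)


def _check_same_variables(a: BinaryDataset, b: BinaryDataset):
    na = list(a.variable_names) if isinstance(a, BinaryDataset) else None
    nb = list(b.variable_names) if isinstance(b, BinaryDataset) else None
    if na is not None and nb is not None and na != nb:
        extra = sorted(set(na) ^ set(nb))
        raise ValueError(
            f"datasets cover different variables (symmetric difference "
            f"{extra[:5]}{'...' if len(extra) > 5 else ''}) or different order")
    ka = a.n_variables if isinstance(a, BinaryDataset) else np.asarray(a).shape[1]
    kb = b.n_variables if isinstance(b, BinaryDataset) else np.asarray(b).shape[1]
    if ka != kb:
        raise ValueError(f"variable count mismatch: {ka} vs {kb}")


def odds_ratio_distance(gen, ref) -> float:
    """d(x_gen, x_ref): RMSE over the strictly lower triangle of the log-OR matrices."""
    _check_same_variables(gen, ref)
    mg = log_odds_ratio_matrix(gen).values
    mr = log_odds_ratio_matrix(ref).values
    i, j = np.tril_indices(mg.shape[0], k=-1)
    return float(np.sqrt(np.mean((mg[i, j] - mr[i, j]) ** 2)))


def overfitting_proportion(gen, train, val) -> float:
    """(d(gen, val) - d(gen, train)) / d(gen, val); positive = closer to training."""
    d_val = odds_ratio_distance(gen, val)
    if d_val == 0.0:
        raise ZeroDivisionError(
            "d(gen, val) is zero; the proportion of overfitting is undefined")
    return (d_val - odds_ratio_distance(gen, train)) / d_val


def _min_hamming(probe: np.ndarray, gen: np.ndarray) -> np.ndarray:
    """Minimum Hamming distance from each probe row to any generated row."""
    probe = probe.astype(float)
    gen = gen.astype(float)
    # d(x, g) = x.(1-g) + (1-x).g, vectorized over all pairs
    d = probe @ (1 - gen).T + (1 - probe) @ gen.T
    return d.min(axis=1)


def membership_attack(train, test, gen, thresholds=range(11)) -> list:
    """Run the distance-based membership attack at each Hamming threshold.

    A probe is guessed to be a training member iff some generated sample is
    within the threshold.  Training probes yield TP/FN, test probes FP/TN.
    """
    _check_same_variables(train, gen)
    _check_same_variables(test, gen)
    tr = train.values if isinstance(train, BinaryDataset) else np.asarray(train)
    te = test.values if isinstance(test, BinaryDataset) else np.asarray(test)
    ge = gen.values if isinstance(gen, BinaryDataset) else np.asarray(gen)
    if tr.shape[0] != te.shape[0]:
        warnings.warn(
            f"train ({tr.shape[0]}) and test ({te.shape[0]}) sample counts "
            f"differ; the attack assumes equal sizes", stacklevel=2)
    d_train = _min_hamming(tr, ge)
    d_test = _min_hamming(te, ge)
    results = []
    for t in thresholds:
        if t < 0:
            raise ValueError("thresholds must be nonnegative")
        tp = int((d_train <= t).sum())
        fp = int((d_test <= t).sum())
        results.append(AttackResult(threshold=int(t), tp=tp, fp=fp,
                                    tn=te.shape[0] - fp, fn=tr.shape[0] - tp))
    return results
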