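"""Baseline generators: independent marginals (IM) and generative MICE.

IM samples every variable independently at its empirical frequency.  MICE
(multivariate imputation by chained equations, used generatively) factorizes
the joint distribution as a sequence of logistic regressions in a random
variable order and samples records sequentially through that chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .dataset import BinaryDataset
from .rbm import as_matrix, _variable_names

__all__ = ["IndependentMarginals", "MICEGenerator", "fit_im", "sample_im",
           "fit_mice", "sample_mice"]

COEF_CLIP = 15.0       # |beta| bound signalling (and capping) separation
RIDGE_LAMBDA = 1e-4    # L2 strength of the fallback fit
RANK_TOL = 1e-8        # relative tolerance of the collinearity rank test


class IndependentMarginals(BaseEstimator):
    """Generator drawing each variable independently at its training frequency.

    Attributes
    ----------
    frequencies_ : ndarray (n_variables,)
        Empirical p(v_i = 1) per variable.
    """

    def __init__(self, random_state=None):
        self.random_state = random_state

    def fit(self, X, y=None):
        V = as_matrix(X)
        if V.shape[0] == 0:
            raise ValueError("cannot fit on empty data")
        self.frequencies_ = V.mean(axis=0)
        self.feature_names_ = _variable_names(X, V.shape[1])
        return self

    def sample(self, n_samples, random_state=None) -> BinaryDataset:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        values = (rng.random((n_samples, len(self.frequencies_)))
                  < self.frequencies_).astype(np.uint8)
        return BinaryDataset(values,
                             sample_ids=[f"gen{i}" for i in range(n_samples)],
                             variable_names=self.feature_names_)


@dataclass
class _Regression:
    """Prediction rule for one variable in the MICE chain.

    Either a constant (the training column had zero variance) or a logistic
    model over the retained predecessors, identified by their positions in
    the sampling order.
    """

    constant: float = None
    predictors: list = field(default_factory=list)  # order positions
    coef: np.ndarray = None
    intercept: float = None


class MICEGenerator(BaseEstimator):
    """Generative MICE via sequential logistic regression.

    Fitting draws a random order of the variables, estimates p(v_1) for the
    first, and for each later variable fits a logistic regression on the
    preceding ones.  Candidate predictors are added consecutively; a
    candidate whose addition does not increase the rank of the design matrix
    (tolerance-based rank test) is collinear and is dropped from this and
    all further models.  A constant target is predicted by its constant
    without a regression.  Sampling walks the chain in order and restores
    the original column order.

    Attributes
    ----------
    order_ : ndarray, permutation of variable indices (sampling order)
    first_prob_ : float, p(v = 1) of the first variable in order
    regressions_ : list of per-variable prediction rules (positions 1..N-1)
    dropped_ : set of variable indices excluded as predictors
    """

    def __init__(self, random_state=None, max_iter=1000):
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        V = as_matrix(X)
        n, k = V.shape
        if k < 2:
            raise ValueError("MICE needs at least 2 variables")
        rng = np.random.default_rng(self.random_state)
        self.order_ = rng.permutation(k)
        self.feature_names_ = _variable_names(X, k)
        ordered = V[:, self.order_]
        self.first_prob_ = float(ordered[:, 0].mean())
        self.dropped_ = set()
        self.regressions_ = []
        retained = [0] if ordered[:, 0].std() > 0 else []
        if not retained:
            self.dropped_.add(int(self.order_[0]))
        for pos in range(1, k):
            target = ordered[:, pos]
            if target.std() == 0:
                self.regressions_.append(_Regression(constant=float(target[0])))
            else:
                preds = [p for p in retained if p < pos]
                self.regressions_.append(self._fit_logistic(ordered, preds, target))
            # decide whether this variable may serve as a later predictor
            if target.std() == 0 or not self._adds_rank(ordered, retained, pos):
                self.dropped_.add(int(self.order_[pos]))
            else:
                retained.append(pos)
        return self

    @staticmethod
    def _adds_rank(ordered, retained, pos):
        base = np.column_stack([np.ones(ordered.shape[0])]
                               + [ordered[:, p] for p in retained])
        aug = np.column_stack([base, ordered[:, pos]])
        tol = RANK_TOL * max(ordered.shape[0], aug.shape[1])
        return (np.linalg.matrix_rank(aug, tol=tol)
                > np.linalg.matrix_rank(base, tol=tol))

    def _fit_logistic(self, ordered, preds, target) -> _Regression:
        if not preds:
            freq = float(np.clip(target.mean(), 1e-12, 1 - 1e-12))
            return _Regression(predictors=[], coef=np.empty(0),
                               intercept=float(np.log(freq / (1 - freq))))
        design = ordered[:, preds]
        import warnings
        model = LogisticRegression(C=np.inf, solver="lbfgs",
                                   max_iter=self.max_iter, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(design, target)
        coefs = np.r_[model.coef_[0], model.intercept_[0]]
        if np.abs(coefs).max() > COEF_CLIP:  # separation: ridge fallback, then cap
            model = LogisticRegression(C=1.0 / RIDGE_LAMBDA, solver="lbfgs",
                                       max_iter=self.max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(design, target)
        coef = np.clip(model.coef_[0], -COEF_CLIP, COEF_CLIP)
        intercept = float(np.clip(model.intercept_[0], -COEF_CLIP, COEF_CLIP))
        return _Regression(predictors=list(preds), coef=coef, intercept=intercept)

    def sample(self, n_samples, random_state=None) -> BinaryDataset:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        k = len(self.order_)
        out = np.zeros((n_samples, k))
        out[:, 0] = rng.random(n_samples) < self.first_prob_
        for pos, reg in enumerate(self.regressions_, start=1):
            if reg.constant is not None:
                out[:, pos] = reg.constant
                continue
            logit = reg.intercept + (out[:, reg.predictors] @ reg.coef
                                     if reg.predictors else 0.0)
            out[:, pos] = rng.random(n_samples) < expit(logit)
        values = np.empty_like(out)
        values[:, self.order_] = out  # back to original column order
        return BinaryDataset(values.astype(np.uint8),
                             sample_ids=[f"gen{i}" for i in range(n_samples)],
                             variable_names=self.feature_names_)


# -- thin functional wrappers ----------------------------------------------

def fit_im(data) -> IndependentMarginals:
    return IndependentMarginals().fit(data)


def sample_im(model, n, seed=None) -> BinaryDataset:
    return model.sample(n, random_state=seed)


def fit_mice(data, seed=None) -> MICEGenerator:
    return MICEGenerator(random_state=seed).fit(data)


def sample_mice(model, n, seed=None) -> BinaryDataset:
    return model.sample(n, random_state=seed)
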