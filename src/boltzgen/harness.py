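"""Simulated multi-site benchmark.

The training data is split into equal consecutive shares ("virtual sites"),
one generator is trained per site on its share only, each site generates as
many synthetic samples as it holds, and the per-site outputs are pooled.
Hyperparameters (training epochs up to a cap, and the random initialization)
are selected by the log-odds-ratio distance d(x_gen, x_test) to a held-out
test set; the selected pooled data is then scored against the validation
set (utility, proportion of overfitting, membership attack).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .dataset import BinaryDataset, split_train_test_val
from .metrics import membership_attack, odds_ratio_distance, overfitting_proportion

__all__ = ["SiteSplit", "ExperimentResult", "split_sites", "run_sites",
           "hyperparameter_search", "run_experiment"]


@dataclass
class SiteSplit:
    """Consecutive equal shares of one dataset, one per virtual site."""

    shares: list  # of BinaryDataset


def derive_seed(master, *key) -> int:
    """Deterministic child seed (< 2^31) from a master seed and a key path."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def split_sites(data: BinaryDataset, n_sites: int) -> SiteSplit:
    """Equal consecutive blocks; any remainder spread over the leading sites."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites > data.n_samples:
        raise ValueError(
            f"cannot split {data.n_samples} samples over {n_sites} sites")
    base, extra = divmod(data.n_samples, n_sites)
    shares, start = [], 0
    for s in range(n_sites):
        size = base + (1 if s < extra else 0)
        shares.append(data.take_rows(np.arange(start, start + size)))
        start += size
    return SiteSplit(shares)


def _sample_n(model, n, seed):
    return model.sample(n, random_state=seed)


def run_sites(split: SiteSplit, generator, seed=None) -> BinaryDataset:
    """Fit a clone of ``generator`` per site and pool the generated data.

    Each site contributes as many synthetic samples as its training share,
    so the pooled output matches the total training size.  Per-site seeds
    derive deterministically from ``seed``.
    """
    pieces = []
    for s, share in enumerate(split.shares):
        if share.n_samples == 0:
            raise ValueError(f"site {s} has no samples")
        est = clone(generator)
        est.set_params(random_state=derive_seed(seed, s, 0))
        try:
            est.fit(share)
        except Exception as err:
            raise RuntimeError(f"fitting failed at site {s}: {err}") from err
        pieces.append(_sample_n(est, share.n_samples, derive_seed(seed, s, 1)))
    return _pool(pieces)


def _pool(pieces) -> BinaryDataset:
    values = np.vstack([p.values for p in pieces])
    ids = [f"site{s}_{sid}" for s, p in enumerate(pieces) for sid in p.sample_ids]
    return BinaryDataset(values, sample_ids=ids,
                         variable_names=pieces[0].variable_names)


def _epoch_grid(epoch_cap, n_checkpoints=20):
    step = max(1, epoch_cap // n_checkpoints)
    grid = list(range(step, epoch_cap + 1, step))
    if grid[-1] != epoch_cap:
        grid.append(epoch_cap)
    return grid


def hyperparameter_search(split: SiteSplit, test: BinaryDataset, generator,
                          epoch_cap=30, n_inits=1, seed=None,
                          n_checkpoints=20):
    """Select (initialization, epoch) minimizing d(x_gen, x_test).

    Generators exposing ``fit_with_checkpoints`` (RBM, DBM) are evaluated
    along the epoch axis at up to ``n_checkpoints`` evenly spaced epochs up
    to ``epoch_cap``; others (IM, MICE) are evaluated once per
    initialization.  Returns ``(best pooled BinaryDataset, record)`` where
    the record holds the winning init, epoch, and distance, plus the
    evaluated grid.
    """
    if epoch_cap < 1 or n_inits < 1:
        raise ValueError("epoch_cap and n_inits must be >= 1")
    checkpointed = hasattr(generator, "fit_with_checkpoints")
    grid = _epoch_grid(epoch_cap, n_checkpoints) if checkpointed else [None]
    best = None
    for init in range(n_inits):
        pooled = {e: [] for e in grid}
        for s, share in enumerate(split.shares):
            est = clone(generator)
            est.set_params(random_state=derive_seed(seed, init, s))
            if checkpointed:
                est.set_params(epochs=epoch_cap)
                for epoch, frozen in est.fit_with_checkpoints(share, grid):
                    pooled[epoch].append(_sample_n(
                        frozen, share.n_samples, derive_seed(seed, init, s, epoch)))
            else:
                est.fit(share)
                pooled[None].append(_sample_n(
                    est, share.n_samples, derive_seed(seed, init, s, 0)))
        for epoch in grid:
            gen = _pool(pooled[epoch])
            d = odds_ratio_distance(gen, test)
            if best is None or d < best[0]:
                best = (d, {"init": init, "epoch": epoch, "distance": d,
                            "epoch_grid": grid, "n_inits": n_inits}, gen)
    return best[2], best[1]


@dataclass
class ExperimentResult:
    """Per-cell metrics and Table-style quantile summaries of an experiment.

    ``cells`` holds one record per (dataset, model, site count); summaries
    use type-7 (linear interpolation) quantiles across datasets.
    """

    cells: list = field(default_factory=list)
    site_counts: list = field(default_factory=list)
    model_types: list = field(default_factory=list)

    def summary(self, metric="utility"):
        """DataFrame of 'median (q05 - q95)' strings, models x site counts."""
        import pandas as pd
        rows = {}
        for model in self.model_types:
            row = {}
            for n_sites in self.site_counts:
                vals = [c[metric] for c in self.cells
                        if c["model"] == model and c["n_sites"] == n_sites]
                med, lo, hi = (np.quantile(vals, q, method="linear")
                               for q in (0.5, 0.05, 0.95))
                row[f"{n_sites} site{'s' if n_sites > 1 else ''}"] = \
                    f"{med:.3g} ({lo:.3g} - {hi:.3g})"
            rows[model] = row
        return pd.DataFrame(rows).T

    def quantiles(self, metric, model, n_sites):
        vals = [c[metric] for c in self.cells
                if c["model"] == model and c["n_sites"] == n_sites]
        return tuple(float(np.quantile(vals, q, method="linear"))
                     for q in (0.05, 0.5, 0.95))


def run_experiment(datasets, models, site_counts, sizes=(500, 100, 1000),
                   epoch_cap=30, n_inits=1, seed=None,
                   attack_thresholds=range(11)) -> ExperimentResult:
    """Full factorial benchmark over datasets x model types x site counts.

    ``models`` maps model-type names to unfitted generator estimators.  For
    each dataset, a train/test/validation split of the given ``sizes`` is
    drawn; per cell the hyperparameter search selects the pooled generated
    data, which is scored for utility d(x_gen, x_val), proportion of
    overfitting, and the membership attack.  The attack's non-member probes
    are the leading ``n_train`` validation samples (the attack wants probe
    sets of the training size).
    """
    n_train, n_test, n_val = sizes
    result = ExperimentResult(site_counts=list(site_counts),
                              model_types=list(models))
    for d_idx, data in enumerate(datasets):
        parts = split_train_test_val(data, n_train, n_test, n_val,
                                     seed=derive_seed(seed, d_idx))
        attack_probes = (parts.validation.take_rows(np.arange(n_train))
                         if n_val >= n_train else parts.test)
        for model_name, est in models.items():
            for n_sites in site_counts:
                sites = split_sites(parts.train, n_sites)
                cell_seed = derive_seed(seed, d_idx,
                                        list(models).index(model_name), n_sites)
                try:
                    gen, record = hyperparameter_search(
                        sites, parts.test, est, epoch_cap=epoch_cap,
                        n_inits=n_inits, seed=cell_seed)
                except Exception as err:
                    raise RuntimeError(
                        f"experiment cell (dataset {d_idx}, model {model_name}, "
                        f"{n_sites} sites) failed: {err}") from err
                attack = membership_attack(parts.train, attack_probes, gen,
                                           thresholds=attack_thresholds)
                result.cells.append({
                    "dataset": d_idx, "model": model_name, "n_sites": n_sites,
                    "utility": odds_ratio_distance(gen, parts.validation),
                    "overfitting": overfitting_proportion(
                        gen, parts.train, parts.validation),
                    "attack": attack, "selection": record,
                })
    return result
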