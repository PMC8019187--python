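"""Binary genotype matrices: the container and its I/O, filtering and splitting.

A :class:`BinaryDataset` is a samples x variables matrix of {0, 1} with
sample ids and variable names.  Rows are haploid chromosomes (or patients),
columns are SNP minor-allele indicators.  Every stage of the package --
simulation, model fitting, sampling, metrics -- consumes and produces this
one container, always with samples as rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinaryDataset",
    "SplitResult",
    "read_matrix",
    "write_matrix",
    "maf_filter",
    "select_locus",
    "split_train_test_val",
]


class FormatError(ValueError):
    """A file's contents violate the expected on-disk format."""


@dataclass
class BinaryDataset:
    """Samples x variables matrix of {0, 1} with names.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
        Entries must be exactly 0 or 1; stored as ``uint8``.
    sample_ids : list of str
        One per row, no duplicates.
    variable_names : list of str
        One per column, no duplicates.
    """

    values: np.ndarray
    sample_ids: list = field(default=None)
    variable_names: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at row {bad[0]}, column {bad[1]}: "
                f"{self.values[bad[0], bad[1]]!r}"
            )
        self.values = self.values.astype(np.uint8)
        n, k = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(n)]
        if self.variable_names is None:
            self.variable_names = [f"var{j}" for j in range(k)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.variable_names) != k:
            raise ValueError(
                f"{len(self.variable_names)} variable names for {k} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.variable_names)) != k:
            raise ValueError("duplicate variable names")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinaryDataset":
        return cls(
            frame.to_numpy(),
            sample_ids=list(frame.index.astype(str)),
            variable_names=list(frame.columns.astype(str)),
        )

    def take_rows(self, indices, ids=None) -> "BinaryDataset":
        indices = np.asarray(indices, dtype=int)
        return BinaryDataset(
            self.values[indices],
            sample_ids=[self.sample_ids[i] for i in indices] if ids is None else ids,
            variable_names=list(self.variable_names),
        )

    def __eq__(self, other):
        if not isinstance(other, BinaryDataset):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.sample_ids == other.sample_ids
            and self.variable_names == other.variable_names
        )


@dataclass
class SplitResult:
    """Disjoint train/test/validation partitions of one dataset."""

    train: BinaryDataset
    test: BinaryDataset
    validation: BinaryDataset


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_matrix(path, format="delimited", delimiter=None, legend=None) -> BinaryDataset:
    """Read a binary matrix from disk.

    ``delimited``: header row of variable names, one sample per row, optional
    leading ``sample_id`` column; delimiter sniffed unless given.

    ``impute_hap``: IMPUTE-style .hap panel, whitespace-separated {0,1} with
    one SNP per row and one chromosome per column; transposed on read so the
    result has chromosomes (samples) as rows.  An optional ``legend`` file
    (header ``id position a0 a1``) supplies variable names.
    """
    path = Path(path)
    if format == "delimited":
        sep = delimiter or _sniff_delimiter(path)
        frame = pd.read_csv(path, sep=sep, dtype=str)
        if frame.columns[0] == "sample_id":
            frame = frame.set_index("sample_id")
        else:
            frame.index = pd.Index([f"sample{i}" for i in range(len(frame))])
        values = np.empty(frame.shape, dtype=np.uint8)
        for j, col in enumerate(frame.columns):
            cells = frame[col].to_numpy()
            ok = np.isin(cells, ("0", "1"))
            if not ok.all():
                i = int(np.argmin(ok))
                raise FormatError(
                    f"non-binary cell {cells[i]!r} at row {i}, column {col!r} in {path}"
                )
            values[:, j] = cells == "1"
        return BinaryDataset(
            values,
            sample_ids=list(frame.index.astype(str)),
            variable_names=list(frame.columns.astype(str)),
        )
    if format == "impute_hap":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                cells = line.split()
                if not cells:
                    continue
                if any(c not in ("0", "1") for c in cells):
                    j = next(k for k, c in enumerate(cells) if c not in ("0", "1"))
                    raise FormatError(
                        f"non-binary cell {cells[j]!r} at SNP row {i}, column {j} in {path}"
                    )
                rows.append([int(c) for c in cells])
        if not rows:
            raise FormatError(f"empty haplotype file {path}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"ragged rows in {path}: widths {sorted(widths)}")
        hap = np.array(rows, dtype=np.uint8)  # SNPs x chromosomes
        names = None
        if legend is not None:
            leg = pd.read_csv(legend, sep=r"\s+")
            if len(leg) != hap.shape[0]:
                raise FormatError(
                    f"legend has {len(leg)} rows for {hap.shape[0]} SNPs"
                )
            names = list(leg["id"].astype(str))
        return BinaryDataset(
            hap.T,
            sample_ids=[f"chrom{i}" for i in range(hap.shape[1])],
            variable_names=names or [f"snp{i}" for i in range(hap.shape[0])],
        )
    raise ValueError(f"unknown format {format!r}")


def write_matrix(dataset: BinaryDataset, path, delimiter=",") -> None:
    """Write the delimited format; ``read_matrix`` reproduces the input exactly."""
    frame = dataset.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=delimiter)


def minor_allele_frequencies(dataset: BinaryDataset) -> np.ndarray:
    f = dataset.values.mean(axis=0)
    return np.minimum(f, 1.0 - f)


def maf_filter(dataset: BinaryDataset, min_maf: float) -> BinaryDataset:
    """Drop variants whose minor allele frequency is strictly below ``min_maf``.

    The MAF of a column with allele-1 frequency f is min(f, 1-f).  A column
    with MAF exactly equal to the threshold is kept.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    if dataset.n_samples == 0:
        raise ValueError("cannot compute allele frequencies of an empty dataset")
    keep = np.flatnonzero(minor_allele_frequencies(dataset) >= min_maf)
    return BinaryDataset(
        dataset.values[:, keep],
        sample_ids=list(dataset.sample_ids),
        variable_names=[dataset.variable_names[j] for j in keep],
    )


def select_locus(dataset: BinaryDataset, start_index: int, width: int) -> BinaryDataset:
    """Extract a contiguous block of ``width`` variants starting at ``start_index`` (0-based)."""
    if width <= 0:
        raise IndexError(f"width must be positive, got {width}")
    if start_index < 0 or start_index + width > dataset.n_variables:
        raise IndexError(
            f"locus [{start_index}, {start_index + width}) out of range for "
            f"{dataset.n_variables} variables"
        )
    sl = slice(start_index, start_index + width)
    return BinaryDataset(
        dataset.values[:, sl],
        sample_ids=list(dataset.sample_ids),
        variable_names=dataset.variable_names[sl],
    )


def split_train_test_val(
    dataset: BinaryDataset, n_train: int, n_test: int, n_val: int, seed: int
) -> SplitResult:
    """Draw three disjoint uniformly random subsamples of the stated sizes."""
    need = n_train + n_test + n_val
    if need > dataset.n_samples:
        raise ValueError(
            f"split needs {need} samples but dataset has {dataset.n_samples}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_samples)
    return SplitResult(
        train=dataset.take_rows(perm[:n_train]),
        test=dataset.take_rows(perm[n_train : n_train + n_test]),
        validation=dataset.take_rows(perm[n_train + n_test : need]),
    )
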