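"""Omics data containers and preprocessing.

A multi-omics dataset is a collection of *blocks*: real-valued sample ×
variable matrices of one measurement type each (copy-number variation, DNA
methylation, microRNA expression, ...) plus a *response* block (gene
expression), all profiled on the same samples.  :class:`OmicsBlock` is the
atomic matrix-with-identifiers unit; :class:`MultiBlockDataset` aligns the
input blocks with the response block.  :func:`preprocess` applies the
standard pipeline used before model fitting: a coefficient-of-variation
filter to drop near-constant variables, column mean-centering, and optional
unit-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateInputError, OverFilteredBlockError

#: means with absolute value below this bypass the sigma/|mu| ratio entirely
NEAR_ZERO_MEAN = 1e-12


@dataclass
class OmicsBlock:
    """One named sample × variable matrix with identifiers.

    Parameters
    ----------
    name:
        Short label for the omics type, e.g. ``"CNV"``.
    values:
        Real matrix of shape ``(n_samples, n_variables)``.
    sample_ids:
        Unique row labels, length ``n_samples``.
    variable_ids:
        Unique column labels, length ``n_variables``.
    """

    name: str
    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.variable_ids = list(self.variable_ids)
        if self.values.ndim != 2:
            raise DegenerateInputError(f"block {self.name!r}: values must be 2-D")
        k, n = self.values.shape
        if k != len(self.sample_ids):
            raise AlignmentError(
                f"block {self.name!r}: {k} rows but {len(self.sample_ids)} sample ids"
            )
        if n != len(self.variable_ids):
            raise AlignmentError(
                f"block {self.name!r}: {n} columns but {len(self.variable_ids)} variable ids"
            )
        for label, ids in (("sample", self.sample_ids), ("variable", self.variable_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise AlignmentError(f"block {self.name!r}: duplicate {label} id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DegenerateInputError(
                f"block {self.name!r}: non-finite value at sample "
                f"{self.sample_ids[r]!r}, variable {self.variable_ids[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str) -> "OmicsBlock":
        return cls(
            name=name,
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            variable_ids=[str(c) for c in frame.columns],
        )

    def take_samples(self, indices: Sequence[int]) -> "OmicsBlock":
        idx = np.asarray(indices, dtype=int)
        return OmicsBlock(
            name=self.name,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            variable_ids=list(self.variable_ids),
        )

    def take_variables(self, indices: Sequence[int]) -> "OmicsBlock":
        idx = np.asarray(indices, dtype=int)
        return OmicsBlock(
            name=self.name,
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            variable_ids=[self.variable_ids[i] for i in idx],
        )

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(
            self.name, self.values.copy(), list(self.sample_ids), list(self.variable_ids)
        )


@dataclass
class MultiBlockDataset:
    """Aligned input blocks X_1..X_R plus one response block Y.

    Every block (inputs and response) must carry identical ``sample_ids`` in
    identical order.  ``preprocessing_record`` accumulates a human-readable
    description of each preprocessing step applied.
    """

    input_blocks: list[OmicsBlock]
    response_block: OmicsBlock
    preprocessing_record: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.input_blocks) < 1:
            raise DegenerateInputError("at least one input block is required")
        ref = self.response_block.sample_ids
        for block in self.input_blocks:
            if block.sample_ids != ref:
                raise AlignmentError(
                    f"block {block.name!r} sample ids do not match the response block"
                )
        names = [b.name for b in self.input_blocks] + [self.response_block.name]
        if len(set(names)) != len(names):
            raise AlignmentError(f"duplicate block names in {names}")
        for block in self.all_blocks():
            if block.n_variables < 2:
                raise DegenerateInputError(
                    f"block {block.name!r} has fewer than 2 variables"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.response_block.n_samples

    @property
    def n_blocks(self) -> int:
        return len(self.input_blocks)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.response_block.sample_ids)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.input_blocks]

    def all_blocks(self) -> list[OmicsBlock]:
        return [*self.input_blocks, self.response_block]

    def block(self, name: str) -> OmicsBlock:
        for b in self.all_blocks():
            if b.name == name:
                return b
        raise KeyError(name)

    def take_samples(self, indices: Sequence[int]) -> "MultiBlockDataset":
        return MultiBlockDataset(
            input_blocks=[b.take_samples(indices) for b in self.input_blocks],
            response_block=self.response_block.take_samples(indices),
            preprocessing_record=list(self.preprocessing_record),
        )

    def copy(self) -> "MultiBlockDataset":
        return MultiBlockDataset(
            input_blocks=[b.copy() for b in self.input_blocks],
            response_block=self.response_block.copy(),
            preprocessing_record=list(self.preprocessing_record),
        )


def _cv_filter_mask(values: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of columns that *survive* the variation filter.

    A column is dropped when its coefficient of variation sigma/|mu| falls
    below ``threshold``.  Columns whose mean is numerically zero bypass the
    unstable ratio and are kept unless their standard deviation is also
    (proportionally) zero.
    """
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)  # population sd; only relative size matters here
    near_zero = np.abs(mu) < NEAR_ZERO_MEAN
    keep = np.empty(values.shape[1], dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sigma / np.abs(mu)
    keep[~near_zero] = cv[~near_zero] >= threshold
    keep[near_zero] = sigma[near_zero] >= threshold * NEAR_ZERO_MEAN
    return keep


def preprocess(
    dataset: MultiBlockDataset,
    scale: bool = True,
    cv_filter_threshold: float = 0.1,
) -> MultiBlockDataset:
    """Filter low-variation variables, then center (and optionally scale).

    Parameters
    ----------
    dataset:
        Raw dataset; all blocks must already share sample identifiers.
    scale:
        If true (default), divide each surviving column by its standard
        deviation after centering, so blocks measured in different units
        contribute comparably to covariances.  Columns with zero variance are
        left centered (all-zero) rather than divided by zero.
    cv_filter_threshold:
        Minimum coefficient of variation sigma/|mu| a variable must show to be
        retained.  ``0`` disables the filter.

    Returns
    -------
    MultiBlockDataset
        New dataset whose columns all have mean 0 (and, with ``scale``,
        standard deviation 1 where nonconstant), with the applied steps
        appended to ``preprocessing_record``.
    """
    if cv_filter_threshold < 0:
        raise OverFilteredBlockError("cv_filter_threshold must be >= 0")

    new_blocks: list[OmicsBlock] = []
    record: list[dict] = list(dataset.preprocessing_record)
    for block in dataset.all_blocks():
        keep = _cv_filter_mask(block.values, cv_filter_threshold)
        removed = [v for v, k in zip(block.variable_ids, keep) if not k]
        if keep.sum() < 2:
            raise OverFilteredBlockError(
                f"over-filtered block {block.name!r}: only {int(keep.sum())} "
                f"variable(s) survive the variation filter at threshold "
                f"{cv_filter_threshold}"
            )
        values = block.values[:, keep]
        values = values - values.mean(axis=0)
        if scale:
            sd = values.std(axis=0)
            values = values / np.where(sd > 0, sd, 1.0)
        new_blocks.append(
            OmicsBlock(
                name=block.name,
                values=values,
                sample_ids=list(block.sample_ids),
                variable_ids=[v for v, k in zip(block.variable_ids, keep) if k],
            )
        )
        record.append(
            {
                "block": block.name,
                "cv_filter_threshold": cv_filter_threshold,
                "n_removed": len(removed),
                "removed": removed if len(removed) <= 50 else removed[:50] + ["..."],
                "centered": True,
                "scaled": bool(scale),
            }
        )
    return MultiBlockDataset(
        input_blocks=new_blocks[:-1],
        response_block=new_blocks[-1],
        preprocessing_record=record,
    )


def assert_centered(dataset: MultiBlockDataset, tol: float = 1e-6) -> None:
    """Raise if any column mean departs from zero by more than ``tol``."""
    for block in dataset.all_blocks():
        worst = float(np.abs(block.values.mean(axis=0)).max()) if block.n_variables else 0.0
        if worst > tol:
            raise DegenerateInputError(
                f"block {block.name!r} is not centered (max |column mean| = {worst:.3g}); "
                "run preprocess() first"
            )
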