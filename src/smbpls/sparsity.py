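"""Lasso soft thresholding and the degree-of-sparsity machinery.

The sparse model constrains each loading vector to a given *degree of
sparsity* — the number of nonzero entries it may carry.  Under a lasso
penalty the constrained maximizer is obtained by soft thresholding, and
requesting exactly ``d`` survivors is equivalent to thresholding at the
``(d+1)``-th largest absolute value of the pre-threshold vector (an order
statistic).  That equivalence is what lets the tuning layer search over
integer degrees instead of continuous penalty weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .exceptions import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .blocks import MultiBlockDataset


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise ``sign(x) * max(|x| - lam, 0)``.

    The proximal operator of the lasso penalty; shrinks every entry toward
    zero by ``lam`` and zeroes those that cross it.
    """
    if lam < 0:
        raise ParameterError(f"soft threshold lambda must be >= 0, got {lam}")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def degree_to_lambda(x: np.ndarray, degree: int) -> float:
    """Penalty weight that leaves ``degree`` nonzero entries after thresholding.

    Returns the ``(degree+1)``-th largest absolute value of ``x`` (0 when
    ``degree`` equals the vector length).  When the degree-th and
    (degree+1)-th order statistics are distinct, ``soft_threshold(x, lam)``
    then has exactly ``degree`` nonzeros; exact ties are resolved by
    :func:`threshold_to_degree`.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 1 <= degree <= n:
        raise ParameterError(f"degree must be in [1, {n}], got {degree}")
    if degree == n:
        return 0.0
    a = np.sort(np.abs(x))[::-1]
    return float(a[degree])


def threshold_to_degree(x: np.ndarray, degree: int) -> np.ndarray:
    """Soft threshold ``x`` so that at most ``degree`` entries survive.

    Generic inputs (distinct absolute values) yield exactly ``degree``
    nonzeros.  Entries tied exactly at the threshold would all shrink to
    zero; to keep runs deterministic the tied entries with the smallest
    indices are retained (at magnitude equal to the threshold) until the
    requested degree is met.
    """
    x = np.asarray(x, dtype=float)
    lam = degree_to_lambda(x, degree)
    out = soft_threshold(x, lam)
    if lam > 0:
        nnz = int(np.count_nonzero(out))
        if nnz < degree:
            tied = np.flatnonzero(np.abs(x) == lam)
            for idx in tied[: degree - nnz]:
                out[idx] = np.sign(x[idx]) * lam
    return out


@dataclass(frozen=True)
class SparsityConfig:
    """Degrees of sparsity for one sparse multi-block PLS component.

    Parameters
    ----------
    loading_degrees:
        One positive integer per input block: the number of nonzero entries
        allowed in that block's loading vector w_i.
    response_degree:
        Nonzero entries allowed in the response loading q.
    sample_degree:
        Nonzero entries allowed in the latent variables t_i and u, i.e. the
        number of samples a module may select.  ``None`` disables sample
        selection (all samples participate).
    """

    loading_degrees: tuple[int, ...]
    response_degree: int
    sample_degree: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "loading_degrees", tuple(int(d) for d in self.loading_degrees))
        for d in self.loading_degrees:
            if d < 1:
                raise ParameterError(f"loading degree must be >= 1, got {d}")
        if self.response_degree < 1:
            raise ParameterError(f"response degree must be >= 1, got {self.response_degree}")
        if self.sample_degree is not None and self.sample_degree < 1:
            raise ParameterError(f"sample degree must be >= 1, got {self.sample_degree}")

    @property
    def total_degree(self) -> int:
        return (
            sum(self.loading_degrees)
            + self.response_degree
            + (self.sample_degree or 0)
        )

    def sort_key(self) -> tuple:
        """Tie-break key: total degree first, then lexicographic degrees."""
        return (
            self.total_degree,
            self.loading_degrees,
            self.response_degree,
            self.sample_degree or 0,
        )

    def validate(self, dataset: "MultiBlockDataset") -> None:
        """Check degrees against the shapes of ``dataset``."""
        if len(self.loading_degrees) != dataset.n_blocks:
            raise ParameterError(
                f"{len(self.loading_degrees)} loading degrees for "
                f"{dataset.n_blocks} input blocks"
            )
        for d, block in zip(self.loading_degrees, dataset.input_blocks):
            if d > block.n_variables:
                raise ParameterError(
                    f"loading degree {d} exceeds the {block.n_variables} "
                    f"variables of block {block.name!r}"
                )
        if self.response_degree > dataset.response_block.n_variables:
            raise ParameterError(
                f"response degree {self.response_degree} exceeds the "
                f"{dataset.response_block.n_variables} response variables"
            )
        if self.sample_degree is not None and self.sample_degree > dataset.n_samples:
            raise ParameterError(
                f"sample degree {self.sample_degree} exceeds the "
                f"{dataset.n_samples} samples"
            )

    @classmethod
    def full(cls, dataset: "MultiBlockDataset") -> "SparsityConfig":
        """Penalty-free configuration: every degree equals its dimension."""
        return cls(
            loading_degrees=tuple(b.n_variables for b in dataset.input_blocks),
            response_degree=dataset.response_block.n_variables,
            sample_degree=None,
        )

    def to_dict(self) -> dict:
        return {
            "loading_degrees": list(self.loading_degrees),
            "response_degree": self.response_degree,
            "sample_degree": self.sample_degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparsityConfig":
        return cls(
            loading_degrees=tuple(d["loading_degrees"]),
            response_degree=int(d["response_degree"]),
            sample_degree=None if d.get("sample_degree") in (None, "off") else int(d["sample_degree"]),
        )
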