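"""Multi-block PLS estimators (classic and sparse).

The model: given centered input blocks X_1..X_R (samples × variables) and a
centered response block Y, find unit-norm block loadings w_i, block weights
b and a unit-norm response loading q such that the covariance between the
super score t = [X_1 w_1 ... X_R w_R] b and the response score u = Y q is
maximal.  The classic estimator solves this with the block-scores iterative
cycle (regress u on each block, combine the block scores into a super block
T, run a PLS cycle between T and Y).  The sparse estimator adds lasso
soft-thresholding of every loading — and optionally of the latent variables
themselves, which selects samples — so the nonzero supports of the
converged vectors delineate a multi-dimensional regulatory module.
Successive modules are extracted by deflating the fitted signal out of
every block and refitting.

Both estimators follow scikit-learn conventions (``fit``, ``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
accept either a :class:`~smbpls.blocks.MultiBlockDataset` or a plain list
of arrays plus a response array.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .blocks import MultiBlockDataset, OmicsBlock, assert_centered
from .exceptions import DegenerateInputError, EmptySupportError, ParameterError
from .modules import MDRM
from .sparsity import SparsityConfig, threshold_to_degree
from .stats import objective_value

logger = logging.getLogger(__name__)

_TINY = 1e-12


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = float(np.linalg.norm(v))
    if norm <= _TINY:
        raise DegenerateInputError(f"{what} is numerically zero; cannot normalize")
    return v / norm


@dataclass
class ComponentFit:
    """One converged (s)MBPLS component.

    Vectors follow the field's standard notation: block loadings ``w_i``
    (unit norm), block scores ``t_i``, block weights ``b`` (unit norm),
    super score ``t = T b``, response loading ``q`` (unit norm), response
    score ``u = Y q``.  ``objective`` is the sample covariance of t and u.
    """

    block_names: list[str]
    block_loadings: list[np.ndarray]
    block_scores: list[np.ndarray]
    block_weights: np.ndarray
    super_score: np.ndarray
    response_loading: np.ndarray
    response_score: np.ndarray
    objective: float
    n_iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)
    sparsity: Optional[SparsityConfig] = None

    @property
    def sample_selection_active(self) -> bool:
        return self.sparsity is not None and self.sparsity.sample_degree is not None

    def selected_sample_indices(self) -> np.ndarray:
        """Module sample support: joint nonzero support of t and u when
        sample selection is active, every sample otherwise."""
        if not self.sample_selection_active:
            return np.arange(self.super_score.size)
        return np.flatnonzero((self.super_score != 0) & (self.response_score != 0))


@dataclass
class ExtractionResult:
    """Ordered modules from sequential extraction, with their fits."""

    modules: list[MDRM]
    fits: list[ComponentFit]
    stop_reason: str  # "objective_floor" | "max_modules" | "degenerate"

    def __post_init__(self) -> None:
        if self.stop_reason not in ("objective_floor", "max_modules", "degenerate"):
            raise ParameterError(f"unknown stop reason {self.stop_reason!r}")

    @property
    def objectives(self) -> list[float]:
        return [f.objective for f in self.fits]


def _coerce_dataset(X, y=None) -> MultiBlockDataset:
    """Accept a MultiBlockDataset, or arrays, and return a dataset.

    Arrays get synthetic identifiers (``s0, s1, ...`` / ``X1_0, ...``) so
    the module bookkeeping downstream always has ids to work with.
    """
    if isinstance(X, MultiBlockDataset):
        if y is not None:
            raise ParameterError("y must be None when X is a MultiBlockDataset")
        return X
    if isinstance(X, np.ndarray):
        X = [X]
    if y is None:
        raise ParameterError("y (the response matrix) is required with array input")
    Xs = [np.asarray(x, dtype=float) for x in X]
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    k = Y.shape[0]
    sample_ids = [f"s{i}" for i in range(k)]
    blocks = [
        OmicsBlock(f"X{i + 1}", x, sample_ids, [f"X{i + 1}_{j}" for j in range(x.shape[1])])
        for i, x in enumerate(Xs)
    ]
    response = OmicsBlock("Y", Y, sample_ids, [f"Y_{j}" for j in range(Y.shape[1])])
    return MultiBlockDataset(input_blocks=blocks, response_block=response)


def _pls_cycle(
    dataset: MultiBlockDataset,
    config: Optional[SparsityConfig],
    tol: float,
    max_iter: int,
    u0: Optional[np.ndarray] = None,
) -> ComponentFit:
    """Run the block-scores (s)MBPLS cycle to convergence of t.

    ``config=None`` runs the classic penalty-free cycle.  With a config, each
    regression step is soft-thresholded at the penalty induced by the
    requested degree of sparsity (the order-statistic lambda, recomputed at
    every iteration from the current pre-threshold vector).
    """
    if tol <= 0 or max_iter < 1:
        raise ParameterError("tol must be > 0 and max_iter >= 1")
    if config is not None:
        config.validate(dataset)
    Xs = [b.values for b in dataset.input_blocks]
    Y = dataset.response_block.values
    names = dataset.block_names
    k = Y.shape[0]
    if k < 2:
        raise DegenerateInputError("at least 2 samples are required")

    s_sample = config.sample_degree if config is not None else None

    if u0 is None:
        # deterministic start: the response column with maximal variance
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    else:
        u = np.asarray(u0, dtype=float).copy()
    if np.linalg.norm(u) <= _TINY:
        raise DegenerateInputError("initial response score is zero")

    t_old: Optional[np.ndarray] = None
    history: list[float] = []
    converged = False
    n_iter = 0
    ws: list[np.ndarray] = []
    ts: list[np.ndarray] = []
    b = np.array([])
    t = np.array([])
    q = np.array([])

    for n_iter in range(1, max_iter + 1):
        ws = []
        for i, (X, name) in enumerate(zip(Xs, names)):
            z = X.T @ u
            if config is not None:
                z = threshold_to_degree(z, config.loading_degrees[i])
                if not np.any(z):
                    raise EmptySupportError(
                        f"empty support: loading of block {name!r} shrank to zero "
                        f"at degree {config.loading_degrees[i]}"
                    )
            ws.append(_unit(z, f"loading of block {name!r}"))
        ts = [X @ w for X, w in zip(Xs, ws)]
        if s_sample is not None:
            ts = [threshold_to_degree(t_i, s_sample) for t_i in ts]
        T = np.column_stack(ts)
        b = _unit(T.T @ u, "block-weight vector b")
        t = T @ b
        zq = Y.T @ t
        if config is not None:
            zq = threshold_to_degree(zq, config.response_degree)
            if not np.any(zq):
                raise EmptySupportError(
                    f"empty support: response loading shrank to zero at degree "
                    f"{config.response_degree}"
                )
        q = _unit(zq, "response loading q")
        u = Y @ q
        if s_sample is not None:
            u = threshold_to_degree(u, s_sample)
            if not np.any(u):
                raise DegenerateInputError(
                    "response score u shrank to zero under sample selection"
                )
        history.append(objective_value(t, u))
        if t_old is not None:
            delta = np.linalg.norm(t - t_old) / max(np.linalg.norm(t_old), _TINY)
            if delta < tol:
                converged = True
                break
        t_old = t

    if not converged:
        msg = f"(s)MBPLS did not converge within {max_iter} iterations"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    # canonical sign: global flip of (w_i, t_i, t, q, u) — which leaves b and
    # the objective unchanged — so the largest-|entry| of q is positive
    if q[int(np.argmax(np.abs(q)))] < 0:
        ws = [-w for w in ws]
        ts = [-t_i for t_i in ts]
        t, q, u = -t, -q, -u

    return ComponentFit(
        block_names=list(names),
        block_loadings=ws,
        block_scores=ts,
        block_weights=b,
        super_score=t,
        response_loading=q,
        response_score=u,
        objective=objective_value(t, u),
        n_iterations=n_iter,
        converged=converged,
        objective_history=history,
        sparsity=config,
    )


def deflate(dataset: MultiBlockDataset, fit: ComponentFit) -> MultiBlockDataset:
    """Remove a fitted component's signal from every block.

    Super-score projection deflation: each block (inputs and response) has
    its projection onto the super score t subtracted,
    ``X <- X - t (X^T t)^T / (t^T t)``, and the result is re-centered so
    every column mean returns to zero.  Successive super scores are thereby
    orthogonal to the deflated blocks.
    """
    t = fit.super_score
    tt = float(t @ t)
    if tt <= _TINY:
        raise DegenerateInputError("cannot deflate with a zero super score")
    new_blocks = []
    for block in dataset.all_blocks():
        p = block.values.T @ t / tt
        values = block.values - np.outer(t, p)
        values = values - values.mean(axis=0)
        new_blocks.append(
            OmicsBlock(block.name, values, list(block.sample_ids), list(block.variable_ids))
        )
    return MultiBlockDataset(
        input_blocks=new_blocks[:-1],
        response_block=new_blocks[-1],
        preprocessing_record=[*dataset.preprocessing_record, {"deflated": True}],
    )


def module_from_fit(
    fit: ComponentFit, dataset: MultiBlockDataset, order: int = 0
) -> MDRM:
    """Convert a converged component into an MDRM via its nonzero supports."""
    sel_samples = fit.selected_sample_indices()
    if sel_samples.size == 0:
        raise DegenerateInputError("component selects no samples")
    sample_ids = [dataset.sample_ids[i] for i in sel_samples]
    selected_variables = {
        block.name: [block.variable_ids[j] for j in np.flatnonzero(w)]
        for block, w in zip(dataset.input_blocks, fit.block_loadings)
    }
    response_ids = [
        dataset.response_block.variable_ids[j]
        for j in np.flatnonzero(fit.response_loading)
    ]
    return MDRM(
        sample_ids=sample_ids,
        selected_variables=selected_variables,
        selected_response=response_ids,
        block_weights=fit.block_weights.copy(),
        objective=fit.objective,
        provenance={
            "order": order,
            "sparsity": fit.sparsity.to_dict() if fit.sparsity else "full",
            "converged": fit.converged,
            "n_iterations": fit.n_iterations,
        },
    )


class MBPLS(BaseEstimator):
    """Classic (non-sparse) multi-block partial least squares, one component.

    Parameters
    ----------
    tol:
        Relative convergence tolerance on the super score t.
    max_iter:
        Iteration cap; non-convergence yields ``converged_ = False`` plus a
        warning rather than an error.

    Attributes
    ----------
    fit_ : ComponentFit
        The converged component.
    block_loadings_, block_scores_, block_weights_, super_score_,
    response_loading_, response_score_, objective_, n_iter_, converged_ :
        Convenience views of the same fit.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def _fit_component(self, dataset: MultiBlockDataset) -> ComponentFit:
        assert_centered(dataset)
        return _pls_cycle(dataset, None, self.tol, self.max_iter)

    def fit(self, X, y=None):
        dataset = _coerce_dataset(X, y)
        self.dataset_ = dataset
        self.fit_ = self._fit_component(dataset)
        self._expose(self.fit_)
        return self

    def _expose(self, fit: ComponentFit) -> None:
        self.block_loadings_ = fit.block_loadings
        self.block_scores_ = fit.block_scores
        self.block_weights_ = fit.block_weights
        self.super_score_ = fit.super_score
        self.response_loading_ = fit.response_loading
        self.response_score_ = fit.response_score
        self.objective_ = fit.objective
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged

    def transform(self, X, y=None) -> np.ndarray:
        """Super scores of new rows under the fitted loadings (column vector)."""
        check_is_fitted(self, "fit_")
        dataset = _coerce_dataset(X, y) if not isinstance(X, MultiBlockDataset) else X
        ts = [
            b.values @ w for b, w in zip(dataset.input_blocks, self.fit_.block_loadings)
        ]
        return (np.column_stack(ts) @ self.fit_.block_weights)[:, None]


class SparseMBPLS(MBPLS):
    """Sparse multi-block PLS with sequential module extraction.

    Each component is fitted by the soft-thresholded block-scores cycle,
    initialized at the classic MBPLS solution; its nonzero supports define a
    multi-dimensional regulatory module.  With ``max_modules > 1`` the
    fitted signal is deflated out of every block and extraction repeats
    until the module cap, an objective floor (relative to the first
    module), or a degenerate fit stops it.

    Parameters
    ----------
    loading_degrees:
        Nonzero entries allowed per input-block loading; ``None`` means full
        (no sparsity) in every block.
    response_degree:
        Nonzero entries allowed in the response loading; ``None`` means full.
    sample_degree:
        Samples a module may select; ``None`` disables sample selection.
    max_modules:
        Maximum number of modules to extract sequentially.
    objective_floor:
        Stop once a component's covariance objective falls below this
        fraction of the first module's objective.
    """

    def __init__(
        self,
        loading_degrees: Optional[Sequence[int]] = None,
        response_degree: Optional[int] = None,
        sample_degree: Optional[int] = None,
        max_modules: int = 1,
        objective_floor: float = 0.05,
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        super().__init__(tol=tol, max_iter=max_iter)
        self.loading_degrees = loading_degrees
        self.response_degree = response_degree
        self.sample_degree = sample_degree
        self.max_modules = max_modules
        self.objective_floor = objective_floor

    def _resolve_config(self, dataset: MultiBlockDataset) -> SparsityConfig:
        full = SparsityConfig.full(dataset)
        degrees = (
            tuple(int(d) for d in self.loading_degrees)
            if self.loading_degrees is not None
            else full.loading_degrees
        )
        resp = (
            int(self.response_degree)
            if self.response_degree is not None
            else full.response_degree
        )
        config = SparsityConfig(degrees, resp, self.sample_degree)
        config.validate(dataset)
        return config

    def _fit_component(self, dataset: MultiBlockDataset) -> ComponentFit:
        assert_centered(dataset)
        config = self._resolve_config(dataset)
        init = _pls_cycle(dataset, None, self.tol, self.max_iter)
        return _pls_cycle(dataset, config, self.tol, self.max_iter, u0=init.response_score)

    def fit(self, X, y=None):
        if self.max_modules < 1:
            raise ParameterError("max_modules must be >= 1")
        if not 0.0 < self.objective_floor < 1.0:
            raise ParameterError("objective_floor must lie in (0, 1)")
        dataset = _coerce_dataset(X, y)
        self.dataset_ = dataset

        modules: list[MDRM] = []
        fits: list[ComponentFit] = []
        stop_reason = "max_modules"
        current = dataset
        first_objective: Optional[float] = None
        for k in range(self.max_modules):
            try:
                fit = self._fit_component(current)
            except DegenerateInputError:
                if not fits:
                    raise
                stop_reason = "degenerate"
                break
            if first_objective is None:
                first_objective = fit.objective
            elif fit.objective < self.objective_floor * first_objective:
                stop_reason = "objective_floor"
                break
            fits.append(fit)
            modules.append(module_from_fit(fit, current, order=k))
            if k + 1 < self.max_modules:
                try:
                    current = deflate(current, fit)
                except DegenerateInputError:
                    stop_reason = "degenerate"
                    break

        self.result_ = ExtractionResult(modules=modules, fits=fits, stop_reason=stop_reason)
        self.modules_ = self.result_.modules
        self.fits_ = self.result_.fits
        self.stop_reason_ = self.result_.stop_reason
        self.fit_ = fits[0]
        self._expose(self.fit_)
        return self
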