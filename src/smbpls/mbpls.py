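"""Classic MBPLS: functional surface and the two-step baseline module.

The two-step baseline discovers a module by fitting the *non-sparse* MBPLS
component and then simply ranking variables (and optionally samples) by the
absolute values of their loadings (scores).  It serves as the negative
control in simulation comparisons: when a planted module's signal is
diluted in the global covariance, top-|loading| selection lands on noise.
"""

from __future__ import annotations

import numpy as np

from .blocks import MultiBlockDataset
from .estimators import MBPLS, ComponentFit
from .exceptions import ParameterError
from .modules import MDRM
from .sparsity import SparsityConfig


def mbpls_fit(
    dataset: MultiBlockDataset, tol: float = 1e-6, max_iter: int = 500
) -> ComponentFit:
    """First classic MBPLS component of a preprocessed (centered) dataset."""
    return MBPLS(tol=tol, max_iter=max_iter).fit(dataset).fit_


def _top_abs(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |values|, smallest index first among ties."""
    if not 1 <= k <= values.size:
        raise ParameterError(f"selection size {k} out of range [1, {values.size}]")
    order = np.argsort(-np.abs(values), kind="stable")
    return np.sort(order[:k])


def mbpls_topk_module(
    fit: ComponentFit, config: SparsityConfig, dataset: MultiBlockDataset
) -> MDRM:
    """Two-step baseline: form a module from the top-|loading| entries.

    Selects the ``s_i`` largest-|w_i| variables per block, the ``s_q``
    largest-|q| response variables, and — when ``sample_degree`` is set —
    the ``s_t`` largest-|t| samples (all samples otherwise).
    """
    config.validate(dataset)
    selected_variables = {
        block.name: [block.variable_ids[j] for j in _top_abs(w, d)]
        for block, w, d in zip(
            dataset.input_blocks, fit.block_loadings, config.loading_degrees
        )
    }
    response_ids = [
        dataset.response_block.variable_ids[j]
        for j in _top_abs(fit.response_loading, config.response_degree)
    ]
    if config.sample_degree is None:
        sample_ids = dataset.sample_ids
    else:
        sample_ids = [
            dataset.sample_ids[i]
            for i in _top_abs(fit.super_score, config.sample_degree)
        ]
    return MDRM(
        sample_ids=sample_ids,
        selected_variables=selected_variables,
        selected_response=response_ids,
        block_weights=fit.block_weights.copy(),
        objective=fit.objective,
        provenance={"method": "mbpls_topk", "sparsity": config.to_dict()},
    )
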