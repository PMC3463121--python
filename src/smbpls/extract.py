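"""Sparse component fitting and sequential module extraction (functional API).

Thin wrappers over :class:`~smbpls.estimators.SparseMBPLS`, plus the
single-merged-block sparse PLS baseline, which concatenates all input
blocks into one and maps the selected merged columns back to their
originating omics type for evaluation.
"""

from __future__ import annotations

from typing import Optional

from .blocks import MultiBlockDataset, OmicsBlock
from .estimators import (  # noqa: F401  (deflate/module_from_fit re-exported here)
    ComponentFit,
    ExtractionResult,
    SparseMBPLS,
    deflate,
    module_from_fit,
)
from .exceptions import ParameterError
from .modules import MDRM
from .sparsity import SparsityConfig

_MERGE_SEP = "::"


def smbpls_component(
    dataset: MultiBlockDataset,
    config: SparsityConfig,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ComponentFit:
    """One sparse MBPLS component (initialized at the classic MBPLS fit)."""
    est = SparseMBPLS(
        loading_degrees=config.loading_degrees,
        response_degree=config.response_degree,
        sample_degree=config.sample_degree,
        max_modules=1,
        tol=tol,
        max_iter=max_iter,
    )
    return est.fit(dataset).fit_


def extract_modules(
    dataset: MultiBlockDataset,
    config: SparsityConfig,
    max_modules: int = 100,
    objective_floor_fraction: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ExtractionResult:
    """Extract modules one by one with deflation between components."""
    est = SparseMBPLS(
        loading_degrees=config.loading_degrees,
        response_degree=config.response_degree,
        sample_degree=config.sample_degree,
        max_modules=max_modules,
        objective_floor=objective_floor_fraction,
        tol=tol,
        max_iter=max_iter,
    )
    return est.fit(dataset).result_


def merge_input_blocks(dataset: MultiBlockDataset) -> MultiBlockDataset:
    """Concatenate all input blocks into a single block named ``merged``.

    Merged variable ids are ``<block name>::<variable id>`` so selections can
    be mapped back to their source omics type.
    """
    import numpy as np

    values = np.hstack([b.values for b in dataset.input_blocks])
    variable_ids = [
        f"{b.name}{_MERGE_SEP}{v}" for b in dataset.input_blocks for v in b.variable_ids
    ]
    merged = OmicsBlock("merged", values, dataset.sample_ids, variable_ids)
    return MultiBlockDataset(
        input_blocks=[merged],
        response_block=dataset.response_block.copy(),
        preprocessing_record=[*dataset.preprocessing_record, {"merged_inputs": True}],
    )


def split_merged_id(merged_id: str) -> tuple[str, str]:
    """``"CNV::CNV_0001"`` -> ``("CNV", "CNV_0001")``."""
    block, sep, variable = merged_id.partition(_MERGE_SEP)
    if not sep:
        raise ParameterError(f"{merged_id!r} is not a merged variable id")
    return block, variable


def _unmerge_module(module: MDRM, block_names: list[str]) -> MDRM:
    selected: dict[str, list[str]] = {name: [] for name in block_names}
    for merged_id in module.selected_variables["merged"]:
        block, variable = split_merged_id(merged_id)
        if block not in selected:
            raise ParameterError(f"merged id {merged_id!r} maps to unknown block {block!r}")
        selected[block].append(variable)
    return MDRM(
        sample_ids=list(module.sample_ids),
        selected_variables=selected,
        selected_response=list(module.selected_response),
        block_weights=module.block_weights.copy(),
        objective=module.objective,
        provenance={**module.provenance, "merged_single_block": True},
    )


def spls_single_block(
    dataset: MultiBlockDataset,
    config: SparsityConfig,
    max_modules: int = 1,
    objective_floor_fraction: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ExtractionResult:
    """Single-merged-block sparse PLS baseline.

    All input blocks are horizontally concatenated and the same sparse
    machinery runs with R = 1; ``config`` may carry either one loading
    degree for the merged block or one per original block (these are then
    summed).  Selected merged columns are mapped back to their source block
    in the returned modules, so evaluation statistics such as
    ``dimensions_missing`` see the original omics dimensions.
    """
    merged = merge_input_blocks(dataset)
    if len(config.loading_degrees) == 1:
        total = config.loading_degrees[0]
    elif len(config.loading_degrees) == dataset.n_blocks:
        total = sum(config.loading_degrees)
    else:
        raise ParameterError(
            "config must carry one merged loading degree or one per input block"
        )
    merged_config = SparsityConfig(
        loading_degrees=(total,),
        response_degree=config.response_degree,
        sample_degree=config.sample_degree,
    )
    result = extract_modules(
        merged,
        merged_config,
        max_modules=max_modules,
        objective_floor_fraction=objective_floor_fraction,
        tol=tol,
        max_iter=max_iter,
    )
    modules = [_unmerge_module(m, dataset.block_names) for m in result.modules]
    return ExtractionResult(modules=modules, fits=result.fits, stop_reason=result.stop_reason)
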