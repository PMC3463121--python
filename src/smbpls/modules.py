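"""Regulatory-module objects and evaluation statistics.

A multi-dimensional regulatory module (MDRM) couples a subset of samples, a
subset of variables from each input omics block, and a subset of response
genes whose profiles co-vary across those samples.  This module provides the
:class:`MDRM` container plus the statistics used to evaluate discovered
modules: hypergeometric overlap significance between two modules (or a
module and a planted truth), counts of missing omics dimensions, recovery
scoring over simulation replicates, and the per-block latent-correlation
test used to rank block contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import DegenerateInputError, ParameterError
from .stats import correlation_pvalue

if TYPE_CHECKING:  # pragma: no cover
    from .estimators import ComponentFit, ExtractionResult
    from .simulate import SimulationTruth

SAMPLES_DIM = "samples"
RESPONSE_DIM = "response"


@dataclass
class MDRM:
    """A multi-dimensional regulatory module.

    Attributes
    ----------
    sample_ids:
        Samples the module spans.
    selected_variables:
        Per input block (keyed by block name), the selected variable ids.
        A key with an empty list marks an omics dimension the module missed.
    selected_response:
        Selected response (gene) ids; never empty.
    block_weights:
        The block-weight vector b of the generating fit (relative
        contribution of each omics layer to the covariance).
    objective:
        Covariance objective of the generating component.
    provenance:
        Free-form metadata: extraction order, degrees used, merged-block
        origin, etc.
    """

    sample_ids: list[str]
    selected_variables: dict[str, list[str]]
    selected_response: list[str]
    block_weights: np.ndarray
    objective: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.block_weights = np.asarray(self.block_weights, dtype=float)
        if len(self.sample_ids) < 1:
            raise DegenerateInputError("a module must select at least one sample")
        if len(self.selected_response) < 1:
            raise DegenerateInputError("a module must select at least one response variable")
        for label, ids in (
            ("sample", self.sample_ids),
            ("response", self.selected_response),
            *((f"block {k!r}", v) for k, v in self.selected_variables.items()),
        ):
            if len(set(ids)) != len(ids):
                raise DegenerateInputError(f"duplicate ids in {label} selection")

    def selection(self, dimension: str) -> list[str]:
        """Selected ids along one dimension name."""
        if dimension == SAMPLES_DIM:
            return list(self.sample_ids)
        if dimension == RESPONSE_DIM:
            return list(self.selected_response)
        if dimension in self.selected_variables:
            return list(self.selected_variables[dimension])
        raise ParameterError(f"unknown dimension {dimension!r}")

    def to_dict(self) -> dict:
        return {
            "samples": list(self.sample_ids),
            "variables": {k: list(v) for k, v in self.selected_variables.items()},
            "response": list(self.selected_response),
            "block_weights": [float(x) for x in self.block_weights],
            "objective": float(self.objective),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MDRM":
        return cls(
            sample_ids=list(d["samples"]),
            selected_variables={k: list(v) for k, v in d["variables"].items()},
            selected_response=list(d["response"]),
            block_weights=np.asarray(d["block_weights"], dtype=float),
            objective=float(d["objective"]),
            provenance=dict(d.get("provenance", {})),
        )


@dataclass
class OverlapResult:
    """Outcome of the per-dimension hypergeometric overlap test."""

    per_dimension_p: dict[str, float]
    n_significant_dimensions: int
    overall_significant: bool
    alpha: float
    family_size: int

    @property
    def corrected_p(self) -> dict[str, float]:
        return {k: min(1.0, p * self.family_size) for k, p in self.per_dimension_p.items()}


def hypergeom_overlap_p(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """Upper-tail probability of observing >= ``n_overlap`` shared elements.

    Two sets of sizes ``n_a`` and ``n_b`` drawn without replacement from a
    universe of ``n_universe`` elements share a hypergeometric number of
    elements; this returns ``P(X >= n_overlap)``.
    """
    if n_a > n_universe or n_b > n_universe:
        raise ParameterError("set larger than its universe")
    if n_overlap == 0:
        return 1.0
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


def overlap_test(
    a: MDRM,
    b: MDRM,
    universe_sizes: Mapping[str, int],
    alpha: float = 0.05,
    min_significant_dims: Optional[int] = None,
    family_size: Optional[int] = None,
) -> OverlapResult:
    """Hypergeometric overlap significance of two modules, per dimension.

    Parameters
    ----------
    a, b:
        Modules drawn from the same universes.
    universe_sizes:
        Mapping from dimension name (each input block name, ``"response"``,
        and optionally ``"samples"``) to the number of elements available in
        that dimension.
    alpha:
        Per-family significance level; Bonferroni-corrected across the
        compared dimensions.
    min_significant_dims:
        Number of dimensions that must be individually significant for
        ``overall_significant``.  Defaults to *all* compared dimensions (the
        strict rule used for truth recovery); module–module robustness
        screens conventionally use 3.
    family_size:
        Bonferroni family size; defaults to the number of compared
        dimensions.  Exposed so a genome-scale screen over many module pairs
        can correct for the full family.

    Notes
    -----
    The sample dimension is only compared when both modules select a proper
    subset of the samples; a module spanning every sample carries no sample
    selection signal.
    """
    pvals: dict[str, float] = {}
    for dim, n_universe in universe_sizes.items():
        set_a = set(a.selection(dim))
        set_b = set(b.selection(dim))
        if dim == SAMPLES_DIM and (
            len(set_a) in (0, n_universe) or len(set_b) in (0, n_universe)
        ):
            continue
        if not set_a or not set_b:
            pvals[dim] = 1.0
            continue
        pvals[dim] = hypergeom_overlap_p(
            n_universe, len(set_a), len(set_b), len(set_a & set_b)
        )
    if not pvals:
        raise ParameterError("no comparable dimensions between the two modules")
    family = family_size if family_size is not None else len(pvals)
    n_sig = sum(1 for p in pvals.values() if p * family <= alpha)
    need = min_significant_dims if min_significant_dims is not None else len(pvals)
    return OverlapResult(
        per_dimension_p=pvals,
        n_significant_dimensions=n_sig,
        overall_significant=n_sig >= need,
        alpha=alpha,
        family_size=family,
    )


def dimensions_missing(module: MDRM, expected_dimensions: Sequence[str]) -> int:
    """Number of expected input omics dimensions with zero selected variables."""
    missing = 0
    for name in expected_dimensions:
        if name not in module.selected_variables:
            raise ParameterError(f"module has no record for block {name!r}")
        if len(module.selected_variables[name]) == 0:
            missing += 1
    return missing


def _jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class RecoveryReport:
    """Recovery scoring of extracted modules against planted truth."""

    table: pd.DataFrame
    recovered_fraction: float
    mean_dimensions_missing: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def recovery_report(
    results: "ExtractionResult | Sequence[ExtractionResult]",
    truths: "SimulationTruth | Sequence[SimulationTruth]",
    alpha: float = 0.05,
) -> RecoveryReport:
    """Score extraction results against the planted modules that generated them.

    Accepts a single (result, truth) pair or matched sequences of them (one
    per simulation replicate).  For every planted module the best-matching
    extracted module (highest mean per-dimension Jaccard) is scored:
    ``recovered`` means a significant hypergeometric overlap in *every*
    compared dimension at Bonferroni-corrected ``alpha``.  Aggregate
    fractions are means of the per-module indicators.
    """
    from .estimators import ExtractionResult  # local import to avoid a cycle

    if isinstance(results, ExtractionResult):
        results = [results]
        truths = [truths]  # type: ignore[list-item]
    if len(results) != len(truths):  # type: ignore[arg-type]
        raise ParameterError("results and truths must have equal length")

    rows = []
    for rep, (result, truth) in enumerate(zip(results, truths)):  # type: ignore[arg-type]
        universe = truth.universe_sizes()
        dims = [*truth.block_names, RESPONSE_DIM, SAMPLES_DIM]
        for j, planted in enumerate(truth.planted_modules()):
            best_idx, best_jac, best_module = -1, -1.0, None
            for idx, module in enumerate(result.modules):
                jac = np.mean([_jaccard(module.selection(d), planted.selection(d)) for d in dims])
                if jac > best_jac:
                    best_idx, best_jac, best_module = idx, float(jac), module
            row = {"replicate": rep, "planted_module": j, "matched_module": best_idx}
            if best_module is None:
                row.update(
                    recovered=False,
                    dimensions_missing=len(truth.block_names),
                    **{f"jaccard_{d}": 0.0 for d in dims},
                )
            else:
                res = overlap_test(best_module, planted, universe, alpha=alpha)
                row["recovered"] = bool(res.overall_significant)
                row["dimensions_missing"] = dimensions_missing(best_module, truth.block_names)
                for d in dims:
                    row[f"jaccard_{d}"] = _jaccard(best_module.selection(d), planted.selection(d))
            rows.append(row)
    table = pd.DataFrame(rows)
    return RecoveryReport(
        table=table,
        recovered_fraction=float(table["recovered"].mean()) if len(table) else 0.0,
        mean_dimensions_missing=float(table["dimensions_missing"].mean()) if len(table) else 0.0,
    )


def block_weight_significance(
    fit: "ComponentFit",
) -> dict[str, Optional[tuple[float, float]]]:
    """Correlation of each block latent t_i with the response latent u.

    Restricted to the module's selected samples (the joint support of t and
    u when sample selection is active; all samples otherwise).  Blocks whose
    loading support is empty carry no latent signal and are reported as
    ``None``.

    Returns
    -------
    dict
        Block name -> ``(r, p)`` from the Student-t correlation test, or
        ``None`` for an empty-support block.
    """
    sel = fit.selected_sample_indices()
    if len(sel) < 3:
        raise DegenerateInputError(
            f"only {len(sel)} selected samples; correlation test needs >= 3"
        )
    out: dict[str, Optional[tuple[float, float]]] = {}
    for name, w, t_i in zip(fit.block_names, fit.block_loadings, fit.block_scores):
        if not np.any(w != 0):
            out[name] = None
            continue
        out[name] = correlation_pvalue(t_i[sel], fit.response_score[sel])
    return out
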