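"""Planted-module simulator for multi-block data.

Generates input blocks and a response block following the general model
Y = XB + E: every cell carries Gaussian background noise (i.i.d., or with a
first-order autoregressive covariance across input variables to inject
multicollinearity), and each planted module adds a shared rank-1 signal — a
latent sample-score vector supported on the module's samples, multiplied by
signed loadings on the module's variables — to its cells in every input
block and in the response.  Because input and response share the latent
score, the response's planted part is structurally a noisy linear image of
the inputs.  The exact planted coordinates and generative vectors are
recorded so recovery can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .blocks import MultiBlockDataset, OmicsBlock
from .exceptions import ParameterError
from .modules import MDRM

DEFAULT_BLOCK_NAMES = ("CNV", "DM", "ME")
DEFAULT_RESPONSE_NAME = "GE"


@dataclass(frozen=True)
class PlantedModuleShape:
    """Shape of one planted module: samples × variables-per-block × genes."""

    n_samples: int
    n_variables: tuple[int, ...]
    n_response: int


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one synthetic multi-block dataset.

    Parameters
    ----------
    K, block_sizes, M:
        Global shapes: samples, variables per input block, response genes.
    modules:
        Planted module shapes; sample and variable positions are drawn
        disjointly across modules unless ``allow_sample_overlap``.
    signal_range:
        Magnitude range of the signed module loadings (signs drawn ± with
        equal probability, so anti-correlated dimensions occur).
    latent_scale:
        Standard deviation of the latent sample scores.
    noise_sd:
        Scale of the Gaussian background (the error term E); 0 gives
        noise-free data in which each planted submatrix is exactly rank 1.
    ar1_rho:
        First-order autocorrelation of the input background: rows are drawn
        from a multivariate normal with covariance rho^|j-k| (times
        noise_sd^2), injecting multicollinearity among input variables.
    """

    K: int
    block_sizes: tuple[int, ...]
    M: int
    modules: tuple[PlantedModuleShape, ...]
    signal_range: tuple[float, float] = (0.5, 1.0)
    latent_scale: float = 1.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.0
    seed: int = 0
    block_names: tuple[str, ...] = DEFAULT_BLOCK_NAMES
    response_name: str = DEFAULT_RESPONSE_NAME
    allow_sample_overlap: bool = False

    def __post_init__(self) -> None:
        if len(self.block_names) != len(self.block_sizes):
            raise ParameterError("block_names and block_sizes lengths differ")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ParameterError("ar1_rho must lie in [0, 1)")
        total_k = sum(m.n_samples for m in self.modules)
        if not self.allow_sample_overlap and total_k > self.K:
            raise ParameterError("planted sample sets exceed K without declared overlap")
        for m in self.modules:
            if len(m.n_variables) != len(self.block_sizes):
                raise ParameterError("planted module has wrong number of blocks")
            if m.n_samples > self.K or m.n_response > self.M:
                raise ParameterError("planted module does not fit the global shapes")
        for i, n in enumerate(self.block_sizes):
            if sum(m.n_variables[i] for m in self.modules) > n:
                raise ParameterError(f"planted variables exceed block {i} size")
        if sum(m.n_response for m in self.modules) > self.M:
            raise ParameterError("planted response variables exceed M")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class PlantedModule:
    """Exact coordinates and generative vectors of one planted module."""

    sample_indices: np.ndarray
    variable_indices: dict[str, np.ndarray]
    response_indices: np.ndarray
    latent: np.ndarray  # scores on the module's samples, in index order
    loadings: dict[str, np.ndarray]
    response_loadings: np.ndarray


@dataclass
class SimulationTruth:
    """Planted-module ground truth plus the id universes for scoring."""

    config: SimulationConfig
    sample_ids: list[str]
    variable_ids: dict[str, list[str]]  # per input block
    response_ids: list[str]
    modules: list[PlantedModule] = field(default_factory=list)

    @property
    def block_names(self) -> list[str]:
        return list(self.config.block_names)

    def universe_sizes(self) -> dict[str, int]:
        sizes = {name: len(ids) for name, ids in self.variable_ids.items()}
        sizes["response"] = len(self.response_ids)
        sizes["samples"] = len(self.sample_ids)
        return sizes

    def planted_modules(self) -> list[MDRM]:
        """The planted modules as MDRM objects (for overlap scoring)."""
        out = []
        for j, m in enumerate(self.modules):
            out.append(
                MDRM(
                    sample_ids=[self.sample_ids[i] for i in m.sample_indices],
                    selected_variables={
                        name: [self.variable_ids[name][i] for i in idx]
                        for name, idx in m.variable_indices.items()
                    },
                    selected_response=[self.response_ids[i] for i in m.response_indices],
                    block_weights=np.ones(len(self.config.block_names))
                    / np.sqrt(len(self.config.block_names)),
                    objective=float("nan"),
                    provenance={"planted": True, "index": j},
                )
            )
        return out

    def to_dict(self) -> dict:
        """JSON view: coordinates only (generative vectors stay in memory)."""
        return {
            "block_names": self.block_names,
            "sample_ids": list(self.sample_ids),
            "variable_ids": {k: list(v) for k, v in self.variable_ids.items()},
            "response_ids": list(self.response_ids),
            "modules": [
                {
                    "samples": [self.sample_ids[i] for i in m.sample_indices],
                    "variables": {
                        name: [self.variable_ids[name][i] for i in idx]
                        for name, idx in m.variable_indices.items()
                    },
                    "response": [self.response_ids[i] for i in m.response_indices],
                    "latent": [float(x) for x in m.latent],
                }
                for m in self.modules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, config: Optional[SimulationConfig] = None) -> "SimulationTruth":
        """Rebuild a truth object (coordinates only) from its JSON view."""
        sample_pos = {s: i for i, s in enumerate(d["sample_ids"])}
        var_pos = {
            name: {v: i for i, v in enumerate(ids)}
            for name, ids in d["variable_ids"].items()
        }
        resp_pos = {v: i for i, v in enumerate(d["response_ids"])}
        block_names = tuple(d["block_names"])
        if config is None:
            config = SimulationConfig(
                K=len(d["sample_ids"]),
                block_sizes=tuple(len(d["variable_ids"][n]) for n in block_names),
                M=len(d["response_ids"]),
                modules=tuple(
                    PlantedModuleShape(
                        n_samples=len(m["samples"]),
                        n_variables=tuple(len(m["variables"][n]) for n in block_names),
                        n_response=len(m["response"]),
                    )
                    for m in d["modules"]
                ),
                block_names=block_names,
                allow_sample_overlap=True,
            )
        truth = cls(
            config=config,
            sample_ids=list(d["sample_ids"]),
            variable_ids={k: list(v) for k, v in d["variable_ids"].items()},
            response_ids=list(d["response_ids"]),
        )
        for m in d["modules"]:
            truth.modules.append(
                PlantedModule(
                    sample_indices=np.array([sample_pos[s] for s in m["samples"]]),
                    variable_indices={
                        name: np.array([var_pos[name][v] for v in ids])
                        for name, ids in m["variables"].items()
                    },
                    response_indices=np.array([resp_pos[v] for v in m["response"]]),
                    latent=np.asarray(m.get("latent", []), dtype=float),
                    loadings={},
                    response_loadings=np.array([]),
                )
            )
        return truth


def _ar1_background(rng: np.random.Generator, k: int, n: int, rho: float) -> np.ndarray:
    """Rows from N(0, Sigma) with Sigma_jk = rho^|j-k| (unit variance).

    Built by the exact AR(1) recursion x_j = rho x_{j-1} + sqrt(1-rho^2) e_j,
    which realizes that covariance without a Cholesky factorization.
    """
    eps = rng.standard_normal((k, n))
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, n):
        out[:, j] = rho * out[:, j - 1] + c * eps[:, j]
    return out


def _draw_disjoint(
    rng: np.random.Generator, universe: int, sizes: Sequence[int], allow_overlap: bool
) -> list[np.ndarray]:
    """Sorted index sets of the given sizes, disjoint unless overlap allowed."""
    picks = []
    available = np.arange(universe)
    for size in sizes:
        if allow_overlap:
            picks.append(np.sort(rng.choice(universe, size=size, replace=False)))
        else:
            chosen = rng.choice(available, size=size, replace=False)
            picks.append(np.sort(chosen))
            available = np.setdiff1d(available, chosen)
    return picks


def simulate_dataset(config: SimulationConfig) -> tuple[MultiBlockDataset, SimulationTruth]:
    """Generate one dataset and its exact planted truth (bit-reproducible)."""
    rng = np.random.default_rng(config.seed)
    K, M = config.K, config.M

    # backgrounds first (fixed draw order keeps runs reproducible)
    block_values = []
    for n in config.block_sizes:
        if config.ar1_rho > 0:
            bg = _ar1_background(rng, K, n, config.ar1_rho)
        else:
            bg = rng.standard_normal((K, n))
        block_values.append(config.noise_sd * bg)
    Y = config.noise_sd * rng.standard_normal((K, M))

    # planted coordinates
    sample_sets = _draw_disjoint(
        rng, K, [m.n_samples for m in config.modules], config.allow_sample_overlap
    )
    variable_sets = [
        _draw_disjoint(rng, n, [m.n_variables[i] for m in config.modules], False)
        for i, n in enumerate(config.block_sizes)
    ]
    response_sets = _draw_disjoint(rng, M, [m.n_response for m in config.modules], False)

    sample_ids = [f"S{i:04d}" for i in range(K)]
    variable_ids = {
        name: [f"{name}_{j:04d}" for j in range(n)]
        for name, n in zip(config.block_names, config.block_sizes)
    }
    response_ids = [f"{config.response_name}_{j:04d}" for j in range(M)]
    truth = SimulationTruth(
        config=config,
        sample_ids=sample_ids,
        variable_ids=variable_ids,
        response_ids=response_ids,
    )

    lo, hi = config.signal_range
    for j, shape in enumerate(config.modules):
        rows = sample_sets[j]
        tau = rng.standard_normal(shape.n_samples)
        # center the latent across the module's samples so planted columns
        # have exactly zero mean, consistent with the centered-variable model
        tau = config.latent_scale * (tau - tau.mean())
        loadings: dict[str, np.ndarray] = {}
        var_idx: dict[str, np.ndarray] = {}
        for i, name in enumerate(config.block_names):
            cols = variable_sets[i][j]
            a = rng.uniform(lo, hi, size=shape.n_variables[i]) * rng.choice(
                [-1.0, 1.0], size=shape.n_variables[i]
            )
            block_values[i][np.ix_(rows, cols)] += np.outer(tau, a)
            loadings[name] = a
            var_idx[name] = cols
        resp_cols = response_sets[j]
        c = rng.uniform(lo, hi, size=shape.n_response) * rng.choice(
            [-1.0, 1.0], size=shape.n_response
        )
        Y[np.ix_(rows, resp_cols)] += np.outer(tau, c)
        truth.modules.append(
            PlantedModule(
                sample_indices=rows,
                variable_indices=var_idx,
                response_indices=resp_cols,
                latent=tau,
                loadings=loadings,
                response_loadings=c,
            )
        )

    blocks = [
        OmicsBlock(name, values, sample_ids, variable_ids[name])
        for name, values in zip(config.block_names, block_values)
    ]
    response = OmicsBlock(config.response_name, Y, sample_ids, response_ids)
    dataset = MultiBlockDataset(input_blocks=blocks, response_block=response)
    return dataset, truth


def default_scenario(difficulty: str = "benchmark") -> SimulationConfig:
    """Named reproducible scenarios.

    ``benchmark``: 100 samples, three input blocks of 200 variables and
    200 response genes, one planted module of 20 samples × 30 variables per
    block × 30 genes, signal magnitudes in [0.5, 1], unit background noise
    and AR(1) multicollinearity rho = 0.3.  The 50-replicate experiments use
    this config with seeds 1..50.  ``noiseless`` keeps the same shapes with
    zero noise and no autocorrelation.
    """
    shapes = dict(
        K=100,
        block_sizes=(200, 200, 200),
        M=200,
        modules=(PlantedModuleShape(20, (30, 30, 30), 30),),
        signal_range=(0.5, 1.0),
        # the latent scale places the planted signal in the regime the
        # comparison experiments probe: strong enough to shape local
        # covariance, weak enough to be swamped in the global covariance
        # that the non-sparse baseline maximizes
        latent_scale=0.5,
    )
    if difficulty == "benchmark":
        return SimulationConfig(noise_sd=1.0, ar1_rho=0.3, seed=1, **shapes)
    if difficulty == "noiseless":
        return SimulationConfig(noise_sd=0.0, ar1_rho=0.0, seed=1, **shapes)
    raise ParameterError(f"unknown scenario {difficulty!r}")


#: seeds of the 50-replicate comparison experiments
REPLICATE_SEEDS = tuple(range(1, 51))


def true_sparsity(truth_or_config) -> "SparsityConfig":
    """SparsityConfig matching the (first) planted module's shape."""
    from .sparsity import SparsityConfig

    config = truth_or_config.config if hasattr(truth_or_config, "config") else truth_or_config
    shape = config.modules[0]
    return SparsityConfig(
        loading_degrees=tuple(shape.n_variables),
        response_degree=shape.n_response,
        sample_degree=shape.n_samples,
    )
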