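"""Shared fixtures: small seeded multi-block datasets."""

from __future__ import annotations

import numpy as np
import pytest

from smbpls import MultiBlockDataset, OmicsBlock


def make_random_dataset(
    seed: int,
    K: int = 30,
    block_sizes: tuple[int, ...] = (15, 10, 12),
    M: int = 20,
    centered: bool = True,
) -> MultiBlockDataset:
    """Pure-noise dataset with deterministic contents."""
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i}" for i in range(K)]
    blocks = []
    for b, n in enumerate(block_sizes):
        values = rng.standard_normal((K, n))
        if centered:
            values = values - values.mean(axis=0)
        blocks.append(
            OmicsBlock(f"B{b}", values, sample_ids, [f"B{b}_v{j}" for j in range(n)])
        )
    Y = rng.standard_normal((K, M))
    if centered:
        Y = Y - Y.mean(axis=0)
    response = OmicsBlock("Y", Y, sample_ids, [f"g{j}" for j in range(M)])
    return MultiBlockDataset(input_blocks=blocks, response_block=response)


@pytest.fixture
def noise_dataset() -> MultiBlockDataset:
    return make_random_dataset(0)


@pytest.fixture
def single_block_dataset() -> MultiBlockDataset:
    return make_random_dataset(11, K=25, block_sizes=(8,), M=6)
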