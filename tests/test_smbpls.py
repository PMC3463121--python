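"""Sparse component solver, deflation and sequential extraction."""

import numpy as np
import pytest

from smbpls import (
    DegenerateInputError,
    ParameterError,
    SparseMBPLS,
    SparsityConfig,
    deflate,
    extract_modules,
    mbpls_fit,
    module_from_fit,
    overlap_test,
    preprocess,
    simulate_dataset,
    smbpls_component,
    spls_single_block,
    true_sparsity,
)
from smbpls.simulate import PlantedModuleShape, SimulationConfig
from smbpls.sparsity import threshold_to_degree

from conftest import make_random_dataset


def planted(seed=1, noise=0.0, **overrides):
    cfg = dict(
        K=40,
        block_sizes=(30, 25, 20),
        M=30,
        modules=(PlantedModuleShape(10, (6, 5, 4), 6),),
        signal_range=(0.5, 1.0),
        latent_scale=1.0,
        noise_sd=noise,
        ar1_rho=0.0,
        seed=seed,
    )
    cfg.update(overrides)
    ds, truth = simulate_dataset(SimulationConfig(**cfg))
    return preprocess(ds, scale=False, cv_filter_threshold=0.0), truth


# -- sparse component --------------------------------------------------------


def test_full_degrees_reduce_to_classic_mbpls(noise_dataset):
    classic = mbpls_fit(noise_dataset, tol=1e-12, max_iter=5000)
    sparse = smbpls_component(
        noise_dataset, SparsityConfig.full(noise_dataset), tol=1e-12, max_iter=5000
    )
    for w1, w2 in zip(classic.block_loadings, sparse.block_loadings):
        np.testing.assert_allclose(w1, w2, atol=1e-8)
    np.testing.assert_allclose(classic.response_loading, sparse.response_loading, atol=1e-8)
    np.testing.assert_allclose(classic.super_score, sparse.super_score, atol=1e-8)


def test_noiseless_planted_supports_recovered_exactly():
    ds, truth = planted(seed=4, noise=0.0)
    fit = smbpls_component(ds, true_sparsity(truth))
    module = module_from_fit(fit, ds)
    expected = truth.planted_modules()[0]
    for name in truth.block_names:
        assert set(module.selected_variables[name]) == set(expected.selected_variables[name])
    assert set(module.selected_response) == set(expected.selected_response)
    assert set(module.sample_ids) == set(expected.sample_ids)


def test_single_block_matches_independent_sparse_power_iteration():
    """R = 1 sparse component equals an independent implementation of
    alternating soft-thresholded power iterations on the cross-covariance
    A = X^T Y (planted sparse signal makes the optimum unambiguous)."""
    rng = np.random.default_rng(9)
    K, n, m = 30, 12, 10
    tau = rng.standard_normal(K)
    a = np.zeros(n)
    a[[1, 4, 7]] = [1.0, -0.9, 0.8]
    c = np.zeros(m)
    c[[0, 5]] = [1.0, 0.7]
    X = np.outer(tau, a) + 0.05 * rng.standard_normal((K, n))
    Y = np.outer(tau, c) + 0.05 * rng.standard_normal((K, m))
    X -= X.mean(0)
    Y -= Y.mean(0)
    ids = [f"s{i}" for i in range(K)]
    from smbpls import MultiBlockDataset, OmicsBlock

    ds = MultiBlockDataset(
        input_blocks=[OmicsBlock("X", X, ids, [f"x{j}" for j in range(n)])],
        response_block=OmicsBlock("Y", Y, ids, [f"y{j}" for j in range(m)]),
    )
    fit = smbpls_component(ds, SparsityConfig((3,), 2), tol=1e-12, max_iter=5000)

    # independent oracle: alternate on A = X^T Y directly
    A = X.T @ Y
    v = np.linalg.svd(A)[2][0]
    for _ in range(500):
        w = threshold_to_degree(A @ v, 3)
        w = w / np.linalg.norm(w)
        v = threshold_to_degree(A.T @ w, 2)
        v = v / np.linalg.norm(v)
    err_w = min(np.abs(fit.block_loadings[0] - w).max(), np.abs(fit.block_loadings[0] + w).max())
    err_q = min(np.abs(fit.response_loading - v).max(), np.abs(fit.response_loading + v).max())
    assert err_w < 1e-6 and err_q < 1e-6


def test_all_zero_block_raises_degenerate_error_naming_it():
    """An all-zero block cannot yield a loading: the initialization step
    fails with a degenerate-block error naming the block (soft thresholding
    itself can never empty a support: the order-statistic penalty plus the
    smallest-index tie rule always keeps a survivor of a nonzero vector)."""
    ds, _ = planted(seed=5, noise=0.0)
    zeroed = ds.copy()
    zeroed.input_blocks[1].values[:] = 0.0
    with pytest.raises(DegenerateInputError, match="'DM'"):
        smbpls_component(zeroed, SparsityConfig((6, 5, 4), 6))


def test_support_sizes_respect_degrees():
    ds, truth = planted(seed=6, noise=1.0)
    config = true_sparsity(truth)
    fit = smbpls_component(ds, config)
    for w, d in zip(fit.block_loadings, config.loading_degrees):
        assert np.count_nonzero(w) <= d
    assert np.count_nonzero(fit.response_loading) <= config.response_degree
    for t_i in fit.block_scores:
        assert np.count_nonzero(t_i) <= config.sample_degree
    assert np.count_nonzero(fit.response_score) <= config.sample_degree


def test_lower_degree_never_adds_support_on_fixed_u():
    """One-step property: against the same response score, shrinking the
    degree can only remove variables from a loading's support."""
    ds, _ = planted(seed=7, noise=1.0)
    u = mbpls_fit(ds).response_score
    z = ds.input_blocks[0].values.T @ u
    for lo in range(1, 10):
        s_lo = set(np.flatnonzero(threshold_to_degree(z, lo)))
        s_hi = set(np.flatnonzero(threshold_to_degree(z, lo + 1)))
        assert s_lo <= s_hi


# -- deflation ---------------------------------------------------------------


def test_deflation_removes_the_score_direction(noise_dataset):
    fit = smbpls_component(noise_dataset, SparsityConfig((5, 4, 4), 6))
    deflated = deflate(noise_dataset, fit)
    for block in deflated.all_blocks():
        assert np.abs(block.values.T @ fit.super_score).max() < 1e-9
        np.testing.assert_allclose(block.values.mean(axis=0), 0.0, atol=1e-10)


def test_deflation_is_idempotent(noise_dataset):
    fit = smbpls_component(noise_dataset, SparsityConfig((5, 4, 4), 6))
    once = deflate(noise_dataset, fit)
    twice = deflate(once, fit)
    for b1, b2 in zip(once.all_blocks(), twice.all_blocks()):
        np.testing.assert_allclose(b1.values, b2.values, atol=1e-9)


def test_deflation_reduces_rank_by_at_most_one(noise_dataset):
    fit = smbpls_component(noise_dataset, SparsityConfig((5, 4, 4), 6))
    deflated = deflate(noise_dataset, fit)
    for before, after in zip(noise_dataset.all_blocks(), deflated.all_blocks()):
        r0 = np.linalg.matrix_rank(before.values)
        r1 = np.linalg.matrix_rank(after.values)
        assert r0 - 1 <= r1 <= r0


def test_deflation_rejects_zero_score(noise_dataset):
    fit = smbpls_component(noise_dataset, SparsityConfig((5, 4, 4), 6))
    fit.super_score = np.zeros_like(fit.super_score)
    with pytest.raises(DegenerateInputError):
        deflate(noise_dataset, fit)


# -- sequential extraction ---------------------------------------------------


def test_max_modules_cap_is_respected():
    ds, truth = planted(seed=8, noise=1.0)
    result = extract_modules(ds, true_sparsity(truth), max_modules=1)
    assert len(result.modules) == 1
    assert result.stop_reason == "max_modules"


def test_pure_noise_extraction_halts_early():
    ds = make_random_dataset(3, K=12, block_sizes=(20, 18), M=15)
    result = extract_modules(
        ds, SparsityConfig((4, 4), 4), max_modules=50, objective_floor_fraction=0.05
    )
    assert result.stop_reason != "max_modules"
    assert len(result.modules) <= 12  # bounded by the sample-space rank


def test_two_disjoint_planted_modules_are_both_recovered():
    cfg = SimulationConfig(
        K=50,
        block_sizes=(40, 40),
        M=40,
        modules=(
            PlantedModuleShape(10, (8, 8), 8),
            PlantedModuleShape(10, (8, 8), 8),
        ),
        block_names=("A", "B"),
        signal_range=(0.5, 1.0),
        latent_scale=1.0,
        noise_sd=0.0,
        seed=13,
    )
    ds, truth = simulate_dataset(cfg)
    ds = preprocess(ds, scale=False, cv_filter_threshold=0.0)
    config = SparsityConfig((8, 8), 8, sample_degree=10)
    result = extract_modules(ds, config, max_modules=2)
    assert len(result.modules) == 2
    universe = truth.universe_sizes()
    for expected in truth.planted_modules():
        hits = [
            overlap_test(m, expected, universe).overall_significant
            for m in result.modules
        ]
        assert any(hits)


def test_extraction_is_deterministic():
    ds, truth = planted(seed=9, noise=1.0)
    r1 = extract_modules(ds, true_sparsity(truth), max_modules=3)
    r2 = extract_modules(ds, true_sparsity(truth), max_modules=3)
    assert [m.to_dict() for m in r1.modules] == [m.to_dict() for m in r2.modules]
    for f1, f2 in zip(r1.fits, r2.fits):
        np.testing.assert_array_equal(f1.super_score, f2.super_score)


def test_estimator_exposes_extraction(noise_dataset):
    est = SparseMBPLS(loading_degrees=(5, 4, 4), response_degree=6, max_modules=2)
    est.fit(noise_dataset)
    assert len(est.modules_) == len(est.fits_) <= 2
    assert est.stop_reason_ in ("max_modules", "objective_floor", "degenerate")
    params = est.get_params()
    assert params["loading_degrees"] == (5, 4, 4)


# -- merged single-block baseline -------------------------------------------


def test_single_input_block_merging_is_a_noop(single_block_dataset):
    config = SparsityConfig((4,), 3)
    direct = extract_modules(single_block_dataset, config, max_modules=1)
    merged = spls_single_block(single_block_dataset, config, max_modules=1)
    d, m = direct.modules[0], merged.modules[0]
    assert d.selected_variables == m.selected_variables
    assert d.selected_response == m.selected_response
    assert d.sample_ids == m.sample_ids


def test_merged_index_bookkeeping():
    from smbpls import merge_input_blocks
    from smbpls.extract import split_merged_id

    ds, _ = planted(seed=10, noise=1.0)
    merged = merge_input_blocks(ds)
    n1 = ds.input_blocks[0].n_variables
    merged_id = merged.input_blocks[0].variable_ids[n1 + 2]
    block, variable = split_merged_id(merged_id)
    assert block == ds.input_blocks[1].name
    assert variable == ds.input_blocks[1].variable_ids[2]


def test_merged_module_maps_back_to_source_blocks():
    ds, truth = planted(seed=11, noise=0.0)
    shape = truth.config.modules[0]
    config = SparsityConfig((sum(shape.n_variables),), shape.n_response)
    result = spls_single_block(ds, config, max_modules=1)
    module = result.modules[0]
    assert set(module.selected_variables) == set(truth.block_names)
    total = sum(len(v) for v in module.selected_variables.values())
    assert total == sum(shape.n_variables)
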