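"""Module overlap statistics, dimension counts and recovery scoring."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from smbpls import (
    DegenerateInputError,
    MDRM,
    ParameterError,
    SparsityConfig,
    block_weight_significance,
    correlation_pvalue,
    dimensions_missing,
    module_from_fit,
    overlap_test,
    preprocess,
    recovery_report,
    simulate_dataset,
    smbpls_component,
    true_sparsity,
)
from smbpls.estimators import ExtractionResult
from smbpls.modules import hypergeom_overlap_p
from smbpls.simulate import PlantedModuleShape, SimulationConfig


def module(samples, variables, response, weights=(0.7, 0.7)):
    return MDRM(
        sample_ids=list(samples),
        selected_variables={k: list(v) for k, v in variables.items()},
        selected_response=list(response),
        block_weights=np.asarray(weights, dtype=float),
        objective=1.0,
    )


UNIVERSE = {"A": 20, "B": 20, "response": 20, "samples": 30}


def ids(prefix, idx):
    return [f"{prefix}{i}" for i in idx]


# -- hypergeometric overlap --------------------------------------------------


def test_complete_overlap_probability_closed_form():
    # two sets of 5 in a universe of 20 agreeing perfectly: 1 / C(20,5)
    assert hypergeom_overlap_p(20, 5, 5, 5) == pytest.approx(1 / comb(20, 5), rel=1e-10)


@pytest.mark.parametrize("n_universe", [8, 12, 15])
def test_hypergeometric_tail_matches_enumeration(n_universe):
    """Exhaustive enumeration over all subsets of the universe."""
    rng = np.random.default_rng(n_universe)
    n_a, n_b = 4, 5
    set_a = set(range(n_a))
    for k in range(0, n_a + 1):
        count = sum(
            1
            for cand in combinations(range(n_universe), n_b)
            if len(set_a & set(cand)) >= k
        )
        exact = count / comb(n_universe, n_b)
        assert hypergeom_overlap_p(n_universe, n_a, n_b, k) == pytest.approx(exact, rel=1e-9)


def test_identical_modules_are_significant():
    m = module(ids("s", range(5)), {"A": ids("a", range(4)), "B": ids("b", range(4))},
               ids("g", range(4)))
    res = overlap_test(m, m, UNIVERSE)
    assert res.overall_significant
    assert res.n_significant_dimensions == 4
    assert res.per_dimension_p["A"] == pytest.approx(1 / comb(20, 4))


def test_disjoint_modules_are_not_significant():
    m1 = module(ids("s", range(4)), {"A": ids("a", range(3)), "B": ids("b", range(3))},
                ids("g", range(3)))
    m2 = module(ids("s", range(10, 14)),
                {"A": ids("a", range(10, 13)), "B": ids("b", range(10, 13))},
                ids("g", range(10, 13)))
    res = overlap_test(m1, m2, UNIVERSE)
    assert not res.overall_significant
    assert res.n_significant_dimensions == 0
    assert all(p == 1.0 for p in res.per_dimension_p.values())


def test_overlap_test_is_symmetric():
    rng = np.random.default_rng(0)
    m1 = module(ids("s", rng.choice(30, 6, replace=False)),
                {"A": ids("a", rng.choice(20, 5, replace=False)),
                 "B": ids("b", rng.choice(20, 4, replace=False))},
                ids("g", rng.choice(20, 5, replace=False)))
    m2 = module(ids("s", rng.choice(30, 7, replace=False)),
                {"A": ids("a", rng.choice(20, 6, replace=False)),
                 "B": ids("b", rng.choice(20, 5, replace=False))},
                ids("g", rng.choice(20, 6, replace=False)))
    r12 = overlap_test(m1, m2, UNIVERSE)
    r21 = overlap_test(m2, m1, UNIVERSE)
    assert r12.per_dimension_p == r21.per_dimension_p


def test_sample_dimension_skipped_when_all_samples_selected():
    m1 = module(ids("s", range(30)), {"A": ids("a", range(4)), "B": ids("b", range(4))},
                ids("g", range(4)))
    res = overlap_test(m1, m1, UNIVERSE)
    assert "samples" not in res.per_dimension_p
    assert res.n_significant_dimensions == 3


def test_min_significant_dims_three_rule():
    """Module-module robustness screens require three significant dimensions."""
    m1 = module(ids("s", range(6)), {"A": ids("a", range(5)), "B": ids("b", range(14, 19))},
                ids("g", range(5)))
    m2 = module(ids("s", range(6)), {"A": ids("a", range(5)), "B": ids("b", range(5))},
                ids("g", range(5)))
    res = overlap_test(m1, m2, UNIVERSE, min_significant_dims=3)
    assert res.n_significant_dimensions == 3  # A, response, samples; not B
    assert res.overall_significant


def test_family_size_override_weakens_significance():
    m = module(ids("s", range(3)), {"A": ids("a", range(2)), "B": ids("b", range(2))},
               ids("g", range(2)))
    strict = overlap_test(m, m, UNIVERSE, family_size=10_000_000)
    assert strict.n_significant_dimensions < 4


def test_universe_smaller_than_set_is_rejected():
    m = module(ids("s", range(5)), {"A": ids("a", range(4))}, ids("g", range(4)))
    with pytest.raises(ParameterError):
        overlap_test(m, m, {"A": 2, "response": 20, "samples": 30})


# -- dimensions missing ------------------------------------------------------


def test_complete_module_misses_nothing():
    m = module(["s1"], {"A": ["a1"], "B": ["b1"], "C": ["c1"]}, ["g1"], weights=(1, 1, 1))
    assert dimensions_missing(m, ["A", "B", "C"]) == 0


def test_single_dimension_module_misses_two():
    m = module(["s1"], {"A": ["a1", "a2"], "B": [], "C": []}, ["g1"], weights=(1, 0, 0))
    assert dimensions_missing(m, ["A", "B", "C"]) == 2


def test_unknown_dimension_name_is_rejected():
    m = module(["s1"], {"A": ["a1"]}, ["g1"], weights=(1.0,))
    with pytest.raises(ParameterError):
        dimensions_missing(m, ["A", "Z"])


def test_missing_count_distribution_matches_hand_count():
    specs = [  # (selections per block) -> hand-counted missing dims
        ({"A": ["a1"], "B": ["b1"], "C": ["c1"]}, 0),
        ({"A": ["a1"], "B": [], "C": ["c1"]}, 1),
        ({"A": [], "B": [], "C": ["c1"]}, 2),
        ({"A": ["a1", "a2"], "B": [], "C": []}, 2),
        ({"A": [], "B": [], "C": []}, 3),
    ]
    counts = [
        dimensions_missing(module(["s1"], sel, ["g1"], weights=(1, 1, 1)), ["A", "B", "C"])
        for sel, _ in specs
    ]
    assert counts == [expected for _, expected in specs]


# -- recovery scoring --------------------------------------------------------


def _planted_run(seed=21, noise=0.0):
    cfg = SimulationConfig(
        K=40, block_sizes=(30, 25), M=30,
        modules=(PlantedModuleShape(10, (6, 5), 6),),
        block_names=("A", "B"), signal_range=(0.5, 1.0),
        latent_scale=1.0, noise_sd=noise, seed=seed,
    )
    ds, truth = simulate_dataset(cfg)
    return preprocess(ds, scale=False, cv_filter_threshold=0.0), truth


def test_perfect_recovery_scores_one():
    ds, truth = _planted_run()
    fit = smbpls_component(ds, true_sparsity(truth))
    result = ExtractionResult([module_from_fit(fit, ds)], [fit], "max_modules")
    report = recovery_report(result, truth)
    assert report.recovered_fraction == 1.0
    jac_cols = [c for c in report.table.columns if c.startswith("jaccard_")]
    assert np.allclose(report.table[jac_cols].to_numpy(), 1.0)


def test_cheating_extractor_round_trip():
    """Returning the planted truth itself must always score full recovery."""
    ds, truth = _planted_run(seed=22, noise=1.0)
    result = ExtractionResult(truth.planted_modules(), [], "max_modules")
    report = recovery_report(result, truth)
    assert report.recovered_fraction == 1.0


def test_empty_extraction_recovers_nothing():
    ds, truth = _planted_run(seed=23)
    report = recovery_report(ExtractionResult([], [], "degenerate"), truth)
    assert report.recovered_fraction == 0.0


def test_aggregate_is_mean_of_indicators():
    ds1, truth1 = _planted_run(seed=24)
    ds2, truth2 = _planted_run(seed=25)
    fit = smbpls_component(ds1, true_sparsity(truth1))
    good = ExtractionResult([module_from_fit(fit, ds1)], [fit], "max_modules")
    empty = ExtractionResult([], [], "degenerate")
    report = recovery_report([good, empty], [truth1, truth2])
    assert report.recovered_fraction == pytest.approx(
        report.table["recovered"].mean()
    )
    assert len(report.table) == 2


# -- block-weight significance ----------------------------------------------


def test_planted_blocks_all_significant():
    ds, truth = _planted_run(seed=26)
    fit = smbpls_component(ds, true_sparsity(truth))
    sig = block_weight_significance(fit)
    for name in truth.block_names:
        r, p = sig[name]
        assert p < 1e-6


def test_block_weight_pvalues_delegate_to_correlation_test():
    ds, truth = _planted_run(seed=27, noise=1.0)
    fit = smbpls_component(ds, true_sparsity(truth))
    sel = fit.selected_sample_indices()
    sig = block_weight_significance(fit)
    for name, t_i in zip(fit.block_names, fit.block_scores):
        expected = correlation_pvalue(t_i[sel], fit.response_score[sel])
        assert sig[name] == pytest.approx(expected)


def test_zero_support_block_is_marked_excluded():
    ds, truth = _planted_run(seed=28)
    fit = smbpls_component(ds, true_sparsity(truth))
    fit.block_loadings[1] = np.zeros_like(fit.block_loadings[1])
    sig = block_weight_significance(fit)
    assert sig["B"] is None


def test_too_few_selected_samples_is_an_error():
    ds, truth = _planted_run(seed=29)
    fit = smbpls_component(ds, true_sparsity(truth))
    fit.super_score = np.zeros_like(fit.super_score)
    fit.super_score[:2] = 1.0
    with pytest.raises(DegenerateInputError):
        block_weight_significance(fit)
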