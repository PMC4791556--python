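import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from creole_core.core_selection import (
    AllocationPlan,
    axis_gower,
    d_method_allocation,
    gower_distance,
    hmfa_two_block,
    impute_mean,
    pca_reduce,
    select_core,
    simulate_core_size,
    stratified_core_search,
    ward_mlm_cluster,
)
from creole_core.diversity import DistanceMatrix, largest_remainder
from creole_core.io_core import GroupAssignment, PhenotypeTable
from creole_core.synthetic_data import SimulationConfig, simulate_population

from conftest import make_genotypes, random_genotypes


def pheno_from_array(X, kinds=None):
    cols = [f"t{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols, index=[f"A{i}" for i in range(X.shape[0])])
    return PhenotypeTable(df, {c: "continuous" for c in cols} if kinds is None else kinds)


class TestPcaReduce:
    def test_full_rank_explains_everything(self, rng):
        g = random_genotypes(rng, n=15, m=10, missing=0.1)
        scores, ratio = pca_reduce(g, n_components=10)
        assert ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_preserves_distances(self, rng):
        g = random_genotypes(rng, n=20, m=15, missing=0.2)
        X = impute_mean(g)
        scores, _ = pca_reduce(g, n_components=15)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(scores), pdist(X), atol=1e-8)

    def test_variance_target_matches_eigenvalue_oracle(self, rng):
        g = random_genotypes(rng, n=40, m=30, missing=0.1)
        scores, ratio = pca_reduce(g, n_components=0.84)
        X = impute_mean(g)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        cum = np.cumsum(evals) / evals.sum()
        k_expected = int(np.searchsorted(cum, 0.84) + 1)
        assert scores.shape[1] == k_expected
        assert ratio.sum() >= 0.84


class TestHmfaTwoBlock:
    def test_identical_blocks_balance_at_fifty_fifty(self, rng):
        A = rng.normal(size=(80, 8))
        res = hmfa_two_block(A, pheno_from_array(A.copy()), n_axes=4,
                             target_ratio=(50, 50), tol=1.0)
        assert res.cumulative_contrib[0] == pytest.approx(50, abs=1.0)
        assert abs(math.log10(res.phenotype_weight)) < 1.0

    def test_zero_variance_phenotype_block_is_error(self, rng):
        A = rng.normal(size=(40, 6))
        flat = pheno_from_array(np.ones((40, 3)))
        with pytest.raises(ValueError, match="100:0|no variance"):
            hmfa_two_block(A, flat, target_ratio=(75, 25))

    def test_axis_contributions_sum_to_hundred(self, rng):
        A = rng.normal(size=(100, 20))
        B = rng.normal(size=(100, 5))
        res = hmfa_two_block(A, pheno_from_array(B), n_axes=6, target_ratio=(75, 25))
        np.testing.assert_allclose(res.axis_block_contrib.sum(axis=1), 100.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # ordered by variance

    def test_contribution_monotone_in_weight(self, rng):
        from creole_core.core_selection import (
            _cumulative_geno_pct,
            _first_eigenvalue,
            _mfa_decompose,
            _standardize,
        )

        A = _standardize(rng.normal(size=(60, 15)))
        B = _standardize(rng.normal(size=(60, 4)))
        A /= np.sqrt(_first_eigenvalue(A))
        B /= np.sqrt(_first_eigenvalue(B))
        pcts = []
        for w in (0.01, 0.1, 1.0, 10.0, 100.0):
            lam, frac, _ = _mfa_decompose(A, B, w, 6)
            pcts.append(_cumulative_geno_pct(lam, frac))
        assert all(a >= b - 1e-9 for a, b in zip(pcts, pcts[1:]))

    def test_bisection_agrees_with_grid_search(self, rng):
        A = rng.normal(size=(200, 50))
        B = rng.normal(size=(200, 10))
        res = hmfa_two_block(A, pheno_from_array(B), n_axes=6,
                             target_ratio=(75, 25), tol=1.0)
        geno, pheno = res.cumulative_contrib
        assert geno == pytest.approx(75, abs=1.0)
        # brute-force grid over w must find a weight no better than bisection's
        from creole_core.core_selection import (
            _cumulative_geno_pct,
            _first_eigenvalue,
            _mfa_decompose,
            _standardize,
        )

        As = _standardize(A) / np.sqrt(_first_eigenvalue(_standardize(A)))
        Bs = _standardize(B) / np.sqrt(_first_eigenvalue(_standardize(B)))
        grid = np.logspace(-3, 3, 400)
        errs = []
        for w in grid:
            lam, frac, _ = _mfa_decompose(As, Bs, w, 6)
            errs.append(abs(_cumulative_geno_pct(lam, frac) - 75))
        w_grid = grid[int(np.argmin(errs))]
        assert abs(math.log10(res.phenotype_weight) - math.log10(w_grid)) < 0.1


class TestWardMlm:
    @staticmethod
    def planted_gaussians(rng, n_per=60, sep=6.0, d=4, k=3):
        centers = rng.normal(scale=sep, size=(k, d))
        X = np.vstack([rng.normal(loc=c, size=(n_per, d)) for c in centers])
        truth = np.repeat(np.arange(k), n_per)
        return X, truth

    def test_three_planted_gaussians_recovered(self, rng):
        X, truth = self.planted_gaussians(rng)
        fit = ward_mlm_cluster(X, g_range=range(1, 7), seed=0)
        assert fit.n_groups == 3
        got = [fit.assignment.labels[str(i)] for i in range(len(truth))]
        assert adjusted_rand_score(truth, got) >= 0.95

    def test_single_gaussian_selects_one_group(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(150, 3))
            fit = ward_mlm_cluster(X, g_range=range(1, 5), seed=seed)
            hits += fit.n_groups == 1
        assert hits >= 4

    def test_loglik_nondecreasing_over_em_iterations(self, rng):
        X, _ = self.planted_gaussians(rng, sep=2.0)
        fit = ward_mlm_cluster(X, g_range=[3], seed=0)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_responsibilities_are_proper(self, rng):
        X, _ = self.planted_gaussians(rng)
        fit = ward_mlm_cluster(X, g_range=range(2, 5), seed=0)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0)
        assert fit.weights.sum() == pytest.approx(1.0)


class TestGowerDistance:
    def test_identical_and_opposite_records(self):
        X = np.array([[0.0, 1.0], [0.0, 1.0], [10.0, 9.0]])
        t = pheno_from_array(X)
        d = gower_distance(pheno=t)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_hand_worked_mixed_example(self):
        # x = (0, 5, A, A), y = (10, 5, A, B); continuous ranges are 10
        # similarities: (0, 1, 1, 0) -> mean 0.5 -> distance 0.5
        cont = pheno_from_array(np.array([[0.0, 5.0], [10.0, 5.0], [5.0, 0.0]]))
        cat = make_genotypes([[0, 0], [0, 2], [2, 2]])
        d = gower_distance(geno=cat, pheno=None, ids=cont.accession_ids)
        # categorical block alone: (1, 0) -> d = 0.5
        assert d.values[0, 1] == pytest.approx(0.5)
        full = gower_distance(geno=cat, pheno=cont)
        assert full.values[0, 1] == pytest.approx(0.5)

    def test_matches_brute_force_per_variable_loop(self, rng):
        g = random_genotypes(rng, n=12, m=8, missing=0.2)
        X = rng.normal(size=(12, 3))
        X[rng.random(X.shape) < 0.15] = np.nan
        t = pheno_from_array(X)
        d = gower_distance(geno=g, pheno=t)
        rngs = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
        for i in range(12):
            for j in range(i + 1, 12):
                sims, cnt = 0.0, 0
                for c in range(8):
                    a, b = g.calls[i, c], g.calls[j, c]
                    if a != -1 and b != -1:
                        sims += float(a == b)
                        cnt += 1
                for c in range(3):
                    a, b = X[i, c], X[j, c]
                    if not (np.isnan(a) or np.isnan(b)):
                        sims += 1 - abs(a - b) / rngs[c]
                        cnt += 1
                expected = 1 - sims / cnt if cnt else np.nan
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_axis_gower_bounds_and_symmetry(self, rng):
        X = rng.normal(size=(30, 6))
        d = axis_gower(X, axis_weights=np.linspace(1, 0.2, 6))
        assert np.all((d.values >= 0) & (d.values <= 1))
        np.testing.assert_allclose(d.values, d.values.T)


def toy_distance(groups_sizes, within):
    """Block distance matrix: constant within-group distance per group, 1 across."""
    ids, vals = [], []
    n = sum(groups_sizes)
    d = np.ones((n, n))
    start = 0
    labels = []
    for gi, (size, w) in enumerate(zip(groups_sizes, within)):
        ids += [f"g{gi}_{i}" for i in range(size)]
        labels += [f"g{gi}"] * size
        d[start:start + size, start:start + size] = w
        start += size
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d), GroupAssignment.from_arrays(ids, labels)


class TestDMethodAllocation:
    def test_quota_proportional_to_diversity(self):
        d, groups = toy_distance([10, 10], [0.2, 0.1])
        plan = d_method_allocation(groups, d, core_size=6)
        assert plan.quotas == {"g0": 4, "g1": 2}
        assert plan.diversity["g0"] == pytest.approx(0.2)

    def test_equal_diversity_splits_evenly(self):
        d, groups = toy_distance([10, 10, 10], [0.15, 0.15, 0.15])
        plan = d_method_allocation(groups, d, core_size=10)
        assert sorted(plan.quotas.values()) == [3, 3, 4]

    def test_clamped_at_group_size_with_redistribution(self):
        d, groups = toy_distance([3, 20], [0.9, 0.1])
        plan = d_method_allocation(groups, d, core_size=12)
        assert plan.quotas["g0"] == 3  # cannot exceed the group
        assert plan.quotas["g1"] == 9
        assert sum(plan.quotas.values()) == 12

    def test_singleton_group_gets_minimum_slot(self):
        d, groups = toy_distance([1, 20], [0.0, 0.3])
        plan = d_method_allocation(groups, d, core_size=5)
        assert plan.quotas["g0"] == 1

    def test_matches_largest_remainder_oracle(self, rng):
        # unconstrained instances: quotas equal plain largest-remainder rounding
        for _ in range(10):
            k = rng.integers(2, 6)
            sizes = rng.integers(20, 40, size=k)
            within = rng.uniform(0.05, 0.5, size=k)
            d, groups = toy_distance(list(sizes), list(within))
            core = int(sizes.sum() * 0.2)
            plan = d_method_allocation(groups, d, core_size=core)
            shares = core * within / within.sum()
            expected = largest_remainder(shares, core)
            got = np.array([plan.quotas[f"g{i}"] for i in range(k)])
            if np.all(expected <= sizes) and np.all(expected > 0):
                np.testing.assert_array_equal(got, expected)

    def test_conserves_core_size_on_random_instances(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            k = r.integers(2, 7)
            sizes = r.integers(1, 30, size=k)
            within = r.uniform(0, 0.6, size=k)
            d, groups = toy_distance(list(sizes), list(within))
            core = int(r.integers(1, sizes.sum() + 1))
            plan = d_method_allocation(groups, d, core_size=core)
            assert sum(plan.quotas.values()) == core
            assert all(plan.quotas[g] <= len(plan.members[g]) for g in plan.quotas)


class TestStratifiedSearch:
    def test_single_candidate_returned_verbatim(self):
        d, groups = toy_distance([8, 8], [0.3, 0.2])
        plan = d_method_allocation(groups, d, core_size=6)
        core = stratified_core_search(plan, d, n_candidates=1, seed=5)
        assert core.candidate_index == 0
        assert len(core.accession_ids) == 6

    def test_full_quota_returns_complete_set(self):
        d, groups = toy_distance([5, 5], [0.4, 0.1])
        plan = AllocationPlan(
            quotas={"g0": 5, "g1": 5}, diversity={"g0": 0.4, "g1": 0.1},
            members=groups.groups(), core_size=10,
        )
        core = stratified_core_search(plan, d, n_candidates=3, seed=0)
        assert sorted(core.accession_ids) == sorted(d.ids)
        assert core.mean_gower == pytest.approx(d.mean_offdiagonal())

    def test_reproducible_and_beats_random_subsets(self, small_population):
        g, pheno, _, truth = small_population
        res1 = select_core(g, pheno, core_fraction=0.15, n_geno_components=20,
                           g_range=range(3, 8), n_candidates=50, seed=42)
        res2 = select_core(g, pheno, core_fraction=0.15, n_geno_components=20,
                           g_range=range(3, 8), n_candidates=50, seed=42)
        assert res1.core.accession_ids == res2.core.accession_ids
        # stratified max-Gower beats the median random subset of the same size
        rng = np.random.default_rng(0)
        k = len(res1.core.accession_ids)
        rand_scores = []
        for _ in range(200):
            idx = rng.choice(g.n_accessions, size=k, replace=False)
            sub = res1.distance.values[np.ix_(idx, idx)]
            rand_scores.append(sub[np.triu_indices(k, 1)].mean())
        assert res1.core.mean_gower >= np.median(rand_scores)


class TestSimulateCoreSize:
    def test_full_sample_has_zero_variance(self, rng):
        g = random_genotypes(rng, n=30, m=60, missing=0.1)
        curve = simulate_core_size(g, levels=[1.0], n_reps=20, seed=0)
        assert curve.s2[0] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_matrix_flat_zero(self):
        g = make_genotypes(np.zeros((20, 10), dtype=np.int8))
        curve = simulate_core_size(g, n_reps=20, seed=0)
        np.testing.assert_allclose(curve.s2, 0.0, atol=1e-12)

    def test_variance_strictly_decreasing_in_level(self, rng):
        g = random_genotypes(rng, n=100, m=300, missing=0.1)
        curve = simulate_core_size(g, n_reps=200, statistic="var_p", seed=2)
        assert len(curve.levels) == 20
        assert np.all(np.diff(curve.s2) < 0)
        assert curve.argmax_level == pytest.approx(0.05)

    def test_fst_statistic_available(self, rng):
        g = random_genotypes(rng, n=50, m=100, missing=0.1)
        curve = simulate_core_size(g, levels=[0.1, 0.5], n_reps=50,
                                   statistic="fst", seed=3)
        assert np.all(curve.s2 >= 0)
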