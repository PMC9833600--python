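"""Eta bounds, active-set identification, KKT audit."""

import itertools
import math

import numpy as np
import pytest

from epilasso import (
    DuplicateRegistry,
    WorkingSetCache,
    eta_bound,
    eta_bound_nonbinary,
    identify_active_set_pairwise,
    identify_active_set_threeway,
    interaction_column,
    kkt_violations,
)
from epilasso.pruning import _branch_eta

from _reference import dense_threshold_set, materialize_xstar
from conftest import random_binary_matrix


def _snapshot(cache, X, x, rho, depth):
    """Store rho_x and the exact pi_x (max |partner . rho| over j > max(x))."""
    p = X.n_cols
    pi = 0.0
    base_sup, base_vals = interaction_column(X, x)
    w = base_vals if base_vals is not None else np.ones(base_sup.size)
    pi = abs(float(w @ rho[base_sup])) if base_sup.size else 0.0
    for extra in range(max(x) + 1, p):
        for id in {tuple(sorted(x + (extra,)))}:
            sup, vals = interaction_column(X, id)
            v = vals if vals is not None else np.ones(sup.size)
            pi = max(pi, abs(float(v @ rho[sup])))
        if depth >= 3 and len(x) == 1:
            for k in range(extra + 1, p):
                sup, vals = interaction_column(X, tuple(sorted(x + (extra, k))))
                v = vals if vals is not None else np.ones(sup.size)
                pi = max(pi, abs(float(v @ rho[sup])))
    cache.rho[x] = rho.copy()
    cache.pi[x] = pi


class TestEtaBound:
    def test_unchanged_residuals_give_pi(self, rng):
        X, _ = random_binary_matrix(rng, 30, 6)
        cache = WorkingSetCache()
        r = rng.normal(size=30)
        _snapshot(cache, X, (1,), r, depth=2)
        eta = eta_bound((1,), r, cache, X.col_supports[1])
        assert eta == pytest.approx(cache.pi[(1,)], rel=1e-12)

    def test_empty_support_gives_zero(self):
        from epilasso import SparseBinaryMatrix

        X = SparseBinaryMatrix(10, 2, [np.array([], dtype=np.int64),
                                       np.array([1, 2])])
        cache = WorkingSetCache()
        cache.rho[(0,)] = np.zeros(10)
        cache.pi[(0,)] = 0.0
        assert eta_bound((0,), np.ones(10), cache, X.col_supports[0]) == 0.0

    def test_missing_snapshot_is_infinite(self, rng):
        X, _ = random_binary_matrix(rng, 20, 4)
        assert math.isinf(
            eta_bound((0,), rng.normal(size=20), WorkingSetCache(),
                      X.col_supports[0])
        )

    @pytest.mark.parametrize("depth", [2, 3])
    def test_bound_dominates_exhaustive_partner_scan(self, rng, depth):
        """eta(x) >= |X*_{x o j} . r| for every supra partner, 1000+ configs."""
        checked = 0
        for trial in range(40):
            X, dense = random_binary_matrix(rng, 40, 10, density=0.25)
            rho = rng.normal(size=40)
            r = rho + rng.normal(scale=rng.uniform(0.01, 2.0), size=40)
            cache = WorkingSetCache()
            branches = [(i,) for i in range(9)]
            if depth == 3:
                branches += [(i, j) for i in range(5) for j in range(i + 1, 9)]
            for x in branches:
                _snapshot(cache, X, x, rho, depth)
                sup, _ = interaction_column(X, x)
                eta = eta_bound(x, r, cache, sup)
                for j in range(max(x) + 1, 10):
                    id = tuple(sorted(x + (j,)))
                    psup, _ = interaction_column(X, id)
                    assert abs(float(r[psup].sum())) <= eta + 1e-10
                    checked += 1
                if depth == 3 and len(x) == 1:
                    for j, k in itertools.combinations(range(max(x) + 1, 10), 2):
                        tsup, _ = interaction_column(X, (x[0], j, k))
                        assert abs(float(r[tsup].sum())) <= eta + 1e-10
                        checked += 1
        assert checked >= 1000

    def test_nonbinary_reduces_to_binary_when_values_one(self, rng):
        X, _ = random_binary_matrix(rng, 30, 6)
        cache = WorkingSetCache()
        rho = rng.normal(size=30)
        r = rho + rng.normal(scale=0.3, size=30)
        _snapshot(cache, X, (2,), rho, depth=2)
        sup = X.col_supports[2]
        assert eta_bound_nonbinary(
            (2,), r, cache, sup, vmax_all=1.0, vmax_x=1.0
        ) == pytest.approx(eta_bound((2,), r, cache, sup), rel=1e-12)

    def test_nonbinary_scales_homogeneously(self, rng):
        X, _ = random_binary_matrix(rng, 30, 6)
        cache = WorkingSetCache()
        rho = rng.normal(size=30)
        r = rho + rng.normal(scale=0.3, size=30)
        cache.rho[(2,)] = rho.copy()
        cache.pi[(2,)] = 0.0  # isolate the remainder term
        sup = X.col_supports[2]
        base = eta_bound_nonbinary((2,), r, cache, sup, 1.0, 1.0)
        scaled = eta_bound_nonbinary((2,), r, cache, sup, 3.0, 2.0)
        assert scaled == pytest.approx(6.0 * base, rel=1e-12)

    def test_nonbinary_bound_dominates_weighted_oracle(self, rng):
        checked = 0
        for trial in range(40):
            X, dense = random_binary_matrix(rng, 30, 8, density=0.3,
                                            real_values=True)
            rho = rng.normal(size=30)
            r = rho + rng.normal(scale=rng.uniform(0.05, 1.0), size=30)
            cache = WorkingSetCache()
            cols = {
                id: np.prod(dense[:, id], axis=1)
                for order in (1, 2, 3)
                for id in itertools.combinations(range(8), order)
            }
            for x in [(i,) for i in range(7)] + [
                (i, j) for i in range(4) for j in range(i + 1, 7)
            ]:
                # weighted snapshot: max |X*_{x o partners} . rho|
                pi = abs(float(cols[x] @ rho))
                for id, c in cols.items():
                    if len(id) > len(x) and set(x) <= set(id):
                        if not (len(x) == 2 and len(id) == 3 and min(set(id) - set(x)) <= max(x)):
                            pi = max(pi, abs(float(c @ rho)))
                cache.rho[x] = rho.copy()
                cache.pi[x] = pi
                sup = np.flatnonzero(cols[x])
                eta = _branch_eta(X, x, r, cache, sup, depth=3)
                for id, c in cols.items():
                    if len(id) == len(x) + 1 and set(x) <= set(id) and min(set(id) - set(x)) > max(x):
                        assert abs(float(c @ r)) <= eta + 1e-9
                        checked += 1
                    if len(x) == 1 and len(id) == 3 and set(x) <= set(id) and min(set(id) - set(x)) > max(x):
                        assert abs(float(c @ r)) <= eta + 1e-9
                        checked += 1
        assert checked >= 1000


class TestActiveSet:
    def test_zero_residual_gives_empty_set(self, rng):
        X, _ = random_binary_matrix(rng, 30, 6)
        active = identify_active_set_pairwise(
            X, np.zeros(30), 0.5, 0.0, WorkingSetCache()
        )
        assert active.members == set()

    def test_lambda_zero_admits_everything_realized(self, rng):
        X, dense = random_binary_matrix(rng, 50, 10, density=0.3)
        r = rng.normal(size=50)
        active = identify_active_set_pairwise(
            X, r, 0.0, float(np.linalg.norm(r)), WorkingSetCache()
        )
        expect = dense_threshold_set(dense, r, 0.0, float(np.linalg.norm(r)), 2)
        assert active.members == expect

    @pytest.mark.parametrize("depth", [2, 3])
    def test_matches_brute_force_thresholding(self, rng, depth):
        identify = (
            identify_active_set_threeway if depth == 3
            else identify_active_set_pairwise
        )
        n, p = (40, 8) if depth == 3 else (50, 10)
        for trial in range(8):
            X, dense = random_binary_matrix(rng, n, p, density=0.3)
            cache = WorkingSetCache()
            r = rng.normal(size=n)
            omega = float(np.linalg.norm(r))
            for lam in [0.0, 0.05, 0.1, 0.3, 0.6]:
                active = identify(X, r, lam, omega, cache)
                expect = dense_threshold_set(dense, r, lam, omega, depth)
                assert active.members == expect
            # second pass with warm caches and a perturbed residual:
            # pruning must stay sound once snapshots exist
            cache.residual_version += 1
            r2 = r + rng.normal(scale=0.2, size=n)
            omega2 = float(np.linalg.norm(r2))
            for lam in [0.05, 0.2, 0.5]:
                active = identify(X, r2, lam, omega2, cache)
                expect = dense_threshold_set(dense, r2, lam, omega2, depth)
                assert active.members == expect

    def test_admission_monotone_in_lambda(self, rng):
        X, _ = random_binary_matrix(rng, 50, 10, density=0.3)
        r = rng.normal(size=50)
        omega = float(np.linalg.norm(r))
        sets = [
            identify_active_set_pairwise(X, r, lam, omega, WorkingSetCache()).members
            for lam in (0.4, 0.2, 0.05)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_eta_cache_invalidated_on_residual_update(self, rng):
        X, _ = random_binary_matrix(rng, 30, 6)
        cache = WorkingSetCache()
        rho = rng.normal(size=30)
        _snapshot(cache, X, (0,), rho, depth=2)
        r1 = rho + rng.normal(scale=0.1, size=30)
        e1 = eta_bound((0,), r1, cache, X.col_supports[0])
        assert cache.eta_cache[(0,)] == (0, e1)
        # same residual version: cached value reused even for different r
        r2 = r1 * 2.0
        assert eta_bound((0,), r2, cache, X.col_supports[0]) == e1
        cache.residual_version += 1
        e2 = eta_bound((0,), r2, cache, X.col_supports[0])
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_duplicate_columns_never_admitted(self, rng):
        dense = (rng.random((40, 6)) < 0.3).astype(float)
        dense[:, 5] = dense[:, 1]  # exact duplicate single column
        from epilasso import SparseBinaryMatrix

        X = SparseBinaryMatrix.from_dense(dense)
        r = rng.normal(size=40) + dense[:, 1]
        dedup = DuplicateRegistry()
        active = identify_active_set_pairwise(
            X, r, 0.01, float(np.linalg.norm(r)), WorkingSetCache(), dedup
        )
        assert (1,) in active.members
        assert (5,) not in active.members
        assert (5,) in dedup.known_duplicates

    def test_hierarchy_filter_restricts_interactions(self, rng):
        X, dense = random_binary_matrix(rng, 50, 8, density=0.35)
        r = rng.normal(size=50)
        omega = float(np.linalg.norm(r))
        active = identify_active_set_pairwise(
            X, r, 0.0, omega, WorkingSetCache(), hierarchy_set={0, 1, 2}
        )
        for id in active.members:
            if len(id) > 1:
                assert set(id) <= {0, 1, 2}


class TestKktViolations:
    def test_all_zero_matrix(self):
        from epilasso import SparseBinaryMatrix

        X = SparseBinaryMatrix(10, 3, [np.array([], dtype=np.int64)] * 3)
        assert kkt_violations(X, {}, np.ones(10), 0.1, 2) == []

    def test_deliberate_violation_reported(self, rng):
        from epilasso import FitConfig, fit

        X, dense = random_binary_matrix(rng, 50, 10, density=0.3)
        y = 2.0 * dense[:, 3] + rng.normal(scale=0.1, size=50)
        res = fit(X, y, FitConfig(depth=2, max_nonzero=100, n_lambda=5,
                                  convergence_tol=1e-10))
        lam = res.state.lambda_current
        assert kkt_violations(
            X, res.state.beta, res.state.r, lam, 2,
            exclude=res.dedup.known_duplicates,
        ) == []
        # zero out a fitted support coefficient: its id must be flagged
        victim = max(res.state.beta, key=lambda id: abs(res.state.beta[id]))
        beta = dict(res.state.beta)
        sup, _ = interaction_column(X, victim)
        r = res.state.r.copy()
        r[sup] += beta[victim]
        beta[victim] = 0.0
        assert victim in kkt_violations(
            X, beta, r, lam, 2, exclude=res.dedup.known_duplicates
        )
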