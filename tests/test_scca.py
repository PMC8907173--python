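"""Sparse CCA core: penalized steps, alternation, deflation, CCA refit."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from microscca import (
    PenaltyGrid,
    SparseCCA,
    build_sparsity_grid,
    deflate,
    elastic_net_step,
    final_cca,
    group_lasso_step,
    run_scca,
    scca_fit,
    selection_overlap,
    selection_summary,
    tune_penalties,
)
from microscca.scca import (
    CanonicalComponent,
    _elastic_net_bounded,
    _group_lasso_bounded,
    elastic_net_max_penalty,
    group_lasso_max_penalty,
)


def cca_first_correlation_oracle(X, Y):
    """Classical first canonical correlation via whitening + SVD,
    implemented independently of the package internals."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    qx, _ = np.linalg.qr(X)
    qy, _ = np.linalg.qr(Y)
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(s[0])


@pytest.fixture
def planted(rng):
    """n=200 with one shared latent factor in 12 X-columns / 8 Y-columns."""
    n = 200
    u = rng.standard_normal(n)
    X = rng.standard_normal((n, 12)) * 0.6
    Y = rng.standard_normal((n, 8)) * 0.6
    X[:, 0] += u
    X[:, 1] += u
    Y[:, 0] += u
    X -= X.mean(axis=0)
    Y -= Y.mean(axis=0)
    groups = np.repeat(np.arange(6), 2)
    return X, Y, groups, u


class TestGroupLassoStep:
    def test_unpenalized_limit_equals_ols(self, rng):
        n, p = 100, 8
        X = rng.standard_normal((n, p))
        z = rng.standard_normal(n)
        groups = np.repeat(np.arange(4), 2)
        b = group_lasso_step(X, groups, z, 0.0)
        ols = np.linalg.lstsq(X, z, rcond=None)[0]
        assert np.abs(b - ols).max() < 1e-6

    def test_full_shrinkage_above_max_penalty(self, rng):
        X = rng.standard_normal((60, 10))
        z = rng.standard_normal(60)
        groups = np.repeat(np.arange(5), 2)
        lam_max = group_lasso_max_penalty(X, z, groups)
        b = group_lasso_step(X, groups, z, lam_max * 1.001)
        assert np.all(b == 0.0)

    def test_matches_generic_convex_solver(self, rng):
        """Planted single informative group; compare against scipy
        minimization of the same objective."""
        n = 120
        groups = np.repeat(np.arange(5), 2)
        X = rng.standard_normal((n, 10))
        z = X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.standard_normal(n)
        lam = 0.3 * group_lasso_max_penalty(X, z, groups)

        def objective(b):
            pen = sum(
                np.sqrt(2.0) * np.linalg.norm(b[2 * g : 2 * g + 2]) for g in range(5)
            )
            return 0.5 * np.sum((z - X @ b) ** 2) / n + lam * pen

        b_pkg = group_lasso_step(X, groups, z, lam, tol=1e-12, max_iter=20000)
        res = minimize(objective, np.zeros(10), method="Powell",
                       options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 200000})
        assert objective(b_pkg) <= objective(res.x) + 1e-8
        # the generating group is selected; selection is group-wise
        assert np.linalg.norm(b_pkg[:2]) > 0
        active = np.flatnonzero(b_pkg != 0)
        for g in range(5):
            pair = b_pkg[2 * g : 2 * g + 2]
            assert (pair == 0).all() or (pair != 0).any()

    def test_negative_penalty_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        with pytest.raises(ValueError):
            group_lasso_step(X, [0, 0, 1, 1], rng.standard_normal(20), -1.0)


class TestElasticNetStep:
    def test_unpenalized_limit_equals_ols(self, rng):
        Y = rng.standard_normal((80, 6))
        z = rng.standard_normal(80)
        a = elastic_net_step(Y, z, 0.0)
        ols = np.linalg.lstsq(Y, z, rcond=None)[0]
        np.testing.assert_allclose(a, ols, atol=1e-8)

    def test_huge_penalty_zeroes_everything(self, rng):
        Y = rng.standard_normal((80, 6))
        z = rng.standard_normal(80)
        lam = 10 * elastic_net_max_penalty(Y, z, 0.5)
        assert np.all(elastic_net_step(Y, z, lam, 0.5) == 0.0)

    def test_grouping_effect_on_duplicated_columns(self, rng):
        """Duplicated informative columns both get near-equal weight when
        the ridge part is active (mixing < 1)."""
        n = 300
        base = rng.standard_normal(n)
        Y = np.column_stack([base, base, rng.standard_normal((n, 4))])
        z = base + 0.1 * rng.standard_normal(n)
        a = elastic_net_step(Y, z, 0.05, mixing=0.5)
        assert a[0] != 0 and a[1] != 0
        assert abs(a[0] - a[1]) < 0.05 * max(abs(a[0]), 1e-12)


class TestBoundedSolvers:
    def test_group_bound_respected_and_kkt_exact(self, rng):
        n, G = 150, 40
        X = rng.standard_normal((n, 2 * G))
        z = X[:, 0] + X[:, 2] + rng.standard_normal(n)
        gidx = np.repeat(np.arange(G), 2)
        for k in (1, 3, 10):
            b, lam = _group_lasso_bounded(X, gidx, z, k)
            ng = len(np.unique(gidx[b != 0]))
            assert ng <= k
            # solution solves the full problem at the returned lambda
            full = group_lasso_step(X, gidx, z, lam, tol=1e-12, max_iter=20000)
            assert np.abs(b - full).max() < 1e-4

    def test_feature_bound_respected(self, rng):
        Y = rng.standard_normal((100, 60))
        z = Y[:, 0] - Y[:, 5] + 0.5 * rng.standard_normal(100)
        for k in (2, 5, 20):
            a, lam = _elastic_net_bounded(Y, z, k, 0.5)
            assert int((a != 0).sum()) <= k


class TestSccaFit:
    def test_identical_planted_column_pair_found(self, rng):
        n = 120
        shared = rng.standard_normal(n)
        X = np.column_stack([shared, rng.standard_normal((n, 9))])
        Y = np.column_stack([shared, rng.standard_normal((n, 5))])
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        groups = np.repeat(np.arange(5), 2)
        comp = scca_fit(X, Y, groups, sparsity=(1, 1))
        assert comp.selected_snps == [0]
        assert comp.selected_features == ["y0"]
        assert comp.canonical_correlation > 0.99

    def test_unpenalized_matches_classical_cca(self, rng):
        n = 200
        u = rng.standard_normal(n)
        X = rng.standard_normal((n, 10)) + 0.5 * u[:, None]
        Y = rng.standard_normal((n, 8)) + 0.5 * u[:, None]
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        groups = np.repeat(np.arange(5), 2)
        comp = scca_fit(X, Y, groups, 0.0, 0.0, tol=1e-12, max_iter=2000)
        rho = cca_first_correlation_oracle(X, Y)
        assert abs(comp.canonical_correlation - rho) < 1e-4

    def test_norm_constraints_hold_at_convergence(self, planted):
        X, Y, groups, _ = planted
        comp = scca_fit(X, Y, groups, sparsity=(3, 4))
        assert abs(np.linalg.norm(X @ comp.beta.to_numpy()) - 1) < 1e-8
        assert abs(np.linalg.norm(Y @ comp.alpha.to_numpy()) - 1) < 1e-8

    def test_objective_non_increasing_in_penalty_mode(self, planted):
        X, Y, groups, _ = planted
        l1 = 0.3 * group_lasso_max_penalty(X, (Y[:, 0]) / np.linalg.norm(Y[:, 0]), groups)
        comp = scca_fit(X, Y, groups, l1, 0.01, max_iter=50)
        trace = comp.objective_trace
        assert trace is not None and len(trace) >= 2
        # non-increasing up to the O(1e-4) perturbation the unit-norm
        # rescaling after each half-step introduces into the penalty terms
        assert np.all(np.diff(trace) <= 1e-4 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_collapse_returns_empty_component(self, rng):
        X = rng.standard_normal((50, 6))
        Y = rng.standard_normal((50, 4))
        groups = np.repeat(np.arange(3), 2)
        lam1 = 100 * group_lasso_max_penalty(X, Y[:, 0] / np.linalg.norm(Y[:, 0]), groups)
        comp = scca_fit(X, Y, groups, lam1, 0.01)
        assert comp.is_empty and not comp.converged
        assert (comp.beta == 0).all()

    def test_too_few_samples_rejected(self, rng):
        X = rng.standard_normal((5, 4))
        Y = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="10 samples"):
            scca_fit(X, Y, [0, 0, 1, 1], 0.1, 0.1)


class TestTunePenalties:
    def test_single_pair_grid_returned(self, planted):
        X, Y, groups, _ = planted
        grid = PenaltyGrid(pairs=((2, 3),), mode="sparsity")
        (k1, k2), table = tune_penalties(X, Y, groups, grid, folds=3)
        assert (k1, k2) == (2, 3)
        assert table.shape == (1, 4)

    def test_pure_noise_has_near_zero_heldout_correlation(self, rng):
        n = 200
        X = rng.standard_normal((n, 10))
        Y = rng.standard_normal((n, 8))
        groups = np.repeat(np.arange(5), 2)
        grid = PenaltyGrid(pairs=((2, 2), (4, 4)), mode="sparsity")
        _, table = tune_penalties(X, Y, groups, grid, folds=5, seed=0)
        assert abs(table["mean"]).max() < 2.0 / np.sqrt(n / 5)

    def test_planted_signal_beats_noise_pair(self, planted):
        X, Y, groups, _ = planted
        (k1, k2), table = tune_penalties(
            X, Y, groups, build_sparsity_grid(k_groups=(2, 4), k_features=(2, 4)),
            folds=4, seed=0,
        )
        assert table["mean"].max() > 0.5


class TestDeflation:
    def test_deflated_columns_orthogonal_to_variates(self, planted):
        X, Y, groups, _ = planted
        comp = scca_fit(X, Y, groups, sparsity=(3, 3))
        u = X @ comp.beta.to_numpy()
        Xd, Yd = deflate(X, Y, comp)
        corr = np.abs(u @ Xd) / (np.linalg.norm(u) * np.linalg.norm(Xd, axis=0) + 1e-300)
        assert corr.max() < 1e-8

    def test_rank_one_matrix_deflates_to_zero(self, rng):
        n = 60
        u = rng.standard_normal(n)
        X = np.outer(u, rng.standard_normal(4))
        Y = np.outer(u, rng.standard_normal(3)) + 1e-6 * rng.standard_normal((n, 3))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        groups = [0, 0, 1, 1]
        comp = scca_fit(X, Y, groups, 0.0, 0.0)
        Xd, _ = deflate(X, Y, comp)
        assert np.abs(Xd).max() < 1e-8

    def test_second_component_weaker_on_one_factor_data(self, planted):
        X, Y, groups, _ = planted
        model = run_scca(X, Y, groups,
                         grid=PenaltyGrid(pairs=((3, 3),), mode="sparsity"),
                         n_components=2, folds=3)
        corrs = [c.canonical_correlation for c in model.components]
        assert len(corrs) == 2
        assert corrs[1] < corrs[0]

    def test_empty_component_cannot_deflate(self, planted):
        X, Y, groups, _ = planted
        from microscca.scca import _empty_component

        comp = _empty_component(pd.RangeIndex(X.shape[1]), pd.RangeIndex(Y.shape[1]))
        with pytest.raises(ValueError):
            deflate(X, Y, comp)


class TestFinalCca:
    def test_single_column_selection_is_pearson_correlation(self, rng):
        n = 100
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        X = np.column_stack([x, x * 0 + rng.standard_normal(n)])
        Y = y[:, None]
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        groups = ["g0", "g0"]
        comp = final_cca(X, Y, ["g0"], ["y0"], groups)
        # both coded columns of g0 enter; compare against 2-vs-1 CCA oracle
        rho = cca_first_correlation_oracle(X, Y)
        assert abs(comp.canonical_correlation - rho) < 1e-8

    def test_matches_eigen_oracle_low_dimensional(self, rng):
        n = 150
        u = rng.standard_normal(n)
        X = rng.standard_normal((n, 6)) + 0.6 * u[:, None]
        Y = rng.standard_normal((n, 4)) + 0.6 * u[:, None]
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        groups = np.repeat([f"g{i}" for i in range(3)], 2)
        comp = final_cca(X, Y, [f"g{i}" for i in range(3)], ["y0", "y1", "y2", "y3"], groups)
        rho = cca_first_correlation_oracle(X, Y)
        assert abs(comp.canonical_correlation - rho) < 1e-10

    def test_ridge_stabilization_continuous_at_zero(self, rng):
        n = 80
        X = rng.standard_normal((n, 6))
        Y = rng.standard_normal((n, 4))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        groups = np.repeat([f"g{i}" for i in range(3)], 2)
        sel = [f"g{i}" for i in range(3)]
        feats = [f"y{j}" for j in range(4)]
        c0 = final_cca(X, Y, sel, feats, groups, ridge=1e-9)
        c1 = final_cca(X, Y, sel, feats, groups, ridge=0.0)
        assert abs(c0.canonical_correlation - c1.canonical_correlation) < 1e-6

    def test_empty_selection_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 3))
        with pytest.raises(ValueError):
            final_cca(X, Y, [], ["y0"], [0, 0, 1, 1])


class TestRunScca:
    def test_single_component_no_deflation(self, planted):
        X, Y, groups, _ = planted
        model = run_scca(X, Y, groups,
                         grid=PenaltyGrid(pairs=((2, 2),), mode="sparsity"),
                         n_components=1, folds=3)
        assert len(model.components) == 1
        assert len(model.deflation_history) == 1

    def test_invalid_component_count(self, planted):
        X, Y, groups, _ = planted
        with pytest.raises(ValueError):
            run_scca(X, Y, groups, n_components=0)

    def test_sklearn_estimator_roundtrip(self, planted):
        X, Y, groups, _ = planted
        est = SparseCCA(
            n_components=1,
            penalty_grid=PenaltyGrid(pairs=((2, 2),), mode="sparsity"),
            cv=3,
        )
        est.fit(X, Y, groups=groups)
        assert est.x_weights_.shape == (X.shape[1], 1)
        xs, ys = est.transform(X, Y)
        assert xs.shape == (X.shape[0], 1)
        params = est.get_params()
        assert params["n_components"] == 1
        est2 = SparseCCA(**params).fit(X, Y, groups=groups)
        np.testing.assert_allclose(est2.correlations_, est.correlations_)


class TestSelectionSummaries:
    def test_inclusion_exclusion_union(self):
        def comp(feats):
            return CanonicalComponent(
                beta=pd.Series(dtype=float), alpha=pd.Series(dtype=float),
                selected_snps=[], selected_features=feats,
                canonical_correlation=0.5, n_iterations=1, converged=True,
            )

        a = [f"s{i}" for i in range(134)]
        b = [f"s{i}" for i in range(134 - 66, 134 - 66 + 417)]
        summary = selection_summary([comp(a), comp(b)], n_total_features=655)
        assert summary["per_component"] == [134, 417]
        assert summary["pairwise_overlap"][(1, 2)] == 66
        assert summary["union"] == 134 + 417 - 66 == 485
        # 485/655 = 74.05% to two decimals (74.04 under truncation)
        assert summary["union_pct"] == pytest.approx(74.04, abs=0.02)
        assert summary["per_component_pct"][0] == pytest.approx(20.45, abs=0.02)
        assert summary["per_component_pct"][1] == pytest.approx(63.66, abs=0.02)

    def test_overlap_fraction(self):
        assert selection_overlap({"a", "b"}, {"b", "c"}) == 0.5
        assert selection_overlap(set(), {"x"}) == 0.0
        assert selection_overlap({"x"}, {"x"}) == 1.0
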