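import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromonet import (
    ClusteringStrengthModel,
    ContactMatrix,
    OptimizationConfig,
    build_network,
    build_triangle_constraints,
    build_triples,
    clustering_coefficients,
    pair_alpha,
    row_weights,
    wish_distances,
)
from chromonet.alpha import WishDistances, masked_row_correlations

from conftest import random_contact_matrix


# ---------------------------------------------------------------- oracles
def oracle_masked_pearson(m: np.ndarray, i: int, j: int) -> float:
    """Pearson between rows i and j with columns i, j removed."""
    a = m.copy()
    np.fill_diagonal(a, 0.0)
    cols = [k for k in range(m.shape[0]) if k not in (i, j)]
    x, y = a[i, cols], a[j, cols]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def oracle_triples(m: np.ndarray, p0: float) -> set:
    n = m.shape[0]
    out = set()
    for i, j, k in itertools.combinations(range(n), 3):
        ps = [
            oracle_masked_pearson(m, i, j),
            oracle_masked_pearson(m, i, k),
            oracle_masked_pearson(m, j, k),
        ]
        if all(np.isfinite(p) and p > p0 for p in ps):
            out.add((i, j, k))
    return out


def oracle_triangles(m: np.ndarray) -> set:
    a = m.copy()
    np.fill_diagonal(a, 0.0)
    n = m.shape[0]
    out = set()
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if (
                    abs(i - j) == 1
                    and i < j
                    and k != i
                    and k != j
                    and a[i, j] > 0
                    and a[i, k] > 0
                    and a[j, k] > 0
                ):
                    out.add((i, j, k))
    return out


# ------------------------------------------------------------- row weights
class TestRowWeights:
    def test_example(self, cm3):
        np.testing.assert_allclose(row_weights(cm3), [2, 6, 4])

    def test_zero_matrix(self):
        cm = ContactMatrix(values=np.zeros((3, 3)))
        np.testing.assert_array_equal(row_weights(cm), np.zeros(3))

    def test_linearity(self):
        cm = random_contact_matrix(8, seed=1)
        cm10 = ContactMatrix(values=cm.values * 10)
        np.testing.assert_allclose(row_weights(cm10), 10 * row_weights(cm))

    def test_diagonal_masked(self):
        m = np.full((3, 3), 2.0)
        np.fill_diagonal(m, 100.0)
        cm = ContactMatrix(values=m)
        np.testing.assert_allclose(row_weights(cm), [4, 4, 4])


# ------------------------------------------------------------- PT triples
class TestBuildTriples:
    def test_scalar_multiple_rows_perfectly_correlated(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cm = ContactMatrix(values=np.outer(v, v))
        triples = build_triples(cm, p0=0.99)
        assert (0, 1, 2) in {tuple(t) for t in triples}

    def test_matches_exhaustive_oracle(self):
        cm = random_contact_matrix(14, seed=7)
        for p0 in (0.3, 0.6, 0.95):
            got = {tuple(t) for t in build_triples(cm, p0=p0, max_triples=10**6)}
            assert got == oracle_triples(cm.values, p0)

    def test_independent_rows_empty_at_high_threshold(self):
        cm = random_contact_matrix(30, seed=11)
        assert len(build_triples(cm, p0=0.95)) == 0

    def test_zero_cap_gives_empty(self):
        v = np.arange(1.0, 7.0)
        cm = ContactMatrix(values=np.outer(v, v))
        assert len(build_triples(cm, p0=0.5, max_triples=0)) == 0

    def test_subsample_deterministic(self):
        v = np.arange(1.0, 11.0)
        cm = ContactMatrix(values=np.outer(v, v))
        a = build_triples(cm, p0=0.5, max_triples=10, seed=3)
        b = build_triples(cm, p0=0.5, max_triples=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_masked_correlation_matches_oracle(self):
        cm = random_contact_matrix(10, seed=5)
        p = masked_row_correlations(cm)
        for i in range(10):
            for j in range(i + 1, 10):
                assert p[i, j] == pytest.approx(
                    oracle_masked_pearson(cm.values, i, j), abs=1e-10
                )


# ---------------------------------------------------- triangle constraints
class TestTriangleConstraints:
    def test_full_4x4_enumeration(self, cm4_full):
        got = {tuple(t) for t in build_triangle_constraints(cm4_full)}
        assert got == {(0, 1, 2), (0, 1, 3), (1, 2, 0), (1, 2, 3), (2, 3, 0), (2, 3, 1)}

    def test_zero_pair_removes_triples(self):
        m = np.ones((4, 4)) * 2
        np.fill_diagonal(m, 0)
        m[0, 2] = m[2, 0] = 0.0
        cm = ContactMatrix(values=m)
        got = {tuple(t) for t in build_triangle_constraints(cm)}
        assert got == {(0, 1, 3), (1, 2, 3), (2, 3, 1)}

    def test_matches_brute_force_on_sparse_random(self):
        cm = random_contact_matrix(20, seed=9, density=0.5)
        got = {tuple(t) for t in build_triangle_constraints(cm, max_triangles=10**6)}
        assert got == oracle_triangles(cm.values)


# --------------------------------------------------------------- pair alpha
class TestPairAlpha:
    def test_equal_weights_arithmetic_mean(self):
        assert pair_alpha([0.2, 0.6], np.array([1.0, 1.0]), 0, 1) == pytest.approx(0.4)

    def test_weighted_mean(self):
        assert pair_alpha([0.2, 0.6], np.array([3.0, 1.0]), 0, 1) == pytest.approx(0.3)

    def test_constant_alpha_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w = rng.uniform(0.1, 10, size=2)
            assert pair_alpha([0.42, 0.42], w, 0, 1) == pytest.approx(0.42)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero row weight"):
            pair_alpha([0.2, 0.6], np.array([0.0, 0.0]), 0, 1)

    @settings(max_examples=50, derandomize=True)
    @given(
        a0=st.floats(0, 1), a1=st.floats(0, 1),
        w0=st.floats(1e-3, 1e3), w1=st.floats(1e-3, 1e3),
    )
    def test_bounded_by_endpoints(self, a0, a1, w0, w1):
        """The contact-weighted pair exponent is a convex combination."""
        val = pair_alpha([a0, a1], np.array([w0, w1]), 0, 1)
        assert min(a0, a1) - 1e-9 <= val <= max(a0, a1) + 1e-9


# ----------------------------------------------------------- wish distances
class TestWishDistances:
    def test_unit_contact_gives_unit_distance(self):
        m = np.ones((3, 3)) - np.eye(3)
        cm = ContactMatrix(values=m)
        wd = wish_distances(cm, np.array([0.1, 0.5, 0.9]))
        np.testing.assert_allclose(wd.delta, 1.0)

    def test_power_law_value(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 8.0
        m[1, 2] = m[2, 1] = 8.0
        cm = ContactMatrix(values=m)
        wd = wish_distances(cm, np.full(3, 1 / 3))
        np.testing.assert_allclose(wd.delta, 0.5)

    def test_monotone_decreasing_in_alpha_for_contact_above_one(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 16.0
        m[1, 2] = m[2, 1] = 16.0
        cm = ContactMatrix(values=m)
        d_small = wish_distances(cm, np.full(3, 0.25)).delta[0]
        d_large = wish_distances(cm, np.full(3, 0.75)).delta[0]
        assert d_small == pytest.approx(0.5) and d_large == pytest.approx(0.125)
        assert d_large < d_small

    def test_monotonicity_flips_below_unit_contact(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.5
        cm = ContactMatrix(values=m)
        d_small = wish_distances(cm, np.full(3, 0.25)).delta[0]
        d_large = wish_distances(cm, np.full(3, 0.75)).delta[0]
        assert d_large > d_small

    def test_defined_exactly_on_nonzero_pairs(self, cm3):
        wd = wish_distances(cm3, np.full(3, 0.5))
        assert set(zip(wd.i.tolist(), wd.j.tolist())) == {(0, 1), (1, 2)}

    def test_tsv_round_trip(self, tmp_path, cm3):
        wd = wish_distances(cm3, np.full(3, 0.5))
        p = tmp_path / "wd.tsv"
        wd.to_tsv(p)
        back = WishDistances.from_tsv(p, n=3)
        np.testing.assert_allclose(back.delta, wd.delta)
        np.testing.assert_allclose(back.alpha, wd.alpha)

    @pytest.mark.parametrize(
        "kwargs, msg",
        [
            (dict(n=3, i=[0], j=[0], delta=[1.0]), "distinct"),
            (dict(n=3, i=[0], j=[1], delta=[-1.0]), "positive"),
            (dict(n=3, i=[0], j=[1], delta=[1.0], alpha=[1.5]), r"\[0, 1\]"),
        ],
    )
    def test_validation(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            WishDistances(**kwargs)


# -------------------------------------------------------------- the solver
class TestSolveAlpha:
    def test_closed_form_when_smoothing_off(self):
        """With lambda3 = 0 and no active constraints the optimum is
        alpha_i = lambda2 * CC_i exactly."""
        cm = random_contact_matrix(30, seed=4, density=0.4)
        cfg = OptimizationConfig(lambda3=0.0, lambda2=0.8, max_triangles=0, seed=0)
        res = ClusteringStrengthModel(cm, config=cfg).fit()
        cc = clustering_coefficients(build_network(cm))
        ok = np.isfinite(res.alpha)
        np.testing.assert_allclose(res.alpha[ok], 0.8 * cc[ok], atol=1e-6)
        assert res.converged

    def test_large_smoothing_equalizes_triple(self):
        """lambda3 >> lambda1 with one PT triple pulls the three strengths
        together."""
        cm = random_contact_matrix(8, seed=6)
        cfg = OptimizationConfig(
            lambda1=1e-3, lambda3=1e3, max_triangles=0, gtol=1e-12, seed=0
        )
        model = ClusteringStrengthModel(
            cm, config=cfg, triples=np.array([[0, 1, 2]])
        )
        res = model.fit()
        a = res.alpha
        assert abs(a[0] - a[2]) < 1e-4 and abs(a[1] - a[2]) < 1e-4

    def test_interior_optimum_matches_kkt_oracle(self):
        """Unconstrained case is a convex quadratic: the stationary point
        of (l1 I + l3 Q) x = l1 t is the exact optimum when interior."""
        cm = random_contact_matrix(12, seed=8)
        triples = np.array([[0, 1, 2], [3, 4, 5], [1, 4, 7]])
        cfg = OptimizationConfig(
            lambda1=1.0, lambda2=0.7, lambda3=0.5, max_triangles=0, seed=0
        )
        model = ClusteringStrengthModel(cm, config=cfg, triples=triples)
        res = model.fit()
        h = model.hessian().toarray() / 2.0  # = l1 I + l3 Q
        t = 0.7 * model.cc
        x_star = np.linalg.solve(h, 1.0 * t)
        assert np.all(x_star > 0) and np.all(x_star < 1), "oracle must be interior"
        np.testing.assert_allclose(res.alpha, x_star, atol=1e-6)

    @pytest.mark.parametrize("backend", ["trust-constr", "penalty"])
    def test_bounds_hold_exactly(self, truth50, backend):
        cfg = OptimizationConfig(
            max_triples=500, max_triangles=500, seed=1, backend=backend
        )
        res = ClusteringStrengthModel(truth50.cm, config=cfg).fit()
        a = res.alpha[np.isfinite(res.alpha)]
        assert np.all(a >= 0.0) and np.all(a <= 1.0)

    def test_backends_agree_on_constrained_problem(self, truth50):
        results = {}
        for backend in ("trust-constr", "penalty"):
            cfg = OptimizationConfig(
                max_triples=300, max_triangles=300, seed=1, backend=backend
            )
            results[backend] = ClusteringStrengthModel(truth50.cm, config=cfg).fit()
        f1 = results["trust-constr"].objective_value
        f2 = results["penalty"].objective_value
        assert f1 == pytest.approx(f2, rel=5e-2, abs=1e-6)
        for res in results.values():
            assert res.diagnostics["max_triangle_violation"] <= res.model.config.tol

    def test_objective_not_above_initial_when_unconstrained(self, truth50):
        """Without triangle constraints the initialization is feasible, so
        the solver can only improve on it.  (With hard constraints an
        infeasible initialization legitimately forces the objective up.)"""
        cfg = OptimizationConfig(max_triples=500, max_triangles=0, seed=1)
        res = ClusteringStrengthModel(truth50.cm, config=cfg).fit()
        assert res.objective_value <= res.diagnostics["initial_objective"] + 1e-12

    def test_triangle_residuals_within_tolerance(self, fitted50):
        assert fitted50.diagnostics["max_triangle_violation"] <= 1e-4

    def test_unmappable_beads_get_nan(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 4.0
        m[1, 2] = m[2, 1] = 2.0
        cm = ContactMatrix(values=m)  # bead 3 has no contacts
        cfg = OptimizationConfig(max_triangles=0, max_triples=0)
        res = ClusteringStrengthModel(cm, config=cfg).fit()
        assert np.isnan(res.alpha[3])
        assert res.diagnostics["n_unmappable_beads"] == 1
        wd = res.wish_distances()
        assert 3 not in set(wd.i) | set(wd.j)

    def test_results_summary_mentions_status(self, fitted50):
        text = fitted50.summary()
        assert "converged" in text and "triangle" in text

    def test_deterministic_given_seed(self, truth50, small_config):
        a = ClusteringStrengthModel(truth50.cm, config=small_config).fit()
        b = ClusteringStrengthModel(truth50.cm, config=small_config).fit()
        np.testing.assert_array_equal(a.alpha, b.alpha)
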