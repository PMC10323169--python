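import numpy as np
import pytest

from isresplus import (
    Archive,
    BoundsBox,
    Individual,
    StagnationGuard,
    cluster_diameter,
    fit_hyperplane,
    fit_quadric,
    linstep_offspring,
    newton_offspring,
    select_cluster,
    update_archive,
)
from isresplus.lls import NotEnoughPoints, OperatorSkip, quadric_min_points

from conftest import make_cluster


def ind(x, f=0.0, phi=0.0, eta=None, origin="mutation", gen=0):
    x = np.asarray(x, float)
    return Individual(
        x=x, eta=np.ones_like(x) if eta is None else np.asarray(eta, float),
        f=float(f), phi=float(phi), feasible=phi == 0.0, origin=origin,
        generation_born=gen,
    )


class TestArchive:
    def test_append_grows_by_generation_size(self):
        arch = Archive(2)
        update_archive(arch, [ind([i, 0], f=i) for i in range(10)])
        assert len(arch) == 10
        for g in range(4):
            update_archive(arch, [ind([i, g], f=i, gen=g) for i in range(10)])
        assert len(arch) == 50

    def test_records_round_trip_unchanged(self):
        arch = Archive(2)
        original = ind([1.5, -2.0], f=3.25, phi=0.5, eta=[0.1, 0.2], origin="linstep", gen=7)
        arch.append([original])
        rec = arch.record(0)
        np.testing.assert_array_equal(rec.x, original.x)
        np.testing.assert_array_equal(rec.eta, original.eta)
        assert (rec.f, rec.phi, rec.feasible) == (3.25, 0.5, False)
        assert rec.origin == "linstep" and rec.generation_born == 7

    def test_rejects_unevaluated_individuals(self):
        arch = Archive(1)
        with pytest.raises(ValueError):
            arch.append([Individual(x=np.zeros(1), eta=np.ones(1))])

    def test_ring_buffer_capacity_keeps_most_recent(self):
        arch = Archive(1, capacity=5)
        arch.append([ind([i], f=i) for i in range(8)])
        assert len(arch) == 5
        np.testing.assert_array_equal(arch.f, [3, 4, 5, 6, 7])


class TestClusterSelection:
    def test_nearest_members_by_inspection(self):
        bounds = BoundsBox(np.zeros(2), np.full(2, 10.0))
        arch = Archive(2)
        arch.append([ind([1, 0], f=1), ind([3, 0], f=2), ind([0.5, 0], f=3)])
        best = ind([0, 0], f=0)
        cluster = select_cluster(arch, best, 2, bounds)
        np.testing.assert_allclose(cluster.member_x, [[0.5, 0], [1, 0]])
        assert cluster.complete

    def test_k_exceeding_archive_returns_all_with_flag(self):
        bounds = BoundsBox(np.zeros(2), np.full(2, 10.0))
        arch = Archive(2)
        arch.append([ind([1, 1], f=1), ind([2, 2], f=2)])
        cluster = select_cluster(arch, ind([0, 0], f=0), 10, bounds)
        assert cluster.k == 2 and not cluster.complete

    def test_matches_exhaustive_distance_sort(self):
        rng = np.random.default_rng(5)
        bounds = BoundsBox(np.array([0.0, 0.0]), np.array([10.0, 1000.0]))
        pts = np.column_stack([rng.uniform(0, 10, 200), rng.uniform(0, 1000, 200)])
        arch = Archive(2)
        arch.append([ind(p, f=i) for i, p in enumerate(pts)])
        best = ind([5.0, 500.0], f=-1)
        k = 17
        cluster = select_cluster(arch, best, k, bounds)
        # oracle: brute-force normalized distances
        z = (pts - bounds.lower) / (bounds.upper - bounds.lower)
        z0 = (best.x - bounds.lower) / (bounds.upper - bounds.lower)
        d = np.sqrt(((z - z0) ** 2).sum(axis=1))
        expected = pts[np.argsort(d, kind="stable")[:k]]
        np.testing.assert_allclose(cluster.member_x, expected)

    def test_infeasible_records_are_never_used(self):
        bounds = BoundsBox(np.zeros(2), np.full(2, 10.0))
        arch = Archive(2)
        arch.append(
            [ind([0.1, 0], f=1, phi=3.0), ind([5, 5], f=2), ind([0.2, 0], f=5, phi=0.1)]
        )
        cluster = select_cluster(arch, ind([0, 0], f=0), 2, bounds)
        np.testing.assert_allclose(cluster.member_x, [[5, 5]])

    def test_duplicates_of_best_excluded(self):
        bounds = BoundsBox(np.zeros(2), np.full(2, 10.0))
        arch = Archive(2)
        arch.append([ind([1, 1], f=0), ind([1, 1], f=0), ind([2, 2], f=1)])
        cluster = select_cluster(arch, ind([1, 1], f=0), 3, bounds)
        np.testing.assert_allclose(cluster.member_x, [[2, 2]])


class TestDiameter:
    def test_three_four_five_triangle(self):
        c = make_cluster([0, 0], lambda x: 0.0, [[3, 4]])
        assert cluster_diameter(c) == pytest.approx(5.0)

    def test_singleton_is_zero(self):
        c = make_cluster([2, 2], lambda x: 0.0, np.empty((0, 2)))
        assert cluster_diameter(c) == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        c = make_cluster(pts[0], lambda x: 0.0, pts[1:])
        expected = max(
            np.linalg.norm(a - b) for i, a in enumerate(pts) for b in pts[i + 1:]
        )
        assert cluster_diameter(c) == pytest.approx(expected)


class TestHyperplaneFit:
    def test_exact_linear_function_recovered(self):
        f = lambda x: 2 * x[0] - 3 * x[1] + 1
        c = make_cluster([0, 0], f, [[1, 0], [0, 1]])
        fit = fit_hyperplane(c)
        assert fit.condition_ok
        np.testing.assert_allclose(fit.gradient, [2, -3], atol=1e-10)

    def test_constant_function_has_zero_gradient(self):
        c = make_cluster([0, 0], lambda x: 7.0, [[1, 0], [0, 1]])
        np.testing.assert_allclose(fit_hyperplane(c).gradient, 0.0, atol=1e-12)

    def test_random_linear_matches_direct_solve_oracle(self):
        rng = np.random.default_rng(11)
        n = 4
        a0, a = rng.normal(), rng.normal(size=n)
        f = lambda x: a0 + a @ x
        pts = rng.normal(size=(n + 1, n))
        fit = fit_hyperplane(make_cluster(pts[0], f, pts[1:]))
        # oracle: solve the (n+1)x(n+1) interpolation system directly
        A = np.column_stack([np.ones(n + 1), pts])
        coef = np.linalg.solve(A, np.array([f(p) for p in pts]))
        np.testing.assert_allclose(fit.gradient, coef[1:], atol=1e-8)
        np.testing.assert_allclose(fit.gradient, a, atol=1e-8)

    def test_insufficient_points_signalled(self):
        c = make_cluster([0, 0], lambda x: 0.0, [[1, 1]])
        with pytest.raises(NotEnoughPoints):
            fit_hyperplane(c)

    def test_degenerate_cluster_flags_condition(self):
        # three collinear points cannot determine a 2-d gradient
        f = lambda x: x[0] + x[1]
        c = make_cluster([0, 0], f, [[1, 0], [2, 0]])
        assert not fit_hyperplane(c).condition_ok


class TestQuadricFit:
    def quad(self):
        return lambda x: (x[0] - 1) ** 2 + (x[1] + 2) ** 2

    def test_exact_quadratic_reproduced(self, rng):
        pts = rng.normal(size=(quadric_min_points(2), 2)) * 2.0
        c = make_cluster([3.0, 0.0], self.quad(), pts)
        fit = fit_quadric(c)
        assert fit.condition_ok
        np.testing.assert_allclose(fit.hessian, 2 * np.eye(2), atol=1e-8)
        # stationary point from the fit: center - H^{-1} g
        x_star = c.center_x - np.linalg.solve(fit.hessian, fit.gradient)
        np.testing.assert_allclose(x_star, [1, -2], atol=1e-8)

    def test_pure_cross_term_hessian(self, rng):
        f = lambda x: x[0] * x[1]
        pts = rng.normal(size=(quadric_min_points(2), 2))
        fit = fit_quadric(make_cluster([0.0, 0.0], f, pts))
        np.testing.assert_allclose(fit.hessian, [[0, 1], [1, 0]], atol=1e-8)

    def test_random_spd_quadratic_recovered(self, rng):
        n = 3
        M = rng.normal(size=(n, n))
        H_true = M @ M.T + n * np.eye(n)
        g_true = rng.normal(size=n)
        x0 = rng.normal(size=n)
        f = lambda x: g_true @ (x - x0) + 0.5 * (x - x0) @ H_true @ (x - x0)
        pts = x0 + rng.normal(size=(12, n))
        fit = fit_quadric(make_cluster(x0, f, pts))
        np.testing.assert_allclose(fit.hessian, H_true, atol=1e-6)
        np.testing.assert_allclose(fit.gradient, g_true, atol=1e-6)

    def test_insufficient_members_signalled(self, rng):
        pts = rng.normal(size=(quadric_min_points(2) - 1, 2))
        with pytest.raises(NotEnoughPoints):
            fit_quadric(make_cluster([0.0, 0.0], lambda x: 0.0, pts))


class TestLinstep:
    def wide_box(self):
        return BoundsBox(np.full(2, -100.0), np.full(2, 100.0))

    def test_step_arithmetic_from_the_fit(self):
        f = lambda x: x[0]
        c = make_cluster([5.0, 5.0], f, [[5.0, 6.0]])  # diameter 1
        fit = fit_hyperplane(make_cluster([5.0, 5.0], f, [[6.0, 5.0], [5.0, 6.0]]))
        out = linstep_offspring(c, fit, 2.0, 1, self.wide_box(), np.random.default_rng(0))
        np.testing.assert_allclose(out[0].x, [3.0, 5.0], atol=1e-12)
        assert out[0].origin == "linstep"

    def test_displacement_scales_linearly_with_beta(self):
        f = lambda x: 3 * x[0] + 4 * x[1]
        c = make_cluster([0.0, 0.0], f, [[1.0, 0.0], [0.0, 1.0]])
        fit = fit_hyperplane(c)
        d = cluster_diameter(c)
        steps = {}
        for beta in (1.0, 2.0):
            (child,) = linstep_offspring(c, fit, beta, 1, self.wide_box(),
                                         np.random.default_rng(0))
            steps[beta] = np.linalg.norm(child.x - c.center_x)
            assert steps[beta] == pytest.approx(beta * d)
        assert steps[2.0] == pytest.approx(2 * steps[1.0])

    def test_descent_on_convex_quadratic(self):
        f = lambda x: float(np.sum(np.asarray(x) ** 2))
        center = np.array([40.0, 30.0])
        members = center + np.array([[1.0, 0.0], [0.0, 1.0]])
        c = make_cluster(center, f, members)
        fit = fit_hyperplane(c)
        out = linstep_offspring(c, fit, 1.0, 2, self.wide_box(), np.random.default_rng(0))
        for child in out:
            assert f(child.x) < f(center)

    def test_zero_gradient_skips(self):
        c = make_cluster([0.0, 0.0], lambda x: 5.0, [[1.0, 0.0], [0.0, 1.0]])
        fit = fit_hyperplane(c)
        with pytest.raises(OperatorSkip):
            linstep_offspring(c, fit, 2.0, 1, self.wide_box(), np.random.default_rng(0))


class TestNewtonStep:
    def setup_fit(self, rng, center=(3.0, 0.0)):
        f = lambda x: (x[0] - 1) ** 2 + (x[1] + 2) ** 2
        pts = np.asarray(center) + rng.normal(size=(quadric_min_points(2), 2))
        c = make_cluster(center, f, pts)
        return c, fit_quadric(c)

    def test_full_step_lands_on_stationary_point(self, rng):
        box = BoundsBox(np.full(2, -50.0), np.full(2, 50.0))
        c, fit = self.setup_fit(rng)
        best = ind(c.center_x, f=c.center_f)
        (child,) = newton_offspring(best, fit, 1, "full_step", np.random.default_rng(0), box)
        np.testing.assert_allclose(child.x, [1, -2], atol=1e-8)
        assert child.origin == "newton"

    def test_damped_step_interpolates_along_newton_direction(self, rng):
        box = BoundsBox(np.full(2, -50.0), np.full(2, 50.0))
        c, fit = self.setup_fit(rng, center=(3.0, 0.0))
        best = ind(c.center_x, f=c.center_f)
        rng_beta = np.random.default_rng(99)
        beta = 1.0 - np.random.default_rng(99).random()
        (child,) = newton_offspring(best, fit, 1, "uniform_random", rng_beta, box)
        expected = best.x - beta * np.linalg.solve(fit.hessian, fit.gradient)
        np.testing.assert_allclose(child.x, expected, atol=1e-10)
        # beta = 0.5 would give the midpoint (2, -1); check the line geometry
        direction = np.linalg.solve(fit.hessian, fit.gradient)
        np.testing.assert_allclose(best.x - 0.5 * direction, [2.0, -1.0], atol=1e-8)

    def test_full_steps_from_all_members_coincide(self, rng):
        """A full Newton step maps every cluster point to the same stationary
        point of the fitted quadric — the fixed-point property."""
        c, fit = self.setup_fit(rng)
        targets = []
        for xm in np.vstack([c.center_x[None, :], c.member_x]):
            g_m = fit.gradient + fit.hessian @ (xm - c.center_x)
            targets.append(xm - np.linalg.solve(fit.hessian, g_m))
        targets = np.asarray(targets)
        np.testing.assert_allclose(targets, np.tile([1.0, -2.0], (len(targets), 1)), atol=1e-8)

    def test_singular_hessian_skips(self):
        from isresplus import SurfaceFit

        fit = SurfaceFit(
            order=2, gradient=np.array([1.0, 0.0]),
            hessian=np.array([[2.0, 0.0], [0.0, 0.0]]),  # flat in x2
        )
        best = ind([3.0, 0.0], f=4.0)
        box = BoundsBox(np.full(2, -50.0), np.full(2, 50.0))
        with pytest.raises(OperatorSkip):
            newton_offspring(best, fit, 1, "full_step", np.random.default_rng(0), box)


class TestStagnationGuard:
    def test_active_above_threshold(self):
        guard = StagnationGuard(eps=1e-6)
        assert guard.decide(0.5, incumbent_improved=False)

    def test_silenced_below_threshold_without_improvement(self):
        guard = StagnationGuard(eps=1e-6)
        assert not guard.decide(1e-9, incumbent_improved=False)
        assert not guard.decide(0.5, incumbent_improved=False)  # stays silenced

    def test_improvement_reactivates(self):
        guard = StagnationGuard(eps=1e-6)
        guard.decide(1e-9, incumbent_improved=False)
        assert guard.decide(1e-9, incumbent_improved=True)
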