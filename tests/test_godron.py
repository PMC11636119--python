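import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from sandstab import (GodronStability, STABILITY_POINT, STABILITY_THRESHOLD,
                      FittedCurve, LifeForm, SpeciesObservation,
                      assess_stability, build_cumulative_curve,
                      classify_stability, distance_to_stability_point,
                      fit_smooth_curve, intersect_with_antidiagonal,
                      shares_matching_curve)
from sandstab.errors import (DegenerateInputError, FitError,
                             NoIntersectionError)

from conftest import STABILITY_ROWS


def fitted(c0, c1, c2):
    return FittedCurve(degree=2 if c2 else 1, coefficients=(c0, c1, c2),
                       r_squared=1.0)


class TestCumulativeCurve:
    def test_single_species(self):
        curve = build_cumulative_curve({"a": 30.0})
        assert curve.points == ((100.0, 100.0),)

    def test_two_species_forced_arithmetic(self):
        curve = build_cumulative_curve({"a": 80.0, "b": 20.0})
        assert curve.points[0] == pytest.approx((50.0, 80.0))
        assert curve.points[1] == pytest.approx((100.0, 100.0))

    def test_geometric_closed_form(self):
        # coverages in geometric ratio 0.8: cumulative share after the top
        # 5 of 21 species is (1 - 0.8^5) / (1 - 0.8^21)
        cov = {f"s{i:02d}": 0.8 ** i for i in range(21)}
        curve = build_cumulative_curve(cov)
        x5, y5 = curve.points[4]
        assert x5 == pytest.approx(100 * 5 / 21)
        assert y5 == pytest.approx(
            100 * (1 - 0.8 ** 5) / (1 - 0.8 ** 21), abs=1e-9)

    def test_zero_total_degenerate(self):
        with pytest.raises(DegenerateInputError):
            build_cumulative_curve({"a": 0.0, "b": 0.0})

    def test_scale_invariance(self):
        cov = {"a": 5.0, "b": 3.0, "c": 1.5, "d": 0.5}
        c1 = build_cumulative_curve(cov)
        c2 = build_cumulative_curve({k: 7.3 * v for k, v in cov.items()})
        assert np.allclose(c1.x, c2.x) and np.allclose(c1.y, c2.y)
        r1 = GodronStability(cov).fit()
        r2 = GodronStability({k: 7.3 * v for k, v in cov.items()}).fit()
        assert r1.distance == pytest.approx(r2.distance, abs=1e-12)


class TestFit:
    def test_recovers_exact_linear_model(self):
        # points exactly on y = 0.5x + 50, a line through (100, 100)
        from sandstab.godron import CumulativeCurve
        x = np.array([20, 40, 60, 80, 100.0])
        exact = CumulativeCurve(
            points=tuple((xi, 0.5 * xi + 50.0) for xi in x), S=5)
        fit = fit_smooth_curve(exact, degree=1)
        assert fit.coefficients[:2] == pytest.approx((50.0, 0.5), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_recovers_exact_quadratic_model(self):
        # y = -0.002x^2 + 0.7x + 50 is monotone on [0, 100], stays below
        # 100 and passes through (100, 100): a legal cumulative profile
        from sandstab.godron import CumulativeCurve
        c0, c1, c2 = 50.0, 0.7, -0.002
        x = np.array([20, 40, 60, 80, 100.0])
        exact = CumulativeCurve(
            points=tuple((xi, c0 + c1 * xi + c2 * xi ** 2) for xi in x), S=5)
        fit = fit_smooth_curve(exact, degree=2)
        assert fit.coefficients == pytest.approx((c0, c1, c2), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degree2_residual_never_worse_than_degree1(self, community_seed1):
        from sandstab import Position, StratumKey, stratify
        d, _ = community_seed1
        obs = stratify(d, StratumKey(45, Position.outside_crown))
        model = GodronStability.from_observations(obs)
        x, y = model.curve.x, model.curve.y
        for deg in (1, 2):
            fit = fit_smooth_curve(model.curve, degree=deg)
            res = y - fit(x)
            if deg == 1:
                ss1 = float(res @ res)
            else:
                ss2 = float(res @ res)
        assert ss2 <= ss1 + 1e-12

    def test_insufficient_points(self):
        curve = build_cumulative_curve({"a": 8.0, "b": 2.0})
        with pytest.raises(FitError):
            fit_smooth_curve(curve, degree=2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_fit_matches_normal_equations_oracle(self, seed):
        """OLS fit agrees with an independent normal-equations solve."""
        rng = np.random.default_rng(seed)
        S = int(rng.integers(4, 25))
        shares = rng.dirichlet(np.ones(S) * rng.uniform(0.3, 3))
        cov = {f"s{i:03d}": float(v) + 1e-6 for i, v in enumerate(shares)}
        curve = build_cumulative_curve(cov)
        fit = fit_smooth_curve(curve, degree=2)
        X = np.vander(curve.x, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ curve.y)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)


class TestIntersection:
    @pytest.mark.parametrize("coeffs,x_expected", [
        ((12.54, 2.287, -0.014), 30.59),
        ((20.09, 1.82, -0.010), 31.96),
    ])
    def test_published_curves(self, coeffs, x_expected):
        x, y = intersect_with_antidiagonal(fitted(*coeffs))
        assert x == pytest.approx(x_expected, abs=0.005)
        assert y == pytest.approx(100 - x, abs=1e-9)

    def test_constant_curve_at_stability_level(self):
        assert intersect_with_antidiagonal(fitted(80.0, 0.0, 0.0)) == \
            pytest.approx((20.0, 80.0))

    def test_matches_bisection_oracle(self):
        f = fitted(20.09, 1.82, -0.010)
        x, _ = intersect_with_antidiagonal(f)
        x_bis = brentq(lambda t: f(t) - (100 - t), 0, 100, xtol=1e-10)
        assert x == pytest.approx(x_bis, abs=1e-6)
        assert x == pytest.approx(31.96, abs=0.005)

    def test_no_intersection(self):
        with pytest.raises(NoIntersectionError):
            intersect_with_antidiagonal(fitted(150.0, 1.0, 0.01))

    @given(st.integers(0, 10_000))
    @settings(max_examples=1000, deadline=None)
    def test_closed_form_equals_bisection_on_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        c2 = rng.uniform(-0.02, -0.001)
        c1 = rng.uniform(0.8, 2.5)
        c0 = rng.uniform(0.0, 40.0)
        f = fitted(c0, c1, c2)
        g = lambda t: f(t) - (100 - t)
        if g(0) > 0 or g(100) < 0:  # ensure a bracketed in-range root
            return
        x, y = intersect_with_antidiagonal(f)
        x_bis = brentq(g, 0, 100, xtol=1e-9)
        assert x == pytest.approx(x_bis, abs=1e-6)
        assert x + y == pytest.approx(100.0, abs=1e-9)
        # identity: Euclidean distance equals sqrt(2)|x*-20| on the line
        assert distance_to_stability_point((x, y)) == \
            pytest.approx(math.sqrt(2) * abs(x - 20), abs=1e-9)


class TestDistanceAndVerdict:
    @pytest.mark.parametrize("point,expected", [
        ((20.0, 80.0), 0.0),
        ((29.88, 70.12), 13.97),
        ((30.38, 69.62), 14.68),
        ((33.95, 66.05), 19.73),
        ((45.48, 54.52), 36.03),
    ])
    def test_distance_published_intersections(self, point, expected):
        assert round(distance_to_stability_point(point), 2) == expected

    def test_threshold_constant(self):
        assert STABILITY_THRESHOLD == pytest.approx(14.142, abs=5e-4)
        assert STABILITY_THRESHOLD == math.sqrt(10 ** 2 + 10 ** 2)

    def test_classification_inclusive_at_threshold(self):
        assert classify_stability(14.142)
        assert classify_stability(STABILITY_THRESHOLD)
        assert not classify_stability(14.143)
        assert classify_stability(0.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(DegenerateInputError):
            classify_stability(-0.1)


class TestEndToEnd:
    def mk_obs(self, coverages):
        return [SpeciesObservation("q1", s, LifeForm.perennial_herb,
                                   height=10.0, coverage=c, density=1.0)
                for s, c in coverages.items()]

    def test_curve_through_stability_point_has_zero_distance(self):
        # a constant fitted curve at y=80 crosses the line exactly at (20,80)
        f = fitted(80.0, 0.0, 0.0)
        x, y = intersect_with_antidiagonal(f)
        d = distance_to_stability_point((x, y))
        assert d == pytest.approx(0.0, abs=1e-9)
        assert classify_stability(d)

    def test_engineered_45yr_outside_stratum(self):
        """A stratum built to reproduce the published 45-yr outside-crown
        fit yields distance 13.97 (2 dp) and a 'stable' verdict under the
        inclusive <= 14.142 rule."""
        shares = shares_matching_curve((26.09, 1.772, -0.010), S=21)
        res = GodronStability(shares).fit(paper_compat=True)
        assert res.intersection == (29.88, 70.12)
        assert res.distance == 13.97
        assert res.stable  # 13.97 <= 14.142
        full = GodronStability(shares).fit()
        assert full.distance == pytest.approx(13.97, abs=0.02)

    def test_stagewise_recomposition(self, community_seed1):
        from sandstab import Position, StratumKey, stratify
        d, _ = community_seed1
        obs = stratify(d, StratumKey(25, Position.under_crown))
        res = GodronStability.from_observations(obs).fit()
        cov = {}
        for o in obs:
            cov[o.species] = cov.get(o.species, 0.0) + o.coverage
        curve = build_cumulative_curve(cov)
        fit = fit_smooth_curve(curve, degree=2)
        x, y = intersect_with_antidiagonal(fit)
        dist = distance_to_stability_point((x, y))
        assert res.params == pytest.approx(fit.coefficients)
        assert res.intersection == pytest.approx((x, y))
        assert res.distance == pytest.approx(dist)
        assert res.stable == classify_stability(dist)
        assert assess_stability(obs).distance == pytest.approx(dist)

    def test_two_species_fallback_to_linear(self):
        res = GodronStability.from_observations(
            self.mk_obs({"a": 60.0, "b": 40.0})).fit()
        assert res.fitted_curve.degree == 1

    def test_monotone_dominance_sweep(self):
        """For two-species strata the intersection x* falls strictly as the
        dominant's share grows, so the distance to (20, 80) is V-shaped:
        it shrinks while the community approaches the 20/80 configuration
        from the even side (x* > 20) and grows once dominance pushes x*
        past it. The closed form x*(s) = 200(1-s)/(3-2s) crosses 20 at
        s = 0.875."""
        shares = np.linspace(0.55, 0.95, 17)
        xs, distances = [], []
        for share in shares:
            res = GodronStability.from_observations(
                self.mk_obs({"a": 100 * share,
                             "b": 100 * (1 - share)})).fit()
            xs.append(res.intersection[0])
            distances.append(res.distance)
        assert all(b < a for a, b in zip(xs, xs[1:]))
        for share, x in zip(shares, xs):
            assert x == pytest.approx(200 * (1 - share) / (3 - 2 * share),
                                      abs=1e-9)
        past = [d for s, d in zip(shares, distances) if s >= 0.875]
        assert all(b >= a - 1e-9 for a, b in zip(past, past[1:]))

    def test_summary_mentions_verdict(self):
        res = GodronStability(
            shares_matching_curve((26.09, 1.772, -0.010), S=21)
        ).fit(paper_compat=True)
        text = res.summary()
        assert "13.97" in text and "stable" in text

    def test_plot_returns_axis(self):
        import matplotlib
        matplotlib.use("Agg")
        res = GodronStability({"a": 50.0, "b": 30, "c": 15, "d": 5}).fit()
        ax = res.plot()
        assert ax.get_xlabel().startswith("cumulative")


class TestPublishedTable:
    @pytest.mark.parametrize("year,pos,coeffs,x_printed,dist_printed",
                             STABILITY_ROWS)
    def test_closed_form_reproduces_published_row(self, year, pos, coeffs,
                                                  x_printed, dist_printed):
        x, y = intersect_with_antidiagonal(fitted(*coeffs))
        # printed coefficients are rounded, so allow 0.02 on x*
        assert x == pytest.approx(x_printed, abs=0.02)
        d = round(distance_to_stability_point((round(x, 2), round(y, 2))), 2)
        assert d == pytest.approx(dist_printed, abs=0.03)
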