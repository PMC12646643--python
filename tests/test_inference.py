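"""Likelihood, MLE refinement, profile-likelihood CIs, and the APM metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telinfer.cme import ParamVector
from telinfer.inference import (
    APMConfig,
    CI_THRESHOLD,
    CountHistogram,
    _ci_from_curve,
    _profile_one,
    apm,
    classify_identifiability,
    fit_mle,
    log_likelihood,
    profile_all,
    ProfileCurve,
    ProfileResult,
)
from telinfer.library import GridSpec
from telinfer.noise import CaptureModel, captured_marginal
from telinfer.synthetic import sample_histogram


class TestCountHistogram:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            CountHistogram(counts=np.array([1.5, 2.0]))
        with pytest.raises(ValueError):
            CountHistogram(counts=np.array([-1, 2]))

    def test_from_cells_round_trip(self):
        hist = CountHistogram.from_cells([0, 0, 3, 1, 3, 3])
        np.testing.assert_array_equal(hist.counts, [2, 1, 0, 3])
        assert hist.N == 6


class TestLogLikelihood:
    def test_zero_count_cells(self, theta_identifiable):
        p0 = captured_marginal(theta_identifiable, CaptureModel(1.0)).probabilities[0]
        hist = CountHistogram(counts=np.array([5]))
        assert log_likelihood(hist, theta_identifiable) == pytest.approx(
            5 * np.log(p0)
        )

    def test_linear_in_counts(self, theta_identifiable):
        hist = CountHistogram.from_cells([0, 2, 5, 5, 9])
        double = CountHistogram(counts=2 * hist.counts)
        ll1 = log_likelihood(hist, theta_identifiable)
        ll2 = log_likelihood(double, theta_identifiable)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_truth_beats_perturbations_at_large_n(self, theta_identifiable):
        # LLN: with 10^4 cells the generating parameters dominate a
        # surrounding 5^3 multiplicative perturbation grid in most seeds
        factors = 1.6 ** np.arange(-2, 3)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            hist = sample_histogram(theta_identifiable, 10_000, seed=seed)
            ll_true = log_likelihood(hist, theta_identifiable)
            best_other = -np.inf
            for a in factors:
                for b in factors:
                    for c in factors:
                        if a == b == c == 1.0:
                            continue
                        th = ParamVector(
                            theta_identifiable.kon * a,
                            theta_identifiable.koff * b,
                            theta_identifiable.ksyn * c,
                        )
                        best_other = max(best_other, log_likelihood(hist, th))
            wins += ll_true >= best_other
        assert wins >= int(0.9 * n_seeds)


class TestFitMLE:
    def test_recovers_grid_point_target(self, mini_library):
        # exact distribution from a grid point: self-consistency
        flat = int(np.ravel_multi_index((3, 5, 8), mini_library.grid.shape))
        theta = mini_library.grid.param_at(flat)
        fit = fit_mle((mini_library.marginal_at(flat), 200.0), mini_library)
        for got, want in zip(fit.theta.as_array(), theta.as_array()):
            assert abs(got / want - 1) < 1e-3

    def test_all_zero_cells_pins_boundary(self, mini_library):
        hist = CountHistogram(counts=np.array([50]))
        fit = fit_mle(hist, mini_library)
        assert any(
            f["lower"] or f["upper"] for f in fit.boundary_flags.values()
        )


class TestProfileMachinery:
    def test_quadratic_toy_ci_half_width(self):
        # parabola in log10 with curvature c: CI half-width sqrt(1.92/c)
        c = 8.0
        center = 0.3
        values = np.linspace(-3, 3, 601)
        pl = c * (values - center) ** 2
        (lb, ub), lo_edge, hi_edge = _ci_from_curve(
            values, pl, 0.0, (1e-3, 1e3)
        )
        half = np.sqrt(CI_THRESHOLD / c)
        assert not lo_edge and not hi_edge
        assert np.log10(ub) == pytest.approx(center + half, abs=2e-2)
        assert np.log10(lb) == pytest.approx(center - half, abs=2e-2)

    def test_flat_curve_pins_both_edges(self):
        values = np.linspace(-3, 3, 40)
        (lb, ub), lo_edge, hi_edge = _ci_from_curve(
            values, np.zeros_like(values), 0.0, (1e-3, 1e3)
        )
        assert lo_edge and hi_edge
        assert lb == pytest.approx(1e-3)
        assert ub == pytest.approx(1e3)

    def test_profile_of_quadratic_objective(self):
        # separable quadratic: profiling must recover each marginal parabola
        center = np.array([-0.5, 0.2, 1.0])
        curv = np.array([2.0, 5.0, 9.0])

        def objective(x):
            return float(curv @ (np.asarray(x) - center) ** 2)

        grid = GridSpec(n_points=12)
        bounds = [(-3, 3), (-3, 3), (-0.3, 2.3)]
        values, pl = _profile_one(objective, 1, center, 0.0, bounds, grid)
        expected = curv[1] * (values - center[1]) ** 2
        np.testing.assert_allclose(pl, expected, atol=1e-4)


class TestAPM:
    def test_worked_examples(self):
        assert apm((0.05, 5.0), 100.0) == pytest.approx(1.0)
        assert apm((2.0, 2.0), 3.0) == 0.0
        assert apm((1.0, 3.0), 3.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            apm((0.0, 1.0), 3.0)

    @given(
        st.floats(1e-3, 1e3), st.floats(1.0, 1e3), st.floats(1.5, 50), st.floats(1.05, 3)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decreasing_in_tolerance_factor(self, lb, ratio, T, bump):
        ci = (lb, lb * ratio)
        assert apm(ci, T * bump) <= apm(ci, T) + 1e-12

    def test_classification_uses_maximum(self):
        def fake(apms):
            curves = {
                name: ProfileCurve(name, np.array([1.0]), np.array([0.0]),
                                   (1.0, 1.0), False, False, a)
                for name, a in zip(("kon", "koff", "ksyn"), apms)
            }
            return ProfileResult(ParamVector(1, 1, 1), 0.0, curves, np.nan, False)

        ok, overall = classify_identifiability(fake((0.2, 0.5, 0.9)))
        assert ok and overall == pytest.approx(0.9)
        bad, overall = classify_identifiability(fake((0.2, 0.5, 1.5)))
        assert not bad and overall == pytest.approx(1.5)


class TestCoverage:
    def test_profile_ci_covers_truth_near_95_percent(self, mini_library):
        # membership check: the true koff is inside the profile CI iff its
        # profiled objective is within the chi-square threshold of the min
        from telinfer.inference import WeightedNegLogLik, _refine

        theta = ParamVector(0.05, 0.1, 10.0)
        n_reps, n_cells = 60, 200
        covered = 0
        for seed in range(n_reps):
            hist = sample_histogram(theta, n_cells, seed=1000 + seed)
            fit = fit_mle(hist, mini_library)
            obj = WeightedNegLogLik(hist.count_vector(), CaptureModel(1.0))
            koff_log10 = np.log10(theta.koff)

            def f2(y):
                return obj(np.array([y[0], koff_log10, y[1]]))

            nb = [fit.bounds_log10[0], fit.bounds_log10[2]]
            x0 = np.log10([fit.theta.kon, fit.theta.ksyn])
            _, pl_true, _ = _refine(f2, x0, nb)
            covered += (pl_true - fit.minus_ll) <= CI_THRESHOLD + 1e-6
        # binomial(60, 0.95): central 99% range is roughly 52..60
        assert covered >= 51
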