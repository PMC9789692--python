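"""Response-curve families, landmarks, and nonlinear fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import quailarg as qa
from quailarg import reference
from quailarg.errors import DesignError, DomainError

SAT = reference.PUBLISHED_SATURATION        # (232, 21, 291, 3.413)
MONO = reference.PUBLISHED_MONOMOLECULAR    # (249, 11, 0.003934, 90)

saturation_params = st.builds(
    qa.SaturationParams,
    rmax=st.floats(100, 400), rmin=st.floats(1, 60),
    km=st.floats(100, 600), n=st.floats(1.2, 8.0),
)


class TestEvaluation:
    def test_saturation_midpoint_and_limits(self):
        assert qa.eval_saturation(SAT, SAT.km) == pytest.approx(126.5)
        assert qa.eval_saturation(SAT, 0.0) == pytest.approx(21.0)
        assert qa.eval_saturation(SAT, 1e9) == pytest.approx(232.0, rel=1e-6)
        # frozen direct evaluation at the standardized D5 intake
        assert qa.eval_saturation(SAT, 685.6) == pytest.approx(221.2518519)

    def test_monomolecular_shifted_anchor_and_limits(self):
        assert qa.eval_monomolecular(MONO, MONO.xm) == pytest.approx(-11.0)
        assert qa.eval_monomolecular(MONO, 1e7) == pytest.approx(249.0)
        assert qa.eval_monomolecular(MONO, 685.6) == pytest.approx(224.0320942)

    def test_printed_form_available_behind_flag(self):
        printed = qa.MonomolecularParams(249, 11, 0.003934, 90, form="printed")
        assert qa.eval_monomolecular(printed, 90.0) == pytest.approx(249.0)
        with pytest.raises(DomainError):
            qa.MonomolecularParams(249, 11, 0.003934, 90, form="wrong")

    @given(p=saturation_params)
    @settings(max_examples=50, deadline=None)
    def test_saturation_strictly_increasing(self, p):
        x = np.linspace(0, 5 * p.km, 200)
        y = qa.eval_saturation(p, x)
        assert np.all(np.diff(y) > 0)

    def test_monomolecular_shifted_strictly_increasing(self):
        x = np.linspace(0, 2000, 500)
        assert np.all(np.diff(qa.eval_monomolecular(MONO, x)) > 0)


class TestEfficiencyCurve:
    def test_matches_central_difference(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(5, 1500, 50)
        h = 1e-4
        for params in (SAT, MONO):
            num = (np.asarray(qa.eval_monomolecular(params, x + h)
                              if isinstance(params, qa.MonomolecularParams)
                              else qa.eval_saturation(params, x + h))
                   - np.asarray(qa.eval_monomolecular(params, x - h)
                                if isinstance(params, qa.MonomolecularParams)
                                else qa.eval_saturation(params, x - h))) / (2 * h)
            np.testing.assert_allclose(qa.efficiency_curve(params, x), num,
                                       rtol=1e-6)

    def test_saturation_derivative_vanishes_at_infinity(self):
        assert qa.efficiency_curve(SAT, 1e8) == pytest.approx(0.0, abs=1e-10)

    def test_monomolecular_slope_at_maintenance(self):
        # k (rmax + rmin) = 0.003934 x 260
        assert qa.efficiency_curve(MONO, MONO.xm) == pytest.approx(1.0228, abs=1e-4)


class TestLandmarks:
    def test_maintenance_published_values(self):
        per_kg, per_bird = qa.maintenance_intake(MONO, body_weight_kg=0.180)
        assert per_kg == 90.0
        assert per_bird == pytest.approx(28.5, abs=0.05)
        assert qa.maintenance_intake(SAT) == pytest.approx(144.0, abs=0.5)

    def test_maintenance_degenerate_cases(self):
        sym = qa.SaturationParams(rmax=100.0, rmin=99.999999, km=300.0, n=2.0)
        assert qa.maintenance_intake(sym) == pytest.approx(300.0, rel=1e-6)
        zero = qa.SaturationParams(rmax=100.0, rmin=0.0, km=300.0, n=2.0)
        with pytest.warns(UserWarning):
            assert qa.maintenance_intake(zero) == 0.0

    def test_saturation_maintenance_harmonic_mean_identity(self):
        x0 = qa.maintenance_intake(SAT)
        harmonic = 2 * SAT.rmin * SAT.rmax / (SAT.rmin + SAT.rmax)
        assert qa.eval_saturation(SAT, x0) == pytest.approx(harmonic, rel=1e-10)

    def test_inflection_published_value_and_oracle(self):
        x_star = qa.intake_at_max_slope(SAT)
        assert round(x_star) == 244
        oracle = minimize_scalar(lambda x: -qa.efficiency_curve(SAT, x),
                                 bounds=(1.0, 3000.0), method="bounded",
                                 options={"xatol": 1e-8})
        assert x_star == pytest.approx(oracle.x, abs=0.1)

    def test_max_efficiency_published_value_and_oracle(self):
        x_star = qa.intake_at_max_efficiency(SAT)
        assert round(x_star) == 377
        oracle = minimize_scalar(
            lambda x: -(qa.eval_saturation(SAT, x) - SAT.rmin) / x,
            bounds=(1.0, 5000.0), method="bounded", options={"xatol": 1e-8})
        assert x_star == pytest.approx(oracle.x, abs=0.1)

    def test_max_efficiency_special_cases(self):
        p2 = qa.SaturationParams(rmax=200, rmin=10, km=100.0, n=2.0)
        assert qa.intake_at_max_efficiency(p2) == pytest.approx(100.0)
        steep = qa.SaturationParams(rmax=200, rmin=10, km=100.0, n=40.0)
        assert qa.intake_at_max_slope(steep) == pytest.approx(100.0, rel=0.01)
        flat = qa.SaturationParams(rmax=200, rmin=10, km=100.0, n=0.9)
        with pytest.raises(DomainError):
            qa.intake_at_max_slope(flat)
        with pytest.raises(DomainError):
            qa.intake_at_max_efficiency(flat)

    @given(p=saturation_params)
    @settings(max_examples=50, deadline=None)
    def test_inflection_precedes_max_efficiency(self, p):
        assert qa.intake_at_max_slope(p) < qa.intake_at_max_efficiency(p)

    @given(p=st.builds(qa.SaturationParams,
                       rmax=st.floats(100, 400), rmin=st.floats(1, 60),
                       km=st.floats(100, 600), n=st.floats(2.05, 8.0)))
    @settings(max_examples=50, deadline=None)
    def test_landmark_ordering_above_quadratic_order(self, p):
        # km separates the landmarks only for n > 2: (n-1)^(1/n) < 1 below
        assert qa.intake_at_max_slope(p) < p.km < qa.intake_at_max_efficiency(p)


class TestFitResponse:
    X = np.linspace(100, 1100, 30)

    def test_saturation_noiseless_recovery(self):
        y = qa.eval_saturation(SAT, self.X)
        fit = qa.fit_response(self.X, y, family="saturation")
        for name in ("rmax", "rmin", "km", "n"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(SAT, name), rel=1e-6)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_standard_errors_and_stats_present(self):
        rng = np.random.default_rng(2)
        y = qa.eval_saturation(SAT, self.X) + rng.normal(0, 10, self.X.size)
        fit = qa.fit_response(self.X, y, family="saturation")
        assert np.all(fit.se >= 0) and np.all(np.isfinite(fit.se))
        assert fit.n_obs == 30
        assert 0.8 < fit.r2_adj <= 1.0

    def test_random_max_mode_needs_bird_ids(self):
        y = qa.eval_saturation(SAT, self.X)
        with pytest.raises(DesignError):
            qa.fit_response(self.X, y, family="saturation", random_max=True)

    def test_random_max_collapses_with_one_obs_per_bird(self):
        rng = np.random.default_rng(4)
        y = qa.eval_saturation(SAT, self.X) + rng.normal(0, 10, self.X.size)
        fixed = qa.fit_response(self.X, y, family="saturation")
        mixed = qa.fit_response(self.X, y, family="saturation",
                                bird_ids=np.arange(self.X.size),
                                random_max=True)
        assert mixed.params.km == pytest.approx(fixed.params.km, rel=1e-9)

    def test_design_errors(self):
        with pytest.raises(DesignError):
            qa.fit_response([1, 2, 3], [1, 2, 3], family="saturation")
        with pytest.raises(DesignError):
            qa.fit_response(np.ones(10), np.ones(10), family="saturation")
        with pytest.raises(DomainError):
            qa.fit_response(self.X, self.X, family="gompertz")


class TestBrokenLine:
    TRUE = qa.BrokenLineParams(plateau=225.0, slope=0.53, breakpoint=484.0)

    def test_noiseless_exact_recovery(self):
        x = np.linspace(100, 1100, 49)
        y = qa.eval_broken_line(self.TRUE, x)
        params, fit = qa.fit_broken_line(x, y)
        assert params.plateau == pytest.approx(225.0, rel=1e-8)
        assert params.slope == pytest.approx(0.53, rel=1e-8)
        assert params.breakpoint == pytest.approx(484.0, rel=1e-8)
        assert params.identified
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_pure_plateau_flagged_unidentified(self):
        x = np.linspace(100, 1100, 20)
        params, _ = qa.fit_broken_line(x, np.full(20, 225.0))
        assert params.slope == pytest.approx(0.0, abs=1e-9)
        assert not params.identified

    def test_degenerate_design_raises(self):
        with pytest.raises(DesignError):
            qa.fit_broken_line(np.full(10, 5.0), np.arange(10.0))
        with pytest.raises(DesignError):
            qa.fit_broken_line([1, 2, 3], [1, 2, 3])
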