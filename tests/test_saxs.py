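"""Form factor, Ornstein-Zernike solver, and 2-Yukawa fitting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import bisect

from nanocolloid import (
    LogNormalSphereFF,
    OZConvergenceError,
    SAXSCurve,
    SolutionState,
    SyntheticSAXSSpec,
    TwoYukawaPotential,
    YukawaTerm,
    average_form_factor,
    decompose_fit,
    fit_saxs,
    hard_sphere_sq_py,
    oz_structure_factor,
    sphere_form_factor,
    synthesize_saxs,
)

SIGMA = 7.0


class TestSphereFormFactor:
    def test_normalized_at_zero(self):
        assert sphere_form_factor(0.0, 1.85) == 1.0

    def test_first_zero_at_tan_x_equals_x(self):
        # root of tan x = x located independently by bisection
        x_star = bisect(lambda x: np.tan(x) - x, np.pi * 1.3, np.pi * 1.49,
                        xtol=1e-14)
        R = 1.85
        assert sphere_form_factor(x_star / R, R) < 1e-10

    def test_bounded_by_one(self):
        q = np.linspace(0.0, 30.0, 500)
        assert np.all(sphere_form_factor(q, 1.85) <= 1.0)

    def test_small_argument_series_is_smooth(self):
        # the series patch must join the closed form continuously
        q = np.array([1e-5 / 1.85, 2e-4 / 1.85])
        p = sphere_form_factor(q, 1.85)
        assert np.all(np.abs(p - 1.0) < 1e-8)


class TestAverageFormFactor:
    def test_zero_width_equals_monodisperse(self):
        q = np.linspace(0.0, 5.0, 64)
        ff = LogNormalSphereFF(1.85, 0.0)
        np.testing.assert_array_equal(average_form_factor(q, ff),
                                      sphere_form_factor(q, 1.85))

    def test_polydispersity_fills_the_minimum(self):
        x_star = 4.493409457909064
        q_min = x_star / 1.85
        mono = sphere_form_factor(q_min, 1.85)
        poly = average_form_factor(np.array([q_min]), LogNormalSphereFF(1.85, 0.15))[0]
        assert poly > mono
        assert poly > 1e-4

    def test_against_dense_lognormal_quadrature(self, rng):
        # independent oracle: brute-force trapezoid over the log-normal pdf
        from scipy.stats import lognorm
        for _ in range(10):
            ff = LogNormalSphereFF(rng.uniform(1.0, 3.0), rng.uniform(0.02, 0.25))
            q = rng.uniform(0.1, 6.0, size=8)
            radii = np.linspace(ff.median_radius * np.exp(-6 * ff.lognormal_sigma),
                                ff.median_radius * np.exp(6 * ff.lognormal_sigma),
                                20_001)
            pdf = lognorm.pdf(radii, s=ff.lognormal_sigma, scale=ff.median_radius)
            x = q[:, None] * radii[None, :]
            p_of_x = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
            num = np.trapezoid(pdf * radii**6 * p_of_x, radii, axis=1)
            den = np.trapezoid(pdf * radii**6, radii)
            oracle = num / den
            np.testing.assert_allclose(average_form_factor(q, ff), oracle, rtol=1e-5)


class TestOZSolver:
    def q(self):
        return np.linspace(0.05, 4.0, 200)

    @pytest.mark.parametrize("phi", [0.05, 0.1, 0.2, 0.3])
    def test_hard_sphere_matches_wertheim_py(self, phi):
        S = oz_structure_factor(TwoYukawaPotential.hard_sphere(SIGMA),
                                SolutionState.from_volume_fraction(phi, SIGMA),
                                self.q(), closure="py")
        ref = hard_sphere_sq_py(self.q(), SIGMA, phi)
        assert np.max(np.abs(S - ref) / ref) < 0.01

    def test_wertheim_formula_against_quadrature(self):
        # independent check of the analytic reference itself: its direct
        # correlation function integrates to the same structure factor
        phi, sigma = 0.2, SIGMA
        a = (1 + 2 * phi) ** 2 / (1 - phi) ** 4
        b = -6 * phi * (1 + phi / 2) ** 2 / (1 - phi) ** 4
        d = phi * a / 2
        rho = 6 * phi / (np.pi * sigma**3)
        for qv in (0.3, 0.9, 1.7):
            integrand = lambda r: -(a + b * (r / sigma) + d * (r / sigma) ** 3) \
                * r * np.sin(qv * r)
            c_hat = 4 * np.pi / qv * quad(integrand, 0.0, sigma, limit=200)[0]
            s_ref = 1.0 / (1.0 - rho * c_hat)
            s_closed = hard_sphere_sq_py(np.array([qv]), sigma, phi)[0]
            assert s_closed == pytest.approx(s_ref, rel=1e-8)

    def test_ideal_dilution_limit(self):
        S = oz_structure_factor(TwoYukawaPotential.hard_sphere(SIGMA),
                                SolutionState.from_volume_fraction(1e-6, SIGMA),
                                self.q(), closure="hnc")
        assert np.max(np.abs(S - 1.0)) < 1e-4

    def test_attraction_raises_compressibility_limit(self):
        sol = SolutionState.from_volume_fraction(0.08, SIGMA)
        q_low = np.array([0.05])
        S_att = oz_structure_factor(
            TwoYukawaPotential(SIGMA, YukawaTerm(1.0, 2.0), YukawaTerm(-4.0, 10.0)),
            sol, q_low, closure="hnc")
        S_ref = oz_structure_factor(
            TwoYukawaPotential(SIGMA, YukawaTerm(0.0, 2.0), YukawaTerm(-4.0, 10.0)),
            sol, q_low, closure="hnc")
        assert S_att[0] > S_ref[0]

    def test_structure_factor_approaches_one_at_large_q(self):
        pot = TwoYukawaPotential(SIGMA, YukawaTerm(1.0, 1.5), YukawaTerm(-6.0, 4.0))
        S = oz_structure_factor(pot, SolutionState.from_volume_fraction(0.1, SIGMA),
                                np.linspace(15.0, 25.0, 20), closure="hnc")
        assert np.max(np.abs(S - 1.0)) < 1e-3

    def test_unstable_state_raises_with_history(self):
        # deep long-range attraction at finite phi: inside the spinodal
        pot = TwoYukawaPotential(SIGMA, YukawaTerm(4.0, 0.8), YukawaTerm(0.0, 1.0))
        with pytest.raises(OZConvergenceError) as err:
            oz_structure_factor(pot, SolutionState.from_volume_fraction(0.2, SIGMA),
                                self.q(), closure="hnc")
        assert len(err.value.residuals) > 0

    def test_unknown_closure_rejected(self):
        with pytest.raises(ValueError):
            oz_structure_factor(TwoYukawaPotential.hard_sphere(SIGMA),
                                SolutionState.from_volume_fraction(0.1, SIGMA),
                                self.q(), closure="msa")


TRUTH = dict(scale=1.0, background=0.001, K1=1.0, Z1=1.5, K2=-6.0, Z2=4.0,
             phi=0.10, sigma=SIGMA)


def truth_potential():
    return TwoYukawaPotential(SIGMA, YukawaTerm(TRUTH["K1"], TRUTH["Z1"]),
                              YukawaTerm(TRUTH["K2"], TRUTH["Z2"]))


def make_curve(noise=0.0, seed=0):
    ff = LogNormalSphereFF(1.85, 0.1)
    spec = SyntheticSAXSSpec(
        q_grid=np.linspace(0.05, 3.0, 200), form_factor=ff,
        potential=truth_potential(), volume_fraction=TRUTH["phi"],
        scale=TRUTH["scale"], background=TRUTH["background"],
        noise_relative_sd=noise, seed=seed)
    return synthesize_saxs(spec), ff


class TestFitSAXS:
    def test_noiseless_round_trip_recovers_truth(self):
        curve, ff = make_curve(noise=0.0)
        res = fit_saxs(curve, ff, dict(TRUTH))
        p = res.params_dict()
        for name in ("K1", "Z1", "K2", "Z2", "phi", "scale"):
            assert p[name] == pytest.approx(TRUTH[name], rel=0.01)
        assert res.redchi < 1e-10
        assert res.success

    def test_perturbed_initials_recover_dominant_term(self):
        curve, ff = make_curve(noise=0.01, seed=3)
        rng = np.random.default_rng(77)
        init = dict(TRUTH)
        for k in ("K1", "Z1", "K2", "Z2", "phi", "scale"):
            init[k] = TRUTH[k] * (1 + rng.uniform(-0.3, 0.3))
        res = fit_saxs(curve, ff, init)
        p = res.params_dict()
        assert p["K2"] == pytest.approx(TRUTH["K2"], rel=0.1)
        assert p["Z2"] == pytest.approx(TRUTH["Z2"], rel=0.1)

    def test_structureless_curve_yields_negligible_yukawa_strengths(self):
        # curve that is exactly scale*<P> + background (S == 1)
        ff = LogNormalSphereFF(1.85, 0.1)
        q = np.linspace(0.05, 3.0, 200)
        I = 1.0 * average_form_factor(q, ff) + 0.001
        curve = SAXSCurve(q=q, I=I, sigma_I=0.01 * I)
        init = dict(TRUTH, K1=0.3, K2=-0.3, Z1=2.0, Z2=5.0, phi=1e-4)
        res = fit_saxs(curve, ff, init)
        p = res.params_dict()
        # either the strengths collapse or the state is effectively ideal
        indeterminate = p["phi"] < 1e-3
        assert indeterminate or (abs(p["K1"]) < 0.1 and abs(p["K2"]) < 0.1)

    def test_too_few_points_rejected(self):
        ff = LogNormalSphereFF(1.85, 0.1)
        q = np.linspace(0.1, 1.0, 10)
        curve = SAXSCurve(q=q, I=np.ones_like(q))
        with pytest.raises(ValueError, match="points"):
            fit_saxs(curve, ff, dict(TRUTH))

    def test_missing_initials_rejected(self):
        curve, ff = make_curve()
        with pytest.raises(ValueError, match="missing"):
            fit_saxs(curve, ff, {"scale": 1.0})


class TestDecomposeFit:
    def test_attractive_curve_from_positive_term_only(self):
        curve, ff = make_curve()
        res = fit_saxs(curve, ff, dict(TRUTH))
        r = np.linspace(SIGMA, 5 * SIGMA, 100)
        rep = decompose_fit(res, r)
        np.testing.assert_allclose(rep["attractive"] + rep["repulsive"],
                                   rep["total"], atol=1e-12)
        assert np.all(rep["attractive"] <= 0.0)   # K > 0 pulls V down
        assert np.all(rep["repulsive"] >= 0.0)

    def test_identical_results_difference_to_zero(self):
        curve, ff = make_curve()
        res = fit_saxs(curve, ff, dict(TRUTH))
        rep = decompose_fit(res, np.linspace(SIGMA, 3 * SIGMA, 50), other=res)
        assert np.max(np.abs(rep["delta_total"])) == 0.0
        assert np.max(np.abs(rep["delta_attractive"])) == 0.0

    def test_unconverged_fit_refused(self):
        curve, ff = make_curve()
        res = fit_saxs(curve, ff, dict(TRUTH))
        bad = type(res)(**{**res.__dict__, "success": False})
        with pytest.raises(ValueError, match="unconverged"):
            decompose_fit(bad, np.linspace(SIGMA, 2 * SIGMA, 10))
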