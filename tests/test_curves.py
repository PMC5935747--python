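"""Forward-model checks: boundary values, oracles, and published maxima."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import sigrow as sg
from sigrow.curves import _nsg_biomass_raw
from sigrow.exceptions import DomainError, ParameterError

SUN_NSG = sg.NSGParameters(-0.049, 3.872, 14.191, 87.525)


class TestNSGRate:
    def test_zero_at_growth_start_and_end(self):
        assert sg.nsg_rate(SUN_NSG.t_b, SUN_NSG) == 0.0
        assert sg.nsg_rate(SUN_NSG.t_e, SUN_NSG) == 0.0

    def test_zero_outside_growth_window(self):
        assert sg.nsg_rate(SUN_NSG.t_b - 5.0, SUN_NSG) == 0.0
        assert sg.nsg_rate(SUN_NSG.t_e + 5.0, SUN_NSG) == 0.0

    def test_direct_substitution_oracle(self):
        # independent arithmetic: square of c (t - t_b) (1 - e^{k (t - t_e)})
        t = 50.0
        expected = ((-0.049) * (t - 14.191)
                    * (1.0 - math.exp(3.872 * (t - 87.525)))) ** 2
        assert sg.nsg_rate(t, SUN_NSG) == pytest.approx(expected, rel=1e-14)

    def test_nonnegative_everywhere(self):
        t = np.linspace(0.0, 120.0, 400)
        assert np.all(sg.nsg_rate(t, SUN_NSG) >= 0.0)


class TestNSGBiomass:
    def test_zero_at_and_before_growth_start(self):
        assert sg.nsg_biomass(SUN_NSG.t_b, SUN_NSG) == 0.0
        assert sg.nsg_biomass(SUN_NSG.t_b - 10.0, SUN_NSG) == 0.0

    def test_matches_quadrature_of_rate(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            c = -rng.uniform(0.005, 1.0)
            k = rng.uniform(0.05, 30.0)
            t_b = rng.uniform(-20.0, 30.0)
            t_e = t_b + rng.uniform(5.0, 200.0)
            p = sg.NSGParameters(c, k, t_b, t_e)
            t = rng.uniform(t_b, t_e)
            ref, _ = quad(lambda s: sg.nsg_rate(s, p), t_b, t, limit=400)
            w = sg.nsg_biomass(t, p)
            assert abs(w - ref) / max(1e-12, ref) <= 1e-8

    def test_sign_of_c_is_unobservable(self):
        t = np.linspace(15.0, 87.0, 11)
        plus = _nsg_biomass_raw(t, 0.049, 3.872, 14.191, 87.525)
        minus = _nsg_biomass_raw(t, -0.049, 3.872, 14.191, 87.525)
        np.testing.assert_array_equal(plus, minus)

    def test_nondecreasing_within_growth_window(self):
        t = np.linspace(SUN_NSG.t_b, SUN_NSG.t_e, 500)
        w = sg.nsg_biomass(t, SUN_NSG)
        assert np.all(np.diff(w) >= 0.0)

    def test_clamped_after_maturity_by_default(self):
        wmax = sg.nsg_max_biomass(SUN_NSG)
        assert sg.nsg_biomass(SUN_NSG.t_e + 30.0, SUN_NSG) == pytest.approx(
            wmax, rel=1e-14)
        # the raw analytic continuation resumes growing past t_e
        raw = sg.nsg_biomass(SUN_NSG.t_e + 30.0, SUN_NSG,
                             clamp_after_te=False)
        assert raw > wmax

    def test_large_k_limit_is_clamped_cubic(self):
        p = sg.NSGParameters(-0.05, 1e3, 10.0, 90.0)
        cubic = 0.05**2 * (90.0 - 10.0) ** 3 / 3.0
        assert sg.nsg_max_biomass(p) == pytest.approx(cubic, rel=5e-3)
        # relative error shrinks as k grows
        p2 = sg.NSGParameters(-0.05, 1e4, 10.0, 90.0)
        err1 = abs(sg.nsg_max_biomass(p) - cubic) / cubic
        err2 = abs(sg.nsg_max_biomass(p2) - cubic) / cubic
        assert err2 < err1


class TestBSGBiomass:
    def test_zero_at_growth_start(self):
        p = sg.BSGParameters(2.267, 73.590, -17.770, 93.217)
        assert sg.bsg_biomass(p.t_b, p) == 0.0

    def test_domain_error_before_growth_start(self):
        p = sg.BSGParameters(2.267, 73.590, -17.770, 93.217)
        with pytest.raises(DomainError):
            sg.bsg_biomass(p.t_b - 1.0, p)

    def test_value_at_peak_rate_time(self):
        # at t = t_m the power base is 1, so the remaining factors give
        # w = c_m (t_m - t_b) (2 t_e - 2 t_m) / (2 t_e - t_m - t_b)
        p = sg.BSGParameters(1.5, 60.0, 10.0, 100.0)
        expected = 1.5 * (60.0 - 10.0) * (200.0 - 120.0) / (200.0 - 60.0 - 10.0)
        assert sg.bsg_biomass(60.0, p) == pytest.approx(expected, rel=1e-14)

    def test_zero_slope_at_maturity(self):
        p = sg.BSGParameters(2.267, 73.590, -17.770, 93.217)
        h = 1e-6
        slope = (sg.bsg_biomass(p.t_e + h, p) - sg.bsg_biomass(p.t_e - h, p)) / (
            2.0 * h)
        assert abs(slope) < 1e-5

    def test_scales_linearly_in_cm(self):
        p1 = sg.BSGParameters(1.0, 60.0, 10.0, 100.0)
        p2 = sg.BSGParameters(3.0, 60.0, 10.0, 100.0)
        assert sg.bsg_biomass(80.0, p2) == pytest.approx(
            3.0 * sg.bsg_biomass(80.0, p1), rel=1e-14)


class TestPublishedMaxima:
    """Recomputing w_max = w(t_e) from the published parameter rows."""

    def test_all_crops_nsg(self, all_crops):
        for fx in all_crops:
            w = sg.nsg_max_biomass(fx.nsg_params)
            assert w == pytest.approx(fx.reference_wmax_nsg, rel=0.035), fx.species

    def test_all_crops_bsg(self, all_crops):
        for fx in all_crops:
            w = sg.bsg_max_biomass(fx.bsg_params)
            assert w == pytest.approx(fx.reference_wmax_bsg, rel=0.005), fx.species

    @pytest.mark.parametrize("species,model,expected,rel", [
        ("sunflower", "nsg", 310.69, 0.035),
        ("sunflower", "bsg", 924.76, 0.005),
        ("peanut", "nsg", 41.90, 0.01),
        ("adzuki bean", "nsg", 23.36, 0.02),
        ("black soybean", "bsg", 54.09, 0.005),
        ("mung bean", "bsg", 202.84, 0.005),
    ])
    def test_spot_values(self, species, model, expected, rel):
        fx = sg.crop_fixture(species)
        if model == "nsg":
            w = sg.nsg_max_biomass(fx.nsg_params)
        else:
            w = sg.bsg_max_biomass(fx.bsg_params)
        assert w == pytest.approx(expected, rel=rel)


class TestBetaRate:
    def test_peak_value_and_maturity_zero(self):
        assert sg.beta_rate(50.0, 2.0, 50.0, 100.0) == pytest.approx(2.0)
        assert sg.beta_rate(100.0, 2.0, 50.0, 100.0) == 0.0

    def test_direct_substitution_oracle(self):
        # c_m ((t_e - t)/(t_e - t_m)) (t/t_m)^{t_m/(t_e - t_m)} at t = 25
        expected = 2.0 * ((100.0 - 25.0) / 50.0) * (25.0 / 50.0) ** (50.0 / 50.0)
        assert sg.beta_rate(25.0, 2.0, 50.0, 100.0) == pytest.approx(
            expected, rel=1e-14)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            sg.beta_rate(-1.0, 2.0, 50.0, 100.0)
        with pytest.raises(DomainError):
            sg.beta_rate(101.0, 2.0, 50.0, 100.0)


class TestSimplifiedBSG:
    def test_boundary_values(self):
        assert sg.bsg_simplified_biomass(80.0, 100.0, 40.0, 80.0) == (
            pytest.approx(100.0))
        assert sg.bsg_simplified_biomass(0.0, 100.0, 40.0, 80.0) == 0.0

    def test_is_antiderivative_of_beta_rate(self):
        # the curve must reproduce the normalised integral of the
        # simplified beta rate -- the quadrature oracle certifies the form
        w_max, t_m, t_e = 100.0, 40.0, 80.0
        total, _ = quad(lambda s: sg.beta_rate(s, 1.0, t_m, t_e), 0.0, t_e)
        for t in (10.0, 40.0, 60.0):
            part, _ = quad(lambda s: sg.beta_rate(s, 1.0, t_m, t_e), 0.0, t)
            expected = w_max * part / total
            assert sg.bsg_simplified_biomass(t, w_max, t_m, t_e) == (
                pytest.approx(expected, rel=1e-9))

    def test_value_at_peak_rate_time(self):
        # frozen from the quadrature oracle above: t = t_m = 40 gives
        # w_max * 2 * (40/80)^(80/40) = 50 exactly
        assert sg.bsg_simplified_biomass(40.0, 100.0, 40.0, 80.0) == (
            pytest.approx(50.0, rel=1e-12))

    def test_domain_error_for_negative_time(self):
        with pytest.raises(DomainError):
            sg.bsg_simplified_biomass(-0.5, 100.0, 40.0, 80.0)


class TestParameterValidation:
    @pytest.mark.parametrize("args", [
        (0.049, 3.872, 14.191, 87.525),   # positive c breaks the convention
        (-0.049, 0.0, 14.191, 87.525),    # k must be positive
        (-0.049, 3.872, 90.0, 87.525),    # t_e must exceed t_b
        (-0.049, float("nan"), 14.191, 87.525),
    ])
    def test_nsg_invalid(self, args):
        with pytest.raises(ParameterError):
            sg.NSGParameters(*args)

    @pytest.mark.parametrize("args", [
        (0.0, 60.0, 10.0, 100.0),         # c_m must be positive
        (1.0, 5.0, 10.0, 100.0),          # t_m below t_b
        (1.0, 110.0, 10.0, 100.0),        # t_m above t_e
    ])
    def test_bsg_invalid(self, args):
        with pytest.raises(ParameterError):
            sg.BSGParameters(*args)

    def test_nsg_allows_zero_and_negative_c(self):
        sg.NSGParameters(0.0, 1.0, 0.0, 10.0)
        sg.NSGParameters(-1.0, 1.0, -5.0, 10.0)
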