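"""Generate-then-fit oracles for the six compression models.

Each model's data are generated from its own closed form, so the fit must
recover the planted parameters exactly (noise-free) and the linearised
estimators must agree with direct nonlinear least squares.
"""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from tabletability.models import (
    CompressionCurve,
    fit_all,
    fit_gurnham,
    fit_heckel,
    fit_kawakita,
    fit_power,
    fit_ryshkewitch_duckworth,
    fit_shapiro,
)

from conftest import FULL_GRID, gurnham_porosity, make_curve, power_ts

DA, DT = 0.5, 1.5


def kawakita_curve(a=0.9, b=0.02, pressures=FULL_GRID):
    c = a * b * pressures / (1.0 + b * pressures)
    rho_app = DA / (1.0 - c)
    eps = 1.0 - rho_app / DT
    return make_curve(pressures, eps, power_ts(pressures))


class TestKawakita:
    def test_exact_recovery(self):
        fit = fit_kawakita(kawakita_curve(a=0.9, b=0.02))
        assert fit.ok
        assert fit.params["a"] == pytest.approx(0.9, rel=1e-6)
        assert fit.params["b"] == pytest.approx(0.02, rel=1e-6)
        assert fit.params["ab"] == pytest.approx(0.018, rel=1e-6)
        assert fit.params["b_inv"] == pytest.approx(50.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_slope_inverse_algebra(self):
        # a = 1/slope of the P/C vs P line
        fit = fit_kawakita(kawakita_curve(a=0.8, b=0.01))
        assert fit.params["a"] == pytest.approx(0.8, rel=1e-8)

    def test_matches_nonlinear_oracle(self):
        curve = kawakita_curve(a=0.95, b=0.015)
        fit = fit_kawakita(curve)
        c = 1.0 - DA / (DT * (1.0 - curve.porosity))
        (a_nls, b_nls), _ = curve_fit(
            lambda p, a, b: a * b * p / (1 + b * p), curve.pressure, c, p0=[0.8, 0.02]
        )
        assert fit.params["a"] == pytest.approx(a_nls, rel=1e-6)
        assert fit.params["b"] == pytest.approx(b_nls, rel=1e-6)

    def test_failure_is_a_value(self):
        # porosity increasing with pressure → negative-slope linearised fit
        eps = np.linspace(0.2, 0.6, len(FULL_GRID))
        fit = fit_kawakita(make_curve(FULL_GRID, eps, power_ts(FULL_GRID)))
        assert not fit.ok and fit.message


class TestShapiro:
    def shapiro_curve(self, f=0.2, k=0.004, pressures=FULL_GRID):
        eps0 = 1.0 - DA / DT
        eps = eps0 * np.exp(-k * pressures - f * np.sqrt(pressures))
        return make_curve(pressures, eps, power_ts(pressures))

    def test_exact_recovery(self):
        fit = fit_shapiro(self.shapiro_curve(f=0.2, k=0.004))
        assert fit.ok
        assert fit.params["f"] == pytest.approx(0.2, rel=1e-8)
        assert fit.params["k"] == pytest.approx(0.004, rel=1e-8)

    def test_constant_porosity_gives_zero_coefficients(self):
        eps0 = 1.0 - DA / DT
        curve = make_curve(FULL_GRID, np.full(len(FULL_GRID), eps0), power_ts(FULL_GRID))
        fit = fit_shapiro(curve)
        assert fit.params["f"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["k"] == pytest.approx(0.0, abs=1e-12)

    def test_brittle_exceeds_plastic_f_by_construction(self):
        brittle = fit_shapiro(self.shapiro_curve(f=0.3, k=0.004))
        plastic = fit_shapiro(self.shapiro_curve(f=0.1, k=0.004))
        assert brittle.params["f"] > plastic.params["f"]

    def test_too_few_low_pressure_points_is_failure_value(self):
        pressures = np.array([60.0, 80.0, 100.0, 140.0])
        curve = make_curve(pressures, gurnham_porosity(pressures), power_ts(pressures))
        fit = fit_shapiro(curve)
        assert not fit.ok


class TestHeckel:
    def heckel_curve(self, k=0.005, A=0.7, pressures=FULL_GRID):
        eps = np.exp(-(k * pressures + A))
        return make_curve(pressures, eps, power_ts(pressures))

    def test_exact_recovery(self):
        fit = fit_heckel(self.heckel_curve(k=0.005))
        assert fit.ok
        assert fit.params["Py"] == pytest.approx(200.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_porosity_rescaling_changes_intercept_not_py(self):
        base = fit_heckel(self.heckel_curve(k=0.005, A=0.7))
        curve = self.heckel_curve(k=0.005, A=0.7)
        doubled = make_curve(curve.pressure, 2.0 * curve.porosity, curve.tensile_strength)
        fit = fit_heckel(doubled)
        assert fit.params["Py"] == pytest.approx(base.params["Py"], rel=1e-10)
        assert fit.params["A"] != pytest.approx(base.params["A"], rel=1e-3)


class TestGurnham:
    def test_exact_recovery(self):
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID, K=10.0, P0=500.0),
                           power_ts(FULL_GRID))
        fit = fit_gurnham(curve)
        assert fit.ok
        assert fit.params["K"] == pytest.approx(10.0, rel=1e-6)
        assert fit.params["P0"] == pytest.approx(500.0, rel=1e-6)

    def test_fitted_model_reaches_zero_porosity_at_p0(self):
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID, K=8.0, P0=700.0),
                           power_ts(FULL_GRID))
        fit = fit_gurnham(curve)
        eps_at_p0 = -np.log(fit.params["P0"] / fit.params["P0"]) / fit.params["K"]
        assert eps_at_p0 == pytest.approx(0.0, abs=1e-12)

    def test_larger_k_flattens_the_curve(self):
        flat = gurnham_porosity(FULL_GRID, K=20.0, P0=500.0)
        steep = gurnham_porosity(FULL_GRID, K=5.0, P0=500.0)
        assert np.ptp(flat) < np.ptp(steep)


class TestRyshkewitchDuckworth:
    def rd_curve(self, kb=8.0, ts0=12.0):
        eps = gurnham_porosity(FULL_GRID)
        return make_curve(FULL_GRID, eps, ts0 * np.exp(-kb * eps))

    def test_exact_recovery(self):
        fit = fit_ryshkewitch_duckworth(self.rd_curve(kb=8.0, ts0=12.0))
        assert fit.ok
        assert fit.params["kb"] == pytest.approx(8.0, rel=1e-6)
        assert fit.params["TS0"] == pytest.approx(12.0, rel=1e-6)

    def test_zero_porosity_intercept_is_ts0(self):
        fit = fit_ryshkewitch_duckworth(self.rd_curve(kb=5.0, ts0=7.0))
        # TS at ε = 0 under the fitted model is exp(intercept) = TS0
        assert fit.params["TS0"] == pytest.approx(7.0, rel=1e-6)

    def test_nonpositive_ts_points_excluded_with_warning(self):
        curve = self.rd_curve()
        curve.tensile_strength[0] = 0.0
        with pytest.warns(UserWarning, match="TS <= 0"):
            fit = fit_ryshkewitch_duckworth(curve)
        assert fit.ok and fit.n_points == len(FULL_GRID) - 1


class TestPower:
    def test_exact_recovery(self):
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID),
                           power_ts(FULL_GRID, d=0.1, g=0.7))
        fit = fit_power(curve)
        assert fit.params["d"] == pytest.approx(0.1, rel=1e-8)
        assert fit.params["g"] == pytest.approx(0.7, rel=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_strong_tabletability_material_refits_exactly(self):
        # a d = 1.00 powder (the strongest tabletability in the library span)
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID),
                           power_ts(FULL_GRID, d=1.00, g=0.5))
        fit = fit_power(curve)
        assert fit.params["d"] == pytest.approx(1.00, rel=1e-8)

    def test_flat_tabletability_gives_zero_exponent(self):
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID),
                           np.full(len(FULL_GRID), 2.5))
        fit = fit_power(curve)
        assert fit.params["g"] == pytest.approx(0.0, abs=1e-12)

    def test_loglog_matches_nls_oracle_on_clean_data(self):
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID),
                           power_ts(FULL_GRID, d=0.05, g=1.2))
        loglog = fit_power(curve, method="loglog")
        nls = fit_power(curve, method="nls")
        assert loglog.params["d"] == pytest.approx(nls.params["d"], rel=1e-6)
        assert loglog.params["g"] == pytest.approx(nls.params["g"], rel=1e-6)


class TestWindowDiscipline:
    @pytest.mark.parametrize(
        "fitter", [fit_kawakita, fit_heckel, fit_gurnham, fit_power]
    )
    def test_points_outside_window_never_change_the_fit(self, fitter):
        inside = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID), power_ts(FULL_GRID))
        extended_p = np.concatenate([[2.0, 5.0], FULL_GRID, [160.0, 180.0]])
        extended = make_curve(
            extended_p, gurnham_porosity(extended_p), power_ts(extended_p)
        )
        fit_in, fit_ext = fitter(inside), fitter(extended)
        for key, value in fit_in.params.items():
            assert fit_ext.params[key] == pytest.approx(value, rel=1e-10)


class TestFitAll:
    def test_all_nine_parameters_populated(self, clean_result):
        cbcs = clean_result.cbcs
        for col in ("a", "ab", "b_inv", "f", "Py", "K", "kb", "d", "g"):
            assert np.isfinite(cbcs[col]).all(), col
        for model in ("kawakita", "shapiro", "heckel", "gurnham",
                      "ryshkewitch_duckworth", "power"):
            assert np.isfinite(cbcs[f"r2_{model}"]).all()

    def test_partial_failure_contract(self):
        # TS ≡ 0 sinks the strength fits but not the porosity fits
        curve = make_curve(FULL_GRID, gurnham_porosity(FULL_GRID),
                           np.zeros(len(FULL_GRID)))
        with pytest.warns(UserWarning):
            res = fit_all(curve)
        assert not res.fits["power"].ok and not res.fits["ryshkewitch_duckworth"].ok
        assert res.fits["heckel"].ok and res.fits["gurnham"].ok
        assert np.isnan(res.d) and np.isnan(res.kb)
        assert np.isfinite(res.Py)

    def test_library_run_attempts_six_fits_per_curve(self, clean_result):
        assert clean_result.n_fits_attempted == 29 * 2 * 6

    def test_recovered_kawakita_a_within_physical_span(self, clean_result):
        a = clean_result.cbcs["a"].dropna()
        assert ((a > 0.3) & (a < 1.2)).all()


def test_curve_validation_rejects_bad_input():
    with pytest.raises(ValueError, match="positive"):
        CompressionCurve("m", "powder", np.array([-1.0, 10, 20, 30]),
                         np.full(4, 0.3), np.ones(4), 0.5, 1.5)
    with pytest.raises(ValueError, match="porosity"):
        CompressionCurve("m", "powder", np.array([5.0, 10, 20, 30]),
                         np.array([0.3, 0.3, 1.2, 0.3]), np.ones(4), 0.5, 1.5)
    with pytest.raises(ValueError, match="distinct"):
        CompressionCurve("m", "powder", np.array([10.0, 10.0, 20.0, 20.0]),
                         np.full(4, 0.3), np.ones(4), 0.5, 1.5)
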