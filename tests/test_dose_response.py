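import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from ndrscreen import (
    DoseSeries,
    DSSConfig,
    LogisticCurve,
    baseline_distance,
    compute_dss,
    curve_rmsd,
    dose_series,
    fit_dose_response,
    negative_dss,
)
from ndrscreen.dose_response import dss_for_series, scale_series
from ndrscreen.errors import ConfigurationError, FitError

CONC5 = dose_series(1e-5, 5)  # 1e-9 .. 1e-5


def series(responses, metric="PI", scaled=True, conc=CONC5, name="d"):
    return DoseSeries(name, conc, tuple(responses), metric, scaled=scaled)


def quadrature_dss(curve: LogisticCurve, conc, a_min=10.0) -> float:
    """Independent DSS oracle: numerical quadrature of the clipped curve,
    splitting at the threshold-crossing kink so quad converges."""
    x1, x2 = np.log10(conc[0]), np.log10(conc[-1])
    excess = lambda x: float(curve.predict([10.0**x])[0]) - a_min
    points = []
    if excess(x1) * excess(x2) < 0:
        points = [brentq(excess, x1, x2, xtol=1e-14)]
    area, _ = quad(
        lambda x: max(excess(x), 0.0),
        x1, x2, points=points, limit=400, epsabs=1e-12, epsrel=1e-12,
    )
    return 100.0 * area / ((100.0 - a_min) * (x2 - x1))


class TestDoseSeries:
    def test_rejects_mismatched_and_unordered(self):
        with pytest.raises(FitError):
            DoseSeries("d", (1e-8, 1e-7), (0.0,), "PI")
        with pytest.raises(FitError):
            DoseSeries("d", (1e-7, 1e-8), (0.0, 1.0), "PI")
        with pytest.raises(FitError):
            DoseSeries("d", (0.0, 1e-8), (0.0, 1.0), "PI")


class TestCurveRmsd:
    def test_reference_values(self):
        assert curve_rmsd([1, 2, 3], [1, 2, 3]) == 0.0
        assert curve_rmsd([0, 0, 50, 100, 100], [0, 10, 50, 90, 100]) == pytest.approx(
            np.sqrt(200 / 5)
        )
        assert curve_rmsd([5.0], [2.0]) == 3.0

    def test_permutation_invariance_and_mismatch(self):
        assert curve_rmsd([1, 5, 2], [0, 4, 3]) == curve_rmsd([5, 1, 2], [4, 0, 3])
        with pytest.raises(FitError):
            curve_rmsd([1, 2], [1, 2, 3])


class TestFit:
    def test_recovers_noise_free_parameters(self):
        true = LogisticCurve(r_max=100.0, r_min=0.0, ec50=1e-7, slope=1.0)
        res = fit_dose_response(series(true.predict(CONC5)))
        assert res.converged
        assert res.curve.r_max == pytest.approx(100.0, rel=1e-3)
        assert res.curve.r_min == pytest.approx(0.0, abs=1e-3 * 100)
        assert res.curve.ec50 == pytest.approx(1e-7, rel=1e-3)
        assert res.curve.slope == pytest.approx(1.0, rel=1e-3)
        assert res.rmsd < 1e-6

    def test_constant_series_gives_flat_curve(self):
        res = fit_dose_response(series([0.0] * 5))
        assert res.rmsd == 0.0
        assert res.curve.r_min == res.curve.r_max == 0.0

    def test_refit_of_fitted_curve_is_idempotent(self):
        first = fit_dose_response(series([2.0, 5.0, 30.0, 80.0, 95.0]))
        refit = fit_dose_response(series(first.fitted_values))
        np.testing.assert_allclose(
            refit.curve.predict(CONC5), first.curve.predict(CONC5), atol=1e-6
        )

    def test_decreasing_series_fits_too(self):
        true = LogisticCurve(r_max=1.0, r_min=-0.8, ec50=1e-7, slope=2.0)
        resp = true.r_max + true.r_min - true.predict(CONC5)  # mirrored: decreasing
        res = fit_dose_response(series(resp, metric="NDR", scaled=False))
        assert res.rmsd < 1e-6

    def test_too_few_points(self):
        with pytest.raises(FitError, match=">= 4"):
            fit_dose_response(series([0, 50, 100], conc=dose_series(1e-5, 3)))

    def test_noisy_ec50_recovery_is_unbiased(self, rng):
        true = LogisticCurve(r_max=100.0, r_min=0.0, ec50=1e-7, slope=1.0)
        clean = true.predict(CONC5)
        errors = []
        for _ in range(50):
            noisy = clean * (1 + 0.02 * rng.standard_normal(5))
            res = fit_dose_response(series(noisy))
            errors.append(abs(np.log10(res.curve.ec50) - np.log10(true.ec50)))
        assert np.median(errors) < 0.1


class TestBaselineDistance:
    def test_reference_values(self):
        assert baseline_distance(series([0.95, 0.9, 0.5, 0.1, 0], "NDR", scaled=False)) == pytest.approx(0.05)
        assert baseline_distance(series([1.0, 0.9, 0.5, 0.1, 0], "NDR", scaled=False)) == 0.0
        assert baseline_distance(series([88, 80, 50, 20, 5], "PI", scaled=False)) == pytest.approx(12.0)
        assert baseline_distance(series([1.0, 1.0, 0.8, 0.3, 0.1], "GR", scaled=False)) == 0.0


class TestDss:
    def test_zero_response_scores_zero(self):
        res = fit_dose_response(series([0.0] * 5))
        assert compute_dss(res, series([0.0] * 5)) == 0.0

    def test_full_plateau_scores_maximum(self):
        s = series([100.0] * 5)
        assert compute_dss(fit_dose_response(s), s, DSSConfig(a_min=10)) == pytest.approx(100.0)

    def test_half_window_plateau_scores_half(self):
        # steep curve crossing a_min at the window midpoint
        curve = LogisticCurve(r_max=100.0, r_min=0.0, ec50=10**-7.0, slope=50.0)
        s = series(curve.predict(CONC5))
        fit = fit_dose_response(s)
        dss = 100.0 * _area(curve) / ((100 - 10) * 4.0)
        assert dss == pytest.approx(quadrature_dss(curve, CONC5), abs=1e-4)
        assert dss == pytest.approx(50.0, abs=1.0)

    def test_analytic_matches_quadrature_on_random_curves(self, rng):
        for _ in range(200):
            curve = LogisticCurve(
                r_max=rng.uniform(20, 120),
                r_min=rng.uniform(-20, 15),
                ec50=10 ** rng.uniform(-9, -5),
                slope=rng.uniform(0.3, 6.0) * rng.choice([-1, 1]),
            )
            s = series(curve.predict(CONC5))
            fit_res = fit_dose_response(s)
            # compare the integral itself, bypassing fit differences
            analytic = 100.0 * _area(curve) / (90.0 * 4.0)
            assert analytic == pytest.approx(quadrature_dss(curve, CONC5), abs=1e-6)
            assert compute_dss(fit_res, s) >= 0.0

    def test_monotone_in_responses(self):
        lo = series([0, 5, 20, 40, 50.0])
        hi = series([10, 15, 30, 60, 70.0])
        dss_lo = compute_dss(fit_dose_response(lo), lo)
        dss_hi = compute_dss(fit_dose_response(hi), hi)
        assert dss_hi >= dss_lo

    def test_unscaled_series_rejected(self):
        s = series([0.9, 0.5, 0.1, 0.0, 0.0], "NDR", scaled=False)
        with pytest.raises(ConfigurationError, match="scale"):
            compute_dss(fit_dose_response(s), s)

    def test_scale_series_marks_and_transforms(self):
        raw = series([1.0, 0.5, 0.0, -0.5, -1.0], "NDR", scaled=False)
        scaled = scale_series(raw)
        assert scaled.scaled
        np.testing.assert_allclose(scaled.responses, [0, 25, 50, 75, 100])


def _area(curve, a_min=10.0, conc=CONC5):
    from ndrscreen.dose_response import _area_above

    return _area_above(curve, a_min, np.log10(conc[0]), np.log10(conc[-1]))


class TestNegativeDss:
    def test_mirror_symmetry(self):
        neg = series([-20.0] * 5)
        pos = series([20.0] * 5)
        dss_pos = compute_dss(fit_dose_response(pos), pos)
        assert negative_dss(neg) == pytest.approx(-dss_pos)
        assert dss_pos > 0

    def test_zero_series_is_fixed_point(self):
        assert negative_dss(series([0.0] * 5)) == 0.0

    def test_stimulatory_ndr_series_scores_negative(self):
        # NDR 1.2 scales to -10% inhibition: exactly at the default a_min=10
        # boundary the mirrored excess has measure zero, so lower a_min to
        # expose the sign; a stronger stimulation is negative at the default.
        raw = DoseSeries("stim", CONC5, (1.2,) * 5, "NDR")
        value, _ = dss_for_series(raw, DSSConfig(a_min=5.0))
        assert value < 0
        stronger = DoseSeries("stim2", CONC5, (1.4,) * 5, "NDR")
        value_default, _ = dss_for_series(stronger)
        assert value_default < 0

    def test_mixed_signs_fall_back_to_plain_dss(self):
        mixed = series([-5.0, 0.0, 20.0, 60.0, 80.0])
        plain = compute_dss(fit_dose_response(mixed), mixed)
        assert negative_dss(mixed) == pytest.approx(plain)
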