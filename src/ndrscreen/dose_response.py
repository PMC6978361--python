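"""Four-parameter log-logistic dose-response fitting, RMSD, and DSS.

A drug's response series — one metric value per tested concentration —
is summarized by a four-parameter log-logistic (4PL) model fitted in
log10-concentration space::

    R(x) = R_min + (R_max - R_min) / (1 + 10^(slope * (log10(EC50) - x)))

with ``x = log10(concentration)``. The drug sensitivity score (DSS)
integrates the fitted curve above a minimum activity threshold ``A_min``
over the tested log-concentration window and normalizes so that a curve
pinned at 100% inhibition across the whole window scores 100::

    DSS = 100 * area(R - A_min; R >= A_min) / ((100 - A_min) * window)

The integral is evaluated in closed form (the 4PL has an elementary
antiderivative in log space). Growth-stimulatory drugs — uniformly
negative on the scaled inhibition axis — are scored by mirroring the
responses about the zero-inhibition baseline, fitting the mirrored
curve, and negating the resulting score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from ndrscreen.errors import ConfigurationError, FitError
from ndrscreen.response_metrics import METRICS, scale_for_dss

logger = logging.getLogger(__name__)

#: |scaled response| above this counts as a non-zero response when
#: selecting drugs for RMSD summaries.
NONZERO_RESPONSE_TOL = 1e-6


@dataclass(frozen=True)
class DoseSeries:
    """One drug's responses across an increasing concentration series.

    ``metric`` tags the scale of ``responses``; ``scaled`` records
    whether :func:`scale_series` has mapped them onto the
    percent-inhibition scale required by DSS.
    """

    drug_name: str
    concentrations: tuple
    responses: tuple
    metric: str
    scaled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
        if len(self.concentrations) != len(self.responses):
            raise FitError(
                f"{self.drug_name}: {len(self.concentrations)} concentrations vs "
                f"{len(self.responses)} responses"
            )
        if len(self.concentrations) == 0:
            raise FitError(f"{self.drug_name}: empty dose series")
        c = np.asarray(self.concentrations)
        if (c <= 0).any():
            raise FitError(f"{self.drug_name}: concentrations must be positive")
        if not (np.diff(c) > 0).all():
            raise FitError(f"{self.drug_name}: concentrations must be strictly increasing")
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")

    def __len__(self) -> int:
        return len(self.concentrations)


def scale_series(series: DoseSeries) -> DoseSeries:
    """Map a raw metric series onto the percent-inhibition scale for DSS."""
    if series.scaled:
        return series
    return replace(
        series,
        responses=tuple(scale_for_dss(series.metric, np.asarray(series.responses))),
        scaled=True,
    )


@dataclass(frozen=True)
class LogisticCurve:
    """Canonicalized 4PL parameters: ``r_max >= r_min``, ``ec50 > 0``.

    ``slope`` is the Hill slope at the inflection in log10 space; a
    positive slope means the response rises with concentration. A flat
    (degenerate) curve has ``r_min == r_max`` and ``slope == 0``.
    """

    r_max: float
    r_min: float
    ec50: float
    slope: float

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise FitError(f"ec50 must be > 0, got {self.ec50}")
        if self.r_max < self.r_min:
            raise FitError("curve not canonical: r_max < r_min")

    def predict(self, concentrations) -> np.ndarray:
        x = np.log10(np.asarray(concentrations, dtype=float))
        return _ll4(x, self.r_min, self.r_max, np.log10(self.ec50), self.slope)


@dataclass(frozen=True)
class CurveFitResult:
    curve: LogisticCurve
    observed: tuple
    fitted_values: tuple
    rmsd: float
    converged: bool
    n_points: int


def _ll4(x, r_min, r_max, log_ec50, slope):
    # evaluated via logaddexp for overflow safety at extreme slopes
    z = slope * np.log(10.0) * (np.asarray(x) - log_ec50)
    return r_min + (r_max - r_min) / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _canonicalize(r_min, r_max, log_ec50, slope) -> LogisticCurve:
    # (c, d, s) and (d, c, -s) describe the same curve; keep r_max >= r_min
    if r_max < r_min:
        r_min, r_max, slope = r_max, r_min, -slope
    if r_max == r_min:
        slope = 0.0
    return LogisticCurve(r_max=float(r_max), r_min=float(r_min), ec50=float(10.0 ** log_ec50), slope=float(slope))


def curve_rmsd(observed, estimated) -> float:
    """Root mean squared distance between observed and fitted responses."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if o.shape != e.shape:
        raise FitError(f"length mismatch: {o.shape} vs {e.shape}")
    if o.size == 0:
        raise FitError("RMSD needs at least one point")
    return float(np.sqrt(np.mean((o - e) ** 2)))


def fit_dose_response(series: DoseSeries, max_nfev: int = 2000) -> CurveFitResult:
    """Least-squares 4PL fit of a dose series in log10-concentration space.

    Levenberg-Marquardt from five data-driven starts: asymptotes from
    the extreme responses, EC50 from the concentration whose response is
    nearest the half-range, Hill slopes {0.5, 1, 2} signed by the
    observed trend, plus two alternative EC50 anchors. The candidate
    with the lowest residual sum of squares wins; ties go to the
    smallest |slope|. A series with identical responses yields the exact
    flat curve without optimization.
    """
    if len(series) < 4:
        raise FitError(f"{series.drug_name}: 4PL fit needs >= 4 points, got {len(series)}")
    x = np.log10(np.asarray(series.concentrations))
    y = np.asarray(series.responses)

    if np.ptp(y) == 0.0:
        curve = LogisticCurve(r_max=float(y[0]), r_min=float(y[0]),
                              ec50=float(10.0 ** np.mean(x)), slope=0.0)
        fitted = curve.predict(series.concentrations)
        return CurveFitResult(curve, tuple(y), tuple(fitted), curve_rmsd(y, fitted),
                              converged=True, n_points=len(series))

    lo, hi = float(y.min()), float(y.max())
    half = 0.5 * (lo + hi)
    ec50_half = x[np.argmin(np.abs(y - half))]
    trend = np.sign(np.corrcoef(x, y)[0, 1])
    if trend == 0 or np.isnan(trend):
        trend = 1.0
    starts = [
        (lo, hi, ec50_half, trend * 0.5),
        (lo, hi, ec50_half, trend * 1.0),
        (lo, hi, ec50_half, trend * 2.0),
        (lo, hi, float(np.mean(x)), trend * 1.0),
        (lo, hi, float(np.median(x)), trend * 1.0),
    ]

    def residuals(theta):
        return _ll4(x, *theta) - y

    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=max_nfev)
        except Exception:  # LM can fail on pathological starts; try the rest
            continue
        ssr = float(2.0 * sol.cost)
        cand = (ssr, abs(sol.x[3]), sol)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitError(f"{series.drug_name}: all optimizer starts failed")
    ssr, _, sol = best
    curve = _canonicalize(*sol.x)
    fitted = curve.predict(series.concentrations)
    return CurveFitResult(
        curve=curve,
        observed=tuple(y),
        fitted_values=tuple(float(v) for v in fitted),
        rmsd=curve_rmsd(y, fitted),
        converged=bool(sol.success),
        n_points=len(series),
    )


def baseline_distance(series: DoseSeries) -> float:
    """Deviation of the lowest-concentration response from its no-effect level.

    The baseline is 1 for NDR and GR series; for PI the distance is
    computed on the 100-anchored viability orientation
    (``viability = 100 * (1 - PI)``, baseline 100), so PI series must
    carry viability-scale responses. At the lowest tested concentration
    a drug is expected to have no effect; large deviations flag
    normalization artifacts that bias EC50 estimates.
    """
    first = series.responses[0]
    baseline = 100.0 if series.metric == "PI" else 1.0
    return abs(first - baseline)


@dataclass(frozen=True)
class DSSConfig:
    """DSS settings: ``a_min`` is the minimum activity threshold in
    percent-inhibition units below which a response does not contribute."""

    a_min: float = 10.0
    dss_normalization: str = "normalized_auc"

    def __post_init__(self) -> None:
        if not 0 <= self.a_min < 100:
            raise ConfigurationError(f"a_min must lie in [0, 100), got {self.a_min}")
        if self.dss_normalization != "normalized_auc":
            raise ConfigurationError(
                f"unknown dss_normalization {self.dss_normalization!r}"
            )


def _ll4_antiderivative(x, c, d, m, k):
    # F(x) for f(x) = c + (d-c)/(1+exp(-k(x-m))), k = slope*ln(10)
    return c * x + (d - c) / k * np.logaddexp(0.0, k * (x - m))


def _area_above(curve: LogisticCurve, a_min: float, x1: float, x2: float) -> float:
    """Closed-form area between the 4PL curve and a_min where R >= a_min,
    over the log10-concentration window [x1, x2]."""
    c, d, s = curve.r_min, curve.r_max, curve.slope
    if d <= a_min:
        return 0.0
    if s == 0.0 or c == d:  # flat curve above threshold
        return (c - a_min) * (x2 - x1) if c > a_min else 0.0
    k = s * np.log(10.0)
    m = np.log10(curve.ec50)
    if c >= a_min:
        a, b = x1, x2
    else:
        # crossing point R(x_c) = a_min
        x_c = m - np.log((d - a_min) / (a_min - c)) / k
        if k > 0:
            a, b = max(x1, x_c), x2
        else:
            a, b = x1, min(x2, x_c)
    if b <= a:
        return 0.0
    integral = _ll4_antiderivative(b, c, d, m, k) - _ll4_antiderivative(a, c, d, m, k)
    return float(integral - a_min * (b - a))


def compute_dss(fit: CurveFitResult, series: DoseSeries, config: DSSConfig | None = None) -> float:
    """DSS of a fitted curve over the series' tested concentration window.

    Requires the series on the scaled percent-inhibition axis (see
    :func:`scale_series`); normalized so a full-window 100%-inhibition
    plateau scores 100 and a curve never exceeding ``a_min`` scores 0.
    """
    config = config or DSSConfig()
    if not series.scaled:
        raise ConfigurationError(
            "DSS requires responses on the percent-inhibition scale; apply scale_series "
            "(scale_for_dss) before fitting"
        )
    x = np.log10(np.asarray(series.concentrations))
    x1, x2 = float(x.min()), float(x.max())
    if x2 <= x1:
        raise FitError("DSS needs a non-degenerate concentration window")
    area = _area_above(fit.curve, config.a_min, x1, x2)
    return 100.0 * area / ((100.0 - config.a_min) * (x2 - x1))


def negative_dss(series: DoseSeries, config: DSSConfig | None = None) -> float:
    """DSS for a growth-stimulatory drug, reported as a negative score.

    When every scaled response is negative (below the zero-inhibition
    baseline), the responses are mirrored about zero, the mirrored curve
    is fitted and scored, and the score is negated. Mixed-sign series
    fall back to the ordinary DSS of the original responses.
    """
    config = config or DSSConfig()
    if not series.scaled:
        raise ConfigurationError(
            "DSS requires responses on the percent-inhibition scale; apply scale_series first"
        )
    y = np.asarray(series.responses)
    if (y == 0).all():
        return 0.0
    if (y < 0).all():
        mirrored = replace(series, responses=tuple(-y))
        fit = fit_dose_response(mirrored)
        return -compute_dss(fit, mirrored, config)
    logger.info(
        "%s: responses are not uniformly negative; scoring the original series",
        series.drug_name,
    )
    fit = fit_dose_response(series)
    return compute_dss(fit, series, config)


def dss_for_series(series: DoseSeries, config: DSSConfig | None = None) -> tuple[float, CurveFitResult]:
    """Score one series end to end: scale, route to the mirrored branch for
    uniformly stimulatory drugs, otherwise fit and integrate. Returns
    (dss, fit of the series actually fitted)."""
    config = config or DSSConfig()
    scaled = scale_series(series)
    y = np.asarray(scaled.responses)
    if (y < 0).all():
        mirrored = replace(scaled, responses=tuple(-y))
        fit = fit_dose_response(mirrored)
        return -compute_dss(fit, mirrored, config), fit
    fit = fit_dose_response(scaled)
    return compute_dss(fit, scaled, config), fit
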