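"""Concentration and enrichment calibrations.

Two linear calibrations anchor the tracer workflow to absolute scales:

* body-water ²H enrichment, read off a line fitted to acetone-exchange
  standards of known ²H mol-fraction excess (gravimetric mixtures of natural
  water and 99.9% ²H₂O);
* analyte concentration, from internal-standard calibration curves
  (analyte/IS peak-area ratio against known amounts).

Plus the bookkeeping that turns compartment concentrations into body-mass
normalized totals (concentration x compartment mass / body mass).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


class ExtrapolationWarning(UserWarning):
    """Sample response lies outside the calibrated range."""


class BelowCurveWarning(UserWarning):
    """Response below the curve intercept; concentration floored at 0."""


@dataclass
class CalibrationCurve:
    """A fitted response line: response = slope * quantity + intercept."""

    slope: float
    intercept: float
    r: float
    x_range: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("flat or inverted calibration: slope must be > 0")

    @property
    def r_squared(self) -> float:
        return self.r**2

    def response(self, quantity):
        return self.slope * np.asarray(quantity, dtype=float) + self.intercept

    def invert(self, response, warn_extrapolation: bool = True):
        """Quantity at a measured response; flags extrapolation."""
        q = (np.asarray(response, dtype=float) - self.intercept) / self.slope
        lo, hi = self.x_range
        if warn_extrapolation and hi > lo and np.any((q < lo) | (q > hi)):
            warnings.warn(
                "response outside calibrated range; extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return float(q) if np.ndim(response) == 0 else q


def fit_calibration(points=None, x=None, y=None, weighting: str | None = None) -> CalibrationCurve:
    """Least-squares calibration line through (known quantity, response) points.

    ``weighting="1/x"`` applies inverse-concentration weights (zero-quantity
    points get the weight of the smallest positive quantity); default is
    ordinary least squares.
    """
    if points is not None:
        pts = np.asarray(points, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate calibration: need >= 2 distinct known quantities")
    if weighting == "1/x":
        floor = x[x > 0].min() if (x > 0).any() else 1.0
        w = 1.0 / np.maximum(x, floor)
    elif weighting is None:
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        x_range=(float(x.min()), float(x.max())),
    )


class LinearCalibrator(RegressorMixin, BaseEstimator):
    """Internal-standard calibration line as a fit/predict estimator.

    ``fit(x, y)`` regresses response (analyte/IS area ratio) on known
    quantity; ``predict`` maps quantity to response and ``inverse`` maps a
    measured response back to quantity.

    Attributes: ``slope_``, ``intercept_``, ``r_``, ``curve_``.
    """

    def __init__(self, weighting: str | None = None):
        self.weighting = weighting

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        self.curve_ = fit_calibration(x=x, y=np.asarray(y, dtype=float),
                                      weighting=self.weighting)
        self.slope_ = self.curve_.slope
        self.intercept_ = self.curve_.intercept
        self.r_ = self.curve_.r
        return self

    def predict(self, X):
        return self.curve_.response(np.asarray(X, dtype=float).ravel())

    def inverse(self, response, warn_extrapolation: bool = True):
        return self.curve_.invert(response, warn_extrapolation)


def quantify(analyte_area: float, is_area: float, curve: CalibrationCurve) -> float:
    """Concentration from peak areas via an internal-standard curve.

    response = analyte area / IS area; concentration = (response - intercept)
    / slope, floored at 0 (with a warning) when the response falls below the
    curve intercept.
    """
    if is_area <= 0:
        raise ValueError("internal standard missing (area <= 0)")
    if analyte_area < 0:
        raise ValueError("analyte area must be >= 0")
    response = analyte_area / is_area
    conc = (response - curve.intercept) / curve.slope
    if -1e-12 < conc < 0:  # round-off at the intercept is not a below-curve event
        return 0.0
    if conc < 0:
        warnings.warn(
            f"response {response:.4g} below curve; concentration floored at 0",
            BelowCurveWarning,
            stacklevel=2,
        )
        return 0.0
    return float(conc)


@dataclass
class WaterEnrichmentMeasurement:
    """An animal's acetone signal ratio plus the gravimetric standards run with it.

    ``standards`` is a list of (known ²H mol-fraction excess, signal ratio);
    the known fractions must lie in [0, 0.10] (heavy-water dosing targets a
    few percent body-water enrichment).
    """

    sample_id: str
    ratio: float
    standards: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.standards) < 2:
            raise ValueError("need >= 2 water-enrichment standards")
        for frac, _ in self.standards:
            if not 0.0 <= frac <= 0.10:
                raise ValueError(f"standard fraction {frac} outside [0, 0.10]")


def water_enrichment(meas: WaterEnrichmentMeasurement) -> float:
    """Body-water ²H mol-fraction excess p from an acetone-exchange measurement.

    Fits the standards' line (signal ratio vs known fraction) and inverts it
    at the sample's ratio; warns when the sample ratio falls outside the
    standards' range (extrapolation).
    """
    std = np.asarray(meas.standards, dtype=float)
    curve = fit_calibration(x=std[:, 0], y=std[:, 1])
    lo, hi = std[:, 1].min(), std[:, 1].max()
    if not lo <= meas.ratio <= hi:
        warnings.warn(
            f"sample {meas.sample_id}: acetone ratio outside standard range",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return curve.invert(meas.ratio, warn_extrapolation=False)


class WaterEnrichmentCalibrator(RegressorMixin, BaseEstimator):
    """Acetone-exchange body-water calibration as a fit/predict estimator.

    ``fit(known_fractions, ratios)`` fits the standards' line; ``predict``
    maps sample acetone signal ratios to ²H mol-fraction excess.
    """

    def __init__(self, warn_extrapolation: bool = True):
        self.warn_extrapolation = warn_extrapolation

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        if np.any((x < 0) | (x > 0.10)):
            raise ValueError("standard fractions must lie in [0, 0.10]")
        self.curve_ = fit_calibration(x=x, y=np.asarray(y, dtype=float))
        self.ratio_range_ = (float(np.min(y)), float(np.max(y)))
        return self

    def predict(self, X):
        ratios = np.asarray(X, dtype=float).ravel()
        lo, hi = self.ratio_range_
        if self.warn_extrapolation and np.any((ratios < lo) | (ratios > hi)):
            warnings.warn(
                "acetone ratio outside standard range",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return (ratios - self.curve_.intercept) / self.curve_.slope


@dataclass
class PoolMeasurement:
    """A compartment concentration with the masses needed to normalize it."""

    analyte_id: str
    concentration: float  # µg/g tissue (or µmol/L for fluids)
    compartment_mass_g: float | None
    body_mass_g: float | None
    compartment: str = "liver"

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def total_content(pool: PoolMeasurement) -> float:
    """Body-mass-normalized total: concentration x compartment mass / body mass.

    The compartment total (e.g. all bile acid in the intestine or a week's
    feces) divided by body mass, in µg per g body mass.
    """
    for name in ("compartment_mass_g", "body_mass_g"):
        value = getattr(pool, name)
        if value is None:
            raise ValueError(f"missing field {name!r} on pool measurement")
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    return pool.concentration * pool.compartment_mass_g / pool.body_mass_g
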