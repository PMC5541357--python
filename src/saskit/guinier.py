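"""Guinier analysis: radius of gyration and forward intensity.

At low angles a globular particle obeys
ln I(s) ~ ln I(0) - (s R_g)^2 / 3, so a weighted linear regression of
ln I against s^2 over a suitable window yields R_g and I(0). Modified
transforms handle elongated and flattened particles: for rods,
ln(s I) against s^2 gives the cross-section radius R_c (slope -R_c^2/2);
for sheets, ln(s^2 I) gives the thickness radius R_t (slope -R_t^2).

:func:`autorg` automates the choice of the fit window by scanning all
candidate windows that satisfy the s_max * R_g cap self-consistently and
scoring them on fit quality, window length, use of the allowed range
and retention of the lowest angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve import ScatteringCurve

__all__ = ["GuinierFit", "guinier_fit", "autorg", "DEFAULT_SRG_CAPS"]

# standard practice caps on s*R_g for the three geometries
DEFAULT_SRG_CAPS = {"globular": 1.3, "rod": 1.0, "sheet": 0.8}

_SLOPE_FACTOR = {"globular": 3.0, "rod": 2.0, "sheet": 1.0}
_MIN_WINDOW = 5


@dataclass
class GuinierFit:
    """Result of a Guinier regression.

    ``rg`` is the radius of gyration for globular geometry, the
    cross-section radius R_c for rods, or the thickness radius R_t for
    sheets (all in the reciprocal of the curve's s unit, canonically A).
    """

    i0: float
    rg: float
    geometry: str
    interval: tuple[int, int]  # inclusive index range
    srg_min: float
    srg_max: float
    rg_stderr: float
    i0_stderr: float
    quality: float


def _transform(curve: ScatteringCurve, idx: np.ndarray, geometry: str):
    s = curve.s[idx]
    i = curve.i[idx]
    if geometry == "globular":
        t = i
    elif geometry == "rod":
        t = s * i
    elif geometry == "sheet":
        t = s**2 * i
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if np.any(t <= 0):
        raise ValueError("non-positive transformed intensities in the fit interval")
    y = np.log(t)
    if curve.sigma is not None:
        # d(ln t)/dI = 1/I for every transform
        sigma_y = curve.sigma[idx] / i
    else:
        sigma_y = np.ones_like(y)
    return s**2, y, sigma_y


def _weighted_line(x: np.ndarray, y: np.ndarray, sigma_y: np.ndarray):
    """Weighted LSQ line fit: returns slope, intercept, their sigmas, R^2."""
    w = 1.0 / sigma_y**2
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    var_slope = sw / det
    var_intercept = swxx / det
    resid = y - (slope * x + intercept)
    ybar = swy / sw
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - (w * resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, np.sqrt(var_slope), np.sqrt(var_intercept), r2


def guinier_fit(
    curve: ScatteringCurve,
    interval: tuple[int, int],
    geometry: str = "globular",
) -> GuinierFit:
    """Weighted Guinier regression over an explicit index interval.

    ``interval`` is the inclusive (first, last) index range. Errors on
    R_g and I(0) come from the regression covariance with weights
    1/sigma_y^2, sigma_y = sigma/I through the log transform.
    """
    first, last = interval
    idx = np.arange(first, last + 1)
    if len(idx) < _MIN_WINDOW:
        raise ValueError(f"interval too short: need >= {_MIN_WINDOW} points")
    x, y, sigma_y = _transform(curve, idx, geometry)
    slope, intercept, slope_err, intercept_err, r2 = _weighted_line(x, y, sigma_y)
    factor = _SLOPE_FACTOR[geometry]
    if slope >= 0:
        raise ValueError("non-negative Guinier slope; no decaying low-angle regime")
    rg = float(np.sqrt(-factor * slope))
    rg_err = float(factor * slope_err / (2.0 * rg))
    i0 = float(np.exp(intercept))
    i0_err = float(i0 * intercept_err)
    return GuinierFit(
        i0=i0,
        rg=rg,
        geometry=geometry,
        interval=(int(first), int(last)),
        srg_min=float(curve.s[first] * rg),
        srg_max=float(curve.s[last] * rg),
        rg_stderr=rg_err,
        i0_stderr=i0_err,
        quality=float(max(min(r2, 1.0), 0.0)),
    )


def autorg(
    curve: ScatteringCurve,
    geometry: str = "globular",
    srg_cap: float | None = None,
    min_window: int = _MIN_WINDOW,
) -> GuinierFit:
    """Automatic Guinier-interval selection.

    Scans candidate windows of >= ``min_window`` points whose upper
    bound satisfies s_max * R_g <= cap with the R_g fitted from the
    window itself (self-consistency). Each valid window is scored by a
    weighted geometric mean of fit R^2 (weight 0.4), window length
    relative to the allowed range (0.3), closeness of the reached
    s_max * R_g to the cap (0.2) and a penalty for discarding low-angle
    points (0.1); the best-scoring window wins, ties going to the
    earliest start.
    """
    if len(curve) < 20:
        raise ValueError("autorg needs at least 20 points")
    curve.require_sigma("autorg")
    cap = srg_cap if srg_cap is not None else DEFAULT_SRG_CAPS[geometry]

    n = len(curve)
    positive = curve.i > 0
    # candidate starts: skip leading non-positive points
    best_fit: GuinierFit | None = None
    best_score = -np.inf

    # precompute a pilot Rg from the first decaying stretch to bound the scan
    for first in range(0, n - min_window + 1):
        if not positive[first]:
            continue
        # grow the window greedily; refit at each length
        last_limit = n - 1
        for last in range(first + min_window - 1, last_limit + 1):
            if not np.all(positive[first : last + 1]):
                break
            try:
                fit = guinier_fit(curve, (first, last), geometry)
            except ValueError:
                continue
            if fit.srg_max > cap:
                break  # larger windows only increase s_max
            score = _window_score(curve, fit, cap, n)
            if score > best_score + 1e-12:
                best_score = score
                best_fit = fit
        # stop scanning once the start itself is beyond the cap of the best fit
        if best_fit is not None and curve.s[first] * best_fit.rg > cap:
            break
    if best_fit is None:
        raise ValueError("no valid Guinier region found")
    best_fit.quality = float(best_score)
    return best_fit


def _window_score(curve: ScatteringCurve, fit: GuinierFit, cap: float, n: int) -> float:
    first, last = fit.interval
    # (a) weighted R^2 of the fit
    r2 = fit.quality
    # (b) fraction of the allowed s range [s_first_usable, cap/rg] covered
    s_hi_allowed = cap / fit.rg
    s_lo = float(curve.s[0])
    denom = max(s_hi_allowed - s_lo, 1e-12)
    length = (curve.s[last] - curve.s[first]) / denom
    length = min(max(length, 0.0), 1.0)
    # (c) closeness of reached srg_max to the cap
    closeness = min(max(fit.srg_max / cap, 0.0), 1.0)
    # (d) penalty for discarding low-s points
    start_pen = 1.0 - first / max(n - 1, 1)
    parts = np.array([r2, length, closeness, start_pen])
    weights = np.array([0.4, 0.3, 0.2, 0.1])
    parts = np.clip(parts, 1e-6, 1.0)
    return float(np.exp((weights * np.log(parts)).sum()))
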