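"""Arithmetic, averaging, scaling/merging, rebinning and calibration.

These are the primary-data-reduction steps applied between background
subtraction and structural analysis: pointwise arithmetic, replicate
averaging, scale/shift matching of related measurements, merging of a
dilution series, extrapolation to infinite dilution, cropping,
regridding and absolute-scale calibration against water.

Error propagation is first-order Gaussian throughout, appropriate for
background-subtracted counting statistics at typical count levels.
Curve arithmetic never interpolates silently: grids must match to a
relative tolerance of 1e-6, and an explicit :func:`regrid` is required
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve import ScatteringCurve

__all__ = [
    "ScaleShift",
    "MergeResult",
    "average_curves",
    "arith",
    "scale_shift_match",
    "merge_ranges",
    "extrapolate_zero_concentration",
    "crop",
    "regrid",
    "to_absolute_scale",
    "WATER_CONSTANT_20C",
]

# Absolute differential scattering cross-section of water at 20 C, cm^-1,
# from the standard water-calibration literature. Configurable everywhere
# it is used; never assumed silently.
WATER_CONSTANT_20C = 0.01632

_GRID_RTOL = 1e-6


@dataclass
class ScaleShift:
    """Result of matching one curve onto another: I_ref ~ factor*I + shift."""

    factor: float
    shift: float
    fit_range: tuple[float, float]


@dataclass
class MergeResult:
    """A merged low/high-concentration curve with per-point provenance."""

    merged: ScatteringCurve
    overlap: tuple[float, float]
    scale_applied: float
    source_map: np.ndarray  # array of "low" | "high" strings


def _check_common_grid(curves: list[ScatteringCurve]) -> np.ndarray:
    s0 = curves[0].s
    for c in curves[1:]:
        if len(c.s) != len(s0) or not np.allclose(c.s, s0, rtol=_GRID_RTOL, atol=0):
            raise ValueError("grid mismatch: curves are not on a common s grid")
    return s0


def average_curves(curves: list[ScatteringCurve]) -> ScatteringCurve:
    """Inverse-variance weighted pointwise mean of replicate curves.

    All curves must share the s grid (to 1e-6 relative) and carry
    errors. The output error is the standard combined-estimate error
    sigma_out = (sum sigma_k^-2)^(-1/2); for N equal-sigma replicates
    this is sigma/sqrt(N).
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    s = _check_common_grid(curves)
    weights = np.array([1.0 / c.require_sigma("average_curves") ** 2 for c in curves])
    intensities = np.array([c.i for c in curves])
    wsum = weights.sum(axis=0)
    i_mean = (weights * intensities).sum(axis=0) / wsum
    sigma = 1.0 / np.sqrt(wsum)
    meta = {"operation": f"average of {len(curves)} curves"}
    return ScatteringCurve(s=s.copy(), i=i_mean, sigma=sigma, unit=curves[0].unit, meta=meta)


def arith(
    a: ScatteringCurve,
    b: ScatteringCurve | float,
    op: str,
) -> ScatteringCurve:
    """Pointwise arithmetic on curves: add | sub | mul | div.

    ``b`` may be a curve on the same grid or a scalar. Errors propagate
    by first-order rules: quadrature for add/sub, relative quadrature
    for mul/div of curves, plain scaling for scalar mul/div.
    """
    if op not in ("add", "sub", "mul", "div"):
        raise ValueError(f"unknown operation {op!r}")
    if isinstance(b, ScatteringCurve):
        _check_common_grid([a, b])
        ib = b.i
        sb = b.sigma
        if op == "div" and np.any(ib == 0):
            raise ZeroDivisionError("division by a curve containing zero intensity")
    else:
        ib = float(b)
        sb = None
        if op == "div" and ib == 0:
            raise ZeroDivisionError("division by scalar zero")

    ia, sa = a.i, a.sigma
    if op == "add":
        i_out = ia + ib
    elif op == "sub":
        i_out = ia - ib
    elif op == "mul":
        i_out = ia * ib
    else:
        i_out = ia / ib

    sigma_out = None
    if op in ("add", "sub"):
        if sa is not None and sb is not None:
            sigma_out = np.hypot(sa, sb)
        elif sa is not None:
            sigma_out = sa.copy()
        elif sb is not None:
            sigma_out = np.asarray(sb).copy()
    else:  # mul / div
        if isinstance(b, ScatteringCurve):
            # relative errors add in quadrature
            parts = []
            if sa is not None:
                parts.append((sa / ia) ** 2)
            if sb is not None:
                parts.append((sb / ib) ** 2)
            if parts:
                with np.errstate(invalid="ignore", divide="ignore"):
                    rel = np.sqrt(np.sum(parts, axis=0))
                sigma_out = np.abs(i_out) * rel
        else:
            if sa is not None:
                sigma_out = sa * abs(ib) if op == "mul" else sa / abs(ib)
    if sigma_out is not None:
        # arithmetic can produce exact zeros (e.g. c - c); keep sigma valid
        sigma_out = np.where(sigma_out > 0, sigma_out, np.finfo(float).tiny)
    meta = dict(a.meta)
    meta["operation"] = f"arith {op}"
    return ScatteringCurve(s=a.s.copy(), i=i_out, sigma=sigma_out, unit=a.unit, meta=meta)


def scale_shift_match(
    target: ScatteringCurve,
    reference: ScatteringCurve,
    fit_range: tuple[float, float] | None = None,
    allow_shift: bool = True,
) -> ScaleShift:
    """Least-squares match of ``target`` onto ``reference``.

    Finds (factor, shift) minimizing
    sum w * (factor*I_target + shift - I_reference)^2 over the common
    points in ``fit_range``, with w = sigma_ref^-2 when the reference
    carries errors and 1 otherwise. With ``allow_shift=False`` the shift
    is fixed at zero (pure rescale).
    """
    _check_common_grid([target, reference])
    s = target.s
    if fit_range is None:
        mask = np.ones(len(s), dtype=bool)
        fit_range = (float(s[0]), float(s[-1]))
    else:
        mask = (s >= fit_range[0]) & (s <= fit_range[1])
    if mask.sum() < 5:
        raise ValueError("insufficient overlap: need >= 5 points in the fit range")
    x = target.i[mask]
    y = reference.i[mask]
    w = 1.0 / reference.sigma[mask] ** 2 if reference.sigma is not None else np.ones(mask.sum())
    if allow_shift:
        # weighted linear LSQ for y = f*x + c
        sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
        swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
        det = sw * swxx - swx**2
        if det <= 0:
            raise ValueError("degenerate fit range")
        factor = (sw * swxy - swx * swy) / det
        shift = (swxx * swy - swx * swxy) / det
    else:
        factor = (w * x * y).sum() / (w * x * x).sum()
        shift = 0.0
    if factor <= 0:
        raise ValueError("non-positive scale factor; curves are incompatible")
    return ScaleShift(factor=float(factor), shift=float(shift), fit_range=fit_range)


def merge_ranges(
    low: ScatteringCurve,
    high: ScatteringCurve,
    low_keep: tuple[float, float],
    high_keep: tuple[float, float],
) -> MergeResult:
    """Merge low-angle data of a dilute sample with high-angle data.

    The high-concentration curve is scaled (no shift) onto the
    low-concentration curve over the overlap of the two keep-intervals;
    the merged curve takes low-curve points below the overlap midpoint
    and scaled high-curve points above it.
    """
    lo, hi = max(low_keep[0], high_keep[0]), min(low_keep[1], high_keep[1])
    ov_lo = max(lo, float(high.s[0]), float(low.s[0]))
    ov_hi = min(hi, float(low.s[-1]), float(high.s[-1]))
    if ov_lo >= ov_hi:
        raise ValueError("no overlap between the keep intervals")
    # match on high's grid points inside the overlap, reference = low interpolated
    m_high = (high.s >= ov_lo) & (high.s <= ov_hi)
    if m_high.sum() < 5:
        raise ValueError("insufficient overlap: need >= 5 high-curve points")
    low_on_high = np.interp(high.s[m_high], low.s, low.i)
    ref_sigma = (
        np.interp(high.s[m_high], low.s, low.sigma) if low.sigma is not None else None
    )
    x = high.i[m_high]
    w = 1.0 / ref_sigma**2 if ref_sigma is not None else np.ones(len(x))
    factor = float((w * x * low_on_high).sum() / (w * x * x).sum())
    if factor <= 0:
        raise ValueError("non-positive merge scale factor")

    mid = 0.5 * (ov_lo + ov_hi)
    keep_low = (low.s >= low_keep[0]) & (low.s <= mid)
    keep_high = (high.s > mid) & (high.s <= high_keep[1])
    s_m = np.concatenate([low.s[keep_low], high.s[keep_high]])
    i_m = np.concatenate([low.i[keep_low], factor * high.i[keep_high]])
    sigma_m = None
    if low.sigma is not None and high.sigma is not None:
        sigma_m = np.concatenate([low.sigma[keep_low], factor * high.sigma[keep_high]])
    source = np.array(["low"] * int(keep_low.sum()) + ["high"] * int(keep_high.sum()))
    if np.any(np.diff(s_m) <= 0):
        raise ValueError("merged grid not strictly increasing; adjust keep intervals")
    merged = ScatteringCurve(
        s=s_m,
        i=i_m,
        sigma=sigma_m,
        unit=low.unit,
        meta={"operation": "merge", "overlap": (ov_lo, ov_hi), "scale": factor},
    )
    return MergeResult(merged=merged, overlap=(ov_lo, ov_hi), scale_applied=factor, source_map=source)


def extrapolate_zero_concentration(
    series: list[tuple[ScatteringCurve, float]],
) -> ScatteringCurve:
    """Extrapolate a concentration series to infinite dilution.

    For each s point, I/c is regressed against c by weighted linear
    least squares and the intercept at c = 0 is returned, with its
    regression standard error as sigma. Exact (to machine precision)
    when I(s, c)/c is linear in c.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 concentrations")
    concs = np.array([c for _, c in series], dtype=float)
    if len(np.unique(concs)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    curves = [c for c, _ in series]
    s = _check_common_grid(curves)

    n_pt = len(s)
    y = np.array([c.i for c in curves]) / concs[:, None]  # (k, n): I/c
    if all(c.sigma is not None for c in curves):
        w = np.array([1.0 / (c.sigma / cc) ** 2 for c, cc in zip(curves, concs)])
    else:
        w = np.ones((len(curves), n_pt))

    x = concs[:, None] * np.ones((1, n_pt))
    sw = w.sum(axis=0)
    swx = (w * x).sum(axis=0)
    swy = (w * y).sum(axis=0)
    swxx = (w * x * x).sum(axis=0)
    swxy = (w * x * y).sum(axis=0)
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    # standard error of the intercept under the stated weights
    sigma_intercept = np.sqrt(swxx / det)
    meta = {"operation": "zero-concentration extrapolation", "concentrations": list(concs)}
    return ScatteringCurve(s=s.copy(), i=intercept, sigma=sigma_intercept, unit=curves[0].unit, meta=meta)


def crop(curve: ScatteringCurve, smin: float, smax: float) -> ScatteringCurve:
    """Restrict a curve to the closed interval [smin, smax]."""
    if smin >= smax:
        raise ValueError("smin must be < smax")
    mask = (curve.s >= smin) & (curve.s <= smax)
    if mask.sum() < 2:
        raise ValueError("crop leaves fewer than 2 points")
    out = ScatteringCurve(
        s=curve.s[mask].copy(),
        i=curve.i[mask].copy(),
        sigma=curve.sigma[mask].copy() if curve.sigma is not None else None,
        unit=curve.unit,
        meta=dict(curve.meta),
    )
    out.meta["crop"] = (float(smin), float(smax))
    return out


def regrid(
    curve: ScatteringCurve,
    mode: str,
    param: int | ScatteringCurve | np.ndarray,
) -> ScatteringCurve:
    """Re-bin (``mode='bin-by-k'``) or interpolate onto a template grid.

    Binning averages consecutive groups of k points (s by arithmetic
    mean, I by inverse-variance mean when errors are present, errors
    combined accordingly). Template mode linearly interpolates I and
    sigma onto the template s values; extrapolation is refused.
    """
    if mode == "bin-by-k":
        k = int(param)
        if k < 2:
            raise ValueError("bin factor k must be >= 2")
        n = (len(curve) // k) * k
        if n < 2 * k:
            raise ValueError("too few points to bin")
        s_g = curve.s[:n].reshape(-1, k)
        i_g = curve.i[:n].reshape(-1, k)
        s_new = s_g.mean(axis=1)
        if curve.sigma is not None:
            w = 1.0 / curve.sigma[:n].reshape(-1, k) ** 2
            i_new = (w * i_g).sum(axis=1) / w.sum(axis=1)
            sigma_new = 1.0 / np.sqrt(w.sum(axis=1))
        else:
            i_new = i_g.mean(axis=1)
            sigma_new = None
        meta = dict(curve.meta)
        meta["regrid"] = f"bin-by-{k}"
        return ScatteringCurve(s=s_new, i=i_new, sigma=sigma_new, unit=curve.unit, meta=meta)

    if mode == "template-grid":
        template = param.s if isinstance(param, ScatteringCurve) else np.asarray(param, dtype=float)
        if template[0] < curve.s[0] - 1e-12 or template[-1] > curve.s[-1] + 1e-12:
            raise ValueError("template grid outside the curve support; no extrapolation")
        i_new = np.interp(template, curve.s, curve.i)
        sigma_new = (
            np.interp(template, curve.s, curve.sigma) if curve.sigma is not None else None
        )
        meta = dict(curve.meta)
        meta["regrid"] = "template"
        return ScatteringCurve(
            s=template.copy(), i=i_new, sigma=sigma_new, unit=curve.unit, meta=meta
        )
    raise ValueError(f"unknown regrid mode {mode!r}")


def to_absolute_scale(
    sample: ScatteringCurve,
    water_minus_empty: ScatteringCurve,
    water_constant: float = WATER_CONSTANT_20C,
    plateau_range: tuple[float, float] | None = None,
) -> ScatteringCurve:
    """Calibrate a sample curve to absolute units (cm^-1) against water.

    The flat plateau of the water-minus-empty-cell curve is averaged
    over ``plateau_range`` and the sample is multiplied by
    water_constant / plateau_mean.
    """
    w = water_minus_empty
    if plateau_range is None:
        plateau_range = (float(w.s[0]), float(w.s[-1]))
    mask = (w.s >= plateau_range[0]) & (w.s <= plateau_range[1])
    if not mask.any():
        raise ValueError("plateau range contains no water-curve points")
    plateau_mean = float(w.i[mask].mean())
    if plateau_mean <= 0:
        raise ValueError("non-positive water plateau mean; cannot calibrate")
    factor = water_constant / plateau_mean
    out = arith(sample, factor, "mul")
    out.meta["operation"] = "absolute calibration"
    out.meta["intensity_unit"] = "cm^-1"
    out.meta["calibration_factor"] = factor
    return out
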