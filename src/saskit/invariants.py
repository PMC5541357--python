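"""Concentration-independent invariants, MW estimation, Shannon analysis.

The Porod invariant Q = int s^2 I ds links the forward intensity to the
excluded (Porod) volume V_p = 2 pi^2 I(0) / Q; the volume of
correlation V_c = I(0) / int s I ds yields the concentration-independent
MW estimator QR = V_c^2 / R_g. Both integrals need the unmeasured
origin region, which is completed analytically with the Guinier model,
and the Porod integral additionally needs the high-angle tail beyond
the last measured point, completed with the fitted Porod asymptote
A/s^4.

Shannon-sampling analysis counts the information content of a curve:
a particle of maximum dimension D_max sampled on [s_min, s_max] carries
N_s = D_max (s_max - s_min) / pi independent channels, and the useful
angular range is where those channel amplitudes remain statistically
significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coefficients import (
    DEFAULT_COEFFICIENTS,
    RESIDUE_MASSES,
    RESIDUE_PSV,
    WATER_MASS,
)
from .curve import ScatteringCurve

__all__ = [
    "MwReport",
    "SequenceStats",
    "porod_volume",
    "mw_from_vc",
    "mw_from_mow",
    "mw_from_absolute_i0",
    "sequence_stats",
    "shannon_channels",
    "useful_angular_range",
    "mw_report",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23


@dataclass
class MwReport:
    """Collected invariants and MW estimates for one curve."""

    q_invariant: float
    vp: float
    vc: float
    qr: float
    ns: float
    mw_estimates: list[tuple[str, float, dict]] = field(default_factory=list)


@dataclass
class SequenceStats:
    n_residues: int
    mw: float  # Da
    psv: float  # cm^3 / g


def _guinier_lowangle_integral(i0: float, rg: float, s_hi: float, power: int) -> float:
    """int_0^s_hi s^power * i0 * exp(-(s rg)^2 / 3) ds by fine quadrature."""
    s = np.linspace(0.0, s_hi, 512)
    return float(np.trapezoid(s**power * i0 * np.exp(-((s * rg) ** 2) / 3.0), s))


def _porod_background(curve: ScatteringCurve) -> tuple[float, float]:
    """Fit s^4 I = K s^4 + A over the top 20% of the s range.

    Returns (K, A): K is a flat residual background, A the Porod
    asymptote constant of s^-4 decay.
    """
    s, i = curve.s, curve.i
    cut = s[-1] - 0.2 * (s[-1] - s[0])
    mask = s >= cut
    if mask.sum() < 3:
        mask = np.zeros(len(s), dtype=bool)
        mask[-3:] = True
    x = s[mask] ** 4
    y = x * i[mask]
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _porod_extrapolate(s: np.ndarray, q_partial: np.ndarray, window: float = 0.4):
    """Asymptotic completion of the running Porod integral.

    For a compact uniform particle I(s) -> K + A s^-4 (with form-factor
    oscillations around the asymptote), so the running invariant obeys

        Q(s) = int_0^s u^2 I du = Q_inf + K s^3 / 3 - A / s + ripple,

    where the ripple damps at least as 1/s. A linear fit of Q(s)
    against [1, s^3, 1/s] over the top ``window`` fraction of the range
    integrates out the oscillations and yields the completed invariant
    Q_inf, the flat background K and the Porod constant A directly.
    """
    cut = s[-1] - window * (s[-1] - s[0])
    mask = s >= cut
    design = np.column_stack(
        [np.ones(mask.sum()), s[mask] ** 3 / 3.0, -1.0 / s[mask]]
    )
    coef, *_ = np.linalg.lstsq(design, q_partial[mask], rcond=None)
    q_inf, k_const, a_porod = coef
    return float(q_inf), float(k_const), float(a_porod)


def porod_volume(
    curve: ScatteringCurve,
    i0: float,
    rg: float,
    smax_cut: float | None = None,
    subtract_constant: bool = True,
    extend_tail: bool = True,
) -> tuple[float, float]:
    """Porod invariant Q and Porod volume V_p = 2 pi^2 I(0) / Q.

    The running invariant int_0^s u^2 I du (origin completed with the
    Guinier model below the first data point) is extrapolated to
    s -> infinity through its asymptotic form
    Q_inf + K s^3/3 - A/s, which simultaneously estimates and removes
    a flat background K and adds the missing high-angle tail of the
    fitted Porod asymptote A/s^4. With ``subtract_constant`` and
    ``extend_tail`` both off, the plain truncated integral (apparent
    invariant) is returned instead.
    """
    if i0 <= 0 or rg <= 0:
        raise ValueError("need positive i0 and rg")
    smax = float(curve.s[-1]) if smax_cut is None else float(smax_cut)
    mask = curve.s <= smax
    s, i = curve.s[mask], curve.i[mask]
    if len(s) < 5:
        raise ValueError("too few points below smax_cut")
    q0 = _guinier_lowangle_integral(i0, rg, float(s[0]), power=2)
    from scipy.integrate import cumulative_trapezoid

    q_running = q0 + cumulative_trapezoid(s**2 * i, s, initial=0.0)
    if subtract_constant or extend_tail:
        q_inf, k_const, _ = _porod_extrapolate(s, q_running)
        if not subtract_constant:
            # keep any flat background in the invariant; only add the tail
            q_inf = q_inf + k_const * s[-1] ** 3 / 3.0
        if not extend_tail:
            q_inf = float(q_running[-1] - k_const * s[-1] ** 3 / 3.0)
        q = q_inf
    else:
        q = float(q_running[-1])
    if q <= 0:
        raise ValueError("non-positive Porod invariant")
    vp = 2.0 * math.pi**2 * i0 / q
    return float(q), float(vp)


def mw_from_vc(
    curve: ScatteringCurve,
    i0: float,
    rg: float,
    smax_cut: float = 0.3,
    molecule_class: str = "protein",
    coefficients: dict | None = None,
) -> tuple[float, float, float]:
    """Volume of correlation V_c, QR = V_c^2/R_g, and the MW estimate.

    V_c = I(0) / int_0^smax s I ds with the origin region completed by
    the Guinier model. MW = (QR / c)^k with class coefficients from the
    editable table (protein linear; nucleic power law).
    """
    if i0 <= 0 or rg <= 0:
        raise ValueError("need positive i0 and rg")
    coeffs = (coefficients or DEFAULT_COEFFICIENTS)["vc"]
    if molecule_class not in coeffs:
        raise ValueError(f"unknown molecule class {molecule_class!r}")
    mask = curve.s <= smax_cut
    s, i = curve.s[mask], curve.i[mask]
    if len(s) < 5:
        raise ValueError("too few points below smax_cut")
    integral = _guinier_lowangle_integral(i0, rg, float(s[0]), power=1)
    integral += float(np.trapezoid(s * i, s))
    if integral <= 0:
        raise ValueError("non-positive int s*I ds")
    vc = i0 / integral
    qr = vc**2 / rg
    cc = coeffs[molecule_class]
    mw = (qr / cc["c"]) ** cc["k"]
    return float(vc), float(qr), float(mw)


def mw_from_mow(
    curve: ScatteringCurve,
    i0: float,
    rg: float,
    smax_cut: float = 0.3,
    coefficients: dict | None = None,
) -> float:
    """MW from the apparent Porod volume at truncated s_max.

    The apparent volume V' = 2 pi^2 I(0) / int_0^smax s^2 I ds is
    computed without constant subtraction or tail extension, then
    converted to mass as V' * correction(smax) / volume_per_dalton with
    coefficients from the editable table.
    """
    coeffs = (coefficients or DEFAULT_COEFFICIENTS)["mow"]
    _, v_apparent = porod_volume(
        curve, i0, rg, smax_cut=smax_cut, subtract_constant=False, extend_tail=False
    )
    if v_apparent <= 0:
        raise ValueError("non-positive apparent Porod volume")
    correction = float(np.polyval(list(reversed(coeffs["correction"])), smax_cut))
    return float(v_apparent * correction / coeffs["volume_per_dalton"])


def mw_from_absolute_i0(i0_abs: float, conc: float, contrast_per_mass: float) -> float:
    """MW (g/mol) from absolute-scale forward scattering.

    MW = I(0)[cm^-1] * N_A / (c [g/cm^3] * (dSigma/dm [cm/g])^2).
    """
    if i0_abs < 0:
        raise ValueError("i0 must be >= 0")
    if conc <= 0 or contrast_per_mass <= 0:
        raise ValueError("concentration and contrast must be positive")
    return i0_abs * AVOGADRO / (conc * contrast_per_mass**2)


def sequence_stats(sequence: str) -> SequenceStats:
    """Chain mass and partial specific volume from an amino-acid sequence.

    MW = sum of average residue masses + one water; PSV is the
    mass-weighted mean of the per-residue partial specific volumes.
    Only the 20 standard one-letter codes are accepted.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    mass = 0.0
    psv_mass = 0.0
    for ch in seq:
        if ch not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue {ch!r}")
        m = RESIDUE_MASSES[ch]
        mass += m
        psv_mass += m * RESIDUE_PSV[ch]
    psv = psv_mass / mass
    return SequenceStats(n_residues=len(seq), mw=mass + WATER_MASS, psv=psv)


def shannon_channels(dmax: float, smin: float, smax: float) -> float:
    """Number of Shannon channels N_s = D_max (s_max - s_min) / pi."""
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if not (0 <= smin <= smax):
        raise ValueError("need 0 <= smin <= smax")
    return dmax * (smax - smin) / math.pi


def useful_angular_range(
    curve: ScatteringCurve, dmax: float, snr_threshold: float = 2.0
) -> float:
    """Largest s with statistically significant Shannon channels.

    A particle of maximum dimension D_max carries one independent
    Shannon channel per angular band of width pi/D_max. Scanning the
    bands k = 1..K_max in order, a channel is deemed reliably
    determined when the median per-point signal-to-noise |I|/sigma
    inside its band reaches ``snr_threshold``; the scan stops at the
    first channel that fails, and s_opt = pi K* / D_max for the last
    channel K* that passed (at least the first channel). The
    band-local criterion is deliberate: a global coefficient
    covariance would let precisely measured low-angle points vouch for
    high-angle channels through the tails of the sampling kernels,
    which is exactly what a useful-range estimate must not do.
    """
    sigma = curve.require_sigma("useful_angular_range")
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    s = curve.s
    width = math.pi / dmax
    k_max = int(np.floor(s[-1] / width))
    if k_max < 1:
        return width
    snr = np.abs(curve.i) / sigma
    k_star = 1
    for k in range(1, k_max + 1):
        band = (s > (k - 0.5) * width) & (s <= (k + 0.5) * width)
        if not band.any():
            continue
        if float(np.median(snr[band])) < snr_threshold:
            break
        k_star = k
    return math.pi * k_star / dmax


def mw_report(
    curve: ScatteringCurve,
    i0: float,
    rg: float,
    dmax: float | None = None,
    smax_cut_vc: float = 0.3,
    molecule_class: str = "protein",
    coefficients: dict | None = None,
) -> MwReport:
    """Assemble the full invariant/MW report for a curve."""
    q, vp = porod_volume(curve, i0, rg)
    vc, qr, mw_vc = mw_from_vc(
        curve, i0, rg, smax_cut=smax_cut_vc, molecule_class=molecule_class,
        coefficients=coefficients,
    )
    mw_mow = mw_from_mow(curve, i0, rg, smax_cut=smax_cut_vc, coefficients=coefficients)
    ns = (
        shannon_channels(dmax, float(curve.s[0]), float(curve.s[-1]))
        if dmax is not None
        else float("nan")
    )
    estimates = [
        ("vc", mw_vc, {"smax_cut": smax_cut_vc, "class": molecule_class}),
        ("mow", mw_mow, {"smax_cut": smax_cut_vc}),
    ]
    return MwReport(q_invariant=q, vp=vp, vc=vc, qr=qr, ns=ns, mw_estimates=estimates)
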