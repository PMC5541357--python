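"""One-dimensional scattering curves.

The central container of the package is :class:`ScatteringCurve`, a
background-subtracted, radially averaged 1D solution-scattering profile:
intensities I(s) on a strictly increasing momentum-transfer grid
s = 4*pi*sin(theta)/lambda, with optional per-point 1-sigma errors.

The canonical internal angular unit is inverse angstroms; curves carry a
unit tag and are converted at the package edges (:func:`convert_units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "AngularUnit",
    "ScatteringCurve",
    "convert_units",
    "validate_curve",
]


# Exact conversion: 1 nm^-1 == 0.1 A^-1.
_NM_TO_A = 0.1


@dataclass(frozen=True)
class AngularUnit:
    """Angular unit of the momentum-transfer axis."""

    tag: str  # "inverse-A" | "inverse-nm"

    INVERSE_A = "inverse-A"
    INVERSE_NM = "inverse-nm"

    def __post_init__(self) -> None:
        if self.tag not in (self.INVERSE_A, self.INVERSE_NM):
            raise ValueError(f"unknown angular unit {self.tag!r}")

    @property
    def to_inverse_angstrom(self) -> float:
        """Multiplicative factor converting s in this unit to inverse A."""
        return 1.0 if self.tag == self.INVERSE_A else _NM_TO_A


INVERSE_A = AngularUnit(AngularUnit.INVERSE_A)
INVERSE_NM = AngularUnit(AngularUnit.INVERSE_NM)


@dataclass
class ScatteringCurve:
    """A 1D scattering profile I(s) with optional errors.

    Parameters
    ----------
    s : array
        Momentum-transfer grid, strictly increasing, non-negative.
    i : array
        Intensities, same length as ``s``. Relative units unless calibrated
        to an absolute scale (cm^-1).
    sigma : array, optional
        1-sigma intensity errors, strictly positive, same length.
    unit : AngularUnit
        Angular unit of ``s`` (default inverse angstroms).
    meta : dict
        Free-form provenance: sample name, concentration (mg/ml),
        parent files, processing history.
    """

    s: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    unit: AngularUnit = INVERSE_A
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        violations = validate_curve(self)
        if violations:
            raise ValueError("invalid curve: " + "; ".join(violations))

    def __len__(self) -> int:
        return len(self.s)

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def require_sigma(self, operation: str) -> np.ndarray:
        """Return sigma, or raise when absent.

        Error-sensitive statistics refuse to run without experimental
        errors rather than imputing them.
        """
        if self.sigma is None:
            raise ValueError(f"{operation} requires intensity errors (sigma)")
        return self.sigma

    def copy(self, **changes: Any) -> "ScatteringCurve":
        """Deep-ish copy with optional field replacement."""
        out = replace(self, **changes)
        if "s" not in changes:
            out.s = self.s.copy()
        if "i" not in changes:
            out.i = self.i.copy()
        if "sigma" not in changes and self.sigma is not None:
            out.sigma = self.sigma.copy()
        if "meta" not in changes:
            out.meta = dict(self.meta)
        return out

    def with_meta(self, **entries: Any) -> "ScatteringCurve":
        out = self.copy()
        out.meta.update(entries)
        return out


def validate_curve(curve: ScatteringCurve) -> list[str]:
    """Check all ScatteringCurve invariants.

    Returns an empty list when the curve is valid; otherwise one message
    per violated invariant, naming the invariant and the first offending
    index.
    """
    violations: list[str] = []
    s = np.asarray(curve.s, dtype=float)
    i = np.asarray(curve.i, dtype=float)
    if s.ndim != 1 or i.ndim != 1:
        violations.append("arrays must be one-dimensional")
        return violations
    if len(s) != len(i):
        violations.append(f"length mismatch: s has {len(s)}, i has {len(i)}")
    if len(s) < 2:
        violations.append(f"too short: {len(s)} points, need >= 2")
    if len(s) and s[0] < 0:
        violations.append("s non-negativity violated at index 0")
    if len(s) >= 2:
        ds = np.diff(s)
        bad = np.flatnonzero(ds <= 0)
        if bad.size:
            violations.append(
                f"strict monotonicity of s violated at index {bad[0] + 1}"
            )
    if curve.sigma is not None:
        sig = np.asarray(curve.sigma, dtype=float)
        if len(sig) != len(s):
            violations.append(
                f"length mismatch: sigma has {len(sig)}, s has {len(s)}"
            )
        else:
            bad = np.flatnonzero(~(sig > 0))
            if bad.size:
                violations.append(
                    f"sigma positivity violated at index {bad[0]}"
                )
    for name, arr in (("s", s), ("i", i)):
        if arr.size and not np.all(np.isfinite(arr)):
            idx = int(np.flatnonzero(~np.isfinite(arr))[0])
            violations.append(f"non-finite {name} value at index {idx}")
    return violations


def convert_units(curve: ScatteringCurve, target: AngularUnit) -> ScatteringCurve:
    """Convert the angular axis between inverse angstroms and inverse nm.

    Intensities are untouched; the s grid is scaled by the exact factor
    10 (or 0.1). Converting to the current unit returns an identical copy.
    """
    if target.tag == curve.unit.tag:
        return curve.copy()
    factor = curve.unit.to_inverse_angstrom / target.to_inverse_angstrom
    return curve.copy(s=curve.s * factor, unit=target)


def to_canonical(curve: ScatteringCurve) -> ScatteringCurve:
    """Return the curve in the internal canonical unit (inverse A)."""
    return convert_units(curve, INVERSE_A)
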