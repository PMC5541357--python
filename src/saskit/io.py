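"""Readers and writers for the ASCII formats the toolkit touches.

``.dat`` files follow the common 3/4-column solution-scattering
convention: whitespace-separated columns s, I(s)[, sigma(s)], with free
header and footer lines. The dialect here is deliberately tolerant: any
line whose first two whitespace-separated tokens parse as floats is a
data row; everything else is preserved verbatim in ``meta``.

IFT solutions are written to a self-describing text file with a
key/value header, an experimental-data/fit block and a p(r) block.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .curve import INVERSE_A, INVERSE_NM, AngularUnit, ScatteringCurve

if TYPE_CHECKING:  # pragma: no cover
    from .ift import IFTSolution

logger = logging.getLogger(__name__)

__all__ = [
    "read_dat",
    "write_dat",
    "write_ift_file",
    "read_ift_file",
    "read_bead_model",
    "write_bead_model",
    "read_formfactor_table",
    "write_formfactor_table",
]

_UNIT_TOKENS = {
    "1/a": INVERSE_A,
    "a^-1": INVERSE_A,
    "inverse-a": INVERSE_A,
    "1/angstrom": INVERSE_A,
    "1/nm": INVERSE_NM,
    "nm^-1": INVERSE_NM,
    "inverse-nm": INVERSE_NM,
}


def _parse_row(line: str) -> tuple[float, ...] | None:
    """Return numeric fields when the line is a data row, else None."""
    tokens = line.split()
    if len(tokens) < 2:
        return None
    values = []
    for tok in tokens:
        try:
            values.append(float(tok))
        except ValueError:
            break
    if len(values) < 2:
        return None
    return tuple(values)


def _detect_unit(header_lines: list[str], s: np.ndarray) -> AngularUnit:
    for line in header_lines:
        low = line.lower()
        for token, unit in _UNIT_TOKENS.items():
            if token in low:
                return unit
    # Heuristic: biological SAXS rarely exceeds 1 A^-1.
    return INVERSE_NM if s.max() > 1.0 else INVERSE_A


def read_dat(
    path: str | Path,
    unit_hint: AngularUnit | None = None,
) -> ScatteringCurve:
    """Read an ASCII scattering curve (columns s, I[, sigma]).

    Unit resolution order: explicit ``unit_hint``, a unit token in a
    header line, then the max(s) > 1 heuristic for inverse nm. Rows with
    non-positive sigma are dropped (logged); header/footer lines are
    kept in ``meta['header']`` / ``meta['footer']``.
    """
    path = Path(path)
    text = path.read_text()
    header: list[str] = []
    footer: list[str] = []
    rows: list[tuple[float, ...]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        parsed = _parse_row(line)
        if parsed is None:
            (footer if rows else header).append(line.rstrip("\n"))
        else:
            rows.append(parsed)
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 parseable data rows")

    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    s, i = data[:, 0], data[:, 1]
    sigma = data[:, 2] if ncol >= 3 else None

    n_dropped = 0
    if sigma is not None:
        keep = sigma > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "%s: dropped %d rows with non-positive sigma", path, n_dropped
            )
            s, i, sigma = s[keep], i[keep], sigma[keep]
    if len(s) < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows after filtering")
    if np.any(np.diff(s) <= 0):
        raise ValueError(f"{path}: non-monotonic grid")

    unit = unit_hint or _detect_unit(header, s)
    meta = {"source": str(path)}
    if header:
        meta["header"] = header
    if footer:
        meta["footer"] = footer
    if n_dropped:
        meta["dropped_nonpositive_sigma"] = n_dropped
    return ScatteringCurve(s=s, i=i, sigma=sigma, unit=unit, meta=meta)


def write_dat(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as fixed-width ASCII with >= 6 significant digits."""
    path = Path(path)
    lines = [f"# saskit scattering curve  unit: {curve.unit.tag}"]
    for key, value in curve.meta.items():
        if key in ("header", "footer"):
            continue
        lines.append(f"# {key}: {value}")
    if curve.sigma is not None:
        for s, i, sig in zip(curve.s, curve.i, curve.sigma):
            lines.append(f"{s:16.8e} {i:16.8e} {sig:16.8e}")
    else:
        for s, i in zip(curve.s, curve.i):
            lines.append(f"{s:16.8e} {i:16.8e}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# IFT result file: header of labelled key/value lines, then two blocks.

_IFT_SCALARS = ("dmax", "alpha", "rg", "i0", "chi2_reduced", "total")


def write_ift_file(solution: "IFTSolution", path: str | Path) -> None:
    """Write an IFT solution to a self-describing text file.

    Layout: key/value header (Dmax, alpha, Rg, I0, chi2, criteria
    scores), a data/fit block (s, I_exp, sigma, I_fit) and a p(r) block
    (r, p, error).
    """
    path = Path(path)
    lines = ["# saskit IFT solution"]
    lines.append(f"Dmax: {solution.pr.dmax:.8e}")
    lines.append(f"alpha: {solution.alpha:.8e}")
    lines.append(f"Rg: {solution.rg:.8e}")
    lines.append(f"I0: {solution.i0:.8e}")
    lines.append(f"chi2_reduced: {solution.chi2_reduced:.8e}")
    for name, score in solution.criteria.items():
        lines.append(f"criterion_{name}: {score:.6f}")
    lines.append(f"total_estimate: {solution.total:.6f}")

    lines.append("## data_and_fit: s I_exp sigma I_fit")
    exp = solution.data
    sig = exp.sigma if exp.sigma is not None else np.zeros_like(exp.s)
    for s, i, e, f in zip(exp.s, exp.i, sig, solution.fit.i):
        lines.append(f"{s:16.8e} {i:16.8e} {e:16.8e} {f:16.8e}")

    lines.append("## pr: r p(r) error")
    for r, p, pe in zip(solution.pr.r, solution.pr.p, solution.pr.perr):
        lines.append(f"{r:16.8e} {p:16.8e} {pe:16.8e}")
    path.write_text("\n".join(lines) + "\n")


def read_ift_file(path: str | Path) -> dict:
    """Parse an IFT text file back into arrays and scalars.

    Returns a dict with keys ``dmax``, ``alpha``, ``rg``, ``i0``,
    ``chi2_reduced``, ``criteria``, ``total``, ``data`` (s, i, sigma),
    ``fit`` (intensities) and ``pr`` (r, p, perr).
    """
    path = Path(path)
    scalars: dict[str, float] = {}
    criteria: dict[str, float] = {}
    blocks: dict[str, list[list[float]]] = {}
    current: list[list[float]] | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("# "):
            continue
        if line.startswith("##"):
            name = line[2:].split(":")[0].strip()
            current = blocks.setdefault(name, [])
            continue
        m = re.match(r"^([A-Za-z0-9_]+):\s*(\S+)$", line)
        if m:
            key, value = m.group(1), float(m.group(2))
            if key.startswith("criterion_"):
                criteria[key[len("criterion_"):]] = value
            else:
                scalars[key.lower()] = value
            continue
        if current is not None:
            current.append([float(t) for t in line.split()])
    data = np.array(blocks.get("data_and_fit", []), dtype=float)
    pr = np.array(blocks.get("pr", []), dtype=float)
    out = {
        "dmax": scalars.get("dmax", math.nan),
        "alpha": scalars.get("alpha", math.nan),
        "rg": scalars.get("rg", math.nan),
        "i0": scalars.get("i0", math.nan),
        "chi2_reduced": scalars.get("chi2_reduced", math.nan),
        "total": scalars.get("total_estimate", math.nan),
        "criteria": criteria,
    }
    if data.size:
        out["data"] = {"s": data[:, 0], "i": data[:, 1], "sigma": data[:, 2]}
        out["fit"] = data[:, 3]
    if pr.size:
        out["pr"] = {"r": pr[:, 0], "p": pr[:, 1], "perr": pr[:, 2]}
    return out


# ---------------------------------------------------------------------------
# Bead models: PDB-convention fixed-width ATOM/HETATM records.


def read_bead_model(
    path: str | Path, occupancy_weights: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Read bead coordinates from a PDB-format file.

    Coordinates are taken from the fixed-width x/y/z fields of
    ATOM/HETATM records (columns 31-54). Weights are 1 unless
    ``occupancy_weights`` is set, in which case the occupancy field is
    used.
    """
    path = Path(path)
    points: list[list[float]] = []
    weights: list[float] = []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            w = float(line[54:60]) if occupancy_weights and len(line) >= 60 else 1.0
        except ValueError as exc:
            raise ValueError(f"{path}: malformed ATOM record: {line!r}") from exc
        points.append([x, y, z])
        weights.append(w)
    if not points:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return np.asarray(points, dtype=float), np.asarray(weights, dtype=float)


def write_bead_model(points: np.ndarray, path: str | Path) -> None:
    """Write bead coordinates as dummy-atom PDB ATOM records."""
    path = Path(path)
    lines = []
    for idx, (x, y, z) in enumerate(np.asarray(points, dtype=float), start=1):
        serial = idx % 100000
        lines.append(
            f"ATOM  {serial:5d}  CA  DUM A{(idx % 10000):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{20.0:6.2f}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Multi-column form-factor tables: s, F1, F2, ...


def write_formfactor_table(
    s: np.ndarray, components: list[np.ndarray], path: str | Path
) -> None:
    """Write a multi-column ASCII table of component intensities."""
    path = Path(path)
    s = np.asarray(s, dtype=float)
    cols = [np.asarray(c, dtype=float) for c in components]
    for c in cols:
        if len(c) != len(s):
            raise ValueError("component length does not match s grid")
    lines = [f"# saskit form-factor table: s + {len(cols)} components"]
    for k in range(len(s)):
        fields = [f"{s[k]:16.8e}"] + [f"{c[k]:16.8e}" for c in cols]
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_formfactor_table(path: str | Path) -> tuple[np.ndarray, list[np.ndarray]]:
    """Read a multi-column form-factor table -> (s, [F1, F2, ...])."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        parsed = _parse_row(line)
        if parsed is not None:
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    return data[:, 0], [data[:, k] for k in range(1, data.shape[1])]
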