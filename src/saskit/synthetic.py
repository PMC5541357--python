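"""Synthetic scattering data: the test substrate for every other module.

Emulates background-subtracted solution-scattering curves of analytic
geometric bodies with Gaussian, intensity-proportional noise. Gaussian
(rather than Poisson) noise with sigma proportional to the model
intensity matches high-count, background-subtracted SAXS practice and
keeps chi-square calibration exact: the sigma column always carries the
true generating standard deviation, so tests can compute exact
z-scores.

Every operation takes an explicit seed and is bit-reproducible; each
call owns one fresh numpy Generator (no hidden global state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve import ScatteringCurve
from .formfactors import (
    Body,
    MixtureModel,
    body_intensity,
    hard_sphere_sf,
    mixture_intensity,
)

__all__ = [
    "NoiseModel",
    "simulate_curve",
    "dilution_series",
    "bead_sphere",
    "random_protein_sequence",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class NoiseModel:
    """Gaussian counting-like noise for simulated curves.

    sigma(s) = relative_level * (I_model(s) + background)
               * (1 + (s/s_max)^s_dependence)

    so the relative error grows toward high angles, as in real
    background-subtracted data. ``relative_level = 0`` yields the exact
    model curve with a nominal small sigma column (1e-6 of the local
    intensity) so that error-weighted algorithms remain applicable.
    """

    relative_level: float = 0.02
    s_dependence: float = 2.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_level < 0:
            raise ValueError("noise level must be >= 0")


def _model_intensity(model, s_grid: np.ndarray) -> np.ndarray:
    if isinstance(model, Body):
        return body_intensity(model, s_grid, normalized=False).i
    if isinstance(model, MixtureModel):
        return mixture_intensity(model, s_grid, normalized=False).i
    if isinstance(model, ScatteringCurve):
        return np.interp(s_grid, model.s, model.i)
    raise TypeError("model must be a Body, MixtureModel or ScatteringCurve")


def simulate_curve(
    model,
    s_grid: np.ndarray,
    noise: NoiseModel | None = None,
    scale: float = 1.0,
) -> ScatteringCurve:
    """Simulate an observed curve: scale * I_model + background + noise.

    The sigma column is filled with the exact generating sigma(s).
    Deterministic per ``noise.seed``.
    """
    s = np.asarray(s_grid, dtype=float)
    noise = noise or NoiseModel(relative_level=0.0)
    i_model = scale * _model_intensity(model, s) + noise.background
    s_ref = s[-1] if s[-1] > 0 else 1.0
    sigma = noise.relative_level * np.abs(i_model) * (1.0 + (s / s_ref) ** noise.s_dependence)
    if noise.relative_level == 0:
        sigma = 1e-6 * np.maximum(np.abs(i_model), np.abs(i_model).max() * 1e-12)
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, 1.0, len(s)) * sigma if noise.relative_level > 0 else 0.0
    meta = {
        "synthetic": True,
        "noise_level": noise.relative_level,
        "seed": noise.seed,
    }
    if isinstance(model, Body):
        meta["model"] = model.kind
        meta["params"] = dict(model.params)
    return ScatteringCurve(s=s, i=i_model + eps, sigma=sigma, meta=meta)


def dilution_series(
    body: Body,
    concentrations: list[float],
    interaction_eta_per_conc: float = 0.0,
    noise: NoiseModel | None = None,
    interaction_radius: float | None = None,
    s_grid: np.ndarray | None = None,
) -> list[ScatteringCurve]:
    """Concentration series with optional hard-sphere interparticle effects.

    Each curve is c * I_body(s) * S_PY(s; eta = interaction * c); the
    structure factor suppresses the lowest angles at high concentration,
    the classic scenario for low/high-concentration merging and
    zero-concentration extrapolation. Metadata carries the
    concentration (mg/ml). Curve k uses seed ``noise.seed + k``.
    """
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    if interaction_eta_per_conc < 0:
        raise ValueError("interaction strength must be >= 0")
    noise = noise or NoiseModel(relative_level=0.0)
    if s_grid is None:
        s_grid = np.linspace(0.005, 0.5, 200)
    s = np.asarray(s_grid, dtype=float)
    if interaction_radius is None:
        from .formfactors import _max_dimension

        interaction_radius = 0.5 * _max_dimension(body)
    i_body = body_intensity(body, s, normalized=False).i
    out = []
    for k, conc in enumerate(concentrations):
        eta = interaction_eta_per_conc * conc
        sf = hard_sphere_sf(s, eta, interaction_radius) if eta > 0 else 1.0
        model = ScatteringCurve(s=s, i=conc * i_body * sf)
        nk = NoiseModel(
            relative_level=noise.relative_level,
            s_dependence=noise.s_dependence,
            background=noise.background,
            seed=noise.seed + k,
        )
        curve = simulate_curve(model, s, nk)
        curve.meta["concentration"] = conc
        out.append(curve)
    return out


def bead_sphere(radius: float, bead_spacing: float, seed: int = 0):
    """Jittered cubic-lattice bead filling of a sphere.

    Lattice points with |x| <= radius are kept and jittered by seeded
    uniform offsets of at most 0.1 * spacing per axis. Returns
    (points (n, 3), unit weights (n,)).
    """
    if bead_spacing >= radius:
        raise ValueError("bead spacing must be smaller than the radius")
    rng = np.random.default_rng(seed)
    axis = np.arange(-radius, radius + bead_spacing / 2, bead_spacing)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = (grid**2).sum(axis=1) <= radius**2
    pts = grid[inside]
    jitter = rng.uniform(-0.1 * bead_spacing, 0.1 * bead_spacing, pts.shape)
    pts = pts + jitter
    return pts, np.ones(len(pts))


def random_protein_sequence(length: int, seed: int = 0) -> str:
    """Uniformly random sequence over the 20 standard amino acids."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
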