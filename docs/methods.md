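# Methods

This note records the models, numerical choices and known limitations
behind each part of the toolkit, in the order a curve moves through it.
All angular arguments are momentum transfer s = 4π sin θ / λ in Å⁻¹
internally (curves tagged in nm⁻¹ are converted on input by the exact
factor 10); real-space lengths are in Å, intensities in arbitrary units
unless calibrated to cm⁻¹.

## Data model and error handling

A curve is (s, I, σ) with a strictly increasing non-negative grid and
strictly positive errors when present. Statistical operations that need
errors (averaging weights, χ², IFT, body fitting) refuse to run without
them rather than imputing: the comparison statistics are σ-sensitive
and a silently invented σ would miscalibrate them. Error propagation is
first-order Gaussian throughout — appropriate for background-subtracted
data at the count levels of modern detectors, where Poisson statistics
are effectively Gaussian. Curve arithmetic requires grids equal to
1e-6 relative; there is no silent interpolation (an explicit `regrid`
exists), so no hidden smoothing enters χ² or CORMAP.

## Curve reduction

Averaging is the inverse-variance weighted mean with
σ_out = (Σ σ_k⁻²)^(-1/2) (σ/√N for equal-σ replicates). Scale/shift
matching minimizes Σ w (f·I_t + c − I_r)² with w = σ_r⁻², solved in
closed form. Merging scales the concentrated curve onto the dilute one
over the overlap (shift disabled — interparticle interference changes
shape, not offset) and stitches at the overlap midpoint, recording
per-point provenance; midpoint stitching keeps provenance
unambiguous, and overlap averaging is deliberately not the default.
Infinite-dilution extrapolation regresses I/c on c per grid point by
weighted linear least squares and returns the intercept with its
standard error; it is exact when I(s,c)/c is linear in c, which is the
leading-order virial behaviour the measurement design assumes.
Absolute calibration multiplies by W/⟨I_water−empty⟩ over a user-chosen
plateau; the default water constant 0.01632 cm⁻¹ holds at 20 °C and is
a parameter, never an assumption.

## Curve comparison

The CORMAP statistic is the longest same-sign run C of the pointwise
differences. Under the null (two measurements of the same signal) each
sign is an independent fair coin, so
P(max run ≥ C) = 1 − 2·K(n)/2ⁿ where K(n) counts compositions of n
with parts < C, evaluated with exact Python integers via the
sliding-window recurrence — exact for n well beyond 10⁴, no logs or
overflow. Exact zero differences are assigned positive sign
(deterministic; ties essentially never occur in real data, and the
divergence risk is documented). The reduced χ² test uses
ν = n − 1 − dof_extra and combines both curves' σ in quadrature; note
E[χ²/ν] = n/(n−1) under the null, which matters when calibrating on
small n. The paired t-test on (I_a−I_b)/σ is included for reference
only. Set comparison applies Bonferroni over the k(k−1)/2 pairs —
conservative, which is the right default when the question is "may
these frames be averaged".

## Guinier analysis

The fit is a weighted linear regression of y(s²) with y = ln I
(globular, slope −R_g²/3), ln sI (rod, −R_c²/2) or ln s²I (sheet,
−R_t²), weights 1/σ_y², σ_y = σ/I. The Guinier law is the leading term
of an expansion; on exact model curves the next term biases R_g
upward by an amount that grows with the window cap: for the sphere
+0.7% at s·R_g ≤ 0.8 and +1.1% at 1.0; for the rod +0.9% at
s·R_c ≤ 0.65; for the sheet the quartic correction is strongest and
1% accuracy needs s·R_t ≤ 0.4. Accuracy-critical closed-form checks
therefore use those quadratic-regime caps, while `autorg` defaults to
the standard practice caps (1.3 globular, 1.0 rod, 0.8 sheet) that
trade a percent of bias for noise averaging on real data.

`autorg` scans all windows of ≥ 5 points whose fitted R_g satisfies
the cap self-consistently and scores each by a weighted geometric mean
of fit R² (0.4), covered fraction of the allowed range (0.3),
closeness of s·R_g to the cap (0.2) and retention of the lowest angles
(0.1); ties go to the earliest window. The weights are this package's
definition; on decent data the chosen window barely moves R_g, and the
score is exposed as the fit quality.

## Indirect Fourier transform

p(r) is sought on a uniform grid of 101 points on [0, D_max]
(trapezoid forward quadrature), minimizing χ² + α·Σ(Δp)², with
p(0) = p(D_max) = 0 enforced by default (squared second differences
available by flag). The stacked system [A; √α D] is solved by SVD —
the kernel's condition number makes normal equations unusable — and
α is normalized by trace(AᵀA)/trace(DᵀD) so that α is dimensionless
and the automatic search range log₁₀α ∈ [−8, 4] is meaningful at any
intensity scale. Errors on p come from the covariance of the
regularized inverse applied to the data covariance. The stored fit is
exactly the forward transform of the returned p (same quadrature), so
the internal-consistency invariant holds to rounding.

Quality is summarized by six named criteria on [0, 1]:
DISCRP = exp(−|χ²_red − 1|); OSCILL compares the arc length of the
dimensionless graph of p with a single-lobe sine; STABIL is one minus
the relative change of p under ±10% α; SYSDEV is the longest-run
p-value of the fit residual signs; POSITV the positive fraction of
∫|p|; VALCEN the |p| mass inside the central 80% of [0, D_max]. The
formulas and the weighted total (DISCRP 0.35, POSITV 0.20, OSCILL
0.15, VALCEN 0.15, STABIL 0.10, SYSDEV 0.05) are this package's
definitions. The fidelity term must dominate: with equal weights an
absurdly oversmoothed solution (perceptually perfect, fit ruined)
outscores the correct one and the α search latches onto it. SYSDEV
gets little weight because noise-free model curves leave systematic
residual signs even for essentially exact solutions. Automatic α
maximizes the total by a coarse bracket plus bounded golden-section on
log₁₀α (tolerance 0.01 decades).

Automatic D_max starts at the top of the bracket [2R_g, 4R_g] (R_g
from `autorg`) and iterates support trimming: solve at the current
D_max with the discrepancy-principle α (largest α keeping χ²_red at
max(1, 1.05·χ²_min) — a stable, criteria-independent choice for this
internal step), find the last point where the positive part of p
exceeds 2% of its peak, and extrapolate to the support end through the
quadratic vanishing of p there (r₀ = r + 2p/|p′|, exact for smooth
compact particles). A tail still heavy at the boundary grows the
candidate instead. On noise-free spheres and dumbbells this lands
within 2% of the true dimension; at 2% noise the median error on
spheres is well under 1%.

The sphere-kernel size distribution solves
I(s) = Σ D_v(R_j) V(R_j) Φ²(sR_j) ΔR by NNLS on the same stacked
regularized system (non-negativity is the physical constraint that
replaces end conditions); automatic α there uses the discrepancy
principle (largest α within 10% of the minimal χ²) since the
perceptual criteria are defined for p(r), not D_v(R).

## Invariants and molecular weight

Both key integrals need completion outside the measured window. The
origin side uses the Guinier model from `autorg` below the first data
point (fine fixed-grid quadrature). For the Porod integral the high-s
side matters more: the running invariant Q(s) = ∫₀ˢ u²I du behaves
asymptotically as Q_∞ + K s³/3 − A/s for a compact uniform particle
with flat background K and Porod constant A, so a linear fit of Q(s)
against [1, s³, 1/s] over the top 40% of the range yields the
completed invariant, the background and the tail in one step.
Integrating first is essential: the form-factor oscillations that make
a direct s⁴I-vs-s⁴ fit meaningless on spheres are damped by the
integral. With data to s·R ≈ 15 this recovers sphere volumes to 0.3%;
the truncated tail it restores is 3–13% of Q in that regime. V_p,
V_c, QR and the MoW estimate are exactly invariant under intensity
rescaling by construction.

V_c uses the default truncation s_max = 0.3 Å⁻¹ and the published
class calibrations (protein MW = QR/0.1231; nucleic
MW = (QR/0.00934)^0.808), stored in an editable coefficient table with
provenance comments, as is the sequence table (average residue masses;
per-residue partial specific volumes from the classical compilations,
mass-weighted). The MoW-style estimate converts the apparent Porod
volume (no background subtraction, no tail) by a correction polynomial
and a volume-per-mass divisor from the same config; the shipped
defaults are the identity correction and 1.66 Å³/Da — a deliberate,
clearly-labelled approximation, since the original truncation
correction is published elsewhere; users supply their preferred
coefficients via `--coeff-config`.

Shannon analysis: N_s = D_max(s_max−s_min)/π exactly. The useful
angular range walks the Shannon bands of width π/D_max in order and
stops at the first whose band-median |I|/σ falls below 2; s_opt is the
last passing channel (at least one). The band-local rule is the point:
a global coefficient covariance lets precisely measured low-angle
points vouch for high-angle channels through the tails of the sampling
kernels, which is exactly what a useful-range estimate must not allow.

## Form factors, mixtures, SVD

Spheres, core–shell spheres and dumbbells are closed-form; cylinders,
core–shell cylinders and ellipsoids use Gauss–Legendre orientation
quadrature of order max(64, 1.5·s_max·D) (capped at 1024), the
parallelepiped a two-dimensional octant product rule; doubling the
order moves nothing at the 1e-6 level on the tested bodies. The Debye
sum is exact O(n²); above 1500 points the pair distances are
accumulated on a grid fine enough that the phase error stays below
1e-5 rad, which is numerically indistinguishable from the direct
double sum (verified to < 1e-6 relative) at O(n_bins) per s point.

Body fitting is weighted least squares over log-sizes with the overall
scale profiled out analytically. The χ² landscape over sizes is
multimodal (form-factor oscillations with basins only a few percent
wide), so local optimization is seeded from a deterministic coarse
scan of size factors around the Guinier-derived characteristic length
plus seeded random restarts; results are bit-reproducible given the
seed. Mixture fitting exploits separability (variable projection):
volume fractions enter linearly and are profiled at every trial
geometry by non-negative least squares, so only the free sizes are
optimized nonlinearly, seeded by a dense precomputed NNLS grid scan.
Size dispersion averages the designated size parameter (radius-like
per body kind) over Gauss–Hermite nodes (gaussian) or a ±4σ log grid
(lognormal), 15 nodes by default; core–shell kinds scale the shell
with the core to keep geometry valid. The only structure factor is
the Percus–Yevick hard sphere, applied to the total intensity
(decoupling approximation).

Oligomer decomposition is σ-weighted NNLS, optionally with Σw = 1
enforced by a heavily weighted equality row; the covariance is the
linearized inverse on the active set, and rank-deficient component
tables warn and flag the minimum-norm solution. SVD component counting
compares the data matrix's singular values (rows I/σ by default)
against 1.5× the median largest singular value of 50 seeded standard
normal matrices of the same shape — with σ-normalization the noise
floor needs no further scaling, and the count is invariant under
intensity rescaling.

## Synthetic data

The generator emulates background-subtracted solution scattering of
analytic bodies: I_obs = scale·I_model + background + ε with Gaussian
ε of σ(s) = level·(I_model+background)·(1 + (s/s_max)^q), q = 2 by
default, so relative noise grows toward high angles as in real data.
The σ column always carries the exact generating value, which keeps
χ² and CORMAP calibrations exact — Gaussian (not Poisson) noise is
deliberate for the same reason and matches high-count practice.
Noise level 0 returns the exact model with a nominal 1e-6 relative σ
so error-weighted algorithms remain applicable. Each call owns one
`numpy` Generator seeded explicitly; a dilution series uses seed + k
for curve k. Dilution series apply the hard-sphere structure factor
with η proportional to concentration — the canonical repulsive
scenario for merging and infinite-dilution tests.

What the generator does not emulate: instrumental smearing, detector
artefacts, buffer-subtraction residuals with structure, radiation
damage, or inter-frame drift. Passing tests demonstrate correctness of
the algorithms under the stated noise model, not robustness to those
effects.

## Problem sizes and defaults in the shipped checks

Test and acceptance fixtures use curves of 200–400 points on
s ∈ [0.004, 0.5] Å⁻¹ (IFT: 250 points to 0.35 Å⁻¹), 2% relative
noise at the reference level, 100-curve ensembles for robustness
medians, 1000–2000 replicates for null calibrations, and a 10 606-bead
sphere (2.2 Å spacing) for the Debye check; Porod fixtures use equal
reduced-angle coverage s_max = 15/R so that all sphere sizes carry the
same information. These sizes are the package's chosen study
conditions; every one is a parameter of the corresponding function.

## Known limitations

- Slit smearing and simultaneous multi-dataset (SANS detector
  distance) fits are out of scope; single curves only.
- The IFT perceptual criteria are this package's formulations; scores
  are comparable within `saskit` but not numerically interchangeable
  with other implementations, and automatic D_max may differ slightly
  from other tools on marginal data.
- The MoW-style MW is only as good as the user-supplied correction
  coefficients; the shipped default deliberately omits the truncation
  correction.
- CORMAP's positive-sign convention for exact ties diverges from
  implementations that drop or randomize ties (no practical effect on
  continuous data).
- Hard-sphere Percus–Yevick is the only interparticle model; attractive
  systems and charged-sphere screening are not modelled.
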