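# Methods

## Physical model

The medium is a homogeneous (or piecewise-homogeneous) isotropic
linear elastic solid with zero material damping, governed by the
Navier equation

    mu lap(W) + (lambda + mu) grad(div W) = rho Wtt,

with W = (u, v, w) the displacement field.  Soft gels are modelled
with Poisson's ratio nu = 0.495 rather than the ideal 0.5, which keeps
the longitudinal branch finite while reproducing the characteristic
stiffness V_L/V_T = sqrt(101) ~ 10.  Viscoelasticity and
frequency-dependent moduli are out of scope.

Parameter conventions used throughout:

| parameter | meaning | default / typical |
|---|---|---|
| E | Young's modulus | 30–120 kPa (gels) |
| nu | Poisson's ratio | 0.495, required < 0.5 |
| rho | density | 1000 kg/m^3 |
| f | drive frequency | 150 Hz, harmonic |
| A | drive amplitude | 1 um, prescribed displacement |
| dx | grid spacing | 1 mm |
| dt | time step | 0.9 dx / (V_L sqrt(3)) |
| S | density scaling factor | >= 1 |

Axis convention: x is the lateral measurement ray, y the thickness /
excitation axis, z the third axis in 3D.  Cells are indexed by their
low-corner node.

## Time-domain scheme

The engine discretises the Navier equation in conservative
(stress-flux) form with second-order central differences on a
collocated grid of parallelepiped cells carrying constant
(lambda, mu, rho).  Material constants are averaged onto the mesh
entities where they act — lambda+2mu, lambda and mu onto cell edges
(the mean of the 2^(d-1) adjacent cells), rho onto nodes (the mean of
the 2^d adjacent cells) — the sharp-interface rule: at a material
interface each cell contributes with its own constants, while in a
homogeneous region the update reduces *exactly* to the textbook
central-difference discretisation (three-point second derivatives,
four-point mixed derivatives).  The test suite asserts that reduction
coefficient-by-coefficient, the step-for-step equivalence of a
1×1×N-cell bar with the 1D reference scheme, and plane-wave phase
speeds within 1% of the analytic V_L and V_T at 20 nodes per
wavelength; those three oracles, rather than any particular printed
form of the update equations, define the scheme.

Outside (vacuum) cells carry zero stiffness and density, which makes
every outer surface traction-free with no special-casing; cross
derivatives at surface nodes fall back to one-sided differences
(second order where two inward neighbours exist).  Fixed-component
boundaries clamp the listed components to zero after each update.
Excitation is a prescribed displacement A sin(2 pi f t) overriding the
update at the driven nodes — a single node in 2D, a 3×3 patch in 3D.
Time integration is leapfrog; a NaN/Inf or runaway amplitude aborts
with the step index.

### Stability

For the 1D reference scheme the amplification polynomial is
g^2 − 2(1 − 2 C^2 s^2) g + 1 = 0 with s = sin(k dx/2); its roots stay
on the unit circle iff C s <= 1.  The quartic expression
8 C^4 s^4 − 8 C^2 s^2 + 1 carried alongside equals cos(2 theta) of the
root phase for the stable scheme — it is *not* a root magnitude there,
which is why `von_neumann_roots` is the rigorous check and the quartic
is reported as a descriptive profile.

For the full collocated scheme the von Neumann symbol is separable per
axis and maximised in closed form (see `scheme_stability_limit_dt`),
giving

    dt_max = 2 / sqrt( sum_i h_max / dx_i^2 / rho ),
    h_max  = lambda + 3 mu + mu^2/(lambda + mu).

Because the four-point mixed stencil's symbol vanishes at the Nyquist
wavenumber, this limit is substantially laxer than the scalar-scheme
bound 1/sqrt(ndim): at nu = 0.495 the longitudinal Courant number may
reach ~1.149 before a mode grows, and the engine's dichotomy test
brackets exactly that limit (bounded at C_L = 0.95/sqrt(3), divergent
5% above dt_max).  The `StabilityReport.stable` flag nevertheless uses
the conservative 1/sqrt(ndim) bound, and the default time step
0.9 dx/(V_L sqrt 3) stays below it in every dimension.

## Density rescaling

Both bulk speeds scale as 1/sqrt(rho), so running with density S·rho
shrinks every wavelength by sqrt(S) at fixed frequency; measured
wavelengths (or profile position axes) are multiplied back by sqrt(S)
afterwards.  Amplitudes and time axes are deliberately not
inverse-scaled.  `recommend_scaling` inverts C_T(S) = C_T(1)/sqrt(S)
for the smallest S >= 1 reaching a requested transverse Courant
number.  Two cross-checks accompany the procedure:

* a paired bulk simulation (S = 3 vs unscaled) whose rescaled
  wavelength and peak positions must land on the unscaled run's, and
* the guided-wave solver: the dominant-mode wavenumber ratio between
  the scaled and unscaled layer equals sqrt(S) to ~1% at S = 2 for the
  30 kPa / 20 mm / 150 Hz operating point.  The ratio is exactly
  sqrt(S) only where the mode is locally nondispersive; the exact
  identity — rho -> S·rho at frequency f solves the same eigenproblem
  as the original density at sqrt(S)·f — holds to 1e-6 and is the
  rigorous form of the equivariance.  The sqrt(S) shortcut degrades
  gently with S (≈1.3% at S = 3 at the same operating point).

## Guided-wave dispersion solver

Plane harmonic waves u(y) e^{i(kx−wt)} in a plane-strain layer reduce
to a quadratic eigenvalue problem in k over the thickness.  The
implementation nondimensionalises (lengths by the thickness, moduli by
mu — essential for conditioning on thin plates at low frequency),
discretises the two coupled components with finite differences
(fourth-order interior, one-sided boundary rows), imposes per-surface,
per-component free (zero traction) or fixed (zero displacement)
conditions row-wise, linearises to a companion pencil and solves with
a dense QZ.  Eigenvalues with positive real part and relative
imaginary part below 1e-6 are the propagating modes.  The dominant
wavenumber changes by <0.1% between 60 and 120 through-thickness
points.

Mode labelling is by displacement-shape dominance (share of |v| in the
through-thickness shape), not by symmetric/antisymmetric class — mixed
boundary conditions break the symmetry classes.  `a0_wavelength`
returns the largest-wavenumber transverse-dominant branch, which
reproduces the Kirchhoff flexural closed form k^4 = w^2 rho h / D on
thin free plates (0.2%) and converges to the Rayleigh surface wave on
thick layers (a limit that is *itself* 4.5% below the bulk shear
wavelength at nu ≈ 0.5, and needs the surface decay length well
resolved — ~15 points per wavelength of depth).

The solver was validated against an exact partial-wave (Lamb-type
determinant) calculation for the 20 mm y-fixed layer: both give
37.87 mm at 150 Hz for E = 90 kPa, bracketing the published 37/37.5 mm
simulation values.

## Measurement pipeline

`estimate_wavelength_peaks` mirrors manual MRE reading: a 3-point
moving average, strict local maxima (plateau ties broken toward the
smaller position), a prominence filter at 5% of the profile range to
reject noise ripple, and mean/std over successive peak spacings.  The
first peak is optionally excluded when it lies within one estimated
wavelength of the drive (source near field).  `estimate_wavelength_spectral`
is the robust alternative: Hann window, zero-padded FFT, parabolic
peak refinement, spread from the half-power width.  Both are exactly
scale-equivariant, which is what makes the sqrt(S) inverse scaling
commute with measurement.

The strip pipeline (`strip_wavelength`) samples the vertical
displacement along the top surface at four equally spaced phases of
the last completed drive cycle, pools the peak intervals of all
phases, truncates the ray where end reflections have already returned
(estimated with V_T), and inverse-rescales by sqrt(S) when the run was
density-scaled.

## Synthetic data

`make_synthetic_profile` generates A exp(−x/L) sin(2 pi x / lambda)
plus seeded Gaussian noise — the idealised shape of a radial
measurement ray.  It emulates decay and sensor noise but not guided
dispersion, near-field asymmetry, reflections or phase jitter, so
estimator tests on it certify accuracy on clean decaying sinusoids
(bias within one sample spacing across decay lengths of 2–10
wavelengths), not performance on pathological experimental data; the
engine-produced profiles cover the guided-wave features.

## Problem sizes

Desk-scale runs are used throughout: the phantom simulation is a 2D
plane-strain 200 × 20 mm strip at 1 mm spacing (~4.2k nodes, ~2.1k
steps for three 150 Hz cycles, seconds on one core) rather than the
multi-million-cell 3D cylinder; 3D runs appear as coarse smoke tests
and oracle boxes (8^3 periodic).  2D plane strain is adequate here
because the layer's guided wavelength, not cylindrical spreading, sets
the peak spacing away from the source.

## Known limitations

* **Near-incompressible dispersion error.**  The collocated
  central-difference stencil's phase error is amplified by roughly
  lambda/mu ≈ 100 for modes that must hold div W ≈ 0; at 1 mm spacing
  the simulated strip wavelength for the 90 kPa phantom reads
  ~41 mm against the semi-analytical 37.9 mm, and converges toward it
  as dx is refined (2nd-order asymptotically, entered only below
  ~0.5 mm here).  The dispersion solver is the accurate instrument at
  coarse grids; the engine's bulk-wave accuracy (<1% at 20 nodes per
  wavelength) is unaffected because plane shear waves are discretely
  divergence-free.
* **Amplitude vs scaling factor.**  With a fixed prescribed
  displacement, the delivered kinetic energy density rho<v^2> grows
  with S, but the steady-state *displacement* amplitude in these
  double-precision simulations does not — it decreases mildly with S.
  Reports of amplitude growth under density scaling are plausibly a
  finite-precision effect at transverse Courant numbers of 1e-4,
  which this float64 leapfrog does not reproduce.
* **Bulk inversion bias.**  G = rho (lambda f)^2 assumes an unbounded
  medium; applied to a guided wavelength it inherits the layer's
  dispersion (e.g. 32.3 kPa from the 37.9 mm guided mode of a 30.1 kPa
  layer).  The bulk-vs-guided table flags exactly this regime
  (disagreement beyond ~10% once the bulk wavelength exceeds the
  layer thickness).
* Cylindrical (Bessel) waveguide modes, leaky/complex modes,
  absorbing boundaries and viscoelastic dispersion are not modelled.
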