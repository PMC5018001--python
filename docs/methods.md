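# Methods

## Model and assumptions

A sphere of radius *a* of conductively isotropic excitable tissue sits at
the origin of an infinite, uniform conducting bath (resistivity ρ_e).  A
point current source (+I₀) and sink (−I₀) lie in the bath, strictly
outside the tissue.  The tissue is a passive bidomain: intracellular and
interstitial continua (resistivities ρ_i, ρ_o) fill the same volume and
exchange current only through a purely resistive membrane — quasistatic
fields, no membrane capacitance, no active channels.  Under these
assumptions the transmembrane potential V_m = φ_i − φ_o obeys the scalar
Helmholtz equation ∇²V_m = V_m/λ² with length constant
λ = √((R_m/β)/(ρ_i+ρ_o)), and the monodomain potential
ψ = (ρ_o φ_i + ρ_i φ_o)/(ρ_i+ρ_o) obeys Laplace's equation.  The bath
field is the two free monopole potentials plus a harmonic secondary field
that decays at infinity.

Sign conventions worth stating: with the decaying Helmholtz form above,
the membrane current density V_m/ρ_m (ρ_m = R_m/β) is a *sink* of
intracellular current, ∇·**J**_i = −V_m/ρ_m = −∇·**J**_o, so the total
tissue current **J**_i + **J**_o is divergence-free.

## Series solution and interface solve

All fields are truncated tesseral-harmonic series (orthonormal complex
harmonics with the Condon–Shortley phase; `Y_μ^{−ν} = (−1)^ν conj(Y_μ^ν)`).
Coefficients are stored for ν ≥ 0 only and real fields are assembled as
the ν = 0 term plus twice the real part of the ν > 0 terms, which halves
the work and enforces realness structurally.

The electrode monopoles are expanded through the separable kernel
`1/|r−r′| = Σ 4π/(2μ+1) · r_<^μ/r_>^{μ+1} · conj(Y(θ′,φ′)) Y(θ,φ)`.  For
field radii below both electrode radii this gives interior coefficients
d_μν of φ_source+φ_sink.  The three interface conditions at r = a —
φ_e = φ_o, ρ_e⁻¹∂_rφ_e = ρ_o⁻¹∂_rφ_o, ρ_i⁻¹∂_rφ_i = 0 — then decouple
mode-by-mode into a 3×3 linear system whose closed-form solution the
package implements (`bidomain_solver.coefficients`); the test suite keeps
the direct linear solve as an independent oracle.  Degree 0 carries no
membrane or secondary response (a₀ = c₀ = 0, b₀ = d₀): a monopole pair of
equal and opposite strength injects no net current, and the uniform mode
sees only the free-field average.

For production evaluation of φ_e and **J**_e the monopole terms use their
closed forms (law-of-cosines distances; the 1/R expansion is kept for
testing).  One consequence matters for validation: the truncated solution
satisfies the interface conditions *exactly* only when the monopoles are
represented at the same truncation.  With closed-form monopoles the r = a
continuity shows the expansion tail, of order (a/r_±)^{μ_max+1} — about
4×10⁻⁵ relative at the default geometry and μ_max = 10, invisible at
plotting precision but far above floating-point noise.  The
boundary-residual checks therefore evaluate φ_source/φ_sink in series
mode at the solution's truncation, and report residuals at machine
precision (≤10⁻¹³ relative).

## Gradients and currents

Current density is J = −ρ⁻¹∇φ with term-wise analytic derivatives:
radial factors in closed form (∂_r i_μ(r/λ) = (μ/r) i_μ + (1/λ) i_{μ+1};
∂_r r^μ; ∂_r r^{−μ−1}), azimuthal derivatives by iν, and polar derivatives
through the coupling identity ∂_θY_μ^ν = ν cotθ Y_μ^ν + τ e^{−iφ} Y_μ^{ν+1}
with τ = √((μ−ν)(μ+ν+1)) (τ ≡ 0 at ν = μ, where the companion harmonic
does not exist).  At the poles θ ∈ {0, π} the cot/csc singularities cancel
analytically; the evaluator switches to the explicit limit (only the
ν = ±1 pair contributes, with parities (−1)^μ and (−1)^{μ+1} at the south
pole) rather than nudging θ by an epsilon.  Every gradient path is checked
against central finite differences.

The interior field reported on grids is **J**_i + **J**_o — both domains
occupy the same volume, and their sum is the solenoidal total tissue
current; bath nodes carry **J**_e.  Nodes on the one-cell shell around
r = a (where the field definition switches) and inside the electrode
exclusion balls (default radius 5% of *a*) are masked and zeroed.

## Biot–Savart

The magnetic flux density of the sampled current,
B_z = (μ₀/4π)[(J_x ∗ G_y) − (J_y ∗ G_x)]dV with G_i = x_i/|x|³, is a
discrete linear convolution.  The kernels are sampled on the full
(2n−1)-per-axis displacement lattice, transforms are zero-padded to the
full linear-convolution length (no circular wrap-around), and the output
window aligned with the current lattice is returned.  The singular
self-voxel is set to zero — the kernels are odd, so the principal value
of the self-term vanishes.  Anisotropic voxels are supported (the default
sampling is 128×128 points per slice and 13 slices over a 3 mm cube, so
dz ≠ dx).  A direct Riemann-sum evaluation (`bz_direct`) is the oracle;
FFT and direct agree to machine precision because both compute the same
discrete sum.  Only the sampled cube is integrated: bath currents beyond
it do not contribute, which is a deliberate truncation of the forward
problem, not an approximation error of the transform.

## Parameters and defaults

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| ρ_e | 0.29 | Ω·m | bath (artificial sea water) resistivity |
| ρ_i | 0.19 | Ω·m | intracellular resistivity |
| ρ_o | 0.29 (= ρ_e) | Ω·m | interstitial resistivity; scenarios vary ρ_e/ρ_o ∈ {1, 0.1, 10} |
| R_m | 0.15 | Ω·m² | membrane resistance × area |
| β | 20000 | m⁻¹ | membrane surface-to-volume ratio |
| a | 2 | mm | tissue radius |
| I₀ | 1 | mA | injected current magnitude |
| p₊, p₋ | (5,0,0), (0,−5,0) | mm (Cartesian) | electrode positions |
| μ_max | 10 | — | series truncation |

Derived: ρ_m = 7.5×10⁻⁶ Ω·m³, λ ≈ 3.9528 mm.  With these values the
potentials at a fixed 50-point probe set stabilize to five decimal places
in volts by μ_max = 10 (the probes are deterministic golden-spiral points
stratified over tissue interior, boundary, and near bath; stabilization is
measured as the max change against μ_max + 4, a conservative
everywhere-max rather than a single-point check).

Geometry orientation: the electrode pair is placed in the z = 0 plane
(source on +x, sink on −y), so that plane — which also contains the
sphere center — is a mirror plane of the problem: J_z vanishes on it and
B_z is even in z, with the bore axis z normal to the electrode plane.
The axisymmetric scenario instead places the pair antipodally on the
polar axis, which removes all azimuthal dependence (only ν = 0 modes
survive, exactly), reducing the problem to two dimensions; its natural
inspection line is the polar diameter.

## Numerical choices

- **Truncation.** μ_max is a free parameter; coefficients decay like
  (a/r_±)^μ, so electrodes further from the sphere converge faster.
  `convergence_study` exposes the stabilization table.
- **Interface assignment.** Points exactly on r = a evaluate tissue
  potentials as interior and φ_e/J_e as bath-side; grid nodes within half
  the largest live spacing of r = a are masked instead.
- **Exclusion zones.** Fields are refused within the exclusion radius of
  an electrode (named error), since the monopole terms diverge there.
- **Degenerate inputs.** Electrodes at or inside the tissue radius are
  rejected at coefficient computation; a coincident source/sink pair is
  allowed and yields identically zero response fields (a useful null
  test).  Polar-angle literals rounded slightly past π (config files) are
  clamped.
- **Validation tolerances.** Boundary residuals: 10⁻⁸ (potential),
  10⁻⁶ (normal current), 10⁻¹⁰ (intracellular current, relative to the
  bath current scale) — all met with orders of magnitude to spare since
  the solve is analytic.  Finite-difference PDE residuals use 7-point
  Cartesian stencils and must fall as O(h²); at h = a/200 the relative
  Helmholtz residual is ~7×10⁻⁵.

## What the checks do and do not show

There is no external data: the model *is* the artifact, and validation is
internal consistency — interface conditions, the governing PDEs, charge
conservation (Gauss-law flux around an electrode recovers I₀ to 0.1% with
a 32-point Gauss–Legendre × 64-point azimuthal rule), symmetry, and
agreement between independent evaluation routes (closed form vs series,
analytic vs finite-difference gradients, FFT vs direct quadrature).
Passing these shows the series solution solves the stated mathematical
problem; it does not validate the bidomain idealization itself against
real tissue (anisotropy, membrane capacitance and nonlinearity, frequency
dependence, finite bath and electrode geometry are all outside the model).

## Known limitations

- Isotropic resistivities only; no anisotropy tensors.
- Static (DC) stimulation; no capacitive or Hodgkin–Huxley dynamics.
- B_z integrates only the sampled cube; far bath currents are excluded.
- The series loses accuracy within ~(r_± − a) of the electrode radii in
  series mode; production code uses closed-form monopoles there.
- Single homogeneous sphere; no multilayer (skull/scalp-style) shells.
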