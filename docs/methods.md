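# Methods

## Physical model

The package models a planar layer of dipolar (zwitterionic) lipids in
contact with a symmetric monovalent electrolyte as a one-dimensional
mean-field electrostatics problem on x ∈ [0, L]. The phosphate charges are
smeared into a surface charge σ = −e₀/a₀ at x = 0; the choline charges are
distributed over 0 < x ≤ D with a self-consistently determined probability
density ℘(x); salt ions follow Boltzmann statistics; and water responds as
a field of permanent point dipoles (moment p₀) with an electronic
background n², including the cavity-field (local field) correction factor
(2+n²)/3. Assumptions worth keeping in mind:

* **Mean field.** Ion–ion and dipole–dipole correlations, image charges and
  charge discreteness are neglected; φ(x) is the only electrostatic degree
  of freedom.
* **Point particles.** Ions and water molecules have zero volume, so the
  water number density n₀w is constant in space and ion densities are pure
  Boltzmann factors. The only steric correction offered is the optional
  lattice-statistics headgroup form (parameter α below).
* **Rigid headgroup geometry.** The P–N charge separation D is fixed; only
  the dipole's tilt ω varies, with projected distance x = D cos ω.
* **1-D planar geometry, equilibrium, symmetric 1:1 salt.**

Governing equation (SI units throughout the library):

    d/dx[ε₀ ε_r(E) φ′] = 2 e₀ n₀ sinh(e₀φβ) − e₀ Λ e^{−e₀φβ} / (D a₀) · 1[x ≤ D]

with ε_r(E) = n² + (3/2)((2+n²)/3)² (n₀w p₀²β/ε₀) ℒ(u)/u, u = γp₀Eβ,
γ = (3/2)(2+n²)/3, and Λ = D / ∫₀ᴰ e^{−e₀φβ} dx. Boundary conditions:
prescribed flux ε₀ε_r(0)φ′(0) = −σ at the plane and φ′(L) = 0 at the far
boundary. No Dirichlet gauge is needed: because the ionic term is written
with bulk densities, φ = 0 is the unique far-field state and the Neumann
pair is well-posed (the converged |φ(L)| is below 10⁻⁴ mV on the default
domain).

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| T | temperature | 310 | K |
| a₀ | area per lipid | 0.48 (gel) / 0.60 (liquid) | nm² |
| D | headgroup charge separation | 0.42 | nm |
| p₀ | water dipole moment | 3.1 | Debye |
| n₀/N_A | bulk salt concentration | 0.1 | mol/l |
| n₀w/N_A | bulk water concentration | 55 | mol/l |
| n | optical refractive index | 1.33 | — |
| α | headgroup/solution volume ratio (lattice form) | off | — |
| L | domain length | 12 | nm |

The defaults are the DPPC parameter set: the areas correspond to the
gel-crystalline phase below the 314 K main transition and the
liquid-crystalline phase above it, and with these water parameters the
zero-field permittivity is 78.5 at 298 K. The phase rule is a hard step at
314 K; the transition temperature itself is rejected, since the model
contains no transition physics. α is deliberately user-facing with no
default: it is a coarse-grained volume ratio, not a measured constant.

## Numerical scheme

* **Grid.** Three uniform segments [0, D], [D, 2D], [2D, L] with a quarter
  of the interval budget on each of the first two, so the headgroup
  boundary x = D is a node *exactly* and the headgroup region is resolved
  ~13× finer than the diffuse tail (default 4000 intervals ⇒ 0.42 pm
  spacing near the plane). Doubling the budget doubles each segment count,
  nesting the node sets.
* **Discretization.** Conservative finite volumes: fluxes ε₀ε_r φ′ on cell
  faces with ε_r evaluated at the face field of the previous iterate. The
  surface flux is imposed exactly as −σ (the ε_r(0) dependence of the
  boundary condition is then implicit in the converged solution). The
  headgroup source at the x = D node is weighted by the half-cell inside
  [0, D] only, matching its support; this keeps the discrete headgroup
  charge equal to −σ to quadrature accuracy and global electroneutrality
  at the 10⁻⁸ level.
* **Nonlinear iteration.** Damped Picard outer loop: ε_r and Λ lagged, the
  ionic sinh and the headgroup Boltzmann factor Newton-linearized about the
  current iterate (both Jacobians are positive, so each inner tridiagonal
  system — solved with a banded LU — is strictly diagonally dominant).
  Defaults: damping 0.25, tolerance 10⁻⁹ V on the undamped update, cap
  10 000 sweeps; the DPPC sets converge in ~600–800 sweeps (< 0.3 s) from
  the deterministic initial guess φ ≡ 0, ε_r ≡ Onsager, Λ = 1. A Boltzmann
  exponent beyond 700 aborts with a diverged-state error.
* **Langevin branches.** ℒ(u) and ℒ(u)/u switch to their Taylor series
  (u/3 − u³/45 + 2u⁵/945, resp. 1/3 − u²/45 + 2u⁴/945) for |u| < 10⁻²: at
  that threshold the closed form's cancellation error (~ε_machine/u²) and
  the series truncation (~u⁶/4725) are both ≈10⁻¹¹ relative, which keeps
  ε_r(E) continuous across the switch and bounded by the Onsager value to
  roundoff. ℒ(u)/u at u = 0 returns exactly 1/3, so the zero-field
  permittivity and the Onsager closed form are the same code path.
* **Fields for output.** Nodal E = |φ′| by centred differences (one-sided
  at the boundaries); with sub-picometre spacing at the plane the one-sided
  value is converged far beyond the reported precision.
* **Quadrature.** Λ, the ℘ normalization and all diagnostic integrals use
  composite trapezoids on the (graded) grid.

Degenerate inputs: σ → 0 with the headgroup term disabled gives the exact
trivial solution in one sweep; n₀ = 0 is accepted by the parameter layer
but leaves the Neumann problem gauge-free, so solves require n₀ > 0.

## Observables and conventions

* ℘(x) forms: point-like Boltzmann ℘ = Λe^{−e₀φβ}, or lattice
  ℘ = Λ αe^{−e₀φβ}/(αe^{−e₀φβ}+1); both normalized to unit mean on [0, D].
  As α → 0 the lattice form reduces to the point-like one; as α → ∞ it
  flattens to ℘ ≡ 1 (close packing).
* **Mean tilt.** ⟨ω⟩ = (1/D)∫₀ᴰ ℘(x) arccos(x/D) dx, in degrees — the
  direct average of the angle implied by x = D cos ω. The alternative of
  averaging cos ω first and taking arccos afterwards is available
  (`convention="mean-cosine"`); the direct angle average is the default
  because it is the plain expectation of the tilt and reproduces the
  model's liquid-phase benchmark of 69.3° with the point-like ℘. ⟨ω⟩ uses
  the point-like form by default: the lattice correction is a refinement of
  the *density*, and the tilt statistic is defined on the same footing as
  the density that sources the field.
* A subtlety: the converged potential is not monotone inside the headgroup
  region — it rises from φ(0) < 0, crosses zero, and peaks slightly inside
  x = D (the headgroup charge overcompensates the plane locally). ℘ is
  therefore decreasing in x only up to a ~10⁻⁵ relative uptick just before
  D; beyond D, |φ| and ε_r relax monotonically to bulk on the Debye scale.

## Validation strategy

* **Analytic oracle.** With ε_r frozen and headgroups off the solver
  reproduces the closed-form constant-permittivity diffuse layer (Grahame /
  tanh solution) to < 0.001 mV, and the full model's far tail decays on the
  analytic Debye length (0.962 nm at 298 K, 0.1 M) to 0.01 %.
* **Conservation.** Global electroneutrality σ + ∫(ρ_Zw + ρ_ions) dx holds
  to ~10⁻⁸ relative on converged states (it is exact in the discrete flux
  balance); the a-posteriori residual, boundary fluxes and the flux jump at
  D are exposed by `residual_diagnostics`.
* **Closed-form spot checks.** Langevin values, the cavity factor, the
  Onsager limit, the polarization and permittivity laws are tested against
  30-digit independent evaluations of the same closed forms.

## Known limitations

* Point-like ions: no Stern layer, no finite-ion-size saturation of the
  counter-ion peak; n₊(0) can exceed close packing at high |σ|.
* Constant water density: no depletion layer at the interface.
* The headgroup is reduced to two charges and one degree of freedom (tilt);
  no azimuthal structure, no headgroup–headgroup correlations, and the
  lattice α is a single scalar the user must supply.
* The gel/liquid step is imposed through a₀, not predicted.
* 1-D planar mean field: results apply to flat bilayers; curvature and
  lateral heterogeneity are out of scope.
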