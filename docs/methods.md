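# Methods

`mtvm` simulates the microwave backscattering coefficient σ⁰ of an idealized
vegetation canopy whose crown envelope shape — not its total biomass — is the
experimental variable. This note records the model, its assumptions, the
numerical choices, and what the tests do and do not establish.

## The model chain

### Crown envelopes

A crown is a surface of revolution ρ(h), h ∈ [0, H]. Every envelope is a
member of a single two-parameter family: in normalized height u = h/H the
squared radius is a quadratic,

    ρ²(h) = (H tan α)² (a u² + b u + c),      α = 45° by default,

and c is always re-derived from the equal-volume constraint
π∫₀ᴴ ρ² dh = (π/3) tan²α H³ (the reference cone volume), which in normalized
units is the linear relation a/3 + b/2 + c = 1/3. The named shapes are exact
family members: cylinder (0, 0, 1/3), cone (1, −2, 1), inverted cone
(1, 0, 0), ellipsoid (−2, 2, 0). A parabola is feasible iff
a u² + b u + c ≥ 0 on [0, 1], checked analytically at the endpoints and the
interior vertex; shapes touching zero (cone, inverted cone, ellipsoid) sit on
the feasibility boundary and count as feasible. The constraint solve is a
single division, so the printed triples are reproduced exactly in floating
point.

### Vegetation dielectric

Component permittivity comes from the dual-dispersion semiempirical model for
fresh vegetation: a nondispersive residual plus a free-water Debye term with
ionic conductivity (σ = 1.27 S/m, room temperature) and a bound-water
Cole–Cole-type term, with the tabulated volumetric moisture fed directly as
the model's moisture parameter (this reproduces the reference value
19.2601 − j6.2882 at m = 0.6, 5.3 GHz to all printed digits). The fitted
free-water volume fraction m(0.55m − 0.076) is clamped at zero below
m ≈ 0.14, where the raw polynomial would give an unphysical negative water
fraction and a non-monotone loss; above that moisture the clamped and
published models are identical.

### Single-scatterer electromagnetics

Components follow the canonical orientations of the crown-shape study:
plate-like leaves horizontal, needle leaves horizontal with uniformly random
in-plane azimuth, stalks and branches vertical. Three approximations are
used, chosen per component:

* **Thin disc (physical optics).** Kirchhoff volume-integral with the
  quasistatic infinite-slab internal field (tangential E unchanged, normal E
  divided by ε), radiated over the disc: amplitude ∝ k²V/4π × tensor
  contraction × sinc(q·n d/2) × 2J₁(q_t a)/(q_t a). Exactly reciprocal. The
  formulation is the thin-disc limit of the Le Vine physical-optics disc;
  its validity requires kd√|ε| small, which holds for the 0.02 cm leaves at
  all three bands.
* **Slender cylinder (generalized Rayleigh–Gans).** Same structure with the
  thin-rod depolarization (axial E unchanged, transverse E scaled by
  2/(ε+1)) and the cylinder form factor sinc(q_∥ l/2) × jinc(q_⊥ r). Errors
  grow as (kr√|ε|)²; cross-checked against the modal solution below.
* **Finite cylinder (infinite-length approximation).** The exact modal
  (Bessel-series) internal field of an obliquely illuminated infinite
  dielectric cylinder — per-harmonic 4×4 boundary solves for the internal
  E_z/H_z coefficients — radiated over the finite length. The transverse
  radiation integrals reduce to Lommel closed forms; the axial integral
  gives the sinc pattern peaking on the specular cone. The series is
  truncated adaptively (the field contribution A_n J_n(λ₁a) must decay below
  10⁻⁹ of its peak). Because the internal field solves the infinite problem
  for the incident direction only, the raw truncated integral violates
  bistatic reciprocity (by up to tens of percent); the returned amplitude is
  the average over the forward and reversed geometries, which restores exact
  reciprocity without leaving the approximation's error band.

With the basis ĥ = ẑ×k̂/|ẑ×k̂|, v̂ = ĥ×k̂, reciprocity reads
F_pq(i→s) = ±F_qp(−s→−i), with the minus sign on cross-polarized elements
(the ĥ vector flips under direction reversal).

Extinction is absorption plus scattering. The optical theorem applied to
the forward amplitude of an internal-field approximation returns only the
absorptive part, k ε″ ∫|E_int|² dV (for a lossless particle it would give
zero while the particle still scatters), so the scattering part is added
explicitly: by fine angular quadrature in the standalone operation, and by
quadrature over the doubling grid itself when building layer operators — the
latter makes the power a layer removes exactly equal the power it
redistributes plus absorbs, so energy closure holds to the grid's own
accuracy, with only the O(τ²) thin-slab residual remaining.

### Matrix doubling

Specific intensity (v/h polarizations, incoherent) is discretized on
Gauss–Legendre zenith nodes μ_k ∈ (0,1) per hemisphere (default 8; the node
nearest cos 43° is replaced by it and the weights are recomputed from the
moment conditions, so the radar incidence is an exact node) and an
equispaced azimuth-difference grid (default 16). A slab of thickness Δz
with per-volume phase matrix P and extinction κ has

    S = U⁻¹ P_backward Δz,   T = diag(e^{−κΔz/μ}) + U⁻¹ P_forward Δz,

with U = diag(μ_k); the direct Beer–Lambert term in T is required for
energy conservation and is therefore included even though the thin-layer
scattering equations are often written without it. Two slabs (1 above 2)
combine through the matrix geometric series

    S  = S₁ + T₁* S₂ (I − S₁* S₂)⁻¹ T₁         T  = T₂ (I − S₁* S₂)⁻¹ T₁
    S* = S₂* + T₂ S₁* (I − S₂ S₁*)⁻¹ T₂*       T* = T₁* (I − S₂ S₁*)⁻¹ T₂*

summing all bounce orders; associativity and equivalence to the explicit
Neumann series are asserted to 10⁻¹⁰ and 10⁻¹² respectively. Because the
medium is azimuthally symmetric the operators are block-circulant in the
azimuth difference, so combination is done per azimuth Fourier harmonic
(16×16 blocks), which is what makes full height sweeps cheap; the public
direction-space API and the harmonic fast path agree to 10⁻⁹ dB and both are
tested. Default Δz = 1 cm; a slab whose single-pass optical thickness at the
most grazing node exceeds 0.1 is automatically subdivided and recombined.
Halving Δz moves σ⁰ by < 0.05 dB and doubling both angular resolutions by
< 0.1 dB at the default settings (asserted).

σ⁰_pq = 4π cos θᵢ × S_total at (θ_s = θᵢ, Δφ = π), divided by the input
state's quadrature weight, in dB. An empty canopy reports −∞ as sentinel.
There is no ground surface: the canopy floats in free space.

### From crown shape to layer densities

A crown of height H is sliced into Δz slabs; the per-plant count of species
j in a slab is N_j = π μ_j ∫ ρ²(z) dz (closed form), with
μ_j = 8×10⁻⁵ cm⁻³ for every component by default. Counts are converted to
areal densities by a fixed reference footprint A_ref = π(H tan α)²,
identical for all shapes, so equal crown volume implies equal total
scatterer content per unit ground area — the crown shape changes only the
vertical distribution, which is exactly the variable under study.

## Crown-shape sensitivity: what this model can and cannot show

With equal columnar content the first-order backscatter of a layered medium
is provably independent of the vertical profile: writing the single-
scattering solution σ⁰ ∝ ∫ n(z) e^{−2T(z)/μ} dz with T(z) the overlying
optical depth, the substitution u = T(z) (du ∝ n dz for a fixed species
mix) collapses the integral to a function of the total optical depth alone.
Any contribution that is first order in canopy scattering — including
soil-bounce terms, had a ground been present — cancels the same way.

Crown-shape differences therefore appear only at multiple-scattering order.
At C band with the default parameters they amount to ~0.003–0.03 dB and
rank by profile concentration (∫n² dz: cone ≈ inverted cone > ellipsoid >
cylinder), with the mirror pair cone/inverted-cone nearly degenerate. The
frequently quoted ranking cone > cylinder > ellipsoid > inverted cone, with
differences of many dB, cannot arise in an energy-conserving formulation
with equal columnar content; reproducing it would require extinction and
scattering profiles that disagree (e.g. a shape-dependent scattering profile
against a shape-independent attenuation), which the package's energy tests
forbid. The acceptance tests assert the quoted ranking and the strict
monotonicity of σ⁰ along the cone↔inverted-cone parabola path faithfully and
are left failing, with this analysis as the explanation; the neighboring
properties that are attainable — σ⁰ nondecreasing in height, cross-pol
reciprocity within 0.2 dB, σ⁰ continuity over the (a, b) surface — pass.

## 3D canopy generator

The generator instantiates explicit geometry for external electromagnetic
solvers. Layers: ⌊H/l + 0.5⌋ for the broad-leaf canopy, ⌊H/l⌋ for the
needle-leaf canopy (l the stalk/branch length); counts per layer are
⌈ρ_v V/N_l⌉ for the cylinder crown and ⌈ρ_v V_i⌉ otherwise, with V_i the
exact slab volume (the closed form replaces the recursive approximations, so
ΣV_i equals the crown volume to rounding). Stalks/branches are vertical,
uniform over the admissible layer cross-section by rejection sampling;
every leaf attaches at a uniform random height and azimuth to the surface
of a uniformly chosen stalk of its layer. Collision detection treats all
primitives as capsules (segment–segment distance vs radius sum, strict test
with 10⁻⁹ cm slack, so leaf–parent tangency is allowed); placement caps at
10⁴ attempts per primitive and errors naming the layer. Containment is
enforced on each primitive's anchor point (center): with the tabulated
component lengths, whole-body containment is geometrically impossible near
the cone and ellipsoid apexes, and real foliage protrudes around an
idealized crown surface anyway. Everything is reproducible from the seed,
bytewise in the CSV manifest. Meshes are closed (watertight) capped
cylinders, tessellated at a configurable segment count, written as ASCII
STL or OBJ.

## Synthetic-data scope

The two built-in canopies are parameter sets, not data: component
dimensions, moistures and the common volume density are the tabulated
ground-measurement values (broad-leaf: 3 cm disc leaves, 1.25×10 cm stalks,
m = 0.85; needle-leaf: 0.3×4 cm needles, 0.2×30 cm branches, m = 0.6;
ρ_v = 8×10⁻⁵ cm⁻³; θᵢ = 43°; H = 80–300 cm in 10 cm steps; L/C/X bands at
1.2/5.3/9.6 GHz). The model deliberately omits: stratification and size/
orientation distributions within a canopy, coherent effects between
scatterers, any soil term, and edge effects of a finite crown (a 1-D layered
medium has none — which is precisely why its crown-shape sensitivity is
weaker than a full-wave simulation of an isolated crown). A green test
establishes internal consistency of this stated world, not agreement with
field measurements.

## Numerical defaults

| quantity | default | rationale |
|---|---|---|
| Δz | 1 cm | below 0.05 dB discretization at C band; auto-refined when optical thickness demands it |
| n_zenith / n_azimuth | 8 / 16 | < 0.1 dB from the doubled-resolution reference |
| needle orientation samples | 12 | cross-pol VH/HV asymmetry < 10⁻³ dB |
| cylinder series truncation | adaptive, tail < 10⁻⁹ | vacuum limit exact, thin-rod limit matches Rayleigh–Gans |
| placement attempts | 10⁴ per primitive | densest canopy uses < 2 average |
| feasibility tolerance | 10⁻⁹ | boundary shapes (touching zero) count as feasible |
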