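# mtvm — crown-shape-aware microwave backscattering of vegetation canopies

`mtvm` asks a forward-modeling question from radar remote sensing of
vegetation: **does the shape of a plant's crown — cylinder, cone, inverted
cone, ellipsoid, or anything in between — change the backscattering
coefficient σ⁰ the radar sees, when everything else (biomass, component
geometry, moisture) is held fixed?** It is written for people building or
stress-testing canopy scattering models: the crown envelope enters the
radiative transfer explicitly, as the vertical profile of scatterer density,
rather than being hidden inside a uniform-slab assumption.

## The model

The canopy is a cloud of independent scatterers (disc leaves, needle leaves,
stalk/branch segments) bounded by a crown envelope ρ(h), a surface of
revolution whose squared radius is a quadratic in normalized height,
ρ²(h) = (H tan α)²(a u² + b u + c), u = h/H. The constant c is always solved
from the equal-volume constraint a/3 + b/2 + c = 1/3, so every shape encloses
the reference cone volume and total biomass is controlled; the four named
shapes are the family members (0,0,1/3), (1,−2,1), (1,0,0), (−2,2,0).

σ⁰ is computed with the **matrix doubling algorithm**: the crown is sliced
into thin slabs, each slab's backward/forward operators are built from its
phase matrix (S = U⁻¹PΔz with the slant-path factor U⁻¹ = diag(1/μ) and a
Beer–Lambert direct term in T), and adjacent slabs combine through the matrix
geometric series S = S₁ + T₁*S₂(I − S₁*S₂)⁻¹T₁ (+ companions), which sums
every order of inter-layer multiple scattering. Single-scatterer amplitudes
use physical optics for thin discs, generalized Rayleigh–Gans for slender
needles, and the modal (Bessel-series) infinite-cylinder internal field
radiated over the finite length for stalks and branches; component
permittivity comes from the dual-dispersion vegetation dielectric model
(moisture + frequency in, ε′ − jε″ out). A seeded 3D generator additionally
instantiates explicit collision-free canopies (vertical stalks, surface-
attached leaves) and exports STL/OBJ meshes plus a CSV manifest for external
full-wave solvers.

Two ready-made canopies are built in: **A** (rice-like: 3 cm disc leaves,
1.25 × 10 cm stalks, moisture 0.85) and **B** (forest-like: 0.3 × 4 cm
needle leaves, 0.2 × 30 cm branches, moisture 0.6), both at volume density
8×10⁻⁵ cm⁻³, incidence 43°, L/C/X bands (1.2/5.3/9.6 GHz).

## Worked example

```python
from mtvm import (SimulationConfig, run_height_sweep,
                  shape_difference_report, vegetation_permittivity)

eps = vegetation_permittivity(0.85, 5.3)   # canopy A components at C band
print(eps.engineering)                     # (35.36144531142821-11.135595477190657j)

cfg = SimulationConfig(canopy="A", frequencies=(5.3,),
                       heights=(100.0, 200.0, 300.0), channels=("VV", "VH"))
table = run_height_sweep(cfg)
print(table.pivot_table(index=["channel", "height_cm"],
                        columns="shape", values="sigma0_db").round(3))
```

```
shape                cone  cylinder  ellipsoid  inverted_cone
channel height_cm
VH      100.0     -35.248   -35.245    -35.247        -35.248
        200.0     -29.838   -29.840    -29.839        -29.838
        300.0     -26.896   -26.899    -26.897        -26.896
VV      100.0     -24.649   -24.650    -24.649        -24.649
        200.0     -21.727   -21.729    -21.727        -21.726
        300.0     -20.069   -20.073    -20.070        -20.069
```

σ⁰ rises with crown height (more scatterers per unit area), cross-pol VH is
~11 dB below co-pol, and — the package's headline finding — the four
equal-volume crown shapes differ by only ~0.003 dB: with total columnar
biomass fixed, first-order backscatter of a layered medium is mathematically
independent of the vertical profile, so crown shape acts only through
multiple scattering. The difference report quantifies this against the
cylinder reference:

```python
print(shape_difference_report(table).round(4))
#  freq_ghz channel          shape  mad_db  mrd_percent
#       5.3      VH           cone  0.0025       0.0083
#       5.3      VH      ellipsoid  0.0020       0.0066
#       5.3      VH  inverted_cone  0.0025       0.0084
#       5.3      VV           cone  0.0023       0.0107
#       5.3      VV      ellipsoid  0.0019       0.0088
#       5.3      VV  inverted_cone  0.0025       0.0115
```

Command-line equivalents:

```sh
mtvm simulate --canopy A --out results.csv
mtvm report --table results.csv --reference cylinder
mtvm parabola --a-min -2 --a-max 1 --b-min -2 --b-max 2 --out surface.csv
mtvm gen3d --shape cone --height-cm 150 --canopy A --seed 42 \
           --format stl --out canopy.stl --manifest canopy.csv
mtvm permittivity --moisture 0.6 --frequency-ghz 5.3
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the installed package, the reference
quantities of the implementation: the vegetation permittivities of the two
canopies' components at 5.3 GHz (real and imaginary parts from the
dual-dispersion dielectric model) and the equal-volume parabola constants c
for the cone and ellipsoid crowns, writing them as JSON.

## Layout

- `src/mtvm/dielectric.py` — dual-dispersion vegetation permittivity
- `src/mtvm/crown_geometry.py` — envelopes, volume constraint, slicing,
  per-layer scatterer counts
- `src/mtvm/scatterer_models.py` — disc PO, needle Rayleigh–Gans, modal
  finite cylinder; extinction; angular-grid kernels
- `src/mtvm/matrix_doubling.py` — angular grid, thin-layer operators, slab
  combination, σ⁰ extraction
- `src/mtvm/simulator.py` — height sweeps, parabola sweeps, MAD/MRD metrics,
  quadratic trend fits
- `src/mtvm/canopy3d.py` — seeded 3D instantiation, collision detection,
  STL/OBJ/CSV export
- `src/mtvm/presets.py` — the two built-in canopy parameter sets
- `docs/methods.md` — model assumptions, numerics, limitations
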