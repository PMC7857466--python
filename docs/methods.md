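# Methods

## Physical model

`bonewave` computes axially propagating ultrasonic guided waves in a
circular cylinder built from concentric layers: an optional fluid-like
core (bone marrow), a stiff shell (cortical bone) and an outer coating
(soft tissue).  All materials are homogeneous and isotropic; the cortex
and tissue are linear elastic, the marrow is a viscous fluid represented
as an equivalent viscoelastic solid.  The waveguide is uniform along its
axis and the outer boundary is traction-free — the models are closed
trilayers, so leakage into an unbounded exterior is *not* represented
(no absorbing layers; attenuation comes only from material loss).

Osteoporotic degradation is modelled as a proportional reduction of the
cortical Young's modulus and density at fixed Poisson ratio, with the
modulus-to-density reduction ratio held near 3 (20/7 %, 30/10 %,
40/13 %).  For the built-in degraded configurations the tabulated
absolute values (11.96/10.465/8.97 GPa with 2145/2070/1993 kg/m³) are
used verbatim even where they round differently from the exact
fractional arithmetic; `apply_degradation` itself is exact.

## Semi-analytical finite-element (SAFE) formulation

The displacement field is `u(x1, x2) · e^{i(k x3 − ω t)}`: the
cross-section is discretised with 6-node isoparametric triangles (three
displacement components per node) and the axial direction is handled
analytically.  Galerkin assembly gives the quadratic eigenproblem in
the wavenumber `k`

    [K1 + i k K2 + k² K3 − ω² M] q = 0,

with `K1 = ∫B1ᵀCB1`, `K2 = ∫(B1ᵀCB2 − B2ᵀCB1)` (skew-symmetric for a
symmetric stiffness), `K3 = ∫B2ᵀCB2`, and the consistent mass `M`;
`B1` holds the in-plane derivative terms of the strain operator and
`B2` the axial (`ik`) terms.  For lossless sections the operators are
real, so eigenvalues appear in `±k` pairs (with complex quadruples for
evanescent modes); this symmetry is verified by a dense solve on a
small fixture.  Transposes, not conjugates, appear in the weak form so
the pencil stays polynomial in `k` for complex (viscoelastic) moduli.

Sign conventions, fixed once: time factor `e^{−iωt}`; dissipative
moduli have non-positive imaginary parts; retained forward modes have
`Re k > 0` and `Im k ≥ 0`, so attenuation is `|Im k|` in Np/m (also
exported in dB/m).  Phase velocity is `ω / Re k`; group velocity is
`dω/d(Re k)` by central finite differences along a tracked branch
(one-sided at the grid ends).  The eigenvector-energy formula for group
velocity would avoid differencing noise but is unnecessary at the grid
steps used here.

The quadratic pencil is linearised in companion form, `z = [q; kq]`,
and solved by shift-invert Arnoldi.  Solving the shifted companion
system only requires an LU factorisation of the *n×n* evaluated pencil
`P(σ)` (block elimination), not of the doubled system.  Shifts are
spread over the wavenumber window that corresponds to the requested
phase-velocity window — by default four shifts, collecting ~32
eigenpairs each; this redundancy is what keeps high-frequency slices
(dense spectra) gap-free.  The Arnoldi start vector is fixed (seeded
noise — a constant vector would be azimuthally deficient), making every
solve bit-reproducible; the physics pipeline contains no stochastic
step.  Retained eigenpairs satisfy a relative pencil residual below
1e−8 (typically ~1e−10).

## Marrow as an equivalent viscoelastic solid

The marrow (bulk modulus 2.2 GPa, density 1000 kg/m³, viscosity
37 cP) enters the same solid assembly path through complex Lamé
constants.  The longitudinal stiffness honours the fluid exactly,
`Re(λ + 2μ/3) = K`.  The shear modulus is whichever is larger in
magnitude of the Newtonian term `−iωη` and a numerical floor
`ρ c_s² (1 − i d)²` with default floor speed `c_s = 100 m/s` and
damping ratio `d = 0.5`.  The floor regularises the otherwise
near-singular shear block of the discretised fluid: spurious
mesh-scale shear modes acquire a tiny phase velocity (~100 m/s, far
below the retained window) and ~50 % loss, so they never contaminate
the retained set.  Retained bone-guided modes feel the floor only
weakly — its magnitude (~1.25e7 Pa) is four orders below the marrow
bulk modulus — and the floor's influence is exercised by the test
suite via the ideal-fluid limit (floor → 0 recovers `sqrt(K/ρ)`).
True marrow-guided modes (energy ≥ 50 % in the core) are removed by the
power-flow filter, mirroring the physical argument that only modes
guided by the bone are useful for assessment.

## Cross-section mesh

The mesher is structured and deterministic: vertex rings at fixed
radii (at least one element band per layer), a fixed sector count set
by the outer circumference, fan triangles around the centre of a solid
core, diagonal-split quads elsewhere, and midside nodes of
circumferential edges snapped onto their circles.  Material interfaces
therefore coincide with (curved) element edges, and tagged region areas
match the analytic annulus areas to ~3e−7 at the default resolution.

The default element size is 1.0 mm.  It is calibrated by the
mesh-halving criterion used throughout: halving the element size must
move retained phase velocities by less than 0.2 %.  A quarter-shear-
wavelength heuristic (~1.6 mm at 200 kHz) fails that test — halving
from 1.6 mm shifts trilayer comparison-band modes by up to 0.6 % and a
free-tube n = 3 mode by 0.33 % — while at 1.0 mm all retained tube
modes move < 0.08 % on halving, except inside the bulk-shear asymptote
cluster (|v − c_T| < 40 m/s) where many flexural branches coalesce onto
c_T and pairing modes between meshes is ill-posed.  Absolute velocities
at 1.0 mm sit within ~0.6 % of fully converged values; velocity
*differences* between configurations are far less mesh-sensitive, so
the packaged comparison studies run them on a 1.6 mm mesh (see problem
sizes below).

## Mode classification, tracking and labelling

Circumferential order is read directly off a full ring of mesh vertices
(uniform azimuth, no interpolation): the azimuthal DFT power of all
three cylindrical displacement components is folded over ±n and the
dominant order returned.  Using all three components keeps the
classification defined for torsional modes, whose radial component
vanishes; a mode with dominant order 0 is flagged torsional when its
circumferential component dominates.

Flexural modes of an axisymmetric section are exactly degenerate
cos/sin pairs.  The eigensolver collapses each pair into a canonical
rotating-wave representative — the combination with purely `e^{+inθ}`
azimuthal content, phase-fixed so its `+n` harmonic is real and
positive.  Without this, the arbitrary mixtures returned by the
eigensolver make cross-frequency mode pairing meaningless (two mixtures
of the same pair can be orthogonal).

Branches are tracked across the frequency grid by greedy best-first
pairing on the modal assurance criterion
`MAC(a,b) = |aᴴb|²/(‖a‖²‖b‖²)`, with a one-grid-step gap bridged so a
single missed solve does not split a branch.  The threshold default is
0.7: measured MACs of physically continuous trilayer branches at
10-kHz steps fall to ~0.75 near cut-offs, so the textbook 0.9 would
fragment branches and corrupt the family numbering.

Labels follow the classical convention: within a family (longitudinal,
torsional, or flexural of fixed order n) branches are numbered
m = 1, 2, … by ascending appearance frequency on the computed grid,
ties broken by ascending phase velocity at the lowest shared frequency.
Two caveats follow from computing on a finite grid and window.  First,
m is relative to the *retained* set: branches living below the
phase-velocity window floor (default 1500 m/s — e.g. the true bending
fundamental at low frequency) or below the grid start are not counted,
so the absolute m of a given physical branch can differ between runs
and between this package and other solvers.  Second, published
nomenclature for the same trilayer depends on exactly which low-order
branches that solver retained.  Comparisons therefore never rely on m:
the comparison utilities resolve a requested mode *structurally* — the
branch of the requested family that spans the whole comparison band
with the highest in-band phase velocity — a rule that is unambiguous on
all built-in configurations, and reports carry both the requested and
the computed label.

## Axial power flow

The time-averaged axial Poynting density
`−Re[(iω/2)(u1*σ31 + u2*σ32 + u3*σ33)]` is evaluated at quadrature
points (stresses recovered per element from the constitutive law and
the `ik` axial-derivative rule; no nodal averaging, so nothing smears
across material interfaces).  Regional powers are quadrature integrals
over tagged elements and are additive to ~1e−12 relative.  Every
retained eigenvector is normalised to unit total cross-section power,
making the cortex power *fraction* the natural scale-free quantity; the
normalised cortex-power table divides by the global maximum so its
largest entry is exactly 1.  All power quantities are invariant under
eigenvector phase rotation.

For a dissipative core the regional powers need not all be positive
(the marrow can carry a small counterflow), so a cortex fraction can
slightly exceed 1.  Cross-mode cortex-power rankings also depend on the
eigenvector normalisation convention, which published figures rarely
state; rank order near ties and the exact location of a cross-mode
maximum should be treated as normalisation-sensitive (the packaged
level-3 table has the flexural candidate's cortex fraction at 100 kHz
and 110 kHz separated by 0.6 %).

## Degradation analysis

For a requested mode and frequency band, the pipeline tabulates
per-frequency phase-velocity differences (healthy − degraded), their
arithmetic band mean, and the percent reduction relative to the healthy
band-mean velocity.  The same machinery accepts externally supplied
velocity columns, giving a pure-arithmetic path that is independent of
the solver.  Candidate modes are ranked by band-averaged difference
(descending), ties broken by cortex power fraction.

Ranking is meaningful only for modes already propagating well below the
band: a branch whose cut-off sits in or near the band shows arbitrarily
large fixed-frequency differences because degradation shifts the
cut-off itself — a different observable.  The packaged ranking
therefore compares the tabulated candidate modes, not the entire
retained population.

A low-frequency consistency check compares the fundamental
longitudinal branch against bar theory `sqrt(E/ρ)` and the predicted
relative reduction `½(ΔE/E − Δρ/ρ)` (the differential of the bar
velocity at fixed Poisson ratio).  On a free rod the bar asymptote is
met within 1 %; on the loaded trilayer the absolute comparison is only
indicative (mass loading depresses the fundamental), which the check
reports via flags rather than hard failures — the *relative* reduction
is the robust quantity.  The `K(ν)` prefactor of the asymptote is
exposed as a pass-through with default 1.

## Analytic oracle

An independent validation path implements the exact dispersion function
of a traction-free single-layer cylinder (hollow or solid): the three
scalar potentials with Bessel radial factors, six traction rows
(σ_rr, σ_rθ, σ_rz on each free surface) derived symbolically with
sympy and lambdified onto scipy's complex Bessel functions — no matrix
entry is transcribed by hand.  Roots in phase velocity are located as
deep minima of the smallest singular value of the column-normalised
boundary matrix.  The potential basis degenerates at the bulk speeds
(α = 0 or β = 0), so neighbourhoods of c_L and c_T are excluded and the
fundamental torsional result (v = c_T exactly, at all frequencies) is
checked in closed form.  SAFE and oracle agree to ≤0.35 % on every
comparable free-tube mode at the test resolutions — two formulations
with no shared discretisation.

## Synthetic fixtures

`random_waveguide_fixture` generates seeded 1–3-layer elastic cylinders
spanning the envelope of the built-in models (radii 3–20 mm, E 5–20
GPa, ν 0.25–0.45, ρ 1000–2500 kg/m³, layer thickness ≥ 1.5 mm) for
property tests: spectrum symmetry, power additivity, mesh validity.
The generator emulates geometry and stiffness ranges only — it does not
produce viscous cores, anisotropy, rough interfaces or non-circular
sections, so passing property tests demonstrate correctness of the
numerics inside the isotropic layered-cylinder model class, not
fidelity to real bones.

## Problem sizes and runtimes

Chosen so a full verification run completes on a single desktop core:

* default production mesh 1.0 mm → ~5,600 quadratic triangles /
  ~50,000 dof on the trilayer (absolute dispersion cells, acceptance
  targets);
* comparison studies 1.6 mm → ~1,200 triangles / ~7,600 dof
  (velocity-difference tables, ordinal checks, power tables), on
  band-covering grids of 5–11 frequencies per configuration;
* free-tube validation meshes 1.0–2.0 mm with a 0.5 mm refinement tier
  for the halving criterion.

## Known limitations

* Closed waveguide: no leakage into surrounding media; absolute
  attenuation reflects material loss plus the marrow shear floor, so
  attenuation curves are comparative, not absolute predictions.
* Isotropic layers only; cortical bone anisotropy and poroelasticity
  are outside the model class.
* Branch numbering is window- and grid-relative (see above); use the
  structural band-selection rule for cross-solver comparisons.
* Cross-mode power rankings are eigenvector-normalisation-sensitive;
  within-mode trends and regional fractions are robust.
* The marrow equivalent solid regularises shear with a documented
  floor; results for modes with substantial marrow energy (which the
  filter removes) should not be trusted.
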