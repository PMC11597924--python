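# Methods

## Geometry and coordinates

The phantom is a 2D cross-section of the implant site.  The lateral
coordinate x spans the 16.5 mm device width (midline at 0); depth y
increases into tissue.  Layer interfaces are concentric circular arcs
sharing a centre of curvature at (0, R); the *radial depth* R − |P − C|
reduces to y in the flat-slab limit (R → ∞), which all analytic tests
use.  The curvature radius is not fixed by the source material (the
contour was atlas-derived); the default is R = 80 mm — head-scale
curvature — and every result is reported with the radius used.  Points
exactly on an interface belong to the deeper layer, a deterministic
tie-break the geometry tests pin down.

Four layers stack source-side → deep: polyurethane case (0.8 mm,
η 1.60), CSF (0.5 mm, η 1.33), gray–white matter (2.5 mm, η 1.50),
cerebellum (3.5 mm, η 1.42); total 7.3 mm.  The baseline optical
coefficients are used verbatim even though they are orders of magnitude
below literature tissue values (μₐ of order 10⁻³–10⁻⁴ m⁻¹, μₛ of
10⁻²–1 m⁻¹): fidelity to the source model's parameter table is the
default, and alternative property sets are a configuration switch (see
*Synthetic property curves*).  One tabulated oddity is kept deliberately:
the polyurethane density of 1.1 kg/m³ (about three orders below the
physical value), which makes the case layer's thermal response
essentially instantaneous; the implicit heat stepper absorbs this without
a stability penalty.

The diode array (four emitters, 1.5 mm pitch, centres at ±0.75 and
±2.25 mm) sits, by default, on the tissue-facing boundary of the case,
emitting into the CSF; an `"outer"` option places it on the outer case
face so that light traverses the polyurethane.  The two placements came
from two conflicting statements of the source design; both are kept, and
the default follows the more specific interface contract.  Emission
combines a Gaussian launch-position profile along the surface
(σ = spot/2 = 0.15 mm, truncated at 2σ) with a direction drawn uniformly
inside the ±60° emission cone about the tilted axis.  The source text
specifies both "a Gaussian beam" and "a 120° view angle" without
reconciling them; the uniform truncated cone is the package default (it
matches the ray-engine contract), and a collimated mode exists for
analytic work.  This choice matters — see *Known discrepancies*.

## Transport

**Monte Carlo engine.**  Weighted packets: free path ~ Exp(μₜ) in the
current layer; at each collision the fraction μₐ/μₜ of the weight is
deposited in the enclosing tally cell (and the layer accumulator), and
the packet deflects by a 2D Henyey–Greenstein angle (closed-form inverse
CDF; the sample mean of cos φ equals g, which a test checks).  Default
g = 0.9, typical of brain tissue in the red/NIR; g = 0 is used in oracle
scenarios.  Interfaces apply unpolarized Fresnel reflectance (mean of s
and p) stochastically, with vector Snell refraction on transmission and
total internal reflection handled exactly.  Packets terminate by Russian
roulette (threshold 10⁻⁴ of the *launch* weight, survival probability
0.1 — unbiased) or by leaving the domain, where their weight is credited
to the reflected port (entry surface), transmitted port (deep surface) or
lateral account.  The domain boundaries themselves are transparent
(no Fresnel at the outer and deep faces): the ports are defined as power
flow through those surfaces.

Reproducibility: each photon's RNG is seeded from a multiplicative hash
of (run seed, diode index, photon index), so results are bit-identical
for a given seed and independent of execution order.  Per-grid-point
sweep seeds are BLAKE2 hashes of (seed, angle, wavelength): adding grid
points never perturbs existing ones.  The power axis of a sweep is filled
by exact linear scaling of one unit-power run — transport is strictly
linear in source power — which keeps the power column noise-free.

**Ray engine.**  Each diode becomes a deterministic fan (Gaussian-weighted
spot nodes × uniform cone nodes, default 9 × 181).  Rays refract at every
interface; the Fresnel-reflected fraction is credited directly to the
reflected port without further tracing, and total internal reflection
terminates a ray into the same account — a first-order treatment that is
exact for index-matched stacks and accurate to O(R·absorption) otherwise.
Scattering removes power from the beam into a `scattered_out` account
(μₛ as pure attenuation).  Per-layer totals use the exact telescoping
exponentials (machine precision — the zero-scattering slab test demands
ten significant digits against e^(−μₐL)); only the spatial grid
deposition is discretised (substep h/2, with exact exponential decrements
per substep).

**Tally grid.**  Cartesian, cell edge h (default 0.05 mm → 330 × 146
cells), labelled by the layer at each cell centre; in curved mode the few
deposits falling below the grid's rectangular footprint near the lateral
edges are clipped into the nearest cell (layer totals are kept in exact
separate accumulators and are unaffected).  2D convention: all powers are
W per unit out-of-plane depth, so the gridded density u = (cell power)/h²
has units W/m³ per unit depth.  Absolute absorbed-power magnitudes from
the full-wave reference cannot be dimensionally reconciled without its
(unpublished) 2D normalisation, so cross-checks are made on argmax
locations, orderings and fractions — never magnitudes.

## Heat transfer

ρc ∂T/∂t = ∇·(k∇T) + u on the tally grid, finite volumes with
harmonic-mean face conductivities (exact for piecewise-constant k).  No
perfusion or metabolic terms by default; a uniform volumetric source can
be added via configuration, and conduction linearity (rise ∝ power) is an
asserted invariant.  Boundary conditions: insulated device face, fixed
310.15 K deep and lateral edges; each edge is configurable, and cells
outside the curved tissue band are excluded (insulated, pinned at body
temperature in the steady solver).  Two steppers: explicit (rejects a dt
above the computed stability bound, reporting the bound) and implicit
backward Euler (one sparse LU factorisation, then triangular solves;
default for 300 s transients).  The two agree on the 1D analytic problem
to <5×10⁻⁴ K, and the steady solver reproduces the linear conduction
profile to machine precision.

## Synthetic property curves

The wavelength-resolved coefficients that drove the reference study's
angle-by-wavelength results exist only as figures, so the fixtures module
generates stand-in curves with the qualitative structure reported for
these tissues: Rayleigh λ⁻⁴ scattering anchored at 660 nm (the particle
scattering model's scaling), a continuously rising gray-matter absorption
ramp (+50% across 660→870 nm), water-like quadratic growth for CSF, and a
cerebellum curve with two minor Gaussian peaks at 660 and 840 nm
(amplitudes of the order of the baseline μₐ; positions, widths and
amplitudes configurable, so digitised measured curves drop in without
code changes).  Two magnitude anchors exist:

* `peaked-curves` (default study conditions) — anchored to the baseline
  property table verbatim, i.e. quasi-ballistic media;
* `literature-curves` — anchored at red/NIR tissue-optics magnitudes
  (absorption ~15–20 m⁻¹, μₛ ~5–6×10³ m⁻¹ with g = 0.9), i.e. the
  scattering-dominated regime of real brain tissue.

What passing tests on these fixtures do show: the sweep machinery,
interpolation, argmax logic, conservation and thermal chain all behave
correctly under both regimes.  What they do not show: agreement with any
particular measured tissue spectrum — the curves are synthetic stand-ins,
not digitised data.

## Sweep and acceptance conditions

The default sweep grid is the study design: tilt 0–90° in 10° steps ×
eight wavelengths 660–870 nm in 30 nm steps × eight power levels (1–8 mW
per diode; the power-unit ambiguity in the source is resolved to mW, and
linearity makes every argmax insensitive to this).  `find_optimum`
breaks ties toward the smaller angle, then the smaller wavelength.
Problem sizes used by the acceptance script: ray engine 6516 rays per
grid point; Monte Carlo 10⁵ photons per grid point for the angle sweeps,
4×10⁵ for the thermal operating point, 10⁶ for the conservation check —
sizes at which the reported quantities are stable to well inside the
comparisons made on them.  The thermal-safety number (t3) is computed
under `literature-curves`: a safety statement about real tissue requires
realistic absorbed power, and under the baseline table's coefficients the
absorbed fraction (~4×10⁻⁶) gives a physically meaningless rise of
~4×10⁻⁸ K (also reported, as `max_rise_table1_K`).  With realistic
optics the 300 s rise at the operating point is ≈1.0×10⁻³ K, matching the
reported order of magnitude.

## Known discrepancies and limitations

* **Angle optimum (t1/t2).**  The reference reports cerebellum-absorption
  optima at 20° (660 nm) and 50° (840 nm).  This package computes 0° at
  both wavelengths under the prescribed source model.  The mechanism is
  robust across both engines: with a ±60° uniform emission cone, tilting
  the axis replaces moderately absorbing directions on one flank with
  grazing/TIR directions on the other, so normal incidence maximises
  deep-layer absorption for *any* wide symmetric angular density in an
  incoherent transport model.  A directed (collimated) beam reproduces an
  interior optimum — ~50° with the tissue-facing launch, ~40° from the
  outer face — because the slant path through the cerebellum grows as
  1/cos θ until lateral escape and internal reflection win.  Obtaining
  *different* optima at 660 vs 840 nm additionally requires
  wavelength-dependent attenuation strong enough to couple angle and
  wavelength (overlying reduced-scattering optical depth of order 1 at
  660 nm but ≪1 at 840 nm); the baseline-anchored curves are far below
  that window, the literature-anchored ones far above it (both
  wavelengths diffusive → optimum 0° again).  The acceptance test prints
  both engines' angle tables and documents the discrepancy rather than
  asserting it away; the reference values likely reflect coherent
  full-wave physics, which is out of scope here.
* The ray engine's first-order treatment of interface reflections
  (credited to the port, not re-traced) biases its S11 slightly low in
  absorbing index-mismatched stacks; the Monte Carlo engine is the
  authority there (the three-layer incoherent multiple-reflection test
  pins this down).
* No polarization, coherence, speckle or time-resolved transport; no 3D
  geometry; no perfusion or thermal-damage integrals; refractive indices
  are wavelength-independent.
* The S-parameters are incoherent power fractions, not complex field
  ratios.
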