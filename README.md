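# paws-sim

Dosimetry simulation for an implanted photobiomodulation (PBMT) diode
array: how much red/near-infrared light does each brain-tissue layer
absorb, how does that depend on the incident angle, wavelength and drive
power, and how much does the tissue heat up?

The package is aimed at photonic-implant designers and tissue-optics
modellers who need a fast, reproducible 2D model of an LED module pressed
against curved brain tissue — the kind of question that full-wave FEM
solvers answer slowly and irreproducibly, and that a layered Monte Carlo
model answers in seconds.

## The model

The phantom is a 2D cross-section of four concentric curved layers (the
polyurethane device case, the cerebrospinal-fluid film, combined
gray–white matter, and the cerebellum target layer), each with thickness
t, refractive index η, absorption coefficient μₐ, scattering coefficient
μₛ, and thermal parameters k, ρ, c.  A four-diode array (1.5 mm pitch,
0.3 mm Gaussian spot, 120° emission cone) illuminates the stack at a
common tilt angle θ from the local surface normal.

Light transport uses two engines behind one interface:

* **Monte Carlo** — weighted photon packets with exponential free paths
  (μₜ = μₐ + μₛ), per-collision deposition of the fraction μₐ/μₜ
  (the absorbed energy density u(x) = μₐ·I(x)), 2D Henyey–Greenstein
  scattering (anisotropy g), stochastic unpolarized Fresnel splits and
  Snell refraction at interfaces, and Russian-roulette termination.
* **Ray engine** — a deterministic fan of refracted rays attenuated by
  Beer–Lambert, I(x) = I₀·e^(−μₐx), along their geometric paths; the
  closed-form oracle for the Monte Carlo engine and the fast path for
  sweeps in low-scattering media.

Power bookkeeping is two-port: S11 is the fraction of launched power
returned through the entry (device) boundary, S21 the fraction delivered
through the deep boundary; lateral escape is tracked separately, and
every launched watt lands in exactly one account (energy conservation is
tested to Monte Carlo precision).  All 2D powers are per unit
out-of-plane depth.

The absorbed-power grid then drives transient heat conduction,
ρc ∂T/∂t = ∇·(k∇T) + u, with harmonic-mean conductivities at layer
interfaces, an insulated device face and body-temperature (310.15 K)
deep/lateral boundaries — solved explicitly (with an automatic stability
bound) or implicitly (sparse backward Euler) for thermal-safety checks.

Wavelength dependence enters through per-layer property curves
(piecewise-linear in λ).  Because the reference coefficient-vs-wavelength
curves exist only as figures, `paws_sim.fixtures` synthesises stand-ins:
Rayleigh λ⁻⁴ scattering (the particle-model scaling
μₛ = (2π⁵d⁶)/(3λ⁴)·(Δn)²·N), a rising gray-matter absorption ramp, and a
cerebellum curve with minor peaks at 660 and 840 nm — anchored either to
the baseline property table (`peaked-curves`) or to literature
tissue-optics magnitudes (`literature-curves`).

## Worked example

```python
import paws_sim as ps

phantom, props, source = ps.make_fixture(
    ps.FixtureSpec(scenario="literature-curves", tilt_angle_deg=0.0)
)
field = ps.run_transport(phantom, source, props, n_photons=200_000, seed=1)
ports = ps.port_summary(field)
print(f"launched power        : {field.launched_power * 1e3:.1f} mW")
for layer, absorbed in zip(phantom.layers, field.per_layer_totals):
    print(f"absorbed in {layer.name:<12}: {absorbed * 1e3:.3f} mW")
print(f"S11 (reflected)       : {ports.s11_power_fraction:.3f}")
print(f"S21 (transmitted)     : {ports.s21_power_fraction:.3f}")
print(f"cerebellum abs. rate  : {ps.absorption_rate(field, 3):.3f}")

series = ps.run_transient(phantom, field, duration_s=300.0, dt=1.0)
print(f"max rise after 300 s  : {ps.max_temperature_rise(series):.2e} K")
```

prints

```
launched power        : 12.0 mW
absorbed in polyurethane: 0.030 mW
absorbed in csf         : 0.006 mW
absorbed in gray_white  : 1.231 mW
absorbed in cerebellum  : 0.803 mW
S11 (reflected)       : 0.520
S21 (transmitted)     : 0.226
cerebellum abs. rate  : 0.111
max rise after 300 s  : 1.02e-03 K
```

Four 3 mW diodes at normal incidence deliver about 0.8 mW to the
cerebellum layer under realistic tissue optics; roughly half the light is
back-scattered out through the device face, and the steady thermal load
warms the tissue by only ~10⁻³ K — far below any damage threshold.

The same sweep the study design calls for — angle 0–90° in 10° steps ×
eight wavelengths (660–870 nm) × eight power levels — runs through
`paws_sim.run_sweep`, and `find_optimum` returns the absorption-maximising
(angle, wavelength) cell with deterministic tie-breaks.  A thin CLI wraps
the library:

```bash
paws-sim run --engine ray --tilt 20 --wavelength 660 --power-mw 3
paws-sim sweep --scenario peaked-curves --engine ray --out sweep.csv
paws-sim optimum --sweep-csv sweep.csv --layer cerebellum
paws-sim thermal --scenario literature-curves --tilt 0 --duration 300
```

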