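# colonypattern

Reaction-diffusion modelling and wavelength analysis of pattern-forming
bacterial colonies.

Engineered *E. coli* populations that couple quorum sensing to cell
elongation and adhesion can break the radial symmetry of a growing colony
and form regular, branched density patterns — a synthetic realisation of
local activation with long-range lateral inhibition. This package is for
computational and synthetic biologists who want to simulate that system,
map its dynamical phases across parameter space, and measure pattern
wavelengths both in simulations and in colony photographs.

## Model

Three coupled fields live on a spatial lattice (1D chain or hexagonal 2D
patch): actively dividing cells *x*, elongated differentiated cells *y*
(non-dividing, immobile), and a fast-diffusing quorum-sensing signal *H*
produced by both populations:

```
∂x/∂t = D_x ∇²x + μ x (1 − x − y − Φ(H)) − κ Φ(H) x + ν y
∂y/∂t =            κ Φ(H) x − ν y
∂H/∂t = D_H ∇²H + α (x + y) − δ_H H
```

Φ(H) = H² / (H_c + H²) is a Hill activation with exponent 2, with H_c the
activation coefficient (semi-activation concentration √H_c). Growth is
logistic toward a shared carrying capacity and is suppressed by the
signal, which also drives differentiation x → y at rate κΦ; elongated
cells revert slowly at rate ν. Because D_H ≫ D_x, the signal acts as a
long-range inhibitor: depending on its decay rate δ_H and the activation
threshold H_c, a colony seeded at the centre of the domain either expands
as an unconstrained traveling front, sweeps the domain leaving a
stationary periodic arrangement of cell density (a standing wave), or
stalls near the inoculum with spatially damped oscillations.

The integrator is explicit Euler (Δt = 0.01) with a neighbour-sum graph
Laplacian (zero-flux boundaries) and a fixed 20 000-iteration budget.
Phases are read from the spatial power spectrum of the final total-cell
profile: a spectral peak with prominence ≥ 1.5 (on the mean-normalised
profile) marks a pattern, its inverse frequency is the characteristic
wavelength λ_c, and growth self-limitation separates damped oscillations
from standing waves.

The image pipeline mirrors the analysis applied to colony photographs:
polar transform about the estimated colony centre, intensity-versus-angle
near the colony edge, and an FFT whose dominant integer harmonic *m*
gives the boundary wavelength λ = 2πr/m in centimetres.

## Worked example

```python
from colonypattern import ModelParams, build_lattice_1d, run_simulation, classify_phase

params = ModelParams().with_log10(delta_H=-5, H_c=-4)   # standing-wave regime
lattice = build_lattice_1d(400)
traj = run_simulation(lattice, params, n_iter=20_000, seed=0)
phase = classify_phase(traj)
print(f"phase: {phase.label}, wavelength: {phase.wavelength:.1f} lattice sites")
```

prints

```
phase: standing_wave, wavelength: 23.5 lattice sites
```

i.e. at δ_H = 10⁻⁵ and H_c = 10⁻⁴ the colony fills the 400-site domain
and freezes a stationary wave whose crests repeat every ~24 lattice
sites. The image pipeline on a synthetic 12-lobed colony (radius 0.4 cm,
noise at 10% of the lobe contrast):

```python
from colonypattern import SyntheticColonySpec, generate_colony_image, analyze_colony_image

spec = SyntheticColonySpec(n_lobes=12, noise_sd=17.0, seed=0)
profile, wavelength = analyze_colony_image(generate_colony_image(spec), radius_fraction=0.95)
print(f"boundary wavelength: {wavelength:.3f} cm at radius {profile.radius_cm:.3f} cm")
```

prints

```
boundary wavelength: 0.198 cm at radius 0.377 cm
```

recovering the generator's 2π·0.95·0.4/12 ≈ 0.199 cm arc-length
wavelength to under 1%, at the ~0.2 cm scale characteristic of the real
colonies.

A command-line layer wraps the same functions:

```
colonypattern simulate --config run.yaml --seed 1 --out run_out/
colonypattern classify --traj run_out/
colonypattern sweep --config sweep.yaml --out sweep_out/ --scale reduced
colonypattern analyze-image --img colony.png --pixel-size-cm 0.0025
colonypattern synth fixtures --out fixtures/
```

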