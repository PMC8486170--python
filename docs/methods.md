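# Methods

## Model and assumptions

The system couples three fields on a lattice: dividing cells *x*,
elongated differentiated cells *y*, and a quorum-sensing signal *H*
(a homoserine lactone produced constitutively by both cell types):

```
∂x/∂t = D_x ∇²x + μ x (1 − x − y − Φ(H)) − κ Φ(H) x + ν y
∂y/∂t =            κ Φ(H) x − ν y
∂H/∂t = D_H ∇²H + α (x + y) − δ_H H
```

Assumptions baked into this form:

- both cell types share one carrying capacity (the `1 − x − y` term), and
  the signal enters the logistic bracket so that high *H* not only
  triggers differentiation but suppresses (and, above capacity, reverses)
  net growth — the population-level analogue of the growth arrest that
  elongation causes;
- only *x* and *H* diffuse; elongated cells are adhesive and immobile;
- *y* cells revert to *x* at a small linear rate ν, and no explicit
  death term exists beyond the logistic bracket;
- signal production is linear in total cell density (rate α per unit
  density) and decay is first order (rate δ_H).

### Hill parameterization

Signal response is a Hill function with the commonly assumed exponent
n = 2, written in the activation-coefficient form

```
Φ(H) = H² / (H_c + H²),
```

i.e. `H_c` carries units of signal², and the semi-activation
concentration is √H_c. Both this form and the semi-activation form
K² + H² are standard in the gene-regulation literature;
`hill_activation` takes the semi-activation concentration directly, and
`ModelParams` documents `H_c` as the activation coefficient. This
parameterization is what places the three reference regimes
(see below) in distinct dynamical phases: with the semi-activation
reading the two low-H_c reference points collapse onto an inert,
fully-saturated regime in which the colony freezes as a three-site
spike, and the δ_H axis of the phase diagram loses all dynamical effect
over five decades. Under the activation-coefficient reading all three
regimes reproduce their expected phenotypes robustly across seeds.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| D_x | active-cell diffusion | 0.005 | site²/time |
| D_H | signal diffusion | 5.0 (= 10³ D_x) | site²/time |
| μ | maximal growth rate | 8 | 1/time |
| α | signal production per unit density | 2 | signal/(density·time) |
| δ_H | signal decay | 10⁻⁵ | 1/time |
| H_c | Hill activation coefficient | 10⁻⁴ | signal² |
| n | Hill exponent | 2 | — |
| ν | reversion y → x | 0.001 | 1/time |
| κ | maximal differentiation rate | 0.1 | 1/time |
| dt | Euler step | 0.01 | time |

The kinetic defaults are the base set used throughout the simulation
studies; δ_H and H_c default to the standing-wave regime because those
two parameters are the axes of the phase diagram and have no single
canonical value. `D_H ≥ D_x` is required for lateral inhibition and is
enforced as a warning, not an error.

## Spatial discretisation and integration

Lattices are 1D chains or hexagonal (triangular-tiling) patches with
unit site spacing; the 2D patch is a rhombus in axial indexing, so every
interior node has six neighbours at distance 1. Diffusion is the
unnormalised graph Laplacian `(Lf)_i = Σ_j f_j − deg(i) f_i`; boundary
nodes simply have fewer neighbours, which makes the boundary zero-flux —
the natural condition for a closed Petri dish. Integration is explicit
Euler with dt = 0.01. Stability is comfortable: the stiffest term obeys
dt · D_H · λ_max(−L) ≤ 0.01 · 5 · 12 = 0.6 < 2 on the hexagonal lattice.
Tiny negative undershoots (never observed below −10⁻⁶ in the study
regimes) are clamped to zero and logged. A fixed 20 000-iteration budget
(t = 200) is used rather than an adaptive stopping rule; an optional
early stop on max-abs change < tol is available but off by default.

Initial conditions follow the study protocol: x = 0.05 + U(0, 0.05)
independently on the 3 central sites (1D) or on every site within
Euclidean distance 10 of the central node (2D); y = H = 0 everywhere.
One integer seed determines a run bit-for-bit; sweep replicate (i, j, r)
derives its seed from `SeedSequence([master, i, j, r])` so any execution
order yields identical results.

## Phase classification

The final total-cell profile x + y is normalised to its relative
modulation `p/mean(p) − 1` and Fourier transformed; spectral peaks are
scored by prominence (`scipy.signal.find_peaks`) with the threshold 1.5.
The mean-normalisation is what makes an absolute threshold meaningful
across regimes whose densities span orders of magnitude: filled
traveling-front profiles keep every normalised peak power below ~0.4,
while genuine patterns produce peak powers of 10³–10⁴. A peak only
counts if its wavelength fits at least two periods inside the occupied
colony width, which rejects envelope components of localized profiles.
A coefficient-of-variation gate (std/mean ≥ 0.1) screens the
essentially-flat filled profiles (measured CV ≈ 0.025) from patterned
ones (CV 0.5–1.8) before peak detection.

The four labels cross the pattern test with growth self-limitation,
measured on the occupied extent (profile above 10% of its maximum — a
level chosen between the sub-percent leaked halo of stalled colonies,
~6% of max, and the bulk plateau of swept ones, >30%) over the last
quarter of the run:

| prominent peak | front swept domain / still growing | label |
|---|---|---|
| no | yes | traveling_front |
| no | no | no_pattern |
| yes | yes | standing_wave |
| yes | no | damped_oscillation |

Self-limitation, rather than a threshold on the spatial envelope decay,
separates damped oscillations from standing waves because the envelope
decay rate is non-monotone across the (δ_H, H_c) plane: both pattern
regimes decay geometrically away from the seed (sustained waves at
~0.55–0.6 per period, stalled ones at ~0.2), and an envelope cut either
merges them or splits the damped phase into two disconnected bands.
Growth self-limitation is monotone in inhibition strength and matches
the qualitative definition of the phases: fronts that cannot limit their
own growth versus patterns formed when the inhibition is stronger. The
envelope measure remains available as `envelope_decay_ratio`.

All thresholds (prominence, scale, CV gate, occupancy fraction) are
configurable; the defaults above are the package's calibration on the
three reference regimes at (log₁₀ δ_H, log₁₀ H_c) = (−1, −1) traveling
front, (−5, −4) standing wave, (−6, −6) damped oscillations, which
classify 5/5 seeds each at defaults.

## Parameter sweep

The full-scale experiment is 51 × 51 parameter pairs × 5 replicates of a
400-site domain and 2·10⁴ iterations (13 005 runs, roughly 2.5 h on one
CPU); routine checks use an 11 × 11 × 2 grid (242 runs, ~3 min) over
log₁₀ δ_H, log₁₀ H_c ∈ [−6, −1] — axis limits reconstructed so that all
three reference regimes lie inside the diagram. Consensus per cell is
the modal replicate label with ties resolved toward the more-patterned
label. On the reduced grid the diagram is three 4-connected bands
(front at weak inhibition, a wide standing-wave band, damped
oscillations at the strongest inhibition) with the three reference cells
correctly labeled.

## 2D runs and symmetry breaking

The 2D reference run uses μ = 2, H_c = 5, δ_H = 0.005 on a hexagonal
patch. At 200 × 200 sites the 20 000-iteration colony stays interior; on
the reduced 100 × 100 patch used for checks the front would escape the
domain (inradius ≈ 43 sites), so reduced runs use 12 000 iterations.
At these parameters the model breaks the homogeneity of the initial
state into a ring-plus-star structure. However, the seeded amplitude
noise *decays* (max |noisy − control| field difference ≈ 10⁻³ after the
full run): the angular structure is driven by the hexagonally pixelated
seeding disc, identically in a noisy and a noise-free control run, so
the noisy/control boundary-variance ratio is ≈ 1, not ≥ 10. The
acceptance check of that ratio is implemented faithfully and fails
honestly; the measured ratio is reported by `scripts/acceptance.py` as
`symmetry_breaking_variance_ratio`. A reconstruction in which amplitude
noise is linearly amplified at the front would need a different (or
differently parameterized) growth instability than this equation set
provides at the printed parameter values.

## Image pipeline

Colony photographs (or synthetic stand-ins) are background-subtracted by
the median of an 8-pixel border frame, thresholded with Otsu's method
for centre estimation and edge contours, and resampled to polar
coordinates by bilinear interpolation (defaults 512 radii × 1024
angles). The colony radius is the largest radius whose angular mean
intensity exceeds the midpoint of the ring-mean range (Otsu is not used
here: on a two-valued histogram `skimage` returns the first maximizing
bin, just above background). The angular profile at 95% of that radius
is mean-normalised and Fourier transformed; only integer cycles per
revolution are physical, and the wavelength is reported as arc length
2πr/m. A dominant peak must carry ≥ 5% of the non-DC spectral power,
which rejects the broadband spectra of noisy featureless disks.

## Synthetic data

The generator replaces the study's undeposited photographs with images
whose ground truth is exact: interior/background intensities 200/30
(8-bit-like arbitrary units), boundary radius R(θ) = R₀ + A·cos(mθ) with
R₀ = 0.4 cm, A = 0.04 cm, 512² pixels at 25 µm/pixel, and additive
Gaussian noise (the robustness checks use SD = 17, i.e. 10% of the
interior/background contrast). A 12-lobe colony at this scale has a
boundary wavelength of ≈ 0.2 cm, matching the characteristic scale of
the real patterns. What the synthetic images deliberately do not
emulate: illumination gradients, out-of-focus blur, the irregular lobe
shapes and radial branching of real colonies, and camera noise
statistics — so passing tests demonstrate correctness of the geometry
and spectral bookkeeping of the pipeline, not robustness to real
microscopy artefacts. The 1D profile generator (sums of sinusoids plus
Gaussian noise) plays the same role for the spectral module.

## Numerical choices and degenerate inputs

- `homogeneous_steady_state` reduces the fixed-point system to one
  scalar equation in the total density s = 1 − Φ(α s/δ_H) (monotone, so
  the root in (0, 1] is unique), solved by Brent bracketing to 10⁻¹⁴;
  the returned state is verified to satisfy all three rate equations to
  10⁻⁸ or `None` is returned — never a silent wrong answer.
- Spectra of constant profiles are exactly zero after mean subtraction;
  `dominant_wavelength` then returns `None`.
- Lattices require ≥ 3 sites per dimension; the 2D inoculum requires a
  patch of at least 21 × 21 sites.
- A non-finite field value raises `IntegrationBlowupError` carrying the
  step index (checked every 200 steps and at the end).

## Known limitations

- The equation reconstruction is constrained only by prose; the Hill
  parameterization choice above is the single point where two standard
  conventions diverge, and it is decided empirically (see ledgered
  analysis of the alternative).
- The 2D noise-amplification property does not hold at the printed 2D
  parameters under this reconstruction (see above).
- Phase classification is defined for 1D trajectories; 2D runs are
  characterised by boundary-radius statistics only.
- Explicit Euler at dt = 0.01 is dissipative at the pattern wavelength
  scale but was not compared against an implicit or higher-order
  integrator beyond step-halving (final-field difference ≈ 3·10⁻⁴).
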