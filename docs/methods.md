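# Methods

## Electron transport model

The transport engine is a single-scattering Monte-Carlo in the continuous
slowing-down approximation (CSDA). Between elastic deflections an electron
travels an exponentially distributed free path `s = −λ ln u` and loses
energy deterministically at the Joy–Luo modified-Bethe rate, which stays
positive down to the 0.05 keV tracking cutoff (plain Bethe turns over near
the mean ionization potential, ~0.8 keV for Au, and would be unusable at
3–5 kV beam energies). No secondary electrons are generated: the transported
primaries stand in for the laterally resolved signal, so the bottom-exit
distribution of primaries is the beam-spread function the imaging model
uses. Electron histories end in exactly one of three fates — crossing z = 0
moving upward (backscattered), crossing the bottom face (transmitted), or
falling below the cutoff (absorbed; the residual energy is booked as
deposited, so per-trajectory energy accounting closes to < 1e-9 keV).

Two elastic models are available:

* **screened Rutherford** (`elastic_model="screened_rutherford"`), the
  textbook single-scattering choice: total cross-section
  `σ = 5.21e-21 (Z/E)² · 4π/(α(1+α)) · ((E+511)/(E+1024))²` cm² with
  screening `α = 3.4e-3 Z^0.67/E` (E in keV; the 511/1024 relativistic
  constants are one fixed convention), and inverse-CDF angular sampling
  `cos θ = 1 − 2αu/(1+α−u)`.
* **Browning's empirical Mott fit** (`elastic_model="browning"`, the
  default): total cross-section
  `σ = 3.0e-18 Z^1.7 / (E + 0.005 Z^1.7 √E + 0.0007 Z²/√E)` cm², angular
  sampling as a strongly forward screened-Rutherford lobe (screening
  `7e-3/E`) taken with probability `R/(1+R)`, `R = 300 E/Z`, and an
  isotropic large-angle component otherwise.

The default matters. Screened Rutherford badly over-scatters heavy elements
at a few keV: on this film stack it predicts ~2% transmission at 4 kV where
Mott-class models predict ~15–20%, and it makes the bulk-gold backscatter
coefficient rise with decreasing energy. The Browning model reproduces the
known flat bulk-Au backscatter yield (we measure η ≈ 0.47 at 5–20 kV,
against ~0.48–0.52 experimentally; bulk SiN gives ≈ 0.13) and transmission
percentages in the teens at 4 kV. Both models share the same free-path,
energy-loss and boundary machinery, so they are directly comparable.

Boundary handling: a sampled step that would cross a layer interface is
truncated at the boundary, the electron is advanced 1e-6 nm into the next
medium, and the free path is resampled there; no step mixes two materials.
Energy loss uses the stopping power of the medium at the step's starting
energy over the path actually travelled, floored at zero.

## Film stack and beam

The built-in stack is the film as built: a 50-nm SiN membrane
(3.12 g/cm³, Si₃N₄ weight fractions 0.6006/0.3994 — the membrane's
composition is assumed stoichiometric since only its density is specified)
sputter-coated with 15 nm Ni (8.9 g/cm³) and 10 nm Au (19.3 g/cm³), beam
incident on the SiN side. A 60-nm-membrane variant is one argument away
(`coated_film_stack(sin_thickness=60)`). We benchmark against the 50-nm
film: it reproduces the reference half-intensity width of the bottom-exit
profile (41.8 nm) to 0.2%, where the 60-nm variant gives ~46 nm.

The beam is Gaussian with FWHM equal to the nominal spot diameter (3 nm); a
top-hat disk profile is available. Electrons start at z = 0 travelling
straight down. Default run size is 100,000 electrons — enough to put the
binomial error of a ~15% transmitted fraction near 0.1 percentage points
while a full run stays in the tens of seconds on one core.

Randomness: one seed per run; electrons are traced in lock-stepped chunks of
20,000 whose generators are seed-sequence children of the run seed, so a
run is bit-reproducible for a given (seed, n_electrons). The fates
partition exactly (`n_t + n_b + n_a = n`) on every run.

Exit histograms use 2-nm bins: the radial histogram (counts per annulus)
feeds the PSF construction, and the 1-D marginal of exit x-positions is what
the half-intensity width (interpolated FWHM) is measured on.

## Charging model

The irradiated spot is an ideal parallel-plate capacitor: plate area
`A = 7.07 nm²` (3-nm-diameter spot), gap `d = 50 nm` (the membrane), SiN
relative permittivity ε = 7.5, giving `C = ε₀εA/d = 9.39e-21 F` and a
one-electron potential `q/C ≈ 17 V`. The elementary charge is deliberately
the 4-digit rounding 1.602e-19 C: the reference per-pixel dose of 5,963
electrons (31.3 pA × 40 s over 1280×1024 px) reproduces only with it.
Potentials are reported in volts throughout; the electron count needed for a
target potential is the exact ceiling `⌈VC/q⌉` (24 for 400 V). The
published analysis this mirrors quotes "approximately 30" electrons for the
same threshold; that reading is available as an explicit override in
`charging_report` and is never substituted silently. The field unit is
V/cm with the field-emission threshold at 1e7 V/cm (10 MV/cm); note the two
reference statements — 400 V across 50 nm (8e7 V/cm) and a 1e7 V/cm
threshold (50 V across 50 nm) — differ by 8×, and both numbers are carried
as given rather than reconciled.

## Phantoms and the forward imaging model

Phantoms are mass-thickness maps (nm of protein-equivalent material):
analytic signed-distance scenes rasterized with 4× supersampling and a
1.5-px C¹ smoothstep anti-aliasing ramp, on odd-sized canvases whose centre
pixel is the geometric origin — this keeps mirror symmetries exact to
floating precision and rotational symmetries good to ~1% under resampling.
Tier thicknesses (envelope 30 / core 60 / internal disks 100 nm for the rod
virion; arm 25 / centre 50 nm for the star; core 25 / caps 40 nm for the
dumbbell) are declared defaults, not measured values: relative densities of
the internal structures are not specified anywhere authoritative, so the
tiers are chosen to give distinct, ordered contrast levels.

The forward model attenuates the locally injected signal exponentially,
`exp(−μ·t)`, then blurs with the beam-spread PSF, then draws Poisson counts
at the per-pixel dose (default 5,963). The attenuate-first/blur-second
order is fixed: it encodes "the film spreads the signal before the specimen
gates it", and swapping the order visibly changes edge profiles. The
exponential law itself is a modelling choice — the simplest monotone map
from thickness to signal consistent with volume contrast; the tunnelling
transmission probability has no published functional form. The default
μ = 0.02/nm makes an 80-nm virion transmit ~20% of the local signal
(strong dark contrast without saturation).

What the synthetic micrographs do **not** emulate: detector geometry and
gain, scan distortion and drift, charging feedback on the trajectories,
specimen-dependent secondary yield, or structural noise of real membranes.
Passing resolution tests on these phantoms demonstrates the pipeline's
behaviour under the stated noise and blur model, not performance on real
detector data.

## Image pipeline

* Gaussian smoothing uses a truncated, renormalized kernel (default 9×9,
  σ = 1 px; the 11×11 variant is a parameter) with reflective borders, so
  flux is conserved to 1e-9.
* The deconvolution PSF is a compound of two centred Gaussians on a 241×241
  grid, `(1−w)G(σ_narrow) + wG(σ_wide)`; presets: (12, 60) px for the rod
  virion, (14, 60) for the star pentamer, (40, 100) for the dumbbell. The
  default wide-component weight is 1/3 of total mass — i.e. the wide
  Gaussian has half the amplitude of the narrow one, which is our reading
  of the garbled published weighting clause; the weight is a plain
  parameter so other readings are one flag away. Sigmas are interpreted in
  pixels (consistent with the 241-pixel kernel they come with).
* Richardson–Lucy uses multiplicative updates with symmetric (reflective)
  padding and a 1e-12 division guard. With symmetric padding and an even
  kernel the blur operator is doubly stochastic, so the iteration conserves
  flux to ~1e-15 relative and fixes constant images and delta kernels
  exactly — these are tested invariants, not accidents of the FFT.
* Edge resolution follows Reimer's criterion: normalize the profile to
  [0, 1] using the means of its outer thirds as plateau estimates (this
  choice changes sub-nm results and is therefore fixed and documented),
  locate the 0.25 and 0.75 crossings by linear interpolation on the
  transition, and scale by the pixel size. For an edge blurred by a
  Gaussian of width σ this equals 2·0.6745·σ = 1.349σ (the 25th–75th
  quantile distance of a normal), which the tests verify to 3%.

The end-to-end property mirroring the method's headline behaviour: on a
simulated rod-virion micrograph at the reference dose with the MC-derived
PSF (pixel size 1.5 nm/px, chosen so the narrow preset Gaussian matches the
film's beam-spread σ), 12 RL iterations strictly improve the Reimer edge
resolution of the processed image (~21 nm → ~15 nm under the default
conditions). The absolute numbers are larger than real-detector values
because the synthetic chain carries the full ~40-nm beam-spread blur with a
volume-contrast signal; the invariant under test is the strict improvement.

## Known limitations

* Transmission percentages run ~3 points below the Mott-interpolation
  reference values (16.7% vs 20% at 4.0 kV; 7.3% vs 10% at 3.6 kV), and
  backscatter (~18%) runs above it, leaving the absorbed fraction at
  3.6 kV near 75% against a reference bound of 80%. This is the cost of an
  empirical Mott fit relative to tabulated phase-shift cross-sections;
  the discrepancy is reported, not calibrated away.
* No secondary-electron cascade, X-ray generation, energy-loss straggling,
  or charge-field feedback on trajectories.
* The screened-Rutherford model is retained for its closed forms and
  oracle tests but should not be used for heavy layers below ~10 keV.
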