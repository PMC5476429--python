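# Methods

This note records the models, defaults and numerical choices behind
`fibsem_phys`, and what the synthetic benchmarks do and do not demonstrate
about real instruments.

## Electron–sample Monte Carlo (`scatter_mc`)

Single-scattering trajectory simulation in the standard low-voltage SEM
style. Per step:

1. **Free path.** s ~ Exponential(λ), λ⁻¹ = Σᵢ nᵢ σᵢ(E) over the elements
   of the local material. The default total elastic cross section is the
   Browning empirical form
   σ = 3.0·10⁻¹⁸ Z^1.7 / (E + 0.005 Z^1.7 √E + 0.0007 Z²/√E) cm² (E in
   keV), a closed-form fit to tabulated Mott data. The classic
   screened-Rutherford total
   σ = 5.21·10⁻²¹ (Z/E)² 4π/(α(1+α)) ((E+511)/(E+1024))²,
   α = 3.4·10⁻³ Z^0.67/E, is available (`elastic_model="rutherford"`).
   Rationale: pure screened Rutherford over-scatters high-Z targets below
   ~2 keV — it yields a 1.2 keV gold backscatter fraction of 0.64 where
   measurements and Mott-based models give ~0.40–0.46 — while the Browning
   form reproduces 0.46 for gold, 0.080 for epoxy and 0.114 for the
   Pt Tetrakis reference at 10⁵ trajectories. Both are download-free;
   a user-supplied tabulated model can be plugged in through the same
   per-element interface.
2. **Deflection.** cos θ = 1 − 2αR/(1+α−R) with the screened-Rutherford
   screening parameter of the selected scatterer; the scatterer is chosen
   with probability ∝ nᵢσᵢ. Azimuth uniform.
3. **Energy loss.** Continuous slowing with the Joy–Luo modified Bethe
   stopping power (weight-fraction mixing, Berger–Seltzer mean ionization
   potentials J = 11.5 Z eV for Z < 13, else 9.76 Z + 58.5 Z^−0.19 eV),
   applied over each flight segment at the segment's starting energy.
   The Joy–Luo form remains positive at all energies down to the 50 eV
   tracking cutoff.

**Geometry.** Axis-aligned regions (z layers and/or x half-spaces) tile
the half-space z ≥ 0; the beam enters at z = 0 travelling +z. A flight
crossing a region boundary is truncated at the boundary and the remainder
resampled in the new material — unbiased for exponential paths
(memorylessness). Electrons re-crossing z = 0 moving outward are recorded
(exit energy, polar angle, exit point, maximum depth); electrons below
0.05 keV or beyond 10,000 steps count as absorbed. Construction-time
tiling checks plus a runtime kernel check reject gapped geometries.

**Determinism.** One seeded generator per `simulate()` call; identical
(seed, configuration) gives bit-identical output. Replicates use
seed + index.

**Mass densities** are user-overridable with defaults gold 19.32, epoxy
(C21H25O5) 1.20, Pt Tetrakis 1.30, lecithin 1.05 g/cm³; the stained-lipid
density interpolates linearly to 1.40 at one osmium atom per lipid
(x_os = 1). Fractional stoichiometry makes partially stained membranes
(x_os = 0.3, 0.8) first-class materials; both presets appear in tests and
neither is privileged.

### Resolution proxies

*Step edge.* Scanning a point beam across a sharp unstained→stained lipid
boundary gives a profile that is a sharp core (backscatter with little
prior lateral scattering) on broad wings from the ~10 nm lateral diffusion
of the interaction volume. The scan therefore spans ±12 nm (0.25 nm steps)
so the wings reach their plateaus; the reported P50 is the 25%→75%
crossing distance read off a two-component cumulative-Gaussian fit
(core + wings, shared centre), which pools all scan positions and is far
less variance-prone than direct level crossings; isotonic-regression
crossings are the fallback. At 10⁵ trajectories/position the converged
model gives ≈0.9 nm (fit) / ≈1.1 nm (crossings) at 1.2 keV, and 49.6% of
the step occurs within a 1.0 nm window.

*Buried layer.* A stained half-space under an unstained cap of thickness
d; contrast against an all-unstained reference, normalized to d = 0, is
monotonized (isotonic) and the 50% depth interpolated. Defaults: sweeps
0–20 nm at 0.8 keV and 0–30 nm at 1.2 keV in 2 nm steps, 10⁵
trajectories/depth, giving P50 ≈ 4.8 nm and ≈ 11 nm respectively — the
depth-resolution cost of higher landing energy.

## Detection (`detection`)

The ray-traced acceptance region of a biased in-column detector is
approximated by the separable rule *angle ≤ 45° AND exit energy >
max(0, bias − 550 V)*. The 550 V offset makes +600 V block ≤ 50 eV
electrons (secondaries) while ≤ +400 V blocks nothing, matching the
observed sharp signal drop at 600 V; it is calibratable, and a CSV
energy×angle lookup (`TabulatedAcceptance`) can replace the separable rule
entirely. Secondary electrons carry no cascade physics: a parametric yield
(default 1.0 at zero bias, 0 above the cutoff) suffices for acquisition
emulation. Channel fusion is inverse-variance weighting.

Stain inversion builds a forward calibration (Monte Carlo contrast vs
epoxy for a grid of x_os at matching energy/mask) and inverts a measured
contrast by monotone interpolation, reporting both the osmium weight
fraction and the equivalent x_os. Recovery of x_os ∈ {0.2, 0.5, 1.0}
through the full forward-MC + inversion loop is part of the test suite.

## Image quality (`image_quality`)

- **Focus index**: mean squared difference of two Gaussian smoothings
  (defaults s₁ = 1 px, s₂ = 4 px, straddling the resolution limit);
  reflective padding avoids edge-driven bias on drifting fields of view.
  Offset-invariant, quadratic in intensity scale.
- **Auto-optimization**: least-squares parabola over a sweep (default ±2
  settings range, 5 points); the fit must open downward, and a vertex
  outside the configured bounds is clamped with a warning. The
  `SimulatedImager` (anisotropic blur growing quadratically with defocus
  and stigmation error around the true optimum) exercises the loop;
  three focus/stig iterations recover the optimum to 0.05.
- **Calibration**: offset = blanked-beam mean; gain = (full-beam mean −
  offset)/(I·t/e), the full beam supplied by a total-reflection target.
- **Shot noise**: RMS of (image − 3×3 mean-smoothed image), divided by
  √(8/9) so white Poisson input returns √mean exactly in expectation.
  Assumes pixel-to-pixel fluctuation is noise-dominated; fine sample
  texture biases it upward.
- **Level estimation** replaces the instrument's adjust-by-eye thresholds
  with explicit threshold inputs plus reported coverage fractions, so the
  "≈50% of membrane covered" criterion is checkable and deterministic.
- **Streak filter**: symmetric rectangular notches in FFT space with a
  raised-cosine taper two bins wide (anti-ringing); DC is always
  preserved, so the image mean is untouched.

## Acquisition emulation (`acquisition_sim`)

The phantom is a seeded Voronoi tessellation: voxels whose two nearest
generators are nearly equidistant (difference < membrane thickness,
default 8 nm) form stained-lipid shells (default x_os = 0.8) in an
epoxy-like interior. It emulates the space-filling cell geometry and
membrane topology of neuropil, not its organelles, vesicles or texture —
so passing tests demonstrate correct signal statistics and geometry
handling, not segmentability of real tissue.

Rendering uses the material of the voxel at the current block-face depth
(no sub-surface mixing by default; sub-slice depth response is available
through the buried-layer kernel but deliberately not convolved, keeping
stages separable and testable). Pixel counts are Poisson with expectation
dose × detected yield. Binning is block-mean (non-divisible trailing
rows/slices are dropped with a logged warning); `emulate_anisotropy`
re-expands z-binned data to the native grid, reproducing the
thick-section comparison. Dose reduction is binomial thinning — exact for
Poisson statistics, unlike additive noise. Throughput planning scales a
configurable anchor operating point (default: 54,000 µm³ at 10 nm voxels
and 4 nA in 14 days) by (V/V_a)·(δ_a³I_a)/(δ³I); the anchor is data, not
a constant, because time contours shift with staining quality.

## Run control (`run_control`)

Control bands are [Q25 − IQR, Q75 + IQR] over a trailing window (default
100 samples; linear-interpolation quantiles), a total span of 3× the
interquartile range; the multiplier and window are configurable. On
Gaussian telemetry this band spans ±2.02σ, so the monitor is quiet at the
few-percent excursion level rather than silent — the property suite
asserts < 7%. Excursions within 2 half-spans of centre alert; beyond,
pause (the alert/pause split is a configuration choice; no published
magnitude rule exists). The pause/resume machine pauses immediately,
requires an operator resume *and* a re-established closed-loop mill lock
before running, and never emits frames otherwise (model-checked over
random event sequences).

The milling plant is deliberately minimal: a Gaussian vertical emission
profile of width w grazing the block face at height y mills the occluded
fraction f(y) = ½ erfc(y/(√2 w)). The inner Faraday cup catches the
non-occluded beam through a finite slot — capture fraction erf(a/(√2 w)) —
which is exactly why inner-cup feedback cannot see emission-profile drift;
the annular cup collects scattered ions ∝ milled flux, independent of
profile shape; the specimen current nets impinging charge against a
√f-scaled secondary/sputter loss, giving the observed near-zero,
sign-ambiguous feedback signal. A 10 Hz discrete PID (default kp = 40,
ki = 20, anti-windup clamp; gains sized against the ~0.045 nA/nm
annular-cup slope so a 20% beam-current step settles well inside 50
cycles) regulates the chosen current by moving y. The simulations
reproduce the qualitative mode ranking — annular feedback rides out
emission drift that inner-cup feedback converts into a removal-rate error,
and specimen-mode operation near its zero-gain point diverges and is
flagged — not any specific instrument's loop dynamics.

## Known limitations

- Closed-form cross sections cap the fidelity of *relative* element trends
  below ~1 keV: the carbon-vs-osmium shift that collapses staining
  contrast toward 600 eV is reproduced in sign but at ~1.4–1.6× between
  1.2 and 0.6 keV rather than the ≥2× seen with full Mott tables. Plug in
  tabulated cross sections for quantitative contrast-vs-energy work.
- No secondary-electron cascade, no ion (Ga⁺) sputtering physics, no
  electron-optical ray tracing (the 45°/bias mask stands in for it), no
  charging or detector-electronics bandwidth effects.
- Monte Carlo benchmark sizes (10⁵ trajectories per condition; step-edge
  scans at 10⁵/position) were chosen so the full physics battery runs in
  minutes on one CPU; statistical tolerances in the tests reflect those
  sizes.
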