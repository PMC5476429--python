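# fibsem-phys

Simulation and quality-control toolkit for the computational machinery
inside a long-running FIB-SEM (focused ion beam scanning electron
microscope) used for large-volume 3D imaging of stained biological tissue.

Serial block-face FIB-SEM alternates ion-beam ablation of a few nanometres
of resin-embedded, heavy-metal-stained tissue with low-voltage SEM imaging
of the freshly exposed surface. Image contrast comes from backscattered
electrons: osmium-stained lipid membranes (high Z) return more of the
primary beam than the epoxy-like cytosol (low Z). Whether a months-long
acquisition succeeds depends on quantitative control of that signal chain —
electron scattering physics, detector acceptance, shot-noise budgets,
autofocus, throughput planning, and closed-loop milling. This package
implements each stage as an importable, testable model:

| module            | what it models |
|-------------------|----------------|
| `materials`       | stoichiometric compounds (fractional staining allowed), weight fractions, number densities, mean ionization potentials |
| `scatter_mc`      | single-scattering electron Monte Carlo in layered / laterally structured samples: yields, energy–angle and depth distributions, step-edge and buried-layer resolution |
| `detection`       | detector acceptance (45° angular cut + sample-bias energy cutoff), channel combination, stain-concentration inversion against a Pt reference |
| `image_quality`   | focus index and parabolic auto-optimization, grey↔electron calibration, SNR/contrast, shot-noise estimation, Fourier streak filtering |
| `acquisition_sim` | Voronoi neuropil phantoms, Poisson image formation, xy/z binning, binomial dose thinning, δ³·I throughput planning |
| `run_control`     | SPC control bands on telemetry, pause/resume state machine, Faraday-cup milling plant with 10 Hz PID feedback |

## The core models

**Monte Carlo.** Electrons take exponential free paths with mean
1/Σᵢ nᵢσᵢ(E); the default total elastic cross section is Browning's
closed-form fit to Mott data (accurate for high-Z targets below 2 keV),
with the classic screened-Rutherford form available via
`elastic_model="rutherford"`. Deflections sample the screened-Rutherford
angular law cos θ = 1 − 2αR/(1+α−R), α = 3.4·10⁻³ Z^0.67/E, and energy
loss follows the Joy–Luo modified Bethe expression
dE/ds = −78500 (ρ/E) Σᵢ cᵢ(Zᵢ/Aᵢ) ln(1.166(E + 0.85Jᵢ)/Jᵢ) keV/cm,
which stays finite at the 0.4–1.2 keV landing energies used on block faces.
A primary is backscattered when it re-crosses the surface, absorbed below
50 eV.

**Signal statistics.** A pixel receives N_p = I_p·t/e primaries; membrane
and cytosol return N_m and N_c detected electrons, giving
contrast = (N_m − N_c)/((N_m + N_c)/2) and shot-noise-limited
SNR = (N_m − N_c)/√((N_m + N_c)/2).

**Focus index.** FI = Σᵢ (I∗S₁ − I∗S₂)²ᵢ / n for Gaussian smoothings of
1 px and 4 px: the power in the highest spatial frequencies. Autofocus
(and stigmation/alignment) fit a parabola to FI vs setting and move to the
vertex.

**Throughput.** At fixed SNR the volume rate obeys dV/dt ∝ δ³·I(δ) — with
the current drop a finer spot demands, doubling resolution costs ~400× in
volume rate.

## Worked example

```python
from fibsem_phys import materials, scatter_mc, detection

gold = materials.get_material("gold")
bset = scatter_mc.simulate(
    scatter_mc.SampleGeometry.bulk(gold),
    scatter_mc.BeamConfig(landing_energy=1.2, n_trajectories=100_000, seed=1))
print(f"backscatter yield: {100 * bset.backscatter_yield:.1f}%")

mask = detection.AcceptanceMask(max_polar_angle=45.0, bias_voltage=600.0)
print(f"detected: {100 * detection.detection_efficiency(bset, mask):.1f}%")
```

prints

```
backscatter yield: 46.4%
detected: 52.0%
```

i.e. ~46% of a 1.2 keV beam re-emerges from bulk gold and about half of
that falls inside the 45° detector acceptance, while the +600 V sample
bias (energy cutoff 50 eV) excludes secondary electrons without touching
the backscatter signal. The `examples/` directory holds one short
narrative script per capability — backscatter yields, bias filtering,
autofocus/SNR, phantom-to-stack rendering, throughput planning, and
milling control — each printing the numbers it computes and what they
mean.

A thin CLI mirrors the library for quick shell runs, e.g.

```bash
fibsem-phys mc yield --material gold --energy 1.2 --n 100000 --seed 1
fibsem-phys detect efficiency --bias 600 --max-angle 45
fibsem-phys ctl mill-sim --feedback annular
```

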