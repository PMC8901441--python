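# smstoich

Single-molecule brightness stoichiometry and oligomerization kinetics
for fluorescence microscopy.

Apoptotic pore-forming proteins such as BAX and BAK assemble into
oligomers on the mitochondrial outer membrane, and the *size* of those
assemblies — dimers, ~10-mers, or foci of hundreds of molecules — is the
quantity that separates their mechanisms. `smstoich` implements the full
analysis chain used to measure it from fluorescence images:

1. **Spot detection and brightness extraction** — Difference-of-Gaussians
   candidate detection, isotropic 2-D Gaussian fitting inside a 3-px ROI
   with local background from a 3–4 px annulus, and quality filters
   (overlapping ROIs, upper-tail σ percentile, z-stack edge planes). The
   brightness of a particle is the fitted Gaussian volume
   `Ip = 2π·A·σ²`.
2. **n-mer decomposition** — the brightness distribution is fitted by
   maximum likelihood as a linear combination of Gaussians
   `Σⱼ wⱼ·N(j·μ₁, j·σ₁²)`, with the monomer unit (μ₁, σ₁) calibrated
   from single-step photobleaching traces; partial labeling with
   efficiency `p` is inverted through the binomial projection
   `wⱼ ∝ Σₙ vₙ·C(n,j)·pʲ(1−p)ⁿ⁻ʲ` (non-negative least squares over the
   visible classes) to recover true n-mer fractions `vₙ`.
3. **Ratiometric molecularity kinetics** — foci intensities in cells are
   converted to molecule numbers against an intracellular counting
   standard of known stoichiometry (Nup96, 32 copies per nuclear pore):
   `Mₚ = Iₚ·Mₛ/Iₛ`. Per-timepoint distributions on a MOMP-aligned clock
   yield average molecularity (exponential fit of survival counts), foci
   per mitochondrial area, and fractions above molecularity thresholds.
4. **GUV assays** — radial intensity profiles with Gaussian rim-peak
   fitting, and permeabilization scoring from inside/outside probe
   ratios.
5. **Synthetic data** — every input (particle fields with Gaussian PSF,
   Poisson/read noise and binomial labeling; bleaching traces; standard
   cells; foci time series in BAK-like saturating or BAX-like linear
   growth regimes) can be generated with full ground truth, so each
   stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from smstoich import (SimConfig, generate_particle_field, analyze_image,
                      generate_bleach_traces, calibrate_monomer,
                      fit_gaussian_mixture, apply_labeling_correction)

# a 512x512 TIRF-like field: 30% monomers, 70% dimers, 80% labeled
cfg = SimConfig(n_particles=800, field_size_px=(512, 512),
                nmer_weights={1: 0.3, 2: 0.7}, labeling_efficiency=0.8,
                monomer_intensity=500.0, min_separation_px=7.0, seed=7)
stack, truth = generate_particle_field(cfg)
fits, report = analyze_image(stack.data[0])

traces = generate_bleach_traces(1, 300, 0.01, 600, 40.0, seed=8,
                                monomer_intensity=500.0, monomer_cv=0.15)
calib = calibrate_monomer(traces=traces.traces)
result = fit_gaussian_mixture(np.array([f.brightness for f in fits]),
                              calib, max_n=6)
apply_labeling_correction(result, 0.8)
print(report)
print("mu1 = %.1f" % calib.mu1)
print("observed w:", np.round(result.weights_observed, 3))
print("corrected v:", np.round(result.weights_corrected, 3))
```

prints

```
{'overlap': 18, 'sigma_outlier': 37, 'edge_frame': 0, 'fit_fail': 4,
 'n_input': 733, 'n_retained': 676}
mu1 = 494.9
observed w: [0.441 0.502 0.057 0.    0.    0.   ]
corrected v: [0.233 0.665 0.103 0.    0.    0.   ]
```

The observed weights count *labeled* units per particle — partial
labeling pushes dimers into the 1-mer class (a dimer shows one
fluorophore with probability 2·0.8·0.2) — while the corrected weights
recover the true composition (~30/70 monomer/dimer, within the residual
error introduced by spot crowding).

The same stages are available as CLI subcommands
(`smstoich simulate | detect | stoich | kinetics | guv | run`); see
`smstoich <cmd> --help`.

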