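# Methods

## Scope and model

`smstoich` measures the oligomeric state of fluorophore-tagged membrane
proteins from fluorescence images in two complementary regimes:

* **In vitro, single molecules (TIRF).** Diffraction-limited spots on a
  supported lipid bilayer are detected and fitted; the brightness
  distribution is decomposed into n-mer species against a
  photobleaching-calibrated monomer unit, and corrected for partial
  labeling.
* **In cells, large foci (confocal z-stacks).** Foci brightness is
  converted into molecule numbers ratiometrically against the Nup96
  nuclear-pore standard (32 mEGFP copies per complex), and per-timepoint
  molecularity distributions after MOMP (Smac release, t = 0) are
  summarized into growth kinetics.

Both regimes share one detection/fitting implementation.

## Spot detection and brightness

Candidates are local maxima of a Difference-of-Gaussians band-pass
(σ = 1.0/1.6 px by default, matched to a ~1.3 px PSF), deduplicated
within one PSF width. The detection threshold defaults to 3.5 robust
standard deviations (MAD-based) of the per-image DoG response; the MAD
is estimated on the full image, so dense fields raise the threshold
conservatively. The threshold is exposed because no universal value
exists: 3.5 rσ keeps the blank-field false-positive rate near 10⁻⁴/px
while retaining ≥ 98% of SNR-5 spots in synthetic fields.

Each candidate is fitted with an isotropic 2-D Gaussian over the disc of
radius 3 px; the local background `b` is the mean of the 3–4 px annulus.
Because the spot's own tail leaks into the annulus, the fit alternates
with re-estimating `b` after subtracting the fitted tail, until `b`
stabilizes (≤ 8 passes); without this refinement amplitudes are biased
low by ~2% at σ = 1.3 px. Brightness is the Gaussian volume
`Ip = 2π·A·σ²`, pinned to a background-subtracted pixel-sum oracle in
the tests. σ is the Gaussian standard deviation (FWHM = 2.355 σ).

Quality filters (each computed independently on the full fit set, so
the retained set is order-independent):

* **overlap** — both members of any pair closer than 7 px (ROI radius +
  background radius, so retained annuli never overlap a neighbor ROI)
  are dropped; survivor selection would bias brightness upward.
* **sigma_outlier** — fits above the per-image 95th σ percentile are
  dropped (wide fits indicate multiple particles in one ROI). One-sided
  by design: narrow fits are not suspicious. Skipped below 20 fits,
  where a 95th percentile is unstable.
* **edge_frame** — on z-stacks, particles brightest in the first or
  last plane are dropped (part of their axial profile was not
  acquired). Max-projection ties resolve to the lowest plane index.

## Monomer calibration and n-mer decomposition

Bleaching traces are median-filtered (window 5 frames by default) and
segmented into plateaus by penalized binary segmentation (penalty
`10·σ̂²·ln n`, with σ̂ from the MAD of first differences; the prefactor
was fixed once on simulated traces). Plateau levels are re-estimated
from the raw trace with a half-window guard band around each change
point — the median filter mixes plateaus near steps and otherwise
biases step heights low by a few percent. Traces that re-brighten are
rejected. Only clean single-step traces enter the monomer calibration
(μ₁ = mean step height, σ₁ = SD); fewer than 50 such traces is an
error.

The brightness sample is then fitted by maximum likelihood as
`Σⱼ wⱼ·N(j·μ₁, j·σ₁²)` with only the simplex-constrained weights free.
Component variances scale linearly with order because an n-mer's
brightness is a sum of n i.i.d. emitter brightnesses. Fitting uses EM
on raw values (no histogram binning); with fixed components each
update is closed-form and the likelihood ascent is monotone. A
degenerate calibration (σ₁ = 0) is floored at 0.05·μ₁.

**Labeling correction.** With labeling efficiency p, a true n-mer shows
j labels with probability `C(n,j)pʲ(1−p)ⁿ⁻ʲ`; the j = 0 class is
invisible. Observed weights are the binomial projection of the true
composition restricted to j ≥ 1 and renormalized — linear in v up to a
scalar — so v is recovered by non-negative least squares against the
projection matrix and renormalized. The default returns the composition
over *all* true n-mers (invisible class included); an alternative mode
(`correct_invisible=False`) conditions each order on visibility and
returns the composition among detectable n-mers. Efficiencies at or
below 0.75 trigger a warning: the inversion conditions poorly there.

## Ratiometric molecularity and kinetics

Per standard cell, a Gaussian is fitted (maximum likelihood; optional
symmetric trimming for outlier clusters, off by default) to the complex
intensity distribution and its mean taken as i_s; I_s averages i_s over
at least 5 cells — fewer is an error, matching standard practice for
this calibration. Molecularity is the exact linear map
`Mₚ = Iₚ·Mₛ/Iₛ`.

Average molecularity per timepoint comes from a least-squares fit of
`A·exp(−M/⟨M⟩)` to the empirical survival count `C(M) = #{foci ≥ M}`
(the complementary cumulative, for which an exponential sample's decay
constant *is* the mean). Below 10 foci, for degenerate samples, or on
fit failure the sample mean is reported with a fallback flag. Threshold
fractions use strict inequality (M > 200, M > 400). Foci density is
count divided by mitochondrial area. Pre-MOMP frames are flagged and
excluded when aligning to the MOMP clock.

Expression level is total GFP intensity divided by the mitochondrial
mask area, the mask being the marker channel above Otsu's threshold
(threshold exposed).

## GUV quantification

Vesicle centers/radii are inputs. Radial profiles are azimuthal means
over equal-width annuli; background is the mean beyond 1.2× the vesicle
radius (outer 20% of the profiled disc when the radius is unknown), and
profiles are normalized to their peak. Rim binding is a Gaussian fit to
the interior maximum; profiles without one are flagged unbound.
Permeabilization scores a vesicle as filled when its inside/outside
probe ratio is ≥ 0.5 — a configurable midpoint between full exclusion
(0) and equilibration (1); vesicles with ~0 outside signal are
excluded.

## Synthetic data: what it emulates, and what it does not

The generators define the verification conditions for every stage:

* **Particle fields** — 100 nm pixels, isotropic Gaussian PSF
  (σ = 1.3 px) sampled at pixel centers with analytic volume equal to
  the drawn brightness (noiseless photon conservation is then exact to
  float tolerance), uniform background, Poisson shot noise, additive
  Gaussian read noise. Labeling is Binomial(n, p); j = 0 particles are
  kept in the truth table and flagged invisible. Monomer brightnesses
  are i.i.d. Normal(μ₁, (cv·μ₁)²), clipped at 0; cv is exposed (default
  0.15) because the emitter-intensity variance of single fluorophores
  is setup-dependent. No Airy/pixel-integrated PSF, no EM-gain noise,
  no drift, no blinking: the analysis fits the same Gaussian model, so
  matched forward/inverse models make oracle tests exact — recovery on
  real cameras will be somewhat worse than these tests show.
* **Bleaching traces** — per-fluorophore geometric bleaching times
  (memoryless photobleaching), fixed per-fluorophore brightness while
  alive, Gaussian noise. No blinking (irrelevant at ~35 ms exposures).
* **Standard cells** — complex intensities Normal(Ms·u, (cv·Ms·u)²)
  truncated at 0; no spatial rendering (standard calibration consumes
  intensity lists).
* **Foci time series** — mean molecularity follows
  `M(t) = plateau·(1 − e^(−t/τ))` with τ = plateau/rate (BAK-like:
  fast, saturating near ~200 molecules) or `M(t) = rate·t` (BAX-like:
  unbounded growth). These functional forms are the simplest choices
  reproducing a stable size versus continued growth; the underlying
  biology is only constrained graphically. Foci are born by a Poisson
  process (constant rate in the saturating regime, linearly
  accelerating in the linear one) and carry a persistent unit-mean
  multiplicative Gamma factor, default cv = 1 — i.e. exponential
  per-timepoint molecularity distributions, the broad right-skewed
  shape cellular foci show and the shape the survival-count fit
  presumes. With tighter dispersions (cv ≲ 0.5) the exponential-fit
  estimator underestimates the mean by design of the method, not by a
  defect of the implementation.

## Problem sizes and numerical choices

Default verification sizes: 10⁴ particles for binomial/σ-filter
statistics, 200 traces × 1200 frames for step-count recovery (long
traces keep plateau durations well above the 2-frame resolution limit
of the segmenter), 4000 brightness values for mixture recovery, 400
spots at 0.01 /px² for detection precision/recall, ~500 foci per cell
by t = 60 min for kinetics (matching typical per-cell foci counts).
Deterministic seeding throughout: every generator takes an explicit
seed, and repeated runs are bit-identical.

Known limitations: no drift correction or multi-channel registration;
no Bayesian selection of the maximum mixture order (max_n is a
parameter, default 10); no correction for fluorophore maturation or
blinking beyond the single labeling-efficiency parameter; no per-focus
tracking across timepoints (the analysis is distributional, as in the
underlying method); vesicle segmentation is out of scope (centers and
radii are inputs).
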