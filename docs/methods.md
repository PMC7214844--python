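# Methods

## Problem and measurement model

`veinpulse` analyses cardiac-gated 2D phase-contrast MRI (pcMRI) of a slice
through the cerebral cortex, asking whether the blood-flow waveform of each
small cortical vein is pulsatile, how strongly (pulsatility index), and how
delayed it is relative to the superior sagittal sinus.  In pcMRI the
through-slice velocity *v* is encoded in the signal phase of the complex
difference between flow-compensated and flow-encoded readouts:
φ = π·v/venc, with venc = 10 cm/s chosen for sensitivity to slow venous
flow (0.3–2 cm/s).  Speeds beyond venc alias: the fast sagittal sinus and
arteries wrap, veins do not.  One cardiac phase spans two TRs
(2 × 11.55 ms = 23.1 ms); a gated acquisition yields 33–45 cardiac phases
per heartbeat.

## Pipeline

1. **Segmentation.** The cycle-averaged magnitude image is thresholded at
   mean + 2·SD (statistics over the whole image, or over an optional ROI
   mask — the two differ when large non-brain background is present, so the
   choice is an explicit parameter rather than a hidden convention).  The
   inequality is strict, making the degenerate uniform image yield an empty
   mask.  Super-threshold voxels are grouped under 8-connectivity (edge or
   corner adjacency); cluster ids are assigned in raster-scan order of each
   component's first voxel so that outputs are deterministic.  Class
   (artery / small vein / surface vein / sinus) and vascular territory
   annotations come from a reference label image; a cluster overlapping
   reference vessels of two different classes is discarded rather than
   guessed, as is a cluster overlapping nothing.

2. **Velocimetry.** Per cardiac phase, a 17 × 17-voxel (≈10 mm) median
   filter estimates the smooth background phase offset, which is
   subtracted; edges are handled by reflection to avoid zero-padding bias.
   The filter is applied to each cardiac phase independently (rather than
   to the time average) because offsets may drift over the cycle.  Phase is
   then unwrapped voxelwise along the cardiac-phase axis (jumps > π), in
   this fixed order: filter first, then unwrap.  Cluster velocity is the
   spatial mean over cluster voxels scaled by venc/π.  The sagittal sinus
   pathway takes the 20 brightest sinus voxels (ties broken in raster
   order), applies the same filtering and temporal unwrapping, then forces
   all voxels onto one wrap branch by subtracting 2π wherever the phase is
   positive — correct for superior-to-inferior (negatively encoded) flow,
   and sign-configurable for other geometries.  The voxelwise median gives
   a timing reference that is robust to residual wrap errors but not an
   absolute speed.

3. **Pulsatility.** Each waveform is low-pass filtered with a
   Savitzky-Golay filter (order 3, frame 15).  The pulsatility
   contrast-to-noise ratio is

       PCNR = Δv / sqrt( Σ res_t² / (N−1) ),

   with Δv the peak-to-trough range of the filtered curve and res the
   unfiltered-minus-filtered residual.  PCNR is exactly invariant to
   scaling and offset, so its null distribution under Gaussian noise is
   free of the noise level; the detection threshold is the empirical
   (1−α) quantile over 10⁵ Monte Carlo noise waveforms (α = 0.01 default;
   threshold ≈ 3.9 at N = 38, varying < 2% over N = 33–45).  A zero
   residual with nonzero range is treated as unambiguous signal (infinite
   PCNR, flagged pulsatile); degeneracy is detected relative to the
   waveform's own scale (tolerance 10⁻⁹·max|v|) so rounding crumbs on a
   constant waveform do not masquerade as signal.  The pulsatility index
   is PI = Δv / mean(|v|): filtered range in the numerator (Δv is defined
   on the filtered curve), unfiltered waveform in the denominator (the
   time-averaged speed).  PI is not assessed for arteries, whose aliased
   phase makes mean speed unreliable at venc = 10 cm/s.  Temporal lag is
   the argmax of the circular cross-correlation of the mean-subtracted
   unfiltered waveforms, mapped to [−N/2, N/2) samples and multiplied by
   the 23.1 ms phase duration; ties go to the smallest |lag|, then to the
   positive one.  Lags are quantized to one cardiac phase by default
   (matching the temporal resolution); parabolic peak interpolation is an
   optional flag.

4. **Cohort statistics.** Vessel-level distributions are skewed, so each
   subject is summarised by medians across vessels (pulsatile vessels
   only, for PI and lag).  Inference on subject summaries: two-tailed
   one-sample t-tests of lag against zero for {small veins, surface veins,
   all veins, arteries}, Bonferroni-corrected ×4 and capped at 1; a paired
   t-test of PI between small and surface veins; one-way ANOVAs of lag
   (veins; arteries) and vein PI across the four vascular territories; and
   a paired t-test of time-averaged speed between pulsatile and
   non-pulsatile veins, on subject means.  A subject with no pulsatile
   vessel in a territory contributes no value to that territory's group
   (the missing cell is dropped; the subject's other cells are kept — this
   reproduces residual degrees of freedom of the n·k−missing−k form).

## Savitzky-Golay edge handling

The filter's behaviour at the first and last 7 samples is the one genuinely
consequential numerical choice.  The default is the standard
polynomial-fit convention (a single order-3 fit to the first/last 15
samples supplies the edge outputs, as in MATLAB's `sgolayfilt` and scipy's
`mode="interp"`); under it the Monte Carlo null 99th percentile at N = 38
is 3.89.  Treating the waveform as periodic instead (circular convolution
with the Savitzky-Golay kernel, available as `sg_mode="wrap"`) suppresses
the edge-fit variance and drives the null quantile down to ≈ 2.5 — a
materially different statistic.  Because the 3.9 threshold is the
published operating point of the method, the polynomial-fit convention is
the default and the circular variant is provided only for sensitivity
analysis.

## Synthetic scene generator

The generator emulates the acquisition in the image domain, with full
ground truth for recovery tests:

- **Geometry.** 8-connected vessel footprints of 1–30 voxels on a grid of
  ≥ 34 voxels per side (the median-filter window must fit); small veins
  1–8 voxels, surface veins 2–27, arteries 1–16, sinus 30 — matching the
  observed size ranges.  Vessels are placed with a one-voxel halo so
  distinct vessels segment into distinct clusters.
- **Waveforms.** A deterministic band-limited pulse template (first 1–3
  cardiac harmonics, 1/h amplitude decay, zero mean, unit peak-to-trough
  range) delayed per vessel by a configurable lag (fractional delays by
  circular linear interpolation).  Default conditions: vein speeds
  uniform 0.3–2 cm/s with pulse amplitude 0.30 × speed (true PI 0.30),
  vein lags Normal(60, 20) ms; artery speeds 12–20 cm/s (forcing phase
  wrap) with lags Normal(0, 20) ms; sinus −12 cm/s (wrapping,
  superior-to-inferior) as the timing reference.
- **Phase.** φ = wrap(background + π·v/venc + ε), wrapped into (−π, π].
  The background is a low-order (≤ 3) 2D polynomial on normalised
  coordinates, smooth at the 17 × 17 scale so the median filter can remove
  it.  Noise is additive Gaussian on phase, SD 0.04 rad by default — the
  level at which the synthetic cohort sits in the same detection regime as
  a high-field acquisition of this type (roughly three quarters of veins
  crossing the PCNR threshold).
- **Magnitude.** A flat background (100 a.u.) plus a vessel elevation
  that grows with volume_fraction·|v| and saturates (tanh, scale
  0.15 cm/s, gain 100 a.u.) — mimicking complex-difference magnitude
  contrast, which saturates once the encoded phase shift is appreciable.
  Saturation is what lets slow veins and fast arteries coexist above the
  mean + 2·SD threshold; a strictly proportional model would let the
  arteries inflate the image SD until slow veins fall below it.  Gaussian
  magnitude noise (SD 5 a.u.) is added and the result clipped at zero.
- **Partial volume** is a single scalar weight per voxel attenuating both
  velocity and magnitude contrast — only its attenuating effect matters
  downstream, so no sub-voxel geometry is modelled.
- **Prospective-gating smoothing** (heart-rate variability blurring
  late-cycle samples) is available as circular convolution of the template
  with a short uniform kernel; off by default.

Not modelled: k-space sampling, coil sensitivities, Rician magnitude
statistics, eddy currents beyond the polynomial background, motion, and
inflow contrast.  Passing recovery tests on these scenes therefore
demonstrates correctness of the pipeline's numerics and logic, not
robustness to every artefact of acquired data.

## Problem sizes and determinism

Scenes default to 96 × 96 voxels with ~24 vessels and 33–45 cardiac
phases; the synthetic cohort uses 8 subjects, matching the study design.
Monte Carlo calibration uses 10⁵ draws (quantile SE ≈ 0.02 at the 99th
percentile); lag-recovery checks use 200 seeded scenes at the minimum
34-voxel grid.  Every stochastic step takes an explicit seed
(`numpy.random.default_rng`), and identical configurations produce
bit-identical outputs, including across the CLI.

## Known limitations

- Absolute flow (mL/s) and vessel cross-sectional area are out of scope;
  velocities are voxel-averaged and partial volume attenuates them.
- The sinus reference is valid for timing only; its absolute level is
  deliberately left on an arbitrary wrap branch.
- Lag estimates inherit noise in the sinus waveform itself, which can bias
  a whole subject; the generator's sinus is comparatively clean, so tests
  do not probe this failure mode.
- Arterial velocities are aliased at venc = 10 cm/s; only their timing and
  PCNR are meaningful here.
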