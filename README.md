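# veinpulse

Flow pulsatility in small cerebral cortical veins from cardiac-gated 2D
phase-contrast MRI (pcMRI).

Cardiac pulsatility reaching the venous side of the cerebral
microcirculation carries information about intracranial compliance and the
damping of the arterial pressure pulse.  `veinpulse` implements a complete,
tested analysis pipeline for gated pcMRI slices through the cortex: it
segments small through-plane vessels from the cycle-averaged magnitude
image, converts their signal phase to velocity waveforms, decides per
vessel whether the waveform is pulsatile, quantifies pulsatility and timing
relative to the superior sagittal sinus, and aggregates vessel-level
results to cohort statistics.  A fully ground-truthed synthetic scene
generator ships with the package so that every stage can be validated
against known truth.

## The statistic at the core

In pcMRI the through-slice velocity *v* is encoded as signal phase
φ = π·v/venc (venc = 10 cm/s here, tuned to slow venous flow; faster
vessels alias).  A vessel's velocity waveform v(t) over N cardiac phases is
low-pass filtered with a Savitzky-Golay filter (order 3, frame 15) and the
**pulsatility contrast-to-noise ratio** is

    PCNR = Δv / sqrt( Σₜ resₜ² / (N−1) )

where Δv is the peak-to-trough range of the filtered curve and
res = v − v_filtered.  PCNR behaves like a t-statistic — invariant to
waveform scale and offset — so a single Monte Carlo calibration of its null
distribution (Gaussian noise waveforms) yields a detection threshold valid
across noise levels and, to within a couple of percent, across N = 33–45:
**PCNR > 3.9 ⇔ p < 0.01** at N = 38.  For pulsatile vessels the pipeline
reports the pulsatility index **PI = Δv / mean(|v|)** and the **temporal
lag** versus the sagittal-sinus reference waveform (peak of the circular
cross-correlation, in units of the 23.1 ms cardiac phase).

See `docs/methods.md` for the full model, parameter defaults and numerical
conventions.

## Worked example

Simulate a demonstration scene (14 vessels: small veins, surface veins,
wrapping arteries and a wrapping sagittal sinus) and run the full pipeline:

```bash
veinpulse simulate --seed 7 --out scene
veinpulse all --scene scene/scene.yaml --mc-reps 100000 --out run
```

which prints

```
PCNR threshold (alpha=0.01): 3.91
veins pulsatile: 8/10
outputs in run
```

The Monte Carlo calibration put the 99th-percentile PCNR of pure noise at
3.91, and 8 of the 10 veins in the scene crossed it.  The per-vessel table
(`run/results.tsv`) reads:

```
 cluster_id  class_label  pcnr   pi  lag_ms  pulsatile  mean_abs_speed
          1   small_vein  3.69 0.26    92.4      False            0.46
          2       artery 25.10  NaN   -23.1       True            1.15
          3 surface_vein 14.45 0.28    46.2       True            1.79
          4   small_vein  9.27 0.35    46.2       True            1.16
          ...
```

Pulsatile veins show PI around 0.3 and lag the sinus by one to three
cardiac phases (23–69 ms), while arteries are synchronous with it
(lag ≈ 0) — the injected ground truth of the generator, recovered by the
pipeline.  PI is NaN for arteries: their speed aliases at venc = 10 cm/s,
so only their timing and PCNR are meaningful.  Vein 1 illustrates the
detection boundary: a slow vein (0.46 cm/s) whose PCNR of 3.69 falls just
short of the threshold.

The same stages are available as library functions
(`veinpulse.render_scene`, `threshold_mask`, `label_clusters`,
`remove_background_phase`, `cluster_waveform`, `sinus_waveform`, `pcnr`,
`calibrate_null`, `temporal_lag`, `summarize_subject`, `group_tests`, …)
and as separate CLI subcommands (`segment`, `waveforms`, `pulsatility`,
`cohort`, `calibrate`).  Acquired data enter through magnitude/phase NIfTI
stacks plus a vessel label image and class table
(`--magnitude/--phase/--labels/--labels-table`).

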