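# puncta

Quantitative image analysis for single-molecule RNA imaging with
multi-probe fluorescent tags (smFISH-style oligo pools or ratiometric
bimolecular beacons, RBMBs). When dozens of probes hybridize to one
transcript, each RNA appears as a diffraction-limited punctum in a
fluorescence z-stack; counting transcripts, comparing two probe channels,
and correcting cell-level fluorescence then become well-defined image
analysis problems. `puncta` implements that stack for microscopists and
probe developers:

- **Spot detection** — per-slice rolling-ball background subtraction and a
  spot-enhancing Laplacian-of-Gaussian filter, then "Find Maxima"-style 2D
  local maxima in every slice (noise tolerance 0, edge maxima excluded),
  gated by a hand-drawn-style polygon cell ROI and a minimum intensity
  threshold, and finally promoted to 3D maxima via a 3×3×3-cube dominance
  test (the 8 in-slice neighbors plus 9 voxels each in the slices above and
  below). Each 3D local maximum is counted as one RNA transcript.
- **Two-channel colocalization** — spots from two channels are matched when
  one lies inside a cylinder centered on the other (default ±4 slices
  axially, 5 pixels laterally, boundary inclusive). Two directional
  percentages are reported: the fraction of channel-A transcripts with a
  channel-B partner, and vice versa, per cell and averaged across cells.
- **Per-cell fluorescence quantification** — integrated density inside each
  cell ROI; reporter-channel autofluorescence predicted from the TMR
  channel via a linear model fitted on probe-negative cells; unopened-probe
  background as R_CLOSED × reference-channel density (R_CLOSED measured on
  emulsion droplets of target-free probe); and the enhancement signal

  `enhancement = (ID_rep − af_rep) − R_CLOSED × ID_ref`

  which is regressed against the transcript count per cell (slope,
  intercept, Pearson r).
- **Probe biophysics** — melting profiles corrected for the intrinsic
  temperature dependence of dye fluorescence, with Tm from either the
  |dF/dT| peak or a two-state sigmoid-with-baselines fit, and
  pseudo-first-order hybridization kinetics
  `F(t) = F_inf − (F_inf − F0)·exp(−k_obs·t)` with `k_on = k_obs/[target]`.
- **Synthetic microscopy** — a ground-truth scene designer and virtual
  microscope (anisotropic Gaussian PSF, autofluorescent background,
  Poisson + Gaussian noise) that renders 56-slice two-channel stacks with an
  *exactly* designed colocalized fraction, cell-field images with designed
  enhancement, and melt/kinetics curves, so every stage is testable without
  real data.

## Worked example

```python
from puncta import (rectangle_roi, make_scene, render_stack, RenderParams,
                    detect_transcripts, DetectionParams, colocalize,
                    simulate_melt_curve, melting_temperature,
                    simulate_kinetics, fit_on_rate)

roi = rectangle_roi(8, 8, 140, 140)
scene = make_scene(40, 40, 0.5, roi, stack_shape=(56, 150, 150), seed=11,
                   min_separation=5.2, separation_z_scale=0.65)
params = RenderParams(seed=12)
spots_a = detect_transcripts(render_stack(scene, params, "a"), roi, DetectionParams())
spots_b = detect_transcripts(render_stack(scene, params, "b"), roi, DetectionParams())
res = colocalize(spots_a, spots_b)
print(f"detected {len(spots_a)} / {len(spots_b)} transcripts (A / B)")
print(f"colocalized: pct_a = {res.pct_a:.1f}%, pct_b = {res.pct_b:.1f}%  ({res.n_pairs} pairs)")

curve = simulate_melt_curve(tm=61.3, transition_width=2.5, f_folded=100.0,
                            f_unfolded=1000.0, noise_sd=9.0, seed=13)
tm = melting_temperature(curve)
print(f"Tm (two-state fit) = {tm.tm:.2f} degC, derivative method = {tm.tm_derivative:.2f} degC")

trace = simulate_kinetics(k_obs=0.01, f0=100.0, f_inf=1000.0, noise_sd=18.0, seed=14)
fit = fit_on_rate(trace)
print(f"k_obs = {fit.k_obs:.5f} /s, k_on = {fit.k_on:.3g} /(M*s)")
```

prints

```
detected 40 / 40 transcripts (A / B)
colocalized: pct_a = 50.0%, pct_b = 50.0%  (20 pairs)
Tm (two-state fit) = 61.39 degC, derivative method = 62.03 degC
k_obs = 0.01007 /s, k_on = 2.01e+04 /(M*s)
```

All 40 transcripts per channel are recovered from the rendered stacks; the
designed 50% colocalized fraction is measured back exactly; Tm is
recovered within 0.1 °C of the simulated 61.3 °C at 1% amplitude noise;
and the fitted observed rate matches the simulated 0.01 s⁻¹ within 1%,
giving the expected on-rate of ~2×10⁴ M⁻¹ s⁻¹ at 500 nM target.

A `puncta` console command exposes the same pipeline for files on disk:
`puncta detect --stack stack.tif --roi cells.json --out spots.csv`,
`puncta coloc`, `puncta quantify`, `puncta melt`, `puncta kinetics`
(see `puncta --help`; parameters come from a YAML config, documented in
`puncta/cli.py`).

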