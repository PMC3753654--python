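# Methods

This note documents the models implemented in `puncta`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the underlying analysis
convention was genuinely open.

## Spot detection

Raw z-stacks are prepared by per-slice **rolling-ball background
subtraction** (the classical morphological algorithm: the smooth
background under each slice is what a ball of radius *r* can reach from
below; default *r* = 5 px, which comfortably exceeds the puncta radius at
Nyquist-sampled high-NA imaging) followed by a **negated
Laplacian-of-Gaussian filter** that turns bright blobs of scale ≈ σ into
positive peaks (default σ = 1.5 px, matched to a diffraction-limited
punctum). The LoG is applied per slice in 2D by default; a true 3D mode
scales the axial sigma by `pixel_size_xy / z_step` so the physical scale
is isotropic. The absolute normalization of the response is arbitrary
(only the relative heights of maxima matter downstream); responses are
clamped at zero so intensity thresholds live on a non-negative scale.
Both filters use kernels long enough (truncate = 8σ for the LoG) that a
flat region maps to numerically zero response.

**2D maxima.** A pixel is an in-slice local maximum iff it is strictly
greater than every in-bounds 8-neighbor. This plateau rule — flat plateaus
of any size yield no maxima — was chosen because it is deterministic and
directly checkable against an exhaustive scan; the common interactive
implementations do not document their plateau handling. Border pixels are
excluded by default (`exclude_edge_maxima`). A `noise_tolerance`
parameter suppresses maxima whose prominence (height above the highest
saddle connecting them to a higher maximum, found by flood fill) is below
the tolerance; at the default setting of 0 this is exactly a no-op, so
the strict rule alone defines the behavior regardless of prominence
implementation details.

**Threshold.** Maxima are gated by a cell ROI (polygon boundary counts as
inside — hand-drawn outlines are generous, and consistency matters more
than the convention) and by a minimum intensity. The threshold is
user-specified by design; when none is given, an exact Otsu split of the
maxima intensities (between-class variance evaluated at every split of
the sorted values, no histogram binning) provides a runnable default.

**3D promotion.** A surviving 2D maximum becomes a 3D maximum — one
transcript — iff its voxel intensity is ≥ all of the up-to-26 neighbors
in the 3×3×3 cube centered on it (slices missing at the stack boundary
contribute no comparisons) and strictly greater than at least one. The
alternative strictly-greater-than-all rule is available as
`cube_rule="gt"`; whether the original interactive analyses used ≥ or >
against the cube is not documented anywhere we know of, so both are
exposed and the default is the more permissive one, which cannot lose a
genuine spot to a single duplicated voxel value. Exact-intensity ties
between candidates lying within each other's cube are resolved by keeping
the lexicographically smallest (z, y, x) — one transcript is never
counted twice. The entire rule set is verified exactly against a
brute-force 26-neighborhood oracle on random stacks.

## Colocalization

Spots from two channels are colocalized when one lies in the cylinder
centered on the other: |Δz| ≤ 4 slices and lateral distance ≤ 5 px, both
**inclusive** ("within a region" is read inclusively; the bounds are
configurable for sensitivity analyses). Distances are deliberately
anisotropic — pixels laterally, slice counts axially — mirroring how such
regions are specified on the instrument rather than converting to µm.
The default counting mode is *any-partner* (a spot is colocalized if at
least one spot of the other channel is in its cylinder), which matches
set-based percentage definitions and keeps both percentages ≤ 100;
percentages count distinct matched spots, never pair multiplicity, and
the raw pair set is returned so multiplicity can be inspected. A greedy
nearest-first *one-to-one* matching is provided for dense data. An
optional constant (Δz, Δy, Δx) offset on channel B supports chromatic
registration; no correction is applied by default. Per-cell results
exclude cells with zero spots in either channel (the percentages are
undefined there) and report mean ± SD (ddof = 1) across the remaining
cells.

## Cell-level quantification

Integrated density is the sum of pixel intensities whose centers fall
inside the (boundary-inclusive) cell polygon, on background-subtracted
single-plane images. Reporter-channel autofluorescence is modeled as a
*linear* function of TMR-channel integrated density fitted on
probe-negative cells — linear rather than proportional because an
intercept absorbs channel offsets, and "a correlation was determined"
implies a fitted relation. R_CLOSED, the reporter:reference ratio of
target-free probe, is measured on emulsion droplets as the ratio of
background-subtracted **mean** intensities (means, not integrated
densities, so droplet size cancels), averaged over droplets.

The enhancement signal of a cell is

```
enhancement = (ID_rep − af_rep) − R_CLOSED × ID_ref
```

Autofluorescence subtraction sits *inside* the formula by default: the
two corrections are described separately in the literature without a
combined expression, so the combined form is stated explicitly here, and
`af_mode="none"` computes the variant without the autofluorescence term
for reporter images that were corrected upstream. Enhancement is exactly
linear in both integrated densities (slope 1 in ID_rep, −R_CLOSED in
ID_ref), and may be negative only within measurement noise of zero.
The copy-number relation is summarized by an ordinary least-squares line
of enhancement against transcript count plus the Pearson correlation on
untransformed values, matching the linearity claim being tested.

## Probe biophysics

Melting profiles are corrected for the intrinsic temperature dependence
of dye fluorescence either by pointwise division by a reference scan (or
linear dye-response model) — dividing a curve by itself yields exactly 1 —
or, when no reference is available, by subtracting a linear drift whose
slope is the mean of two lines fitted separately to the first and last
10% of samples: the intrinsic drift tilts both baselines equally while
the transition step between them enters neither local fit. The default
(linear model) is a pragmatic choice, not a claim about any particular
instrument's reference protocol; both options are implemented.

Tm comes from two standard routes, both always reported: the temperature
of maximal |dF/dT| on a 3-point-smoothed curve (minimal smoothing —
typical 1 °C grids are coarse and heavier smoothing biases Tm), refined
by quadratic interpolation around the grid peak; and a two-state sigmoid
with linear folded/unfolded baselines whose fitted midpoint is Tm,
initialized from the derivative estimate and the curve ends. A curve
whose amplitude is below ~5× the point-to-point noise yields an explicit
no-estimate result rather than a spurious number.

Hybridization kinetics at ≥ 5-fold target excess follow the
pseudo-first-order form `F(t) = F_inf − (F_inf − F0)·exp(−k_obs·t)`,
fitted by least squares with F0/F_inf initialized from the first/last
10% of samples and k_obs from a log-linear fit of the normalized
approach; `k_on = k_obs / [target]` in molar units. Non-convergence, a
non-positive rate, or a fitted amplitude below 5× the residual SD raise
an explicit error. These closed forms are the standard two-state /
pseudo-first-order models for hairpin probes; thermodynamic parameters
(ΔH, ΔS) and off-rates are out of scope.

## Synthetic microscopy

The generator emulates the acquisition setting the pipeline targets:
56-slice stacks (configurable) at 0.2 µm z-spacing, a Gaussian PSF with
σ_xy = 1.3 px and σ_z = 2.0 slices (high-NA oil objective near Nyquist),
flat background 10 intensity units with optional linear ramp, and
Poisson + Gaussian noise (read noise SD 2), which reproduces EMCCD-like
statistics qualitatively. Spot peak amplitudes default to 200 with a 10%
lognormal spread: multi-probe puncta are bright, and no published SNR
figure exists for them, so the default was set where puncta are
unmistakable by eye (SNR ≈ 50) while the amplitude remains a free
parameter for low-SNR studies.

Scene design is exact by construction. Sub-voxel spot centers are drawn
uniformly in the cell polygon (intersected with the stack bounds);
exactly `round(f·n_A)` A-spots receive a B partner sampled uniformly in
the colocalization cylinder shrunk by a 1 px / 1 slice margin, and all
other cross-channel pairs are kept outside every cylinder grown by the
same margin — the margins make designed pairs and designed non-pairs
robust to voxelization at detection, while leaving the ground-truth
fraction exact. When pairs are designed, A spots keep two
cylinder-widths of mutual clearance so partner placement is always
feasible. All placement is rejection sampling with a 10,000-attempt cap
and an explicit `SceneGeometryError` on failure — ground truth is never
silently degraded. An optional minimum same-channel separation uses the
PSF-normalized metric `sqrt(dy² + dx² + (s·dz)²)` with a caller-chosen
axial scale *s*.

Cell-field rendering writes per-pixel *densities* inside each (non-
overlapping) cell polygon — TMR autofluorescence, probe reference, and
the reporter combination `af_ratio·tmr + R_CLOSED·ref + enhancement` —
so designed integrated densities are exactly density × mask area at zero
noise and the whole quantification chain closes.

What the generator does **not** emulate: realistic PSFs (Gibson–Lanni),
camera gain and pixel non-uniformity, photobleaching, spot motion,
intracellular background structure, or clustered/overlapping transcripts.
Passing tests therefore demonstrate correctness of the *algorithms* under
controlled conditions and exact agreement with their specifications, not
detection performance on real cells, where background structure and spot
crowding dominate the error budget.

## Validation battery and problem sizes

`puncta.validation` (driven by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) regenerates its inputs from a seed and measures:
exact agreement of the detection pipeline with a brute-force
26-neighborhood oracle (100 random 16×16×9 stacks, coarse-valued to force
ties); exact agreement of pair finding with a dense all-pairs cylinder
oracle (20 scenes × 500 spots/channel) plus the three boundary cases;
exact ground-truth recovery of designed fractions {0.2, 0.5, 0.75} and
their end-to-end recovery after rendering and detection (40 spots/channel,
56 slices); detection F1 and the threshold-monotonicity sweep (50 spots,
10 thresholds); enhancement closure, exact linearity and full-chain slope
recovery (8-cell fields); the copy-number correlation (48 cells, counts
0–300, 10% multiplicative noise); Tm and k_obs recovery over 100 noisy
simulations each (1% and 2% amplitude noise); and bit-level determinism
of every stage. These sizes exercise every code path at realistic scale
while the whole battery completes in well under a minute per stage on one
CPU.

## Known limitations

- No sub-pixel localization: transcripts are reported at voxel
  resolution, which is sufficient for counting and cylinder-based
  colocalization but not for distance distributions below ~1 px.
- The any-partner percentages saturate at high spot density; use
  one-to-one mode and inspect pair multiplicity when densities approach
  one spot per cylinder volume.
- The autofluorescence model is global (one line for all cells of a
  field); strongly heterogeneous cell populations would need per-subset
  fits.
- The prominence flood-fill is exact but O(region) per maximum; it is a
  no-op at the default noise tolerance of 0.
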