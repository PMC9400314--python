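# Methods

This note documents the quantitative procedures implemented in `endoquant`,
the modelling assumptions behind the synthetic-data generator, the
parameters that matter and their defaults, and the numerical choices made
where the underlying procedure left the design open.

## Image model and coordinate conventions

Images are `T × C × Y × X` stacks (`FrameStack`) with a physical pixel size
(nm/px) and frame interval (s). Indices are 0-based and a pixel's centre
sits at integer coordinates; all physical distances are computed in nm via
the pixel size, so the 320 nm colocalization cutoff is applied on a
physical scale regardless of sampling. Intensities are treated as photon
counts.

## Synthetic-data generator

The generator exists so that every analysis stage can be validated against
a known truth. It emulates:

- a roughly disk-shaped cell (interior level over background, both blurred
  by the PSF — a hard intensity step at the cell outline would be an
  imaging artefact no diffraction-limited microscope produces);
- diffraction-limited vesicles as 2-D Gaussian profiles with configurable
  integrated photon count (`spot_intensity`; the rendered peak is
  `spot_intensity / 2πσ²`);
- noise as signal-dependent shot noise (Poisson on the expected photon
  image) plus additive Gaussian read noise, approximating sCMOS/PMT
  acquisition without modelling a specific camera;
- controllable radial dispersion: each spot's radial fraction of the
  usable cell radius is drawn from Beta(2s, 2) with s =
  `dispersion_scale`, whose mean s/(s+1) is strictly increasing in s, so
  the dial maps monotonically onto the measured dispersion statistic
  (verified over five levels);
- an exactly imposed colocalization fraction: `round(f·n_B)` channel-B
  spots are co-positioned with distinct channel-A partners (offset uniform
  in a disk of radius `coloc_offset_nm`), the rest rejection-sampled at
  more than `exclusion_radius_nm` (default 640 nm, twice the 320 nm
  cutoff) from every A spot. The realized fraction among ground-truth
  spots is therefore imposed, not sampled. A same-channel minimum spacing
  (`min_spot_separation_nm`, default 800 nm) keeps spots resolvable by the
  detector, mirroring the sparse vesicle fields of the real assays.

Defaults represent the imaged system: 100 nm pixels, a 45 px (4.5 µm)
radius cell in a 128×128 px field, 12 vesicles per channel, PSF σ = 1.5 px,
cell interior 40 counts over 10 counts background with 3-count read noise.

TIRF fusion movies place events on a flat background; the cargo channel's
spot collapses exponentially (τ = 1.5 frames) after a per-event fusion
frame, and the marker channel either co-decays (a co-fusion, with the
configured rate imposed exactly by rounding) or persists at constant
expected intensity. Grouped time series share a linear baseline; the
second group is location-shifted by the effect size from a known timepoint
onward.

What the generator does **not** emulate: 3-D PSFs, photobleaching and
blinking, cell motility, vesicle motion between frames (tracks are
validated on constructed trajectories instead), spatially varying
background, and camera fixed-pattern artefacts. Tests passing on this
synthetic data therefore demonstrate correctness of the procedures under
the stated noise model, not performance on arbitrary real recordings.

## Cell segmentation

Gaussian smoothing (σ = 2 px), Otsu threshold computed on the
log-transformed smoothed image, largest connected component, holes filled.
The log transform matters: a handful of vesicles hundreds of times
brighter than the cell body would otherwise dominate the intensity
histogram and Otsu would "segment" the brightest spot. The cell centroid
is intensity-weighted over the mask. A constant frame raises a
"no cell found" error.

## Spot detection

Difference of Gaussians at (σ, 1.6σ) with σ = `expected_spot_sigma_px`
(default 1.5 px), local maxima above a robust threshold of
median + k·MAD (scaled) of the band-passed frame, k =
`detection_threshold` = 7 by default. Expressing the threshold in robust
noise units makes counts invariant to global intensity scaling. Maxima
with an edge-like local Hessian (principal-curvature ratio above 5, the
standard blob/ridge discriminator) are rejected — this suppresses residual
responses of the cell outline, which is a ridge, not a blob. Sub-pixel
positions come from centre-of-mass refinement of the non-negative
band-passed patch in a ±⌈2σ⌉ window; with the defaults the localization
RMSE on synthetic spots is ≈ 0.1 px at peak SNR 10 (SNR here = Gaussian
peak amplitude / total noise sd at the peak). Two true spots closer than
`min_separation_px` (default 4 px) merge into a single detection at their
intensity-weighted midpoint; this is documented behaviour of the
local-maximum picker, and detections are deduplicated so no two reported
centroids violate the separation. k = 7 was chosen so that, under the
generator's noise model, the expected false-detection count per frame is
far below one while spots at peak SNR ≥ 8 are still detected with
essentially unit recall; detection parameters are always reported next to
results because they are this implementation's own defaults.

## Tracking

Greedy mutual nearest neighbours between consecutive frames under a hard
displacement gate (`max_link_displacement_px`, default 5 px), no gap
closing. On unambiguous instances this coincides with the
minimal-total-displacement assignment (tested against an exhaustive
assignment oracle); when two spots would have to swap across more than the
gate, tracks terminate rather than swap identities.

## Colocalization

Distances are centroid-to-centroid in nm; the double-positive criterion is
inclusive (≤ 320 nm). Percentages are directional ("% of reference-channel
vesicles with a query-channel neighbour within the cutoff"); both
directions can be computed and are never averaged. The random control
re-draws both point sets uniformly inside the segmented cell mask —
matching the observed per-channel counts, which preserves density — and
classifies them identically, 100 iterations by default; the mean control
percentage agrees with the closed form 1 − (1 − πd\*²/A)^m for m query
points in a mask of area A up to edge effects (validated within Monte
Carlo error).

## Dispersion

D = Σ wᵢ‖pᵢ − c‖ / Σ wᵢ over all pixels of the cell mask (not detected
vesicles only), with c the intensity centre of mass of the same channel.
Closed forms used for validation: a point mass at the centre gives 0, a
thin ring of radius r gives r, a uniform disk of radius R gives 2R/3
(∫r·2πr dr / πR² = 2R/3). The weight support and the per-channel centre
are deliberate choices where the procedure was ambiguous; a
vesicle-restricted variant (`mean_dispersion_points`) and an optional
constant-background subtraction (clamped at zero, off by default) are
provided, clearly labelled, for sensitivity analysis.

## Compartment cargo signal

The marker channel is thresholded (Otsu by default — invariant to positive
scaling of marker intensities; fixed-value and percentile methods
selectable; method and realized value always recorded). "Background set to
zero" is implemented as subtracting the median cargo intensity outside the
segmented cell, clamped at zero. The masked mean restricts to mask pixels
rather than zero-filling outside — zero-filling would dilute the mean by
mask area and no longer measure the signal *present in* the compartment.
Empty masks are flagged and yield a missing value (NaN), never zero.
Masks are computed per frame by default; a single pooled-threshold
per-movie mode is selectable.

## Co-fusion rule

For the classified channel, the per-frame maximum intensity within a disk
footprint (radius 3 px by default) over the event window is extracted; the
event is positive when (M₀ − M̄ₖ)/M₀ strictly exceeds the drop threshold
(0.10), with M₀ the initial frame's maximum and M̄ₖ the mean of the last
k = 3 per-frame maxima. "Mean of the last three maxima" is the adopted
reading; the alternative ("max of the last three footprint means") is
selectable via `reading="max-of-means"`. The rule is a ratio and hence
invariant to positive scaling of the trace; a drop of exactly 10% is
negative. Events are supplied manually as a CSV of centres and windows
(mirroring visual identification); an automatic proposal from cargo-channel
disappearance is out of scope as a validated detector.

Noise sensitivity: the statistic compares a *single* initial-frame maximum
against a 3-frame tail, so for persisting markers the false-positive
probability is roughly P(z > 0.1/σ_rel) with σ_rel ≈ 1.15·σ_max/M₀. At
peak SNR 10 this is ~5–8%, and label recovery on synthetic events hovers
near 93–97%; from peak SNR ≈ 12.5 upward recovery is reliably above 95%.
The validation suite therefore runs the recovery study at SNR ≈ 12.6 —
consistent with the fact that visually identified fusion events are
conspicuous by construction — and the acceptance script additionally
reports recovery at a low-SNR setting to show the graceful degradation.

## Time of divergence

At each timepoint the pooled per-cell (or per-vesicle) values of the two
groups are compared with a two-sided Wilcoxon rank-sum test: exact null
enumeration when both samples have ≤ 10 observations and no ties, else the
normal approximation with tie and continuity corrections (the method used
is recorded per timepoint; the approximation stays within |Δp| ≤ 0.04 of
full enumeration for tie-free samples of 3–8 observations, while for
2-observation samples no normal approximation is meaningful). The
divergence index is the first timepoint after which **all** subsequent
p-values are ≤ α (inclusive); a single early dip does not count. Both
α = 0.05 and α = 0.01 are reported. No multiple-testing correction is
applied across timepoints, matching the procedure as used; instead the
power study quantifies the family-level false-positive rate empirically
(≈ 3–4% at α = 0.05 with 8 timepoints and n = 15 per group).

A structural property worth knowing: with a shift starting at index i, the
probability that the last pre-shift timepoint is spuriously significant is
α itself, in which case the recovered index is i − 1. Exact-index recovery
is therefore capped near 1 − α regardless of effect size (≈ 95% at
α = 0.05, ≈ 99% at α = 0.01 — both observed in the Monte-Carlo study).

Pooling across cells is the default ingestion mode; a per-cell-summary
mode (one value per cell) is available through the same long-format
interface since pooling ignores within-cell correlation. Missing values
are dropped listwise per timepoint.

## Assay arithmetic

All operations are ratios or differences of median fluorescence
intensities or counts and are invariant to common positive rescaling of
their inputs. Unstained-background subtraction before a fold change is a
per-assay flag (on for activation-marker panels, off for uptake/recycling
by default, mirroring how each readout is acquired). Conjugate percentages
are computed relative to the minority cell type's total (singles +
conjugates) and the unpulsed-control percentage is subtracted; negative
corrected values are reported, not clamped, to avoid biasing group means.
Immunoblot bands are scaled to the brightest target band on the blot and
divided by the lane's loading control scaled to its own brightest band —
this order makes the result invariant to the units of either channel
(tested under randomized rescaling).

## Problem sizes used in validation

The test suite and acceptance script use: 128×128 px cells with 12 spots
per channel and 20 cells per colocalization level; 200 TIRF events in a
512×512 px field over 12 frames; 200 seeds for divergence recovery and 500
for the null rate (8 timepoints, 15 observations per group); 100 random
point-set pairs (n ≤ 200) for the nearest-neighbour oracle and 50 random
images for the dispersion oracle. These sizes give Monte-Carlo standard
errors comfortably below the asserted margins.

## Known limitations

- Detection and linking are 2-D; z-stacks are analysed slice by slice.
- The dispersion statistic conflates radial spread with cell size; it is
  comparable across cells of similar size only.
- The random colocalization control assumes uniform point placement inside
  the cell mask, ignoring intracellular exclusion volumes (nucleus,
  organelles).
- The co-fusion rule inherits the noise of a single-frame maximum (see
  above); at low SNR its false-positive rate on persisting markers rises
  smoothly.
- Pixel-intensity correlation measures (Pearson/Manders) and kinetic
  fitting of fusion flashes are out of scope.
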