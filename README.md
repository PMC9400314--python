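# endoquant

Quantification of endosomal trafficking in fluorescence microscopy of
T cells, built for studies of transferrin-receptor (TfR/CD71) recycling:
how internalised cargo moves through Rab5-positive sorting and
Rab11a-positive recycling endosomes, how those endosomes are spatially
organised, and when two experimental groups (e.g. wild-type vs
flotillin-knockout cells) start to differ. The package also covers the
deterministic arithmetic of the accompanying flow-cytometry and immunoblot
readouts, and ships a ground-truth synthetic-data generator so that every
stage of the pipeline is testable without microscope data.

## What it computes

- **Vesicle detection and tracking** — diffraction-limited spots per frame
  and channel via a difference-of-Gaussians band-pass, a robust threshold
  (median + k·MAD, so counts are invariant to global intensity scaling),
  centre-of-mass sub-pixel refinement, and greedy mutual-nearest-neighbour
  linking with a hard displacement gate.
- **Object-based colocalization** — a vesicle is double-positive when its
  nearest cross-channel neighbour lies within a physical cutoff
  (default d\* = 320 nm, centroid-to-centroid). Percentages are directional
  and compared against random-point controls drawn uniformly in the cell
  mask with the observed vesicle counts.
- **Dispersion** — the intensity-weighted mean distance of cell pixels from
  the cell's intensity centre of mass,
  D = Σᵢ wᵢ‖pᵢ − c‖ / Σᵢ wᵢ, reported in px and nm; higher D means more
  peripheral/scattered endosomes.
- **Compartment cargo signal** — the marker channel (Rab5/Rab11a/flotillin)
  is thresholded into a compartment mask; the cargo channel is
  background-zeroed and its mean over the mask reported per frame.
- **TIRF co-fusion classification** — a fusion event contains a second
  marker when the relative drop from the initial frame's footprint maximum
  M₀ to the mean of the last three per-frame maxima strictly exceeds 10%:
  (M₀ − M̄₃)/M₀ > 0.10.
- **Time of divergence** — a two-sided Wilcoxon rank-sum test of the pooled
  group distributions at each timepoint; the divergence time is the first
  timepoint after which all subsequent p-values stay at or below the
  significance level (α = 0.05 and 0.01 both reported).
- **Assay arithmetic** — activated/resting median-FI fold changes,
  recycling relative to t = 0, treated/control normalization, T-cell:APC
  conjugate fractions relative to the minority cell type with
  unpulsed-control subtraction, and loading-corrected immunoblot band
  normalization.

## Worked example

```python
import numpy as np
import endoquant as eq

# a synthetic two-channel cell with half the channel-B spots co-positioned
cfg = eq.SynthImageConfig(coloc_fraction=0.5, spot_intensity=2000.0, seed=1)
stack, truth = eq.generate_cell_image(cfg)

cell = eq.segment_cell(stack, channel=0, frame=0)
det_a = eq.detect_vesicles(stack, channel=0, frame=0)
det_b = eq.detect_vesicles(stack, channel=1, frame=0)
print(f"cell area: {cell.area_px} px  ({len(det_a)} chA and {len(det_b)} chB vesicles)")

result = eq.analyze_coloc(det_b, det_a, cell=cell, pixel_size_nm=cfg.pixel_size_nm)
print(f"double-positive: {result.percent_double_positive:.1f}%  "
      f"(chance level {result.random_control.mean_percent:.1f}%)")

disp = eq.mean_dispersion(stack.frame(0, 0), cell, pixel_size_nm=cfg.pixel_size_nm)
print(f"dispersion: {disp.dispersion_px:.2f} px = {disp.dispersion_nm:.0f} nm")

series, _ = eq.generate_grouped_timeseries(
    n_per_group_per_timepoint=15, timepoints=np.arange(8.0) * 30.0,
    shift_start_index=4, effect_size=10.0, noise_sd=1.0, seed=1)
print(eq.time_of_divergence(series, alphas=(0.05, 0.01)).summary())
```

prints

```
cell area: 6627 px  (12 chA and 12 chB vesicles)
double-positive: 50.0%  (chance level 6.4%)
dispersion: 29.61 px = 2961 nm
Time-of-divergence analysis (group_a vs group_b)
   timepoint    p-value       method
           0     0.2998   asymptotic
          30     0.5338   asymptotic
          60     0.9669   asymptotic
          90     0.5614   asymptotic
         120  3.392e-06   asymptotic
         150  3.392e-06   asymptotic
         180  3.392e-06   asymptotic
         210  3.392e-06   asymptotic
alpha=0.05: divergence at timepoint 120 s (index 4)
alpha=0.01: divergence at timepoint 120 s (index 4)
```

The detected double-positive percentage recovers the imposed 50%
colocalization fraction exactly and sits far above the ~6% chance level of
equally many random points in the same cell; the divergence analysis
recovers the configured shift onset (index 4, here 120 s) at both
significance levels.

A `endoquant` command-line interface exposes the same stages
(`simulate`, `detect`, `track`, `coloc`, `dispersion`, `compartment`,
`fusion`, `diverge`, `assay`); every stage is byte-deterministic given its
inputs and seed.

## Layout

- `src/endoquant/synthetic.py` — ground-truth generators (cell images,
  TIRF event movies, grouped time series)
- `src/endoquant/detection.py` — cell segmentation, spot detection, linking
- `src/endoquant/coloc.py` — nearest-neighbour colocalization + controls
- `src/endoquant/dispersion.py` — dispersion statistic
- `src/endoquant/compartment.py` — compartment masks and cargo means
- `src/endoquant/fusion.py` — TIRF co-fusion rule
- `src/endoquant/divergence.py` — rank-sum tests and time of divergence
- `src/endoquant/assays.py` — cytometry/blot arithmetic
- `src/endoquant/cli.py`, `src/endoquant/io.py` — CLI and TIFF I/O
- `docs/methods.md` — models, parameter choices and limitations
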