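# Methods

This note documents the models, parameters and numerical choices behind
spherolec, and what the phantom-based validation does and does not show.

## Conventions

Arrays are `(z, y, x)`, 0-based, with half-open bounding boxes. All
physical calibration is in micrometres; voxel volume is `dz·dy·dx` and
every reported volume is `voxel count × voxel volume`, exactly. Voxel
centres sit at `(index + 0.5) × voxel_size`. Intensities live on a
linear 16-bit-like scale `[0, 65535]`. Anisotropic voxels (`dz ≠ dx`)
are supported throughout: every spatial parameter is given in µm and
converted per axis, and morphological footprints are ellipsoids
rasterized from a physical ball.

## Measurement model and preprocessing

A stack is conditioned in three steps, in order:

1. **Contrast rescale.** Intensities are mapped linearly so the
   (low, high) percentiles hit `[0, 65535]`, clipping outside; the
   transform is monotone, and a constant image is returned unchanged.
   Defaults (0.5, 99.95). The high percentile must lie *inside* the
   foreground plateau: in sparse 3D stacks the foreground is often
   below 1% of voxels, and a high percentile that lands in the blur
   gradient (e.g. 99.5 here) clips halo voxels onto the plateau, after
   which every global threshold over-segments. 0.05% clipping still
   removes hot pixels. Stacks with foreground sparser than ~0.05% of
   voxels would need a higher setting; this is the main tuning knob for
   real data.
2. **Gaussian smoothing**, per-axis sigma = `smooth_sigma / voxel_size`.
   Default 0.75 µm: enough to suppress shot noise at the default noise
   level while adding little width on top of a typical confocal PSF
   (larger values measurably inflate the segmentation halo). Sigma 0 is
   the identity; interior-supported signal mass is conserved to
   numerical precision.
3. **Median despeckling** with a physical-radius ball footprint
   (default 1 µm; 0 disables). Removes single-voxel impulses without
   shifting edges.

No illumination-field correction and no deconvolution are attempted.

## Segmentation

Global Otsu threshold (default; a fixed threshold is available for
controlled experiments), then morphological closing with a 1 µm ball,
3D hole filling, and removal of connected components below
`min_object_volume` (default 500 µm³ — object-level noise removal, well
below one cell). A constant image leaves Otsu undefined; the result is
an empty mask with a logged warning, not an error. Objects are labeled
with 26-connectivity; labels are dense `1..N`, ordered by descending
voxel count with ties broken by first-voxel scan position, making
outputs reproducible run to run. Segmentation is deterministic and
idempotent on its own binary output.

## Overlap statistic

`degree = v_inside / v_lec` with `v_lec` the LEC mask volume. Two
readings of `v_inside` are implemented because the defining phrase
"tumor volume inside the network" is genuinely ambiguous:

* **object mode (default)**: the LEC mask is dilated by `lec_dilation`
  (default 5 µm, about half a cell diameter, tolerating the gap between
  membrane signal and spheroid surface); each spheroid's overlap
  fraction is the share of its voxels under the dilated mask; spheroids
  with fraction ≥ τ (default 0.5, majority rule) are *inside*, and
  their whole volumes are summed. The ratio can exceed 1 when inside
  tumor volume exceeds network volume; it is reported as-is.
* **voxel mode**: `v_inside` is the volume of the voxelwise
  intersection of the two undilated masks; bounded in [0, 1].

Both modes are exposed and tested; no claim is made about which one any
particular published figure used. An empty LEC mask raises an explicit
undefined-statistic error rather than returning 0 or infinity.

## Core / outgrowth decomposition

Core = morphological opening of the spheroid mask with a physical ball
of `core_opening_radius`; outgrowth = mask ∖ core. The partition is
exact by construction. Each labeled spheroid is decomposed on its own
padded bounding box (identical result to the full grid, much faster).
If the whole object is thinner than the radius the opening is empty and
the object is reported entirely as outgrowth with an `all_outgrowth`
flag.

The radius is the method's one structural parameter. It must exceed the
*apparent* (post-blur) half-width of an outgrowth and stay below the
core radius; within that window, smaller is better because the opening
strips a junction band off the core and assigns it to the outgrowth,
and that band grows with the radius. At the phantom scale (3 µm
outgrowth radius, ~8.5 µm core radius, ~1.3 µm lateral blur) the
default is 4 µm; measured against generator truth this keeps core
volumes within ~3% and outgrowth volumes within ~15-25%, while 6 µm
already doubles the outgrowth error. Real stacks with larger spheroids
warrant a proportionally larger radius.

## Phantom generator

The generator emulates the two phenotypes of these cocultures, with
exact truth recorded **before** blur and noise (the PSF and noise are
part of the measurement model the pipeline must undo):

* **LEC channel**: nodes sampled uniformly (margin = 1.5 tube radii),
  connected by their Euclidean minimum spanning tree plus a few extra
  short edges added with probability `network_edge_probability` (capped
  at half the node count) — a tree with occasional cycles, i.e. a
  reticular pattern. Nodes are rasterized as balls of 1.4 tube radii,
  edges as capsules of `network_tube_radius`.
* **TNBC channel**: each spheroid is a ball (core) with
  `outgrowth_count_per_spheroid` capsules of `outgrowth_radius` running
  from the centre to `radius + outgrowth_length` along random
  directions; truth outgrowth = capsule ∖ ball. Radii are normal
  (mean 8.5 µm, sd 1.5), clipped to [0.3·mean, mean+3·sd]. With
  probability `association_strength` a centre is placed on the network
  skeleton (edge picked ∝ length), else uniformly. Overlapping claims
  between spheroids are resolved first-come, so per-spheroid truth
  voxel sets are always disjoint and bookkeeping is exact.

Rendering: background 1000, signal 10000, anisotropic Gaussian PSF
(σ = 1.5/0.75/0.75 µm in z/y/x), then Poisson noise at a gain of 50
intensity units per photon and additive Gaussian noise (sd 1800). The
contrast-to-noise ratio at the default settings is ≈ 5. Defaults
describe a 64×128×128 µm volume at 2×1×1 µm voxels with three
spheroids and an eight-node network whose volume is ~5× the tumor
volume, echoing the 1:5 tumor:endothelial seeding ratio of the
emulated cultures. The generator is bit-deterministic in
`(config, seed)`; geometry and noise use separate seed-derived streams.

**Timecourses** freeze one geometry across all timepoints. Each
spheroid carries a fixed uniform draw `u`; it is on-network at day *t*
iff `u < a(t)`, with `a(t)` ramping linearly from one sixth of
`association_strength` to `association_strength`. Core radii scale as
`core_growth_factor^((day-d0)/(d1-d0))` in volume (geometric
interpolation; default 3.5-fold across reference days 3→6), and
outgrowth capsules extend with the growing core. Because masks are
monotone in the radius and the on-network set only grows, the true
overlap is nondecreasing in time *by construction*, which is what the
timecourse validation then checks end to end. Noise is re-drawn per
timepoint. The real systems' network morphometry (tube radii, node
counts) is not quantified anywhere we know of; those defaults are free
parameters, not claims.

## Statistics

One-way fixed-effects ANOVA (scipy) on a compartment's volumes,
followed by Tukey's HSD (statsmodels) at family-wise α = 0.05;
`significant ⇔ p_adj ≤ α ⇔ CI excludes 0` (asserted). Box-whisker
summaries use linear interpolation of order statistics (numpy's default
quantile rule) and **min/max whiskers**, not 1.5·IQR fences — the
convention used in this field's plots. Replicates are treated as
exchangeable observations; no normality or variance-homogeneity test is
added, and no procedures beyond Tukey. Degenerate inputs (a group with
fewer than two observations, all-identical data) raise named errors.

## Pipeline

One structured config (YAML or dict) with exactly one input mode —
`simulate` (phantom timecourse per replicate; seed mandatory) or `load`
(existing OME-TIFF stacks). Outputs under `output_dir`: stacks and a
truth table (simulate), the long-format volume table
(condition / day / replicate / compartment ∈ {lec_total, tnbc_core,
tnbc_outgrowth, tnbc_total} / volume), per-stack overlap table, stats
CSV + plain-text report, optional orthogonal-projection QC images, and
a `manifest.json` echoing every parameter actually used (including
defaults) plus the package version. CSVs use a fixed float format;
identical config + seed reruns are byte-identical. Spheroids are not
tracked across timepoints — populations are imaged per day, not
registered objects.

## Problem sizes used in validation

The test suite and the acceptance script validate at the generator's
default scale (32×128×128 voxels): 10 seeded phantoms for recovery
(median Dice, total-volume error, voxel-mode overlap error), 4
timepoints × 3 replicates for the monotone overlap trend, 3 replicate
pairs for outgrowth-invariance and the day-3→6 core fold-change, 50
randomized grids (≤ 24³) against the exhaustive-enumeration oracle, 100
truth-only draws for the association dial, and 1000 resamples for the
null rejection rate. These sizes give stable medians while keeping a
full validation run in the low minutes on one CPU.

## What passing the phantom validation does and does not show

The generator shares the real data's *structure* (two channels, blur,
mixed noise, anisotropy, sparse foreground) but idealizes much of its
physics: uniform background, spatially constant PSF, no bleed-through,
no depth attenuation, no touching spheroid clusters beyond incidental
contact, and simple capsule-shaped outgrowths rather than branching
strands. Recovery within a few percent on phantoms is therefore a
*correctness* statement about the implementation and its parameter
conventions, not an accuracy guarantee for arbitrary microscopes.
Equivalence with the proprietary software originally used for such
measurements is not claimed anywhere; the oracle is geometric truth.
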