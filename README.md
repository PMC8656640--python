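# spherolec

Quantification of tumor-spheroid / lymphatic-network interactions in
two-channel 3D coculture image stacks.

## The problem

In 3D cocultures on reconstituted basement membrane, triple-negative
breast cancer (TNBC) cells form spheroids with multicellular invasive
outgrowths, while lymphatic endothelial cells (LECs) self-assemble into
branching reticular networks. Two quantities summarize how the two
compartments interact in confocal z-stacks of such cultures:

* **Degree of overlap** between spheroids and the network,

  *degree* = V(tumor inside LEC network) / V(LEC network),

  where "inside" is decided per spheroid: a spheroid with at least a
  fraction τ of its voxels inside the (optionally dilated) network mask
  counts as inside (*object mode*, default τ = 0.5). A *voxel mode*
  that uses the voxelwise intersection volume instead is also provided;
  it is bounded in [0, 1], whereas object mode may exceed 1 and is
  reported unclipped.

* **Core / invasive-outgrowth decomposition** of each spheroid: the
  core is the morphological opening of the spheroid mask with a ball of
  physical radius *r* (anisotropy-corrected); the outgrowths are
  everything the opening removes. Core + outgrowth = total, exactly.
  Core volume proxies proliferation; outgrowth volume proxies invasion.

The package provides the full chain for calibrated (µm) anisotropic
stacks: OME-TIFF I/O and tile stitching, preprocessing (percentile
contrast rescale, Gaussian smoothing, median despeckling), Otsu
segmentation with physical-unit morphology, 26-connected object
labeling, the two statistics above, long-format volume tables, and the
group comparison standard in this field (one-way ANOVA with Tukey's HSD
at family-wise α = 0.05, box-whisker summaries with min/max whiskers).

Because real coculture stacks of this kind are rarely public, the
package ships a first-class **phantom generator**: synthetic two-channel
volumes with spheroids-plus-outgrowths and node-and-tube networks at
controllable spatial association, growth, blur and noise — with exact
ground truth recorded before the measurement model is applied. Every
claim the pipeline makes is validated against that truth.

## Worked example

`examples/02_overlap_statistic.py` generates a phantom, segments both
channels and measures the overlap statistic:

```
TNBC Dice vs truth: 0.971
LEC  Dice vs truth: 0.980
object mode: degree 0.326 (truth 0.327); 2/2 spheroids inside
voxel  mode: degree 0.161 (truth 0.159); 2/2 spheroids inside
```

Dice near 1 means the masks recover the true geometry through blur and
noise; the recovered degree of overlap tracks the generator's truth in
both modes. `examples/04_timecourse_stats.py` runs the full pipeline on
a simulated 4-day timecourse (3 replicates) and prints, among others:

```
mean degree of overlap by day ...:
day
1.0    0.0600
2.0    0.0699
3.0    0.1375
4.0    0.2067

one-way ANOVA across days: F(3, 8) = 16.39, p = 0.000888
  Tukey day 1.0 vs 4.0: diff      9739 µm³, p_adj = 0.00079 *
```

The overlap rises monotonically because the generator ramps the
spheroid–network association across days; the ANOVA/Tukey lines are the
volume comparison an actual experiment would receive.

There is also a thin CLI over the same functions:

```bash
spherolec simulate --seed 11 --out-prefix /tmp/phantom
spherolec quantify --tnbc /tmp/phantom_TNBC.ome.tif --lec /tmp/phantom_LEC.ome.tif
spherolec run-all --config my_run.yaml
```

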