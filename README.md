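# tractcluster

Data-driven parcellation of spinal-cord white matter from axon/myelin
morphometry maps.

White-matter tracts (fasciculus gracilis, corticospinal tract, ...) are
classically mapped by tracer injection — slow, invasive, and available for
only a handful of specimens. But axon populations differ between tracts in
their morphometrics: axon density, axon diameter, axon volume fraction,
g-ratio and myelin thickness. `tractcluster` asks how far those
morphometric signatures alone can delineate tracts: it clusters pixelwise
metric maps (50 × 50 μm grid) of rat spinal cord cross-sections into
spatially contiguous parcels and scores them against a reference tract
atlas.

Because the maps derive from electron-microscopy data that not everyone
has, the package includes a **synthetic spinal cord generator**: a
parametric toy atlas (cord outline, gray-matter butterfly, nine tract
regions mimicking the standard rat atlas topology) from which subject-level
metric maps are drawn per-tract, with published tract statistics as
defaults. Every stage of the pipeline runs, and is tested, without any
download.

## The method

1. **Simulate / load** — per subject and spinal level (31 levels C1–S4,
   grouped into cervical/thoracic/lumbar/sacral), a 5-channel metric stack
   with a white-matter mask. Synthetic subjects add truncated-normal pixel
   noise and a smooth random deformation.
2. **Template** — subjects at each level are co-registered (affine on the
   WM masks, then B-spline free-form deformation on the axon-density map),
   averaged pixelwise, and right–left symmetrized.
3. **Region aggregation** — within each region, slices are chained to the
   mid-slice by stepwise adjacent-pair registration (fields composed
   outward from the reference), all channels plus one-hot tract labels are
   warped, and the superior–inferior average taken; tract channels become
   partial volumes in [0, 1].
4. **Clustering** — the core step, written from scratch: pixels inside the
   mask, described by min–max normalized metrics, are greedily agglomerated
   under a pixel-adjacency constraint using the Ward criterion

   Δ(i, j) = nᵢnⱼ/(nᵢ+nⱼ) · ‖μᵢ − μⱼ‖²,

   merging only adjacent clusters, so every parcel is spatially connected.
   Runs slice-wise (one clustering per level) or region-wise (one per
   aggregated region), at a fixed cluster count or a count sweep.
5. **Evaluation** — cluster↔tract overlap matrices drive color matching
   (each cluster inherits its best tract's hue; clusters sharing a tract
   get intensities in [0.2, 1] scaled by overlap), hemi-section renderings
   (clusters left, atlas right), per-tract recall, and Adjusted Rand Index
   against synthetic ground truth.

## Worked example

```python
from tractcluster import (ToyAtlasSpec, build_reference_atlas, cluster_stack,
                          default_signatures, sample_subject, tract_recalls)

atlas, wm = build_reference_atlas(ToyAtlasSpec(merge_lf_vf=True), "C4")
sample = sample_subject(atlas, default_signatures(),
                        noise_scale=1.0, deform_amplitude=1.5, seed=0)
parc, dendrogram = cluster_stack(sample.stack, n_clusters=8)
print(tract_recalls(parc, sample.truth))
```

Averaged over 20 such noisy realizations (`analysis/05_evaluate.py`), the
per-tract recall of each tract's best-matching cluster is:

```
tract  mean_recall    sd
 dCST        0.969 0.012
 PSdc        0.896 0.136
  LVF        0.889 0.109
   FG        0.863 0.171
 LatC        0.722 0.205
  LSp        0.670 0.221
  RST        0.605 0.196
   FC        0.592 0.210
```

The dorsal corticospinal tract (dCST) is recovered almost perfectly and
most stably — its axon density (168,800 axons/mm²) is far from every other
tract — while the fasciculus gracilis (FG) and the postsynaptic dorsal
column (PSdc), whose signatures overlap heavily, fused into a single
cluster in 16 of the 20 runs. On noise-free maps the clustering recovers
the contiguous tract regions exactly (ARI = 1).

## Analysis scripts

`analysis/01_simulate.py` … `05_evaluate.py` run the full study on
synthetic data (5 subjects × 31 levels): cohort generation, per-level
templates, region aggregation (4 regions × 5 metrics = 20 maps),
slice-wise + region-wise clustering at 8 clusters plus a 7–30 count sweep,
and evaluation with hemi-section renderings. Tables land in `results/`.

The same stages are available as a CLI:

```
tractcluster all --subjects 5 --seed 0 --n-clusters 8 --out pipeline_out
tractcluster cluster --mode region --sweep 8:31 --out pipeline_out
```

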