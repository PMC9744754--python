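# Methods

This note documents the models, parameters and numerical choices behind
`tractcluster`, and what the synthetic data do and do not establish.

## Synthetic cord model

**Geometry.** Each axial slice is built parametrically: an elliptical cord
outline, a gray-matter "butterfly" (central commissure + dorsal and
ventral horn ellipses), and nine tract regions tiling the white matter
with the topology of the standard rat atlas — dorsal column with the
fasciculus gracilis (FG) medial and superficial, the postsynaptic dorsal
column (PSdc) deep to it, the fasciculus cuneatus (FC) lateral, and the
dorsal corticospinal tract (dCST) at the column's base; small lateral
structures (LatC, LSp, RST); and the lateral/ventral funiculi (LF, VF)
filling the rest. All shapes are expressed in cord-normalized coordinates,
so one spec scales to any grid. Geometry uses |left–right coordinate|
throughout, so label maps are exactly mirror-symmetric. `merge_lf_vf`
collapses LF and VF into one ventrolateral label, giving the 8-tract
convention of the reference atlas. Cord size is modulated smoothly along
the rostro-caudal axis: a linear taper (35% from C1 to S4) plus Gaussian
bumps for the cervical and lumbar enlargements. Default grid: 64 × 64
pixels at 50 μm (3.2 mm across — a realistic rat cord footprint).

**Signatures.** Per-tract means and SDs for six metrics (axon density,
axon diameter, axon volume fraction, g-ratio, myelin thickness, myelin
volume fraction) live in `data/default_signatures.yaml`. Anchors are the
published template statistics: density from 78,000 axons/mm² (FG) to
168,800 (dCST); diameter 1.1 μm (dCST) to 1.35 μm (dorsal column, taken
as FG/PSdc/FC); myelin thickness spanning 0.35–0.5 μm; myelin volume
fraction spanning 15–30%; g-ratio approximately flat at 0.7. Tracts
without printed values are interpolated inside those ranges, preserving
the qualitative structure that matters for clustering: dCST far denser
than everything else, FG overlapping the funiculi. Interpolated entries
are a modelling choice, marked as such in the YAML. SDs are sized so
density distributions of neighboring tracts overlap strongly (SD
15,000–20,000 axons/mm²), as real per-tract violin plots do.

**Noise model.** Pixel values are truncated normals: mean = signature
mean, SD = signature SD × `noise_scale`, truncated at 0 (all metrics) and
at 1 (fractions, g-ratio) or 100 (percent). Truncation keeps values
physical; at the default parameters the bounds are > 4 SD from the means,
so tract means are effectively unbiased. Noise is white at the 50 μm map
resolution: the generator emulates the *downsampled metric maps*, not raw
microscopy. No spatially correlated artifacts (staining gradients,
segmentation failures, slice damage) are simulated — passing tests
demonstrate correct behavior of the pipeline under the stated statistical
model, not robustness to every failure mode of real histology.

**Deformations.** Inter-subject anatomical variability is a smooth random
displacement: white noise on a 6 × 6 control grid, cubic-spline upsampled,
rescaled to a peak magnitude (`deform_amplitude`, default 1.5 px). Small
amplitude relative to the control spacing keeps displacement gradients
≪ 1, hence invertibility. Labels are warped nearest-neighbor first and
metrics are then drawn from the warped labels, so ground truth and
metrics are exactly aligned and noise stays white.

**Determinism.** Every sample's seed derives from the master seed via
`numpy` seed-sequence spawning; identical seeds give bit-identical
cohorts and manifests.

## Registration

The engine is a deliberately compact 2D stand-in for the heavyweight
B-spline-regularized diffeomorphic registration used with real data; the
pipeline only relies on the contracts it honors (masked SSD never
increases; fields are smooth and composable).

* **Affine**: initialized from intensity centroids/second moments,
  refined by Powell on whole-image SSD (NaN treated as 0); falls back to
  identity if no improvement.
* **Nonrigid**: cubic B-spline free-form deformation (control spacing
  8 px, 3-level multiresolution pyramid), optimized by L-BFGS on masked
  SSD with an analytic gradient and a second-difference (Laplacian)
  penalty on control displacements (weight 0.5). Images are
  intensity-normalized first so the penalty weight is scale-invariant —
  without this, metric maps in axons/mm² would drown any regularizer. A
  global translation is estimated by phase correlation before the
  B-spline stage, because a free-form field gets no data force in
  texture-free interiors (aperture problem). A final check guarantees the
  returned field is never worse than the identity on masked SSD.
* **Fields** use the pull convention, `warped(x) = moving(x + v(x))`;
  composition samples the inner field at outer-displaced coordinates, so
  one resampling replaces a chain of warps. Warping is NaN-aware: values
  and a validity mask are interpolated separately and the result is
  re-masked at 50% validity, so undefined pixels neither bleed into nor
  erode the mask.
* **Chains**: within a region, each slice is registered to its neighbor
  on the reference side (the mid-slice; lower median index for even
  counts) and pairwise fields are composed outward. The opposite pairing
  convention is selectable (`chain_direction`), since either reading of
  "register r with r+1" is defensible.

## Template and aggregation

Per level, subjects are registered to the first subject's slice as the
provisional common space (the real common-space construction is
unspecified; with symmetrization the choice only shifts the template by a
subject-sized deformation). Metrics are averaged pixelwise over defined
values, symmetrized (average of image and mirror; a pixel defined on
either side is defined in the output, making symmetrize idempotent), and
the template mask keeps pixels covered by ≥ half the subjects — a union
rim would carry single-subject values.

Region aggregation warps one-hot tract channels with *linear*
interpolation (not nearest) before averaging along the
superior–inferior axis: the averages are then genuine partial volumes in
[0, 1] per tract.

## Clustering

Greedy agglomeration under a pixel-adjacency constraint (4-neighborhood
default; 8-neighborhood selectable — conservative spatial smoothness was
preferred where the choice was open). Merge costs are the Ward increase
in within-cluster variance, computed from maintained (count, feature-sum)
statistics; this is the same quantity the Lance–Williams Ward recurrence
propagates, but remains well-defined for cluster pairs that only become
adjacent mid-agglomeration (where the recurrence lacks one of its
inputs). Candidates live in a lazy-deletion binary heap keyed by
(cost, id_a, id_b); merged clusters receive fresh ids, so staleness is
detected by liveness, and cost ties break deterministically toward the
smallest id pair. Features are the five metrics min–max normalized over
masked pixels (constant metrics map to zero with a warning); a metric
subset is configurable (e.g. the density + volume-fraction two-metric
variant).

Disconnected masks are clustered per connected component, with the
cluster budget apportioned by pixel share (largest-remainder rounding,
at least one per component, never more clusters than pixels); an
auto-bridging alternative was considered and rejected as silently
changing the user's graph. If the component count exceeds the requested
count, the result has one cluster per component.

Correctness, not speed, is the contract: the implementation is validated
against a brute-force oracle that recomputes all pairwise costs at every
step, and cross-checked against an independent library implementation on
fully connected graphs.

## Evaluation

Overlap matrices count pixel co-occurrence (discrete references) or sum
partial volume (soft references). Matching is per-cluster argmax — several
clusters may share a tract, and a tract may go unmatched — mirroring how
parcellations actually behave. Intensity coding uses
`0.2 + 0.8 · (f / f_max)` where `f` is the fraction of the tract covered
by the cluster; the dominant cluster shows at full intensity. ARI is
computed over pixels labeled by both parcellation and reference. Because
connectivity-constrained clusters are necessarily contiguous while
bilateral tracts are not, exact-recovery scores compare against the
connected-component relabeling of the ground truth (`contiguous_truth`);
ARI against raw tract labels is also reported but cannot reach 1 on a
bilateral atlas.

## Problem sizes

Default study conditions: 5 subjects × 31 levels on 64 × 64 grids,
noise_scale 1.0, deform_amplitude 1.5 px. The full analysis chain
(155 simulated slices, 124 template registrations, 27 chained
region registrations, 35 clusterings + a 24-count sweep) runs in about
two minutes on one CPU; the test suite regenerates everything it needs at
the same grid scale or smaller.

## Known limitations

* The registration engine is small-deformation; it is not diffeomorphic
  and inverse fields are approximated by negation where requested.
* The toy atlas is a topological, not metric, stand-in for the digitized
  reference atlas; real tract shapes and their rostro-caudal migration
  are richer than the smooth scaling modelled here.
* Signatures are constant across levels (per-level variation is
  unreported for most tracts); level effects enter only through geometry.
* Region-wise clustering operates on the 2D superior–inferior average.
  Clustering the registered 3D stack with through-plane adjacency is a
  conceivable alternative but is not implemented: averaging first is the
  simpler model, and the two approaches only coincide for perfectly
  registered slices.
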