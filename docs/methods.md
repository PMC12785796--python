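# Methods

This note documents the models, conventions and parameter choices
behind `virotrace3d`, and what the synthetic tests do and do not show
about real microscopy data.

## Imaging model and coordinate conventions

All grids are indexed `(t, c, z, y, x)`. Channel order is fixed:
0 plasma-membrane/cytoplasmic marker, 1 labeled viral particles,
2 transgene eGFP, 3 nuclear DNA marker. Voxel spacing defaults to
(0.762, 0.0618, 0.0618) µm — 762 nm optical sections and 61.8 nm XY
pixels, the geometry of the super-resolution acquisitions the pipeline
targets; the ~12× Z/XY anisotropy is carried through every physical
distance. Coordinates in tables are 0-based voxel indices `(z, y, x)`;
distances are micrometres. Thresholds treat `value ≥ t` as foreground
for particle detection, while Otsu masks use `value > t`; both
conventions are fixed for reproducibility and stated at the function
level.

## Segmentation

Nuclei are found in two stages. A maximum-intensity projection of the
nuclear channel is instance-segmented in 2D; the default backend is
classical (Gaussian blur, Otsu threshold, distance-transform-seeded
watershed to split touching nuclei) so the package carries no trained
weights, and any callable `2D image → 2D labels` can be plugged in
instead (e.g. an external learned instance model). In 3D the channel
goes through local-mean downscaling, in-plane Gaussian blur (σ = 3),
Otsu thresholding, resizing back, and hole filling along z. "Along z"
is interpreted per (y, x) column: background runs bounded above and
below by foreground are filled; in-plane holes are untouched. The 3D
mask is fused with the planar labels by intersecting it with the label
footprint extruded along z and giving each 3D connected region the
planar label covering the majority of its voxels — the simplest fusion
that lets the planar instances carve the 3D mask. The 10,000-voxel
minimum instance volume is applied after fusion, on final 3D instances,
and mirrored onto cells (the filter's unit is acquisition-resolution
voxels; desk-scale profiles scale it, see below).

Cells reuse the same thresholding chain on the cytoplasmic marker and
are partitioned among nuclei by a watershed on the distance-to-nucleus
map restricted to the cell mask; mask islands unreachable from any
nucleus are dropped (cells without nuclei), and each cell is
union-expanded to contain its nucleus so that nucleus ⊆ cell holds by
construction — distance normalization requires it. The Otsu threshold
itself is computed by exhaustive maximization of the between-class
variance over the histogram (one bin per gray level for integer data,
256 equal-width bins otherwise, lowest maximizer on ties), so it is
bit-reproducible and directly checkable against a brute-force search.

## Tracking

Nucleus centroids are tracked on projected 2D coordinates — the same
plane the planar segmentation works in. Linking between consecutive
timepoints is an optimal minimum-total-displacement assignment
(Hungarian algorithm) with links forbidden beyond the 400-pixel search
range; an object missing for up to 3 consecutive timepoints (the
"memory") can re-link to its track, after which a new identity is
issued. Optimal assignment rather than greedy nearest-neighbour makes
linking deterministic and order-independent; remaining ties are broken
by processing detections in label order. Cells inherit the track id of
their nucleus; a cell claimed by two differently-tracked nuclei is
flagged multi-nucleated and excluded with a warning.

## Particle detection and measurement

Spot centroids are local maxima of the negated, scale-normalized
Laplacian-of-Gaussian response with per-axis scales (0.6, 1.3, 1.3)
voxels matched to a diffraction-limited spot on the anisotropic grid,
above a response floor of 100 intensity units. Segmentation is a seeded
watershed on inverted intensity restricted to the ≥ 600 super-level
set; seeds on sub-threshold voxels are dropped, and foreground
unreachable from any seed is discarded. Because super-level sets nest,
particle counts are non-increasing in the threshold — the property the
300–800 calibration sweep reports.

The nuclear ratio is a plain voxel-count ratio. The
particle-to-nucleus distance is measured from the particle *centroid*
(not its nearest surface voxel) to the nearest nucleus voxel centre in
anisotropic physical units, computed exactly via a KD-tree over nucleus
voxel coordinates, and forced to 0 whenever NR > 0 so the two
conventions agree on every boundary case used in classification.
`D_max` is the maximum of the nucleus distance transform over the
cell's voxels. `x = d/D_max` is clipped to [0, 1]; a degenerate cell
with `D_max = 0` yields 0 with a warning. These conventions are
isolated in one operation so they can be swapped.

## Classification and analysis

The four-way spatial classification partitions every consistent
(NR, x) pair; inconsistent inputs (NR > 0 with x > 0) are a validation
error, not a silent class. "Nuclear" particles in fractions and
distribution tables are inside + boundary particles; a switch restricts
per-nucleus counts to strictly-inside particles, since count-based
figures can reasonably use either definition. Expression categories use
the 50th/75th percentiles (linear interpolation between order
statistics) of per-cell mean eGFP intensity pooled over all cells and
timepoints of one condition, with boundary assignment `≤ p50 → non`,
`≤ p75 → low`, `> p75 → high`; longitudinal grouping uses the category
observed at the final timepoint. Cells with zero particles carry a
flagged nuclear fraction of 0 and are excluded from fraction plots by
default (configurable). No multiple-testing correction is applied;
comparisons are pairwise two-tailed Mann–Whitney U tests at α = 0.05.
The exact branch enumerates all rank allocations when n₁+n₂ ≤ 16 and
the pooled sample is tie-free; the asymptotic branch uses the normal
approximation with tie and continuity corrections plus a one-term
Edgeworth (kurtosis) refinement, which keeps the two branches within
|Δp| ≤ 0.001 at n = 8+8 instead of ~0.011 for the plain normal.

## Synthetic data generator

The generator renders what the pipeline assumes about the specimen, not
real morphology: randomly oriented convex cells (ellipses extruded
through most of the z-range — a columnar adherent-cell approximation),
one thin ellipsoidal nucleus each, Gaussian particle spots of
diffraction-limited size, per-channel Gaussian blur, Poisson photon
noise (variance = mean / gain) plus Gaussian read noise, a rigid
integer-voxel drift per timepoint, and 8/16-bit quantization. Output
defaults to 16 bits with spot amplitude 1500 over background 100 so the
calibrated 300–800 detection thresholds are meaningful on an intensity
scale of the kind produced by post-processed super-resolution exports;
the raw acquisitions' own scale is instrument-specific, so these units
are conventional.

Placement guarantees classes by construction: a particle's ground-truth
footprint is the voxel set its rendered intensity pushes to ≥ the
detection threshold, and candidate positions per class are derived from
that footprint and from the *same* distance code the measurement module
uses, then verified by actually measuring the rasterized footprint.
This removes simulator/measurer disagreement as a failure mode. Two
geometric consequences are worth noting. First, at 61.8 nm XY pixels a
one-voxel centre-to-centre step costs 0.0618 µm, so the perinuclear
shell (x ≤ 0.01 AU) contains whole voxels only when `D_max ≳ 12.4` µm —
hence the tall columnar cells; a geometry that cannot host a requested
class raises an explicit placement error rather than mislabeling.
Second, cytosolic spots keep a ~2-voxel margin off the plasma membrane
so their ownership and class survive sub-voxel segmentation jitter.
Cell placement anneals the sampled radius downwards over retries so
crowded layouts still resolve; truly infeasible requests exhaust the
bounded retry budget and raise.

What the synthetic fields do **not** emulate: real point-spread
functions or detector artifacts, photobleaching, cell migration beyond
rigid drift, mitosis/apoptosis (the workflow excludes such cells by
manual curation), nucleus texture, autofluorescence, or particle
motion between timepoints (particles ride the rigid drift). Passing the
recovery tests therefore demonstrates that the pipeline's geometry,
bookkeeping and statistics are correct under the stated imaging model —
not that segmentation or detection will reach the same accuracy on real
acquisitions.

## Problem sizes and profiles

The paper-scale defaults (min instance volume 10,000 voxels, downscale
factor 4, planar seed separation 10 px, search range 400 px) suit
3428 × 3428 × 40 acquisitions. Synthetic desk-scale fields are
128–160 px wide, ~27× smaller linearly, so `SegmentationParams.desk_scale()`
/ `PipelineConfig.desk_scale()` provide a profile scaled accordingly
(downscale 1, blur σ 1, minimum volumes 500, seed separation 8); the
acceptance experiments use a 40 × 128 × 128 field with 3 cells and 60
particles per timepoint over 3 timepoints, which runs in seconds.

## Known limitations

* Tracking is 2D (projected centroids) and not mitosis-aware; dividing
  cells must be excluded via the curation list.
* The distance convention is centroid-based; surface-based distances
  would differ for large particles far from the nucleus (identical on
  all classification boundary cases, where distances are 0).
* The planar/3D mask fusion assigns each 3D component to one planar
  instance by majority; nuclei merged in the projection but separated
  in z are not split.
* OME-TIFF support covers TCZYX stacks with physical pixel sizes;
  vendor container formats must be converted upstream.
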