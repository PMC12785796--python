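# virotrace3d

Automated 3D live-cell quantification of fluorescently labeled viral
particle trafficking in cultured cells.

Gene-therapy vectors such as recombinant adeno-associated virus (rAAV)
must travel from the plasma membrane through the cytoplasm and into the
nucleus before their cargo can be expressed. Time-lapse confocal imaging
of dye-labeled capsids in live cells produces multi-channel 3D stacks in
which that journey can be measured — but only with an automated pipeline
that segments every cell and nucleus, keeps their identities over time,
detects each diffraction-limited particle in 3D, and turns positions
into biologically meaningful coordinates. `virotrace3d` implements that
pipeline end to end, together with a synthetic-field generator that
makes every stage verifiable against exact ground truth.

## What it computes

For each detected particle the package measures two unit-free
quantities against the owning cell's nucleus:

* **Nuclear ratio** `NR = |P ∩ N| / |P|` — the fraction of the
  particle's voxel volume `P` inside the nucleus mask `N`.
* **Normalized distance** `x = d(centroid, N) / D_max ∈ [0, 1]` AU,
  where `d` is the anisotropic Euclidean distance (µm) to the nearest
  nucleus voxel (0 whenever `NR > 0`) and `D_max` is the maximum
  nucleus-to-membrane distance within the same cell.

Each particle then receives exactly one spatial class:

| class | NR | x (AU) |
|---|---|---|
| inside nucleus | NR = 1 | x = 0 |
| nuclear membrane boundary | 0 < NR < 1 | x = 0 |
| perinuclear | NR = 0 | 0 ≤ x ≤ 0.01 |
| cytoplasmic | NR = 0 | 0.01 < x ≤ 1 |

Per cell and timepoint the pipeline aggregates particle counts per
class, the nuclear particle fraction (inside + boundary over total),
cell/nucleus volumes and mean transgene (eGFP) intensity; cells are
categorized non/low/high-expressing by the 50th/75th percentiles of
intensity pooled within a condition. Group comparisons use the
two-tailed Mann–Whitney U test (exact enumeration for small tie-free
samples, Edgeworth-refined normal approximation otherwise), and
trafficking is summarized by cumulative-fraction curves of `x` and by
condition × timepoint distribution tables.

## Pipeline stages

1. **Segmentation** — nuclei from a maximum-intensity projection
   (classical blur/Otsu/seeded-watershed instance backend, pluggable)
   fused with a 3D downscale → blur → Otsu → resize → z-hole-fill mask;
   cells from the cytoplasmic marker channel, partitioned among their
   nuclei; instances below 10,000 voxels are dropped (default).
2. **Tracking** — optimal-assignment linking of nucleus centroids with
   a 400-pixel search range and a gap memory of 3 timepoints; cells
   inherit their nucleus's track identity.
3. **Particle detection** — Laplacian-of-Gaussian centroids, then a
   seeded watershed on the ≥ 600 intensity super-level set (threshold
   calibrated by a 300–800 sweep on control samples).
4. **Measurement & analysis** — NR, distances, classes, per-cell
   aggregates, expression categories, cumulative curves, statistics.

## Worked example

Simulate a small field and quantify it:

```bash
virotrace3d simulate --config sim.yaml --seed 3 --out demo/sim
virotrace3d run --in demo/sim/stack.ome.tiff --out demo/out --no-qc
```

or directly from Python:

```python
from virotrace3d import SimulationConfig, generate_timelapse
from virotrace3d import PipelineConfig, run_pipeline

config = SimulationConfig(grid_shape=(40, 128, 128), n_cells=3,
                          n_timepoints=3, seed=7).high_snr()
stack, truth = generate_timelapse(config)
result = run_pipeline(stack, PipelineConfig.desk_scale())
print(result["particles"]["spatial_class"].value_counts())
```

With the default 4/2/1/13 particles per class in each of 3 cells over
3 timepoints this prints:

```
spatial_class
cytoplasmic         117
inside_nucleus       36
nuclear_boundary     18
perinuclear           9
```

i.e. the pipeline recovers every ground-truth particle (60 per
timepoint) in its intended class: 65 % cytoplasmic, 20 % inside the
nucleus, 10 % at the nuclear boundary, 5 % perinuclear, giving a mean
per-cell nuclear fraction of 0.30.

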